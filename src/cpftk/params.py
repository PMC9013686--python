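"""Default parameter tables for the chlorpyrifos (CPF) toxicokinetic models.

Everything a scenario needs is collected here as plain data: apparent
Michaelis-Menten kinetics per enzyme source, CYP abundances and phenotype
frequencies, intersystem extrapolation factors (ISEFs), physiological
constants of the adult Caucasian reference individual, and the coefficients
of variation used by the population Monte Carlo.  All values can be
overridden through the YAML scenario configuration (see :mod:`cpftk.workbench`).

Units follow the conventions used throughout the package:

* apparent Vmax  - pmol/min/pmol CYP (recombinant CYP), nmol/min/mg
  microsomal protein (liver microsomes), nmol/min/ml plasma (plasma PON1)
* Km             - uM
* scaled Vmax    - umol/h (whole liver or whole plasma)
* flows          - L/h, volumes - L, body weight - kg
"""

from __future__ import annotations

from dataclasses import dataclass, field

# ---------------------------------------------------------------------------
# Molecular weights (g/mol)
# ---------------------------------------------------------------------------
MW_CPF = 350.59   # chlorpyrifos
MW_CPO = 334.52   # chlorpyrifos-oxon
MW_TCPY = 198.43  # 3,5,6-trichloro-2-pyridinol

# ---------------------------------------------------------------------------
# Liver scaling constants
# ---------------------------------------------------------------------------
MPL = 32.0        # microsomal protein yield, mg/g liver
VLC = 0.0257      # liver volume as fraction of body weight (kg/kg)
VBC = 0.0753      # blood volume fraction; gives VB 5.27 L at BW 70
PLASMA_FRACTION_OF_BLOOD = 0.55

BW_DEFAULT = 70.0  # kg


@dataclass(frozen=True)
class ApparentMM:
    """Apparent Michaelis-Menten parameters for one enzyme source/pathway."""

    vmax_app: float
    km_app: float

    @property
    def ce_app(self) -> float:
        return self.vmax_app / self.km_app


# ---------------------------------------------------------------------------
# Recombinant CYP (Supersome) apparent kinetics of CPF conversion.
# Pathway 1 = bioactivation CPF -> CPO, pathway 2 = detox CPF -> TCPy.
# Vmax in pmol/min/pmol CYP, Km in uM.
# ---------------------------------------------------------------------------
SUPERSOME_PATHWAY1 = {
    "CYP1A2": ApparentMM(3.96, 0.61),
    "CYP2B6": ApparentMM(7.76, 0.14),
    "CYP2C19": ApparentMM(2.74, 1.89),
    "CYP3A4": ApparentMM(17.78, 29.77),
}
SUPERSOME_PATHWAY2 = {
    "CYP1A2": ApparentMM(2.96, 1.25),
    "CYP2B6": ApparentMM(5.49, 1.28),
    "CYP2C19": ApparentMM(17.51, 1.37),
    "CYP3A4": ApparentMM(23.86, 18.13),
}

# Mean CYP abundance in human liver microsomes, pmol CYP/mg protein,
# used for ISEF derivation and for scaling the reference individual.
CYP_ABUNDANCE = {"CYP1A2": 52.0, "CYP2B6": 15.8, "CYP2C19": 5.4, "CYP3A4": 137.0}

# Probe-substrate Vmax pairs behind the ISEF determination.
# (pooled HLM nmol/min/mg, Supersome pmol/min/pmol CYP)
PROBE_VMAX = {
    "CYP1A2": ("phenacetin", 0.15, 39.06),
    "CYP2B6": ("bupropion", 0.31, 40.77),
    "CYP2C19": ("(S)-mephenytoin", 0.02, 20.59),
    "CYP3A4": ("testosterone", 17.29, 1179.0),
}

# ISEFs as adopted for scaling.  The 2C19 value is not exactly recoverable
# from the rounded probe Vmax values above, so the adopted set is carried
# explicitly; recomputation from PROBE_VMAX is available in
# :func:`cpftk.kinetics.compute_isef`.
ISEF = {"CYP1A2": 0.07, "CYP2B6": 0.48, "CYP2C19": 0.21, "CYP3A4": 0.11}

# ---------------------------------------------------------------------------
# Pooled-HLM kinetics (HLM-based model).
# Pathway 1 biphasic: high-affinity phase (low Km, 0.02-10 uM design) and
# low-affinity phase (3-100 uM design).  Vmax nmol/min/mg, Km uM.
# ---------------------------------------------------------------------------
HLM_PATHWAY1_HIGH = ApparentMM(0.275, 0.270)
HLM_PATHWAY1_LOW = ApparentMM(0.353, 29.8)
HLM_PATHWAY2 = ApparentMM(0.653, 12.0)

# Pathway 3: hepatic PON1-mediated CPO -> TCPy (pooled HLM, nmol/min/mg).
HLM_PATHWAY3 = ApparentMM(37.98, 627.9)

# Pathway 4: plasma PON1-mediated CPO -> TCPy; mean of the 25-individual
# plasma panel, nmol/min/ml plasma.
PLASMA_PATHWAY4 = ApparentMM(1844.0, 290.0)

# ---------------------------------------------------------------------------
# Phenotype table for the Monte Carlo (abundance mean pmol/mg, CV,
# population frequency).  CYPs with a single known phenotype carry EM only.
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class PhenotypeEntry:
    cyp: str
    phenotype: str  # EM / PM / UM
    abundance: float
    cv: float
    frequency: float


PHENOTYPE_TABLE = (
    PhenotypeEntry("CYP1A2", "EM", 52.0, 0.67, 1.000),
    PhenotypeEntry("CYP2B6", "EM", 17.0, 1.22, 0.890),
    PhenotypeEntry("CYP2B6", "PM", 6.0, 2.00, 0.110),
    PhenotypeEntry("CYP2C19", "EM", 4.4, 0.71, 0.590),
    PhenotypeEntry("CYP2C19", "PM", 0.0, 0.00, 0.092),
    PhenotypeEntry("CYP2C19", "UM", 8.7, 0.71, 0.318),
    PhenotypeEntry("CYP3A4", "EM", 137.0, 0.41, 1.000),
)

# CVs on pooled-HLM kinetic parameters (individual-HLM panel, n=30).
CV_PATHWAY3 = {"vmax": 0.57, "km": 0.39}
CV_PATHWAY4 = {"vmax": 0.29, "km": 0.33}
CV_HLM_PATHWAY1 = {"vmax": 0.59, "km": 0.61}
CV_HLM_PATHWAY2 = {"vmax": 0.53, "km": 0.89}

# ---------------------------------------------------------------------------
# Other influential parameters (mean, CV) for the extended Monte Carlo scope.
# fa is the mean of the two reported human oral absorption fractions.
# ---------------------------------------------------------------------------
FA_REPORTED = (0.224, 0.7)
FA_DEFAULT = sum(FA_REPORTED) / len(FA_REPORTED)  # 0.462
KA_DEFAULT = 0.46        # 1/h
FU_CPO_PLASMA = 0.15     # unbound fraction of CPO in plasma
BP_CPO = 2.7             # CPO blood:plasma concentration ratio
BP_CPF = 1.3             # CPF blood:plasma concentration ratio

INFLUENTIAL_CV = {
    "bw": 0.3,
    "ka": 0.3,
    "fa": 0.73,   # upper truncation capped at fa = 1
    "mpl": 0.46,
    "fu_cpo_plasma": 0.3,
    "bp_cpo": 0.3,  # sampled correlated with fu_cpo_plasma
}

# ---------------------------------------------------------------------------
# Reference physiology (adult Caucasian).  Flow fractions sum to 1;
# volume fractions sum to < 1 (remainder = non-perfused carcass).
# Cardiac output follows the allometric QC = QCC * BW^0.74.
# ---------------------------------------------------------------------------
PHYSIOLOGY_DEFAULTS = dict(
    bw=BW_DEFAULT,
    vlc=VLC,       # liver
    vbc=VBC,       # blood
    vfc=0.21,      # fat
    vrc=0.05,      # richly perfused (kidney, viscera, brain)
    vsc=0.55,      # slowly perfused (muscle, skin, bone)
    qcc=15.0,      # cardiac output allometric coefficient, L/h/kg^0.74
    qlc=0.25,      # fraction of cardiac output to liver
    qrc=0.26,      # to richly perfused tissue
    qfc=0.05,      # to fat
    qsc=0.44,      # to slowly perfused tissue
    mpl=MPL,
    ka=KA_DEFAULT,
    fa=FA_DEFAULT,
    ke_tcpy=0.03,  # 1/h first-order urinary elimination of TCPy
)

# logP values used by the tissue-composition partition algorithm.
LOGP_CPF = 4.784
LOGP_CPO = 3.89

# Tissue composition (volume fractions of neutral lipid, phospholipid,
# water) used by the Poulin-Krishnan style partition estimate.
TISSUE_COMPOSITION = {
    # tissue: (neutral lipid, phospholipid, water)
    "blood": (0.0033, 0.0024, 0.82),
    "liver": (0.035, 0.025, 0.745),
    "fat": (0.798, 0.002, 0.15),
    "rich": (0.020, 0.020, 0.78),
    "slow": (0.035, 0.007, 0.76),
}


def partition_coefficient(logp: float, tissue: str) -> float:
    """Tissue:blood partition coefficient from logP and tissue composition.

    A lipid-fraction weighted octanol:water surrogate: neutral lipid plus
    30% of phospholipid partitions like octanol, water plus 70% of
    phospholipid like water.  Adequate for a flow-limited model of the two
    highly lipophilic species handled here; override via config if measured
    values are available.
    """
    kow = 10.0 ** logp
    nl_t, ph_t, w_t = TISSUE_COMPOSITION[tissue]
    nl_b, ph_b, w_b = TISSUE_COMPOSITION["blood"]
    num = kow * (nl_t + 0.3 * ph_t) + (w_t + 0.7 * ph_t)
    den = kow * (nl_b + 0.3 * ph_b) + (w_b + 0.7 * ph_b)
    return num / den


def default_partitions() -> dict:
    """CPF and CPO tissue:blood partition coefficients."""
    return {
        "cpf": {t: partition_coefficient(LOGP_CPF, t) for t in ("liver", "fat", "rich", "slow")},
        "cpo": {t: partition_coefficient(LOGP_CPO, t) for t in ("liver", "rich")},
    }


# In vitro concentration designs (uM for incubations, nM for the AChE assay)
INCUBATION_DESIGNS = {
    "CYP1A2": (0.05, 0.1, 0.25, 0.5, 1, 5, 10),
    "CYP2B6": (0.05, 0.1, 0.25, 0.5, 1, 5, 10, 25),
    "CYP2C19": (1, 2.5, 5, 10, 25, 50),
    "CYP3A4": (0.5, 1, 2.5, 5, 10, 25, 50),
    "plasma": (10, 50, 100, 250, 500, 1000),
}
ACHE_DESIGN_NM = (0.05, 0.1, 0.5, 1, 2.5, 5, 10, 25, 50)
IC50_CPO_NM = 1.89  # rhAChE inhibition midpoint used as generator truth
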