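"""Physiologically based kinetic (PBK) model of oral chlorpyrifos (CPF)
exposure in the adult human.

Structure
---------
CPF is absorbed from the gut lumen by a first-order process (rate ``ka``,
fraction absorbed ``fa``; the remainder leaves in faeces) into the liver
and distributes flow-limited over liver, fat, richly and slowly perfused
tissue and blood.  In the liver CPF is bioactivated to chlorpyrifos-oxon
(CPO, pathway 1) and detoxified to TCPy (pathway 2) by CYPs; CPO is
hydrolysed to TCPy by hepatic PON1 (pathway 3) and, in the blood
compartment, by plasma PON1 (pathway 4).  TCPy is collected in a single
body compartment with first-order urinary elimination.  All metabolic
rates are Michaelis-Menten in the liver-venous (pathways 1-3) or blood
(pathway 4) concentration of their substrate.

The liver CYP description is selectable: a four-isoform sum of
recombinant-CYP kinetics scaled through ISEFs (``supersome``), a
two-phase high/low-affinity microsomal description (``hlm_biphasic``) or
a single low-affinity Michaelis-Menten term (``hlm_nonbiphasic``, kept
only to demonstrate the consequences of missing the high-affinity phase).

State vector (amounts, umol): gut lumen, faeces, CPF in liver/fat/richly
perfused/slowly perfused/blood, CPO in liver/blood/rest-of-body, TCPy in
body, TCPy in urine.  The sum of all states equals the administered dose
at all times (molar 1:1 stoichiometry along every pathway), which is the
mass-balance invariant checked on every simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint

from . import params as P
from .kinetics import scale_hlm_vmax, scale_plasma_vmax, scale_supersome_vmax

__all__ = [
    "PhysiologyParams",
    "PartitioningParams",
    "LiverKineticModel",
    "Scenario",
    "SimulationResult",
    "SimulationError",
    "pathway1_rate",
    "pathway_rate_mm",
    "simulate",
    "dose_to_cmax_curve",
    "sensitivity_analysis",
]


class SimulationError(RuntimeError):
    """ODE integration failed; message carries solver diagnostics."""


@dataclass(frozen=True)
class PhysiologyParams:
    """Reference physiology.  Volumes in L (derived from fractions of body
    weight), flows in L/h; ``qc = qcc * bw**0.74``."""

    bw: float = P.BW_DEFAULT
    vlc: float = P.PHYSIOLOGY_DEFAULTS["vlc"]
    vbc: float = P.PHYSIOLOGY_DEFAULTS["vbc"]
    vfc: float = P.PHYSIOLOGY_DEFAULTS["vfc"]
    vrc: float = P.PHYSIOLOGY_DEFAULTS["vrc"]
    vsc: float = P.PHYSIOLOGY_DEFAULTS["vsc"]
    qcc: float = P.PHYSIOLOGY_DEFAULTS["qcc"]
    qlc: float = P.PHYSIOLOGY_DEFAULTS["qlc"]
    qrc: float = P.PHYSIOLOGY_DEFAULTS["qrc"]
    qfc: float = P.PHYSIOLOGY_DEFAULTS["qfc"]
    qsc: float = P.PHYSIOLOGY_DEFAULTS["qsc"]
    mpl: float = P.MPL
    ka: float = P.KA_DEFAULT
    fa: float = P.FA_DEFAULT
    ke_tcpy: float = P.PHYSIOLOGY_DEFAULTS["ke_tcpy"]

    def __post_init__(self):
        fracs = (self.vlc, self.vbc, self.vfc, self.vrc, self.vsc)
        if any(not 0 < f < 1 for f in fracs):
            raise ValueError("tissue volume fractions must lie in (0, 1)")
        if sum(fracs) >= 1.0:
            raise ValueError("tissue volume fractions must sum to < 1")
        if abs(self.qlc + self.qrc + self.qfc + self.qsc - 1.0) > 1e-9:
            raise ValueError("flow fractions must sum to 1")
        if not 0 < self.fa <= 1.0:
            raise ValueError("fa must lie in (0, 1]")

    # derived quantities -------------------------------------------------
    @property
    def vl(self) -> float:
        return self.vlc * self.bw

    @property
    def vb(self) -> float:
        return self.vbc * self.bw

    @property
    def qc(self) -> float:
        return self.qcc * self.bw ** 0.74


@dataclass(frozen=True)
class PartitioningParams:
    """Protein binding and tissue partitioning of CPF and CPO.

    ``fu_cpo_blood`` is derived as fu(plasma)/BP; ``partitions`` maps
    species -> tissue -> tissue:blood coefficient.
    """

    fu_cpo_plasma: float = P.FU_CPO_PLASMA
    bp_cpo: float = P.BP_CPO
    bp_cpf: float = P.BP_CPF
    partitions: dict = field(default_factory=P.default_partitions)

    def __post_init__(self):
        if not 0 < self.fu_cpo_plasma <= 1:
            raise ValueError("fu_cpo_plasma must lie in (0, 1]")
        if self.bp_cpo <= 0 or self.bp_cpf <= 0:
            raise ValueError("blood:plasma ratios must be positive")

    @property
    def fu_cpo_blood(self) -> float:
        return self.fu_cpo_plasma / self.bp_cpo


@dataclass(frozen=True)
class LiverKineticModel:
    """In vivo rate laws for the four metabolic pathways.

    ``pathway1_terms``/``pathway2_terms`` are tuples of (Vmax umol/h,
    Km uM) Michaelis-Menten terms summed at the same substrate
    concentration; pathways 3 and 4 are single terms.
    """

    mode: str  # supersome | hlm_biphasic | hlm_nonbiphasic
    pathway1_terms: tuple
    pathway2_terms: tuple
    pathway3: tuple
    pathway4: tuple
    pathway4_on_unbound: bool = False

    def __post_init__(self):
        for vmax, km in (*self.pathway1_terms, *self.pathway2_terms,
                         self.pathway3, self.pathway4):
            if vmax < 0 or km <= 0:
                raise ValueError("Vmax must be >= 0 and Km > 0")


def pathway_rate_mm(s: float, vmax: float, km: float) -> float:
    """Single Michaelis-Menten rate, umol/h at substrate s (uM)."""
    if s < 0:
        raise ValueError("substrate concentration must be nonnegative")
    return vmax * s / (km + s)


def pathway1_rate(s: float, model: LiverKineticModel) -> float:
    """Total CPF bioactivation rate (umol/h): sum of the mode's terms."""
    if s < 0:
        raise ValueError("substrate concentration must be nonnegative")
    return sum(vmax * s / (km + s) for vmax, km in model.pathway1_terms)


# ---------------------------------------------------------------------------
# Scenario: everything needed to assemble a parameterized model, kept at the
# level of apparent in vitro values so that per-draw resampling (Monte Carlo)
# and one-at-a-time perturbation (sensitivity) rebuild the scaled model
# consistently, e.g. body weight moving liver and blood volume together.
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class Scenario:
    mode: str = "supersome"
    bw: float = P.BW_DEFAULT
    ka: float = P.KA_DEFAULT
    fa: float = P.FA_DEFAULT
    mpl: float = P.MPL
    fu_cpo_plasma: float = P.FU_CPO_PLASMA
    bp_cpo: float = P.BP_CPO
    # supersome route: per-CYP abundance, ISEF and apparent kinetics
    abundance: dict = field(default_factory=lambda: dict(P.CYP_ABUNDANCE))
    isef: dict = field(default_factory=lambda: dict(P.ISEF))
    supersome_p1: dict = field(
        default_factory=lambda: {k: (v.vmax_app, v.km_app) for k, v in P.SUPERSOME_PATHWAY1.items()}
    )
    supersome_p2: dict = field(
        default_factory=lambda: {k: (v.vmax_app, v.km_app) for k, v in P.SUPERSOME_PATHWAY2.items()}
    )
    # microsomal route
    hlm_p1_high: tuple = (P.HLM_PATHWAY1_HIGH.vmax_app, P.HLM_PATHWAY1_HIGH.km_app)
    hlm_p1_low: tuple = (P.HLM_PATHWAY1_LOW.vmax_app, P.HLM_PATHWAY1_LOW.km_app)
    hlm_p2: tuple = (P.HLM_PATHWAY2.vmax_app, P.HLM_PATHWAY2.km_app)
    # PON1 pathways (apparent)
    p3: tuple = (P.HLM_PATHWAY3.vmax_app, P.HLM_PATHWAY3.km_app)
    p4: tuple = (P.PLASMA_PATHWAY4.vmax_app, P.PLASMA_PATHWAY4.km_app)
    pathway4_on_unbound: bool = False
    physiology_overrides: dict = field(default_factory=dict)
    partition_overrides: dict = field(default_factory=dict)

    def with_(self, **kw) -> "Scenario":
        return replace(self, **kw)

    def physiology(self) -> PhysiologyParams:
        return PhysiologyParams(
            bw=self.bw, ka=self.ka, fa=self.fa, mpl=self.mpl,
            **self.physiology_overrides,
        )

    def partitioning(self) -> PartitioningParams:
        parts = P.default_partitions()
        for sp, d in self.partition_overrides.items():
            parts[sp].update(d)
        return PartitioningParams(
            fu_cpo_plasma=self.fu_cpo_plasma, bp_cpo=self.bp_cpo, partitions=parts
        )

    def liver_model(self) -> LiverKineticModel:
        phys = self.physiology()
        vl, vb, mpl = phys.vl, phys.vb, phys.mpl
        if self.mode == "supersome":
            p1 = tuple(
                (scale_supersome_vmax(v, self.abundance[c], self.isef[c], mpl, vl), km)
                for c, (v, km) in self.supersome_p1.items()
            )
            p2 = tuple(
                (scale_supersome_vmax(v, self.abundance[c], self.isef[c], mpl, vl), km)
                for c, (v, km) in self.supersome_p2.items()
            )
        elif self.mode == "hlm_biphasic":
            p1 = (
                (scale_hlm_vmax(self.hlm_p1_high[0], mpl, vl), self.hlm_p1_high[1]),
                (scale_hlm_vmax(self.hlm_p1_low[0], mpl, vl), self.hlm_p1_low[1]),
            )
            p2 = ((scale_hlm_vmax(self.hlm_p2[0], mpl, vl), self.hlm_p2[1]),)
        elif self.mode == "hlm_nonbiphasic":
            p1 = ((scale_hlm_vmax(self.hlm_p1_low[0], mpl, vl), self.hlm_p1_low[1]),)
            p2 = ((scale_hlm_vmax(self.hlm_p2[0], mpl, vl), self.hlm_p2[1]),)
        else:
            raise ValueError(f"unknown liver kinetic mode {self.mode!r}")
        return LiverKineticModel(
            mode=self.mode,
            pathway1_terms=p1,
            pathway2_terms=p2,
            pathway3=(scale_hlm_vmax(self.p3[0], mpl, vl), self.p3[1]),
            pathway4=(scale_plasma_vmax(self.p4[0], vb), self.p4[1]),
            pathway4_on_unbound=self.pathway4_on_unbound,
        )

    def assemble(self):
        return self.physiology(), self.partitioning(), self.liver_model()


# ---------------------------------------------------------------------------
# ODE right-hand side.  Written over scalars/small arrays for speed: the
# Monte Carlo solves this system tens of thousands of times.
# ---------------------------------------------------------------------------
N_STATES = 12
(GI, FECES, L_CPF, F_CPF, R_CPF, S_CPF, B_CPF,
 L_CPO, B_CPO, REST_CPO, TCPY, URINE) = range(N_STATES)


def _pack(phys: PhysiologyParams, part: PartitioningParams, model: LiverKineticModel):
    qc = phys.qc
    ql, qf, qr, qs = phys.qlc * qc, phys.qfc * qc, phys.qrc * qc, phys.qsc * qc
    bw = phys.bw
    pc_f, pc_o = part.partitions["cpf"], part.partitions["cpo"]
    v1 = np.array([t[0] for t in model.pathway1_terms])
    k1 = np.array([t[1] for t in model.pathway1_terms])
    v2 = np.array([t[0] for t in model.pathway2_terms])
    k2 = np.array([t[1] for t in model.pathway2_terms])
    v_rest = (phys.vfc + phys.vrc + phys.vsc) * bw
    fu_b = part.fu_cpo_blood if model.pathway4_on_unbound else 1.0
    return (
        phys.ka * phys.fa,               # absorption flux coefficient
        phys.ka * (1.0 - phys.fa),       # fecal flux coefficient
        ql, qf, qr, qs, qc,
        phys.vb,
        phys.vl * pc_f["liver"], phys.vfc * bw * pc_f["fat"],
        phys.vrc * bw * pc_f["rich"], phys.vsc * bw * pc_f["slow"],
        phys.vl * pc_o["liver"], v_rest * pc_o["rich"], qc - ql,
        v1, k1, v2, k2,
        model.pathway3[0], model.pathway3[1],
        model.pathway4[0], model.pathway4[1],
        phys.ke_tcpy, fu_b,
    )


def _rhs(y, t, c):
    (kafa, kawaste, ql, qf, qr, qs, qc, vb,
     vlpl, vfpf, vrpr, vsps, vlplo, vrestpro, qrest,
     v1, k1, v2, k2, v3max, k3, v4max, k4, ke, fu4) = c

    cb = y[B_CPF] / vb
    cvl = y[L_CPF] / vlpl
    cvf = y[F_CPF] / vfpf
    cvr = y[R_CPF] / vrpr
    cvs = y[S_CPF] / vsps

    rate1 = float(np.sum(v1 * cvl / (k1 + cvl)))
    rate2 = float(np.sum(v2 * cvl / (k2 + cvl)))

    cvlo = y[L_CPO] / vlplo
    cbo = y[B_CPO] / vb
    cvro = y[REST_CPO] / vrestpro
    rate3 = v3max * cvlo / (k3 + cvlo)
    s4 = cbo * fu4
    rate4 = v4max * s4 / (k4 + s4)

    absorb = kafa * y[GI]
    dy = np.empty(N_STATES)
    dy[GI] = -(kafa + kawaste) * y[GI]
    dy[FECES] = kawaste * y[GI]
    dy[L_CPF] = ql * (cb - cvl) + absorb - rate1 - rate2
    dy[F_CPF] = qf * (cb - cvf)
    dy[R_CPF] = qr * (cb - cvr)
    dy[S_CPF] = qs * (cb - cvs)
    dy[B_CPF] = ql * cvl + qf * cvf + qr * cvr + qs * cvs - qc * cb
    dy[L_CPO] = rate1 - rate3 + ql * (cbo - cvlo)
    dy[B_CPO] = ql * cvlo + qrest * cvro - qc * cbo - rate4
    dy[REST_CPO] = qrest * (cbo - cvro)
    dy[TCPY] = rate2 + rate3 + rate4 - ke * y[TCPY]
    dy[URINE] = ke * y[TCPY]
    return dy


@dataclass(frozen=True)
class SimulationResult:
    time: np.ndarray                  # h
    amounts: np.ndarray               # (n_times, 12) umol
    dose_umol: float
    fu_cpo_blood: float
    vb: float
    cmax_cpo_total: float             # uM, total CPO in blood
    tmax_cpo: float                   # h
    cmax_tcpy: float                  # uM (blood, nominal TCPy space)
    mass_balance_residual: float      # max relative deviation from dose

    @property
    def cmax_cpo_free(self) -> float:
        return self.cmax_cpo_total * self.fu_cpo_blood

    def concentration(self, state: int) -> np.ndarray:
        """Blood concentration trace (uM) for a blood-resident state."""
        return self.amounts[:, state] / self.vb


def _refine_max(t, y):
    """Parabolic refinement of the maximum of a sampled curve."""
    i = int(np.argmax(y))
    if i == 0 or i == len(y) - 1:
        return float(t[i]), float(y[i])
    t0, t1, t2 = t[i - 1], t[i], t[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (y0 - 2 * y1 + y2)
    if denom >= 0:
        return float(t1), float(y1)
    dt = 0.5 * (y0 - y2) / denom * (t2 - t0) / 2.0
    tm = t1 + dt
    # quadratic value at the vertex
    ym = y1 - 0.25 * (y0 - y2) * dt / ((t2 - t0) / 2.0)
    return float(tm), float(max(ym, y1))


def simulate(
    dose_mg_per_kg: float,
    phys: PhysiologyParams,
    part: PartitioningParams,
    model: LiverKineticModel,
    duration: float = 24.0,
    n_out: int = 241,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> SimulationResult:
    """Integrate the PBK model for a single oral dose (mg/kg bw).

    Cmax values are taken from the output grid with parabolic refinement
    around the bracketed maximum.  Raises :class:`SimulationError` when the
    stiff integrator fails, and verifies mass balance on every call.
    """
    if dose_mg_per_kg < 0:
        raise ValueError("dose must be nonnegative")
    if duration <= 0:
        raise ValueError("duration must be positive")
    dose_umol = dose_mg_per_kg * phys.bw / P.MW_CPF * 1000.0
    t = np.linspace(0.0, duration, n_out)
    y0 = np.zeros(N_STATES)
    y0[GI] = dose_umol
    if dose_umol == 0.0:
        amounts = np.zeros((n_out, N_STATES))
        return SimulationResult(t, amounts, 0.0, part.fu_cpo_blood, phys.vb,
                                0.0, 0.0, 0.0, 0.0)
    c = _pack(phys, part, model)
    sol, info = odeint(_rhs, y0, t, args=(c,), rtol=rtol, atol=atol,
                       full_output=True, mxstep=100000)
    if info["message"] != "Integration successful.":
        raise SimulationError(f"ODE integration failed: {info['message']}")
    total = sol.sum(axis=1)
    residual = float(np.max(np.abs(total - dose_umol)) / dose_umol)
    cbo = sol[:, B_CPO] / phys.vb
    tmax, cmax = _refine_max(t, cbo)
    ctcpy = sol[:, TCPY] / phys.vb
    _, cmax_tcpy = _refine_max(t, ctcpy)
    return SimulationResult(
        time=t, amounts=sol, dose_umol=dose_umol,
        fu_cpo_blood=part.fu_cpo_blood, vb=phys.vb,
        cmax_cpo_total=cmax, tmax_cpo=tmax, cmax_tcpy=cmax_tcpy,
        mass_balance_residual=residual,
    )


def dose_to_cmax_curve(
    doses,
    scenario: Scenario,
    duration: float = 24.0,
    free: bool = True,
    **kw,
):
    """Tabulate the monotone dose -> CPO Cmax map used by reverse dosimetry.

    Returns (doses, cmax) arrays; ``free`` selects the free (unbound) blood
    Cmax, otherwise the total.  Monotonicity of the map is verified.
    """
    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        return doses, np.array([])
    if np.any(np.diff(doses) <= 0) or np.any(doses < 0):
        raise ValueError("doses must be sorted, nonnegative and distinct")
    phys, part, model = scenario.assemble()
    cmax = np.empty_like(doses)
    for i, d in enumerate(doses):
        res = simulate(d, phys, part, model, duration=duration, **kw)
        cmax[i] = res.cmax_cpo_free if free else res.cmax_cpo_total
    if np.any(np.diff(cmax) < 0):
        raise RuntimeError("dose -> Cmax map is not monotone")
    return doses, cmax


# Scenario fields eligible for one-at-a-time sensitivity perturbation.
_SENSITIVITY_FIELDS = ("bw", "ka", "fa", "mpl", "fu_cpo_plasma", "bp_cpo")


def sensitivity_analysis(
    scenario: Scenario,
    dose_mg_per_kg: float,
    perturbation: float = 0.05,
    extra_fields: dict | None = None,
    duration: float = 24.0,
) -> dict:
    """Normalized sensitivity coefficients of the free CPO blood Cmax.

    Each parameter is increased by ``perturbation`` (fraction, in (0, 0.1])
    one at a time and the model reassembled, so covariant quantities (liver
    and blood volume under a body-weight change, scaled Vmax under an MPL
    change) move together.  SC = (dCmax/Cmax)/(dP/P).

    ``extra_fields`` maps label -> callable(Scenario, factor) -> Scenario
    for parameters beyond the scalar scenario fields (e.g. one isoform's
    abundance).
    """
    if not 0 < perturbation <= 0.1:
        raise ValueError("perturbation must lie in (0, 0.1]")
    base = simulate(dose_mg_per_kg, *scenario.assemble(), duration=duration)
    c0 = base.cmax_cpo_free
    out = {}

    def run(sc):
        return simulate(dose_mg_per_kg, *sc.assemble(), duration=duration).cmax_cpo_free

    for name in _SENSITIVITY_FIELDS:
        value = getattr(scenario, name)
        if name == "fa":  # fa is capped at 1
            pert = min(value * (1 + perturbation), 1.0)
        else:
            pert = value * (1 + perturbation)
        frac = pert / value - 1.0
        if frac == 0.0:
            out[name] = 0.0
            continue
        c1 = run(scenario.with_(**{name: pert}))
        out[name] = (c1 / c0 - 1.0) / frac
    for name, fn in (extra_fields or {}).items():
        c1 = run(fn(scenario, 1 + perturbation))
        out[name] = (c1 / c0 - 1.0) / perturbation
    return out
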