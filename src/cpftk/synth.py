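"""Synthetic in vitro datasets for every stage of the pipeline.

Three generators mirror the real assays the analysis consumes:

* CYP/plasma incubation velocity-vs-concentration data following
  Michaelis-Menten kinetics with multiplicative lognormal observation
  noise (velocities are positive and span decades);
* a panel of individual plasma CPO-hydrolysis datasets whose (Vmax, Km)
  are themselves drawn from truncated lognormal population distributions,
  emulating inter-individual spread;
* 96-well AChE inhibition plates whose absorbance deltas are constructed
  so that the control-normalized activity recovers a four-parameter
  logistic in CPO concentration.

Each generator is a deterministic function of its seed, and each forms a
calibrated pair with the corresponding fitter: noiseless round trips are
exact to solver tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import params as P
from .dosimetry import ConcentrationResponseFit, PlateReading
from .kinetics import MichaelisMentenParams
from .population import DistributionSpec, lognormal_spec

__all__ = [
    "GeneratorConfig",
    "generate_incubation",
    "generate_plasma_panel",
    "generate_ache_plate",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Noise model and design shared by the generators.

    ``cv`` is the multiplicative lognormal observation CV per measurement;
    ``replicates`` the number of independent measurements per
    concentration (the assays report means of duplicate experiments, so 2
    is the default).
    """

    seed: int = 0
    cv: float = 0.05
    replicates: int = 2
    concentrations: tuple = ()

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be nonnegative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if any(c <= 0 for c in self.concentrations):
            raise ValueError("concentrations must be strictly positive")
        if list(self.concentrations) != sorted(self.concentrations):
            raise ValueError("concentrations must be sorted")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative lognormal factors with unit median."""
    if cv == 0.0:
        return np.ones(size)
    sigma = np.sqrt(np.log(1.0 + cv ** 2))
    return np.exp(rng.normal(0.0, sigma, size))


def generate_incubation(
    truth: MichaelisMentenParams,
    config: GeneratorConfig,
    enzyme_source: str = "supersome",
    pathway: int = 1,
) -> pd.DataFrame:
    """Velocity dataset v = MM(S) * exp(eps) on the configured design.

    Returns a tidy frame with columns (enzyme_source, pathway,
    concentration_uM, velocity, velocity_units, replicate) plus the
    generating truth in ``DataFrame.attrs`` for recovery studies.
    """
    if not config.concentrations:
        raise ValueError("config.concentrations must name the design")
    rng = config.rng()
    s = np.repeat(np.asarray(config.concentrations, float), config.replicates)
    rep = np.tile(np.arange(1, config.replicates + 1), len(config.concentrations))
    v = truth.vmax_app * s / (truth.km_app + s) * _noise(rng, config.cv, s.size)
    df = pd.DataFrame(
        {
            "enzyme_source": enzyme_source,
            "pathway": pathway,
            "concentration_uM": s,
            "velocity": v,
            "velocity_units": truth.units,
            "replicate": rep,
        }
    )
    df.attrs["truth"] = {"vmax_app": truth.vmax_app, "km_app": truth.km_app}
    return df


def generate_plasma_panel(
    config: GeneratorConfig,
    n_individuals: int = 25,
    vmax_spec: DistributionSpec | None = None,
    km_spec: DistributionSpec | None = None,
):
    """Per-individual plasma CPO-hydrolysis incubation datasets.

    Individual (Vmax, Km) pairs are drawn independently from truncated
    lognormal population distributions (defaults: the plasma PON1 panel
    truth, Vmax 1844 nmol/min/ml CV 0.29, Km 290 uM CV 0.33), then an
    incubation dataset is generated per individual on the plasma design.

    Returns (datasets, truth_frame) where ``truth_frame`` holds each
    individual's generating parameters.
    """
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    vmax_spec = vmax_spec or lognormal_spec(P.PLASMA_PATHWAY4.vmax_app, P.CV_PATHWAY4["vmax"])
    km_spec = km_spec or lognormal_spec(P.PLASMA_PATHWAY4.km_app, P.CV_PATHWAY4["km"])
    design = config.concentrations or P.INCUBATION_DESIGNS["plasma"]
    rng = config.rng()

    def draw(spec):
        if spec.cv_x == 0.0:
            return np.full(n_individuals, spec.mu_x)
        out = np.empty(n_individuals)
        k = 0
        while k < n_individuals:
            w = rng.normal(spec.mu_w, spec.sigma_w)
            if spec.lower_w <= w <= spec.upper_w:
                out[k] = np.exp(w)
                k += 1
        return out

    vmaxes, kms = draw(vmax_spec), draw(km_spec)
    datasets = []
    for i in range(n_individuals):
        sub = GeneratorConfig(
            seed=int(rng.integers(0, 2 ** 31)), cv=config.cv,
            replicates=config.replicates, concentrations=tuple(design),
        )
        truth = MichaelisMentenParams(vmaxes[i], kms[i], units="nmol/min/ml plasma")
        df = generate_incubation(truth, sub, enzyme_source=f"plasma_{i+1:02d}", pathway=4)
        datasets.append(df)
    truth_frame = pd.DataFrame(
        {"individual": np.arange(1, n_individuals + 1), "vmax": vmaxes, "km": kms}
    )
    truth_frame["ce"] = truth_frame.vmax / truth_frame.km
    return datasets, truth_frame


def generate_ache_plate(
    config: GeneratorConfig,
    truth: ConcentrationResponseFit | None = None,
    delta_solvent: float = 0.9,
    delta_positive: float = 0.1,
):
    """96-well AChE inhibition plate readings following a 4PL truth.

    Absorbance deltas are constructed so that control normalization
    returns exactly the 4PL activity (plus multiplicative noise on the
    test wells).  Defaults: the nine-point CPO design 0.05-50 nM and an
    IC50 of 1.89 nM.
    """
    if truth is None:
        truth = ConcentrationResponseFit(
            top=100.0, bottom=0.0, ic50=P.IC50_CPO_NM, hill_slope=1.0,
            ic50_ci=(P.IC50_CPO_NM, P.IC50_CPO_NM), rss=0.0,
        )
    design = config.concentrations or P.ACHE_DESIGN_NM
    rng = config.rng()
    readings = []
    for conc in design:
        act = truth.activity(conc) / 100.0
        for _ in range(config.replicates):
            noisy = act * float(_noise(rng, config.cv, 1)[0])
            delta = delta_positive + noisy * (delta_solvent - delta_positive)
            readings.append(
                PlateReading(
                    delta_a412_test=float(delta),
                    delta_a412_positive=delta_positive,
                    delta_a412_solvent=delta_solvent,
                    cpo_concentration=float(conc),
                )
            )
    return readings
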