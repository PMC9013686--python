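"""Monte Carlo simulation of inter-individual toxicokinetic variability
and chemical-specific adjustment factors (HK_AF).

Inter-individual spread of each input parameter is described by a
lognormal distribution parameterized by its arithmetic mean and
coefficient of variation (CV).  Sampling happens in log space where the
distribution is normal with

    sigma_w^2 = ln(1 + CV^2),     mu_w = ln(mu_x / sqrt(1 + CV^2)),

and draws outside mu_w +/- 3 sigma_w are rejected: the whole run is
discarded, not clipped or redrawn, so accepted-run counts are reported
alongside the results.  The oral absorption fraction additionally carries
a hard physical cap at 1.

CYP2B6 and CYP2C19 occur in several phenotypes (extensive, poor and, for
2C19, ultra-rapid metabolizers); the population is represented as a
mixture over the six phenotype combinations, each run with its own
abundance distributions and weighted by the product of the phenotype
frequencies.

HK_AF is the ratio of a high percentile (95th or 99th) of the free blood
Cmax of chlorpyrifos-oxon to the population geometric mean, the standard
CSAF construction for toxicokinetic variability.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from . import params as P
from .pbk import Scenario, SimulationError, simulate

__all__ = [
    "DistributionSpec",
    "PhenotypeCombination",
    "VariabilityResult",
    "lognormal_spec",
    "sample",
    "enumerate_phenotype_combinations",
    "run_population",
    "hk_af",
    "weighted_quantile",
    "weighted_geometric_mean",
]


@dataclass(frozen=True)
class DistributionSpec:
    """Truncated lognormal described by arithmetic mean and CV.

    ``mu_w``/``sigma_w`` are the normal-in-log-space parameters; the
    truncation bounds sit at +/- 3 sigma_w around mu_w, with ``cap``
    (natural scale) optionally tightening the upper bound.
    """

    mu_x: float
    cv_x: float
    cap: float | None = None

    def __post_init__(self):
        if self.mu_x <= 0:
            raise ValueError("mu_x must be positive")
        if self.cv_x < 0:
            raise ValueError("cv_x must be nonnegative")

    @property
    def sigma_w(self) -> float:
        return math.sqrt(math.log(1.0 + self.cv_x ** 2))

    @property
    def mu_w(self) -> float:
        return math.log(self.mu_x / math.sqrt(1.0 + self.cv_x ** 2))

    @property
    def lower_w(self) -> float:
        return self.mu_w - 3.0 * self.sigma_w

    @property
    def upper_w(self) -> float:
        hi = self.mu_w + 3.0 * self.sigma_w
        if self.cap is not None:
            hi = min(hi, math.log(self.cap))
        return hi


def lognormal_spec(mu_x: float, cv_x: float, cap: float | None = None) -> DistributionSpec:
    return DistributionSpec(mu_x=mu_x, cv_x=cv_x, cap=cap)


def _draw_w(spec: DistributionSpec, n: int, rng: np.random.Generator):
    """Log-space draws and their in-bounds mask."""
    if spec.cv_x == 0.0:
        w = np.full(n, spec.mu_w)
        return w, np.ones(n, dtype=bool)
    w = rng.normal(spec.mu_w, spec.sigma_w, n)
    return w, (w >= spec.lower_w) & (w <= spec.upper_w)


def truncated_moments(spec: DistributionSpec) -> tuple:
    """Closed-form (mean, CV) of the +/-3 sigma_w truncated lognormal.

    Truncation trims the heavy upper tail, so the realized CV sits a few
    percent below the nominal CV_x; these are the moments the sampler is
    validated against.  An explicit ``cap`` is not folded in here.
    """
    from scipy.stats import norm

    if spec.cv_x == 0.0:
        return spec.mu_x, 0.0
    s = spec.sigma_w
    z = norm.cdf(3.0) - norm.cdf(-3.0)
    m1 = spec.mu_x * (norm.cdf(3.0 - s) - norm.cdf(-3.0 - s)) / z
    m2 = (spec.mu_x ** 2 * math.exp(s * s)
          * (norm.cdf(3.0 - 2 * s) - norm.cdf(-3.0 - 2 * s)) / z)
    return m1, math.sqrt(m2 / m1 ** 2 - 1.0)


def sample(spec: DistributionSpec, n: int, seed) -> np.ndarray:
    """Accepted lognormal draws (length <= n after truncation-rejection)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w, ok = _draw_w(spec, n, rng)
    return np.exp(w[ok])


@dataclass(frozen=True)
class PhenotypeCombination:
    """One per-CYP phenotype selection with its population weight."""

    selection: dict  # cyp -> PhenotypeEntry
    weight: float

    def label(self) -> str:
        return "/".join(f"{c}{e.phenotype}" for c, e in sorted(self.selection.items()))


def enumerate_phenotype_combinations(table=P.PHENOTYPE_TABLE):
    """Cartesian product of phenotypes over CYPs with more than one.

    Weights are products of per-CYP phenotype frequencies and sum to 1.
    """
    by_cyp: dict[str, list] = {}
    for entry in table:
        by_cyp.setdefault(entry.cyp, []).append(entry)
    for cyp, entries in by_cyp.items():
        tot = sum(e.frequency for e in entries)
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"phenotype frequencies of {cyp} sum to {tot}, not 1")
    cyps = sorted(by_cyp)
    combos = []
    for choice in itertools.product(*(by_cyp[c] for c in cyps)):
        weight = math.prod(e.frequency for e in choice)
        combos.append(PhenotypeCombination(dict(zip(cyps, choice)), weight))
    return combos


def weighted_quantile(values, weights, q: float) -> float:
    """Inverse of the weighted empirical CDF with linear interpolation.

    Plotting positions are (cumw - 0.5*w)/sum(w), the weighted analogue of
    the usual midpoint convention; with equal weights this reduces to
    ``numpy.percentile`` (linear, midpoint-anchored)."""
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    order = np.argsort(x)
    x, w = x[order], w[order]
    cw = np.cumsum(w) - 0.5 * w
    cw /= np.sum(w)
    return float(np.interp(q, cw, x))


def weighted_geometric_mean(values, weights) -> float:
    x = np.asarray(values, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    w = np.asarray(weights, dtype=float)
    return float(np.exp(np.average(np.log(x), weights=w)))


@dataclass(frozen=True)
class VariabilityResult:
    """Weighted free-Cmax sample with its summary statistics."""

    values: np.ndarray          # accepted free CPO Cmax draws (uM)
    weights: np.ndarray         # sample weights (combo frequency / n accepted)
    combo_labels: tuple
    accepted_runs: int
    total_runs: int
    failed_runs: int
    gm: float
    p1: float
    p95: float
    p99: float

    @property
    def hk_af_95(self) -> float:
        return self.p95 / self.gm

    @property
    def hk_af_99(self) -> float:
        return self.p99 / self.gm

    @property
    def ratio_p1(self) -> float:
        return self.p1 / self.gm


def hk_af(result: VariabilityResult, percentile: int) -> float:
    """HK_AF at the 95th or 99th percentile: weighted Pxx / weighted GM."""
    if percentile == 95:
        return result.hk_af_95
    if percentile == 99:
        return result.hk_af_99
    raise ValueError("percentile must be 95 or 99")


def summarize(values, weights, combo_labels, accepted, total, failed) -> VariabilityResult:
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise ValueError("no accepted runs")
    return VariabilityResult(
        values=values, weights=weights, combo_labels=tuple(combo_labels),
        accepted_runs=accepted, total_runs=total, failed_runs=failed,
        gm=weighted_geometric_mean(values, weights),
        p1=weighted_quantile(values, weights, 0.01),
        p95=weighted_quantile(values, weights, 0.95),
        p99=weighted_quantile(values, weights, 0.99),
    )


# ---------------------------------------------------------------------------
# Population run
# ---------------------------------------------------------------------------
def _kinetic_specs(scenario: Scenario, combo: PhenotypeCombination):
    """Distribution specs for the metabolism parameters of one combo."""
    specs = {}
    if scenario.mode == "supersome":
        for cyp, entry in combo.selection.items():
            if entry.abundance > 0:
                specs[f"abundance:{cyp}"] = lognormal_spec(entry.abundance, entry.cv)
    else:
        cv1, cv2 = P.CV_HLM_PATHWAY1, P.CV_HLM_PATHWAY2
        specs["hlm_p1_high:vmax"] = lognormal_spec(scenario.hlm_p1_high[0], cv1["vmax"])
        specs["hlm_p1_high:km"] = lognormal_spec(scenario.hlm_p1_high[1], cv1["km"])
        specs["hlm_p1_low:vmax"] = lognormal_spec(scenario.hlm_p1_low[0], cv1["vmax"])
        specs["hlm_p1_low:km"] = lognormal_spec(scenario.hlm_p1_low[1], cv1["km"])
        specs["hlm_p2:vmax"] = lognormal_spec(scenario.hlm_p2[0], cv2["vmax"])
        specs["hlm_p2:km"] = lognormal_spec(scenario.hlm_p2[1], cv2["km"])
    specs["p3:vmax"] = lognormal_spec(scenario.p3[0], P.CV_PATHWAY3["vmax"])
    specs["p3:km"] = lognormal_spec(scenario.p3[1], P.CV_PATHWAY3["km"])
    specs["p4:vmax"] = lognormal_spec(scenario.p4[0], P.CV_PATHWAY4["vmax"])
    specs["p4:km"] = lognormal_spec(scenario.p4[1], P.CV_PATHWAY4["km"])
    return specs


def _influential_specs(scenario: Scenario):
    cv = P.INFLUENTIAL_CV
    return {
        "bw": lognormal_spec(scenario.bw, cv["bw"]),
        "ka": lognormal_spec(scenario.ka, cv["ka"]),
        "fa": lognormal_spec(scenario.fa, cv["fa"], cap=1.0),
        "mpl": lognormal_spec(scenario.mpl, cv["mpl"]),
        "fu_cpo_plasma": lognormal_spec(scenario.fu_cpo_plasma, cv["fu_cpo_plasma"]),
    }


def _apply_draw(scenario: Scenario, combo, draw: dict) -> Scenario:
    kw = {}
    if scenario.mode == "supersome":
        abundance = {c: e.abundance for c, e in combo.selection.items()}
        for key, val in draw.items():
            if key.startswith("abundance:"):
                abundance[key.split(":")[1]] = val
        kw["abundance"] = abundance
    else:
        for name in ("hlm_p1_high", "hlm_p1_low", "hlm_p2"):
            vmax = draw.get(f"{name}:vmax", getattr(scenario, name)[0])
            km = draw.get(f"{name}:km", getattr(scenario, name)[1])
            kw[name] = (vmax, km)
    kw["p3"] = (draw["p3:vmax"], draw["p3:km"])
    kw["p4"] = (draw["p4:vmax"], draw["p4:km"])
    for name in ("bw", "ka", "fa", "mpl", "fu_cpo_plasma", "bp_cpo"):
        if name in draw:
            kw[name] = draw[name]
    return scenario.with_(**kw)


def run_population(
    scenario: Scenario,
    dose_mg_per_kg: float,
    n_per_combo: int = 2000,
    seed: int = 0,
    scope: str = "kinetic_only",
    duration: float = 12.0,
    n_out: int = 301,
    rtol: float = 1e-6,
    atol: float = 1e-10,
) -> VariabilityResult:
    """Population Monte Carlo of the free blood Cmax of CPO.

    Per phenotype combination, ``n_per_combo`` parameter sets are drawn
    from the truncated lognormals in scope (metabolism only, or also body
    weight with its covariant physiology, ka, fa, MPL and plasma protein
    binding with correlated blood:plasma ratio), each accepted set is run
    through the PBK model, and the per-combo free-Cmax distributions are
    pooled with frequency weights.  Each combo gets an independent,
    deterministic RNG substream, so results are reproducible and
    independent of combo execution order.
    """
    if dose_mg_per_kg <= 0:
        raise ValueError("dose must be positive")
    if scope not in ("kinetic_only", "all_influential"):
        raise ValueError("scope must be kinetic_only or all_influential")
    base = scenario
    if scenario.mode == "hlm_nonbiphasic":
        raise ValueError("the non-biphasic liver description is not used for "
                         "population simulation (inadequate at low dose)")

    combos = enumerate_phenotype_combinations()
    if scenario.mode != "supersome":
        # phenotype mixture only applies to the recombinant-CYP route
        combos = [PhenotypeCombination({}, 1.0)]

    values, weights, labels = [], [], []
    accepted = total = failed = 0
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(len(combos))

    for combo, stream in zip(combos, streams):
        rng = np.random.default_rng(stream)
        specs = _kinetic_specs(base, combo)
        if scope == "all_influential":
            specs.update(_influential_specs(base))
        names = list(specs)
        n = n_per_combo
        draws_w = np.empty((len(names), n))
        ok = np.ones(n, dtype=bool)
        z_fu = None
        for i, name in enumerate(names):
            w, good = _draw_w(specs[name], n, rng)
            draws_w[i] = w
            ok &= good
            if name == "fu_cpo_plasma":
                s = specs[name]
                z_fu = (w - s.mu_w) / s.sigma_w
        # blood:plasma ratio of CPO moves with the protein-binding draw:
        # same standardized deviate, its own mean/CV
        bp_w = None
        if scope == "all_influential":
            bp_spec = lognormal_spec(base.bp_cpo, P.INFLUENTIAL_CV["bp_cpo"])
            bp_w = bp_spec.mu_w + bp_spec.sigma_w * z_fu
        total += n
        combo_vals = []
        for j in range(n):
            if not ok[j]:
                continue
            draw = {name: math.exp(draws_w[i, j]) for i, name in enumerate(names)}
            if bp_w is not None:
                draw["bp_cpo"] = math.exp(bp_w[j])
            sc = _apply_draw(base, combo, draw)
            try:
                res = simulate(dose_mg_per_kg, *sc.assemble(),
                               duration=duration, n_out=n_out, rtol=rtol, atol=atol)
            except SimulationError:
                failed += 1
                continue
            combo_vals.append(res.cmax_cpo_free)
        if not combo_vals:
            continue
        accepted += len(combo_vals)
        w_each = combo.weight / len(combo_vals)
        values.extend(combo_vals)
        weights.extend([w_each] * len(combo_vals))
        labels.append((combo.label(), len(combo_vals)))

    return summarize(values, weights, labels, accepted, total, failed)
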