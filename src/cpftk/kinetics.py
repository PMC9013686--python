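"""In vitro enzyme kinetics: Michaelis-Menten fitting, intersystem
extrapolation factors (ISEF) and scaling of apparent kinetic constants to
whole-body in vivo values.

Three enzyme sources are handled, each with its own apparent-Vmax unit and
scaling route to the whole body:

* recombinant single-CYP preparations (pmol/min/pmol CYP), scaled through
  CYP abundance, ISEF, microsomal protein yield (MPL) and liver weight;
* pooled human liver microsomes (nmol/min/mg protein), scaled through MPL
  and liver weight;
* human plasma (nmol/min/ml plasma), scaled through blood volume and the
  55% plasma fraction of blood.

Catalytic efficiency (CE) is Vmax/Km throughout; scaled CE is in L/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .params import MPL, PLASMA_FRACTION_OF_BLOOD

__all__ = [
    "MichaelisMentenParams",
    "MichaelisMentenFit",
    "ProbeAssay",
    "IsoformRecord",
    "ScaledPathway",
    "FitFailure",
    "fit_michaelis_menten",
    "compute_isef",
    "scale_supersome_vmax",
    "scale_hlm_vmax",
    "scale_plasma_vmax",
    "scale_supersome_pathway",
    "summed_scaled_ce",
    "eadie_hofstee_diagnostic",
]


class FitFailure(RuntimeError):
    """Raised when a nonlinear fit does not converge or yields an
    inadmissible (non-positive) parameter estimate."""


@dataclass(frozen=True)
class MichaelisMentenParams:
    """Apparent Vmax/Km for one enzyme source and pathway.

    ``units`` tags the Vmax convention (e.g. ``pmol/min/pmolCYP``).
    """

    vmax_app: float
    km_app: float
    units: str = ""

    def __post_init__(self):
        if self.vmax_app <= 0 or self.km_app <= 0:
            raise ValueError("vmax_app and km_app must be positive")

    @property
    def ce_app(self) -> float:
        return self.vmax_app / self.km_app


@dataclass(frozen=True)
class MichaelisMentenFit(MichaelisMentenParams):
    """Michaelis-Menten estimate with least-squares diagnostics."""

    rss: float = float("nan")
    se_vmax: float = float("nan")
    se_km: float = float("nan")


@dataclass(frozen=True)
class ProbeAssay:
    """Probe-substrate Vmax pair behind one ISEF determination."""

    cyp_name: str
    probe: str
    vmax_pooled_hlm: float   # nmol/min/mg microsomal protein
    vmax_supersome: float    # pmol/min/pmol CYP

    def __post_init__(self):
        if self.vmax_pooled_hlm <= 0 or self.vmax_supersome <= 0:
            raise ValueError("probe Vmax values must be positive")


@dataclass(frozen=True)
class IsoformRecord:
    """One CYP isoform/phenotype with its abundance and CPF kinetics."""

    cyp_name: str
    phenotype: str                     # EM / PM / UM
    abundance: float                   # pmol CYP/mg microsomal protein
    frequency: float                   # population fraction
    isef: float
    kinetics_pathway1: MichaelisMentenParams
    kinetics_pathway2: MichaelisMentenParams

    def __post_init__(self):
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError("frequency must lie in [0, 1]")
        if self.abundance < 0:
            raise ValueError("abundance must be nonnegative")


@dataclass(frozen=True)
class ScaledPathway:
    """Whole-body in vivo kinetics: Vmax in umol/h, Km in uM, CE in L/h."""

    vmax_invivo: float
    km: float

    @property
    def ce_invivo(self) -> float:
        return self.vmax_invivo / self.km


def _mm(s, vmax, km):
    return vmax * s / (km + s)


def fit_michaelis_menten(
    concentrations,
    velocities,
    units: str = "",
    relative_weighting: bool = True,
) -> MichaelisMentenFit:
    """Least-squares Michaelis-Menten fit v = Vmax*S/(Km+S).

    Parameters
    ----------
    concentrations, velocities
        Paired observations; replicates may share a concentration but at
        least four distinct substrate levels are required.
    relative_weighting
        Weight residuals by the predicted velocity (proportional error),
        appropriate when velocities span orders of magnitude.  Absolute
        weighting is available for homoscedastic data.

    Raises
    ------
    FitFailure
        On non-convergence, degenerate data (e.g. all-zero velocities) or a
        non-positive parameter estimate.
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if s.shape != v.shape:
        raise ValueError("concentrations and velocities must be the same length")
    if np.unique(s).size < 4:
        raise ValueError("need at least 4 distinct concentrations")
    if np.any(s <= 0) or np.any(v < 0):
        raise ValueError("concentrations must be positive, velocities nonnegative")
    if not np.any(v > 0):
        raise FitFailure("all velocities are zero: no kinetic information")

    vmax0 = float(v.max()) * 1.2
    # crude Km start: concentration closest to half-maximal velocity
    km0 = float(s[np.argmin(np.abs(v - v.max() / 2.0))])
    km0 = max(km0, 1e-6)

    sigma = None
    if relative_weighting:
        sigma = np.maximum(v, v[v > 0].min() * 0.1)
    try:
        popt, pcov = curve_fit(
            _mm, s, v, p0=(vmax0, km0), sigma=sigma, absolute_sigma=False, maxfev=20000
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise FitFailure(f"Michaelis-Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise FitFailure("fit produced non-positive parameter estimate")
    resid = v - _mm(s, vmax, km)
    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else (np.nan, np.nan)
    return MichaelisMentenFit(
        vmax_app=float(vmax),
        km_app=float(km),
        units=units,
        rss=float(resid @ resid),
        se_vmax=float(perr[0]),
        se_km=float(perr[1]),
    )


def compute_isef(probe: ProbeAssay, abundance: float) -> float:
    """Intersystem extrapolation factor for one CYP.

    ISEF = Vmax_probe(pooled HLM) * 1000 / (Vmax_probe(Supersome) * abundance)

    with the factor 1000 converting nmol/min/mg to pmol/min/mg.  The result
    is dimensionless; a value of 1 means the recombinant system, weighted by
    its microsomal abundance, exactly matches pooled-microsome activity.
    """
    if abundance <= 0:
        raise ValueError("ISEF undefined for zero or negative abundance")
    return probe.vmax_pooled_hlm * 1000.0 / (probe.vmax_supersome * abundance)


def scale_supersome_vmax(
    vmax_app: float, abundance: float, isef: float, mpl: float = MPL, vl: float = 1.8
) -> float:
    """Whole-liver Vmax (umol/h) from a recombinant-CYP apparent Vmax.

    vmax_app [pmol/min/pmol CYP] * abundance [pmol/mg] * ISEF
    * 60 [min/h] * mpl [mg/g] * 1000 [g/kg] * vl [kg] / 1e6 [pmol/umol].
    A zero abundance (poor-metabolizer phenotype) yields zero.
    """
    if vmax_app < 0 or abundance < 0 or isef < 0 or mpl <= 0 or vl <= 0:
        raise ValueError("invalid scaling input")
    return vmax_app * abundance * isef * 60.0 * mpl * 1000.0 * vl / 1e6


def scale_hlm_vmax(vmax_app: float, mpl: float = MPL, vl: float = 1.8) -> float:
    """Whole-liver Vmax (umol/h) from a microsomal apparent Vmax
    [nmol/min/mg]: vmax_app * 60 * mpl * 1000 * vl / 1000."""
    if vmax_app < 0 or mpl <= 0 or vl <= 0:
        raise ValueError("invalid scaling input")
    return vmax_app * 60.0 * mpl * 1000.0 * vl / 1000.0


def scale_plasma_vmax(vmax_app: float, vb: float) -> float:
    """Whole-plasma Vmax (umol/h) from a plasma apparent Vmax
    [nmol/min/ml]: vmax_app * 60 * 1000 * vb * 0.55 / 1000, where 0.55 is
    the plasma fraction of blood volume vb [L]."""
    if vmax_app < 0 or vb < 0:
        raise ValueError("invalid scaling input")
    return vmax_app * 60.0 * 1000.0 * vb * PLASMA_FRACTION_OF_BLOOD / 1000.0


def scale_supersome_pathway(
    record: IsoformRecord, pathway: int, mpl: float = MPL, vl: float = 1.8
) -> ScaledPathway:
    """Scale one isoform's apparent kinetics for pathway 1 or 2."""
    mm = record.kinetics_pathway1 if pathway == 1 else record.kinetics_pathway2
    vmax = scale_supersome_vmax(mm.vmax_app, record.abundance, record.isef, mpl, vl)
    return ScaledPathway(vmax_invivo=vmax, km=mm.km_app)


def summed_scaled_ce(
    isoforms, pathway: int = 1, mpl: float = MPL, vl: float = 1.8
) -> float:
    """Sum of scaled catalytic efficiencies (L/h) over CYP isoforms."""
    records = list(isoforms)
    if not records:
        raise ValueError("empty isoform list")
    return sum(
        scale_supersome_pathway(r, pathway, mpl, vl).ce_invivo for r in records
    )


def eadie_hofstee_diagnostic(
    concentrations,
    velocities,
    improvement_factor: float = 0.5,
    km_separation: float = 10.0,
):
    """Eadie-Hofstee biphasicity check on a summed velocity curve.

    Plots v against v/S; a single Michaelis-Menten enzyme gives a straight
    line (slope -Km, intercept Vmax) while a mixture of well-separated
    affinities shows two distinct limbs.  The curve is flagged biphasic
    when a two-segment linear fit (best split searched over interior
    points) reduces the single-line residual sum of squares by at least
    ``improvement_factor`` AND the Km estimates implied by the two segment
    slopes differ by at least ``km_separation``-fold.  The slope criterion
    keeps smoothly curved mixtures of similar affinities (less than an
    order of magnitude apart) monophasic, matching how such plots are read
    in practice; an exactly linear plot (relative nonlinearity below 1e-10)
    is always monophasic.

    Returns
    -------
    (table, biphasic) where ``table`` is an (n, 2) array of (v, v/S) pairs
    sorted by v/S and ``biphasic`` is a bool.
    """
    s = np.asarray(concentrations, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if np.any(s <= 0) or np.any(v <= 0):
        raise ValueError("Eadie-Hofstee requires strictly positive v and S")
    x = v / s
    order = np.argsort(x)
    x, v = x[order], v[order]
    table = np.column_stack([v, x])

    def line(xi, vi):
        coef = np.polyfit(xi, vi, 1)
        r = vi - np.polyval(coef, xi)
        return coef, float(r @ r)

    _, rss1 = line(x, v)
    if rss1 <= 1e-10 * float(v @ v):
        return table, False
    best = None
    for k in range(2, x.size - 1):
        (ca, ra) = line(x[:k], v[:k])
        (cb, rb) = line(x[k:], v[k:])
        if best is None or ra + rb < best[0]:
            best = (ra + rb, -ca[0], -cb[0])
    rss2, km_a, km_b = best
    if min(km_a, km_b) <= 0:
        slope_ok = True  # a flat/positive-slope limb: saturated phase
    else:
        slope_ok = max(km_a, km_b) / min(km_a, km_b) >= km_separation
    return table, bool(rss2 < improvement_factor * rss1 and slope_ok)
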