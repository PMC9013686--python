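"""Reverse dosimetry: from in vitro acetylcholinesterase (AChE) inhibition
by chlorpyrifos-oxon (CPO) to in vivo dose-response curves and benchmark
doses.

The chain is: plate absorbances -> % residual rhAChE activity (relative to
solvent and fully-inhibited controls) -> four-parameter logistic (4PL)
concentration-response fit -> equate in vitro free concentrations with in
vivo free blood Cmax of CPO -> invert the PBK dose->Cmax map to obtain the
external oral dose per response level -> continuous benchmark-dose (BMD)
analysis at a 10% response with exponential and Hill models, profile-
likelihood BMDL and AIC-based model selection.

Free-concentration matching: with fu the unbound fraction,

    C_vitro * fu_vitro = C_blood,total * fu_blood,
    fu_blood = fu_plasma / BP,

where BP is the CPO blood:plasma concentration ratio.  The in vitro
medium carries only a trace of albumin, so fu_vitro defaults to 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .pbk import PartitioningParams

__all__ = [
    "PlateReading",
    "ConcentrationResponseFit",
    "DoseResponseCurve",
    "BMDResult",
    "FitFailure",
    "relative_activity",
    "four_pl",
    "fit_concentration_response",
    "in_vitro_to_blood",
    "blood_to_in_vitro",
    "reverse_dose",
    "build_dose_response",
    "shift_curve",
    "bmd_analysis",
]


class FitFailure(RuntimeError):
    pass


@dataclass(frozen=True)
class PlateReading:
    """10-min absorbance changes at 412 nm for one test well and the plate
    controls (solvent = 100% activity, saturating CPO = 0%)."""

    delta_a412_test: float
    delta_a412_positive: float
    delta_a412_solvent: float
    cpo_concentration: float  # nM

    def __post_init__(self):
        if self.delta_a412_solvent <= self.delta_a412_positive:
            raise ValueError("no dynamic range: solvent control must exceed positive control")


def relative_activity(reading: PlateReading) -> float:
    """Residual AChE activity in % of the solvent control."""
    num = reading.delta_a412_test - reading.delta_a412_positive
    den = reading.delta_a412_solvent - reading.delta_a412_positive
    return 100.0 * num / den


@dataclass(frozen=True)
class ConcentrationResponseFit:
    """4PL fit of % activity against log10 CPO concentration."""

    top: float
    bottom: float
    ic50: float          # nM
    hill_slope: float
    ic50_ci: tuple       # 95% CI (lower, upper)
    rss: float

    def __post_init__(self):
        if self.bottom >= self.top:
            raise ValueError("bottom must be below top")
        if self.ic50 <= 0:
            raise ValueError("ic50 must be positive")

    def activity(self, conc_nm):
        return four_pl(np.log10(conc_nm), self.top, self.bottom,
                       math.log10(self.ic50), self.hill_slope)


def four_pl(logc, top, bottom, logic50, hill):
    """log(inhibitor) vs response, variable slope (four parameters)."""
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - logic50) * hill))


def fit_concentration_response(concentrations, activities) -> ConcentrationResponseFit:
    """Fit the 4PL to (nM concentration, % activity) data.

    Requires at least 5 concentrations spanning the transition.  The IC50
    confidence interval comes from the standard error of log10(IC50) under
    the Gaussian approximation of the least-squares fit.
    """
    c = np.asarray(concentrations, dtype=float)
    a = np.asarray(activities, dtype=float)
    if np.unique(c).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.any(c <= 0):
        raise ValueError("concentrations must be positive")
    logc = np.log10(c)
    p0 = (float(a.max()), float(a.min()), float(np.median(logc)), 1.0)
    try:
        popt, pcov = optimize.curve_fit(four_pl, logc, a, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise FitFailure(f"4PL fit did not converge: {exc}") from exc
    top, bottom, logic50, hill = popt
    if not np.isfinite(popt).all():
        raise FitFailure("4PL fit returned non-finite parameters")
    dof = max(len(a) - 4, 1)
    se_logic50 = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else np.nan
    tval = stats.t.ppf(0.975, dof)
    ci = (10.0 ** (logic50 - tval * se_logic50), 10.0 ** (logic50 + tval * se_logic50))
    resid = a - four_pl(logc, *popt)
    return ConcentrationResponseFit(
        top=float(top), bottom=float(bottom), ic50=float(10.0 ** logic50),
        hill_slope=float(hill), ic50_ci=ci, rss=float(resid @ resid),
    )


# ---------------------------------------------------------------------------
# In vitro <-> in vivo concentration translation
# ---------------------------------------------------------------------------
def in_vitro_to_blood(c_in_vitro: float, part: PartitioningParams,
                      fu_in_vitro: float = 1.0) -> float:
    """Total blood CPO concentration matching an in vitro concentration.

    C_total,blood = C_vitro * fu_vitro / fu_blood with
    fu_blood = fu_plasma / BP.
    """
    if not 0 < fu_in_vitro <= 1:
        raise ValueError("fu_in_vitro must lie in (0, 1]")
    return c_in_vitro * fu_in_vitro / part.fu_cpo_blood


def blood_to_in_vitro(c_total_blood: float, part: PartitioningParams,
                      fu_in_vitro: float = 1.0) -> float:
    """Inverse of :func:`in_vitro_to_blood` (round-trip identity)."""
    return c_total_blood * part.fu_cpo_blood / fu_in_vitro


def reverse_dose(c_free_blood: float, doses, cmax_free) -> float:
    """Invert the tabulated monotone dose -> free Cmax map.

    Monotone log-log interpolation; a target outside the tabulated range
    raises, naming the bracketing values.
    """
    doses = np.asarray(doses, dtype=float)
    cmax = np.asarray(cmax_free, dtype=float)
    if c_free_blood == 0.0:
        return 0.0
    if c_free_blood < cmax[0] or c_free_blood > cmax[-1]:
        raise ValueError(
            f"target free Cmax {c_free_blood:.3g} outside tabulated range "
            f"[{cmax[0]:.3g}, {cmax[-1]:.3g}] uM (doses {doses[0]:.3g}-{doses[-1]:.3g} mg/kg)"
        )
    from scipy.interpolate import PchipInterpolator

    inv = PchipInterpolator(np.log(cmax), np.log(doses))
    return float(np.exp(inv(np.log(c_free_blood))))


@dataclass(frozen=True)
class DoseResponseCurve:
    """Predicted in vivo dose-response: % RBC AChE inhibition vs oral dose."""

    doses: np.ndarray        # mg/kg bw
    inhibition: np.ndarray   # %
    population: str = "average"  # average | p99_sensitive | p1_insensitive

    def __post_init__(self):
        inh = np.asarray(self.inhibition, dtype=float)
        if np.any(inh < -1e-9) or np.any(inh > 100 + 1e-9):
            raise ValueError("inhibition must lie in [0, 100]")


def build_dose_response(
    fit: ConcentrationResponseFit,
    doses,
    cmax_free,
    part: PartitioningParams,
    concentrations_nm=None,
    fu_in_vitro: float = 1.0,
) -> DoseResponseCurve:
    """Translate the in vitro curve to an in vivo dose-response curve.

    Each in vitro concentration (free, fu_vitro = 1 by default) is equated
    with the free blood Cmax; the dose axis comes from inverting the PBK
    dose->Cmax map and the response values are carried over unchanged as
    % inhibition = 100 - % activity.  Concentrations whose free-equivalent
    falls outside the tabulated map are dropped.
    """
    if concentrations_nm is None:
        lo = math.log10(fit.ic50) - 2.0
        concentrations_nm = np.logspace(lo, lo + 4.0, 25)
    conc = np.asarray(concentrations_nm, dtype=float)
    out_d, out_i = [0.0], [0.0]
    for c in conc:
        c_free_um = c * fu_in_vitro * 1e-3  # nM free in vitro -> uM free blood
        try:
            d = reverse_dose(c_free_um, doses, cmax_free)
        except ValueError:
            continue
        inh = float(np.clip(100.0 - fit.activity(c), 0.0, 100.0))
        out_d.append(d)
        out_i.append(inh)
    order = np.argsort(out_d)
    return DoseResponseCurve(np.asarray(out_d)[order], np.asarray(out_i)[order])


def shift_curve(curve: DoseResponseCurve, factor: float, population: str = "average") -> DoseResponseCurve:
    """Shift the dose axis by an adjustment factor, responses unchanged.

    For the sensitive (99th percentile) curve the factor is HK_AF = P99/GM
    and doses are divided by it; for the insensitive (1st percentile) curve
    the factor is P1/GM < 1, which moves the curve right.
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    return DoseResponseCurve(curve.doses / factor, curve.inhibition, population)


# ---------------------------------------------------------------------------
# Benchmark-dose analysis (continuous; exponential and Hill families)
# ---------------------------------------------------------------------------
@dataclass(frozen=True)
class BMDResult:
    model: str       # exponential | hill
    bmd10: float     # mg/kg bw
    bmdl10: float    # lower one-sided 95% profile-likelihood limit
    aic: float
    params: tuple

    def __post_init__(self):
        if self.bmdl10 > self.bmd10 + 1e-12:
            raise ValueError("BMDL must not exceed BMD")


def _hill_model(d, top, k, n):
    return top * d ** n / (k ** n + d ** n)


def _exp_model(d, a, b, c):
    return a * (1.0 - np.exp(-((b * d) ** c)))


def _gauss_loglik(resid, n):
    sigma2 = max(float(resid @ resid) / n, 1e-12)
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


def _fit_family(doses, resp, family):
    d = np.asarray(doses, dtype=float)
    y = np.asarray(resp, dtype=float)
    dmax = d[d > 0].max()
    ymax = y.max()
    if family == "hill":
        fun, p0 = _hill_model, (max(ymax, 1.0), np.median(d[d > 0]), 1.5)
        bounds = ([1e-6, 1e-9, 0.2], [200.0, dmax * 100, 20.0])
    else:
        fun, p0 = _exp_model, (max(ymax, 1.0), 1.0 / max(np.median(d[d > 0]), 1e-9), 1.0)
        bounds = ([1e-6, 1e-12, 0.2], [200.0, 1e9, 20.0])
    popt, _ = optimize.curve_fit(fun, d, y, p0=p0, bounds=bounds, maxfev=50000)
    resid = y - fun(d, *popt)
    ll = _gauss_loglik(resid, len(y))
    aic = 2 * (len(popt) + 1) - 2 * ll  # +1 for sigma
    return fun, tuple(popt), ll, aic


def _bmd_from_params(fun, params, bmr, dmax):
    f = lambda d: fun(d, *params) - bmr
    if f(dmax * 10) < 0:
        raise FitFailure("response never reaches the benchmark level")
    return float(optimize.brentq(f, 1e-12, dmax * 10))


def _profile_bmdl(doses, resp, family, fun, params, bmd, bmr, ll_hat):
    """One-sided 95% profile-likelihood lower bound on the BMD.

    The BMD is made an explicit parameter by solving the model's scale
    parameter from the BMR constraint; the bound is where the profile
    log-likelihood drops by chi2(1, 0.90)/2 (one-sided 95%).
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(resp, dtype=float)
    n = len(y)
    crit = stats.chi2.ppf(0.90, 1) / 2.0

    def profile_ll(bmd_c):
        # reparameterize: given candidate BMD, the dose-scale parameter is
        # pinned by f(bmd_c) = bmr; optimize the remaining shape parameters.
        def nll(theta):
            if family == "hill":
                top, nn = theta
                if top <= bmr or nn <= 0:
                    return 1e12
                k = bmd_c * ((top - bmr) / bmr) ** (1.0 / nn)
                resid = y - _hill_model(d, top, k, nn)
            else:
                a, c = theta
                if a <= bmr or c <= 0:
                    return 1e12
                b = (-math.log(1.0 - bmr / a)) ** (1.0 / c) / bmd_c
                resid = y - _exp_model(d, a, b, c)
            return -_gauss_loglik(resid, n)

        if family == "hill":
            x0 = (params[0], params[2])
        else:
            x0 = (params[0], params[2])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        return -res.fun

    target = ll_hat - crit

    def gap(bmd_c):
        return profile_ll(bmd_c) - target

    lo, hi = bmd, bmd
    for _ in range(60):
        lo *= 0.8
        if gap(lo) < 0:
            return float(optimize.brentq(gap, lo, hi, xtol=bmd * 1e-4))
        hi = lo
    return float(lo)  # profile flat: bound indistinguishable from zero at this scale


def bmd_analysis(curve: DoseResponseCurve, bmr: float = 0.10):
    """Continuous BMD analysis of a predicted dose-response curve.

    Fits the exponential and Hill families, computes the dose at a ``bmr``
    (fraction of the 0-100% scale, default 10 percentage points of AChE
    inhibition), the one-sided 95% profile-likelihood BMDL and the AIC.

    Returns (results, best) where ``best`` has the lowest AIC.
    """
    d, y = curve.doses, curve.inhibition
    if np.unique(d).size < 5:
        raise ValueError("need at least 5 dose points")
    if y.max() - y.min() < 1e-9:
        raise FitFailure("flat dose-response: no finite BMD")
    bmr_abs = bmr * 100.0
    results = []
    for family in ("exponential", "hill"):
        try:
            fun, params, ll, aic = _fit_family(d, y, family)
            bmd = _bmd_from_params(fun, params, bmr_abs, d.max())
            bmdl = _profile_bmdl(d, y, family, fun, params, bmd, bmr_abs, ll)
            bmdl = min(bmdl, bmd)
            results.append(BMDResult(family, bmd, bmdl, aic, params))
        except (RuntimeError, ValueError, FitFailure):
            continue
    if not results:
        raise FitFailure("all benchmark-dose fits failed")
    best = min(results, key=lambda r: r.aic)
    return results, best
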