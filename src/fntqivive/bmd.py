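"""Benchmark-dose analysis of predicted dose–response curves.

Continuous-endpoint conventions in the EFSA style: the benchmark response
(BMR) is a relative deviation (default 10%) from the fitted model's
background (dose-0) response; candidate decreasing families are

* exponential-3:  y = a·exp(−b·d^g)
* exponential-4:  y = a·(c + (1 − c)·exp(−b·d))      (plateau at a·c)
* hill-4:         y = a·(1 − (1 − c)·d^g / (k^g + d^g))

selected by AIC.  The BMD solves y(BMD) = (1 − BMR)·y(0) in closed form for
each family.  BMDL (one-sided lower 95% confidence limit) comes from a
parametric bootstrap with residual-estimated noise (default) or from a
profile-likelihood bound at the 90% two-sided level.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, minimize
from scipy.stats import chi2

from .errors import DomainError, FittingError, InsufficientRangeError, UnreachableTargetError
from .qivive import DoseResponseCurve

FAMILIES = ("exponential-3", "exponential-4", "hill-4")


def _exp3(d, a, b, g):
    return a * np.exp(-b * np.asarray(d, float) ** g)


def _exp4(d, a, b, c):
    return a * (c + (1.0 - c) * np.exp(-b * np.asarray(d, float)))


def _hill4(d, a, c, k, g):
    d = np.asarray(d, float)
    return a * (1.0 - (1.0 - c) * d ** g / (k ** g + d ** g))


_MODEL_FUNCS = {"exponential-3": _exp3, "exponential-4": _exp4, "hill-4": _hill4}


@dataclass(frozen=True)
class BMDModelFit:
    """One fitted dose–response family with its least-squares diagnostics."""

    family: str
    params: dict[str, float]
    sse: float
    n_obs: int
    aic: float
    sigma: float  # residual standard deviation (ddof = #params)
    dose: np.ndarray
    response: np.ndarray

    def predict(self, d):
        return _MODEL_FUNCS[self.family](d, **self.params)

    @property
    def background(self) -> float:
        """Fitted response at dose 0."""
        return float(self.params["a"])


@dataclass(frozen=True)
class BMDResult:
    """BMD with its confidence limits; always bmdl <= bmd <= bmdu."""

    model_family: str
    params: dict[str, float]
    bmr: float
    bmd: float
    bmdl: float
    bmdu: float
    ci_method: str
    n_bootstrap: int = 0
    seed: int | None = None
    aic: float = float("nan")
    warnings: tuple[str, ...] = field(default=())


def fit_bmd_model(curve: DoseResponseCurve, family: str) -> BMDModelFit:
    """Unweighted least-squares fit of one decreasing family.

    Requires at least 5 dose points whose response declines by at least the
    default BMR (10%) relative to the top of the curve; otherwise raises
    :class:`InsufficientRangeError`.
    """
    if family not in FAMILIES:
        raise DomainError(f"unknown model family {family!r}; choose from {FAMILIES}")
    d = np.asarray(curve.dose, float)
    y = np.asarray(curve.response, float)
    if len(d) < 5:
        raise InsufficientRangeError("at least 5 dose points are required")
    y_top = float(y.max())
    if y_top <= 0 or (y_top - float(y.min())) / y_top < 0.10:
        raise InsufficientRangeError(
            "response declines by less than the benchmark response over the dose range")

    a0 = y_top
    d_scale = float(np.median(d[d > 0])) if np.any(d > 0) else 1.0
    # crude initial decay rate from the half-decline dose
    half_idx = int(np.argmin(np.abs(y - (y_top + y.min()) / 2.0)))
    d_half = float(d[half_idx]) if d[half_idx] > 0 else d_scale
    starts: list[tuple]
    if family == "exponential-3":
        func, names = _exp3, ("a", "b", "g")
        bounds = ([0.0, 1e-12, 0.1], [np.inf, np.inf, 15.0])
        starts = [(a0, math.log(2.0) / d_half ** g0, g0) for g0 in (0.7, 1.0, 2.0, 4.0)]
    elif family == "exponential-4":
        func, names = _exp4, ("a", "b", "c")
        bounds = ([0.0, 1e-12, 0.0], [np.inf, np.inf, 1.0])
        c0 = max(float(y.min()) / a0, 0.0)
        starts = [(a0, math.log(2.0) / d_half, c) for c in (0.0, c0)]
    else:
        func, names = _hill4, ("a", "c", "k", "g")
        bounds = ([0.0, 0.0, 1e-12, 0.1], [np.inf, 1.0, np.inf, 15.0])
        c0 = max(float(y.min()) / a0, 0.0)
        starts = [(a0, c0, d_half, g0) for g0 in (0.7, 1.0, 2.0, 4.0)]

    best = None
    for p0 in starts:
        try:
            popt, _ = curve_fit(func, d, y, p0=np.asarray(p0, float),
                                bounds=bounds, maxfev=20000)
        except RuntimeError:
            continue
        sse = float(np.sum((y - func(d, *popt)) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        raise FittingError(f"{family} fit failed to converge from every start")
    sse, popt = best
    n, k = len(y), len(popt)
    aic = n * math.log(max(sse, 1e-300) / n) + 2 * (k + 1)
    sigma = math.sqrt(sse / max(n - k, 1))
    return BMDModelFit(family=family, params=dict(zip(names, map(float, popt))),
                       sse=sse, n_obs=n, aic=aic, sigma=sigma, dose=d, response=y)


def compute_bmd(fit: BMDModelFit, bmr: float = 0.10, method: str = "closed_form") -> float:
    """Dose at which the fitted response equals (1 − bmr) × background.

    Closed form for every family (relative-deviation BMR, decreasing
    endpoint); ``method="root"`` instead brackets the benchmark crossing of
    the fitted curve and solves it numerically.  Raises
    :class:`UnreachableTargetError` when the family's plateau lies above the
    benchmark level (or, for the root method, no crossing exists below the
    dose ceiling).
    """
    if not (0 < bmr < 1):
        raise DomainError(f"bmr must lie in (0, 1), got {bmr}")
    if method == "root":
        return _bmd_by_root(fit, bmr)
    p = fit.params
    if fit.family == "exponential-3":
        return float((math.log(1.0 / (1.0 - bmr)) / p["b"]) ** (1.0 / p["g"]))
    if fit.family == "exponential-4":
        if p["c"] >= 1.0 - bmr:
            raise UnreachableTargetError(
                f"fitted plateau ({p['c']:.3f}·background) lies above the benchmark level")
        return float(-math.log((1.0 - bmr - p["c"]) / (1.0 - p["c"])) / p["b"])
    r = bmr / (1.0 - p["c"]) if p["c"] < 1.0 else float("inf")
    if r >= 1.0:
        raise UnreachableTargetError(
            f"fitted plateau ({p['c']:.3f}·background) lies above the benchmark level")
    return float(p["k"] * (r / (1.0 - r)) ** (1.0 / p["g"]))


def _bmd_by_root(fit: BMDModelFit, bmr: float, dose_ceiling: float = 1e6) -> float:
    from scipy.optimize import brentq

    target = (1.0 - bmr) * fit.background

    def f(d):
        return float(fit.predict(d)) - target

    hi = max(float(fit.dose.max()), 1e-6)
    while f(hi) > 0:
        hi *= 10.0
        if hi > dose_ceiling:
            raise UnreachableTargetError(
                "fitted curve does not cross the benchmark level below the dose ceiling")
    return float(brentq(f, 0.0, hi, rtol=1e-14, xtol=1e-15, maxiter=300))


def compute_bmdl(fit: BMDModelFit, curve: DoseResponseCurve | None = None,
                 bmr: float = 0.10, ci_method: str = "parametric_bootstrap",
                 n_bootstrap: int = 1000, seed: int | None = None,
                 ) -> tuple[float, float, tuple[str, ...]]:
    """One-sided 95% lower (and upper) confidence limits on the BMD.

    parametric_bootstrap (default): residual-estimated Gaussian noise is
    added to the fitted curve, each resample refitted and its BMD computed;
    BMDL/BMDU are the 5th/95th percentiles.  A refit failure rate above 10%
    is recorded as a warning.  profile_likelihood: likelihood-ratio bound at
    the 90% two-sided level on the SSE profile in BMD.
    """
    bmd = compute_bmd(fit, bmr)
    warnings: list[str] = []
    if ci_method == "parametric_bootstrap":
        if n_bootstrap < 200:
            raise DomainError("n_bootstrap must be >= 200")
        if fit.sigma == 0.0:
            return bmd, bmd, ()
        rng = np.random.default_rng(seed)
        yhat = fit.predict(fit.dose)
        bmds = []
        failures = 0
        for _ in range(n_bootstrap):
            y_star = yhat + rng.normal(0.0, fit.sigma, size=len(yhat))
            try:
                bmds.append(compute_bmd(_quick_refit(fit, y_star), bmr))
            except Exception:
                failures += 1
        if failures > 0.10 * n_bootstrap:
            warnings.append(f"bootstrap non-convergence rate {failures / n_bootstrap:.1%} > 10%")
        if not bmds:
            raise FittingError("every bootstrap refit failed")
        bmdl = float(np.percentile(bmds, 5.0))
        bmdu = float(np.percentile(bmds, 95.0))
    elif ci_method == "profile_likelihood":
        bmdl = _profile_bound(fit, bmr, bmd, lower=True)
        bmdu = _profile_bound(fit, bmr, bmd, lower=False)
    else:
        raise DomainError(f"unknown ci_method {ci_method!r}")
    return min(bmdl, bmd), max(bmdu, bmd), tuple(warnings)


_FAMILY_BOUNDS = {
    "exponential-3": (("a", "b", "g"), ([0.0, 1e-12, 0.1], [np.inf, np.inf, 15.0])),
    "exponential-4": (("a", "b", "c"), ([0.0, 1e-12, 0.0], [np.inf, np.inf, 1.0])),
    "hill-4": (("a", "c", "k", "g"), ([0.0, 0.0, 1e-12, 0.1], [np.inf, 1.0, np.inf, 15.0])),
}


def _quick_refit(fit: BMDModelFit, y_star: np.ndarray) -> BMDModelFit:
    """Single-start refit of a bootstrap resample, warm-started at the
    original estimates (the resample is a perturbation of the fitted curve)."""
    func = _MODEL_FUNCS[fit.family]
    names, bounds = _FAMILY_BOUNDS[fit.family]
    p0 = np.clip([fit.params[n] for n in names],
                 np.asarray(bounds[0]) + 1e-12, bounds[1])
    popt, _ = curve_fit(func, fit.dose, y_star, p0=p0, bounds=bounds, maxfev=5000)
    sse = float(np.sum((y_star - func(fit.dose, *popt)) ** 2))
    n, k = len(y_star), len(popt)
    return BMDModelFit(family=fit.family, params=dict(zip(names, map(float, popt))),
                       sse=sse, n_obs=n, aic=n * math.log(max(sse, 1e-300) / n) + 2 * (k + 1),
                       sigma=math.sqrt(sse / max(n - k, 1)), dose=fit.dose,
                       response=y_star)


def _profile_sse(fit: BMDModelFit, bmr: float, bmd_value: float) -> float:
    """Minimum SSE subject to the constraint BMD(params) = bmd_value.

    The rate/location parameter is substituted from the constraint, leaving
    the remaining parameters free.
    """
    d, y = fit.dose, fit.response
    lnr = math.log(1.0 / (1.0 - bmr))

    if fit.family == "exponential-3":
        def sse(theta):
            a, g = theta
            if a <= 0 or not (0.1 <= g <= 15.0):
                return 1e30
            b = lnr / bmd_value ** g
            return float(np.sum((y - _exp3(d, a, b, g)) ** 2))
        x0 = [fit.params["a"], fit.params["g"]]
    elif fit.family == "exponential-4":
        def sse(theta):
            a, c = theta
            if a <= 0 or not (0.0 <= c < 1.0 - bmr):
                return 1e30
            b = -math.log((1.0 - bmr - c) / (1.0 - c)) / bmd_value
            return float(np.sum((y - _exp4(d, a, b, c)) ** 2))
        x0 = [fit.params["a"], min(fit.params["c"], 1.0 - bmr - 1e-6)]
    else:
        def sse(theta):
            a, c, g = theta
            if a <= 0 or not (0.0 <= c < 1.0 - bmr) or not (0.1 <= g <= 15.0):
                return 1e30
            r = bmr / (1.0 - c)
            k = bmd_value * ((1.0 - r) / r) ** (1.0 / g)
            return float(np.sum((y - _hill4(d, a, c, k, g)) ** 2))
        x0 = [fit.params["a"], min(fit.params["c"], 1.0 - bmr - 1e-6), fit.params["g"]]

    res = minimize(sse, x0, method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
    return float(res.fun)


def _profile_bound(fit: BMDModelFit, bmr: float, bmd: float, lower: bool) -> float:
    """Likelihood-ratio bound: n·ln(SSE_profile/SSE_min) = χ²₁(0.90)."""
    crit = chi2.ppf(0.90, 1)
    n = fit.n_obs
    sse_min = max(fit.sse, 1e-300)

    def excess(b):
        return n * math.log(max(_profile_sse(fit, bmr, b), 1e-300) / sse_min) - crit

    factor = 0.5 if lower else 2.0
    b_in, b_out = bmd, bmd * factor
    for _ in range(60):
        if excess(b_out) > 0:
            break
        b_in, b_out = b_out, b_out * factor
    else:
        return b_out  # profile essentially flat; bound at search limit
    lo, hi = (b_out, b_in) if lower else (b_in, b_out)
    for _ in range(80):
        mid = math.sqrt(lo * hi)
        if (excess(mid) > 0) == lower:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1.0 + 1e-8:
            break
    return math.sqrt(lo * hi)


def bmd_analysis(curve: DoseResponseCurve, bmr: float = 0.10,
                 families: tuple[str, ...] = FAMILIES,
                 ci_method: str = "parametric_bootstrap",
                 n_bootstrap: int = 1000, seed: int | None = None) -> BMDResult:
    """Fit every candidate family, select by AIC, and return the BMD/BMDL.

    Families whose fit or BMD computation fails are skipped (recorded in the
    result's warnings); at least one family must succeed.
    """
    fits: list[tuple[float, BMDModelFit]] = []
    warnings: list[str] = []
    for fam in families:
        try:
            f = fit_bmd_model(curve, fam)
            compute_bmd(f, bmr)  # must be computable to be selectable
            fits.append((f.aic, f))
        except (FittingError, InsufficientRangeError, UnreachableTargetError) as exc:
            warnings.append(f"{fam}: {exc}")
    if not fits:
        raise FittingError(f"no candidate family could be fitted: {warnings}")
    fits.sort(key=lambda t: t[0])
    best = fits[0][1]
    bmd = compute_bmd(best, bmr)
    bmdl, bmdu, w = compute_bmdl(best, curve, bmr, ci_method, n_bootstrap, seed)
    return BMDResult(model_family=best.family, params=best.params, bmr=bmr,
                     bmd=bmd, bmdl=bmdl, bmdu=bmdu, ci_method=ci_method,
                     n_bootstrap=n_bootstrap if ci_method == "parametric_bootstrap" else 0,
                     seed=seed, aic=best.aic, warnings=tuple(warnings) + w)
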