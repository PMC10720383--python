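"""Concentration–response fitting of blood AChE inhibition and IC50 extraction.

Erythrocyte AChE activity (% of solvent control) measured at increasing
inhibitor concentrations is fitted with a four-parameter log-logistic curve

    activity(c) = bottom + (top − bottom) / (1 + (c / ic50)^hill)

on the raw concentration axis, so that solvent controls (c = 0) enter the
sum of squares directly.  When the activity never crosses half of the
control level within the tested range, the IC50 is censored and reported as
"greater than the highest tested concentration".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import (CensoredIC50Error, DomainError, FittingError,
                     ParameterValidationError)


@dataclass(frozen=True)
class ConcentrationResponseData:
    """Replicate-resolved AChE activity vs inhibitor concentration (μM)."""

    inhibitor_conc: np.ndarray
    activity: np.ndarray
    species_label: str
    inhibitor_label: str = "FNO"

    def __post_init__(self):
        conc = np.asarray(self.inhibitor_conc, dtype=float)
        act = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "inhibitor_conc", conc)
        object.__setattr__(self, "activity", act)
        if conc.shape != act.shape:
            raise ParameterValidationError("inhibitor_conc and activity must be the same length")
        if np.any(conc < 0):
            raise ParameterValidationError("concentrations must be >= 0")
        if not np.any(conc == 0):
            raise ParameterValidationError("a solvent control (concentration 0) is required")
        if not np.all(np.isfinite(act)):
            raise ParameterValidationError("activities must be finite")


def read_cr_csv(path, species_label: str, inhibitor_label: str = "FNO") -> ConcentrationResponseData:
    """Read a concentration–response table (columns: conc_uM, activity_pct,
    optionally replicate)."""
    df = pd.read_csv(path)
    return ConcentrationResponseData(
        inhibitor_conc=df["conc_uM"].to_numpy(float),
        activity=df["activity_pct"].to_numpy(float),
        species_label=species_label, inhibitor_label=inhibitor_label)


def log_logistic(c, top, bottom, ic50, hill):
    """Four-parameter log-logistic curve, evaluated on raw concentrations."""
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(c > 0, (c / ic50) ** hill, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio)


@dataclass(frozen=True)
class CRFit:
    """A fitted four-parameter log-logistic concentration–response curve.

    ``censored`` marks data whose activity never crosses half the control
    level in the tested range; then ``ic50_bound`` carries the highest tested
    concentration as a lower bound for the IC50.
    """

    top: float
    bottom: float
    ic50_value: float | None
    hill: float | None
    covariance: np.ndarray | None
    r_squared: float
    sse: float
    censored: bool = False
    ic50_bound: float | None = None
    species_label: str = ""
    inhibitor_label: str = ""

    @property
    def parameters(self) -> dict[str, float | None]:
        return {"top": self.top, "bottom": self.bottom,
                "ic50": self.ic50_value, "hill": self.hill}


def fit_concentration_response(data: ConcentrationResponseData,
                               top_max: float = 110.0,
                               bottom_min: float = 0.0) -> CRFit:
    """Pooled unweighted least-squares fit of the four-parameter curve.

    ``top`` is estimated (bounded at ``top_max``, default 110%) rather than
    fixed at 100 to absorb control noise; ``bottom`` is bounded below at 0.
    Requires at least 5 distinct concentrations including the control.
    """
    conc = data.inhibitor_conc
    act = data.activity
    if len(np.unique(conc)) < 5:
        raise ParameterValidationError(
            "at least 5 distinct concentrations (including control) are required")

    means = pd.Series(act).groupby(pd.Series(conc)).mean()
    control_mean = float(means.loc[0.0])
    min_mean = float(means.min())

    if min_mean > control_mean / 2.0:
        # no half-inhibition within the tested range: censored IC50
        return CRFit(top=control_mean, bottom=float("nan"), ic50_value=None,
                     hill=None, covariance=None, r_squared=float("nan"),
                     sse=float("nan"), censored=True,
                     ic50_bound=float(conc.max()),
                     species_label=data.species_label,
                     inhibitor_label=data.inhibitor_label)

    pos = np.unique(conc[conc > 0])
    # concentration nearest the half-activity crossing as the IC50 start
    mean_pos = means.loc[means.index > 0]
    half = (control_mean + max(min_mean, bottom_min)) / 2.0
    ic50_0 = float(mean_pos.index[np.argmin(np.abs(mean_pos.to_numpy() - half))])
    best = None
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        for ic50_start in (ic50_0, float(np.median(pos))):
            try:
                popt, pcov = curve_fit(
                    log_logistic, conc, act,
                    p0=[control_mean, max(min_mean, bottom_min), ic50_start, hill0],
                    bounds=([0.0, bottom_min, 1e-12, 1e-6],
                            [top_max, np.inf, np.inf, np.inf]),
                    maxfev=20000)
            except RuntimeError:
                continue
            if popt[1] > popt[0]:  # bottom above top: reject
                continue
            sse = float(np.sum((act - log_logistic(conc, *popt)) ** 2))
            if best is None or sse < best[0]:
                best = (sse, popt, pcov)
    if best is None:
        raise FittingError("log-logistic fit failed to converge from every start")
    sse, popt, pcov = best
    top, bottom, ic50_v, hill = (float(x) for x in popt)

    mean_c = means.index.to_numpy(float)
    mean_a = means.to_numpy(float)
    ss_tot = float(np.sum((mean_a - mean_a.mean()) ** 2))
    ss_res = float(np.sum((mean_a - log_logistic(mean_c, *popt)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    return CRFit(top=top, bottom=bottom, ic50_value=ic50_v, hill=hill,
                 covariance=pcov, r_squared=r2, sse=sse,
                 species_label=data.species_label,
                 inhibitor_label=data.inhibitor_label)


def ic50(fit: CRFit) -> float:
    """Concentration at half-way activity, (top + bottom)/2 — the curve's
    ic50 parameter for this symmetric family."""
    if fit.censored:
        raise CensoredIC50Error(
            f"IC50 greater than the highest tested concentration ({fit.ic50_bound} μM)",
            bound=fit.ic50_bound)
    return fit.ic50_value


def predict_activity(fit: CRFit, conc) -> np.ndarray | float:
    """Evaluate the fitted curve (% activity); monotone non-increasing."""
    arr = np.asarray(conc, dtype=float)
    if np.any(arr < 0):
        raise DomainError("concentrations must be >= 0")
    if fit.censored:
        raise CensoredIC50Error("cannot predict from a censored fit", bound=fit.ic50_bound)
    out = log_logistic(arr, fit.top, fit.bottom, fit.ic50_value, fit.hill)
    return float(out) if np.isscalar(conc) else out
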