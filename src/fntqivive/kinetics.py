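"""Michaelis–Menten fitting of in vitro incubation data and IVIVE scaling.

Incubations measure metabolite formation velocity (nmol/min/mg protein) at
increasing substrate concentrations in liver microsomes or plasma.  The
fitted in vitro Vmax is scaled to a whole-compartment in vivo Vmax (μmol/h)
using the liver microsomal protein yield or the plasma protein
concentration; Km is taken to be the same in vitro and in vivo.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDataError, FittingError, ParameterValidationError, UsageError
from .parameters import MMKinetics, SpeciesParameterSet


@dataclass(frozen=True)
class IncubationDataset:
    """Replicate-resolved velocity measurements from one incubation series.

    ``substrate_conc`` (μM) and ``velocity`` (nmol/min/mg protein) are
    parallel vectors; replicates appear as repeated concentrations.
    """

    substrate_conc: np.ndarray
    velocity: np.ndarray
    matrix: str
    species_label: str
    reaction_label: str | None = None

    def __post_init__(self):
        conc = np.asarray(self.substrate_conc, dtype=float)
        vel = np.asarray(self.velocity, dtype=float)
        object.__setattr__(self, "substrate_conc", conc)
        object.__setattr__(self, "velocity", vel)
        if conc.shape != vel.shape:
            raise ParameterValidationError("substrate_conc and velocity must be the same length")
        if np.any(conc < 0):
            raise ParameterValidationError("substrate concentrations must be >= 0")
        if not np.all(np.isfinite(vel)):
            raise ParameterValidationError("velocities must be finite")
        if len(np.unique(conc)) < 4:
            raise ParameterValidationError(
                "at least 4 distinct substrate concentrations are required for fitting")


def read_incubation_csv(path, matrix: str, species_label: str,
                        reaction_label: str | None = None) -> IncubationDataset:
    """Read an incubation table (columns: concentration_uM,
    velocity_nmol_min_mg and optionally replicate)."""
    df = pd.read_csv(path)
    return IncubationDataset(
        substrate_conc=df["concentration_uM"].to_numpy(float),
        velocity=df["velocity_nmol_min_mg"].to_numpy(float),
        matrix=matrix, species_label=species_label, reaction_label=reaction_label)


@dataclass(frozen=True)
class MMFitDiagnostics:
    r_squared: float
    sse: float
    residuals: np.ndarray
    std_errors: dict[str, float] = field(default_factory=dict)


def michaelis_menten(s, vmax, km):
    """v = Vmax·S / (Km + S)."""
    s = np.asarray(s, dtype=float)
    return vmax * s / (km + s)


def fit_michaelis_menten(data: IncubationDataset) -> tuple[MMKinetics, MMFitDiagnostics]:
    """Unweighted least-squares fit of the Michaelis–Menten equation.

    Replicates are fitted pooled.  Multi-start initialization guards against
    the shallow SSE valleys of curves that do not plateau: Vmax starts at the
    maximum observed velocity and Km at {0.1, 1, 10} × the median tested
    concentration; the start with the lowest SSE wins, ties broken by the
    smallest Km.  r² is computed against replicate means.
    """
    conc = data.substrate_conc
    vel = data.velocity
    if np.all(vel == 0):
        raise DegenerateDataError("all velocities are zero; nothing to fit")

    vmax0 = float(np.max(vel))
    km_starts = np.array([0.1, 1.0, 10.0]) * float(np.median(conc[conc > 0]))
    best = None
    last_iterate = None
    for km0 in km_starts:
        try:
            popt, pcov = curve_fit(
                michaelis_menten, conc, vel, p0=[vmax0, km0],
                bounds=([0.0, 1e-12], [np.inf, np.inf]), maxfev=20000)
        except RuntimeError:
            last_iterate = (vmax0, km0)
            continue
        sse = float(np.sum((vel - michaelis_menten(conc, *popt)) ** 2))
        cand = (sse, popt[1], popt, pcov)
        if best is None or cand[:2] < best[:2]:
            best = cand
    if best is None:
        raise FittingError("Michaelis-Menten fit failed to converge from every start",
                           last_iterate=last_iterate)
    sse, _, popt, pcov = best
    vmax, km = float(popt[0]), float(popt[1])

    # r^2 against replicate means, as velocity curves are reported
    means = pd.Series(vel).groupby(pd.Series(conc)).mean()
    mean_conc = means.index.to_numpy(float)
    mean_vel = means.to_numpy(float)
    ss_tot = float(np.sum((mean_vel - mean_vel.mean()) ** 2))
    ss_res = float(np.sum((mean_vel - michaelis_menten(mean_conc, vmax, km)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    perr = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [float("nan")] * 2
    diag = MMFitDiagnostics(
        r_squared=r2, sse=sse,
        residuals=vel - michaelis_menten(conc, vmax, km),
        std_errors={"vmax": float(perr[0]), "km": float(perr[1])})
    k = MMKinetics(vmax=vmax, km=km, matrix=data.matrix,
                   reaction_label=data.reaction_label or "FNT_to_FNO",
                   scaling="in_vitro")
    return k, diag


def catalytic_efficiency(k: MMKinetics) -> float:
    """Vmax/Km, the (unscaled) catalytic efficiency / intrinsic clearance.

    In vitro: (nmol/min/mg) / (μM = nmol/mL) = mL/min/mg protein.
    In vivo: (μmol/h) / (μM = μmol/L) = L/h.
    """
    return k.vmax / k.km


def scale_vmax_liver(k: MMKinetics, sp: SpeciesParameterSet) -> MMKinetics:
    """Scale a microsomal Vmax to the whole liver.

    μmol/h = nmol/min/mg × (mg microsomal protein / g liver) × g liver × 60/1000.
    """
    if k.matrix != "liver_microsomes":
        raise UsageError(f"liver scaling requires liver_microsomes kinetics, got {k.matrix}")
    if k.scaling != "in_vitro":
        raise UsageError("kinetics are already scaled to in vivo units")
    vmax_vivo = k.vmax * sp.microsomal_yield * sp.liver_mass_g * 60.0 / 1000.0
    return k.model_copy(update={"vmax": vmax_vivo, "scaling": "in_vivo"})


def scale_vmax_plasma(k: MMKinetics, sp: SpeciesParameterSet) -> MMKinetics:
    """Scale a plasma-matrix Vmax to the whole plasma pool.

    μmol/h = nmol/min/mg × (mg protein/mL plasma) × plasma volume [mL] × 60/1000,
    with plasma volume = blood volume × (1 − hematocrit).
    """
    if k.matrix != "plasma":
        raise UsageError(f"plasma scaling requires plasma kinetics, got {k.matrix}")
    if k.scaling != "in_vitro":
        raise UsageError("kinetics are already scaled to in vivo units")
    plasma_mL = sp.plasma_volume * 1000.0
    vmax_vivo = k.vmax * sp.plasma_protein_conc * plasma_mL * 60.0 / 1000.0
    return k.model_copy(update={"vmax": vmax_vivo, "scaling": "in_vivo"})


def scale_kinetics(kinetics: dict[str, MMKinetics], sp: SpeciesParameterSet) -> dict[str, MMKinetics]:
    """Scale every in vitro reaction to in vivo units per its matrix."""
    out = {}
    for reaction, k in kinetics.items():
        if k.scaling == "in_vivo":
            out[reaction] = k
        elif k.matrix == "liver_microsomes":
            out[reaction] = scale_vmax_liver(k, sp)
        else:
            out[reaction] = scale_vmax_plasma(k, sp)
    return out
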