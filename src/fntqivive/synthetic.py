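"""Seeded synthetic data generators for every pipeline stage.

These stand in for the raw in vitro and in vivo datasets (incubation
velocity curves, blood AChE inhibition curves, literature blood/urine time
courses) that the real analysis digitizes from figures.  Defaults emulate
the stated experimental designs: three replicates, additive Gaussian noise
at 5% of Vmax for incubation velocities, 5 percentage points for AChE
activity, and 30% CV multiplicative log-normal error for in vivo
observations (mirroring the large interindividual variation of the human
volunteer data).  Fixed seeds make every generator bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ache import ConcentrationResponseData, log_logistic
from .errors import DomainError
from .kinetics import IncubationDataset, michaelis_menten
from .parameters import DosingRegimen
from .pbk import PBKModel, cumulative_urinary, simulate

#: Incubation designs: CYP450 assays span sub-Km to saturating parent
#: concentrations; PON1 hydrolysis runs to the 5000 μM solubility limit
#: without reaching a plateau.
CYP_CONCENTRATIONS = (5.0, 10.0, 25.0, 50.0, 100.0, 250.0, 500.0)
HYDROLYSIS_CONCENTRATIONS = (50.0, 100.0, 250.0, 500.0, 1000.0, 2500.0, 5000.0)

#: AChE assay design: solvent control plus a 4-decade concentration series.
ACHE_CONCENTRATIONS = (0.0, 0.01, 0.032, 0.1, 0.32, 1.0, 3.2, 10.0, 32.0, 100.0)

#: Concentration–response presets for the two species' blood AChE curves:
#: the rat curve resists low FNO concentrations then drops fast (high Hill),
#: the human curve declines progressively (Hill near 1); the IC50s are the
#: blood-assay estimates (μM).
CR_PRESETS = {
    "rat_like": {"top": 100.0, "bottom": 0.0, "ic50": 0.95, "hill": 3.0},
    "human_like": {"top": 100.0, "bottom": 0.0, "ic50": 0.84, "hill": 1.0},
}


@dataclass(frozen=True)
class SyntheticSpec:
    """A reproducible description of one synthetic dataset."""

    seed: int
    true_params: dict = field(default_factory=dict)
    design: tuple = ()
    noise_sd: float = 0.0
    noise_cv: float = 0.0
    n_replicates: int = 3


def gen_incubation(vmax: float, km: float, concentrations=None,
                   noise_sd: float | None = None, noise_cv: float = 0.0,
                   n_replicates: int = 3, seed: int = 0,
                   matrix: str = "liver_microsomes", species_label: str = "rat",
                   reaction_label: str = "FNT_to_FNO") -> IncubationDataset:
    """Michaelis–Menten velocities with Gaussian noise.

    ``noise_sd`` is additive (homoscedastic; defaults to 5% of Vmax when
    ``noise_cv`` is 0); ``noise_cv`` > 0 instead applies relative Gaussian
    noise proportional to each true velocity.  Negative noisy velocities are
    kept as generated (real velocity estimates can scatter below zero near
    the detection limit).
    """
    if concentrations is None:
        concentrations = (HYDROLYSIS_CONCENTRATIONS if km > 500
                          else CYP_CONCENTRATIONS)
    conc = np.repeat(np.asarray(concentrations, float), n_replicates)
    rng = np.random.default_rng(seed)
    vel = michaelis_menten(conc, vmax, km)
    if noise_cv > 0:
        vel = vel * (1.0 + rng.normal(0.0, noise_cv, size=conc.shape))
    else:
        if noise_sd is None:
            noise_sd = 0.05 * vmax
        if noise_sd > 0:
            vel = vel + rng.normal(0.0, noise_sd, size=conc.shape)
    return IncubationDataset(substrate_conc=conc, velocity=vel, matrix=matrix,
                             species_label=species_label, reaction_label=reaction_label)


def gen_ache_cr(preset: str | None = None, top: float = 100.0, bottom: float = 0.0,
                ic50: float = 1.0, hill: float = 1.5, concentrations=ACHE_CONCENTRATIONS,
                noise_sd: float = 5.0, n_replicates: int = 3, seed: int = 0,
                species_label: str = "rat",
                inhibitor_label: str = "FNO") -> ConcentrationResponseData:
    """Log-logistic AChE activity data with additive Gaussian noise.

    ``preset`` = "rat_like" or "human_like" replaces the curve parameters
    with the species presets (plateau-then-drop vs progressive decline).
    ``noise_sd`` is in percentage points of activity (default 5).
    """
    if preset is not None:
        if preset not in CR_PRESETS:
            raise DomainError(f"unknown preset {preset!r}; choose from {sorted(CR_PRESETS)}")
        p = CR_PRESETS[preset]
        top, bottom, ic50, hill = p["top"], p["bottom"], p["ic50"], p["hill"]
        species_label = preset.split("_")[0]
    conc = np.repeat(np.asarray(concentrations, float), n_replicates)
    rng = np.random.default_rng(seed)
    act = log_logistic(conc, top, bottom, ic50, hill)
    if noise_sd > 0:
        act = act + rng.normal(0.0, noise_sd, size=conc.shape)
    return ConcentrationResponseData(inhibitor_conc=conc, activity=act,
                                     species_label=species_label,
                                     inhibitor_label=inhibitor_label)


def gen_invivo_timecourse(model: PBKModel, regimen: DosingRegimen,
                          sampling_times, quantity: str = "blood_FNT_conc",
                          cv: float = 0.30, seed: int = 0) -> pd.DataFrame:
    """PBK-simulated observations with multiplicative log-normal error.

    ``quantity`` is "blood_<compound>_conc" (μM) or "urinary_<compound>"
    (cumulative μmol).  The log-normal factor has unit median and coefficient
    of variation ``cv`` (default 30%).
    """
    times = np.asarray(sampling_times, float)
    if np.any(times < 0):
        raise DomainError("sampling times must be >= 0")
    duration = float(times.max()) if times.max() > 0 else 1.0
    result = simulate(model, regimen, duration)
    parts = quantity.split("_")
    if parts[0] == "blood" and parts[-1] == "conc":
        compound = parts[1]
        truth = np.interp(times, result.time, result.concentrations[(compound, "blood")])
        unit = "uM"
    elif parts[0] == "urinary":
        compound = parts[1]
        truth = np.array([cumulative_urinary(result, compound, t)[0] for t in times])
        unit = "umol"
    else:
        raise DomainError(f"unknown quantity {quantity!r}")
    rng = np.random.default_rng(seed)
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv ** 2))
        obs = truth * rng.lognormal(mean=0.0, sigma=sigma, size=times.shape)
    else:
        obs = truth.copy()
    return pd.DataFrame({"time_h": times, "observed": obs, "true_value": truth,
                         "quantity": quantity, "unit": unit})
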