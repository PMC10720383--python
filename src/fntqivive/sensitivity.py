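"""Local sensitivity analysis of the Cmax dose metric and fold-difference
model evaluation.

Normalized sensitivity coefficients are one-at-a-time relative derivatives
of the maximum blood FNO concentration:

    SC(p) = [(Cmax(p·(1+δ)) − Cmax(p)) / Cmax(p)] / δ

normalized by the unperturbed Cmax (forward difference by default, central
by flag).  Predictions are evaluated against observations with the WHO
2-fold rule: a pair passes when max(pred/obs, obs/pred) ≤ 2 (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DomainError
from .kinetics import scale_kinetics
from .parameters import (COMPOUNDS, PERFUSED_TISSUES, REACTIONS, CompoundParameterSet,
                         DosingRegimen, MMKinetics, SpeciesParameterSet)
from .pbk import PBKModel, build_model, cmax, simulate


@dataclass(frozen=True)
class SensitivityReport:
    """Normalized sensitivity coefficients, sorted by |coefficient|."""

    coefficients: dict[str, float]
    delta: float
    regimen: DosingRegimen
    species_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"parameter": list(self.coefficients),
                             "coefficient": list(self.coefficients.values())})


@dataclass(frozen=True)
class FoldComparison:
    """Predicted/observed pairs with their symmetric fold differences."""

    predicted: np.ndarray
    observed: np.ndarray
    folds: np.ndarray
    threshold: float
    passed: bool


_SPECIES_SCALARS = ("body_weight", "cardiac_output", "hematocrit", "fa",
                    "ka_s", "ka_i", "ks_i", "gfr", "microsomal_yield",
                    "plasma_protein_conc")
_COMPOUND_SCALARS = ("fup", "bpr")


def default_parameter_list(include_kinetics: bool = True) -> list[str]:
    """All scalar model parameters, addressed as dotted paths."""
    params = ["dose"]
    params += [f"species.{k}" for k in _SPECIES_SCALARS]
    params += [f"species.tissue_flow_fractions.{t}" for t in PERFUSED_TISSUES]
    params += [f"species.tissue_volume_fractions.{t}" for t in PERFUSED_TISSUES + ("blood",)]
    for c in COMPOUNDS:
        params += [f"compounds.{c}.{k}" for k in _COMPOUND_SCALARS]
        params += [f"compounds.{c}.partition_blood.{t}" for t in PERFUSED_TISSUES]
    if include_kinetics:
        for r in REACTIONS:
            params += [f"kinetics.{r}.vmax", f"kinetics.{r}.km"]
    return params


def _perturbed_model(model: PBKModel, invitro_kinetics, path: str,
                     factor: float) -> tuple[PBKModel, DosingRegimen | None]:
    """Rebuild the model with one parameter scaled by ``factor``.

    Validation is bypassed for the perturbed copy: one-at-a-time perturbation
    of, e.g., a flow fraction intentionally breaks the sum-to-one constraint.
    If in vitro kinetics are supplied, Vmax scaling is re-derived after the
    perturbation so that scaling factors (microsomal yield, plasma protein,
    liver mass) show their true influence.
    """
    parts = path.split(".")
    species_d = model.species.model_dump()
    compounds_d = {c: model.compounds[c].model_dump() for c in COMPOUNDS}
    kin_src = invitro_kinetics if invitro_kinetics is not None else model.kinetics
    kinetics_d = {r: kin_src[r].model_dump() for r in REACTIONS}

    if parts[0] == "species":
        target = species_d
        for p in parts[1:-1]:
            target = target[p]
        target[parts[-1]] *= factor
    elif parts[0] == "compounds":
        target = compounds_d[parts[1]]
        for p in parts[2:-1]:
            target = target[p]
        target[parts[-1]] *= factor
    elif parts[0] == "kinetics":
        kinetics_d[parts[1]][parts[2]] *= factor
    else:
        raise DomainError(f"unknown parameter path {path!r}")

    species = SpeciesParameterSet.model_construct(**species_d)
    compounds = {c: CompoundParameterSet.model_construct(**d) for c, d in compounds_d.items()}
    kinetics = {r: MMKinetics.model_construct(**d) for r, d in kinetics_d.items()}
    if invitro_kinetics is not None:
        kinetics = scale_kinetics(kinetics, species)
    return PBKModel(species=species, compounds=compounds, kinetics=kinetics,
                    solver_options=model.solver_options), None


def local_sensitivity(model: PBKModel, regimen: DosingRegimen,
                      parameters: list[str] | None = None,
                      delta: float = 0.05, mode: str = "forward",
                      invitro_kinetics: dict[str, MMKinetics] | None = None,
                      horizon: float = 24.0) -> SensitivityReport:
    """One-at-a-time normalized sensitivity of Cmax blood FNO.

    ``parameters`` are dotted paths (see :func:`default_parameter_list`);
    ``dose`` perturbs the regimen.  Raises :class:`DomainError` when the
    unperturbed Cmax is zero (sensitivity undefined).
    """
    if not (0 < delta <= 0.2):
        raise DomainError(f"delta must lie in (0, 0.2], got {delta}")
    if parameters is None:
        parameters = default_parameter_list(include_kinetics=True)

    base = cmax(simulate(model, regimen, horizon), "FNO", "blood")[0]
    if base == 0.0:
        raise DomainError("unperturbed Cmax is zero; sensitivity coefficients undefined")

    def run(path, factor):
        if path == "dose":
            reg = regimen.model_copy(update={"dose": regimen.dose * factor})
            return cmax(simulate(model, reg, horizon), "FNO", "blood")[0]
        m, _ = _perturbed_model(model, invitro_kinetics, path, factor)
        return cmax(simulate(m, regimen, horizon), "FNO", "blood")[0]

    coeffs = {}
    for path in parameters:
        if mode == "forward":
            sc = (run(path, 1.0 + delta) - base) / base / delta
        elif mode == "central":
            sc = (run(path, 1.0 + delta) - run(path, 1.0 - delta)) / base / (2.0 * delta)
        else:
            raise DomainError(f"unknown mode {mode!r}")
        coeffs[path] = float(sc)
    ordered = dict(sorted(coeffs.items(), key=lambda kv: abs(kv[1]), reverse=True))
    return SensitivityReport(coefficients=ordered, delta=delta, regimen=regimen,
                             species_label=model.species.species_label)


def fold_difference(predicted, observed, threshold: float = 2.0,
                    quantile: float = 1.0) -> FoldComparison:
    """Symmetric fold differences max(p/o, o/p) with an inclusive pass rule.

    ``quantile`` < 1 relaxes the rule to "the stated quantile of folds is
    within the threshold" (the WHO guidance tolerates occasional outliers
    when studies disagree).
    """
    p = np.asarray(predicted, float)
    o = np.asarray(observed, float)
    if p.shape != o.shape:
        raise DomainError("predicted and observed must be paired vectors of equal length")
    if np.any(p <= 0) or np.any(o <= 0):
        raise DomainError("fold differences require strictly positive values")
    folds = np.maximum(p / o, o / p)
    stat = float(np.quantile(folds, quantile)) if len(folds) else 1.0
    return FoldComparison(predicted=p, observed=o, folds=folds,
                          threshold=threshold, passed=bool(stat <= threshold))
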