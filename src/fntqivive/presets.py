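"""Convenience constructors from the packaged default parameter files."""

from __future__ import annotations

from .kinetics import scale_kinetics
from .parameters import (MMKinetics, SpeciesParameterSet, CompoundParameterSet,
                         default_parameter_path, load_kinetics, load_parameters)
from .pbk import PBKModel, SolverOptions, build_model


def load_defaults(species: str) -> tuple[SpeciesParameterSet, list[CompoundParameterSet],
                                         dict[str, MMKinetics]]:
    """Species parameters, compound parameters and in vitro kinetics for
    ``rat`` or ``human`` from the packaged TOML defaults."""
    path = default_parameter_path(species)
    sp, compounds = load_parameters(path)
    kinetics = load_kinetics(path)
    return sp, compounds, kinetics


def default_model(species: str, solver_options: SolverOptions | None = None) -> PBKModel:
    """Assembled PBK model for ``rat`` or ``human`` with packaged defaults,
    in vitro Vmax values scaled to whole-compartment in vivo rates."""
    sp, compounds, kin_vitro = load_defaults(species)
    return build_model(sp, compounds, scale_kinetics(kin_vitro, sp),
                       solver_options=solver_options)
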