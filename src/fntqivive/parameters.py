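"""Typed parameter sets for the fenitrothion (FNT) PBK/QIVIVE analysis.

All parameters are carried in one internal unit convention: time in h,
volume in L, amounts in μmol, concentrations in μM, body mass in kg.
Quantities conventionally reported in other units (GFR in mL/min/kg BW,
microsomal Vmax in nmol/min/mg protein) keep their reporting unit in the
field name and are converted at the point of use.

Configuration files are TOML with one ``[species]`` block, one
``[[compounds]]`` array entry per compound (FNT, FNO, MNP) and one
``[kinetics.<reaction>]`` block per metabolic reaction.  Packaged rat and
human defaults live under ``fntqivive/data/``.
"""

from __future__ import annotations

import math
import tomllib
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .errors import DomainError, ParameterValidationError, SchemaError, UsageError

#: The five perfused tissue compartments shared by every (sub)model.
PERFUSED_TISSUES = ("liver", "kidney", "fat", "rapidly_perfused", "slowly_perfused")

#: Compartments that carry a volume fraction (blood is the reference pool).
VOLUME_TISSUES = PERFUSED_TISSUES + ("blood",)

COMPOUNDS = ("FNT", "FNO", "MNP")

#: Metabolic reactions of the model: hepatic CYP450 bioactivation/detoxification
#: of the parent and PON1 hydrolysis of the oxon in liver and blood.
REACTIONS = ("FNT_to_FNO", "FNT_to_MNP", "FNO_to_MNP_liver", "FNO_to_MNP_blood")

Matrix = Literal["liver_microsomes", "plasma"]


class SpeciesParameterSet(BaseModel):
    """Physiology, oral absorption and clearance constants for one species.

    Attributes
    ----------
    body_weight : float
        kg.
    tissue_volume_fractions : dict
        Fraction of body weight for liver, kidney, fat, blood and the rapidly
        and slowly perfused lumped tissues (tissue density taken as 1 kg/L).
    cardiac_output : float
        L/h.
    tissue_flow_fractions : dict
        Fraction of cardiac output perfusing each of the five tissues; must
        sum to 1 (blood is the reference pool, not separately perfused).
    fa : float
        Fraction of an oral dose absorbed; the unabsorbed remainder never
        enters the system.
    ka_s, ka_i, ks_i : float
        First-order rate constants (1/h): stomach→liver, intestine→liver and
        stomach→intestine transfer of the two-compartment GI tract.
    gfr : float
        Glomerular filtration rate in mL/min/kg BW, the sole renal clearance.
    microsomal_yield : float
        mg microsomal protein per g liver, scales microsomal Vmax to the
        whole organ.
    plasma_protein_conc : float
        mg protein per mL plasma, scales plasma-matrix Vmax to whole plasma.
    """

    model_config = ConfigDict(frozen=True)

    species_label: Literal["rat", "human"]
    body_weight: float
    tissue_volume_fractions: dict[str, float]
    cardiac_output: float
    tissue_flow_fractions: dict[str, float]
    hematocrit: float
    fa: float
    ka_s: float
    ka_i: float
    ks_i: float
    gfr: float
    microsomal_yield: float
    plasma_protein_conc: float

    @field_validator("body_weight", "cardiac_output", "ka_s", "ka_i", "ks_i",
                     "gfr", "microsomal_yield", "plasma_protein_conc")
    @classmethod
    def _positive(cls, v, info):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{info.field_name} must be strictly positive, got {v}")
        return v

    @field_validator("fa", "hematocrit")
    @classmethod
    def _fraction(cls, v, info):
        if not (0 < v <= 1):
            raise ValueError(f"{info.field_name} must lie in (0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _check_tissues(self):
        missing = set(VOLUME_TISSUES) - set(self.tissue_volume_fractions)
        if missing:
            raise ValueError(f"tissue_volume_fractions missing {sorted(missing)}")
        missing = set(PERFUSED_TISSUES) - set(self.tissue_flow_fractions)
        if missing:
            raise ValueError(f"tissue_flow_fractions missing {sorted(missing)}")
        for name, v in self.tissue_volume_fractions.items():
            if not (0 < v <= 1):
                raise ValueError(f"tissue_volume_fractions[{name}] must lie in (0, 1], got {v}")
        for name, v in self.tissue_flow_fractions.items():
            if not (0 < v <= 1):
                raise ValueError(f"tissue_flow_fractions[{name}] must lie in (0, 1], got {v}")
        flow_sum = sum(self.tissue_flow_fractions[t] for t in PERFUSED_TISSUES)
        if abs(flow_sum - 1.0) > 1e-9:
            raise ValueError(
                f"tissue_flow_fractions must sum to 1 over the five perfused "
                f"tissues, got {flow_sum!r}")
        vol_sum = sum(self.tissue_volume_fractions[t] for t in VOLUME_TISSUES)
        if vol_sum > 1.0 + 1e-12:
            raise ValueError(f"tissue_volume_fractions sum to {vol_sum} > 1")
        return self

    # -- derived physiology (internal units) --------------------------------

    def tissue_volume(self, tissue: str) -> float:
        """Compartment volume in L (density 1 kg/L)."""
        return self.tissue_volume_fractions[tissue] * self.body_weight

    def tissue_flow(self, tissue: str) -> float:
        """Blood flow to a perfused tissue in L/h."""
        return self.tissue_flow_fractions[tissue] * self.cardiac_output

    @property
    def liver_mass_g(self) -> float:
        return self.tissue_volume("liver") * 1000.0

    @property
    def blood_volume(self) -> float:
        return self.tissue_volume("blood")

    @property
    def plasma_volume(self) -> float:
        """Plasma volume in L: blood volume × (1 − hematocrit)."""
        return self.blood_volume * (1.0 - self.hematocrit)

    @property
    def gfr_L_per_h(self) -> float:
        """GFR converted from mL/min/kg BW to whole-body L/h."""
        return self.gfr * self.body_weight * 60.0 / 1000.0


class CompoundParameterSet(BaseModel):
    """Per-compound molecular weight, plasma binding and tissue partitioning.

    ``partition_blood`` holds tissue:blood partition coefficients; when the
    source predicts tissue:plasma coefficients they are converted by dividing
    by the blood:plasma ratio ``bpr`` (see
    :func:`convert_plasma_to_blood_partition`).
    """

    model_config = ConfigDict(frozen=True)

    compound_label: Literal["FNT", "FNO", "MNP"]
    molecular_weight: float
    fup: float
    bpr: float
    partition_blood: dict[str, float]

    @field_validator("molecular_weight", "bpr")
    @classmethod
    def _positive(cls, v, info):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"{info.field_name} must be strictly positive, got {v}")
        return v

    @field_validator("fup")
    @classmethod
    def _fup_fraction(cls, v):
        if not (0 < v <= 1):
            raise ValueError(f"fup must lie in (0, 1], got {v}")
        return v

    @model_validator(mode="after")
    def _check_partitions(self):
        missing = set(PERFUSED_TISSUES) - set(self.partition_blood)
        if missing:
            raise ValueError(f"partition_blood missing {sorted(missing)}")
        for name, v in self.partition_blood.items():
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"partition_blood[{name}] must be > 0, got {v}")
        return self

    @property
    def unbound_blood_fraction(self) -> float:
        """fup / BPr: unbound fraction referenced to whole-blood concentration."""
        return self.fup / self.bpr


class MMKinetics(BaseModel):
    """A Michaelis–Menten (Vmax, Km) pair with its matrix of origin.

    ``scaling`` distinguishes the in vitro form (Vmax in nmol/min/mg protein)
    from the in vivo whole-compartment form (Vmax in μmol/h).  Km (μM) is the
    same in both: the in vitro Km is postulated to equal the in vivo Km.
    Catalytic efficiency Vmax/Km is always derived, never stored.
    """

    model_config = ConfigDict(frozen=True)

    vmax: float
    km: float
    matrix: Matrix
    reaction_label: Literal["FNT_to_FNO", "FNT_to_MNP", "FNO_to_MNP_liver", "FNO_to_MNP_blood"]
    scaling: Literal["in_vitro", "in_vivo"] = "in_vitro"

    @field_validator("vmax")
    @classmethod
    def _vmax_nonneg(cls, v):
        if not (v >= 0 and math.isfinite(v)):
            raise ValueError(f"vmax must be >= 0, got {v}")
        return v

    @field_validator("km")
    @classmethod
    def _km_pos(cls, v):
        if not (v > 0 and math.isfinite(v)):
            raise ValueError(f"km must be strictly positive, got {v}")
        return v


class DosingRegimen(BaseModel):
    """An oral or intravenous dosing schedule in mg/kg body weight."""

    model_config = ConfigDict(frozen=True)

    route: Literal["oral", "iv"]
    dose: float
    n_doses: int = 1
    dose_interval: float = 24.0

    @field_validator("dose")
    @classmethod
    def _dose_nonneg(cls, v):
        if v < 0:
            raise ValueError(f"dose must be >= 0, got {v}")
        return v

    @field_validator("n_doses")
    @classmethod
    def _n_pos(cls, v):
        if v < 1:
            raise ValueError(f"n_doses must be >= 1, got {v}")
        return v

    @model_validator(mode="after")
    def _interval(self):
        if self.n_doses > 1 and not self.dose_interval > 0:
            raise ValueError("dose_interval must be > 0 when n_doses > 1")
        return self


def convert_plasma_to_blood_partition(
    partition_plasma: Mapping[str, float] | float, bpr: float
):
    """Convert tissue:plasma partition coefficients to tissue:blood.

    Dividing by the blood:plasma concentration ratio corrects for the
    difference in compound distribution between whole blood and plasma.
    Accepts a single coefficient or a per-tissue mapping.
    """
    if not bpr > 0:
        raise DomainError(f"bpr must be > 0, got {bpr}")
    if isinstance(partition_plasma, Mapping):
        out = {}
        for tissue, p in partition_plasma.items():
            if not p > 0:
                raise DomainError(f"partition coefficient for {tissue} must be > 0, got {p}")
            out[tissue] = p / bpr
        return out
    if not partition_plasma > 0:
        raise DomainError(f"partition coefficient must be > 0, got {partition_plasma}")
    return partition_plasma / bpr


# ---------------------------------------------------------------------------
# TOML configuration I/O
# ---------------------------------------------------------------------------

_SPECIES_KEYS = {
    "species_label", "body_weight", "tissue_volume_fractions", "cardiac_output",
    "tissue_flow_fractions", "hematocrit", "fa", "ka_s", "ka_i", "ks_i",
    "gfr", "microsomal_yield", "plasma_protein_conc",
}
_COMPOUND_KEYS = {"compound_label", "molecular_weight", "fup", "bpr", "partition_blood"}


def default_parameter_path(species: str) -> Path:
    """Path of the packaged default TOML file for ``rat`` or ``human``."""
    if species not in ("rat", "human"):
        raise UsageError(f"no packaged defaults for species {species!r}")
    return Path(str(resources.files("fntqivive").joinpath(f"data/{species}.toml")))


def load_parameters(config_path) -> tuple[SpeciesParameterSet, list[CompoundParameterSet]]:
    """Load and validate one species block and its compound blocks from TOML.

    Raises :class:`SchemaError` for missing keys and
    :class:`ParameterValidationError` when an invariant is violated.
    """
    raw = _read_toml(config_path)
    if "species" not in raw:
        raise SchemaError(f"{config_path}: missing [species] block")
    if "compounds" not in raw or not raw["compounds"]:
        raise SchemaError(f"{config_path}: missing [[compounds]] blocks")
    species = _build(SpeciesParameterSet, raw["species"], _SPECIES_KEYS, config_path)
    compounds = [
        _build(CompoundParameterSet, block, _COMPOUND_KEYS, config_path)
        for block in raw["compounds"]
    ]
    return species, compounds


def load_kinetics(config_path) -> dict[str, MMKinetics]:
    """Load the in vitro Michaelis–Menten blocks (``[kinetics.<reaction>]``)."""
    raw = _read_toml(config_path)
    if "kinetics" not in raw:
        raise SchemaError(f"{config_path}: missing [kinetics] blocks")
    out = {}
    for reaction, block in raw["kinetics"].items():
        if reaction not in REACTIONS:
            raise SchemaError(f"{config_path}: unknown reaction {reaction!r}")
        for key in ("vmax", "km", "matrix"):
            if key not in block:
                raise SchemaError(f"{config_path}: kinetics.{reaction} missing key {key!r}")
        try:
            out[reaction] = MMKinetics(reaction_label=reaction, scaling="in_vitro", **block)
        except Exception as exc:  # pydantic ValidationError
            raise ParameterValidationError(f"{config_path}: kinetics.{reaction}: {exc}") from exc
    missing = set(REACTIONS) - set(out)
    if missing:
        raise SchemaError(f"{config_path}: kinetics blocks missing {sorted(missing)}")
    return out


def save_parameters(
    path,
    species: SpeciesParameterSet,
    compounds: list[CompoundParameterSet],
    kinetics: Mapping[str, MMKinetics] | None = None,
) -> None:
    """Write a TOML configuration that :func:`load_parameters` round-trips
    bit-for-bit (floats are emitted with ``repr``, which is lossless)."""
    lines = ["[species]"]
    sp = species.model_dump()
    for key in ("species_label", "body_weight", "cardiac_output", "hematocrit",
                "fa", "ka_s", "ka_i", "ks_i", "gfr", "microsomal_yield",
                "plasma_protein_conc"):
        lines.append(f"{key} = {_toml_value(sp[key])}")
    for sub in ("tissue_volume_fractions", "tissue_flow_fractions"):
        lines.append(f"\n[species.{sub}]")
        for name, v in sp[sub].items():
            lines.append(f"{name} = {_toml_value(v)}")
    for comp in compounds:
        cd = comp.model_dump()
        lines.append("\n[[compounds]]")
        for key in ("compound_label", "molecular_weight", "fup", "bpr"):
            lines.append(f"{key} = {_toml_value(cd[key])}")
        lines.append("[compounds.partition_blood]")
        for name, v in cd["partition_blood"].items():
            lines.append(f"{name} = {_toml_value(v)}")
    if kinetics:
        for reaction in REACTIONS:
            if reaction not in kinetics:
                continue
            k = kinetics[reaction]
            lines.append(f"\n[kinetics.{reaction}]")
            lines.append(f"vmax = {_toml_value(k.vmax)}")
            lines.append(f"km = {_toml_value(k.km)}")
            lines.append(f"matrix = {_toml_value(k.matrix)}")
    Path(path).write_text("\n".join(lines) + "\n")


def _read_toml(config_path) -> dict:
    path = Path(config_path)
    if not path.exists():
        raise SchemaError(f"configuration file not found: {path}")
    try:
        with open(path, "rb") as fh:
            return tomllib.load(fh)
    except tomllib.TOMLDecodeError as exc:
        raise SchemaError(f"{path}: not valid TOML: {exc}") from exc


def _build(cls, block: dict, required: set, origin):
    missing = required - set(block)
    if missing:
        raise SchemaError(f"{origin}: missing key(s) {sorted(missing)} for {cls.__name__}")
    try:
        return cls(**block)
    except Exception as exc:  # pydantic ValidationError
        raise ParameterValidationError(f"{origin}: {exc}") from exc


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        r = repr(v)
        return r if any(c in r for c in ".eE") else r + ".0"
    if isinstance(v, int):
        return str(v)
    return '"' + str(v).replace('"', '\\"') + '"'
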