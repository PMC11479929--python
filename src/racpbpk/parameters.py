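"""Physiological and drug-specific parameters of the goat ractopamine model.

The model describes a ~30 kg goat as a set of organ compartments connected by
the blood circulation.  Organ sizes are expressed as fractions of body weight
(density 1 kg/L, so mass fractions double as volume fractions) and perfusion
as fractions of cardiac output.  Drug-specific constants — tissue:plasma
partition coefficients, permeability fractions for the membrane-limited
tissues, hepatic/renal clearances and the three first-order GI rate constants
(gastric emptying Kst, intestinal absorption Ka, fecal loss Kgut) — live in
:class:`DrugParams`.

``resolve`` turns the fractional description into absolute volumes (L) and
flows (L/h) for a given animal, which is what the mass-balance core consumes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

log = logging.getLogger(__name__)

#: organs with an explicit mass fraction (Table-3 style inventory)
MASS_ORGANS = (
    "liver", "kidney", "muscle", "lungs", "fat", "brain", "spleen", "heart",
    "rest",
)
#: perfused compartments carrying a flow fraction of cardiac output
FLOW_ORGANS = ("liver", "kidney", "muscle", "fat", "heart", "rest")
#: tissues modelled with a vascular/cellular split and a permeability barrier
MEMBRANE_TISSUES = ("muscle", "fat", "brain", "rest")
#: flow-limited solid tissues (venous blood leaves at C/P equilibrium)
FLOW_LIMITED_TISSUES = ("liver", "spleen", "kidney", "heart", "lung")

PARTITION_TISSUES = (
    "liver", "kidney", "spleen", "heart", "lung", "muscle", "fat", "brain",
    "rest",
)


class ValidationError(ValueError):
    """A parameter violated one of its documented bounds."""


class ConfigError(ValueError):
    """A configuration file could not be parsed or is structurally wrong."""


def _check_fraction(name: str, value: float, *, closed_top: bool = False) -> None:
    top_ok = value <= 1.0 if closed_top else value < 1.0
    if not (0.0 < value and top_ok):
        bound = "(0, 1]" if closed_top else "(0, 1)"
        raise ValidationError(f"{name} = {value!r} must lie in {bound}")


@dataclass(frozen=True)
class PhysioProfile:
    """Anatomy and physiology of the animal, in fractional form.

    ``organ_flow_fraction`` carries the classic flow table (liver entry =
    *total* hepatic inflow, portal plus arterial); brain and spleen perfusion
    are absent from that table and are supplied separately: the brain fraction
    is carved out of the remaining-tissue fraction and the spleen fraction out
    of the hepatic total, so that perfused flows still sum to cardiac output.
    """

    body_mass: float = 30.0                  # kg
    cardiac_output: float = 5.97             # L/h per kg BW
    organ_mass_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "liver": 0.0129, "kidney": 0.0031, "muscle": 0.3527, "lungs": 0.0078,
        "fat": 0.0274, "brain": 0.0032, "spleen": 0.0028, "heart": 0.0035,
        "rest": 0.5866,
    })
    organ_flow_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "liver": 0.4832, "kidney": 0.1705, "muscle": 0.14, "fat": 0.085,
        "heart": 0.0498, "rest": 0.0715,
    })
    brain_flow_fraction: float = 0.02        # of cardiac output, taken from rest
    spleen_flow_fraction: float = 0.02       # of cardiac output, within liver total
    blood_volume_fraction: float = 0.07      # of BW, taken from rest mass
    arterial_fraction: float = 1.0 / 3.0     # of blood volume
    tissue_blood_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "muscle": 0.04, "fat": 0.02, "brain": 0.04, "rest": 0.04,
    })
    hematocrit: float = 0.30                 # packed cell volume, dimensionless
    blood_plasma_ratio: float = 1.0          # venous blood : plasma concentration

    def __post_init__(self) -> None:
        if self.body_mass <= 0:
            raise ValidationError(f"body_mass = {self.body_mass!r} must be > 0")
        if self.cardiac_output <= 0:
            raise ValidationError(
                f"cardiac_output = {self.cardiac_output!r} must be > 0")
        missing = set(MASS_ORGANS) - set(self.organ_mass_fraction)
        if missing:
            raise ValidationError(f"organ_mass_fraction missing {sorted(missing)}")
        missing = set(FLOW_ORGANS) - set(self.organ_flow_fraction)
        if missing:
            raise ValidationError(f"organ_flow_fraction missing {sorted(missing)}")
        for name, value in self.organ_mass_fraction.items():
            _check_fraction(f"organ_mass_fraction[{name}]", value)
        for name, value in self.organ_flow_fraction.items():
            _check_fraction(f"organ_flow_fraction[{name}]", value)
        for name, value in self.tissue_blood_fraction.items():
            _check_fraction(f"tissue_blood_fraction[{name}]", value)
        for name in ("brain_flow_fraction", "spleen_flow_fraction",
                     "blood_volume_fraction", "arterial_fraction",
                     "hematocrit"):
            _check_fraction(name, getattr(self, name))
        if self.blood_plasma_ratio <= 0:
            raise ValidationError("blood_plasma_ratio must be > 0")
        mass_sum = sum(self.organ_mass_fraction.values())
        if mass_sum > 1.0 + 1e-9:
            raise ValidationError(
                f"organ mass fractions sum to {mass_sum:.6f} > 1")
        if self.blood_volume_fraction >= self.organ_mass_fraction["rest"]:
            raise ValidationError(
                "blood_volume_fraction must be smaller than the remaining-"
                "tissue mass fraction it is carved from")
        if self.spleen_flow_fraction >= self.organ_flow_fraction["liver"]:
            raise ValidationError(
                "spleen_flow_fraction must be below the total hepatic inflow "
                f"fraction {self.organ_flow_fraction['liver']!r}")
        if self.brain_flow_fraction >= self.organ_flow_fraction["rest"]:
            raise ValidationError(
                "brain_flow_fraction must be below the remaining-tissue flow "
                "fraction it is carved from")
        # brain flow is carved out of 'rest', so the carve-out preserves the
        # total: the table itself must sum to 1 for perfusion to balance
        flow_sum = sum(self.organ_flow_fraction.values())
        if abs(flow_sum - 1.0) > 1e-9:
            raise ValidationError(
                f"perfused flow fractions sum to {flow_sum:.9f}, expected 1 "
                "(brain flow is carved out of 'rest', so the table itself "
                "must total 100%)")


@dataclass(frozen=True)
class DrugParams:
    """Ractopamine-specific constants (partition, permeability, clearance,
    GI kinetics, plasma free fraction)."""

    partition: Mapping[str, float] = field(default_factory=lambda: {
        "liver": 2.5584, "kidney": 1.7734, "spleen": 1.0047, "heart": 1.3839,
        "lung": 1.5333, "muscle": 1.0686, "fat": 0.7526, "brain": 0.6896,
        "rest": 9.0888,
    })
    permeability_fraction: Mapping[str, float] = field(default_factory=lambda: {
        "muscle": 0.0271, "fat": 0.0054, "brain": 0.0068, "rest": 0.0021,
    })
    cl_hepatic: float = 0.0624     # L/h per kg BW
    cl_renal: float = 0.0001       # L/h per kg BW
    k_stomach: float = 0.0910      # 1/h, gastric emptying
    k_absorption: float = 0.9861   # 1/h, intestinal absorption
    k_gut: float = 0.9016          # 1/h, fecal loss from intestine
    free_fraction: float = 1.0     # unbound plasma fraction for elimination
    permeability_absolute: bool = False  # interpret fractions as L/h/kg if True

    def __post_init__(self) -> None:
        missing = set(PARTITION_TISSUES) - set(self.partition)
        if missing:
            raise ValidationError(f"partition missing {sorted(missing)}")
        missing = set(MEMBRANE_TISSUES) - set(self.permeability_fraction)
        if missing:
            raise ValidationError(
                f"permeability_fraction missing {sorted(missing)}")
        for name, value in self.partition.items():
            if value <= 0:
                raise ValidationError(f"partition[{name}] = {value!r} must be > 0")
        for name, value in self.permeability_fraction.items():
            if value < 0:
                raise ValidationError(
                    f"permeability_fraction[{name}] = {value!r} must be >= 0")
        for name in ("cl_hepatic", "cl_renal", "k_stomach", "k_absorption",
                     "k_gut"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        _check_fraction("free_fraction", self.free_fraction, closed_top=True)

    def replace(self, **changes: object) -> "DrugParams":
        return dataclasses.replace(self, **changes)

    def get_param(self, path: str) -> float:
        """Read a scalar by dotted path, e.g. ``partition.liver`` or ``k_absorption``."""
        head, _, tail = path.partition(".")
        value = getattr(self, head)
        if tail:
            value = value[tail]
        return float(value)

    def set_param(self, path: str, value: float) -> "DrugParams":
        """Return a copy with the scalar at ``path`` replaced."""
        head, _, tail = path.partition(".")
        if tail:
            mapping = dict(getattr(self, head))
            if tail not in mapping:
                raise KeyError(f"unknown parameter {path!r}")
            mapping[tail] = float(value)
            return self.replace(**{head: mapping})
        if not hasattr(self, head):
            raise KeyError(f"unknown parameter {path!r}")
        return self.replace(**{head: float(value)})


@dataclass(frozen=True)
class DoseEvent:
    """A bolus administration: oral boluses land in gastric contents, IV
    boluses in venous blood.  ``amount`` is the absolute dose in μg."""

    time: float          # h
    route: str           # "oral" | "iv"
    amount: float        # μg

    def __post_init__(self) -> None:
        if self.route not in ("oral", "iv"):
            raise ValidationError(f"unknown route {self.route!r}")
        if self.time < 0:
            raise ValidationError("dose time must be >= 0")
        if self.amount < 0:
            raise ValidationError("dose amount must be >= 0")


def daily_oral_regimen(dose_mg_per_kg: float, body_mass: float,
                       n_days: int) -> list[DoseEvent]:
    """One oral gavage every 24 h for ``n_days`` days (μg resolved from mg/kg)."""
    amount = dose_mg_per_kg * body_mass * 1000.0
    return [DoseEvent(time=24.0 * d, route="oral", amount=amount)
            for d in range(n_days)]


@dataclass(frozen=True)
class AbsolutePhysiology:
    """Volumes (L) and flows (L/h) for a concrete animal.

    ``flows['lung']`` equals the summed perfused flows (venous return), which
    is the mass-balance precondition for the circulation loop.  For the
    membrane-limited tissues the vascular sub-volume is
    ``tissue_blood_fraction × V`` and the cellular sub-volume the remainder.
    """

    body_mass: float
    volumes: Mapping[str, float]        # per tissue, plus arterial/venous blood
    flows: Mapping[str, float]          # per perfused compartment, plus lung/spleen
    blood_sub_volume: Mapping[str, float]
    tissue_sub_volume: Mapping[str, float]
    hematocrit: float
    blood_plasma_ratio: float


def resolve(profile: PhysioProfile) -> AbsolutePhysiology:
    """Turn fractions into absolute volumes and flows (density 1 kg/L).

    The remaining-tissue compartment donates the blood volume (mass side) and
    the brain perfusion (flow side); the spleen draws its flow from the total
    hepatic inflow, mirroring its anatomical drainage through the liver.
    """
    bw = profile.body_mass
    co = profile.cardiac_output * bw  # L/h

    volumes = {organ: frac * bw
               for organ, frac in profile.organ_mass_fraction.items()}
    volumes["lung"] = volumes.pop("lungs")
    volumes["rest"] -= profile.blood_volume_fraction * bw
    blood = profile.blood_volume_fraction * bw
    volumes["arterial_blood"] = profile.arterial_fraction * blood
    volumes["venous_blood"] = (1.0 - profile.arterial_fraction) * blood

    flows = {organ: frac * co
             for organ, frac in profile.organ_flow_fraction.items()}
    flows["rest"] -= profile.brain_flow_fraction * co
    flows["brain"] = profile.brain_flow_fraction * co
    flows["spleen"] = profile.spleen_flow_fraction * co
    # venous return: everything that perfuses a tissue comes back through the
    # lung; the spleen is inside the hepatic total, so it is not re-added
    flows["lung"] = sum(flows[o] for o in
                        ("liver", "kidney", "muscle", "fat", "heart", "brain",
                         "rest"))

    blood_sub = {t: profile.tissue_blood_fraction[t] * volumes[t]
                 for t in MEMBRANE_TISSUES}
    tissue_sub = {t: volumes[t] - blood_sub[t] for t in MEMBRANE_TISSUES}
    return AbsolutePhysiology(
        body_mass=bw, volumes=volumes, flows=flows,
        blood_sub_volume=blood_sub, tissue_sub_volume=tissue_sub,
        hematocrit=profile.hematocrit,
        blood_plasma_ratio=profile.blood_plasma_ratio,
    )


# --- configuration file handling -------------------------------------------

_PHYSIO_KEYS = {f.name for f in dataclasses.fields(PhysioProfile)}
_DRUG_KEYS = {f.name for f in dataclasses.fields(DrugParams)}

DEFAULT_CONFIG = Path(__file__).parent / "data" / "goat_default.yaml"


def load_config(path: str | Path | None = None) -> tuple[PhysioProfile, DrugParams]:
    """Load and validate a YAML configuration.

    The file has two top-level sections, ``physiology`` and ``drug``.  Any
    key left out falls back to the documented default and is reported through
    the ``racpbpk`` logger, so a run log always shows which values were
    assumed rather than configured.
    """
    path = Path(path) if path is not None else DEFAULT_CONFIG
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(raw) - {"physiology", "drug"}
    if unknown:
        raise ConfigError(f"{path}: unknown sections {sorted(unknown)}")

    def build(cls, section: str, known: set[str]):
        data = raw.get(section) or {}
        bad = set(data) - known
        if bad:
            raise ConfigError(f"{path}: unknown {section} keys {sorted(bad)}")
        for key in sorted(known - set(data)):
            default = getattr(cls(), key)
            log.info("config %s: %s.%s not set, using default %r",
                     path.name, section, key, default)
        return cls(**data)

    return (build(PhysioProfile, "physiology", _PHYSIO_KEYS),
            build(DrugParams, "drug", _DRUG_KEYS))


def save_config(path: str | Path, profile: PhysioProfile,
                drug: DrugParams) -> None:
    """Serialize a configuration; ``load_config`` of the result round-trips
    every value bit-exactly (floats written with full repr precision)."""
    def plain(obj):
        out = {}
        for f in dataclasses.fields(obj):
            value = getattr(obj, f.name)
            out[f.name] = dict(value) if isinstance(value, Mapping) else value
        return out

    payload = {"physiology": plain(profile), "drug": plain(drug)}
    Path(path).write_text(
        yaml.safe_dump(payload, sort_keys=True, default_flow_style=False))
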