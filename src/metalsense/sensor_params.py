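"""Sensor thermodynamic parameters and the coupling-free-energy calculus.

Each metalloregulator (Zur, ZntR, RcnR, FrmR, FrmR^E64H) is described by its
metal dissociation constants, apo- and metalated-sensor DNA dissociation
constants, cellular abundance of the functional assembly (dimer or
tetramer), the number of operator–promoter targets per cell, and its
regulatory mode.  Affinity values may be exact or bound-flagged (a ">=" or
"<=" limit from the underlying titration); bounds are carried through for
reporting but used as point estimates in computation.

The allosteric coupling free energy

    dG_C = R * T * ln(Kd_holo / Kd_apo)

is negative when metal binding tightens DNA binding (co-repression) and
positive when it weakens DNA binding (de-repression).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

__all__ = [
    "AVOGADRO",
    "R_KCAL",
    "STANDARD_TEMPERATURE_K",
    "CELL_VOLUME_L",
    "Bound",
    "AffinityConstant",
    "CellContext",
    "SensorParams",
    "RegistrySchemaError",
    "load_sensor_registry",
    "packaged_registry_path",
    "copies_to_concentration",
    "coupling_free_energy",
    "average_affinity",
    "estimate_missing_holo_dna_kd",
]

AVOGADRO = 6.02214076e23  # per mol
R_KCAL = 1.98720e-3  # kcal / (mol K)
STANDARD_TEMPERATURE_K = 298.15
CELL_VOLUME_L = 1e-15  # 1 fl bacterial cell volume


class RegistrySchemaError(ValueError):
    """Raised when a registry file is missing or malforms a required field."""


# bound semantics: "lower" means the true Kd is at least the stated value
# (affinity determination hit a weak-binding limit), "upper" the converse.
Bound = str
_BOUNDS = ("exact", "lower", "upper")
_MODES = ("co_repressor", "de_repressor", "activator")
_ASSEMBLIES = ("dimer", "tetramer")


@dataclass(frozen=True)
class AffinityConstant:
    """A dissociation constant in molar, with bound flag and optional s.d."""

    kd: float
    bound: Bound = "exact"
    sd: float | None = None

    def __post_init__(self) -> None:
        if not (self.kd > 0.0):
            raise ValueError(f"dissociation constant must be > 0, got {self.kd}")
        if self.bound not in _BOUNDS:
            raise ValueError(f"bound must be one of {_BOUNDS}, got {self.bound!r}")
        if self.sd is not None and not (self.sd >= 0.0):
            raise ValueError(f"sd must be >= 0, got {self.sd}")

    @property
    def k_assoc(self) -> float:
        """The corresponding association constant (per molar)."""
        return 1.0 / self.kd

    def to_json(self) -> dict:
        return {"kd_M": self.kd, "bound": self.bound, "sd_M": self.sd}

    @classmethod
    def from_json(cls, obj: dict, where: str = "affinity") -> "AffinityConstant":
        if not isinstance(obj, dict) or "kd_M" not in obj:
            raise RegistrySchemaError(f"{where}: expected an object with 'kd_M'")
        try:
            return cls(
                kd=float(obj["kd_M"]),
                bound=obj.get("bound", "exact"),
                sd=None if obj.get("sd_M") is None else float(obj["sd_M"]),
            )
        except ValueError as exc:
            raise RegistrySchemaError(f"{where}: {exc}") from exc


@dataclass(frozen=True)
class CellContext:
    """Cell volume and temperature used for copies→molar and dG conversions."""

    volume: float = CELL_VOLUME_L  # litres
    temperature: float = STANDARD_TEMPERATURE_K  # kelvin

    def __post_init__(self) -> None:
        if not (self.volume > 0.0):
            raise ValueError("cell volume must be > 0")
        if not (self.temperature > 0.0):
            raise ValueError("temperature must be > 0")


@dataclass
class SensorParams:
    """Full thermodynamic description of one sensor."""

    name: str
    assembly: str  # dimer | tetramer
    abundance: float  # assemblies per cell
    dna_targets: int  # operator-promoter copies per cell
    mode: str  # co_repressor | de_repressor | activator
    metal_kd: dict[str, AffinityConstant]
    apo_dna_kd: AffinityConstant
    holo_dna_kd: dict[str, AffinityConstant]
    abundance_sd: float | None = None
    notes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assembly not in _ASSEMBLIES:
            raise RegistrySchemaError(
                f"sensor {self.name!r}: assembly must be one of {_ASSEMBLIES}"
            )
        if self.mode not in _MODES:
            raise RegistrySchemaError(f"sensor {self.name!r}: mode must be one of {_MODES}")
        if not (self.abundance >= 0.0):
            raise RegistrySchemaError(f"sensor {self.name!r}: abundance must be >= 0")
        if self.dna_targets < 1:
            raise RegistrySchemaError(f"sensor {self.name!r}: dna_targets must be >= 1")
        missing = set(self.holo_dna_kd) - set(self.metal_kd)
        if missing:
            raise RegistrySchemaError(
                f"sensor {self.name!r}: holo_dna_kd metals {sorted(missing)} "
                "have no matching metal_kd entry"
            )

    @property
    def metals(self) -> list[str]:
        return sorted(self.holo_dna_kd)


_REQUIRED_FIELDS = (
    "name",
    "assembly",
    "abundance",
    "dna_targets",
    "mode",
    "metal_kd",
    "apo_dna_kd",
    "holo_dna_kd",
)


def _sensor_from_json(obj: dict) -> SensorParams:
    name = obj.get("name", "<unnamed>")
    for f_ in _REQUIRED_FIELDS:
        if f_ not in obj:
            raise RegistrySchemaError(f"sensor {name!r}: missing required field {f_!r}")
    metal_kd = {
        m: AffinityConstant.from_json(v, f"sensor {name!r} metal_kd[{m}]")
        for m, v in obj["metal_kd"].items()
    }
    holo = {
        m: AffinityConstant.from_json(v, f"sensor {name!r} holo_dna_kd[{m}]")
        for m, v in obj["holo_dna_kd"].items()
    }
    return SensorParams(
        name=obj["name"],
        assembly=obj["assembly"],
        abundance=float(obj["abundance"]),
        dna_targets=int(obj["dna_targets"]),
        mode=obj["mode"],
        metal_kd=metal_kd,
        apo_dna_kd=AffinityConstant.from_json(obj["apo_dna_kd"], f"sensor {name!r} apo_dna_kd"),
        holo_dna_kd=holo,
        abundance_sd=None if obj.get("abundance_sd") is None else float(obj["abundance_sd"]),
        notes=obj.get("notes", {}),
    )


def load_sensor_registry(source: str | Path) -> list[SensorParams]:
    """Load and validate a JSON sensor registry.

    The file is a JSON array of sensor objects (see the packaged
    ``data/sensor_registry.json`` for the reference layout).  All
    dissociation constants are stated in molar (``kd_M``).
    """
    path = Path(source)
    try:
        raw = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise RegistrySchemaError(f"registry {path}: not valid JSON ({exc})") from exc
    if isinstance(raw, dict) and "sensors" in raw:
        raw = raw["sensors"]
    if not isinstance(raw, list) or not raw:
        raise RegistrySchemaError(f"registry {path}: expected a non-empty list of sensors")
    return [_sensor_from_json(obj) for obj in raw]


def packaged_registry_path() -> Path:
    """Path to the packaged sensor registry fixture."""
    return Path(str(resources.files("metalsense").joinpath("data/sensor_registry.json")))


def copies_to_concentration(copies: float, cell: CellContext = CellContext()) -> float:
    """Convert copies per cell to a molar concentration: copies / (N_A * V)."""
    if copies < 0:
        raise ValueError("copies must be >= 0")
    return copies / (AVOGADRO * cell.volume)


def coupling_free_energy(
    apo_dna_kd: float | AffinityConstant,
    holo_dna_kd: float | AffinityConstant,
    temperature: float = STANDARD_TEMPERATURE_K,
) -> float | tuple[float, Bound]:
    """Allosteric coupling free energy dG_C = R*T*ln(Kd_holo/Kd_apo), kcal/mol.

    Accepts bare floats (returns a float) or :class:`AffinityConstant`
    values, in which case a ``(value, bound)`` pair is returned with the
    bound flag propagated: a lower-bounded apo Kd (DNA binding at least
    this weak) with an exact holo Kd makes dG_C an upper bound, and
    vice versa.
    """
    flagged = isinstance(apo_dna_kd, AffinityConstant) or isinstance(
        holo_dna_kd, AffinityConstant
    )
    apo = apo_dna_kd.kd if isinstance(apo_dna_kd, AffinityConstant) else float(apo_dna_kd)
    holo = holo_dna_kd.kd if isinstance(holo_dna_kd, AffinityConstant) else float(holo_dna_kd)
    if not (apo > 0.0 and holo > 0.0):
        raise ValueError("dissociation constants must be > 0")
    if not (temperature > 0.0):
        raise ValueError("temperature must be > 0")
    value = R_KCAL * temperature * math.log(holo / apo)
    if not flagged:
        return value
    apo_b = apo_dna_kd.bound if isinstance(apo_dna_kd, AffinityConstant) else "exact"
    holo_b = holo_dna_kd.bound if isinstance(holo_dna_kd, AffinityConstant) else "exact"
    # dG rises with holo Kd and falls with apo Kd
    contrib = {
        ("exact", "exact"): "exact",
        ("lower", "exact"): "upper",  # apo at least this weak => dG at most this
        ("upper", "exact"): "lower",
        ("exact", "lower"): "lower",
        ("exact", "upper"): "upper",
        ("lower", "lower"): "exact",  # conflicting limits: report as point value
        ("upper", "upper"): "exact",
        ("lower", "upper"): "upper",
        ("upper", "lower"): "lower",
    }[(apo_b, holo_b)]
    return value, contrib


def average_affinity(kds: Iterable[float]) -> float:
    """Arithmetic mean of dissociation constants (molar).

    Used where per-metal DNA affinities agree within error and a single
    combined value drives the occupancy model.
    """
    values = [float(k) for k in kds]
    if not values:
        raise ValueError("cannot average an empty list of affinities")
    if any(v <= 0 for v in values):
        raise ValueError("all dissociation constants must be > 0")
    return sum(values) / len(values)


def estimate_missing_holo_dna_kd(
    base_kd: float, ratio_numerator_kd: float, ratio_denominator_kd: float
) -> float:
    """Scale a known Kd by a fold-difference taken from a homologous pair.

    ``base_kd * (ratio_numerator_kd / ratio_denominator_kd)`` — e.g. the
    Co(II)-FrmR DNA affinity estimated from Zn(II)-FrmR and the Co/Zn
    fold-difference of the FrmR^E64H variant.
    """
    if not (base_kd > 0 and ratio_numerator_kd > 0 and ratio_denominator_kd > 0):
        raise ValueError("all dissociation constants must be > 0")
    return base_kd * (ratio_numerator_kd / ratio_denominator_kd)
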