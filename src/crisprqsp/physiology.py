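"""Species physiology: compartment volumes, plasma flows, lymph flows.

Volumes and flows for the three bundled species are reconstructed reference
values (plasma volume ~4.9% of body weight, standard hepatic/renal plasma
flows); every entry can be overridden from a user config file.  Body weights
are the ones the model was parameterised at: 28 g mouse, 5 kg NHP, 71 kg
human.  Lymph flow of every organ is a fixed 0.2% of its plasma flow.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

SPECIES = ("mouse", "nhp", "human")

_ORGAN_FLOWS = {"liver": "Q_liver", "kidney": "Q_kidney", "remainder": "Q_remainder"}


@dataclass(frozen=True)
class SpeciesPhysiology:
    """Physiological constants for one species.

    Units: BW in kg, volumes in mL, flows in mL/h. ``sigma_V`` and
    ``sigma_I`` are the vascular and interstitial reflection coefficients
    (dimensionless, in [0, 1]); ``lymph_fraction`` is the organ lymph flow
    expressed as a fraction of the organ plasma flow.
    """

    species_id: str
    BW: float
    V_plasma: float
    V_liver_vasc: float
    V_liver_int: float
    V_liver_cell: float
    V_kidney: float
    V_remainder: float
    Q_liver: float
    Q_kidney: float
    Q_remainder: float
    lymph_fraction: float = 0.002
    sigma_V: float = 0.95
    sigma_I: float = 0.20

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if f.name in ("species_id",):
                continue
            value = getattr(self, f.name)
            if not isinstance(value, (int, float)) or not value == value:
                raise ValueError(f"{f.name} must be a finite number, got {value!r}")
        positive = (
            "BW",
            "V_plasma",
            "V_liver_vasc",
            "V_liver_int",
            "V_liver_cell",
            "V_kidney",
            "V_remainder",
            "Q_liver",
            "Q_kidney",
            "Q_remainder",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        for name in ("sigma_V", "sigma_I"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.lymph_fraction < 1.0:
            raise ValueError(f"lymph_fraction must lie in [0, 1), got {self.lymph_fraction}")

    @property
    def V_liver(self) -> float:
        """Total liver volume (mL): the single source of truth is the sub-compartment sum."""
        return self.V_liver_vasc + self.V_liver_int + self.V_liver_cell

    def replace(self, **kwargs) -> "SpeciesPhysiology":
        return dataclasses.replace(self, **kwargs)


def _field_names() -> set[str]:
    return {f.name for f in dataclasses.fields(SpeciesPhysiology)}


def _from_mapping(raw: dict, source: str) -> SpeciesPhysiology:
    if not isinstance(raw, dict):
        raise ValueError(f"physiology config {source} must be a mapping")
    known = _field_names()
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown physiology keys in {source}: {sorted(unknown)}")
    missing = {n for n in known if n not in raw} - {"lymph_fraction", "sigma_V", "sigma_I"}
    if missing:
        raise ValueError(f"missing physiology keys in {source}: {sorted(missing)}")
    return SpeciesPhysiology(**raw)


def load_physiology(species_or_path: str | Path) -> SpeciesPhysiology:
    """Load physiology for a bundled species id or from a YAML config file.

    Raises ``ValueError`` for an unknown species id and propagates validation
    errors (non-positive volumes/flows, out-of-range reflection coefficients)
    from user configs.
    """
    key = str(species_or_path)
    if key in SPECIES:
        text = resources.files("crisprqsp.data").joinpath(f"physiology_{key}.yaml").read_text()
        return _from_mapping(yaml.safe_load(text), f"bundled:{key}")
    path = Path(species_or_path)
    if path.exists():
        return _from_mapping(yaml.safe_load(path.read_text()), str(path))
    raise ValueError(f"unknown species id or missing config file: {species_or_path!r} (bundled: {SPECIES})")


def lymph_flow(phys: SpeciesPhysiology, organ: str) -> float:
    """Lymph flow of ``organ`` in mL/h: ``lymph_fraction`` x organ plasma flow."""
    try:
        q_name = _ORGAN_FLOWS[organ]
    except KeyError:
        raise ValueError(f"unknown organ {organ!r}; expected one of {sorted(_ORGAN_FLOWS)}") from None
    return phys.lymph_fraction * getattr(phys, q_name)
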