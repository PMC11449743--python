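"""Dose regimens and interspecies scaling.

A regimen splits the total-RNA dose into its sgRNA (33.3%) and mRNA (66.7%)
components, derives the co-dosed LNP lipid mass from an LNP-to-total-RNA
mass ratio (default 18.5), and supports bolus or constant-rate short
infusions (default 2 h).  Rate constants can be scaled across species by a
body-weight power law.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from crisprqsp.physiology import SpeciesPhysiology

COMPONENTS = ("sgRNA", "mRNA", "LNP")

_FRAC_TOL = 1e-3  # accommodates the rounded 33.3/66.7 split


@dataclass(frozen=True)
class DoseRegimen:
    """A single-administration dose regimen.

    ``total_rna_mgkg`` is total RNA in mg/kg; absolute component amounts are
    exposed in ug.  ``lnp_dose_mgkg`` overrides the ratio-derived LNP dose
    for study arms whose printed LNP dose does not follow the 18.5 ratio.
    """

    total_rna_mgkg: float
    BW: float
    frac_sgRNA: float = 0.333
    frac_mRNA: float = 0.667
    lnp_ratio: float = 18.5
    route: str = "bolus"
    infusion_duration: float = 2.0
    lnp_dose_mgkg: float | None = None

    def __post_init__(self) -> None:
        if self.total_rna_mgkg < 0:
            raise ValueError(f"negative dose: {self.total_rna_mgkg}")
        if self.BW <= 0:
            raise ValueError(f"non-positive body weight: {self.BW}")
        for name in ("frac_sgRNA", "frac_mRNA"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if abs(self.frac_sgRNA + self.frac_mRNA - 1.0) > _FRAC_TOL:
            raise ValueError(
                f"frac_sgRNA + frac_mRNA must equal 1 within {_FRAC_TOL}, "
                f"got {self.frac_sgRNA + self.frac_mRNA}"
            )
        if self.lnp_ratio < 0:
            raise ValueError(f"negative lnp_ratio: {self.lnp_ratio}")
        if self.route not in ("bolus", "infusion"):
            raise ValueError(f"route must be 'bolus' or 'infusion', got {self.route!r}")
        if self.route == "infusion" and self.infusion_duration <= 0:
            raise ValueError(f"infusion_duration must be > 0, got {self.infusion_duration}")
        if self.lnp_dose_mgkg is not None and self.lnp_dose_mgkg < 0:
            raise ValueError(f"negative LNP dose override: {self.lnp_dose_mgkg}")

    # --- derived absolute amounts (ug) ---------------------------------
    @property
    def amount_total_rna(self) -> float:
        return self.total_rna_mgkg * self.BW * 1000.0

    @property
    def amount_sgRNA(self) -> float:
        return self.amount_total_rna * self.frac_sgRNA

    @property
    def amount_mRNA(self) -> float:
        return self.amount_total_rna * self.frac_mRNA

    @property
    def lnp_mgkg(self) -> float:
        if self.lnp_dose_mgkg is not None:
            return self.lnp_dose_mgkg
        return self.total_rna_mgkg * self.lnp_ratio

    @property
    def amount_LNP(self) -> float:
        return self.lnp_mgkg * self.BW * 1000.0

    def amount(self, component: str) -> float:
        if component not in COMPONENTS:
            raise ValueError(f"unknown component {component!r}; expected one of {COMPONENTS}")
        return {"sgRNA": self.amount_sgRNA, "mRNA": self.amount_mRNA, "LNP": self.amount_LNP}[component]

    def replace(self, **kwargs) -> "DoseRegimen":
        return dataclasses.replace(self, **kwargs)


def build_regimen(
    total_rna_mgkg: float,
    phys: SpeciesPhysiology,
    route: str = "bolus",
    **overrides,
) -> DoseRegimen:
    """Build a :class:`DoseRegimen` for a species.

    ``overrides`` may set frac_sgRNA, frac_mRNA, lnp_ratio, lnp_dose_mgkg
    and infusion_duration.
    """
    allowed = {"frac_sgRNA", "frac_mRNA", "lnp_ratio", "lnp_dose_mgkg", "infusion_duration"}
    unknown = set(overrides) - allowed
    if unknown:
        raise ValueError(f"unknown regimen overrides: {sorted(unknown)}")
    return DoseRegimen(total_rna_mgkg=total_rna_mgkg, BW=phys.BW, route=route, **overrides)


def infusion_input(regimen: DoseRegimen, t: float, component: str) -> float:
    """Zero-order input rate (ug/h) of ``component`` at time ``t`` (h).

    Bolus regimens are placed in plasma as an initial condition, so the rate
    is identically zero.  Infusions deliver amount/duration on
    [0, duration) and zero afterwards; the time integral equals the dose.
    """
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t}")
    amount = regimen.amount(component)
    if regimen.route == "bolus":
        return 0.0
    if 0.0 <= t < regimen.infusion_duration:
        return amount / regimen.infusion_duration
    return 0.0


def scale_allometric(value_ref: float, bw_ref: float, bw_target: float, exponent: float = -0.25) -> float:
    """Power-law body-weight scaling: value_ref x (bw_target/bw_ref)**exponent."""
    if bw_ref <= 0 or bw_target <= 0:
        raise ValueError(f"body weights must be positive, got {bw_ref}, {bw_target}")
    return value_ref * (bw_target / bw_ref) ** exponent
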