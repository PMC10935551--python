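"""Estimated weekly methylmercury intake (EWI) and hazard quotient (HQ).

For a consumer with body weight W (kg) eating WI kg of a seafood item per
week at muscle concentration AC (µg kg⁻¹), the weekly intake per kg body
weight is

    EWI = AC · mehg · F · WI · AB · Frac / W        [µg kg⁻¹ bw week⁻¹]

where ``mehg`` is the methylmercury share of muscle total mercury (95 %
for fish, 30 % for zooplankton-type and 15 % for phytoplankton-type
items), ``F`` the bioaccessible fraction released from the food matrix,
``AB`` the stomach epithelial absorption rate (79 %) and ``Frac`` the
share of the item coming from the source considered. Seafood is split
into three food groups (oily fish, white fish, shellfish); a group's
weekly intake is divided evenly over the species in the group, the
North-Sea share of each species carries the scenario concentration while
the imported share carries the status-quo (ES A) concentration, and the
three group totals add up to the weekly EWI.

The EWI is screened against the tolerable weekly intake of 1.3 µg kg⁻¹ bw
week⁻¹, and the hazard quotient divides the weekly exposure dose by the
EPA reference dose (0.0001 mg kg⁻¹ d⁻¹, i.e. 0.0007 mg kg⁻¹ week⁻¹);
HQ ≤ 1 means adverse effects are not expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConsumerProfile",
    "RiskParams",
    "SpeciesExposure",
    "EwiResult",
    "ExposureError",
    "FOOD_GROUPS",
    "ewi_species",
    "ewi_food_group",
    "ewi_total",
    "hazard_quotient",
    "weekly_rfc_from_daily",
    "read_profiles_csv",
    "write_profiles_csv",
]

FOOD_GROUPS = ("oily_fish", "white_fish", "shellfish")
REGIMES = ("NHS", "NDNS")

#: Tolerable weekly intake for methylmercury, µg per kg bw per week.
TWI_UG_PER_KG_BW_WEEK = 1.3
#: EPA reference dose, mg per kg bw per day.
RFC_DAILY_MG_PER_KG = 0.0001


class ExposureError(ValueError):
    """Invalid exposure inputs."""


def weekly_rfc_from_daily(rfc_daily_mg_per_kg: float = RFC_DAILY_MG_PER_KG) -> float:
    """Convert the daily reference dose to its weekly form (×7 days)."""
    if rfc_daily_mg_per_kg <= 0:
        raise ExposureError("reference dose must be positive")
    return rfc_daily_mg_per_kg * 7.0


@dataclass(frozen=True)
class ConsumerProfile:
    """One consumer group under one consumption regime.

    ``weekly_intake_kg`` maps each of the three seafood food groups to the
    kg eaten per week. Regime "NHS" is the dietary recommendation, "NDNS"
    the survey-reported actual consumption.
    """

    label: str
    regime: str
    body_weight_kg: float
    weekly_intake_kg: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "weekly_intake_kg", dict(self.weekly_intake_kg))
        if self.regime not in REGIMES:
            raise ExposureError(f"unknown regime {self.regime!r}")
        if self.body_weight_kg <= 0:
            raise ExposureError(f"{self.label}: body weight must be positive")
        for g, wi in self.weekly_intake_kg.items():
            if g not in FOOD_GROUPS:
                raise ExposureError(f"{self.label}: unknown food group {g!r}")
            if wi < 0:
                raise ExposureError(f"{self.label}: negative weekly intake for {g}")


@dataclass(frozen=True)
class RiskParams:
    """Transfer fractions and thresholds of the intake calculation.

    ``north_sea_fraction`` per food-group category: 21 % of UK fish and
    23 % of UK shellfish are North Sea landings; the imported remainder
    carries the status-quo concentration. ``mehg_fraction_default`` applies
    where no per-species value is given.
    """

    absorption: float = 0.79
    bioaccessibility_default: float = 1.0
    mehg_fraction_default: float = 0.95
    north_sea_fraction: Mapping[str, float] = field(
        default_factory=lambda: {"oily_fish": 0.21, "white_fish": 0.21, "shellfish": 0.23}
    )
    twi: float = TWI_UG_PER_KG_BW_WEEK
    rfc_weekly_mg_per_kg: float = weekly_rfc_from_daily()

    def __post_init__(self) -> None:
        object.__setattr__(self, "north_sea_fraction", dict(self.north_sea_fraction))
        for name, v in (
            ("absorption", self.absorption),
            ("bioaccessibility_default", self.bioaccessibility_default),
            ("mehg_fraction_default", self.mehg_fraction_default),
        ):
            if not 0.0 <= v <= 1.0:
                raise ExposureError(f"{name} must lie in [0, 1]")
        for g, v in self.north_sea_fraction.items():
            if not 0.0 <= v <= 1.0:
                raise ExposureError(f"north-sea fraction for {g} must lie in [0, 1]")
        if self.twi <= 0 or self.rfc_weekly_mg_per_kg <= 0:
            raise ExposureError("TWI and RfC must be positive")


@dataclass(frozen=True)
class SpeciesExposure:
    """Per-species inputs to the food-group intake.

    ``conc_scenario`` and ``conc_background`` are muscle total-mercury
    concentrations (µg kg⁻¹) under the scenario of interest and under the
    status quo; the latter is applied to the imported share.
    """

    species: str
    food_group: str
    conc_scenario_ug_kg: float
    conc_background_ug_kg: float
    bioaccessibility: float | None = None
    mehg_fraction: float | None = None


def ewi_species(
    ac_ug_kg: float,
    bioaccessibility: float,
    weekly_intake_kg: float,
    absorption: float,
    body_weight_kg: float,
    frac: float = 1.0,
    mehg_fraction: float = 1.0,
) -> float:
    """Weekly intake from one item: AC·mehg·F·WI·AB·Frac / W (µg kg⁻¹ bw wk⁻¹)."""
    if body_weight_kg <= 0:
        raise ExposureError("body weight must be positive")
    for name, v in (
        ("AC", ac_ug_kg), ("F", bioaccessibility), ("WI", weekly_intake_kg),
        ("AB", absorption), ("Frac", frac), ("mehg fraction", mehg_fraction),
    ):
        if v < 0:
            raise ExposureError(f"{name} must be nonnegative")
    return ac_ug_kg * mehg_fraction * bioaccessibility * weekly_intake_kg * absorption * frac / body_weight_kg


def ewi_food_group(
    species: Sequence[SpeciesExposure],
    weekly_intake_kg: float,
    body_weight_kg: float,
    params: RiskParams = RiskParams(),
) -> float:
    """Weekly intake from one food group (µg kg⁻¹ bw week⁻¹).

    The group's weekly intake is split evenly over its species; each
    species mixes the North-Sea share (scenario concentration) with the
    imported share (background concentration); species contributions sum.
    """
    if not species:
        raise ExposureError("food group has no species")
    groups = {s.food_group for s in species}
    if len(groups) != 1:
        raise ExposureError(f"species from multiple food groups: {sorted(groups)}")
    group = species[0].food_group
    frac_ns = params.north_sea_fraction.get(group)
    if frac_ns is None:
        raise ExposureError(f"no north-sea fraction configured for {group!r}")
    wi_share = weekly_intake_kg / len(species)
    total = 0.0
    for s in species:
        f = s.bioaccessibility if s.bioaccessibility is not None else params.bioaccessibility_default
        mehg = s.mehg_fraction if s.mehg_fraction is not None else params.mehg_fraction_default
        total += ewi_species(
            s.conc_scenario_ug_kg, f, wi_share, params.absorption,
            body_weight_kg, frac=frac_ns, mehg_fraction=mehg,
        )
        total += ewi_species(
            s.conc_background_ug_kg, f, wi_share, params.absorption,
            body_weight_kg, frac=1.0 - frac_ns, mehg_fraction=mehg,
        )
    return total


@dataclass(frozen=True)
class EwiResult:
    """Combined weekly intake for one consumer profile."""

    label: str
    regime: str
    per_group: Mapping[str, float]
    total: float
    twi_exceeded: bool
    hq: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "per_group", dict(self.per_group))
        if self.total < 0 or self.hq < 0:
            raise ExposureError("EWI and HQ must be nonnegative")


def ewi_total(
    profile: ConsumerProfile,
    species_by_group: Mapping[str, Sequence[SpeciesExposure]],
    params: RiskParams = RiskParams(),
) -> EwiResult:
    """Combine the three seafood food groups into the weekly EWI and HQ."""
    per_group: dict[str, float] = {}
    for g in FOOD_GROUPS:
        if g not in species_by_group or not species_by_group[g]:
            raise ExposureError(f"missing food group {g!r}")
        per_group[g] = ewi_food_group(
            species_by_group[g],
            profile.weekly_intake_kg.get(g, 0.0),
            profile.body_weight_kg,
            params,
        )
    total = float(sum(per_group.values()))
    hq = hazard_quotient(total * 1e-3, params.rfc_weekly_mg_per_kg)
    return EwiResult(
        label=profile.label,
        regime=profile.regime,
        per_group=per_group,
        total=total,
        twi_exceeded=total > params.twi,
        hq=hq,
    )


def hazard_quotient(ed_mg_per_kg_week: float, rfc_weekly_mg_per_kg: float) -> float:
    """HQ = ED / RfC on the weekly scale; ≤ 1 means no adverse effect expected."""
    if rfc_weekly_mg_per_kg <= 0:
        raise ExposureError("RfC must be positive")
    if ed_mg_per_kg_week < 0:
        raise ExposureError("exposure dose must be nonnegative")
    return ed_mg_per_kg_week / rfc_weekly_mg_per_kg


# -- I/O -------------------------------------------------------------------

_PROFILE_COLUMNS = [
    "label", "regime", "body_weight_kg",
    "wi_oily_kg", "wi_white_kg", "wi_shellfish_kg",
]


def write_profiles_csv(profiles: Sequence[ConsumerProfile], path: str | Path) -> None:
    rows = [
        {
            "label": p.label,
            "regime": p.regime,
            "body_weight_kg": p.body_weight_kg,
            "wi_oily_kg": p.weekly_intake_kg.get("oily_fish", 0.0),
            "wi_white_kg": p.weekly_intake_kg.get("white_fish", 0.0),
            "wi_shellfish_kg": p.weekly_intake_kg.get("shellfish", 0.0),
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=_PROFILE_COLUMNS).to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> list[ConsumerProfile]:
    df = pd.read_csv(path)
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ExposureError(f"profiles CSV missing columns: {sorted(missing)}")
    return [
        ConsumerProfile(
            label=str(r["label"]),
            regime=str(r["regime"]),
            body_weight_kg=float(r["body_weight_kg"]),
            weekly_intake_kg={
                "oily_fish": float(r["wi_oily_kg"]),
                "white_fish": float(r["wi_white_kg"]),
                "shellfish": float(r["wi_shellfish_kg"]),
            },
        )
        for _, r in df.iterrows()
    ]
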