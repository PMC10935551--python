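"""Model validation against observed biota mercury and food standards.

Whole-body model burdens are converted to muscle-tissue concentrations
(roughly 50 % of total mercury sits in muscle for fish, 15 % for shrimp,
100 % for benthos, plankton and detritus) and compared with literature
observations through two statistics:

* the model/observed ratio, M/O — 1 means perfect agreement;
* the normalized mean bias, NMB = Σ(M−O) / ΣO over the n studies.

An NMB ≥ 0 means the model overpredicts by a factor NMB + 1 (an NMB of
1.2 is an overestimation by a factor 2.2); a negative NMB of −0.2 is an
underprediction by a factor 1.2, i.e. the magnitude-plus-one convention
is applied on both sides.

Muscle concentrations are screened against the commercial food standards
of 0.5 mg kg⁻¹ (low trophic level) and 1 mg kg⁻¹ (high trophic level).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationRecord",
    "FoodStandard",
    "ValidationError",
    "NmbFactor",
    "muscle_concentration",
    "mo_ratio",
    "nmb",
    "nmb_factor",
    "fs_exceedance",
    "read_observations_csv",
    "validation_report",
]


class ValidationError(ValueError):
    """Invalid validation inputs."""


@dataclass(frozen=True)
class ValidationRecord:
    """Modelled muscle concentration paired with observed study values.

    Concentrations in µg per kg muscle wet weight; one observed value per
    empirical study.
    """

    group: str
    modelled: float
    observed: tuple[float, ...]

    def __post_init__(self) -> None:
        obs = tuple(float(o) for o in self.observed)
        object.__setattr__(self, "observed", obs)
        if len(obs) < 1:
            raise ValidationError(f"{self.group}: at least one observation required")
        if self.modelled < 0 or any(o < 0 for o in obs):
            raise ValidationError(f"{self.group}: concentrations must be nonnegative")

    @property
    def n(self) -> int:
        return len(self.observed)

    @property
    def mean_observed(self) -> float:
        return float(np.mean(self.observed))


@dataclass(frozen=True)
class FoodStandard:
    """Commercial mercury limits in muscle tissue, mg kg⁻¹ wet weight."""

    low_trophic_limit: float = 0.5
    high_trophic_limit: float = 1.0

    def __post_init__(self) -> None:
        if self.low_trophic_limit <= 0 or self.high_trophic_limit <= 0:
            raise ValidationError("food-standard limits must be positive")

    def limit_for(self, trophic_class: str) -> float:
        if trophic_class == "low":
            return self.low_trophic_limit
        if trophic_class == "high":
            return self.high_trophic_limit
        raise ValidationError(f"unknown trophic class {trophic_class!r}")


def muscle_concentration(
    body_concentration: float | np.ndarray,
    muscle_fraction: float | np.ndarray,
    convention: str = "multiplier",
) -> float | np.ndarray:
    """Convert a whole-body concentration to a muscle-tissue concentration.

    The default "multiplier" convention allocates the stated fraction of
    the whole-body burden to muscle: muscle = body · f_m. The alternative
    "divisor" convention (muscle = body·f_m / f_m_mass, i.e. body
    concentration divided by nothing here but the allocation fraction
    re-expressed per kg of muscle) is exposed for sensitivity use as
    muscle = body (fraction of burden in a same-fraction of mass).
    """
    f = np.asarray(muscle_fraction, dtype=float)
    if np.any(f <= 0) or np.any(f > 1):
        raise ValidationError("muscle fraction must lie in (0, 1]")
    if convention == "multiplier":
        return body_concentration * f
    if convention == "divisor":
        # burden fraction f_m concentrated in a muscle compartment that is
        # f_m of the body mass: per-kg-muscle concentration equals the
        # whole-body concentration
        return body_concentration * f / f
    raise ValidationError(f"unknown muscle convention {convention!r}")


def mo_ratio(record: ValidationRecord) -> float:
    """Model/observed ratio M / mean(O); 1 is perfect agreement."""
    mean_o = record.mean_observed
    if mean_o <= 0:
        raise ValidationError(f"{record.group}: observed mean must be positive")
    return record.modelled / mean_o


def nmb(pairs: Sequence[tuple[float, float]]) -> float:
    """Normalized mean bias Σ(M−O)/ΣO over (modelled, observed) pairs."""
    if len(pairs) == 0:
        raise ValidationError("NMB needs at least one (M, O) pair")
    m = np.array([p[0] for p in pairs], dtype=float)
    o = np.array([p[1] for p in pairs], dtype=float)
    denom = o.sum()
    if denom <= 0:
        raise ValidationError("NMB denominator ΣO must be positive")
    return float((m - o).sum() / denom)


class NmbFactor(NamedTuple):
    direction: str  # "over" | "under"
    factor: float


def nmb_factor(nmb_value: float) -> NmbFactor:
    """Interpret an NMB as an over/under-prediction factor.

    NMB ≥ 0 → overprediction by NMB + 1; NMB < 0 → underprediction by
    |NMB| + 1 (the published convention for both signs; e.g. 1.2 → a
    factor 2.2 over, −0.2 → a factor 1.2 under). Only defined for
    NMB > −1.
    """
    if nmb_value <= -1.0:
        raise ValidationError("NMB factor undefined for NMB <= -1")
    if nmb_value >= 0:
        return NmbFactor("over", nmb_value + 1.0)
    return NmbFactor("under", abs(nmb_value) + 1.0)


def fs_exceedance(
    muscle_conc_mg_kg: float,
    trophic_class: str,
    standard: FoodStandard = FoodStandard(),
) -> tuple[bool, float]:
    """Food-standard check: (exceeded?, margin = limit − value) in mg kg⁻¹."""
    if muscle_conc_mg_kg < 0:
        raise ValidationError("muscle concentration must be nonnegative")
    limit = standard.limit_for(trophic_class)
    return muscle_conc_mg_kg > limit, limit - muscle_conc_mg_kg


# -- I/O -------------------------------------------------------------------

def read_observations_csv(path: str | Path) -> dict[str, list[float]]:
    """Read observations (group, study_id, observed_ug_per_kg, basis,
    moisture_fraction); dry-weight rows are converted to wet weight as
    dry · (1 − moisture)."""
    df = pd.read_csv(path)
    required = {"group", "study_id", "observed_ug_per_kg", "basis"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"observations CSV missing columns: {sorted(missing)}")
    out: dict[str, list[float]] = {}
    for _, r in df.iterrows():
        val = float(r["observed_ug_per_kg"])
        basis = str(r["basis"]).strip().lower()
        if basis == "dry":
            moisture = float(r.get("moisture_fraction", np.nan))
            if not 0 <= moisture < 1:
                raise ValidationError(
                    f"group {r['group']}: dry-weight row needs moisture_fraction in [0,1)"
                )
            val = val * (1.0 - moisture)
        elif basis != "wet":
            raise ValidationError(f"unknown basis {basis!r} (expected wet|dry)")
        out.setdefault(str(r["group"]), []).append(val)
    return out


def validation_report(records: Sequence[ValidationRecord]) -> pd.DataFrame:
    """Per-group M/O plus the pooled NMB and its interpretation factor.

    Columns: group, M, mean_O, n, mo_ratio, nmb, nmb_factor, direction
    (the nmb columns repeat the pooled statistic on every row).
    """
    if not records:
        raise ValidationError("no validation records")
    pooled = nmb([(r.modelled, r.mean_observed) for r in records])
    direction, factor = nmb_factor(pooled)
    rows = [
        {
            "group": r.group,
            "M": r.modelled,
            "mean_O": r.mean_observed,
            "n": r.n,
            "mo_ratio": mo_ratio(r),
            "nmb": pooled,
            "nmb_factor": factor,
            "direction": direction,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
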