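"""Static mass-balanced trophic food web.

The food web follows the Ecopath bookkeeping convention: each functional
group *i* carries a biomass density ``B`` (t km⁻², wet weight), a
production/biomass ratio ``PB`` (yr⁻¹), a consumption/biomass ratio ``QB``
(yr⁻¹, zero for producers and detritus) and an ecotrophic efficiency ``EE``
(the fraction of production consumed by predators or removed by fisheries).
Diet composition ``DC[i, j]`` gives the fraction of predator *i*'s
consumption taken from prey *j*; consumer rows sum to one.

The static balance for a living group reads

    B_i * PB_i * EE_i  =  sum_j B_j * QB_j * DC[j, i]  +  Y_i

with ``Y_i`` the fishery removals. Biomass accumulation and net migration
are fixed at zero (closed system, no migration of biota). Flows to detritus
are not tracked in the static balance; the contaminant engine handles the
detrital pool explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FunctionalGroup",
    "FoodWebModel",
    "FoodWebError",
    "consumption_matrix",
    "mass_balance_residuals",
    "trophic_levels",
    "read_foodweb_csv",
    "write_foodweb_csv",
]

GROUP_CLASSES = ("producer", "consumer", "detritus")
TROPHIC_CLASSES = ("low", "high")

#: Diet rows of consumers must sum to one within this tolerance.
DIET_ROW_TOL = 1e-9


class FoodWebError(ValueError):
    """Raised when a food web violates its structural invariants."""


@dataclass(frozen=True)
class FunctionalGroup:
    """One compartment of the trophic model (a species or guild).

    Parameters
    ----------
    name:
        Text label, unique within a web.
    group_class:
        ``"producer"``, ``"consumer"`` or ``"detritus"``.
    biomass:
        Standing stock B, t km⁻² wet weight. Must be positive (the
        contaminant engine divides by it to form body concentrations).
    production_rate:
        P/B, yr⁻¹.
    consumption_rate:
        Q/B, yr⁻¹; zero for producers and detritus.
    ecotrophic_efficiency:
        EE, fraction of production consumed within the system, in [0, 1].
    direct_uptake:
        True only for groups that take mercury up directly from the water
        column (photosynthetic plankton, copepods, euphausiids); all other
        groups accumulate through diet alone.
    muscle_fraction:
        Fraction of the whole-body mercury burden allocated to muscle
        tissue: 0.5 for fish, 0.15 for shrimp-like crustaceans, 1.0 for
        benthos, plankton and detritus.
    trophic_class:
        ``"low"`` or ``"high"`` — selects the applicable food standard.
    commercial:
        Whether the group appears in the landings / dietary-risk layer.
    """

    name: str
    group_class: str
    biomass: float
    production_rate: float
    consumption_rate: float
    ecotrophic_efficiency: float
    direct_uptake: bool = False
    muscle_fraction: float = 1.0
    trophic_class: str = "low"
    commercial: bool = False

    def __post_init__(self) -> None:
        if self.group_class not in GROUP_CLASSES:
            raise FoodWebError(
                f"group {self.name!r}: unknown class {self.group_class!r}"
            )
        if self.trophic_class not in TROPHIC_CLASSES:
            raise FoodWebError(
                f"group {self.name!r}: unknown trophic class {self.trophic_class!r}"
            )
        if not self.biomass > 0:
            raise FoodWebError(f"group {self.name!r}: biomass must be > 0")
        if self.production_rate < 0:
            raise FoodWebError(f"group {self.name!r}: negative P/B")
        if self.consumption_rate < 0:
            raise FoodWebError(f"group {self.name!r}: negative Q/B")
        if self.group_class in ("producer", "detritus") and self.consumption_rate != 0:
            raise FoodWebError(
                f"group {self.name!r}: {self.group_class} must have Q/B = 0"
            )
        if self.group_class == "consumer" and self.consumption_rate < self.production_rate:
            raise FoodWebError(
                f"group {self.name!r}: consumer requires Q/B >= P/B "
                f"({self.consumption_rate} < {self.production_rate})"
            )
        if not 0.0 <= self.ecotrophic_efficiency <= 1.0:
            raise FoodWebError(f"group {self.name!r}: EE outside [0, 1]")
        if not 0.0 < self.muscle_fraction <= 1.0:
            raise FoodWebError(f"group {self.name!r}: muscle fraction outside (0, 1]")


@dataclass(frozen=True)
class FoodWebModel:
    """A mass-balanced food web plus its physical environment.

    ``diet[i, j]`` is the fraction of predator *i*'s diet coming from prey
    *j*. Group order is the file/construction order and indexes every
    matrix in the package. ``area`` (km²) and ``depth`` (m) define the
    water volume the contaminant engine mixes releases into.
    """

    groups: tuple[FunctionalGroup, ...]
    diet: np.ndarray
    area: float = 570_000.0
    depth: float = 95.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "groups", tuple(self.groups))
        dc = np.asarray(self.diet, dtype=float)
        object.__setattr__(self, "diet", dc)
        n = len(self.groups)
        if dc.shape != (n, n):
            raise FoodWebError(f"diet matrix shape {dc.shape} != ({n}, {n})")
        if not (self.area > 0 and self.depth > 0):
            raise FoodWebError("area and depth must be positive")
        names = [g.name for g in self.groups]
        if len(set(names)) != n:
            raise FoodWebError("group names must be unique")
        if np.any(dc < 0):
            raise FoodWebError("diet fractions must be nonnegative")
        for i, g in enumerate(self.groups):
            row = dc[i].sum()
            if g.group_class == "consumer":
                if abs(row - 1.0) > DIET_ROW_TOL:
                    raise FoodWebError(
                        f"diet row of consumer {g.name!r} sums to {row!r}, not 1"
                    )
            else:
                if row != 0.0:
                    raise FoodWebError(
                        f"{g.group_class} {g.name!r} must have an all-zero diet row"
                    )

    # -- convenience views ------------------------------------------------
    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def names(self) -> list[str]:
        return [g.name for g in self.groups]

    @property
    def biomass(self) -> np.ndarray:
        return np.array([g.biomass for g in self.groups])

    @property
    def production_rate(self) -> np.ndarray:
        return np.array([g.production_rate for g in self.groups])

    @property
    def consumption_rate(self) -> np.ndarray:
        return np.array([g.consumption_rate for g in self.groups])

    @property
    def ecotrophic_efficiency(self) -> np.ndarray:
        return np.array([g.ecotrophic_efficiency for g in self.groups])

    @property
    def direct_uptake_mask(self) -> np.ndarray:
        return np.array([g.direct_uptake for g in self.groups], dtype=bool)

    @property
    def detritus_mask(self) -> np.ndarray:
        return np.array([g.group_class == "detritus" for g in self.groups], dtype=bool)

    @property
    def water_volume_litres(self) -> float:
        """Mixed water volume: area [km²] · depth [m] · 1e9 L per km²·m."""
        return self.area * self.depth * 1e9

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"no group named {name!r}") from None

    def with_groups(self, groups: Iterable[FunctionalGroup]) -> "FoodWebModel":
        return replace(self, groups=tuple(groups))


def consumption_matrix(model: FoodWebModel) -> np.ndarray:
    """Per-link consumption flows Q[i, j] = B_i · QB_i · DC[i, j] (t km⁻² yr⁻¹).

    Row *i* sums to the total consumption B_i·QB_i of predator *i*;
    producer and detritus rows are zero.
    """
    b = model.biomass
    qb = model.consumption_rate
    return (b * qb)[:, None] * model.diet


def mass_balance_residuals(
    model: FoodWebModel, landings: Sequence[float] | np.ndarray | None = None
) -> np.ndarray:
    """Signed static-balance residual per group (t km⁻² yr⁻¹).

    residual_i = B_i·PB_i·EE_i − Σ_j B_j·QB_j·DC[j, i] − Y_i.

    A balanced web has every |residual| at numerical tolerance. Detritus
    groups return 0 (the detrital budget is not part of the static
    balance). ``landings`` Y must be nonnegative, one value per group
    (default all zero).
    """
    n = model.n_groups
    if landings is None:
        y = np.zeros(n)
    else:
        y = np.asarray(landings, dtype=float)
        if y.shape != (n,):
            raise FoodWebError(
                f"landings has shape {y.shape}, expected ({n},)"
            )
        if np.any(y < 0):
            raise FoodWebError("landings must be nonnegative")
    q = consumption_matrix(model)
    predation = q.sum(axis=0)
    production = model.biomass * model.production_rate * model.ecotrophic_efficiency
    resid = production - predation - y
    resid[model.detritus_mask] = 0.0
    return resid


def trophic_levels(model: FoodWebModel) -> np.ndarray:
    """Fractional trophic levels from the diet matrix.

    Solves TL = 1 + DC·TL restricted to consumer rows; producers and
    detritus sit at TL 1. Raises on a singular system (a consumer whose
    diet closes a self-feeding loop of full weight).
    """
    n = model.n_groups
    dc = model.diet.copy()
    a = np.eye(n) - dc
    try:
        tl = np.linalg.solve(a, np.ones(n))
    except np.linalg.LinAlgError:
        raise FoodWebError(
            "trophic-level system is singular (degenerate cannibalism loop)"
        ) from None
    if not np.all(np.isfinite(tl)):
        raise FoodWebError("trophic-level solution is not finite")
    return tl


# -- CSV I/O ---------------------------------------------------------------
#
# Group table columns: name, class, B, PB, QB, EE, direct_uptake,
# muscle_fraction, trophic_class, commercial.
# Diet matrix: square, header row/column of group names, predator rows x
# prey columns.

_GROUP_COLUMNS = [
    "name", "class", "B", "PB", "QB", "EE",
    "direct_uptake", "muscle_fraction", "trophic_class", "commercial",
]


def write_foodweb_csv(model: FoodWebModel, group_path: str | Path, diet_path: str | Path) -> None:
    rows = [
        {
            "name": g.name,
            "class": g.group_class,
            "B": g.biomass,
            "PB": g.production_rate,
            "QB": g.consumption_rate,
            "EE": g.ecotrophic_efficiency,
            "direct_uptake": g.direct_uptake,
            "muscle_fraction": g.muscle_fraction,
            "trophic_class": g.trophic_class,
            "commercial": g.commercial,
        }
        for g in model.groups
    ]
    pd.DataFrame(rows, columns=_GROUP_COLUMNS).to_csv(group_path, index=False)
    pd.DataFrame(model.diet, index=model.names, columns=model.names).to_csv(diet_path)


def read_foodweb_csv(
    group_path: str | Path,
    diet_path: str | Path,
    area: float = 570_000.0,
    depth: float = 95.0,
) -> FoodWebModel:
    """Load a web from the group-parameter and diet-matrix CSV files."""
    gdf = pd.read_csv(group_path)
    missing = set(_GROUP_COLUMNS) - set(gdf.columns)
    if missing:
        raise FoodWebError(f"group table missing columns: {sorted(missing)}")
    groups = [
        FunctionalGroup(
            name=str(r["name"]),
            group_class=str(r["class"]),
            biomass=float(r["B"]),
            production_rate=float(r["PB"]),
            consumption_rate=float(r["QB"]),
            ecotrophic_efficiency=float(r["EE"]),
            direct_uptake=_as_bool(r["direct_uptake"]),
            muscle_fraction=float(r["muscle_fraction"]),
            trophic_class=str(r["trophic_class"]),
            commercial=_as_bool(r["commercial"]),
        )
        for _, r in gdf.iterrows()
    ]
    ddf = pd.read_csv(diet_path, index_col=0)
    names = [g.name for g in groups]
    if list(ddf.index) != names or list(ddf.columns) != names:
        raise FoodWebError("diet matrix names do not match the group table order")
    return FoodWebModel(groups=tuple(groups), diet=ddf.to_numpy(dtype=float),
                        area=area, depth=depth)


def _as_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    return str(v).strip().lower() in ("true", "1", "yes")
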