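"""Synthetic inputs: mass-balanced webs, tracer calibrations, observation
sets and consumer profiles.

The published North Sea parameterization is not redistributable, so every
input the pipeline needs can be generated here with the statistical
structure the analysis assumes. The default web has 29 functional groups
(one detritus, two phytoplankton guilds, zooplankton, benthos, shrimp-like
crustaceans and named fish guilds up to birds and mammals) with invented
parameter values drawn from documented synthetic conventions:

* biomass log-uniform within a window that shrinks geometrically with
  position in the trophic ordering (0.01–50 t km⁻² overall);
* P/B decreasing with trophic position within 0.1–100 yr⁻¹;
* Q/B = P/B / GE with gross food-conversion efficiency GE ∈ [0.1, 0.3];
* diet drawn over lower-ordered groups (acyclic except the detritus loop)
  with Dirichlet weights at the requested connectance.

Ecotrophic efficiencies are back-solved from the realized predation so the
emitted web balances exactly; consumer biomass is capped during generation
so no prey's EE can exceed the cap (0.9). All draws go through one
explicit integer seed; there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exposure import FOOD_GROUPS, ConsumerProfile
from .foodweb import FoodWebModel, FunctionalGroup, trophic_levels
from .tracer import (
    ContaminantState,
    TracerParams,
    TracerError,
    run_to_equilibrium,
    _rate_matrix,
)
from .validation import ValidationRecord

__all__ = [
    "WebGenSpec",
    "SynthError",
    "generate_foodweb",
    "calibrate_uptake",
    "calibrate_to_background",
    "generate_observations",
    "generate_consumer_profiles",
    "DEFAULT_GUILDS",
    "FOOD_GROUP_SPECIES",
]

EE_CAP = 0.9
#: Trophic level at or above which a group counts as "high" trophic class.
HIGH_TROPHIC_TL = 4.0


class SynthError(ValueError):
    """Infeasible generator specification."""


# name, class, direct_uptake, muscle_fraction guild, commercial
# (fish f_m 0.5, shrimp-like crustaceans 0.15, everything else 1.0)
DEFAULT_GUILDS: list[tuple[str, str, bool, float, bool]] = [
    ("detritus", "detritus", False, 1.0, False),
    ("phytoplankton_diatoms", "producer", True, 1.0, False),
    ("phytoplankton_flagellates", "producer", True, 1.0, False),
    ("microzooplankton", "consumer", False, 1.0, False),
    ("copepods", "consumer", True, 1.0, False),
    ("euphausiids", "consumer", True, 1.0, False),
    ("gelatinous_zooplankton", "consumer", False, 1.0, False),
    ("infaunal_macrobenthos", "consumer", False, 1.0, False),
    ("epifaunal_macrobenthos", "consumer", False, 1.0, False),
    ("suspension_feeders", "consumer", False, 1.0, True),
    ("shrimp", "consumer", False, 0.15, True),
    ("nephrops", "consumer", False, 0.15, True),
    ("crabs", "consumer", False, 0.15, True),
    ("sandeel", "consumer", False, 0.5, False),
    ("herring", "consumer", False, 0.5, True),
    ("sprat", "consumer", False, 0.5, True),
    ("norway_pout", "consumer", False, 0.5, False),
    ("mackerel", "consumer", False, 0.5, True),
    ("haddock", "consumer", False, 0.5, True),
    ("whiting", "consumer", False, 0.5, True),
    ("cod", "consumer", False, 0.5, True),
    ("saithe", "consumer", False, 0.5, True),
    ("plaice", "consumer", False, 0.5, True),
    ("sole", "consumer", False, 0.5, True),
    ("gurnards", "consumer", False, 0.5, False),
    ("rays", "consumer", False, 0.5, False),
    ("monkfish", "consumer", False, 0.5, True),
    ("seabirds", "consumer", False, 1.0, False),
    ("seals", "consumer", False, 1.0, False),
]

#: Mapping of the commercial guilds to the three seafood food groups.
FOOD_GROUP_SPECIES: dict[str, tuple[str, ...]] = {
    "oily_fish": ("herring", "sprat", "mackerel"),
    "white_fish": ("haddock", "whiting", "cod", "saithe", "plaice", "sole", "monkfish"),
    "shellfish": ("shrimp", "nephrops", "crabs", "suspension_feeders"),
}


@dataclass(frozen=True)
class WebGenSpec:
    """Shape and distributions of a generated web."""

    n_groups: int = 29
    n_producers: int = 2
    n_detritus: int = 1
    connectance: float = 0.35
    biomass_range: tuple[float, float] = (0.01, 50.0)
    pb_range: tuple[float, float] = (0.1, 100.0)
    ge_range: tuple[float, float] = (0.1, 0.3)
    detritus_diet_prob: float = 0.3
    #: wire each consumer to the single preceding living group (forces a
    #: linear chain with integer trophic levels; used for small test webs)
    chain: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_producers < 1:
            raise SynthError("need at least one producer")
        if self.n_detritus != 1:
            raise SynthError("exactly one detritus group is supported")
        if not 0.0 < self.connectance <= 1.0:
            raise SynthError("connectance must lie in (0, 1]")
        n_consumers = self.n_groups - self.n_producers - self.n_detritus
        if n_consumers < 1:
            raise SynthError("need at least one consumer")


def _guild_table(spec: WebGenSpec) -> list[tuple[str, str, bool, float, bool]]:
    if (spec.n_groups == 29 and spec.n_producers == 2):
        return list(DEFAULT_GUILDS)
    rows: list[tuple[str, str, bool, float, bool]] = [
        ("detritus", "detritus", False, 1.0, False)
    ]
    for p in range(spec.n_producers):
        rows.append((f"producer_{p + 1}", "producer", True, 1.0, False))
    n_consumers = spec.n_groups - spec.n_producers - 1
    for c in range(n_consumers):
        # first two consumers mimic the direct-uptake mesozooplankton
        direct = c < 2
        fm = 1.0 if c < max(1, n_consumers // 3) else 0.5
        commercial = fm == 0.5
        rows.append((f"consumer_{c + 1}", "consumer", direct, fm, commercial))
    return rows


def generate_foodweb(spec: WebGenSpec) -> FoodWebModel:
    """Draw a mass-balanced web; exact balance by EE back-solve.

    Deterministic per seed. Consumers feed only on lower-ordered groups
    (plus optionally detritus), so the predator ordering is acyclic;
    consumer biomass is capped so no prey's ecotrophic efficiency can
    exceed 0.9, which keeps every emitted web balanceable.
    """
    rng = np.random.default_rng(spec.seed)
    guilds = _guild_table(spec)
    n = len(guilds)
    lo_b, hi_b = spec.biomass_range
    lo_pb, hi_pb = spec.pb_range

    classes = [g[1] for g in guilds]
    biomass = np.empty(n)
    pb = np.zeros(n)
    qb = np.zeros(n)

    # trophic position proxy: index within the ordering
    for i, cls in enumerate(classes):
        frac = i / max(n - 1, 1)
        if cls == "detritus":
            biomass[i] = float(rng.uniform(5.0, 25.0))
            continue
        # window shrinking with position (log10 span of the full range)
        span = np.log10(hi_b) - np.log10(lo_b)
        centre = np.log10(hi_b) - frac * span
        biomass[i] = 10 ** rng.uniform(
            max(np.log10(lo_b), centre - 0.8), min(np.log10(hi_b), centre + 0.8)
        )
        if cls == "producer":
            pb[i] = 10 ** rng.uniform(np.log10(20.0), np.log10(hi_pb))
        else:
            span_pb = np.log10(20.0) - np.log10(lo_pb)
            centre_pb = np.log10(20.0) - frac * span_pb
            pb[i] = 10 ** rng.uniform(
                max(np.log10(lo_pb), centre_pb - 0.4),
                min(np.log10(hi_pb), centre_pb + 0.4),
            )
            ge = rng.uniform(*spec.ge_range)
            qb[i] = pb[i] / ge

    diet = np.zeros((n, n))
    # remaining consumable production per prey (EE cap enforced on the fly)
    remaining = np.where(
        [c == "detritus" for c in classes], np.inf, EE_CAP * biomass * pb
    )
    for i, cls in enumerate(classes):
        if cls != "consumer":
            continue
        candidates = [
            j for j in range(i)
            if classes[j] != "detritus" and remaining[j] > 1e-9
        ]
        if not candidates:
            raise SynthError(f"consumer {guilds[i][0]} has no feasible prey")
        if spec.chain:
            take = [candidates[-1]]
        else:
            # keep diets local in the ordering so chains, not hubs, dominate
            window = candidates[-8:]
            take = [j for j in window if rng.uniform() < spec.connectance]
            if not take:
                take = [window[-1]]
            if rng.uniform() < spec.detritus_diet_prob:
                take = [0] + take
        weights = rng.dirichlet(np.ones(len(take)))
        demand = biomass[i] * qb[i]
        cap = np.inf
        for j, w in zip(take, weights):
            if w > 0 and np.isfinite(remaining[j]):
                cap = min(cap, remaining[j] / w)
        if demand > cap:
            # shrink the predator to what its prey can sustain, and shrink
            # the production it offers its own predators accordingly
            biomass[i] = max(cap / qb[i], 1e-9)
            demand = biomass[i] * qb[i]
            remaining[i] = EE_CAP * biomass[i] * pb[i]
        for j, w in zip(take, weights):
            diet[i, j] = w
            flow = w * demand
            if np.isfinite(remaining[j]):
                remaining[j] -= flow
        # fix tiny float drift so rows sum to exactly 1
        diet[i, take] /= diet[i, take].sum()

    # back-solve EE from the realized predation so the web balances exactly
    predation = ((biomass * qb)[:, None] * diet).sum(axis=0)
    ee = np.zeros(n)
    for i, cls in enumerate(classes):
        if cls == "detritus":
            continue
        prod = biomass[i] * pb[i]
        ee[i] = min(predation[i] / prod, 1.0) if prod > 0 else 0.0

    groups = []
    for i, (name, cls, direct, fm, commercial) in enumerate(guilds):
        groups.append(
            FunctionalGroup(
                name=name,
                group_class=cls,
                biomass=float(biomass[i]),
                production_rate=float(pb[i]),
                consumption_rate=float(qb[i]),
                ecotrophic_efficiency=float(ee[i]),
                direct_uptake=direct,
                muscle_fraction=fm,
                trophic_class="low",
                commercial=commercial,
            )
        )
    model = FoodWebModel(groups=tuple(groups), diet=diet)
    tl = trophic_levels(model)
    groups = [
        FunctionalGroup(
            name=g.name, group_class=g.group_class, biomass=g.biomass,
            production_rate=g.production_rate, consumption_rate=g.consumption_rate,
            ecotrophic_efficiency=g.ecotrophic_efficiency,
            direct_uptake=g.direct_uptake, muscle_fraction=g.muscle_fraction,
            trophic_class="high" if tl[i] >= HIGH_TROPHIC_TL else "low",
            commercial=g.commercial,
        )
        for i, g in enumerate(model.groups)
    ]
    return model.with_groups(groups)


def calibrate_uptake(
    model: FoodWebModel,
    target_body_concentrations: dict[str, float],
    excretion_rate: float = 0.10,
    water_concentration: float = 0.57,
    detritus_routing: bool = True,
) -> TracerParams:
    """Solve the direct-uptake rates so flagged groups hit target burdens.

    ``target_body_concentrations`` maps each direct-uptake group to its
    desired equilibrium whole-body concentration (µg kg⁻¹ wet weight) at
    the fixed background water concentration. Because the tracer system is
    linear, the equilibrium body concentration of every group is linear in
    the uptake-rate vector; the targets define a small square system over
    the flagged groups. A negative solution means the dietary inflow from
    other flagged groups already exceeds the target — reported per group.
    """
    flagged = np.flatnonzero(model.direct_uptake_mask)
    names = model.names
    missing = [names[i] for i in flagged if names[i] not in target_body_concentrations]
    if missing:
        raise SynthError(f"no target for direct-uptake groups: {missing}")
    targets = np.array([float(target_body_concentrations[names[i]]) for i in flagged])
    if np.any(targets < 0):
        raise SynthError("targets must be nonnegative")

    base = TracerParams(
        uptake_rates=np.zeros(model.n_groups),
        excretion_rate=excretion_rate,
        detritus_routing=detritus_routing,
    )
    m = _rate_matrix(model, base)
    mg = m[1:, 1:]
    area = model.area
    b = model.biomass
    # equilibrium total pools are linear in u: P(u) = -mg^{-1} (u ∘ C_w B area)
    # restricted to flagged columns; match P at the flagged rows to targets.
    cols = np.zeros((model.n_groups, flagged.size))
    for k, i in enumerate(flagged):
        src = np.zeros(model.n_groups)
        src[i] = water_concentration * b[i] * area  # flux for u_i = 1
        cols[:, k] = np.linalg.solve(mg, -src)
    target_pools = targets * b[flagged] * 1e3 * area  # µg/kg -> total µg
    try:
        u_flagged = np.linalg.solve(cols[flagged, :], target_pools)
    except np.linalg.LinAlgError:
        raise SynthError("calibration system is singular") from None
    bad = {
        names[i]: float(u)
        for i, u in zip(flagged, u_flagged)
        if u < -1e-12 * max(1.0, np.abs(u_flagged).max())
    }
    if bad:
        raise SynthError(
            "targets unreachable (dietary inflow alone exceeds the target) "
            f"for: {sorted(bad)}"
        )
    u = np.zeros(model.n_groups)
    u[flagged] = np.maximum(u_flagged, 0.0)
    return TracerParams(
        uptake_rates=u, excretion_rate=excretion_rate,
        detritus_routing=detritus_routing,
    )


def calibrate_to_background(
    model: FoodWebModel,
    max_commercial_muscle_mg_kg: float = 0.15,
    excretion_rate: float = 0.10,
    water_concentration: float = 0.57,
    detritus_routing: bool = True,
) -> TracerParams:
    """Scale the flagged uptake rates to a sub-food-standard baseline.

    Starts from a unit clearance rate for every flagged group,
    equilibrates, then uses the linearity of the system to rescale all
    uptake rates so the largest commercial-group muscle concentration at
    the background water concentration equals
    ``max_commercial_muscle_mg_kg`` (default 0.15 mg kg⁻¹, below both
    food standards).
    """
    if not any(g.direct_uptake for g in model.groups):
        raise SynthError("model has no direct-uptake groups to calibrate")
    params = TracerParams(
        uptake_rates=np.where(model.direct_uptake_mask, 1.0, 0.0),
        excretion_rate=excretion_rate,
        detritus_routing=detritus_routing,
    )
    state = run_to_equilibrium(
        model, params,
        init=ContaminantState(0.0, water_concentration, np.zeros(model.n_groups)),
    )
    conc = state.body_concentrations(model)
    fm = np.array([g.muscle_fraction for g in model.groups])
    commercial = np.array([g.commercial for g in model.groups])
    muscle_mg = conc * fm / 1e3
    peak = float(muscle_mg[commercial].max())
    if peak <= 0:
        raise SynthError("commercial groups receive no contaminant; cannot scale")
    scale = max_commercial_muscle_mg_kg / peak
    return TracerParams(
        uptake_rates=params.uptake_rates * scale,
        excretion_rate=excretion_rate,
        detritus_routing=detritus_routing,
    )


def generate_observations(
    muscle_concentrations: dict[str, float],
    bias: float = 0.0,
    noise_cv: float = 0.0,
    n_studies: int = 5,
    seed: int = 0,
) -> list[ValidationRecord]:
    """Observation sets O = M/(1+bias) · lognormal noise with the given CV.

    ``bias`` is the normalized mean bias the construction embeds: with no
    noise the pooled NMB of the emitted records is exactly ``bias``.
    """
    if noise_cv < 0:
        raise SynthError("noise CV must be nonnegative")
    if bias <= -1:
        raise SynthError("bias must exceed -1")
    rng = np.random.default_rng(seed)
    records = []
    if noise_cv > 0:
        sigma2 = np.log1p(noise_cv**2)
        sigma = np.sqrt(sigma2)
    for group, m in muscle_concentrations.items():
        centre = m / (1.0 + bias)
        if noise_cv > 0:
            # mean-one lognormal noise
            noise = rng.lognormal(mean=-sigma2 / 2, sigma=sigma, size=n_studies)
        else:
            noise = np.ones(n_studies)
        records.append(
            ValidationRecord(group=group, modelled=float(m),
                             observed=tuple(centre * noise))
        )
    return records


def generate_consumer_profiles(seed: int = 0) -> list[ConsumerProfile]:
    """Four consumer groups × two regimes with NHS ≥ NDNS intakes.

    Synthetic stand-ins for the survey tables: body weights around UK
    adult/child averages, NHS intakes built from the two-140-g-portions
    guidance (one oily), NDNS intakes drawn strictly below the NHS values
    component-wise so the recommended regime dominates by construction.
    """
    rng = np.random.default_rng(seed)
    base_weights = {
        "men": 85.0, "women": 72.0, "children": 30.0, "pregnant women": 72.0,
    }
    profiles: list[ConsumerProfile] = []
    for label, w0 in base_weights.items():
        weight = float(w0 * rng.uniform(0.95, 1.05))
        # NHS guidance: at least two 140 g portions a week, one oily
        nhs = {
            "oily_fish": 0.14 * float(rng.uniform(1.0, 1.2)),
            "white_fish": 0.14 * float(rng.uniform(1.0, 1.5)),
            "shellfish": 0.05 * float(rng.uniform(0.8, 1.2)),
        }
        if label == "children":
            nhs = {g: v * 0.6 for g, v in nhs.items()}
        ndns = {g: v * float(rng.uniform(0.3, 0.9)) for g, v in nhs.items()}
        for regime, intake in (("NHS", nhs), ("NDNS", ndns)):
            profiles.append(
                ConsumerProfile(
                    label=label, regime=regime, body_weight_kg=weight,
                    weekly_intake_kg=intake,
                )
            )
    return profiles
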