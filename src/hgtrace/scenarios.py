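"""Decommissioning exposure scenarios and pipeline-release arithmetic.

Four preset scenarios describe mercury forcing of the North Sea model:

* **ES A** — status quo: background concentration 0.57 µg L⁻¹ and the
  CEFAS-derived anthropogenic influx of 0.01 t yr⁻¹, no releases.
* **ES B** — the 317.12 km of currently abandoned pipeline decommissioned
  in place after cleaning: a single 0.07 t release at year 50.
* **ES C** — all 45 000 km of North Sea pipeline cleaned and left in
  place: a single 9.9 t release at year 50.
* **ES D** — all 45 000 km cleaned only to the smelting threshold of
  2 mg Hg per kg steel: a single 72.93 t release at year 50.

Preset release masses are stored as the published constants and never
recomputed from pipe geometry: standard annulus arithmetic on the stated
schedule-60, 10-inch pipe gives a steel mass (~8.2e4 kg km⁻¹) an order of
magnitude below the value the release masses imply (~8.1e5 kg km⁻¹), so
the geometry helpers in this module serve custom scenarios and sensitivity
analyses only. Presets C and D additionally carry the published
post-release background influx of 4e-6 t yr⁻¹, which is inconsistent with
ES A's 0.01 t yr⁻¹ as printed; both values are kept as data rather than
silently reconciled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = [
    "ExposureScenario",
    "PipelineSpec",
    "ScenarioError",
    "steel_mass_per_km",
    "pipeline_release_mass",
    "influx_mass_to_concentration",
    "scale_release_mass",
    "build_preset",
    "PRESET_IDS",
]

#: North Sea geometry used for mass-to-concentration conversions.
DEFAULT_AREA_KM2 = 570_000.0
DEFAULT_DEPTH_M = 95.0
#: Background water concentration, µg L⁻¹ (ICES dataset).
DEFAULT_WATER_CONC = 0.57
#: Background anthropogenic influx, t yr⁻¹ (CEFAS 2005–2014 average).
DEFAULT_INFLUX = 0.01
#: Post-release background used by the C/D presets, t yr⁻¹ (as published).
POST_RELEASE_INFLUX = 4e-6

PRESET_IDS = ("A", "B", "C", "D")


class ScenarioError(ValueError):
    """Invalid scenario or pipeline specification."""


@dataclass(frozen=True)
class ExposureScenario:
    """Mercury forcing: initial concentration, influx and timed releases."""

    id: str
    initial_water_concentration: float = DEFAULT_WATER_CONC
    background_influx: float = DEFAULT_INFLUX
    release_events: tuple[tuple[float, float], ...] = ()
    area: float = DEFAULT_AREA_KM2
    depth: float = DEFAULT_DEPTH_M
    post_release_influx: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "release_events",
            tuple((float(y), float(m)) for y, m in self.release_events),
        )
        if self.initial_water_concentration < 0 or self.background_influx < 0:
            raise ScenarioError("concentration and influx must be nonnegative")
        if not (self.area > 0 and self.depth > 0):
            raise ScenarioError("area and depth must be positive")
        for year, mass in self.release_events:
            if year < 0:
                raise ScenarioError(f"release year {year} must be nonnegative")
            if mass < 0:
                raise ScenarioError(f"release mass {mass} must be nonnegative")
        if self.post_release_influx is not None and self.post_release_influx < 0:
            raise ScenarioError("post-release influx must be nonnegative")

    def spread_release(self, n_years: int) -> "ExposureScenario":
        """Distribute each pulse evenly over ``n_years`` yearly sub-releases.

        Sensitivity variant: published results found no difference between
        single and setwise release, so presets use the single pulse.
        """
        if n_years < 1:
            raise ScenarioError("n_years must be >= 1")
        events: list[tuple[float, float]] = []
        for year, mass in self.release_events:
            events.extend((year + k, mass / n_years) for k in range(n_years))
        return ExposureScenario(
            id=f"{self.id}-spread{n_years}",
            initial_water_concentration=self.initial_water_concentration,
            background_influx=self.background_influx,
            release_events=tuple(events),
            area=self.area,
            depth=self.depth,
            post_release_influx=self.post_release_influx,
        )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "id": self.id,
            "initial_concentration_ug_per_L": self.initial_water_concentration,
            "background_influx_t_per_yr": self.background_influx,
            "events": [
                {"year": y, "mass_t": m} for y, m in self.release_events
            ],
            "area_km2": self.area,
            "depth_m": self.depth,
        }
        if self.post_release_influx is not None:
            payload["post_release_influx_t_per_yr"] = self.post_release_influx
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExposureScenario":
        p = yaml.safe_load(Path(path).read_text())
        return cls(
            id=str(p["id"]),
            initial_water_concentration=float(
                p.get("initial_concentration_ug_per_L", DEFAULT_WATER_CONC)
            ),
            background_influx=float(
                p.get("background_influx_t_per_yr", DEFAULT_INFLUX)
            ),
            release_events=tuple(
                (float(ev["year"]), float(ev["mass_t"]))
                for ev in p.get("events", [])
            ),
            area=float(p.get("area_km2", DEFAULT_AREA_KM2)),
            depth=float(p.get("depth_m", DEFAULT_DEPTH_M)),
            post_release_influx=(
                float(p["post_release_influx_t_per_yr"])
                if "post_release_influx_t_per_yr" in p
                else None
            ),
        )


@dataclass(frozen=True)
class PipelineSpec:
    """Geometry and residual contamination of a subsea pipeline.

    Default geometry is the schedule-60 10-inch pipe reported as the North
    Sea average: outer diameter 27.31 cm, wall thickness 12.7 mm.
    ``residual_concentration`` is µg mercury per kg steel.
    """

    length_km: float
    outer_diameter_m: float = 0.2731
    wall_thickness_m: float = 0.0127
    steel_density_kg_m3: float = 7850.0
    residual_concentration_ug_kg: float = 260.0
    steel_mass_per_km_override: float | None = None

    def __post_init__(self) -> None:
        if min(self.length_km, self.outer_diameter_m, self.wall_thickness_m,
               self.steel_density_kg_m3) <= 0:
            raise ScenarioError("pipeline dimensions must be positive")
        if self.residual_concentration_ug_kg < 0:
            raise ScenarioError("residual concentration must be nonnegative")
        if self.wall_thickness_m >= self.outer_diameter_m / 2:
            raise ScenarioError("wall thickness must be below outer radius")
        if (self.steel_mass_per_km_override is not None
                and self.steel_mass_per_km_override <= 0):
            raise ScenarioError("steel-mass override must be positive")


def steel_mass_per_km(spec: PipelineSpec) -> float:
    """Steel mass of one km of pipe, kg km⁻¹ (thin annulus π·(OD−t)·t·ρ)."""
    if spec.steel_mass_per_km_override is not None:
        return spec.steel_mass_per_km_override
    import math

    area_m2 = math.pi * (spec.outer_diameter_m - spec.wall_thickness_m) * spec.wall_thickness_m
    return area_m2 * spec.steel_density_kg_m3 * 1000.0


def pipeline_release_mass(spec: PipelineSpec) -> float:
    """Total mercury inventory of the pipeline, tonnes."""
    ug = spec.length_km * steel_mass_per_km(spec) * spec.residual_concentration_ug_kg
    return ug / 1e12


def scale_release_mass(mass_t: float, length_km: float, to_length_km: float) -> float:
    """Scale a release inventory linearly to another pipeline length.

    Mirrors how the full-network release is obtained from the abandoned
    317.12 km inventory: same per-km burden, different length.
    """
    if length_km <= 0 or to_length_km < 0:
        raise ScenarioError("lengths must be positive")
    return mass_t * to_length_km / length_km


def influx_mass_to_concentration(
    mass_t: float,
    area_km2: float = DEFAULT_AREA_KM2,
    depth_m: float = DEFAULT_DEPTH_M,
) -> float:
    """Convert a mercury mass (t) fully mixed into the water volume to µg L⁻¹."""
    if area_km2 <= 0 or depth_m <= 0:
        raise ScenarioError("area and depth must be positive")
    volume_litres = area_km2 * depth_m * 1e9
    return mass_t * 1e12 / volume_litres


def build_preset(preset_id: str) -> ExposureScenario:
    """Construct one of the ES A–D presets (release at year 50)."""
    pid = str(preset_id).upper()
    if pid == "A":
        return ExposureScenario(id="A")
    if pid == "B":
        return ExposureScenario(id="B", release_events=((50.0, 0.07),))
    if pid == "C":
        return ExposureScenario(
            id="C", release_events=((50.0, 9.9),),
            post_release_influx=POST_RELEASE_INFLUX,
        )
    if pid == "D":
        return ExposureScenario(
            id="D", release_events=((50.0, 72.93),),
            post_release_influx=POST_RELEASE_INFLUX,
        )
    raise ScenarioError(f"unknown preset {preset_id!r}; expected one of {PRESET_IDS}")
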