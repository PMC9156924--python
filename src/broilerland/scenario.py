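"""Constant-land consumption scenarios.

For each breed × management scenario the model first computes the land the
scenario would need at full (present-day) consumption, then asks the inverse
question: if total land use is capped at the conventional Ross-in-CAFO
footprint, how much chicken can be produced? Because every land component is
linear in the flock size, the answer is a single scale factor

    scale = baseline_total_land / scenario_total_land,

applied to consumption, slaughter rate and standing population alike.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .demographics import FlockState, breed_flock, steady_state_population
from .land import LandFootprint, footprint
from .parameters import (
    BreedSpec,
    FeedModel,
    ManagementKind,
    ManagementSpec,
    NationalBaseline,
    ParameterSet,
)
from .units import UNITS, UnitRegistry

__all__ = [
    "ScenarioResult",
    "constant_land_scale",
    "baseline_footprint",
    "run_scenario",
    "run_all",
    "scenarios_frame",
    "footprints_frame",
    "components_long_frame",
]


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome of one breed × management constant-land scenario."""

    breed: str
    management: ManagementKind
    full_consumption_land: LandFootprint
    max_consumption: float  # MMT/yr at the land cap
    consumption_decrease_mmt: float
    consumption_decrease_pct: float
    slaughter_rate_at_cap: float  # birds/yr
    population_at_cap: float  # birds
    scale_factor: float

    def to_row(self) -> dict[str, float | str]:
        """One CSV row (Table-style layout plus land columns)."""
        return {
            "breed": self.breed,
            "management": self.management.value,
            "max_consumption_mmt_per_yr": self.max_consumption,
            "slaughter_rate_at_cap_birds_per_yr": self.slaughter_rate_at_cap,
            "population_at_cap_birds": self.population_at_cap,
            "consumption_decrease_mmt_per_yr": self.consumption_decrease_mmt,
            "consumption_decrease_pct": self.consumption_decrease_pct,
            "scale_factor": self.scale_factor,
            "full_consumption_total_km2": self.full_consumption_land.total,
            "full_consumption_direct_km2": self.full_consumption_land.direct,
            "full_consumption_indirect_km2": self.full_consumption_land.indirect,
        }


def constant_land_scale(scenario_land: float, baseline_land: float) -> float:
    """Consumption scale factor holding total land at the baseline cap."""
    if scenario_land <= 0:
        raise ValueError("scenario land must be positive")
    return baseline_land / scenario_land


def _is_baseline_flock(flock: FlockState, baseline: NationalBaseline) -> bool:
    # The conventional flock is the one slaughtered at the national rate.
    return math.isclose(flock.slaughter_rate, baseline.slaughter_rate, rel_tol=1e-12)


def baseline_footprint(baseline: NationalBaseline, breeds: Sequence[BreedSpec] = (),
                       feed_model: FeedModel | None = None,
                       managements: Sequence[ManagementSpec] | None = None,
                       units: UnitRegistry = UNITS) -> LandFootprint:
    """The conventional Ross-in-CAFO footprint that caps every scenario.

    The conventional breed is looked up in ``breeds`` (the one whose flock
    is slaughtered at the national rate); when none qualifies, the default
    conventional breed is used.
    """
    from .parameters import default_breeds, default_feed_model

    if feed_model is None:
        feed_model = default_feed_model()
    cafo = None
    if managements is not None:
        cafo = next((m for m in managements if m.kind is ManagementKind.CAFO), None)
    if cafo is None:
        cafo = ManagementSpec(kind=ManagementKind.CAFO)
    base_breed = next(
        (b for b in list(breeds) + default_breeds()
         if _is_baseline_flock(breed_flock(baseline, b, units), baseline)),
        None,
    )
    if base_breed is None:
        raise ValueError("no breed reproduces the baseline slaughter rate")
    flock = breed_flock(baseline, base_breed, units)
    return footprint(flock, cafo, feed_model, baseline=baseline,
                     baseline_mode=True, units=units)


def run_scenario(breed: BreedSpec, mgmt: ManagementSpec, baseline: NationalBaseline,
                 feed_model: FeedModel, baseline_land: float | None = None,
                 units: UnitRegistry = UNITS) -> ScenarioResult:
    """Solve one breed × management constant-land scenario.

    Parameters
    ----------
    baseline_land : float, optional
        Total land cap in km²; computed from the conventional Ross-in-CAFO
        footprint when omitted.
    """
    flock = breed_flock(baseline, breed, units)
    use_reported_masses = _is_baseline_flock(flock, baseline)
    land = footprint(flock, mgmt, feed_model, baseline=baseline,
                     baseline_mode=use_reported_masses, units=units)
    if baseline_land is None:
        baseline_land = baseline_footprint(baseline, [breed], feed_model,
                                           units=units).total

    scale = constant_land_scale(land.total, baseline_land)
    w_conv = baseline.annual_dressed_production(units)
    max_consumption = scale * w_conv
    slaughter_at_cap = flock.slaughter_rate * scale
    population_at_cap = steady_state_population(slaughter_at_cap, breed.residence, units)
    return ScenarioResult(
        breed=breed.name,
        management=mgmt.kind,
        full_consumption_land=land,
        max_consumption=max_consumption,
        consumption_decrease_mmt=w_conv - max_consumption,
        consumption_decrease_pct=(1.0 - scale) * 100.0,
        slaughter_rate_at_cap=slaughter_at_cap,
        population_at_cap=population_at_cap,
        scale_factor=scale,
    )


_MGMT_ORDER = {k: i for i, k in enumerate(ManagementKind)}


def run_all(baseline: NationalBaseline, breeds: Sequence[BreedSpec],
            managements: Sequence[ManagementSpec], feed_model: FeedModel,
            units: UnitRegistry = UNITS) -> list[ScenarioResult]:
    """Run the full breed × management cross-product.

    Rows come out in deterministic order — breeds sorted with the baseline
    breed first then by name, managements in CAFO/outdoor/pasture order —
    regardless of input ordering.
    """
    if not breeds or not managements:
        raise ValueError("breeds and managements must be non-empty")
    cap = baseline_footprint(baseline, breeds, feed_model, managements, units).total

    def breed_key(b: BreedSpec):
        flock = breed_flock(baseline, b, units)
        return (0 if _is_baseline_flock(flock, baseline) else 1, b.name)

    ordered_breeds = sorted(breeds, key=breed_key)
    ordered_mgmt = sorted(managements, key=lambda m: _MGMT_ORDER[m.kind])
    return [
        run_scenario(b, m, baseline, feed_model, baseline_land=cap, units=units)
        for b in ordered_breeds
        for m in ordered_mgmt
    ]


def run_parameter_set(params: ParameterSet, units: UnitRegistry = UNITS) -> list[ScenarioResult]:
    """Convenience wrapper: run the cross-product of a full parameter set."""
    return run_all(params.baseline, params.breeds, params.managements,
                   params.feed_model, units)


def scenarios_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Scenario report table (one row per scenario, unit-suffixed columns)."""
    return pd.DataFrame([r.to_row() for r in results])


def footprints_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Full-consumption land footprints, one row per scenario."""
    rows = []
    for r in results:
        row = {"breed": r.breed}
        row.update(r.full_consumption_land.to_row())
        rows.append(row)
    return pd.DataFrame(rows)


def components_long_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Long-format (scenario × land component) table for plotting."""
    rows = []
    for r in results:
        fp = r.full_consumption_land
        for component, value in [
            ("direct", fp.direct),
            ("indirect_maize", fp.indirect_maize),
            ("indirect_soy", fp.indirect_soy),
        ]:
            rows.append(
                {
                    "breed": r.breed,
                    "management": r.management.value,
                    "component": component,
                    "land_km2": value,
                }
            )
    return pd.DataFrame(rows)
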