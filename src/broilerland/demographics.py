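"""Steady-state flock demographics.

The national flock is modelled as two well-mixed boxes — a breeding flock of
hens and a much larger fattening flock — each at steady state, so that a
box's standing population equals its residence time multiplied by its
placement (throughput) rate, and placements equal slaughters.

For a breed substituted at national scale, the slaughter rate is set so that
annual dressed production matches the conventional baseline, the fattening
population follows from the breed's longer residence, and the breeding flock
scales proportionally to the fattening population.
"""

from __future__ import annotations

from dataclasses import dataclass

from .parameters import BreedSpec, NationalBaseline
from .units import UNITS, UnitRegistry

__all__ = [
    "FlockState",
    "ProductionSummary",
    "steady_state_population",
    "dressed_weight",
    "breed_slaughter_rate",
    "breed_flock",
    "production_summary",
]


@dataclass(frozen=True)
class FlockState:
    """Steady-state populations and flow rates for one breed's national flock.

    Attributes
    ----------
    fattening_population : float
        Birds in grow-out at any moment.
    breeding_population : float
        Hens in the breeding flock at any moment.
    fattening_placement_rate : float
        Birds placed (= slaughtered, at steady state) per year.
    hen_placement_rate : float
        Pullet chicks placed into the breeding flock per year.
    breed : BreedSpec
        The breed this flock is made of.
    """

    fattening_population: float
    breeding_population: float
    fattening_placement_rate: float
    hen_placement_rate: float
    breed: BreedSpec

    @property
    def slaughter_rate(self) -> float:
        """Annual slaughter rate, equal to the placement rate at steady state."""
        return self.fattening_placement_rate

    def to_row(self, units: UnitRegistry = UNITS) -> dict[str, float | str]:
        """One CSV row with unit-suffixed headers."""
        return {
            "breed": self.breed.name,
            "fattening_population_birds": self.fattening_population,
            "breeding_population_hens": self.breeding_population,
            "slaughter_rate_birds_per_yr": self.fattening_placement_rate,
            "hen_placement_rate_hens_per_yr": self.hen_placement_rate,
        }


@dataclass(frozen=True)
class ProductionSummary:
    """Per-bird and annual production figures for one breed's flock."""

    dressed_weight_per_bird: float  # kg/bird
    annual_dressed_production: float  # MMT/yr
    annual_live_production: float  # MMT/yr


def steady_state_population(placement_rate: float, residence: float,
                            units: UnitRegistry = UNITS) -> float:
    """Standing population of a steady-state box.

    Parameters
    ----------
    placement_rate : float
        Throughput in animals per year.
    residence : float
        Mean residence time in **days**.

    Returns
    -------
    float
        Population = placement_rate × residence / days_per_year.
    """
    if placement_rate < 0 or residence < 0:
        raise ValueError("placement_rate and residence must be non-negative")
    return placement_rate * residence / units.days_per_year


def steady_state_population_years(placement_rate: float, residence_years: float) -> float:
    """As :func:`steady_state_population`, with residence given in years
    (used for the hen flock, whose 40-week cycle is quoted as 0.767 yr)."""
    if placement_rate < 0 or residence_years < 0:
        raise ValueError("placement_rate and residence must be non-negative")
    return placement_rate * residence_years


def dressed_weight(live_weight: float, dressing_fraction: float) -> float:
    """Dressed (carcass) weight from live weight and dressing fraction."""
    if not 0.0 < dressing_fraction < 1.0:
        raise ValueError(f"dressing_fraction must be in (0, 1), got {dressing_fraction}")
    if live_weight < 0:
        raise ValueError("live_weight must be non-negative")
    return live_weight * dressing_fraction


def breed_slaughter_rate(baseline: NationalBaseline, breed: BreedSpec,
                         units: UnitRegistry = UNITS) -> float:
    """Annual slaughter rate for a breed holding dressed production constant.

    In multiplier mode the rate is the baseline rate times the breed's
    slaughter multiplier. In weight mode the baseline annual dressed
    production is divided by the breed's dressed weight (scaled live weight ×
    its dressing fraction). Both parameterizations conserve annual dressed
    meat output.
    """
    if breed.mode == "multiplier":
        return baseline.slaughter_rate * breed.slaughter_multiplier
    w_dressed = dressed_weight(breed.scaled_live_weight, breed.dressing_fraction)
    if w_dressed <= 0:
        raise ValueError("breed dressed weight must be positive")
    return baseline.annual_dressed_production(units) * units.kg_per_mmt / w_dressed


def breed_flock(baseline: NationalBaseline, breed: BreedSpec,
                units: UnitRegistry = UNITS) -> FlockState:
    """Steady-state national flock for one breed at full (baseline) production.

    The fattening population follows from the breed slaughter rate and
    residence; the breeding flock keeps the conventional breeding-to-
    fattening population ratio, and hen placements follow from the hen
    residence time.
    """
    slaughter = breed_slaughter_rate(baseline, breed, units)
    fattening = steady_state_population(slaughter, breed.residence, units)

    base_fattening = steady_state_population(
        baseline.slaughter_rate, baseline.broiler_residence, units
    )
    base_breeding = steady_state_population_years(
        baseline.hen_placement_rate, baseline.hen_residence
    )
    breeding = base_breeding * fattening / base_fattening
    hen_placements = breeding / baseline.hen_residence
    return FlockState(
        fattening_population=fattening,
        breeding_population=breeding,
        fattening_placement_rate=slaughter,
        hen_placement_rate=hen_placements,
        breed=breed,
    )


def production_summary(baseline: NationalBaseline, breed: BreedSpec,
                       units: UnitRegistry = UNITS) -> ProductionSummary:
    """Per-bird dressed weight and annual production mass for a breed's flock."""
    slaughter = breed_slaughter_rate(baseline, breed, units)
    dressed_total = baseline.annual_dressed_production(units)
    w_dressed = dressed_total * units.kg_per_mmt / slaughter
    w_live = w_dressed / breed.dressing_fraction
    return ProductionSummary(
        dressed_weight_per_bird=w_dressed,
        annual_dressed_production=dressed_total,
        annual_live_production=slaughter * w_live / units.kg_per_mmt,
    )
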