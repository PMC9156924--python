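"""Direct and indirect land-use accounting.

Direct land is the housing or pasture footprint of the standing fattening
flock: CAFO floor space at 0.0743 m²/bird, outdoor access adding an outdoor
area equal to 75% of the indoor floor space, or pasture at 10.12 m²/bird.

Indirect land is the maize and soy cropland growing the flock's feed: the
annual feed bill is split by the national feed composition, and each crop's
mass is divided by its national average yield (tonnes/acre) to give acres,
converted to km². The "other" feed fraction (minerals, by-products) is
conservatively assigned zero cropland. Management choice never changes feed
demand, so indirect land depends on the breed only.
"""

from __future__ import annotations

from dataclasses import dataclass

from .demographics import FlockState
from .parameters import FeedModel, ManagementKind, ManagementSpec, NationalBaseline
from .units import UNITS, UnitRegistry

__all__ = [
    "LandFootprint",
    "direct_land",
    "cropland_from_masses",
    "feed_demand",
    "footprint",
]


@dataclass(frozen=True)
class LandFootprint:
    """One flock × management land account, all areas in km²."""

    direct: float
    indirect_maize: float
    indirect_soy: float
    annual_feed: float  # MMT/yr
    management: ManagementKind

    @property
    def indirect(self) -> float:
        """Total feed cropland, km²."""
        return self.indirect_maize + self.indirect_soy

    @property
    def total(self) -> float:
        """Direct plus indirect land, km²."""
        return self.direct + self.indirect_maize + self.indirect_soy

    def to_row(self) -> dict[str, float | str]:
        """One CSV row with unit-suffixed headers."""
        return {
            "management": self.management.value,
            "direct_km2": self.direct,
            "indirect_maize_km2": self.indirect_maize,
            "indirect_soy_km2": self.indirect_soy,
            "total_km2": self.total,
            "annual_feed_mmt_per_yr": self.annual_feed,
        }


def direct_land(flock: FlockState, mgmt: ManagementSpec,
                units: UnitRegistry = UNITS) -> float:
    """Direct housing/pasture land for a flock under one management, km²."""
    pop = flock.fattening_population
    if mgmt.kind is ManagementKind.CAFO:
        area_m2 = pop * mgmt.cafo_stocking
    elif mgmt.kind is ManagementKind.OUTDOOR:
        area_m2 = pop * mgmt.cafo_stocking * (1.0 + mgmt.outdoor_fraction)
    elif mgmt.kind is ManagementKind.PASTURE:
        area_m2 = pop * mgmt.pasture_stocking
    else:  # pragma: no cover - enum is closed
        raise ValueError(f"unknown management kind: {mgmt.kind!r}")
    return area_m2 / units.m2_per_km2


def cropland_from_masses(maize: float, soy: float, feed_model: FeedModel,
                         units: UnitRegistry = UNITS) -> tuple[float, float]:
    """Cropland for given annual maize and soy masses.

    Parameters
    ----------
    maize, soy : float
        Annual crop masses in MMT.

    Returns
    -------
    (float, float)
        Maize and soy cropland in km² (mass ÷ yield gives acres, converted
        through the acre area).
    """
    if maize < 0 or soy < 0:
        raise ValueError("crop masses must be non-negative")
    if feed_model.maize_yield <= 0 or feed_model.soy_yield <= 0:
        raise ValueError("crop yields must be positive")
    tonnes_per_mmt = units.kg_per_mmt / 1000.0
    maize_km2 = maize * tonnes_per_mmt / feed_model.maize_yield * feed_model.acre_area / units.m2_per_km2
    soy_km2 = soy * tonnes_per_mmt / feed_model.soy_yield * feed_model.acre_area / units.m2_per_km2
    return maize_km2, soy_km2


def feed_demand(flock: FlockState, feed_model: FeedModel,
                units: UnitRegistry = UNITS) -> tuple[float, float, float]:
    """Annual feed demand of a flock and its per-crop masses.

    Returns
    -------
    (total, maize, soy) : tuple of float
        Total feed and maize/soy masses, MMT/yr. Total feed is the slaughter
        rate times the breed's feed per bird; crop masses follow the feed
        composition (the "other" fraction carries no cropland downstream).
    """
    if flock.breed.feed_per_bird is None or flock.breed.feed_per_bird <= 0:
        raise ValueError(f"breed {flock.breed.name!r} has no feed_per_bird set")
    total = flock.slaughter_rate * flock.breed.feed_per_bird / units.kg_per_mmt
    return total, total * feed_model.maize_fraction, total * feed_model.soy_fraction


def footprint(flock: FlockState, mgmt: ManagementSpec, feed_model: FeedModel,
              baseline: NationalBaseline | None = None,
              baseline_mode: bool = False,
              units: UnitRegistry = UNITS) -> LandFootprint:
    """Assemble the full direct + indirect land footprint of a scenario flock.

    With ``baseline_mode`` the reported national per-crop masses in
    ``baseline`` (35.56 MMT maize, 15.78 MMT soy by default) are used
    directly instead of composition × total feed; the two differ by ~1.4%
    because the reported masses do not exactly match the composition
    fractions, and the reported masses are authoritative for the
    conventional system.
    """
    if baseline_mode:
        if baseline is None:
            raise ValueError("baseline_mode requires the national baseline")
        total_feed = baseline.feed_total
        maize_mass, soy_mass = baseline.maize_mass, baseline.soy_mass
    else:
        total_feed, maize_mass, soy_mass = feed_demand(flock, feed_model, units)
    maize_km2, soy_km2 = cropland_from_masses(maize_mass, soy_mass, feed_model, units)
    return LandFootprint(
        direct=direct_land(flock, mgmt, units),
        indirect_maize=maize_km2,
        indirect_soy=soy_km2,
        annual_feed=total_feed,
        management=mgmt.kind,
    )
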