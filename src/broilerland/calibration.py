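"""Calibration of breed parameters from breeder performance-objective tables.

Breeder-published performance objectives (age-by-age live weight and
cumulative feed intake) describe birds grown under ideal conditions and
systematically overstate average commercial performance. Two top-down
corrections reconcile them with national statistics:

* the **weight scale factor** — USDA mean slaughter weight at 47 days divided
  by the breeder-table Ross weight at 47 days — rescales every breed's live
  weight to commercial reality;
* the **performance scale factor** — national feed use per slaughtered bird
  divided by the breeder-table Ross cumulative feed at 47 days — inflates
  every breed's feed requirement the same way (≈1.35 with national defaults).

Both are pointwise ratios at the conventional slaughter age; tables are
linearly interpolated between rows when an age falls between entries.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .parameters import BreedSpec, ConfigurationError, NationalBaseline
from .units import UNITS, UnitRegistry

__all__ = [
    "PerformanceTable",
    "read_performance_table",
    "weight_scale_factor",
    "scaled_slaughter_weight",
    "performance_scale_factor",
    "calibrate_breed",
]

#: Delimited-text performance table header.
PERFORMANCE_TABLE_COLUMNS = ["age_days", "live_weight_kg", "cumulative_feed_kg"]


@dataclass(frozen=True)
class PerformanceTable:
    """One breed's performance objectives: live weight and cumulative feed by age."""

    breed: str
    age_days: tuple[float, ...]
    live_weight_kg: tuple[float, ...]
    cumulative_feed_kg: tuple[float, ...]
    source: str = "synthetic"  # "supplementary" | "synthetic"

    def __post_init__(self) -> None:
        age = np.asarray(self.age_days, dtype=float)
        w = np.asarray(self.live_weight_kg, dtype=float)
        f = np.asarray(self.cumulative_feed_kg, dtype=float)
        if not (len(age) == len(w) == len(f)) or len(age) == 0:
            raise ValueError("table columns must be non-empty and equal length")
        if np.any(np.diff(age) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(np.diff(w) < 0) or np.any(np.diff(f) < 0):
            raise ValueError("live weight and cumulative feed must be non-decreasing")

    def _interp(self, values: Sequence[float], age: float, what: str) -> float:
        ages = np.asarray(self.age_days, dtype=float)
        if age < ages[0] or age > ages[-1]:
            raise ValueError(
                f"{self.breed} table covers days {ages[0]:g}–{ages[-1]:g}; "
                f"cannot evaluate {what} at day {age:g}"
            )
        return float(np.interp(age, ages, np.asarray(values, dtype=float)))

    def weight_at(self, age: float) -> float:
        """Live weight (kg) at an age, linearly interpolated."""
        return self._interp(self.live_weight_kg, age, "live weight")

    def feed_at(self, age: float) -> float:
        """Cumulative feed intake (kg) at an age, linearly interpolated."""
        return self._interp(self.cumulative_feed_kg, age, "cumulative feed")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "age_days": self.age_days,
                "live_weight_kg": self.live_weight_kg,
                "cumulative_feed_kg": self.cumulative_feed_kg,
            }
        )


def read_performance_table(source: str | os.PathLike, breed: str,
                           table_source: str = "supplementary") -> PerformanceTable:
    """Read a performance table from CSV with header
    ``age_days,live_weight_kg,cumulative_feed_kg``."""
    df = pd.read_csv(source)
    missing = set(PERFORMANCE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"performance table missing column(s): {sorted(missing)}")
    return PerformanceTable(
        breed=breed,
        age_days=tuple(df["age_days"].astype(float)),
        live_weight_kg=tuple(df["live_weight_kg"].astype(float)),
        cumulative_feed_kg=tuple(df["cumulative_feed_kg"].astype(float)),
        source=table_source,
    )


def weight_scale_factor(baseline: NationalBaseline, ross_table: PerformanceTable) -> float:
    """USDA mean slaughter weight ÷ breeder-table Ross weight at the
    conventional slaughter age."""
    table_weight = ross_table.weight_at(baseline.broiler_residence)
    if table_weight <= 0:
        raise ValueError("table weight at slaughter age must be positive")
    return baseline.mean_live_weight / table_weight


def scaled_slaughter_weight(breed_table: PerformanceTable, factor: float,
                            slaughter_age: float) -> float:
    """Breed live slaughter weight rescaled to commercial performance."""
    if factor <= 0:
        raise ValueError("weight scale factor must be positive")
    return breed_table.weight_at(slaughter_age) * factor


def performance_scale_factor(baseline: NationalBaseline, ross_table: PerformanceTable,
                             units: UnitRegistry = UNITS) -> float:
    """National feed per slaughtered bird ÷ breeder-table Ross cumulative
    feed at the conventional slaughter age (≈1.35 with defaults)."""
    table_feed = ross_table.feed_at(baseline.broiler_residence)
    if table_feed <= 0:
        raise ValueError("table cumulative feed at slaughter age must be positive")
    return baseline.feed_per_bird(units) / table_feed


def calibrate_breed(breed_table: PerformanceTable, ross_table: PerformanceTable,
                    baseline: NationalBaseline, slaughter_age: float,
                    dressing_fraction: float = 0.76,
                    units: UnitRegistry = UNITS) -> BreedSpec:
    """Build a weight-parameterized :class:`BreedSpec` from performance tables.

    The breed's live weight at ``slaughter_age`` is rescaled by the weight
    scale factor and its cumulative feed by the performance scale factor,
    both derived from the Ross table against national statistics. Calibrating
    the Ross table against itself at the conventional age and dressing
    fraction reproduces the national per-bird figures exactly.
    """
    w_factor = weight_scale_factor(baseline, ross_table)
    p_factor = performance_scale_factor(baseline, ross_table, units)
    return BreedSpec(
        name=breed_table.breed,
        residence=slaughter_age,
        scaled_live_weight=scaled_slaughter_weight(breed_table, w_factor, slaughter_age),
        dressing_fraction=dressing_fraction,
        feed_per_bird=breed_table.feed_at(slaughter_age) * p_factor,
    )
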