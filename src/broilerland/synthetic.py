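"""Synthetic breeder performance tables and national statistics.

Real breeder performance objectives are published as booklets and are not
bundled here; this module generates stand-in tables with known ground truth
so that calibration and the full pipeline are testable end to end offline.

Each breed's live-weight curve is a Gompertz saturating function

    w(t) = A · exp(−exp(−k (t − T)))

with the amplitude ``A`` anchored so the curve passes exactly through the
breed's target weight at its slaughter age; cumulative feed is a monotone
power function of weight anchored the same way. Because both anchors are
exact, every calibration quantity has a closed-form ground truth. Optional
multiplicative measurement noise is truncated (running maximum) to keep the
tables monotone, and all randomness flows from the single generator seed.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import numpy as np
import yaml

from .calibration import PerformanceTable
from .parameters import NationalBaseline
from .units import UNITS, UnitRegistry

__all__ = [
    "BreedCurve",
    "GeneratorSpec",
    "default_generator_spec",
    "generate_performance_table",
    "national_totals",
    "generate_national_stats",
    "write_synthetic_suite",
]


@dataclass(frozen=True)
class BreedCurve:
    """Ground-truth growth and feed-intake curve for one synthetic breed."""

    name: str
    slaughter_age: float  # days
    weight_at_slaughter: float  # kg, breeder-table (pre-scaling) value
    feed_at_slaughter: float  # kg cumulative, breeder-table value
    growth_rate: float  # 1/day, Gompertz rate constant
    inflection_age: float  # days, Gompertz inflection
    feed_exponent: float = 1.25  # cumulative feed ∝ weight^b, b ≥ 1

    def _shape(self, t: np.ndarray | float) -> np.ndarray | float:
        return np.exp(-np.exp(-self.growth_rate * (np.asarray(t, dtype=float)
                                                   - self.inflection_age)))

    def weight(self, t: np.ndarray | float) -> np.ndarray | float:
        """Analytic live weight (kg) at age ``t`` days."""
        return self.weight_at_slaughter * self._shape(t) / self._shape(self.slaughter_age)

    def feed(self, t: np.ndarray | float) -> np.ndarray | float:
        """Analytic cumulative feed (kg) at age ``t`` days."""
        rel = self.weight(t) / self.weight_at_slaughter
        return self.feed_at_slaughter * np.asarray(rel) ** self.feed_exponent


@dataclass(frozen=True)
class GeneratorSpec:
    """Full ground truth for a synthetic data suite.

    ``true_weight_scale`` and ``true_performance_scale`` are the factors the
    calibration step should recover: the generated national statistics are
    constructed as scaled versions of the Ross curve's per-bird values.
    """

    breeds: tuple[BreedCurve, ...]
    seed: int = 0
    noise_scale: float = 0.0  # relative s.d. of multiplicative table noise
    true_weight_scale: float = 2.93 / 3.35
    true_performance_scale: float = 1.35
    flock_slaughter_rate: float = 9.25e9  # birds/yr
    maize_share: float = 35.56 / 58.1  # reported crop shares of total feed
    soy_share: float = 15.78 / 58.1
    hen_placement_rate: float = 98.0e6
    hen_residence: float = 0.767
    broiler_residence: float = 47.0
    dressing_fraction: float = 0.74

    def curve(self, breed: str) -> BreedCurve:
        for c in self.breeds:
            if c.name == breed:
                return c
        raise KeyError(f"no synthetic curve for breed {breed!r}")

    def ground_truth(self, breed: str) -> dict[str, float]:
        """Closed-form truth for one breed at its slaughter age."""
        c = self.curve(breed)
        return {
            "slaughter_age_days": c.slaughter_age,
            "table_weight_kg": c.weight_at_slaughter,
            "table_feed_kg": c.feed_at_slaughter,
            "scaled_weight_kg": c.weight_at_slaughter * self.true_weight_scale,
            "scaled_feed_kg": c.feed_at_slaughter * self.true_performance_scale,
        }


def default_generator_spec(seed: int = 0, noise_scale: float = 0.0) -> GeneratorSpec:
    """Paper-like synthetic suite.

    The Ross curve is anchored so that national statistics divided by its
    table values give a weight scale factor of 2.93/3.35 ≈ 0.8746 and a
    performance scale factor of ≈1.35; the slower breeds are anchored so
    their scaled weights sit 0.409/0.661/0.499 kg below the conventional
    2.93 kg and their scaled feed matches the effective per-bird feed of the
    default breed set.
    """
    ws = 2.93 / 3.35
    breeds = (
        BreedCurve("Ross308", 47.0, 3.35, 4.653, growth_rate=0.045, inflection_age=32.0),
        BreedCurve("RC", 57.0, (2.93 - 0.409) / ws, 6.456905643706603 / 1.35,
                   growth_rate=0.040, inflection_age=36.0),
        BreedCurve("RG", 57.0, (2.93 - 0.661) / ws, 5.652662056123428 / 1.35,
                   growth_rate=0.038, inflection_age=36.0),
        BreedCurve("RR", 69.0, (2.93 - 0.499) / ws, 6.535553033115864 / 1.35,
                   growth_rate=0.034, inflection_age=42.0),
    )
    return GeneratorSpec(breeds=breeds, seed=seed, noise_scale=noise_scale)


def _breed_rng(spec: GeneratorSpec, breed: str) -> np.random.Generator:
    index = next(i for i, c in enumerate(spec.breeds) if c.name == breed)
    return np.random.default_rng([spec.seed, index])


def generate_performance_table(spec: GeneratorSpec, breed: str,
                               margin_days: int = 7) -> PerformanceTable:
    """Generate daily performance rows from day 0 past the slaughter age.

    With zero noise the rows are the exact analytic curve values; with noise
    each value is jittered multiplicatively and the running maximum is taken
    so the table stays monotone. The same spec and seed always produce the
    identical table.
    """
    c = spec.curve(breed)
    days = np.arange(0.0, math.ceil(c.slaughter_age) + margin_days + 1)
    w = np.asarray(c.weight(days), dtype=float)
    f = np.asarray(c.feed(days), dtype=float)
    if spec.noise_scale > 0:
        rng = _breed_rng(spec, breed)
        w = w * (1.0 + spec.noise_scale * rng.standard_normal(len(days)))
        f = f * (1.0 + spec.noise_scale * rng.standard_normal(len(days)))
        w = np.maximum.accumulate(np.clip(w, 0.0, None))
        f = np.maximum.accumulate(np.clip(f, 0.0, None))
    return PerformanceTable(
        breed=breed,
        age_days=tuple(days),
        live_weight_kg=tuple(w),
        cumulative_feed_kg=tuple(f),
        source="synthetic",
    )


def national_totals(spec: GeneratorSpec,
                    true_breed_mix: Optional[Mapping[str, float]] = None,
                    flock_slaughter_rate: Optional[float] = None,
                    units: UnitRegistry = UNITS) -> dict[str, float]:
    """Top-down national totals implied by the generator's ground truth.

    ``true_breed_mix`` gives slaughter-share weights per breed (defaults to
    all-Ross); per-bird truth × flock size gives the totals, so a zero
    flock size yields zero totals.
    """
    rate = spec.flock_slaughter_rate if flock_slaughter_rate is None else flock_slaughter_rate
    if rate < 0:
        raise ValueError("flock slaughter rate must be non-negative")
    mix = dict(true_breed_mix) if true_breed_mix else {"Ross308": 1.0}
    total_share = sum(mix.values())
    if total_share <= 0:
        raise ValueError("breed mix shares must sum to a positive value")
    live_weight = sum(
        share * spec.ground_truth(b)["scaled_weight_kg"] for b, share in mix.items()
    ) / total_share
    feed_per_bird = sum(
        share * spec.ground_truth(b)["scaled_feed_kg"] for b, share in mix.items()
    ) / total_share
    feed_total = rate * feed_per_bird / units.kg_per_mmt
    return {
        "slaughter_rate": rate,
        "mean_live_weight": live_weight,
        "feed_total": feed_total,
        "maize_mass": feed_total * spec.maize_share,
        "soy_mass": feed_total * spec.soy_share,
    }


def generate_national_stats(spec: GeneratorSpec,
                            true_breed_mix: Optional[Mapping[str, float]] = None,
                            reporting_noise: float = 0.0,
                            units: UnitRegistry = UNITS) -> NationalBaseline:
    """Build a :class:`NationalBaseline` consistent with the ground truth.

    Optional multiplicative ``reporting_noise`` (relative s.d., truncated at
    ±3σ to keep values positive) emulates survey error in the reported
    totals; the per-crop masses stay proportional to the noisy feed total so
    the record remains internally consistent.
    """
    totals = national_totals(spec, true_breed_mix, units=units)
    if reporting_noise > 0:
        rng = np.random.default_rng([spec.seed, len(spec.breeds)])
        for key in ("slaughter_rate", "mean_live_weight", "feed_total"):
            eps = float(np.clip(rng.standard_normal(), -3.0, 3.0))
            totals[key] *= 1.0 + reporting_noise * eps
        totals["maize_mass"] = totals["feed_total"] * spec.maize_share
        totals["soy_mass"] = totals["feed_total"] * spec.soy_share
    return NationalBaseline(
        slaughter_rate=totals["slaughter_rate"],
        broiler_residence=spec.broiler_residence,
        hen_placement_rate=spec.hen_placement_rate,
        hen_residence=spec.hen_residence,
        mean_live_weight=totals["mean_live_weight"],
        dressing_fraction=spec.dressing_fraction,
        feed_total=totals["feed_total"],
        maize_mass=totals["maize_mass"],
        soy_mass=totals["soy_mass"],
    )


def write_synthetic_suite(spec: GeneratorSpec, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write per-breed performance CSVs plus a ground-truth manifest (YAML).

    Returns a map of artifact name → path.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: dict[str, str] = {}
    manifest: dict[str, object] = {
        "seed": spec.seed,
        "noise_scale": spec.noise_scale,
        "true_weight_scale": spec.true_weight_scale,
        "true_performance_scale": spec.true_performance_scale,
        "breeds": {},
    }
    for c in spec.breeds:
        table = generate_performance_table(spec, c.name)
        path = os.path.join(out_dir, f"performance_{c.name}.csv")
        table.to_frame().to_csv(path, index=False)
        paths[c.name] = path
        manifest["breeds"][c.name] = {  # type: ignore[index]
            k: float(v) for k, v in spec.ground_truth(c.name).items()
        }
    manifest_path = os.path.join(out_dir, "ground_truth.yaml")
    with open(manifest_path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    paths["manifest"] = manifest_path
    return paths
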