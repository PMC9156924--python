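"""Model constants and parameter records.

Every constant that anchors the national broiler model lives here: the
conventional-system national baseline (slaughter rate, residence times, live
and dressed weight, national feed use), the per-breed demographic and feed
parameters, the stocking rules for the three management systems, and the
feed-composition / crop-yield model that converts feed mass into cropland.

Records are pydantic models so that units and ranges are validated at
construction, and a YAML config plus a delimited-text breed table provide the
override surface.
"""

from __future__ import annotations

import enum
import io
import os
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .units import UNITS, UnitRegistry

__all__ = [
    "NationalBaseline",
    "BreedSpec",
    "ManagementKind",
    "ManagementSpec",
    "FeedModel",
    "ParameterSet",
    "ConfigurationError",
    "default_baseline",
    "default_breeds",
    "default_managements",
    "default_feed_model",
    "load_parameters",
    "dump_parameters",
    "read_breed_table",
    "write_breed_table",
    "BREED_TABLE_COLUMNS",
]


class ConfigurationError(ValueError):
    """Raised when a config source is malformed or names an unknown field."""


class NationalBaseline(BaseModel):
    """Conventional-system national statistics (US, 2018/2019 reporting).

    The baseline describes Ross 308 broilers raised in concentrated animal
    feeding operations (CAFOs): the annual slaughter rate, the grow-out and
    hen-laying residence times, mean live weight and dressing fraction, and
    the national feed bill split into maize, soy and other feed.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    slaughter_rate: float = Field(default=9.25e9, gt=0, description="birds/yr")
    broiler_residence: float = Field(default=47.0, gt=0, description="days")
    hen_placement_rate: float = Field(default=98.0e6, gt=0, description="hens/yr")
    hen_residence: float = Field(default=0.767, gt=0, description="years")
    mean_live_weight: float = Field(default=2.93, gt=0, description="kg/bird")
    dressing_fraction: float = Field(default=0.74, gt=0, lt=1)
    feed_total: float = Field(default=58.1, gt=0, description="MMT/yr")
    maize_mass: float = Field(default=35.56, gt=0, description="MMT/yr")
    soy_mass: float = Field(default=15.78, gt=0, description="MMT/yr")

    @model_validator(mode="after")
    def _crops_within_total(self) -> "NationalBaseline":
        if self.maize_mass + self.soy_mass > self.feed_total + 1e-9:
            raise ValueError(
                "maize_mass + soy_mass exceeds feed_total "
                f"({self.maize_mass} + {self.soy_mass} > {self.feed_total})"
            )
        return self

    @property
    def dressed_weight(self) -> float:
        """Mean dressed (carcass) weight, kg/bird."""
        return self.mean_live_weight * self.dressing_fraction

    def annual_dressed_production(self, units: UnitRegistry = UNITS) -> float:
        """Annual dressed chicken-meat production, MMT/yr."""
        return self.slaughter_rate * self.dressed_weight / units.kg_per_mmt

    def feed_per_bird(self, units: UnitRegistry = UNITS) -> float:
        """National feed use per slaughtered bird, kg/bird."""
        return self.feed_total * units.kg_per_mmt / self.slaughter_rate


class BreedSpec(BaseModel):
    """Demographic and feed parameters for one broiler breed.

    Exactly one of ``slaughter_multiplier`` (ratio of the breed's slaughter
    rate to the baseline rate at equal dressed production) or
    ``scaled_live_weight`` (the breed's live slaughter weight after scaling
    to national statistics) drives the demographic scaling; the active mode
    is reported by :attr:`mode`.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    name: str
    residence: float = Field(gt=0.999, description="days; grow-out period")
    slaughter_multiplier: Optional[float] = Field(default=None, gt=0)
    scaled_live_weight: Optional[float] = Field(default=None, gt=0, description="kg/bird")
    dressing_fraction: float = Field(gt=0, lt=1)
    feed_per_bird: float = Field(gt=0, description="kg feed/bird over grow-out")

    @model_validator(mode="after")
    def _exactly_one_mode(self) -> "BreedSpec":
        if (self.slaughter_multiplier is None) == (self.scaled_live_weight is None):
            raise ValueError(
                f"breed {self.name!r}: exactly one of slaughter_multiplier or "
                "scaled_live_weight must be given"
            )
        return self

    @property
    def mode(self) -> str:
        """Demographic parameterization mode: ``"multiplier"`` or ``"weight"``."""
        return "multiplier" if self.slaughter_multiplier is not None else "weight"


class ManagementKind(str, enum.Enum):
    """Housing / grow-out management system."""

    CAFO = "cafo"
    OUTDOOR = "outdoor"
    PASTURE = "pasture"


class ManagementSpec(BaseModel):
    """Stocking rules for the three management systems.

    CAFO stocking follows the National Chicken Council grow-out house
    description (20 000 birds per 1486 m² house → 0.0743 m²/bird); outdoor
    access adds an outdoor area equal to 75% of the indoor floor space on top
    of the CAFO footprint; pasture stocking follows the Humane Farm Animal
    Care minimum of 0.0101 km² per 1000 birds (10.12 m²/bird, their rounding).
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    kind: ManagementKind
    cafo_stocking: float = Field(default=0.0743, gt=0, description="m²/bird")
    outdoor_fraction: float = Field(default=0.75, ge=0)
    pasture_stocking: float = Field(default=10.12, gt=0, description="m²/bird")


class FeedModel(BaseModel):
    """Feed composition and crop yields converting feed mass to cropland.

    Fractions are the national feed composition (maize/soy/other); the
    "other" fraction is conservatively assumed non-crop and contributes zero
    cropland. Yields are national averages in tonnes per acre.
    """

    model_config = ConfigDict(frozen=True, extra="forbid")

    maize_fraction: float = Field(default=0.603, ge=0, le=1)
    soy_fraction: float = Field(default=0.268, ge=0, le=1)
    other_fraction: float = Field(default=0.129, ge=0, le=1)
    maize_yield: float = Field(default=4.802, gt=0, description="tonnes/acre")
    soy_yield: float = Field(default=1.403, gt=0, description="tonnes/acre")
    acre_area: float = Field(default=UNITS.m2_per_acre, gt=0, description="m²/acre")

    @model_validator(mode="after")
    def _fractions_sum_to_one(self) -> "FeedModel":
        total = self.maize_fraction + self.soy_fraction + self.other_fraction
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"feed fractions sum to {total}, expected 1")
        return self


# Effective feed per bird (kg) for the default breeds. The baseline figure is
# the national feed bill divided by the slaughter rate (58.1e9 kg / 9.25e9
# birds); the slower-breed figures are fixed by inverting each breed's
# national indirect-cropland requirement (91 229 / 90 437 / 98 521 km² for
# RC / RG / RR) through the feed-composition and crop-yield chain at that
# breed's slaughter rate. tests/test_parameters.py re-runs this inversion.
ROSS_FEED_PER_BIRD = 58.1e9 / 9.25e9  # 6.281081... kg/bird
RC_FEED_PER_BIRD = 6.456905643706603
RG_FEED_PER_BIRD = 5.652662056123428
RR_FEED_PER_BIRD = 6.535553033115864


def default_baseline() -> NationalBaseline:
    """The conventional-system national baseline with all default constants."""
    return NationalBaseline()


def default_breeds() -> list[BreedSpec]:
    """The four modelled breeds with default parameters.

    Ross 308 is the conventional fast-growing breed (47-day grow-out,
    dressing 74%); Ranger Classic (RC) and Ranger Gold (RG) are
    intermediate-growing (57 days) and Rowan Ranger (RR) slow-growing
    (69 days), all with dressing 76%. The slaughter multipliers (1.1922,
    1.35, 1.272) hold annual dressed production at the baseline level.
    """
    return [
        BreedSpec(
            name="Ross308",
            residence=47,
            slaughter_multiplier=1.0,
            dressing_fraction=0.74,
            feed_per_bird=ROSS_FEED_PER_BIRD,
        ),
        BreedSpec(
            name="RC",
            residence=57,
            slaughter_multiplier=1.1922,
            dressing_fraction=0.76,
            feed_per_bird=RC_FEED_PER_BIRD,
        ),
        BreedSpec(
            name="RG",
            residence=57,
            slaughter_multiplier=1.35,
            dressing_fraction=0.76,
            feed_per_bird=RG_FEED_PER_BIRD,
        ),
        BreedSpec(
            name="RR",
            residence=69,
            slaughter_multiplier=1.272,
            dressing_fraction=0.76,
            feed_per_bird=RR_FEED_PER_BIRD,
        ),
    ]


def default_managements() -> list[ManagementSpec]:
    """The three management systems with default stocking values."""
    return [ManagementSpec(kind=k) for k in ManagementKind]


def default_feed_model() -> FeedModel:
    """Default national feed composition and crop yields."""
    return FeedModel()


class ParameterSet(NamedTuple):
    """A validated, fully resolved parameter bundle.

    ``provenance`` maps ``section.field`` to ``"paper-default"`` or
    ``"user-supplied"`` so report logs can state where each value came from.
    """

    baseline: NationalBaseline
    breeds: list[BreedSpec]
    managements: list[ManagementSpec]
    feed_model: FeedModel
    provenance: dict[str, str]


_SECTION_MODELS = {"baseline": NationalBaseline, "feed": FeedModel}


def _build_section(model, overrides: Mapping, section: str, provenance: dict) -> object:
    defaults = model()
    for key in overrides:
        if key not in model.model_fields:
            raise ConfigurationError(f"unknown field {section}.{key}")
    merged = {**defaults.model_dump(), **dict(overrides)}
    for field in model.model_fields:
        provenance[f"{section}.{field}"] = (
            "user-supplied" if field in overrides else "paper-default"
        )
    try:
        return model(**merged)
    except Exception as exc:  # pydantic ValidationError carries field names
        raise ConfigurationError(f"invalid {section} configuration: {exc}") from exc


def load_parameters(config_source: str | os.PathLike | Mapping | None = None) -> ParameterSet:
    """Load a full parameter set from a YAML config, filling defaults.

    Parameters
    ----------
    config_source
        YAML text, a path to a YAML file, a pre-parsed mapping, or ``None``
        / empty for the pure default parameter set. Recognized sections:
        ``baseline``, ``feed``, ``management`` (per-field stocking
        overrides applied to all three systems), and ``breeds`` (a list of
        breed records replacing the defaults; omitted optional fields are
        not filled per-breed).

    Returns
    -------
    ParameterSet
        Validated records plus a field-level provenance map.
    """
    if config_source is None:
        raw: Mapping = {}
    elif isinstance(config_source, Mapping):
        raw = config_source
    else:
        text = None
        if isinstance(config_source, os.PathLike) or (
            isinstance(config_source, str)
            and "\n" not in config_source
            and os.path.exists(config_source)
        ):
            with open(config_source, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            text = str(config_source)
        try:
            raw = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed config: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigurationError("config root must be a mapping")

    known = {"baseline", "feed", "management", "breeds"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config section(s): {sorted(unknown)}")

    provenance: dict[str, str] = {}
    baseline = _build_section(NationalBaseline, raw.get("baseline", {}), "baseline", provenance)
    feed_model = _build_section(FeedModel, raw.get("feed", {}), "feed", provenance)

    mgmt_over = dict(raw.get("management", {}))
    for key in mgmt_over:
        if key not in ManagementSpec.model_fields or key == "kind":
            raise ConfigurationError(f"unknown field management.{key}")
    managements = []
    for kind in ManagementKind:
        try:
            managements.append(ManagementSpec(kind=kind, **mgmt_over))
        except Exception as exc:
            raise ConfigurationError(f"invalid management configuration: {exc}") from exc
    for field in ManagementSpec.model_fields:
        if field == "kind":
            continue
        provenance[f"management.{field}"] = (
            "user-supplied" if field in mgmt_over else "paper-default"
        )

    if "breeds" in raw:
        try:
            breeds = [BreedSpec(**rec) for rec in raw["breeds"]]
        except Exception as exc:
            raise ConfigurationError(f"invalid breed configuration: {exc}") from exc
        provenance["breeds"] = "user-supplied"
    else:
        breeds = default_breeds()
        provenance["breeds"] = "paper-default"

    return ParameterSet(baseline, breeds, managements, feed_model, provenance)


def dump_parameters(params: ParameterSet) -> str:
    """Serialize a parameter set to YAML text; round-trips through
    :func:`load_parameters` bit-identically."""
    doc = {
        "baseline": params.baseline.model_dump(),
        "feed": params.feed_model.model_dump(),
        "management": {
            k: v
            for k, v in params.managements[0].model_dump().items()
            if k != "kind"
        },
        "breeds": [
            {k: v for k, v in b.model_dump().items() if v is not None}
            for b in params.breeds
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


#: Delimited-text breed table header (unit-suffixed).
BREED_TABLE_COLUMNS = [
    "name",
    "residence_days",
    "slaughter_multiplier",
    "dressing_fraction",
    "feed_per_bird_kg",
]


def read_breed_table(source: str | os.PathLike | io.IOBase) -> list[BreedSpec]:
    """Read breeds from a CSV table with header ``name,residence_days,
    slaughter_multiplier,dressing_fraction,feed_per_bird_kg``."""
    df = pd.read_csv(source)
    missing = set(BREED_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigurationError(f"breed table missing column(s): {sorted(missing)}")
    breeds = []
    for rec in df.to_dict("records"):
        try:
            breeds.append(
                BreedSpec(
                    name=str(rec["name"]),
                    residence=float(rec["residence_days"]),
                    slaughter_multiplier=float(rec["slaughter_multiplier"]),
                    dressing_fraction=float(rec["dressing_fraction"]),
                    feed_per_bird=float(rec["feed_per_bird_kg"]),
                )
            )
        except Exception as exc:
            raise ConfigurationError(f"invalid breed row {rec!r}: {exc}") from exc
    return breeds


def write_breed_table(breeds: Sequence[BreedSpec], target: str | os.PathLike | io.IOBase) -> None:
    """Write breeds to the CSV layout read by :func:`read_breed_table`."""
    rows = []
    for b in breeds:
        if b.mode != "multiplier":
            raise ConfigurationError(
                f"breed {b.name!r} is weight-parameterized; the CSV table carries multipliers"
            )
        rows.append(
            {
                "name": b.name,
                "residence_days": b.residence,
                "slaughter_multiplier": b.slaughter_multiplier,
                "dressing_fraction": b.dressing_fraction,
                "feed_per_bird_kg": b.feed_per_bird,
            }
        )
    pd.DataFrame(rows, columns=BREED_TABLE_COLUMNS).to_csv(target, index=False)
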