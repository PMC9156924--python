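"""Unit-conversion constants.

All conversions in the package route through this module so that a single
definition of the year length, the international acre, and the MMT (million
metric ton) is used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class UnitRegistry:
    """Fixed conversion constants.

    Attributes
    ----------
    days_per_year : float
        Calendar year length used to convert residence times (365).
    kg_per_mmt : float
        Kilograms per million metric tons (1e9).
    m2_per_km2 : float
        Square metres per square kilometre (1e6).
    m2_per_acre : float
        Square metres per international acre (4046.8564).
    """

    days_per_year: float = 365.0
    kg_per_mmt: float = 1e9
    m2_per_km2: float = 1e6
    m2_per_acre: float = 4046.8564


#: Shared default registry used throughout the package.
UNITS = UnitRegistry()
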