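"""Green water indicators: footprint and water productivity.

The green water footprint (GWF) of a rainfed crop is the volume of
evapotranspired precipitation water per tonne of yield,

    GWF = 10 * sum(ET_d) / Y        [m3/t]

where ET_d is the daily evapotranspiration in mm accumulated over the
length of the growing period, Y the yield in t/ha, and the factor 10
converts mm over one hectare to m3 (1 mm * 1 ha = 10 m3).  Water
productivity for yield is the reciprocal indicator,

    WPet = 100 * Y / sum(ET_d)      [kg/m3]

so that the exact identity ``GWF * WPet = 1000 kg/t`` holds for any
positive (yield, ET) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

from .crop_surrogate import SeasonResult
from .exceptions import CropFailureError, DomainError

__all__ = [
    "WaterIndicators",
    "green_water_footprint",
    "water_productivity",
    "indicators_from_season",
]

#: m3 of water per mm of depth over one hectare.
M3_PER_MM_HA = 10.0

#: kg per tonne; the GWF * WPet conservation constant.
KG_PER_TONNE = 1000.0


@dataclass(frozen=True)
class WaterIndicators:
    """Derived water indicators for one crop season."""

    gwf: float           # m3/t
    wpet: float          # kg/m3
    et_sum: float        # mm
    yield_t_ha: float    # t/ha
    season_precip: float  # mm


def green_water_footprint(et_sum: float, yield_t_ha: float) -> float:
    """Green water footprint in m3 per tonne of yield.

    Raises :class:`CropFailureError` for non-positive yield: a failed
    crop has an undefined footprint and must be reported explicitly.
    """
    if et_sum < 0:
        raise DomainError("et_sum must be >= 0")
    if yield_t_ha <= 0:
        raise CropFailureError(
            f"green water footprint undefined for yield {yield_t_ha} t/ha"
        )
    return M3_PER_MM_HA * et_sum / yield_t_ha


def water_productivity(yield_t_ha: float, et_sum: float) -> float:
    """Water productivity for yield in kg per m3 of evapotranspired water."""
    if et_sum <= 0:
        raise DomainError("water productivity undefined for et_sum <= 0")
    if yield_t_ha < 0:
        raise DomainError("yield must be >= 0")
    # t/ha per mm -> kg/m3: (1000 kg/t) / (10 m3 per mm ha) = 100
    return KG_PER_TONNE / M3_PER_MM_HA * yield_t_ha / et_sum


def indicators_from_season(result: SeasonResult) -> WaterIndicators:
    """Bundle the indicators for one simulated season."""
    return WaterIndicators(
        gwf=green_water_footprint(result.et_sum, result.yield_t_ha),
        wpet=water_productivity(result.yield_t_ha, result.et_sum),
        et_sum=result.et_sum,
        yield_t_ha=result.yield_t_ha,
        season_precip=result.season_precip,
    )
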