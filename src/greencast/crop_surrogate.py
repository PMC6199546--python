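"""A minimal water-driven crop simulator.

This is a declared surrogate for a full crop-water model (the AquaCrop
family): it keeps the core identity of that model class --

* phenology driven by growing degree-days (GDD) from planting to a
  maturity requirement, hard-capped by the end of the weather window;
* a single-layer soil-water bucket between wilting point and field
  capacity over the root zone, with overflow above capacity discarded
  as drainage/runoff;
* crop transpiration ``Tr = Ks * Kcb * ET0`` with a linear water-stress
  coefficient ``Ks`` once depletion exceeds the readily available water;
* soil evaporation ``E = Ke * ET0 * (1 - Kcb/Kcb_max)`` as a canopy
  shading proxy;
* biomass ``B = WP* * sum(Tr/ET0)`` (normalized water productivity) and
  yield ``Y = HI * B``

-- while deliberately omitting canopy-cover dynamics, stress effects on
the harvest index, CO2 response and fertility effects.  Reference
evapotranspiration defaults to the Hargreaves temperature/radiation
formula; a precomputed ET0 series can be supplied instead (e.g. from a
Penman-Monteith computation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DomainError
from .synthetic_weather import WeatherSeries, extraterrestrial_radiation

__all__ = [
    "CropParams",
    "SoilParams",
    "SeasonResult",
    "gdd",
    "hargreaves_et0",
    "run_season",
]

#: g/m2 -> t/ha.
GM2_TO_THA = 0.01


@dataclass(frozen=True)
class CropParams:
    """Phenology, canopy and water-productivity constants for one crop.

    ``kcb_stages`` holds the basal canopy coefficient for the four
    phenological stages (initial, development, mid-season, late) and
    ``stage_fractions`` the three internal stage boundaries as strictly
    increasing fractions of ``gdd_requirement``.  ``wp_star`` is the
    normalized water productivity in g/m2 per unit of accumulated
    Tr/ET0; ``hi`` the harvest index; ``depletion_fraction`` the share
    of total available water that can be depleted before transpiration
    is reduced.
    """

    name: str
    planting_doy: int
    gdd_requirement: float   # deg C day
    tbase: float             # deg C
    kcb_stages: tuple[float, float, float, float]
    stage_fractions: tuple[float, float, float]
    ke_soil: float           # soil evaporation coefficient
    wp_star: float           # g/m2 per unit sum(Tr/ET0)
    hi: float                # harvest index, (0, 1]
    root_depth: float        # m
    depletion_fraction: float  # p, (0, 1)

    def __post_init__(self) -> None:
        if len(self.kcb_stages) != 4 or len(self.stage_fractions) != 3:
            raise DomainError("need 4 Kcb values and 3 stage boundary fractions")
        if any(k < 0 for k in self.kcb_stages) or self.ke_soil < 0:
            raise DomainError("canopy and soil-evaporation coefficients must be >= 0")
        b = self.stage_fractions
        if not (0.0 < b[0] < b[1] < b[2] <= 1.0):
            raise DomainError("stage fractions must be strictly increasing in (0, 1]")
        if self.gdd_requirement <= 0:
            raise DomainError("gdd_requirement must be positive")
        if not 0.0 < self.hi <= 1.0:
            raise DomainError("harvest index must lie in (0, 1]")
        if self.wp_star < 0 or self.root_depth <= 0:
            raise DomainError("wp_star must be >= 0 and root_depth > 0")
        if not 0.0 < self.depletion_fraction < 1.0:
            raise DomainError("depletion fraction p must lie in (0, 1)")

    def kcb_at(self, gdd_fraction: float) -> float:
        """Basal canopy coefficient at a given fraction of thermal time."""
        b1, b2, b3 = self.stage_fractions
        if gdd_fraction < b1:
            return self.kcb_stages[0]
        if gdd_fraction < b2:
            return self.kcb_stages[1]
        if gdd_fraction < b3:
            return self.kcb_stages[2]
        return self.kcb_stages[3]


@dataclass(frozen=True)
class SoilParams:
    """Soil hydrology: volumetric water contents and initial bucket fill.

    ``initial_fill`` is the fraction of total available water (between
    wilting point and field capacity) present at planting.
    """

    fc: float
    wp: float
    sat: float
    initial_fill: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.wp < self.fc < self.sat < 1.0:
            raise DomainError("require 0 < wp < fc < sat < 1")
        if not 0.0 <= self.initial_fill <= 1.0:
            raise DomainError("initial_fill must lie in [0, 1]")

    def taw_mm(self, root_depth: float) -> float:
        """Total available water over the root zone, mm."""
        return (self.fc - self.wp) * root_depth * 1000.0


@dataclass(frozen=True)
class SeasonResult:
    """Outputs of one crop-season simulation.

    ``season_precip`` and ``et_sum`` are accumulated over the realized
    growing period of ``lgp`` days; ``matured`` is False when the
    weather window ended before the GDD requirement was met.  The water
    bookkeeping fields (``drainage``, ``w_initial``, ``w_final``) close
    the bucket balance: precip - drainage - et_sum = w_final - w_initial.
    """

    season_precip: float       # mm
    et_sum: float              # mm
    transpiration_sum: float   # mm
    biomass: float             # t/ha
    yield_t_ha: float          # t/ha
    lgp: int                   # days
    matured: bool
    gdd_sum: float             # deg C day
    drainage: float            # mm
    w_initial: float           # mm
    w_final: float             # mm


def gdd(tmax: float, tmin: float, tbase: float) -> float:
    """Growing degree-days for one day: ``max(0, (tmax+tmin)/2 - tbase)``."""
    if tmax < tmin:
        raise DomainError(f"tmax {tmax} < tmin {tmin}")
    return max(0.0, 0.5 * (tmax + tmin) - tbase)


def hargreaves_et0(tmax, tmin, ra):
    """Hargreaves-Samani reference evapotranspiration, mm/day.

    ``ET0 = 0.0023 * (Tmean + 17.8) * sqrt(Tmax - Tmin) * (0.408 * Ra)``
    with Ra the extraterrestrial radiation in MJ m-2 day-1 (0.408
    converts it to mm/day of evaporation equivalent); floored at zero.
    """
    tmax_a = np.asarray(tmax, dtype=float)
    tmin_a = np.asarray(tmin, dtype=float)
    ra_a = np.asarray(ra, dtype=float)
    if np.any(tmax_a < tmin_a):
        raise DomainError("tmax < tmin")
    if np.any(ra_a < 0):
        raise DomainError("negative extraterrestrial radiation")
    et0 = 0.0023 * (0.5 * (tmax_a + tmin_a) + 17.8) * np.sqrt(tmax_a - tmin_a) * 0.408 * ra_a
    et0 = np.maximum(et0, 0.0)
    if np.isscalar(tmax) and np.isscalar(tmin) and np.isscalar(ra):
        return float(et0)
    return et0


def run_season(
    weather: WeatherSeries,
    crop: CropParams,
    soil: SoilParams,
    et0: np.ndarray | None = None,
) -> SeasonResult:
    """Simulate one crop season from planting to maturity or window end.

    The daily loop accumulates GDD, updates the soil-water bucket
    (infiltration capped at field capacity, overflow counted as
    drainage), applies the linear stress coefficient and partitions
    evapotranspiration into transpiration and soil evaporation; both
    fluxes are jointly rescaled when the bucket would be overdrawn, so
    the balance closes exactly.

    ``et0``, when given, must be a daily reference-ET series aligned
    with ``weather`` (a plug-point for external ET0 computations);
    otherwise Hargreaves ET0 is computed from the series' temperatures
    and its latitude.  The simulation is fully deterministic.
    """
    doy = weather.doy
    planting_idx = np.nonzero(doy == crop.planting_doy)[0]
    if len(planting_idx) == 0:
        raise DomainError(
            f"weather window does not contain planting day-of-year {crop.planting_doy}"
        )
    start = int(planting_idx[0])

    if et0 is None:
        ra = extraterrestrial_radiation(doy.astype(float), weather.latitude)
        et0_arr = hargreaves_et0(weather.tmax, weather.tmin, ra)
    else:
        et0_arr = np.asarray(et0, dtype=float)
        if et0_arr.shape != (len(weather),):
            raise DomainError("et0 must align with the weather series")
        if np.any(et0_arr < 0):
            raise DomainError("negative reference evapotranspiration")

    taw = soil.taw_mm(crop.root_depth)
    raw = crop.depletion_fraction * taw
    kcb_max = max(crop.kcb_stages)

    w = soil.initial_fill * taw
    w_initial = w
    gdd_sum = 0.0
    season_precip = 0.0
    et_sum = 0.0
    tr_sum = 0.0
    tr_over_et0 = 0.0
    drainage = 0.0
    lgp = 0
    matured = False

    for i in range(start, len(weather)):
        lgp += 1
        gdd_sum += gdd(float(weather.tmax[i]), float(weather.tmin[i]), crop.tbase)

        precip = float(weather.precip[i])
        season_precip += precip
        w += precip
        if w > taw:
            drainage += w - taw
            w = taw

        depletion = taw - w
        if depletion <= raw:
            ks = 1.0
        else:
            ks = max(0.0, (taw - depletion) / (taw - raw))

        kcb = crop.kcb_at(min(gdd_sum / crop.gdd_requirement, 1.0))
        day_et0 = float(et0_arr[i])
        tr = ks * kcb * day_et0
        shading = 1.0 - (kcb / kcb_max if kcb_max > 0 else 0.0)
        ev = crop.ke_soil * day_et0 * shading
        et_pot = tr + ev
        if et_pot > w and et_pot > 0.0:
            scale = w / et_pot
            tr *= scale
            ev *= scale
            et_pot = w
        w -= et_pot

        et_sum += et_pot
        tr_sum += tr
        if day_et0 > 0.0:
            tr_over_et0 += tr / day_et0

        if gdd_sum >= crop.gdd_requirement:
            matured = True
            break

    biomass = crop.wp_star * tr_over_et0 * GM2_TO_THA
    return SeasonResult(
        season_precip=season_precip,
        et_sum=et_sum,
        transpiration_sum=tr_sum,
        biomass=biomass,
        yield_t_ha=crop.hi * biomass,
        lgp=lgp,
        matured=matured,
        gdd_sum=gdd_sum,
        drainage=drainage,
        w_initial=w_initial,
        w_final=w,
    )
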