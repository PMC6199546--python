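"""Seeded synthetic seasonal weather ensembles.

This module generates daily weather series for the 1 March - 1 October
window (215 days; the leap day never falls inside the window, so every
season has the same length) with the statistical structure of a seasonal
ensemble forecast:

* a *truth* series (``OB``) playing the role of station observations:
  sinusoidal annual temperature cycle plus lag-1 autocorrelated noise,
  two-state Markov-chain precipitation occurrence with gamma-distributed
  wet-day amounts, and solar radiation reconstructed from a sampled
  sunshine fraction through the Angstrom-Prescott formula;
* a *control run* (``CR``): the truth transformed by the configured
  systematic biases only, with no stochastic perturbation;
* ``N`` *ensemble members* (``M01`` ... ``MNN``): the control plus
  member-specific noise -- additive daily temperature noise,
  multiplicative (mean-preserving lognormal) noise on wet-day amounts,
  and partially re-sampled precipitation occurrence that retains the
  Markov dry/wet-spell structure.

All randomness flows through :func:`numpy.random.default_rng` streams
derived from explicit integer seeds, and member ``k`` consumes a stream
that does not depend on how many members are requested, so enlarging the
ensemble never perturbs existing members.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import DomainError

__all__ = [
    "SEASON_DAYS",
    "DailyWeather",
    "WeatherSeries",
    "ClimateConfig",
    "extraterrestrial_radiation",
    "prescott_radiation",
    "generate_truth",
    "perturb_members",
    "markov_wet_fraction",
]

#: Solar constant, MJ m-2 min-1 (standard solar-geometry value).
SOLAR_CONSTANT = 0.0820

#: Days in the fixed 1 March - 1 October season window.
SEASON_DAYS = 215

# Base scales multiplied by the member-noise inflation factor.
_MEMBER_AMOUNT_LOG_SD = 0.3      # lognormal sigma on wet-day amounts at inflation 1
_MEMBER_OCCURRENCE_RESAMPLE = 0.25  # per-day occurrence re-sampling prob at inflation 1


@dataclass(frozen=True)
class DailyWeather:
    """One day of weather for one realization.

    Units: temperatures deg C, relative humidity percent, wind m/s,
    solar radiation MJ m-2 day-1, precipitation mm/day.
    """

    date: pd.Timestamp
    tmax: float
    tmin: float
    rhum: float
    wind: float
    srad: float
    precip: float

    def __post_init__(self) -> None:
        if self.tmax < self.tmin:
            raise DomainError(f"tmax {self.tmax} < tmin {self.tmin} on {self.date}")
        if self.precip < 0:
            raise DomainError(f"negative precipitation on {self.date}")
        if not 0.0 <= self.rhum <= 100.0:
            raise DomainError(f"relative humidity outside [0, 100] on {self.date}")
        if self.srad < 0 or self.wind < 0:
            raise DomainError(f"negative radiation or wind on {self.date}")


@dataclass
class WeatherSeries:
    """One season of daily weather for one realization.

    Data are stored as aligned NumPy arrays (one value per day); use
    :meth:`day` or iterate for :class:`DailyWeather` views, or
    :meth:`to_frame` for a :class:`pandas.DataFrame`.

    ``realization`` is ``"OB"`` (observed truth), ``"CR"`` (control run)
    or ``"M01"``..``"M50"`` (ensemble members).
    """

    site_id: str
    realization: str
    latitude: float
    dates: pd.DatetimeIndex
    tmax: np.ndarray
    tmin: np.ndarray
    rhum: np.ndarray
    wind: np.ndarray
    srad: np.ndarray
    precip: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.dates)
        for name in ("tmax", "tmin", "rhum", "wind", "srad", "precip"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise DomainError(f"field {name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        self.validate()

    def validate(self) -> None:
        d = np.diff(self.dates.to_julian_date())
        if len(self.dates) < 1:
            raise DomainError("empty weather series")
        if len(d) and not np.all(d == 1.0):
            raise DomainError("dates must be strictly increasing daily with no gaps")
        if np.any(self.tmax < self.tmin):
            raise DomainError("tmax < tmin")
        if np.any(self.precip < 0):
            raise DomainError("negative precipitation")
        if np.any((self.rhum < 0) | (self.rhum > 100)):
            raise DomainError("relative humidity outside [0, 100]")
        if np.any(self.srad < 0) or np.any(self.wind < 0):
            raise DomainError("negative radiation or wind")

    def __len__(self) -> int:
        return len(self.dates)

    def day(self, i: int) -> DailyWeather:
        return DailyWeather(
            date=self.dates[i],
            tmax=float(self.tmax[i]),
            tmin=float(self.tmin[i]),
            rhum=float(self.rhum[i]),
            wind=float(self.wind[i]),
            srad=float(self.srad[i]),
            precip=float(self.precip[i]),
        )

    def __iter__(self):
        return (self.day(i) for i in range(len(self)))

    @property
    def doy(self) -> np.ndarray:
        """Day of year for each date."""
        return self.dates.dayofyear.to_numpy()

    def to_frame(self, include_realization: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "date": self.dates.strftime("%Y-%m-%d"),
                "tmax": self.tmax,
                "tmin": self.tmin,
                "rhum": self.rhum,
                "wind": self.wind,
                "srad": self.srad,
                "precip": self.precip,
            }
        )
        if include_realization:
            df["realization"] = self.realization
        return df

    def copy_with(self, **overrides) -> "WeatherSeries":
        fields = dict(
            site_id=self.site_id,
            realization=self.realization,
            latitude=self.latitude,
            dates=self.dates,
            tmax=self.tmax.copy(),
            tmin=self.tmin.copy(),
            rhum=self.rhum.copy(),
            wind=self.wind.copy(),
            srad=self.srad.copy(),
            precip=self.precip.copy(),
        )
        fields.update(overrides)
        return WeatherSeries(**fields)


def _default_members_per_year() -> dict[int, int]:
    # Ensemble size grows linearly from 10 (2006) to 50 (2014), mirroring
    # the expansion of operational seasonal forecast systems over that span.
    return {year: 10 + 5 * (year - 2006) for year in range(2006, 2015)}


@dataclass
class ClimateConfig:
    """Parameters of the synthetic climate and of the ensemble perturbation.

    Temperature follows ``level + amplitude * cos(2*pi*(doy - phase)/365.25)``
    plus AR(1) noise with stationary standard deviation ``temp_noise_sd``
    and lag-1 autocorrelation ``temp_noise_ar1``; ``diurnal_range`` splits
    the daily mean symmetrically into tmax/tmin. Precipitation occurrence
    is a two-state Markov chain (``p01`` = P(wet | dry), ``p11`` =
    P(wet | wet)); wet-day amounts are Gamma(``precip_shape``,
    ``precip_scale``). Radiation comes from a clipped-Gaussian sunshine
    fraction through the Angstrom-Prescott coefficients ``prescott_a``/``_b``.

    The ensemble perturbation has three knobs: ``temp_bias`` (deg C,
    additive, applied to control and members), ``precip_bias``
    (multiplicative on wet-day amounts, > 0) and ``member_inflation``
    (>= 0, scales all member-specific noise; 0 makes every member equal
    to the control).
    """

    latitude: float = 45.3
    temp_level: float = 16.5          # deg C, mean of the annual cycle
    temp_amplitude: float = 10.5      # deg C, annual cycle amplitude
    temp_phase_doy: float = 197.0     # day of year of the warm peak
    diurnal_range: float = 10.0       # deg C, tmax - tmin
    temp_noise_sd: float = 2.0        # deg C, stationary sd of daily noise
    temp_noise_ar1: float = 0.6       # lag-1 autocorrelation, in [0, 1)
    p01: float = 0.25                 # P(wet | previous day dry)
    p11: float = 0.50                 # P(wet | previous day wet)
    precip_shape: float = 0.8         # gamma shape of wet-day amounts
    precip_scale: float = 7.5         # gamma scale, mm
    sunshine_mean: float = 0.55       # mean relative sunshine fraction
    sunshine_sd: float = 0.15
    rhum_mean: float = 70.0           # %, clipped Gaussian
    rhum_sd: float = 8.0
    wind_mean: float = 2.5            # m/s, clipped Gaussian
    wind_sd: float = 1.0
    prescott_a: float = 0.25
    prescott_b: float = 0.50
    temp_bias: float = 0.0            # deg C additive forecast bias
    precip_bias: float = 1.0          # multiplicative forecast bias (> 0)
    member_inflation: float = 1.0     # >= 0, scales member noise
    members_per_year: dict[int, int] = field(default_factory=_default_members_per_year)

    def __post_init__(self) -> None:
        if not -66.0 < self.latitude < 66.0:
            raise DomainError("latitude must lie strictly within (-66, 66) degrees")
        for name in ("p01", "p11", "sunshine_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if self.precip_shape <= 0 or self.precip_scale <= 0:
            raise DomainError("gamma shape and scale must be positive")
        if not 0.0 <= self.temp_noise_ar1 < 1.0:
            raise DomainError("temp_noise_ar1 must lie in [0, 1)")
        if self.temp_noise_sd < 0 or self.diurnal_range < 0:
            raise DomainError("temp_noise_sd and diurnal_range must be >= 0")
        if self.precip_bias <= 0:
            raise DomainError("precip_bias must be > 0")
        if self.member_inflation < 0:
            raise DomainError("member_inflation must be >= 0")
        if self.prescott_a < 0 or self.prescott_b < 0 or self.prescott_a + self.prescott_b > 1:
            raise DomainError("Prescott coefficients require a >= 0, b >= 0, a + b <= 1")
        for year, n in self.members_per_year.items():
            if n < 2:
                raise DomainError(f"members_per_year[{year}] = {n}; need N >= 2")

    def n_members(self, year: int) -> int:
        """Ensemble size for ``year`` (nearest configured year if absent)."""
        if year in self.members_per_year:
            return self.members_per_year[year]
        nearest = min(self.members_per_year, key=lambda y: abs(y - year))
        return self.members_per_year[nearest]

    def with_scenario(self, temp_bias: float | None = None,
                      precip_bias: float | None = None,
                      member_inflation: float | None = None) -> "ClimateConfig":
        """Copy of this config with the perturbation knobs overridden."""
        kwargs = {}
        if temp_bias is not None:
            kwargs["temp_bias"] = temp_bias
        if precip_bias is not None:
            kwargs["precip_bias"] = precip_bias
        if member_inflation is not None:
            kwargs["member_inflation"] = member_inflation
        return replace(self, **kwargs)


def markov_wet_fraction(p01: float, p11: float) -> float:
    """Stationary wet-day frequency of the two-state occurrence chain."""
    denom = 1.0 + p01 - p11
    if denom <= 0:
        raise DomainError("degenerate occurrence chain: 1 + p01 - p11 must be > 0")
    return p01 / denom


def extraterrestrial_radiation(doy, latitude: float):
    """Daily extraterrestrial radiation Ra in MJ m-2 day-1.

    Standard solar-geometry closed form: inverse relative Earth-Sun
    distance, solar declination and sunset hour angle.  ``doy`` may be a
    scalar or array in [1, 366]; ``latitude`` must lie strictly within
    (-66, 66) degrees so that polar day/night never occurs.
    """
    doy_arr = np.asarray(doy, dtype=float)
    if np.any((doy_arr < 1) | (doy_arr > 366)):
        raise DomainError("day of year must lie in [1, 366]")
    if not -66.0 < latitude < 66.0:
        raise DomainError("latitude outside (-66, 66): polar day/night not supported")
    phi = math.radians(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy_arr / 365.0)
    delta = 0.409 * np.sin(2.0 * np.pi * doy_arr / 365.0 - 1.39)
    ws = np.arccos(np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0))
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * math.sin(phi) * np.sin(delta)
        + math.cos(phi) * np.cos(delta) * np.sin(ws)
    )
    return float(ra) if np.isscalar(doy) else ra


def prescott_radiation(sunshine_fraction, ra, a: float = 0.25, b: float = 0.50):
    """Angstrom-Prescott estimate of global radiation from sunshine duration.

    ``Rs = (a + b * n/N) * Ra`` with ``n/N`` the relative sunshine
    fraction.  Defaults ``a = 0.25``, ``b = 0.50`` are the widely used
    general-purpose coefficients.
    """
    frac = np.asarray(sunshine_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise DomainError("sunshine fraction must lie in [0, 1]")
    if a < 0 or b < 0 or a + b > 1:
        raise DomainError("Prescott coefficients require a >= 0, b >= 0, a + b <= 1")
    ra_arr = np.asarray(ra, dtype=float)
    if np.any(ra_arr < 0):
        raise DomainError("extraterrestrial radiation must be >= 0")
    rs = (a + b * frac) * ra_arr
    return float(rs) if np.isscalar(sunshine_fraction) and np.isscalar(ra) else rs


def season_index(year: int) -> pd.DatetimeIndex:
    """Dates of the fixed 1 March - 1 October forecast window."""
    return pd.date_range(f"{year}-03-01", f"{year}-10-01", freq="D")


def _markov_occurrence(rng: np.random.Generator, n_days: int, p01: float, p11: float) -> np.ndarray:
    wet = np.empty(n_days, dtype=bool)
    pi_wet = markov_wet_fraction(p01, p11)
    u = rng.random(n_days)
    wet[0] = u[0] < pi_wet
    for t in range(1, n_days):
        wet[t] = u[t] < (p11 if wet[t - 1] else p01)
    return wet


def generate_truth(config: ClimateConfig, year: int, seed: int) -> WeatherSeries:
    """Generate the observed-truth series for one season.

    Identical ``(config, year, seed)`` always reproduce the identical
    series; the year enters the stream so different seasons under one
    seed are independent.
    """
    dates = season_index(year)
    n = len(dates)
    doy = dates.dayofyear.to_numpy().astype(float)
    rng = np.random.default_rng([int(seed), int(year), 0])

    mean_t = config.temp_level + config.temp_amplitude * np.cos(
        2.0 * np.pi * (doy - config.temp_phase_doy) / 365.25
    )
    rho = config.temp_noise_ar1
    noise = np.zeros(n)
    if config.temp_noise_sd > 0:
        shocks = rng.normal(0.0, config.temp_noise_sd, size=n)
        noise[0] = shocks[0]
        innov_scale = math.sqrt(1.0 - rho * rho)
        for t in range(1, n):
            noise[t] = rho * noise[t - 1] + innov_scale * shocks[t]
    level = mean_t + noise
    tmax = level + 0.5 * config.diurnal_range
    tmin = level - 0.5 * config.diurnal_range

    wet = _markov_occurrence(rng, n, config.p01, config.p11)
    amounts = rng.gamma(config.precip_shape, config.precip_scale, size=n)
    precip = np.where(wet, amounts, 0.0)

    sunshine = np.clip(rng.normal(config.sunshine_mean, config.sunshine_sd, size=n), 0.0, 1.0)
    ra = extraterrestrial_radiation(doy, config.latitude)
    srad = prescott_radiation(sunshine, ra, config.prescott_a, config.prescott_b)

    rhum = np.clip(rng.normal(config.rhum_mean, config.rhum_sd, size=n), 0.0, 100.0)
    wind = np.clip(rng.normal(config.wind_mean, config.wind_sd, size=n), 0.0, None)

    return WeatherSeries(
        site_id="synthetic",
        realization="OB",
        latitude=config.latitude,
        dates=dates,
        tmax=tmax,
        tmin=tmin,
        rhum=rhum,
        wind=wind,
        srad=srad,
        precip=precip,
    )


def _apply_bias(truth: WeatherSeries, config: ClimateConfig) -> WeatherSeries:
    control = truth.copy_with(realization="CR")
    control.tmax = control.tmax + config.temp_bias
    control.tmin = control.tmin + config.temp_bias
    control.precip = control.precip * config.precip_bias
    return control


def perturb_members(
    truth: WeatherSeries,
    n_members: int,
    config: ClimateConfig,
    seed: int,
) -> tuple[list[WeatherSeries], WeatherSeries]:
    """Build the control run and ``n_members`` perturbed ensemble members.

    The control is the truth with the configured biases applied and no
    stochastic noise.  Each member adds, on top of the control: a daily
    additive temperature perturbation (applied to tmax and tmin jointly,
    sd = ``member_inflation * temp_noise_sd``); mean-preserving lognormal
    noise on wet-day amounts; and per-day re-sampling of precipitation
    occurrence from the Markov transition law (probability
    ``0.25 * member_inflation`` per day), which preserves the dry/wet
    spell statistics.  With ``member_inflation = 0`` every member equals
    the control exactly.

    Returns ``(members, control)``.  Noise streams are indexed so that
    member ``k`` is unchanged when ``n_members`` grows.
    """
    if n_members < 2:
        raise DomainError(f"need at least 2 ensemble members, got {n_members}")
    n_days = len(truth)
    inflation = config.member_inflation
    control = _apply_bias(truth, config)

    base = [int(seed)]
    shape = (n_members, n_days)  # row-major: member k owns a stable block
    if inflation > 0:
        temp_noise = np.random.default_rng(base + [1]).normal(
            0.0, inflation * config.temp_noise_sd, size=shape
        )
        resample_u = np.random.default_rng(base + [2]).random(shape)
        trans_u = np.random.default_rng(base + [3]).random(shape)
        log_sd = _MEMBER_AMOUNT_LOG_SD * inflation
        amount_noise = np.exp(
            log_sd * np.random.default_rng(base + [4]).normal(size=shape)
            - 0.5 * log_sd * log_sd
        )
        fresh_amounts = np.random.default_rng(base + [5]).gamma(
            config.precip_shape, config.precip_scale, size=shape
        )
    else:
        temp_noise = np.zeros(shape)
        resample_u = np.ones(shape)  # never re-sample
        trans_u = np.zeros(shape)
        amount_noise = np.ones(shape)
        fresh_amounts = np.zeros(shape)

    q = min(1.0, _MEMBER_OCCURRENCE_RESAMPLE * inflation)
    truth_wet = truth.precip > 0.0
    pi_wet = markov_wet_fraction(config.p01, config.p11)

    wet = np.empty(shape, dtype=bool)
    keep = resample_u[:, 0] >= q
    redraw0 = trans_u[:, 0] < pi_wet
    wet[:, 0] = np.where(keep, truth_wet[0], redraw0)
    for t in range(1, n_days):
        keep = resample_u[:, t] >= q
        p_wet = np.where(wet[:, t - 1], config.p11, config.p01)
        redraw = trans_u[:, t] < p_wet
        wet[:, t] = np.where(keep, truth_wet[t], redraw)

    biased_truth_amount = truth.precip * config.precip_bias
    members: list[WeatherSeries] = []
    for k in range(n_members):
        precip_k = np.where(
            wet[k] & truth_wet,
            biased_truth_amount * amount_noise[k],
            np.where(wet[k], fresh_amounts[k] * config.precip_bias, 0.0),
        )
        tmax_k = control.tmax + temp_noise[k]
        tmin_k = control.tmin + temp_noise[k]
        # joint level noise preserves the diurnal range; clip defensively
        tmin_k = np.minimum(tmin_k, tmax_k)
        members.append(
            control.copy_with(
                realization=f"M{k + 1:02d}",
                tmax=tmax_k,
                tmin=tmin_k,
                precip=precip_k,
            )
        )
    return members, control
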