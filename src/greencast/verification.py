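"""Per-year ensemble accuracy/dispersion statistics and multi-year summaries.

For one (year, crop, variable) with member outcomes ``Y_i``, ensemble
average ``Y_EA`` and the observation-based outcome ``Y_OB``:

    RMSE = sqrt( (1/N) * sum_i (Y_i - Y_OB)^2 )
    SPRD = sqrt( (1/N) * sum_i (Y_i - Y_EA)^2 )

Both use the 1/N (population) divisor by default, which makes the
decomposition ``RMSE^2 = SPRD^2 + (Y_EA - Y_OB)^2`` an exact algebraic
identity, so RMSE >= SPRD always, with equality exactly when the
ensemble mean hits the observation -- the ideal-ensemble property.  A
sample (1/(N-1)) divisor is available via ``ddof=1``.

Skill is assessed with two reality-check criteria: (a) the RMSE of a
simulated dataset is below the standard deviation of the observed
values, and (b) the simulated standard deviation is close to the
observed one, operationalised here as a ratio within a configurable
closeness band (default within a factor of 2).

Multi-year summaries report mean, standard deviation (sample
convention, since a handful of years is a sample) and coefficient of
variation per dataset (OB, CR, EA) plus cross-year RMSEs of CR and EA
against OB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError

__all__ = [
    "EnsembleOutcome",
    "YearStats",
    "DatasetStats",
    "MultiYearSummary",
    "year_rmse",
    "year_spread",
    "year_stats",
    "pielke_skill",
    "multi_year_summary",
]

VARIABLES = ("precip", "et", "yield", "gwf", "wpet")


@dataclass
class EnsembleOutcome:
    """Member, control and observed outcomes for one (year, crop, variable)."""

    year: int
    site: str
    crop: str
    variable: str
    members: np.ndarray
    control: float | None
    observed: float

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=float)
        if self.members.ndim != 1 or len(self.members) < 2:
            raise DomainError("need at least 2 ensemble member values")
        extra = [self.observed] if self.control is None else [self.control, self.observed]
        values = np.concatenate([self.members, extra])
        if not np.all(np.isfinite(values)):
            raise DomainError(
                f"non-finite outcome in {self.site}/{self.crop}/{self.variable}/{self.year}"
            )

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def ensemble_average(self) -> float:
        # identical members: return the common value exactly, so that a
        # degenerate (zero-perturbation) ensemble yields spread and mean
        # error of exactly zero instead of a rounding ulp
        if np.all(self.members == self.members[0]):
            return float(self.members[0])
        return float(np.mean(self.members))


@dataclass(frozen=True)
class YearStats:
    """RMSE/spread decomposition and skill flags for one outcome."""

    rmse: float
    sprd: float
    ea_error: float      # Y_EA - Y_OB
    skill_a: bool | None = None
    skill_b: bool | None = None


@dataclass(frozen=True)
class DatasetStats:
    """Mean, standard deviation and coefficient of variation over years."""

    mean: float
    sigma: float
    cv: float | None  # undefined (None) for zero mean


@dataclass(frozen=True)
class MultiYearSummary:
    """Per-dataset statistics over years plus cross-dataset RMSEs and skill."""

    site: str
    crop: str
    variable: str
    n_years: int
    datasets: dict[str, DatasetStats] = field(default_factory=dict)  # OB/CR/EA
    rmse_cr: float = np.nan   # cross-year RMSE of CR against OB
    rmse_ea: float = np.nan   # cross-year RMSE of EA against OB
    skill: dict[str, tuple[bool, bool]] = field(default_factory=dict)  # per dataset


def _check_outcome(outcome: EnsembleOutcome) -> None:
    if outcome.n < 2:
        raise DomainError("ensemble statistics require N >= 2 members")


def year_rmse(outcome: EnsembleOutcome, ddof: int = 0) -> float:
    """Per-year ensemble RMSE against the observation-based outcome."""
    _check_outcome(outcome)
    dev = outcome.members - outcome.observed
    return float(np.sqrt(np.sum(dev * dev) / (outcome.n - ddof)))


def year_spread(outcome: EnsembleOutcome, ddof: int = 0) -> float:
    """Per-year ensemble spread about the ensemble average."""
    _check_outcome(outcome)
    dev = outcome.members - outcome.ensemble_average
    return float(np.sqrt(np.sum(dev * dev) / (outcome.n - ddof)))


def year_stats(
    outcome: EnsembleOutcome,
    sigma_obs: float | None = None,
    closeness_band: float = 2.0,
    ddof: int = 0,
) -> YearStats:
    """RMSE, spread and mean error for one outcome.

    When ``sigma_obs`` (the multi-year standard deviation of the
    observed series) is given, the two skill flags are evaluated for
    this year, comparing the year's RMSE with ``sigma_obs`` and its
    spread with the closeness band.
    """
    rmse = year_rmse(outcome, ddof=ddof)
    sprd = year_spread(outcome, ddof=ddof)
    ea_error = outcome.ensemble_average - outcome.observed
    skill_a = skill_b = None
    if sigma_obs is not None:
        skill_a, skill_b = pielke_skill(rmse, sprd, sigma_obs, closeness_band)
    return YearStats(rmse=rmse, sprd=sprd, ea_error=ea_error,
                     skill_a=skill_a, skill_b=skill_b)


def pielke_skill(
    rmse_sim: float,
    sigma_sim: float,
    sigma_obs: float,
    closeness_band: float = 2.0,
) -> tuple[bool, bool]:
    """Reality-check skill criteria for a simulated dataset.

    ``skill_a``: the simulation error is below the natural variability
    of the observations (``rmse_sim < sigma_obs``).  ``skill_b``: the
    simulated variability is close to the observed one,
    ``1/band <= sigma_sim/sigma_obs <= band``.
    """
    if sigma_obs <= 0:
        raise DomainError("sigma_obs must be > 0")
    if closeness_band < 1.0:
        raise DomainError("closeness_band must be >= 1")
    skill_a = bool(rmse_sim < sigma_obs)
    ratio = sigma_sim / sigma_obs
    skill_b = bool(1.0 / closeness_band <= ratio <= closeness_band)
    return skill_a, skill_b


def multi_year_summary(
    outcomes: list[EnsembleOutcome],
    closeness_band: float = 2.0,
) -> MultiYearSummary:
    """Summarise one (site, crop, variable) group over years.

    Uses the sample (N-1) convention for the per-dataset standard
    deviations, since the years form a sample of seasons, and the 1/n
    mean-square for the cross-year RMSEs of CR and EA against OB.
    """
    if len(outcomes) < 2:
        raise DomainError("multi-year summary requires at least 2 years")
    keys = {(o.site, o.crop, o.variable) for o in outcomes}
    if len(keys) != 1:
        raise DomainError(f"outcomes mix groups: {sorted(keys)}")
    site, crop, variable = keys.pop()
    outcomes = sorted(outcomes, key=lambda o: o.year)

    series = {
        "OB": np.array([o.observed for o in outcomes]),
        "EA": np.array([o.ensemble_average for o in outcomes]),
    }
    if all(o.control is not None for o in outcomes):
        series["CR"] = np.array([o.control for o in outcomes])
    datasets = {}
    for name, values in series.items():
        mean = float(np.mean(values))
        sigma = float(np.std(values, ddof=1))
        cv = sigma / mean if mean != 0.0 else None
        datasets[name] = DatasetStats(mean=mean, sigma=sigma, cv=cv)

    rmse_ea = float(np.sqrt(np.mean((series["EA"] - series["OB"]) ** 2)))
    rmse_cr = (
        float(np.sqrt(np.mean((series["CR"] - series["OB"]) ** 2)))
        if "CR" in series
        else float("nan")
    )

    skill: dict[str, tuple[bool, bool]] = {}
    sigma_obs = datasets["OB"].sigma
    if sigma_obs > 0:
        skill["EA"] = pielke_skill(rmse_ea, datasets["EA"].sigma, sigma_obs, closeness_band)
        if "CR" in series:
            skill["CR"] = pielke_skill(rmse_cr, datasets["CR"].sigma, sigma_obs, closeness_band)

    return MultiYearSummary(
        site=site,
        crop=crop,
        variable=variable,
        n_years=len(outcomes),
        datasets=datasets,
        rmse_cr=rmse_cr,
        rmse_ea=rmse_ea,
        skill=skill,
    )
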