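"""Probabilistic ensemble evaluation with the Ignorance score.

The ensemble of outcome estimates for one (year, crop, variable) is
screened for normality, fitted with a Gaussian (mu = ensemble mean,
sigma = ensemble standard deviation), and the verifying observation is
standardized,

    Z = (Y_OB - mu) / sigma,

so that the Ignorance (logarithmic) score is evaluated against the
standard Gaussian density phi:

    S = -log2 phi(Z) = 0.5*log2(2*pi) + Z^2 / (2*ln 2)   [bits]

S is even and strictly convex in Z with minimum ~1.3257 bits at Z = 0;
lower is better.  Because the Gaussian obeys the 68-95-99.7 rule, the
one/two/three-sigma boundary scores ~2.05 / ~4.21 / ~7.82 bits carry a
direct probabilistic meaning (S below the one-sigma boundary with
probability ~0.68, etc.) and serve as interpretation thresholds: a
score below ~2.04 is very good, above ~7.81 the fitted distribution is
not adequate for that year.

Multi-year summaries flag two diagnostic patterns: a high average score
with a *low* standard deviation suggests the chosen distribution family
itself is inadequate, while a high average with a *high* standard
deviation points at an intermittent effect disrupting either the
forecast or the simulation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import DegenerateEnsembleError, DomainError

__all__ = [
    "GaussianFit",
    "IgnoranceResult",
    "ScoreSummary",
    "SCORE_MINIMUM_BITS",
    "VERY_GOOD_MAX_BITS",
    "NOT_ADEQUATE_MIN_BITS",
    "score_at_z",
    "prob_score_below",
    "fit_gaussian",
    "ignorance_score",
    "summarize_scores",
]


def score_at_z(z: float) -> float:
    """Ignorance of the standard Gaussian density at standardized error z."""
    return 0.5 * math.log2(2.0 * math.pi) + (z * z) / (2.0 * math.log(2.0))


def prob_score_below(threshold_bits: float) -> float:
    """P(S < threshold) when the observation is drawn from the fitted Gaussian.

    Closed form: S < s iff |Z| < z(s) with ``z(s) = sqrt((s - S_min) * 2 ln 2)``,
    so the probability is ``2*Phi(z(s)) - 1``.
    """
    if threshold_bits <= SCORE_MINIMUM_BITS:
        return 0.0
    z = math.sqrt((threshold_bits - SCORE_MINIMUM_BITS) * 2.0 * math.log(2.0))
    return float(2.0 * stats.norm.cdf(z) - 1.0)


#: Minimum attainable score, at Z = 0: -log2(1/sqrt(2*pi)) ~ 1.3257 bits.
SCORE_MINIMUM_BITS = score_at_z(0.0)

#: Analytic one- and three-sigma boundary scores.
ONE_SIGMA_BOUNDARY_BITS = score_at_z(1.0)    # ~2.047
THREE_SIGMA_BOUNDARY_BITS = score_at_z(3.0)  # ~7.818

# Categorisation uses the conventional rounded boundary values so that a
# printed score of e.g. 2.04 is still "very good".
VERY_GOOD_MAX_BITS = 2.04
NOT_ADEQUATE_MIN_BITS = 7.81


@dataclass(frozen=True)
class GaussianFit:
    """Gaussian fit to the ensemble plus the normality screening verdict."""

    mu: float
    sigma: float
    n: int
    normality_pvalue: float
    is_normal: bool


@dataclass(frozen=True)
class IgnoranceResult:
    """Standardized error, score in bits and its interpretation."""

    z: float
    score: float
    category: str  # very_good | acceptable | not_adequate
    valid: bool    # False when the normality screen rejected the ensemble


@dataclass(frozen=True)
class ScoreSummary:
    """Multi-year average score, its standard deviation and a diagnostic flag."""

    mean_score: float
    sigma_score: float
    n_years: int
    n_excluded: int
    flag: str  # ok | distribution_inadequate | systematic_disruption


def fit_gaussian(members, alpha: float = 0.05, ddof: int = 0) -> GaussianFit:
    """Fit a Gaussian to the member values and screen it for normality.

    ``sigma`` uses the population (1/N) convention by default, matching
    the spread statistic; ``ddof=1`` switches to the sample convention.
    Normality is screened with the Shapiro-Wilk test at level ``alpha``
    (the screening only sets ``is_normal``; it does not alter the fit).
    """
    values = np.asarray(members, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise DomainError("need at least 3 member values for a screened fit")
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must lie in (0, 1)")
    sigma = float(np.std(values, ddof=ddof))
    if sigma == 0.0:
        raise DegenerateEnsembleError("all members identical: sigma = 0")
    pvalue = float(stats.shapiro(values).pvalue)
    return GaussianFit(
        mu=float(np.mean(values)),
        sigma=sigma,
        n=len(values),
        normality_pvalue=pvalue,
        is_normal=bool(pvalue >= alpha),
    )


def _categorize(score: float) -> str:
    if score < VERY_GOOD_MAX_BITS:
        return "very_good"
    if score > NOT_ADEQUATE_MIN_BITS:
        return "not_adequate"
    return "acceptable"


def ignorance_score(y_obs: float, fit: GaussianFit, raw: bool = False) -> IgnoranceResult:
    """Score the verifying observation against the fitted ensemble density.

    Standardization makes the score comparable across variables with
    different units; ``raw=True`` adds ``log2(sigma)`` back, i.e. scores
    the unstandardized fitted density (single-variable use only).
    Results for normality-rejected ensembles are computed but marked
    ``valid=False`` so downstream summaries can exclude them.
    """
    if fit.sigma <= 0:
        raise DegenerateEnsembleError("degenerate fit: sigma must be > 0")
    z = (y_obs - fit.mu) / fit.sigma
    score = score_at_z(z)
    if raw:
        score += math.log2(fit.sigma)
    return IgnoranceResult(
        z=float(z),
        score=float(score),
        category=_categorize(score),
        valid=fit.is_normal,
    )


def summarize_scores(
    results,
    high_score_threshold: float = 4.21,
    high_sigma_threshold: float = 2.0,
) -> ScoreSummary:
    """Average the valid yearly scores and attach a diagnostic flag.

    ``distribution_inadequate``: persistently high scores with little
    year-to-year variation (mean above ``high_score_threshold``, sigma
    at or below ``high_sigma_threshold``) -- the distribution family is
    a poor choice.  ``systematic_disruption``: both mean and sigma are
    high -- some intermittent effect disrupts the forecast chain.
    Normality-rejected years are excluded and counted.
    """
    results = list(results)
    valid = [r for r in results if r.valid]
    if len(valid) < 2:
        raise DomainError("score summary requires at least 2 valid years")
    scores = np.array([r.score for r in valid])
    mean_score = float(np.mean(scores))
    sigma_score = float(np.std(scores, ddof=1))
    if mean_score > high_score_threshold and sigma_score > high_sigma_threshold:
        flag = "systematic_disruption"
    elif mean_score > high_score_threshold:
        flag = "distribution_inadequate"
    else:
        flag = "ok"
    return ScoreSummary(
        mean_score=mean_score,
        sigma_score=sigma_score,
        n_years=len(valid),
        n_excluded=len(results) - len(valid),
        flag=flag,
    )
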