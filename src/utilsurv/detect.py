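"""Prediction intervals and excess/deficit classification.

Given a fitted baseline, the expected count at the target month is the
plug-in mean exp(alpha + beta * t); block 0 is the baseline seasonal level
and the target always sits in block 0 by construction, so no block effect
enters.  The two-sided prediction interval is taken from the plug-in
negative-binomial distribution with mean Yhat and variance Phi * Yhat
(size parameter k = Yhat / (Phi - 1)); when Phi = 1 the interval falls
back to exact Poisson quantiles.  An observation strictly above the upper
bound is an excess, strictly below the lower bound a deficit.

Parameter-estimation uncertainty is not propagated into the interval —
the bounds are plug-in quantiles — which yields mild under-coverage in
short histories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .errors import NotConvergedError
from .glm import BaselineFit
from .month import MonthStamp
from .series import Flag, FlagRecord, recompute_flag


@dataclass(frozen=True)
class Prediction:
    """Expected value and prediction interval for one target month."""

    target: MonthStamp
    expected: float
    dispersion: float
    lower: int
    upper: int
    level: float

    def __post_init__(self) -> None:
        if self.expected <= 0:
            raise ValueError("expected must be positive")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


def predict_expected(fit: BaselineFit, target: MonthStamp | None = None) -> float:
    """Plug-in expected count at the target month.

    The target's month-of-year lies in the reference window (block 0, the
    baseline factor level), so Yhat = exp(alpha + beta * trend_index).
    """
    if not fit.converged:
        raise NotConvergedError("prediction requested from an unconverged fit")
    design = fit.design
    if target is None:
        target = design.target
    if design.block_map[target.month] != 0:
        raise ValueError(
            f"target {target} falls outside the reference window of this design"
        )
    t = design.series_start.months_until(target)
    return math.exp(fit.alpha + fit.beta * t)


def prediction_interval(
    expected: float, phi: float, level: float
) -> tuple[int, int]:
    """Two-sided prediction interval from the plug-in count distribution.

    For phi > 1 the distribution is negative binomial with mean
    ``expected`` and variance ``phi * expected``; for phi = 1 it is
    Poisson.  Each bound is the smallest integer y whose CDF reaches the
    corresponding tail probability ((1-level)/2 and 1-(1-level)/2).
    """
    if expected <= 0:
        raise ValueError("expected must be positive")
    if phi < 1:
        raise ValueError("phi must be >= 1 (floor upstream)")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    lo_q = (1.0 - level) / 2.0
    hi_q = 1.0 - lo_q
    if phi > 1.0:
        size = expected / (phi - 1.0)
        p = 1.0 / phi  # NB success probability: mean = size*(1-p)/p
        dist = stats.nbinom(size, p)
    else:
        dist = stats.poisson(expected)
    lower = int(dist.ppf(lo_q))
    upper = int(dist.ppf(hi_q))
    return max(0, lower), max(0, upper)


def predict(fit: BaselineFit, target: MonthStamp | None = None) -> Prediction:
    """Expected value plus interval for the fit's target month."""
    if target is None:
        target = fit.design.target
    expected = predict_expected(fit, target)
    level = fit.design.config.level
    lower, upper = prediction_interval(expected, fit.phi, level)
    return Prediction(
        target=target,
        expected=expected,
        dispersion=fit.phi,
        lower=lower,
        upper=upper,
        level=level,
    )


def classify(observed: int, prediction: Prediction) -> FlagRecord:
    """Compare an observation to its prediction interval.

    Bounds are inclusive for "normal": only observations strictly above
    the upper bound (excess) or strictly below the lower bound (deficit)
    are flagged.
    """
    if observed < 0:
        raise ValueError("observed count must be non-negative")
    flag = recompute_flag(observed, prediction.lower, prediction.upper)
    return FlagRecord(
        month=prediction.target,
        observed=observed,
        expected=prediction.expected,
        lower=prediction.lower,
        upper=prediction.upper,
        level=prediction.level,
        flag=flag,
        dispersion_used=prediction.dispersion,
    )
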