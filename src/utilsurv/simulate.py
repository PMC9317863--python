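"""Synthetic monthly utilization series.

The generator draws count series with exactly the structure the detection
model assumes plus controlled departures from it: a log-linear trend,
month-of-year seasonality richer than the model's block approximation,
Poisson or negative-binomial noise with variance ``phi * mean``, and
optional multiplicative shock windows that emulate pandemic-era
suppression (factor < 1) or inflation (factor > 1) of utilization.

``simulate_study_panel`` produces a full outcome-by-stratum panel shaped
like Japan's monthly hospital report — 80 months from March 2015 through
October 2021, four outcomes stratified by hospital type or bed type —
with per-cell magnitudes and shock schedules that echo the pandemic
patterns seen in the real data (persistent inpatient deficits, transient
outpatient deficits, an excess schedule for one tuberculosis-bed cell).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .month import MonthStamp
from .series import Outcome, UtilizationSeries


@dataclass(frozen=True)
class Shock:
    """A multiplicative disturbance over a closed month range."""

    start: MonthStamp
    end: MonthStamp
    factor: float

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("shock factor must be positive")
        if self.end < self.start:
            raise ValueError("shock end precedes start")

    def active(self, month: MonthStamp) -> bool:
        return self.start <= month <= self.end


@dataclass(frozen=True)
class GeneratorSpec:
    """Full description of one synthetic series.

    ``seasonal`` is a 12-vector of month-of-year log-effects indexed by
    month-of-year (entry 0 = January); it should be mean-zero so ``alpha``
    is the annual-average log level.
    """

    alpha: float
    beta: float = 0.0
    seasonal: tuple[float, ...] = (0.0,) * 12
    phi: float = 1.0
    start: MonthStamp = field(default_factory=lambda: MonthStamp(2015, 3))
    n_months: int = 80
    shocks: tuple[Shock, ...] = ()
    outcome: Outcome = Outcome.INPATIENTS_PER_DAY
    stratum: str = "total"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.seasonal) != 12:
            raise ValueError("seasonal must have 12 entries")
        if self.phi < 1:
            raise ValueError("phi must be >= 1")
        if self.n_months < 1:
            raise ValueError("n_months must be >= 1")

    def mean_at(self, t: int) -> float:
        """Deterministic mean mu_t at trend index t (0-based from start)."""
        month = self.start.shift(t)
        mu = math.exp(self.alpha + self.beta * t + self.seasonal[month.month - 1])
        for s in self.shocks:
            if s.active(month):
                mu *= s.factor
        return mu


def seasonal_harmonic(amplitude: float, phase: float = 0.0) -> tuple[float, ...]:
    """A mean-zero annual cosine of given log-amplitude as a 12-vector."""
    return tuple(
        amplitude * math.cos(2 * math.pi * (m / 12.0) + phase) for m in range(12)
    )


def simulate_series(
    spec: GeneratorSpec, rng: np.random.Generator | None = None
) -> UtilizationSeries:
    """Draw one series from a generator spec.

    Counts are Poisson(mu_t) when phi == 1, otherwise negative binomial
    with mean mu_t and variance phi * mu_t via the size/mean
    parametrization k = mu / (phi - 1) — the same family the detection
    module inverts.  A fixed seed yields identical output.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    mu = np.array([spec.mean_at(t) for t in range(spec.n_months)])
    if spec.phi == 1.0:
        values = rng.poisson(mu)
    else:
        size = mu / (spec.phi - 1.0)
        values = rng.negative_binomial(size, 1.0 / spec.phi)
    months = tuple(spec.start.shift(t) for t in range(spec.n_months))
    return UtilizationSeries(
        outcome=spec.outcome,
        stratum=spec.stratum,
        months=months,
        values=tuple(int(v) for v in values),
    )


# Per-cell panel layout: (outcome, stratum, typical level, trend per month).
# Levels echo the scale of the national hospital report: ~1.3M outpatient
# visits/day, ~1.2M inpatients/day in total, stays of weeks-to-months
# depending on bed type, and monthly admissions from ~1e3 (tuberculosis
# beds) to ~1.3M (all beds).
_HOSPITAL_STRATA = ("general", "psychiatric", "total")
_BED_STRATA = ("psychiatric", "tuberculosis", "long_term_care", "general", "ltci", "total")

_PANEL_LEVELS: dict[tuple[Outcome, str], tuple[float, float]] = {
    (Outcome.OUTPATIENTS_PER_DAY, "general"): (1_300_000, -0.0015),
    (Outcome.OUTPATIENTS_PER_DAY, "psychiatric"): (60_000, -0.0010),
    (Outcome.OUTPATIENTS_PER_DAY, "total"): (1_360_000, -0.0015),
    (Outcome.INPATIENTS_PER_DAY, "psychiatric"): (280_000, -0.0020),
    (Outcome.INPATIENTS_PER_DAY, "tuberculosis"): (2_200, -0.0060),
    (Outcome.INPATIENTS_PER_DAY, "long_term_care"): (280_000, -0.0020),
    (Outcome.INPATIENTS_PER_DAY, "general"): (680_000, -0.0010),
    (Outcome.INPATIENTS_PER_DAY, "ltci"): (7_000, -0.0100),
    (Outcome.INPATIENTS_PER_DAY, "total"): (1_250_000, -0.0015),
    (Outcome.AVG_STAY_DAYS, "psychiatric"): (270, -0.0010),
    (Outcome.AVG_STAY_DAYS, "tuberculosis"): (60, -0.0008),
    (Outcome.AVG_STAY_DAYS, "long_term_care"): (140, -0.0010),
    (Outcome.AVG_STAY_DAYS, "general"): (16, -0.0005),
    (Outcome.AVG_STAY_DAYS, "ltci"): (200, -0.0010),
    (Outcome.AVG_STAY_DAYS, "total"): (28, -0.0008),
    (Outcome.NEW_HOSPITALIZATIONS, "psychiatric"): (30_000, -0.0010),
    (Outcome.NEW_HOSPITALIZATIONS, "tuberculosis"): (1_400, -0.0050),
    (Outcome.NEW_HOSPITALIZATIONS, "long_term_care"): (15_000, -0.0020),
    (Outcome.NEW_HOSPITALIZATIONS, "general"): (1_250_000, 0.0005),
    (Outcome.NEW_HOSPITALIZATIONS, "ltci"): (2_000, -0.0080),
    (Outcome.NEW_HOSPITALIZATIONS, "total"): (1_300_000, 0.0003),
}


def _panel_shocks(outcome: Outcome, stratum: str) -> tuple[Shock, ...]:
    """Pandemic-era shock schedule for one panel cell.

    Outpatient cells see a transient early-pandemic deficit; inpatient and
    admission cells a persistent deficit across the whole shock era; the
    tuberculosis-bed admission cell an excess; psychiatric-bed stays an
    excess (fewer discharges lengthen stays); LTCI stays swing both ways.
    """
    era_start, era_end = MonthStamp(2020, 4), MonthStamp(2021, 10)
    if outcome is Outcome.OUTPATIENTS_PER_DAY:
        return (Shock(era_start, MonthStamp(2020, 9), 0.90),)
    if outcome is Outcome.INPATIENTS_PER_DAY:
        return (Shock(era_start, era_end, 0.93),)
    if outcome is Outcome.NEW_HOSPITALIZATIONS:
        if stratum == "tuberculosis":
            return (Shock(era_start, era_end, 1.18),)
        return (Shock(era_start, era_end, 0.92),)
    # average length of stay
    if stratum == "psychiatric":
        return (Shock(era_start, era_end, 1.06),)
    if stratum == "tuberculosis":
        return (Shock(era_start, era_end, 0.85),)
    if stratum == "ltci":
        return (
            Shock(era_start, MonthStamp(2020, 12), 0.92),
            Shock(MonthStamp(2021, 4), era_end, 1.08),
        )
    return ()


def panel_specs(seed: int = 0, with_shocks: bool = True) -> list[GeneratorSpec]:
    """Generator specs for the default 21-cell study panel.

    Outpatients per day are stratified by hospital type (3 cells); the
    other three outcomes by bed type (6 cells each).  Each cell gets its
    own sub-seed, a mild seasonal harmonic, and dispersion scaled to its
    magnitude (small-count cells closer to Poisson).
    """
    rng = np.random.default_rng(seed)
    specs = []
    for outcome in Outcome:
        strata = (
            _HOSPITAL_STRATA if outcome is Outcome.OUTPATIENTS_PER_DAY else _BED_STRATA
        )
        for stratum in strata:
            level, trend = _PANEL_LEVELS[(outcome, stratum)]
            phase = float(rng.uniform(0, 2 * math.pi))
            amplitude = 0.02 if level > 10_000 else 0.04
            phi = 2.0 if level > 1_000 else 1.3
            specs.append(
                GeneratorSpec(
                    alpha=math.log(level),
                    beta=trend,
                    seasonal=seasonal_harmonic(amplitude, phase),
                    phi=phi,
                    shocks=_panel_shocks(outcome, stratum) if with_shocks else (),
                    outcome=outcome,
                    stratum=stratum,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            )
    return specs


def simulate_study_panel(
    seed: int = 0, with_shocks: bool = True
) -> list[UtilizationSeries]:
    """Simulate the full 21-series outcome-by-stratum panel."""
    return [simulate_series(spec) for spec in panel_specs(seed, with_shocks)]
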