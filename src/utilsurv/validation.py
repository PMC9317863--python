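"""Simulation-based calibration checks for the detection pipeline.

These experiments quantify, by Monte Carlo, two operating characteristics
every surveillance deployment should know:

* **interval calibration** — how often the two-sided prediction interval
  at a post-cutoff target month covers a fresh draw when the data truly
  come from the fitted model family (log-linear trend, block-constant
  seasonality, negative-binomial noise with variance ``phi * mean``);
* **detection power / false-flag rate** — how often an injected
  multiplicative deficit shock at the target month is flagged, and how
  often an unshocked month is flagged by chance.

Because the intervals are plug-in (parameter-estimation uncertainty is
not propagated), empirical coverage runs one-to-two percentage points
below nominal at typical history lengths; these functions make that
measurable rather than anecdotal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .detect import predict
from .glm import fit_quasipoisson
from .month import MonthStamp
from .pipeline import detect_month
from .series import Flag
from .simulate import GeneratorSpec, Shock, simulate_series
from .windows import WindowConfig, assign_blocks, build_reference_design

#: Default calibration world: 70 months from March 2015, mean level 500,
#: +0.1%/month trend, block-constant seasonal effects of amplitude 0.1,
#: dispersion 2; cutoff December 2019 (month 58), target July 2020
#: (month 65).
CAL_START = MonthStamp(2015, 3)
CAL_N_MONTHS = 70
CAL_CUTOFF_INDEX = 57  # 0-based: 58th month = 2019-12
CAL_TARGET_INDEX = 64  # 0-based: 65th month = 2020-07
CAL_ALPHA = math.log(500.0)
CAL_BETA = 0.001
CAL_PHI = 2.0
#: Per-block seasonal log-effects (block 0 = reference window of the
#: default target month), realized as a 12-vector below.
CAL_BLOCK_EFFECTS = {0: -0.05, 1: 0.10, 2: 0.05, 3: -0.10}


def calibration_spec(config: WindowConfig | None = None) -> GeneratorSpec:
    """The default matched-family generator spec for coverage experiments."""
    target = CAL_START.shift(CAL_TARGET_INDEX)
    if config is None:
        config = WindowConfig(exclusion_cutoff=CAL_START.shift(CAL_CUTOFF_INDEX))
    block_map = assign_blocks(target.month, config)
    seasonal = tuple(CAL_BLOCK_EFFECTS[block_map[m]] for m in range(1, 13))
    return GeneratorSpec(
        alpha=CAL_ALPHA,
        beta=CAL_BETA,
        seasonal=seasonal,
        phi=CAL_PHI,
        start=CAL_START,
        n_months=CAL_N_MONTHS,
    )


@dataclass(frozen=True)
class CoverageResult:
    n_reps: int
    covered: int

    @property
    def coverage(self) -> float:
        return self.covered / self.n_reps


def coverage_experiment(n_reps: int, seed: int) -> CoverageResult:
    """Empirical coverage of the full pipeline's interval at the target month.

    Each replicate draws a fresh series from :func:`calibration_spec`,
    runs window construction, quasi-Poisson fit and interval prediction
    with w=3, B=5, n=3 and the December-2019 cutoff, and records whether
    the replicate's own target-month draw lies inside the interval.
    """
    spec = calibration_spec()
    cfg = WindowConfig(exclusion_cutoff=CAL_START.shift(CAL_CUTOFF_INDEX))
    target = CAL_START.shift(CAL_TARGET_INDEX)
    covered = 0
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        series = simulate_series(spec, rng=rng)
        record, _ = detect_month(series, target, cfg)
        covered += record.flag is Flag.NORMAL
    return CoverageResult(n_reps=n_reps, covered=covered)


@dataclass(frozen=True)
class PowerResult:
    n_reps: int
    flagged_deficit: int
    flagged_any: int

    @property
    def deficit_rate(self) -> float:
        return self.flagged_deficit / self.n_reps

    @property
    def flag_rate(self) -> float:
        return self.flagged_any / self.n_reps


def shock_detection_experiment(
    n_reps: int,
    seed: int,
    shock_factor: float | None = 0.7,
    baseline_mean: float = 5000.0,
    phi: float = 2.0,
) -> PowerResult:
    """Deficit-detection power (or, with ``shock_factor=None``, false-flag rate).

    Simulates matched-family series with baseline mean ``baseline_mean``
    and dispersion ``phi``; if ``shock_factor`` is given, a multiplicative
    shock of that factor is applied at the target month before drawing the
    observation.  Reports how many replicates flag the target month as a
    deficit and how many flag it at all.
    """
    cfg = WindowConfig(exclusion_cutoff=CAL_START.shift(CAL_CUTOFF_INDEX))
    target = CAL_START.shift(CAL_TARGET_INDEX)
    base = calibration_spec(cfg)
    shocks = ()
    if shock_factor is not None:
        shocks = (Shock(target, target, shock_factor),)
    spec = GeneratorSpec(
        alpha=math.log(baseline_mean),
        beta=base.beta,
        seasonal=base.seasonal,
        phi=phi,
        start=base.start,
        n_months=base.n_months,
        shocks=shocks,
    )
    n_deficit = n_any = 0
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        series = simulate_series(spec, rng=rng)
        record, _ = detect_month(series, target, cfg)
        n_deficit += record.flag is Flag.DEFICIT
        n_any += record.flag is not Flag.NORMAL
    return PowerResult(n_reps=n_reps, flagged_deficit=n_deficit, flagged_any=n_any)


def parameter_recovery_experiment(
    n_points: int, n_reps: int, seed: int, phi: float = 2.0
) -> dict[str, float]:
    """Median absolute estimation errors at a given design size.

    Replicates a generic fit problem: ``n_points`` months of
    matched-family data ending at the cutoff are fitted against a target
    chosen so that all seasonal blocks are populated, and the absolute
    errors of intercept, trend and block coefficients are recorded.
    Returns the median absolute error per coefficient plus the median
    raw dispersion estimate.
    """
    # anchor span wide enough that every simulated month enters the design
    cfg = WindowConfig(
        b_years=n_points // 12 + 2,
        exclusion_cutoff=CAL_START.shift(n_points - 1),
    )
    target = CAL_START.shift(n_points + 6)
    block_map = assign_blocks(target.month, cfg)
    seasonal = tuple(CAL_BLOCK_EFFECTS[block_map[m]] for m in range(1, 13))
    spec = GeneratorSpec(
        alpha=CAL_ALPHA,
        beta=CAL_BETA,
        seasonal=seasonal,
        phi=phi,
        start=CAL_START,
        n_months=n_points,
    )
    # true coefficients relative to block 0 as the baseline level
    true = {"intercept": CAL_ALPHA + CAL_BLOCK_EFFECTS[0], "trend": CAL_BETA}
    for b in range(1, cfg.n_blocks + 1):
        true[f"block_{b}"] = CAL_BLOCK_EFFECTS[b] - CAL_BLOCK_EFFECTS[0]

    errors: dict[str, list[float]] = {k: [] for k in true}
    phis: list[float] = []
    for child in np.random.SeedSequence(seed).spawn(n_reps):
        rng = np.random.default_rng(child)
        series = simulate_series(spec, rng=rng)
        design = build_reference_design(series, target, cfg)
        fit = fit_quasipoisson(design)
        for name, est in fit.coefficients.items():
            errors[name].append(abs(est - true[name]))
        phis.append(fit.phi_raw)
    out = {name: float(np.median(errs)) for name, errs in errors.items()}
    out["phi_raw_median"] = float(np.median(phis))
    return out
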