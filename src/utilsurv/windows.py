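"""Reference-window construction for the moving-baseline regression.

For a target month with month-of-year ``a`` in year ``A``, the baseline is
fitted to historical data drawn from a reference window of half-width
``w`` months centred on ``a`` in each of the ``B`` preceding anchor years,
plus the current-year partial window ``a-w .. a-1`` when those months are
admissible.  The remaining months-of-year are partitioned into ``n``
near-equal cyclic blocks whose dummies absorb residual seasonality, so
every usable month in the anchor years can enter the regression.

A hard calendar cutoff (default December 2019) keeps pandemic-era data out
of every fit regardless of the target month.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InsufficientHistoryError
from .month import MonthStamp
from .series import UtilizationSeries


@dataclass(frozen=True)
class WindowConfig:
    """Tuning constants of the detection algorithm.

    Parameters
    ----------
    w
        Half-width of the reference window in months.  The window spans
        ``2w+1`` months-of-year centred on the target's month-of-year.
    b_years
        Number of past anchor years contributing reference data.
    n_blocks
        Number of near-equal seasonal blocks covering the months-of-year
        outside the reference window.
    periods_per_year
        Number of periods in a seasonal cycle (12 for monthly data).
    level
        Nominal two-sided coverage of the prediction interval.
    exclusion_cutoff
        Last data month allowed into any fit; months after it never enter
        a design, which keeps shock-era data out of the baseline.
    """

    w: int = 3
    b_years: int = 5
    n_blocks: int = 3
    periods_per_year: int = 12
    level: float = 0.95
    exclusion_cutoff: MonthStamp = field(default_factory=lambda: MonthStamp(2019, 12))

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be >= 0")
        if self.b_years < 1:
            raise ValueError("b_years must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if 2 * self.w + 1 + self.n_blocks > self.periods_per_year:
            raise ValueError(
                "window plus blocks exceed the seasonal cycle: "
                f"2*{self.w}+1 + {self.n_blocks} > {self.periods_per_year}"
            )
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must be in (0, 1)")

    @property
    def window_size(self) -> int:
        return 2 * self.w + 1


@dataclass(frozen=True)
class ReferencePoint:
    """One historical month entering the design."""

    month: MonthStamp
    trend_index: int
    block: int
    value: int


@dataclass(frozen=True)
class ReferenceDesign:
    """The usable history for one target month, labelled for regression.

    ``points`` are sorted by month; ``block`` 0 is the reference window
    (the baseline level of the seasonal factor), blocks 1..n the cyclic
    inter-window blocks.
    """

    target: MonthStamp
    series_start: MonthStamp
    config: WindowConfig
    points: tuple[ReferencePoint, ...]
    block_map: dict[int, int]

    @property
    def target_trend_index(self) -> int:
        return self.series_start.months_until(self.target)

    def months_used(self) -> list[MonthStamp]:
        return [p.month for p in self.points]

    def audit(self) -> None:
        """Assert that no design point postdates the cutoff or the target."""
        for p in self.points:
            if p.month > self.config.exclusion_cutoff:
                raise AssertionError(
                    f"design point {p.month} postdates cutoff "
                    f"{self.config.exclusion_cutoff}"
                )
            if p.month >= self.target:
                raise AssertionError(
                    f"design point {p.month} does not precede target {self.target}"
                )


def assign_blocks(target_month_of_year: int, config: WindowConfig) -> dict[int, int]:
    """Partition the 12 months-of-year into reference window + seasonal blocks.

    The ``2w+1`` months-of-year centred (mod 12) on the target's
    month-of-year form block 0.  The remaining months, taken cyclically
    starting immediately after the window, are split into ``n_blocks``
    contiguous blocks whose sizes differ by at most one, larger blocks
    first.

    Returns a map from month-of-year (1..12) to block id (0..n_blocks).
    """
    if not 1 <= target_month_of_year <= config.periods_per_year:
        raise ValueError(f"month-of-year {target_month_of_year} out of range")
    p = config.periods_per_year
    mapping: dict[int, int] = {}
    for d in range(-config.w, config.w + 1):
        moy = (target_month_of_year - 1 + d) % p + 1
        mapping[moy] = 0
    leftovers = []
    for d in range(1, p - 2 * config.w):
        moy = (target_month_of_year - 1 + config.w + d) % p + 1
        leftovers.append(moy)
    r = len(leftovers)
    base, rem = divmod(r, config.n_blocks)
    pos = 0
    for b in range(1, config.n_blocks + 1):
        size = base + (1 if b <= rem else 0)
        for moy in leftovers[pos : pos + size]:
            mapping[moy] = b
        pos += size
    assert len(mapping) == p
    return mapping


def anchor_years(target: MonthStamp, config: WindowConfig) -> range:
    """The B calendar years whose data may enter the fit for ``target``.

    When the target postdates the exclusion cutoff, the anchors are the
    last B years ending at the cutoff's year (so the same pre-shock years
    serve every post-cutoff target).  Otherwise they are the B years
    preceding the target's own year, the ordinary moving-window regime.
    """
    if target > config.exclusion_cutoff:
        last = config.exclusion_cutoff.year
    else:
        last = target.year - 1
    return range(last - config.b_years + 1, last + 1)


def build_reference_design(
    series: UtilizationSeries, target: MonthStamp, config: WindowConfig
) -> ReferenceDesign:
    """Collect the usable historical points for one target month.

    Admissible points are (i) every series month in an anchor year that
    does not postdate the exclusion cutoff and precedes the target, each
    labelled with its seasonal block, and (ii) the current-year partial
    window ``target-w .. target-1`` intersected with the usable era.  The
    inter-window points identify the seasonal block coefficients; the
    block-0 points pin down the baseline level at the target's season.

    Raises
    ------
    InsufficientHistoryError
        If fewer than ``2w+1`` reference-window (block-0) points exist.
    """
    block_map = assign_blocks(target.month, config)
    years = anchor_years(target, config)
    hard_end = min(config.exclusion_cutoff, target.shift(-1))

    months: list[MonthStamp] = []
    for m in (series.months[k] for k in range(len(series))):
        if m > hard_end:
            break
        if m.year in years:
            months.append(m)
    # current-year partial window: the w months immediately before the target
    for d in range(config.w, 0, -1):
        m = target.shift(-d)
        if m.year in years:
            continue  # already collected above
        if m < series.start or m > hard_end:
            continue
        months.append(m)
    months.sort()

    points = tuple(
        ReferencePoint(
            month=m,
            trend_index=series.trend_index(m),
            block=block_map[m.month],
            value=series.value_at(m),
        )
        for m in months
    )
    n_block0 = sum(1 for p in points if p.block == 0)
    if n_block0 < config.window_size:
        raise InsufficientHistoryError(
            f"target {target}: only {n_block0} reference-window points, "
            f"need at least {config.window_size}"
        )
    return ReferenceDesign(
        target=target,
        series_start=series.start,
        config=config,
        points=points,
        block_map=block_map,
    )


def design_matrix(
    design: ReferenceDesign,
) -> tuple[np.ndarray, np.ndarray, list[str], list[int]]:
    """Build the regression design for a reference design.

    Columns are intercept, the 0-based monthly trend index, and one
    indicator per seasonal block 1..n (block 0, the reference window, is
    the baseline level).  Blocks with no usable points have their column
    dropped and are reported so the fit can record them.

    Returns ``(X, y, column_names, dropped_blocks)``.
    """
    n = design.config.n_blocks
    present = {p.block for p in design.points}
    dropped = [b for b in range(1, n + 1) if b not in present]
    kept = [b for b in range(1, n + 1) if b in present]

    rows = len(design.points)
    X = np.zeros((rows, 2 + len(kept)))
    y = np.zeros(rows)
    col_of = {b: 2 + i for i, b in enumerate(kept)}
    for i, p in enumerate(design.points):
        X[i, 0] = 1.0
        X[i, 1] = p.trend_index
        if p.block != 0:
            X[i, col_of[p.block]] = 1.0
        y[i] = p.value
    names = ["intercept", "trend"] + [f"block_{b}" for b in kept]
    return X, y, names, dropped
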