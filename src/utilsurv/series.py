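"""Data model and I/O for monthly utilization count series and flag tables.

A :class:`UtilizationSeries` holds one nationally aggregated monthly count
series for a single (outcome, stratum) pair — e.g. inpatients per day in
psychiatric beds.  Series live on a gapless monthly grid of non-negative
integer counts; average-length-of-stay series must be rounded to integers
before entering the count model (see :func:`round_to_integer`).

The long-format CSV exchanged with users has columns
``date,outcome,stratum,value`` with ``date`` as ISO ``YYYY-MM``.  Flag
tables are written with columns
``date,observed,expected,lower,upper,level,flag``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ContiguityError, FormatError
from .month import MonthStamp


class Outcome(str, enum.Enum):
    """The four utilization outcomes tracked by the monthly hospital report."""

    OUTPATIENTS_PER_DAY = "outpatients_per_day"
    INPATIENTS_PER_DAY = "inpatients_per_day"
    AVG_STAY_DAYS = "avg_stay_days"
    NEW_HOSPITALIZATIONS = "new_hospitalizations"


class Flag(str, enum.Enum):
    """Classification of one month against its prediction interval."""

    DEFICIT = "deficit"
    NORMAL = "normal"
    EXCESS = "excess"


@dataclass(frozen=True)
class UtilizationSeries:
    """An ordered, gapless monthly count series for one (outcome, stratum).

    Parameters
    ----------
    outcome
        Which utilization measure the counts represent.
    stratum
        Free-text stratum label, e.g. ``"general"``, ``"psychiatric"``,
        ``"total"`` (hospital type) or a bed type such as
        ``"tuberculosis"`` or ``"ltci"``.
    months
        Strictly increasing, gapless months.
    values
        Non-negative integer counts, one per month.
    """

    outcome: Outcome
    stratum: str
    months: tuple[MonthStamp, ...]
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.months) != len(self.values):
            raise ValueError("months and values must have equal length")
        if len(self.months) == 0:
            raise ValueError("series must contain at least one observation")
        for prev, cur in zip(self.months, self.months[1:]):
            if prev.months_until(cur) != 1:
                raise ContiguityError(
                    f"series {self.outcome.value}/{self.stratum}: "
                    f"gap or disorder between {prev} and {cur}"
                )
        for m, v in zip(self.months, self.values):
            if v < 0:
                raise ValueError(f"negative count {v} at {m}")
            if v != int(v):
                raise ValueError(f"non-integer count {v} at {m}")

    def __len__(self) -> int:
        return len(self.months)

    @property
    def start(self) -> MonthStamp:
        return self.months[0]

    @property
    def end(self) -> MonthStamp:
        return self.months[-1]

    def value_at(self, month: MonthStamp) -> int:
        """The count observed in ``month``; KeyError if outside the series."""
        k = self.start.months_until(month)
        if not 0 <= k < len(self.months):
            raise KeyError(f"{month} outside series [{self.start}, {self.end}]")
        return self.values[k]

    def trend_index(self, month: MonthStamp) -> int:
        """Months elapsed since the series start (0-based trend covariate)."""
        return self.start.months_until(month)

    @classmethod
    def from_observations(
        cls,
        outcome: Outcome | str,
        stratum: str,
        observations: Iterable[tuple[MonthStamp, int]],
    ) -> "UtilizationSeries":
        obs = sorted(observations, key=lambda mv: mv[0])
        months = tuple(m for m, _ in obs)
        values = tuple(int(v) for _, v in obs)
        return cls(Outcome(outcome), stratum, months, values)


@dataclass(frozen=True)
class FlagRecord:
    """The per-month verdict: observation vs model-based prediction interval."""

    month: MonthStamp
    observed: int
    expected: float
    lower: int
    upper: int
    level: float
    flag: Flag
    dispersion_used: float = 1.0

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} > upper {self.upper}")
        if self.flag is not recompute_flag(self.observed, self.lower, self.upper):
            raise ValueError(
                f"flag {self.flag} inconsistent with observed={self.observed}, "
                f"bounds=[{self.lower}, {self.upper}]"
            )


def recompute_flag(observed: int, lower: int, upper: int) -> Flag:
    """Classify from the bounds: strictly above → excess, below → deficit."""
    if observed > upper:
        return Flag.EXCESS
    if observed < lower:
        return Flag.DEFICIT
    return Flag.NORMAL


def round_to_integer(values: Sequence[float]) -> list[int]:
    """Round non-negative reals half-up to the nearest integer.

    Count regression needs integer responses, so continuous outcomes such
    as the average length of stay in days are rounded first.  Half-up
    (0.5 → 1) is used rather than banker's rounding so results are
    deterministic and match the everyday convention.
    """
    out = []
    for v in values:
        if v < 0:
            raise ValueError(f"negative value {v}")
        out.append(int(np.floor(v + 0.5)))
    return out


_SERIES_COLUMNS = ["date", "outcome", "stratum", "value"]
_FLAG_COLUMNS = ["date", "observed", "expected", "lower", "upper", "level", "flag"]


def read_series(
    path: str | Path, outcome: Outcome | str, stratum: str
) -> UtilizationSeries:
    """Read one (outcome, stratum) series from a long-format CSV.

    The CSV must have header columns ``date,outcome,stratum,value``; months
    must form a gapless grid for the selected pair and values must be
    non-negative integers.
    """
    outcome = Outcome(outcome)
    df = _read_long_csv(path)
    sel = df[(df["outcome"] == outcome.value) & (df["stratum"] == stratum)]
    if sel.empty:
        raise FormatError(
            f"no rows for outcome={outcome.value!r}, stratum={stratum!r} in {path}"
        )
    obs = []
    for _, row in sel.iterrows():
        try:
            month = MonthStamp.parse(str(row["date"]))
        except ValueError as exc:
            raise FormatError(f"bad date in {path}: {exc}") from exc
        raw = row["value"]
        try:
            value = float(raw)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"non-numeric value {raw!r} at {month}") from exc
        if value < 0:
            raise ValueError(f"negative value {value} at {month}")
        if value != int(value):
            raise ValueError(
                f"non-integer value {value} at {month}; round upstream "
                "(see round_to_integer)"
            )
        obs.append((month, int(value)))
    return UtilizationSeries.from_observations(outcome, stratum, obs)


def list_series_keys(path: str | Path) -> list[tuple[Outcome, str]]:
    """All (outcome, stratum) pairs present in a long-format CSV, in file order."""
    df = _read_long_csv(path)
    keys: list[tuple[Outcome, str]] = []
    for outcome, stratum in df[["outcome", "stratum"]].drop_duplicates().itertuples(
        index=False
    ):
        keys.append((Outcome(outcome), str(stratum)))
    return keys


def _read_long_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype={"date": str, "outcome": str, "stratum": str})
    missing = [c for c in _SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return df


def write_series(series_list: Iterable[UtilizationSeries], path: str | Path) -> None:
    """Write one or more series to the long-format CSV."""
    rows = []
    for s in series_list:
        for m, v in zip(s.months, s.values):
            rows.append(
                {
                    "date": m.isoformat(),
                    "outcome": s.outcome.value,
                    "stratum": s.stratum,
                    "value": v,
                }
            )
    pd.DataFrame(rows, columns=_SERIES_COLUMNS).to_csv(path, index=False)


def write_flags(records: Sequence[FlagRecord], path: str | Path) -> None:
    """Write flag records to CSV.

    Round-trips losslessly except ``expected``, which is serialized with
    two decimal places; the integer bounds and flags are exact.
    """
    if not records:
        raise ValueError("records must be non-empty")
    rows = [
        {
            "date": r.month.isoformat(),
            "observed": r.observed,
            "expected": f"{r.expected:.2f}",
            "lower": r.lower,
            "upper": r.upper,
            "level": r.level,
            "flag": r.flag.value,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_FLAG_COLUMNS).to_csv(path, index=False)


def read_flags(path: str | Path) -> list[FlagRecord]:
    """Read a flag table written by :func:`write_flags`."""
    df = pd.read_csv(path, dtype={"date": str, "flag": str})
    missing = [c for c in _FLAG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    return [
        FlagRecord(
            month=MonthStamp.parse(row["date"]),
            observed=int(row["observed"]),
            expected=float(row["expected"]),
            lower=int(row["lower"]),
            upper=int(row["upper"]),
            level=float(row["level"]),
            flag=Flag(row["flag"]),
        )
        for _, row in df.iterrows()
    ]
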