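"""Calendar-month timestamps.

The whole package works on a gapless monthly grid, so the only time type
needed is a (year, month) pair with total ordering and well-defined
month arithmetic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_MONTH_RE = re.compile(r"^(\d{4})-(\d{2})$")


@dataclass(frozen=True, order=True)
class MonthStamp:
    """A calendar month, e.g. ``MonthStamp(2020, 6)`` for June 2020.

    Ordering is lexicographic on (year, month).  Differences and shifts
    are in whole months.
    """

    year: int
    month: int

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"month must be in 1..12, got {self.month}")

    @property
    def index(self) -> int:
        """Months elapsed since year 0, month 1 (an absolute month count)."""
        return self.year * 12 + (self.month - 1)

    def shift(self, months: int) -> "MonthStamp":
        """Return the month ``months`` after (or before, if negative) self."""
        i = self.index + months
        return MonthStamp(i // 12, i % 12 + 1)

    def months_until(self, other: "MonthStamp") -> int:
        """Signed number of months from self to ``other``."""
        return other.index - self.index

    @classmethod
    def parse(cls, text: str) -> "MonthStamp":
        """Parse an ISO ``YYYY-MM`` string."""
        m = _MONTH_RE.match(text.strip())
        if m is None:
            raise ValueError(f"expected 'YYYY-MM', got {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))

    def isoformat(self) -> str:
        return f"{self.year:04d}-{self.month:02d}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.isoformat()


def month_range(start: MonthStamp, end: MonthStamp) -> list[MonthStamp]:
    """All months from ``start`` to ``end`` inclusive."""
    if end < start:
        raise ValueError(f"end {end} precedes start {start}")
    return [start.shift(k) for k in range(start.months_until(end) + 1)]
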