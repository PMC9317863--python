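"""Study orchestration: window → fit → predict → classify, per series & month.

``run_study`` replays the full surveillance analysis over an
outcome-by-stratum panel: for every series and every month in the
prediction window it builds the reference design, fits the quasi-Poisson
baseline, computes the negative-binomial prediction interval, and flags
the observation.  It emits per-series flag tables, a human-readable run
summary that compresses consecutive flagged months into ranges
("2020-06 to 2020-09" style), and a JSON-lines audit log from which one
can verify that no post-cutoff month ever entered a fit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .detect import classify, predict
from .errors import InsufficientHistoryError, UtilsurvError
from .glm import fit_quasipoisson
from .month import MonthStamp, month_range
from .series import (
    Flag,
    FlagRecord,
    Outcome,
    UtilizationSeries,
    list_series_keys,
    read_series,
    write_flags,
)
from .windows import WindowConfig, build_reference_design


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one full study run."""

    window: WindowConfig = field(default_factory=WindowConfig)
    prediction_start: MonthStamp = field(default_factory=lambda: MonthStamp(2020, 6))
    prediction_end: MonthStamp = field(default_factory=lambda: MonthStamp(2021, 10))
    shaded_intervals: tuple[tuple[MonthStamp, MonthStamp], ...] = ()

    def __post_init__(self) -> None:
        if self.prediction_end < self.prediction_start:
            raise ValueError("prediction_end precedes prediction_start")
        if self.prediction_start <= self.window.exclusion_cutoff:
            raise ValueError(
                "prediction window must start after the exclusion cutoff"
            )

    @property
    def prediction_months(self) -> list[MonthStamp]:
        return month_range(self.prediction_start, self.prediction_end)


@dataclass
class StudyResult:
    """Flags, per-fit audit records and per-series failures of one run."""

    flags: dict[tuple[Outcome, str], list[FlagRecord]]
    audit: list[dict]
    errors: dict[tuple[Outcome, str], str]

    def summary_text(self) -> str:
        lines = []
        for (outcome, stratum), recs in self.flags.items():
            runs = summarize_runs(recs)
            label = f"{outcome.value}/{stratum}"
            if not runs:
                lines.append(f"{label}: no significant months")
                continue
            parts = []
            for flag, start, end in runs:
                span = start.isoformat() if start == end else f"{start} to {end}"
                parts.append(f"{flag.value} {span}")
            lines.append(f"{label}: " + "; ".join(parts))
        for (outcome, stratum), msg in self.errors.items():
            lines.append(f"{outcome.value}/{stratum}: ERROR {msg}")
        return "\n".join(lines) + "\n"


def detect_month(
    series: UtilizationSeries, target: MonthStamp, config: WindowConfig
) -> tuple[FlagRecord, dict]:
    """Run the full per-month procedure; returns the flag and an audit record."""
    if not series.start <= target <= series.end:
        raise InsufficientHistoryError(
            f"target {target} outside observed series [{series.start}, {series.end}]"
        )
    design = build_reference_design(series, target, config)
    design.audit()
    fit = fit_quasipoisson(design)
    prediction = predict(fit)
    record = classify(series.value_at(target), prediction)
    audit = {
        "outcome": series.outcome.value,
        "stratum": series.stratum,
        "target": target.isoformat(),
        "n_points": fit.n_points,
        "max_month_used": max(design.months_used()).isoformat(),
        "cutoff": config.exclusion_cutoff.isoformat(),
        "phi": fit.phi,
        "phi_raw": fit.phi_raw,
        "converged": fit.converged,
        "dropped_blocks": fit.dropped_blocks,
        "expected": prediction.expected,
        "lower": prediction.lower,
        "upper": prediction.upper,
        "observed": record.observed,
        "flag": record.flag.value,
    }
    return record, audit


def run_series(
    series: UtilizationSeries, config: StudyConfig
) -> tuple[list[FlagRecord], list[dict]]:
    """All monthly flags for one series over the prediction window."""
    records, audits = [], []
    for target in config.prediction_months:
        record, audit = detect_month(series, target, config.window)
        records.append(record)
        audits.append(audit)
    return records, audits


def run_study(
    series_list: Sequence[UtilizationSeries],
    config: StudyConfig | None = None,
    outdir: str | Path | None = None,
) -> StudyResult:
    """Run the full study over a panel of series.

    A series whose history cannot support the window scheme is recorded
    as a per-series error; the run continues with the rest.  When
    ``outdir`` is given, writes ``flags_<outcome>_<stratum>.csv`` per
    series, ``summary.txt``, and ``audit.jsonl``.
    """
    if config is None:
        config = StudyConfig()
    result = StudyResult(flags={}, audit=[], errors={})
    for series in series_list:
        key = (series.outcome, series.stratum)
        try:
            records, audits = run_series(series, config)
        except UtilsurvError as exc:
            result.errors[key] = str(exc)
            continue
        result.flags[key] = records
        result.audit.extend(audits)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for (outcome, stratum), records in result.flags.items():
            write_flags(records, outdir / f"flags_{outcome.value}_{stratum}.csv")
        (outdir / "summary.txt").write_text(result.summary_text())
        with open(outdir / "audit.jsonl", "w") as fh:
            for rec in result.audit:
                fh.write(json.dumps(rec) + "\n")
    return result


def run_study_csv(
    input_csv: str | Path,
    config: StudyConfig | None = None,
    outdir: str | Path | None = None,
) -> StudyResult:
    """As :func:`run_study`, reading every (outcome, stratum) from a long CSV."""
    series_list = [
        read_series(input_csv, outcome, stratum)
        for outcome, stratum in list_series_keys(input_csv)
    ]
    return run_study(series_list, config, outdir)


def summarize_runs(
    flags: Sequence[FlagRecord],
) -> list[tuple[Flag, MonthStamp, MonthStamp]]:
    """Maximal consecutive runs of identical non-normal flags.

    Input must be sorted by month.  Each run is reported as a closed
    month range; expanding the ranges reproduces exactly the non-normal
    flag set.
    """
    for prev, cur in zip(flags, flags[1:]):
        if cur.month <= prev.month:
            raise ValueError("flags must be sorted by strictly increasing month")
    runs: list[tuple[Flag, MonthStamp, MonthStamp]] = []
    for rec in flags:
        if rec.flag is Flag.NORMAL:
            continue
        if (
            runs
            and runs[-1][0] is rec.flag
            and runs[-1][2].months_until(rec.month) == 1
        ):
            flag, start, _ = runs[-1]
            runs[-1] = (flag, start, rec.month)
        else:
            runs.append((rec.flag, rec.month, rec.month))
    return runs


def verify_audit(audit: Sequence[dict]) -> None:
    """Machine-check that no fit used data beyond its exclusion cutoff."""
    for rec in audit:
        used = MonthStamp.parse(rec["max_month_used"])
        cutoff = MonthStamp.parse(rec["cutoff"])
        if used > cutoff:
            raise AssertionError(
                f"fit for {rec['outcome']}/{rec['stratum']} at {rec['target']} "
                f"used {used}, beyond cutoff {cutoff}"
            )
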