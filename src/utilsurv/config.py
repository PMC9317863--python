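"""YAML serialization of run configuration.

A config file holds the window constants and the study window, e.g.::

    window:
      w: 3
      b_years: 5
      n_blocks: 3
      level: 0.95
      exclusion_cutoff: "2019-12"
    prediction_start: "2020-06"
    prediction_end: "2021-10"
    shaded_intervals:
      - ["2020-04", "2020-05"]
      - ["2021-01", "2021-03"]
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .month import MonthStamp
from .pipeline import StudyConfig
from .windows import WindowConfig


def window_config_to_dict(cfg: WindowConfig) -> dict:
    return {
        "w": cfg.w,
        "b_years": cfg.b_years,
        "n_blocks": cfg.n_blocks,
        "periods_per_year": cfg.periods_per_year,
        "level": cfg.level,
        "exclusion_cutoff": cfg.exclusion_cutoff.isoformat(),
    }


def window_config_from_dict(d: dict) -> WindowConfig:
    kwargs = dict(d)
    if "exclusion_cutoff" in kwargs:
        kwargs["exclusion_cutoff"] = MonthStamp.parse(str(kwargs["exclusion_cutoff"]))
    return WindowConfig(**kwargs)


def study_config_to_dict(cfg: StudyConfig) -> dict:
    return {
        "window": window_config_to_dict(cfg.window),
        "prediction_start": cfg.prediction_start.isoformat(),
        "prediction_end": cfg.prediction_end.isoformat(),
        "shaded_intervals": [
            [a.isoformat(), b.isoformat()] for a, b in cfg.shaded_intervals
        ],
    }


def study_config_from_dict(d: dict) -> StudyConfig:
    kwargs = {}
    if "window" in d:
        kwargs["window"] = window_config_from_dict(d["window"])
    for key in ("prediction_start", "prediction_end"):
        if key in d:
            kwargs[key] = MonthStamp.parse(str(d[key]))
    if "shaded_intervals" in d:
        kwargs["shaded_intervals"] = tuple(
            (MonthStamp.parse(str(a)), MonthStamp.parse(str(b)))
            for a, b in d["shaded_intervals"]
        )
    return StudyConfig(**kwargs)


def generator_spec_to_dict(spec: "GeneratorSpec") -> dict:
    return {
        "alpha": spec.alpha,
        "beta": spec.beta,
        "seasonal": list(spec.seasonal),
        "phi": spec.phi,
        "start": spec.start.isoformat(),
        "n_months": spec.n_months,
        "shocks": [
            {"start": s.start.isoformat(), "end": s.end.isoformat(), "factor": s.factor}
            for s in spec.shocks
        ],
        "outcome": spec.outcome.value,
        "stratum": spec.stratum,
        "seed": spec.seed,
    }


def generator_spec_from_dict(d: dict) -> "GeneratorSpec":
    from .series import Outcome
    from .simulate import GeneratorSpec, Shock

    kwargs = dict(d)
    if "start" in kwargs:
        kwargs["start"] = MonthStamp.parse(str(kwargs["start"]))
    if "seasonal" in kwargs:
        kwargs["seasonal"] = tuple(float(v) for v in kwargs["seasonal"])
    if "shocks" in kwargs:
        kwargs["shocks"] = tuple(
            Shock(
                MonthStamp.parse(str(s["start"])),
                MonthStamp.parse(str(s["end"])),
                float(s["factor"]),
            )
            for s in kwargs["shocks"]
        )
    if "outcome" in kwargs:
        kwargs["outcome"] = Outcome(kwargs["outcome"])
    return GeneratorSpec(**kwargs)


def load_study_config(path: str | Path) -> StudyConfig:
    with open(path) as fh:
        return study_config_from_dict(yaml.safe_load(fh) or {})


def dump_study_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(study_config_to_dict(cfg), fh, sort_keys=False)
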