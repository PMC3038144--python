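"""File formats: trace CSV dialect, cohort/profile JSON, run configuration.

A trace CSV has header columns ``minute_index, clock, vo2_l_min, vco2_l_min,
pa_index, interaction, asleep, feeding`` (flags as 0/1).  A file may instead
carry a pre-computed ``ee_kcal_min`` column in place of the gas columns, in
which case gas conversion is skipped downstream.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .processing import CalorimetryConfig, MetabolicProfile
from .records import InfantRecord
from .synthetic import TRACE_COLUMNS, CohortParams, TraceParams

__all__ = [
    "read_trace_csv",
    "write_trace_csv",
    "read_cohort_json",
    "write_cohort_json",
    "write_profiles_json",
    "RunConfig",
]

_FLAG_COLUMNS = ("interaction", "asleep", "feeding")
_BASE_COLUMNS = ("minute_index", "clock", "pa_index") + _FLAG_COLUMNS


def write_trace_csv(trace: pd.DataFrame, path) -> None:
    out = trace.copy()
    for c in _FLAG_COLUMNS:
        out[c] = out[c].astype(int)
    out.to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    """Read and validate a minute-level trace.

    Requires the base columns plus either both gas columns or a direct
    ``ee_kcal_min`` column; rejects missing values and non-contiguous
    minute indices.
    """
    df = pd.read_csv(path)
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    has_gas = {"vo2_l_min", "vco2_l_min"}.issubset(df.columns)
    if not has_gas and "ee_kcal_min" not in df.columns:
        raise ValueError(
            f"{path}: need either vo2_l_min+vco2_l_min or an ee_kcal_min column"
        )
    value_cols = [c for c in df.columns if c != "clock"]
    if df[value_cols].isna().any().any():
        bad = df[value_cols].isna().any()
        raise ValueError(f"{path}: NaN values in {list(bad.index[bad])}")
    idx = df["minute_index"].to_numpy()
    steps = np.diff(idx)
    if np.any(steps != 1):
        where = int(idx[np.argmax(steps != 1)])
        raise ValueError(f"{path}: gap in minute_index after minute {where}")
    for c in _FLAG_COLUMNS:
        df[c] = df[c].astype(bool)
    return df


def write_cohort_json(cohort: list[InfantRecord], path) -> None:
    Path(path).write_text(
        json.dumps([inf.to_dict() for inf in cohort], indent=2) + "\n"
    )


def read_cohort_json(path) -> list[InfantRecord]:
    data = json.loads(Path(path).read_text())
    return [InfantRecord.from_dict(d) for d in data]


def write_profiles_json(profiles: list[MetabolicProfile], ids: list[str], path) -> None:
    payload = {i: p.to_dict() for i, p in zip(ids, profiles)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> process -> evaluate)."""

    cohort: CohortParams = dataclasses.field(default_factory=CohortParams)
    trace: TraceParams = dataclasses.field(default_factory=TraceParams)
    calorimetry: CalorimetryConfig = dataclasses.field(default_factory=CalorimetryConfig)
    alpha: float = 0.05
    ee24_mode: str = "censored"
    seed: int = 0

    def to_dict(self) -> dict:
        def plain(obj):
            d = dataclasses.asdict(obj)
            return {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}

        return {
            "cohort": plain(self.cohort),
            "trace": plain(self.trace),
            "calorimetry": plain(self.calorimetry),
            "alpha": self.alpha,
            "ee24_mode": self.ee24_mode,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        def build(klass, sub):
            if sub is None:
                return klass()
            fields = {f.name: f.type for f in dataclasses.fields(klass)}
            kwargs = {}
            for k, v in sub.items():
                if k not in fields:
                    raise ValueError(f"unknown {klass.__name__} field {k!r}")
                kwargs[k] = tuple(v) if isinstance(v, list) else v
            return klass(**kwargs)

        return cls(
            cohort=build(CohortParams, d.get("cohort")),
            trace=build(TraceParams, d.get("trace")),
            calorimetry=build(CalorimetryConfig, d.get("calorimetry")),
            alpha=float(d.get("alpha", 0.05)),
            ee24_mode=d.get("ee24_mode", "censored"),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load from YAML (or JSON, which YAML subsumes)."""
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
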