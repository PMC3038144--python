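"""Reduction of a minute-level chamber trace to EE24, RMR and SMR.

The processing chain mirrors standard whole-room indirect calorimetry
practice for infants:

1. minute gas exchange -> energy expenditure (kcal/min) via the abbreviated
   Weir relation ``EE = 3.941*VO2 + 1.106*VCO2`` (litres);
2. five-minute summary periods, censoring any period touched by parental
   interaction;
3. RMR: ordinary least squares of period EE on period physical activity (PA),
   intercept (EE at zero activity) times 1440 min, per kg;
4. SMR: mean EE of periods that lie wholly inside the 23:30-05:30 night
   window, are fully asleep, have mean PA <= 1.5 and are not censored, times
   1440, per kg;
5. EE24: mean EE over retained (or, optionally, all) periods times 1440,
   per kg.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .records import InfantRecord

__all__ = [
    "CalorimetryConfig",
    "MetabolicProfile",
    "RegressionDiagnostics",
    "ee_from_gas",
    "add_energy_column",
    "summarize",
    "compute_rmr",
    "compute_smr",
    "compute_ee24",
    "process_trace",
    "SMRUndeterminableError",
    "DegenerateActivityError",
    "minute_of_day_from_clock",
    "clock_from_minute_of_day",
    "in_clock_window",
]

MINUTES_PER_DAY = 1440


class SMRUndeterminableError(ValueError):
    """No period qualifies for the sleeping-metabolic-rate estimate."""


class DegenerateActivityError(ValueError):
    """The EE-on-PA regression cannot be fit (constant activity)."""


def minute_of_day_from_clock(clock: str) -> int:
    """Parse ``"HH:MM"`` into minutes past midnight."""
    hh, mm = clock.split(":")
    m = int(hh) * 60 + int(mm)
    if not 0 <= m < MINUTES_PER_DAY:
        raise ValueError(f"clock out of range: {clock!r}")
    return m


def clock_from_minute_of_day(minute: int) -> str:
    minute = int(minute) % MINUTES_PER_DAY
    return f"{minute // 60:02d}:{minute % 60:02d}"


@dataclass(frozen=True)
class CalorimetryConfig:
    """Constants of the trace-reduction pipeline.

    o2_coef/co2_coef are the caloric equivalents (kcal per litre of O2
    consumed / CO2 produced) of the abbreviated Weir relation;
    ``smr_window`` is the night interval (half-open on the right, wrapping
    midnight) and ``pa_threshold`` the activity-index ceiling for a sleeping
    period.
    """

    o2_coef: float = 3.941
    co2_coef: float = 1.106
    summary_minutes: int = 5
    smr_window: tuple[str, str] = ("23:30", "05:30")
    pa_threshold: float = 1.5

    def __post_init__(self) -> None:
        if not (self.o2_coef > 0 and self.co2_coef > 0):
            raise ValueError("caloric coefficients must be positive")
        if MINUTES_PER_DAY % self.summary_minutes:
            raise ValueError("summary_minutes must divide 1440")
        if self.pa_threshold < 0:
            raise ValueError("pa_threshold must be non-negative")
        # validate clock syntax eagerly
        minute_of_day_from_clock(self.smr_window[0])
        minute_of_day_from_clock(self.smr_window[1])


def in_clock_window(minute_of_day, window: tuple[str, str]):
    """Membership of minutes-past-midnight in a half-open clock window.

    The window may wrap midnight, e.g. ("23:30", "05:30").
    """
    start = minute_of_day_from_clock(window[0])
    end = minute_of_day_from_clock(window[1])
    length = (end - start) % MINUTES_PER_DAY
    return (np.asarray(minute_of_day) - start) % MINUTES_PER_DAY < length


def ee_from_gas(vo2, vco2, config: CalorimetryConfig = CalorimetryConfig()):
    """Energy expenditure (kcal/min) from VO2 and VCO2 (L/min).

    Accepts scalars or arrays.  VO2 must be strictly positive and VCO2
    non-negative.
    """
    vo2 = np.asarray(vo2, dtype=float)
    vco2 = np.asarray(vco2, dtype=float)
    if np.any(vo2 <= 0):
        raise ValueError("vo2 must be strictly positive")
    if np.any(vco2 < 0):
        raise ValueError("vco2 must be non-negative")
    out = config.o2_coef * vo2 + config.co2_coef * vco2
    return float(out) if out.ndim == 0 else out


def add_energy_column(
    trace: pd.DataFrame, config: CalorimetryConfig = CalorimetryConfig()
) -> pd.DataFrame:
    """Return a copy of ``trace`` with an ``ee_kcal_min`` column.

    Traces that already carry ``ee_kcal_min`` (pre-computed energy) are
    returned unchanged; otherwise it is derived from the gas columns.
    """
    if "ee_kcal_min" in trace.columns:
        return trace
    out = trace.copy()
    out["ee_kcal_min"] = ee_from_gas(
        trace["vo2_l_min"].to_numpy(), trace["vco2_l_min"].to_numpy(), config
    )
    return out


def summarize(
    trace: pd.DataFrame, config: CalorimetryConfig = CalorimetryConfig()
) -> pd.DataFrame:
    """Aggregate contiguous minutes into fixed summary periods.

    Blocks are aligned to the recording start.  Period EE and PA are
    arithmetic means; period RQ is the ratio of summed VCO2 to summed VO2
    (when gas columns are present).  A period is

    - ``censored_interaction`` if ANY member minute had parental interaction,
    - ``all_asleep`` if ALL member minutes were observed asleep,
    - ``in_smr_window`` if ALL member minutes fall inside the night window.
    """
    n = len(trace)
    k = config.summary_minutes
    if n == 0 or n % k:
        raise ValueError(f"trace length {n} is not a multiple of {k}")
    idx = trace["minute_index"].to_numpy()
    if np.any(np.diff(idx) != 1):
        gap = int(idx[np.argmax(np.diff(idx) != 1)])
        raise ValueError(f"trace minutes are not contiguous (gap after minute {gap})")

    trace = add_energy_column(trace, config)
    shape = (n // k, k)
    ee = trace["ee_kcal_min"].to_numpy().reshape(shape)
    pa = trace["pa_index"].to_numpy(dtype=float).reshape(shape)
    interaction = trace["interaction"].to_numpy(dtype=bool).reshape(shape)
    asleep = trace["asleep"].to_numpy(dtype=bool).reshape(shape)
    mod = np.array(
        [minute_of_day_from_clock(c) for c in trace["clock"]], dtype=int
    ).reshape(shape)
    in_window = in_clock_window(mod, config.smr_window).reshape(shape)

    periods = pd.DataFrame(
        {
            "start_minute": idx.reshape(shape)[:, 0],
            "ee": ee.mean(axis=1),
            "pa": pa.mean(axis=1),
            "censored_interaction": interaction.any(axis=1),
            "all_asleep": asleep.all(axis=1),
            "in_smr_window": in_window.all(axis=1),
        }
    )
    if {"vo2_l_min", "vco2_l_min"}.issubset(trace.columns):
        vo2 = trace["vo2_l_min"].to_numpy().reshape(shape)
        vco2 = trace["vco2_l_min"].to_numpy().reshape(shape)
        periods["rq"] = vco2.sum(axis=1) / vo2.sum(axis=1)
    else:
        periods["rq"] = np.nan
    return periods


@dataclass(frozen=True)
class RegressionDiagnostics:
    """OLS fit of period EE (kcal/min) on period PA."""

    intercept: float  # kcal/min at PA = 0
    slope: float  # kcal/min per PA unit
    r_squared: float
    n_used: int
    negative_intercept: bool = False


@dataclass
class MetabolicProfile:
    """Processed 24-h metabolic summary for one infant (kcal/kg/d)."""

    ee24: float
    rmr: float
    smr: float  # NaN when undeterminable (see smr_error)
    n_periods_total: int
    n_censored: int
    n_smr_used: int
    regression: RegressionDiagnostics
    smr_error: str | None = None

    def to_dict(self) -> dict:
        return {
            "ee24": self.ee24,
            "rmr": self.rmr,
            "smr": self.smr,
            "n_periods_total": self.n_periods_total,
            "n_censored": self.n_censored,
            "n_smr_used": self.n_smr_used,
            "regression": {
                "intercept": self.regression.intercept,
                "slope": self.regression.slope,
                "r_squared": self.regression.r_squared,
                "n_used": self.regression.n_used,
                "negative_intercept": self.regression.negative_intercept,
            },
            "smr_error": self.smr_error,
        }


def _retained(periods: pd.DataFrame) -> pd.DataFrame:
    return periods[~periods["censored_interaction"]]


def compute_rmr(
    periods: pd.DataFrame,
    weight_kg: float,
    config: CalorimetryConfig = CalorimetryConfig(),
) -> tuple[float, RegressionDiagnostics]:
    """RMR (kcal/kg/d): OLS intercept of EE on PA, extrapolated to 24 h.

    Uses non-censored periods only.  Requires at least three periods and at
    least two distinct PA values; a negative intercept is returned flagged
    rather than silently.
    """
    kept = _retained(periods)
    if len(kept) < 3:
        raise ValueError(f"need >= 3 non-censored periods, have {len(kept)}")
    pa = kept["pa"].to_numpy(dtype=float)
    ee = kept["ee"].to_numpy(dtype=float)
    if np.ptp(pa) == 0:
        raise DegenerateActivityError("all PA values identical; intercept undefined")
    fit = sm.OLS(ee, sm.add_constant(pa)).fit()
    intercept, slope = float(fit.params[0]), float(fit.params[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = float(fit.rsquared)  # undefined for constant EE
    diag = RegressionDiagnostics(
        intercept=intercept,
        slope=slope,
        r_squared=r2 if np.isfinite(r2) else float("nan"),
        n_used=len(kept),
        negative_intercept=intercept < 0,
    )
    rmr = intercept * MINUTES_PER_DAY / weight_kg
    return rmr, diag


def compute_smr(
    periods: pd.DataFrame,
    weight_kg: float,
    config: CalorimetryConfig = CalorimetryConfig(),
) -> tuple[float, int]:
    """SMR (kcal/kg/d): mean EE of quiet-sleep night periods, times 1440.

    Qualifying periods lie wholly in the night window, are fully asleep, have
    mean PA <= threshold and are not censored.  Raises
    :class:`SMRUndeterminableError` when none qualify.
    """
    q = periods[
        periods["in_smr_window"]
        & periods["all_asleep"]
        & (periods["pa"] <= config.pa_threshold)
        & ~periods["censored_interaction"]
    ]
    if len(q) == 0:
        raise SMRUndeterminableError(
            "SMR undeterminable: no uncensored asleep period with "
            f"PA <= {config.pa_threshold} inside {config.smr_window[0]}-"
            f"{config.smr_window[1]}"
        )
    smr = float(q["ee"].mean()) * MINUTES_PER_DAY / weight_kg
    return smr, len(q)


def compute_ee24(
    periods: pd.DataFrame,
    weight_kg: float,
    config: CalorimetryConfig = CalorimetryConfig(),
    mode: str = "censored",
) -> float:
    """24-h EE (kcal/kg/d) as a time-normalised mean times 1440.

    ``mode="censored"`` (default) averages over non-censored periods only,
    consistent with the interaction correction applied for RMR/SMR;
    ``mode="full"`` averages over every period.
    """
    if mode not in ("censored", "full"):
        raise ValueError(f"unknown ee24 mode {mode!r}")
    use = _retained(periods) if mode == "censored" else periods
    if len(use) == 0:
        raise ValueError("no periods available for EE24 (all censored)")
    return float(use["ee"].mean()) * MINUTES_PER_DAY / weight_kg


def process_trace(
    trace: pd.DataFrame,
    infant: InfantRecord,
    config: CalorimetryConfig = CalorimetryConfig(),
    ee24_mode: str = "censored",
) -> MetabolicProfile:
    """Full reduction of one minute trace to a :class:`MetabolicProfile`.

    An undeterminable SMR is surfaced in the profile (``smr`` NaN plus
    ``smr_error``) instead of aborting the other estimates.
    """
    periods = summarize(trace, config)
    weight = infant.weight_kg
    rmr, diag = compute_rmr(periods, weight, config)
    ee24 = compute_ee24(periods, weight, config, mode=ee24_mode)
    try:
        smr, n_smr = compute_smr(periods, weight, config)
        smr_error = None
    except SMRUndeterminableError as exc:
        smr, n_smr, smr_error = float("nan"), 0, str(exc)
    return MetabolicProfile(
        ee24=ee24,
        rmr=rmr,
        smr=smr,
        n_periods_total=len(periods),
        n_censored=int(periods["censored_interaction"].sum()),
        n_smr_used=n_smr,
        regression=diag,
        smr_error=smr_error,
    )
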