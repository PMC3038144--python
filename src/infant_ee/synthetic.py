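"""Synthetic infant cohorts and 24-h metabolic-chamber traces.

No public minute-level recordings accompany the reference study, so this
module generates cohorts with the reference anthropometric distributions and
minute-level gas-exchange/activity traces with *known* ground truth, making
the trace-processing and agreement layers fully testable.

The latent minute energy expenditure (kcal/min) is

    EE(t) = basal * WT/1440 * (1 - A*cos(2*pi*(t - trough)/1440))   circadian basal
          + activity_ee_coef * WT * PA(t)                             movement cost
          + thermic(t)                                               post-feed thermogenesis
          (+ independent Gaussian observation noise)

Sleep and wake alternate in bouts of 2-4 h; wake bouts that begin at night
are brief (night wakings).  Feeds occur only while awake, are accompanied by
parental interaction, and trigger a linearly decaying thermic response.  Gas
exchange is obtained by exact inversion of the calorimetric relation at a
simulated respiratory quotient, so recomputing EE from (VO2, VCO2)
reproduces the noisy latent signal to machine precision.

Between-infant heterogeneity (a truncated-normal basal rate and a lognormal
awake-activity scale) is calibrated so that a default cohort's processed
EE24/RMR/SMR reproduce the reference cohort statistics; see docs/methods.md
for the calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .processing import (
    MINUTES_PER_DAY,
    CalorimetryConfig,
    clock_from_minute_of_day,
    in_clock_window,
    minute_of_day_from_clock,
)
from .records import FEMALE, MALE, InfantRecord, weight_from_bmi

__all__ = [
    "CohortParams",
    "TraceParams",
    "GroundTruth",
    "SimulatedInfant",
    "generate_cohort",
    "simulate_trace",
    "simulate_study",
    "TRACE_COLUMNS",
]

TRACE_COLUMNS = (
    "minute_index",
    "clock",
    "vo2_l_min",
    "vco2_l_min",
    "pa_index",
    "interaction",
    "asleep",
    "feeding",
)


@dataclass(frozen=True)
class CohortParams:
    """Anthropometric distribution of a simulated cohort.

    Defaults reproduce the reference cohort: n=10 with 7 males, age
    5.0 +/- 0.8 months, length 68.8 +/- 2.8 cm, BMI 15.5 +/- 1.5 kg/m^2.
    Lengths/BMIs/ages are normal, truncated at +/- 3 SD; weight is derived
    from BMI and length.
    """

    n: int = 10
    male_fraction: float = 0.7
    age_mean: float = 5.0
    age_sd: float = 0.8
    length_mean: float = 68.8
    length_sd: float = 2.8
    bmi_mean: float = 15.5
    bmi_sd: float = 1.5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must be in [0, 1]")
        for name in ("age_sd", "length_sd", "bmi_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("age_mean", "length_mean", "bmi_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class TraceParams:
    """Physiological and behavioural parameters of one simulated 24-h trace.

    Rates are kcal/kg/d unless noted.  The energetic cost of movement scales
    with body mass (the PA index itself is weight-normalised), so
    ``activity_ee_coef`` is kcal/min per PA unit per kg.  It and
    ``thermic_effect_fraction`` are calibrated so that processed
    outputs of a default cohort land on the reference cohort means;
    ``basal_sd_between`` and ``activity_sigma_between`` reproduce its
    between-infant spread and are consumed by :func:`simulate_study`.
    """

    start_clock: str = "09:30"
    duration_min: int = 1440
    basal_rate: float = 66.0  # kcal/kg/d; RMR ground truth
    circadian_amplitude: float = 0.05  # fraction of basal
    circadian_trough_clock: str = "02:30"
    sleep_cycle_range: tuple[float, float] = (120.0, 240.0)  # minutes
    night_wake_range: tuple[float, float] = (20.0, 45.0)  # minutes
    night_window: tuple[str, str] = ("23:00", "06:00")
    activity_ee_coef: float = 0.00269  # kcal/min per PA unit per kg (calibrated)
    pa_awake_mean: float = 4.0
    pa_awake_sd: float = 2.0
    pa_asleep_mean: float = 0.5
    pa_asleep_sd: float = 0.3
    pa_feeding_mean: float = 1.5
    pa_feeding_sd: float = 0.8
    feeds_per_day: int = 6
    feed_energy_kcal: float = 110.0
    feed_duration_min: int = 15
    feed_min_spacing_min: int = 90
    feed_window: tuple[str, str] = ("06:00", "22:00")  # feeds start in daytime
    thermic_effect_fraction: float = 0.062  # of feed energy (calibrated)
    thermic_delay_min: int = 25  # post-meal lag before the thermic peak
    thermic_duration_min: int = 60
    interaction_prob_per_feed: float = 1.0
    interaction_extra_minutes: int = 10
    rq_mean: float = 0.88
    rq_sd: float = 0.04
    noise_sd: float = 0.005  # kcal/min
    basal_sd_between: float = 3.5  # kcal/kg/d across infants
    activity_sigma_between: float = 0.65  # lognormal sigma of awake PA scale
    activity_scale_cap: float = 4.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.duration_min % 5:
            raise ValueError("duration_min must be a multiple of 5")
        if self.duration_min < 5:
            raise ValueError("duration_min must be positive")
        nonneg = (
            "basal_rate",
            "circadian_amplitude",
            "activity_ee_coef",
            "pa_awake_mean",
            "pa_awake_sd",
            "pa_asleep_mean",
            "pa_asleep_sd",
            "pa_feeding_mean",
            "pa_feeding_sd",
            "feed_energy_kcal",
            "thermic_effect_fraction",
            "rq_mean",
            "rq_sd",
            "noise_sd",
            "basal_sd_between",
            "activity_sigma_between",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.pa_asleep_mean > 1.5:
            raise ValueError("pa_asleep_mean must be <= 1.5 (sleep PA cutoff)")
        if self.feeds_per_day < 0:
            raise ValueError("feeds_per_day must be >= 0")
        if not 0.0 <= self.interaction_prob_per_feed <= 1.0:
            raise ValueError("interaction_prob_per_feed must be in [0, 1]")
        lo, hi = self.sleep_cycle_range
        if not 0 < lo <= hi:
            raise ValueError("sleep_cycle_range must be increasing and positive")
        minute_of_day_from_clock(self.start_clock)
        minute_of_day_from_clock(self.circadian_trough_clock)


@dataclass
class GroundTruth:
    """Latent quantities of one simulated trace (kcal/kg/d; EE in kcal/min)."""

    true_rmr: float
    true_smr: float
    true_ee24: float
    latent_ee: np.ndarray  # noiseless kcal/min, one entry per minute

    def to_dict(self) -> dict:
        return {
            "true_rmr": self.true_rmr,
            "true_smr": self.true_smr,
            "true_ee24": self.true_ee24,
        }


@dataclass
class SimulatedInfant:
    """One cohort member with its trace and ground truth."""

    infant: InfantRecord
    trace: pd.DataFrame
    truth: GroundTruth


def _truncated_normal(rng, mean, sd, size, nsd=3.0):
    """Normal draws rejected outside mean +/- nsd*sd."""
    if sd == 0:
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = np.abs(out - mean) > nsd * sd
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = np.abs(out - mean) > nsd * sd
    return out


def _resolve_rng(rng, seed, params_seed):
    if rng is not None:
        return rng
    if seed is None:
        seed = params_seed
    return np.random.default_rng(seed)


def generate_cohort(
    params: CohortParams = CohortParams(),
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> list[InfantRecord]:
    """Draw a cohort of :class:`InfantRecord`.

    Sex assignment is deterministic: ``round(n * male_fraction)`` males first.
    Weight is computed from the drawn BMI and length.
    """
    rng = _resolve_rng(rng, seed, params.seed)
    n_male = int(round(params.n * params.male_fraction))
    sexes = [MALE] * n_male + [FEMALE] * (params.n - n_male)
    ages = _truncated_normal(rng, params.age_mean, params.age_sd, params.n)
    lengths = _truncated_normal(rng, params.length_mean, params.length_sd, params.n)
    bmis = _truncated_normal(rng, params.bmi_mean, params.bmi_sd, params.n)
    return [
        InfantRecord(
            id=f"inf{i:03d}",
            sex=sexes[i],
            age_months=float(max(ages[i], 0.0)),
            length_cm=float(lengths[i]),
            bmi=float(bmis[i]),
        )
        for i in range(params.n)
    ]


def _sleep_schedule(rng, params: TraceParams, minute_of_day: np.ndarray) -> np.ndarray:
    """Boolean asleep flag per minute.

    Bouts alternate starting awake at the recording start; sleep bouts and
    daytime wake bouts are uniform on ``sleep_cycle_range`` while wake bouts
    beginning inside ``night_window`` are brief night wakings.
    """
    n = params.duration_min
    asleep = np.zeros(n, dtype=bool)
    night = in_clock_window(minute_of_day, params.night_window)
    t = 0
    awake = True
    lo, hi = params.sleep_cycle_range
    nlo, nhi = params.night_wake_range
    while t < n:
        if awake and night[t]:
            dur = int(round(rng.uniform(nlo, nhi)))
        else:
            dur = int(round(rng.uniform(lo, hi)))
        dur = max(dur, 1)
        if not awake:
            asleep[t : t + dur] = True
        t += dur
        awake = not awake
    return asleep


def _place_feeds(
    rng, params: TraceParams, asleep: np.ndarray, minute_of_day: np.ndarray
) -> list[int]:
    """Feed start minutes: fully-awake daytime windows, starts >= spacing apart."""
    n = params.duration_min
    dur = params.feed_duration_min
    awake = ~asleep
    daytime = in_clock_window(minute_of_day, params.feed_window)
    ok = np.array(
        [t + dur <= n and daytime[t] and awake[t : t + dur].all() for t in range(n)],
        dtype=bool,
    )
    candidates = set(np.flatnonzero(ok).tolist())
    starts: list[int] = []
    for _ in range(params.feeds_per_day):
        if not candidates:
            break
        pool = np.array(sorted(candidates))
        t = int(rng.choice(pool))
        starts.append(t)
        candidates -= set(range(t - params.feed_min_spacing_min, t + params.feed_min_spacing_min + 1))
    return sorted(starts)


def simulate_trace(
    infant: InfantRecord,
    params: TraceParams = TraceParams(),
    *,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
    calorimetry: CalorimetryConfig = CalorimetryConfig(),
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one 24-h minute-level chamber trace plus its ground truth.

    Ground truth is computed from the noiseless latent EE: ``true_rmr`` is the
    basal rate parameter, ``true_smr`` the mean latent EE over asleep minutes
    inside the SMR night window (x 1440 / WT) and ``true_ee24`` the overall
    mean latent EE (x 1440 / WT).
    """
    rng = _resolve_rng(rng, seed, params.seed)
    n = params.duration_min
    wt = infant.weight_kg
    start = minute_of_day_from_clock(params.start_clock)
    minute_of_day = (start + np.arange(n)) % MINUTES_PER_DAY

    asleep = _sleep_schedule(rng, params, minute_of_day)
    feed_starts = _place_feeds(rng, params, asleep, minute_of_day)

    feeding = np.zeros(n, dtype=bool)
    interaction = np.zeros(n, dtype=bool)
    thermic = np.zeros(n, dtype=float)
    tef_energy = params.feed_energy_kcal * params.thermic_effect_fraction
    d = params.thermic_duration_min
    for t0 in feed_starts:
        feeding[t0 : t0 + params.feed_duration_min] = True
        if rng.uniform() < params.interaction_prob_per_feed:
            a = max(t0 - params.interaction_extra_minutes, 0)
            b = min(t0 + params.feed_duration_min + params.interaction_extra_minutes, n)
            interaction[a:b] = True
        if tef_energy > 0 and d > 0:
            # post-meal thermogenesis: peak after an absorption lag, then
            # linear decay integrating to tef_energy kcal
            on = t0 + params.thermic_delay_min
            tau = np.arange(max(min(d, n - on), 0))
            thermic[on : on + len(tau)] += 2.0 * tef_energy / d * (1.0 - tau / d)

    pa = np.empty(n)
    awake_idx = ~asleep & ~feeding
    pa[asleep] = rng.normal(params.pa_asleep_mean, params.pa_asleep_sd, int(asleep.sum()))
    pa[feeding] = rng.normal(params.pa_feeding_mean, params.pa_feeding_sd, int(feeding.sum()))
    pa[awake_idx] = rng.normal(params.pa_awake_mean, params.pa_awake_sd, int(awake_idx.sum()))
    pa = np.clip(pa, 0.0, None)

    trough = minute_of_day_from_clock(params.circadian_trough_clock)
    circadian = 1.0 - params.circadian_amplitude * np.cos(
        2.0 * np.pi * (minute_of_day - trough) / MINUTES_PER_DAY
    )
    latent = (
        params.basal_rate * wt / MINUTES_PER_DAY * circadian
        + params.activity_ee_coef * wt * pa
        + thermic
    )
    observed = latent + rng.normal(0.0, params.noise_sd, n)

    rq = np.clip(rng.normal(params.rq_mean, params.rq_sd, n), 0.75, 1.05)
    vo2 = observed / (calorimetry.o2_coef + calorimetry.co2_coef * rq)
    vco2 = rq * vo2

    trace = pd.DataFrame(
        {
            "minute_index": np.arange(n),
            "clock": [clock_from_minute_of_day(m) for m in minute_of_day],
            "vo2_l_min": vo2,
            "vco2_l_min": vco2,
            "pa_index": pa,
            "interaction": interaction,
            "asleep": asleep,
            "feeding": feeding,
        }
    )

    smr_minutes = asleep & in_clock_window(minute_of_day, CalorimetryConfig().smr_window)
    true_smr = (
        float(latent[smr_minutes].mean()) * MINUTES_PER_DAY / wt
        if smr_minutes.any()
        else float("nan")
    )
    truth = GroundTruth(
        true_rmr=params.basal_rate,
        true_smr=true_smr,
        true_ee24=float(latent.mean()) * MINUTES_PER_DAY / wt,
        latent_ee=latent,
    )
    return trace, truth


def simulate_study(
    cohort_params: CohortParams = CohortParams(),
    trace_params: TraceParams = TraceParams(),
    *,
    seed: int | None = None,
    calorimetry: CalorimetryConfig = CalorimetryConfig(),
) -> list[SimulatedInfant]:
    """Simulate a whole cohort: anthropometrics plus one trace per infant.

    A single master seed drives everything through a spawned
    ``numpy.random.SeedSequence`` tree (one child stream for the cohort, one
    for between-infant physiology, one per trace), so runs are reproducible
    and traces mutually independent.  Per-infant basal rates are truncated
    normal around ``trace_params.basal_rate`` and awake activity is scaled by
    a capped lognormal factor.
    """
    if seed is None:
        seed = trace_params.seed if trace_params.seed is not None else cohort_params.seed
    ss = np.random.SeedSequence(seed)
    cohort_ss, hetero_ss, *trace_ss = ss.spawn(2 + cohort_params.n)
    cohort = generate_cohort(cohort_params, rng=np.random.default_rng(cohort_ss))

    hrng = np.random.default_rng(hetero_ss)
    basals = _truncated_normal(
        hrng, trace_params.basal_rate, trace_params.basal_sd_between, cohort_params.n
    )
    sigma = trace_params.activity_sigma_between
    scales = np.minimum(
        np.exp(hrng.normal(-0.5 * sigma**2, sigma, cohort_params.n)),
        trace_params.activity_scale_cap,
    )

    out = []
    for i, infant in enumerate(cohort):
        p_i = replace(
            trace_params,
            basal_rate=float(basals[i]),
            pa_awake_mean=trace_params.pa_awake_mean * float(scales[i]),
            pa_awake_sd=trace_params.pa_awake_sd * float(scales[i]),
        )
        trace, truth = simulate_trace(
            infant, p_i, rng=np.random.default_rng(trace_ss[i]), calorimetry=calorimetry
        )
        out.append(SimulatedInfant(infant=infant, trace=trace, truth=truth))
    return out
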