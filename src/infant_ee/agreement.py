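"""Method-comparison statistics: paired t-tests and Bland-Altman limits.

Each prediction equation is compared with the directly measured quantity it
estimates (24-h EE, RMR or SMR, all kcal/kg/d), pairing by infant:

- a two-sided paired t-test on per-infant differences (calculated - reference);
- per-infant percent differences, summarised as mean +/- SD;
- Bland-Altman limits of agreement, ``mean difference +/- 2 SD`` (exactly 2);
- a verdict: *agreement* when the paired t-test is non-significant at alpha.

The difference sign convention defaults to calculated - reference (matching
the published agreement tables); ``orientation="ref-calc"`` flips it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .equations import cohort_apply, equation_target, EQUATION_NAMES
from .processing import MetabolicProfile
from .records import InfantRecord

__all__ = [
    "PairedTResult",
    "BlandAltmanResult",
    "AgreementResult",
    "paired_t",
    "percent_difference",
    "bland_altman",
    "evaluate_cohort",
]

#: below this p-value floor a zero-variance nonzero difference is reported
P_FLOOR = np.finfo(float).tiny


def _paired(reference, calculated):
    ref = np.asarray(reference, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if ref.shape != calc.shape or ref.ndim != 1:
        raise ValueError("reference and calculated must be 1-d and equally long")
    return ref, calc


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p: float
    zero_variance: bool = False


def paired_t(reference, calculated) -> PairedTResult:
    """Two-sided paired t-test of calculated vs reference.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = calculated - reference`` and
    ``df = n-1``.  Identical series give t=0, p=1; a constant nonzero
    difference has zero variance and is reported at the p floor with a flag.
    """
    ref, calc = _paired(reference, calculated)
    n = len(ref)
    if n < 2:
        raise ValueError("paired t-test needs n >= 2")
    d = calc - ref
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return PairedTResult(t=0.0, df=n - 1, p=1.0)
        return PairedTResult(
            t=np.inf if d.mean() > 0 else -np.inf, df=n - 1, p=P_FLOOR, zero_variance=True
        )
    res = stats.ttest_rel(calc, ref)
    return PairedTResult(t=float(res.statistic), df=n - 1, p=float(res.pvalue))


def percent_difference(reference, calculated) -> tuple[float, float]:
    """Mean and sample SD of per-pair percent differences.

    ``100 * (calculated - reference) / reference`` per infant; all reference
    values must be strictly positive.
    """
    ref, calc = _paired(reference, calculated)
    if np.any(ref <= 0):
        raise ValueError("reference values must be strictly positive")
    pct = 100.0 * (calc - ref) / ref
    sd = float(pct.std(ddof=1)) if len(pct) > 1 else 0.0
    return float(pct.mean()), sd


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    limits: tuple[float, float]  # mean_diff -/+ 2*sd_diff
    averages: np.ndarray  # per-pair (ref+calc)/2
    differences: np.ndarray


def bland_altman(reference, calculated, orientation: str = "calc-ref") -> BlandAltmanResult:
    """Bland-Altman limit analysis on a paired series.

    Per-pair averages ``(ref+calc)/2`` against differences; limits of
    agreement are ``mean +/- 2 SD`` of the differences (the conventional 1.96
    rounded to 2).
    """
    ref, calc = _paired(reference, calculated)
    if len(ref) < 2:
        raise ValueError("Bland-Altman analysis needs n >= 2")
    if orientation == "calc-ref":
        d = calc - ref
    elif orientation == "ref-calc":
        d = ref - calc
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    mean_diff = float(d.mean())
    sd_diff = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_diff=mean_diff,
        sd_diff=sd_diff,
        limits=(mean_diff - 2.0 * sd_diff, mean_diff + 2.0 * sd_diff),
        averages=(ref + calc) / 2.0,
        differences=d,
    )


@dataclass(frozen=True)
class AgreementResult:
    """Cohort-level comparison of one equation with its measured reference."""

    equation: str
    target: str  # EE24 | RMR | SMR
    value_mean: float  # cohort mean of the calculated values, kcal/kg/d
    value_sd: float
    pct_diff_mean: float
    pct_diff_sd: float
    t: float
    df: int
    p: float
    ba_mean_diff: float
    ba_sd_diff: float
    ba_limits: tuple[float, float]
    verdict: str  # agreement | no_agreement

    def to_dict(self) -> dict:
        return {
            "equation": self.equation,
            "target": self.target,
            "value_mean": self.value_mean,
            "value_sd": self.value_sd,
            "pct_diff_mean": self.pct_diff_mean,
            "pct_diff_sd": self.pct_diff_sd,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "ba_mean_diff": self.ba_mean_diff,
            "ba_sd_diff": self.ba_sd_diff,
            "ba_lower": self.ba_limits[0],
            "ba_upper": self.ba_limits[1],
            "verdict": self.verdict,
        }


def _reference_series(profiles: list[MetabolicProfile], target: str) -> np.ndarray:
    attr = {"EE24": "ee24", "RMR": "rmr", "SMR": "smr"}[target]
    return np.array([getattr(p, attr) for p in profiles], dtype=float)


def evaluate_cohort(
    profiles: list[MetabolicProfile],
    cohort: list[InfantRecord],
    equation_names: tuple[str, ...] = EQUATION_NAMES,
    alpha: float = 0.05,
    orientation: str = "calc-ref",
) -> list[AgreementResult]:
    """Compare every requested equation against the measured cohort profiles.

    ``profiles`` and ``cohort`` must be aligned (same infants, same order).
    Each equation is paired with the measured quantity it targets; the
    verdict is *agreement* iff the paired-t p-value is >= alpha.
    """
    if len(profiles) != len(cohort):
        raise ValueError(
            f"profiles ({len(profiles)}) and cohort ({len(cohort)}) misaligned"
        )
    results = []
    for name in equation_names:
        target = equation_target(name)
        ref = _reference_series(profiles, target)
        if np.any(np.isnan(ref)):
            raise ValueError(
                f"measured {target} unavailable for some infants; cannot "
                f"evaluate equation {name!r}"
            )
        pred = cohort_apply(name, cohort)
        tt = paired_t(ref, pred.values)
        pct_mean, pct_sd = percent_difference(ref, pred.values)
        ba = bland_altman(ref, pred.values, orientation=orientation)
        results.append(
            AgreementResult(
                equation=name,
                target=target,
                value_mean=pred.mean,
                value_sd=pred.sd,
                pct_diff_mean=pct_mean,
                pct_diff_sd=pct_sd,
                t=tt.t,
                df=tt.df,
                p=tt.p,
                ba_mean_diff=ba.mean_diff,
                ba_sd_diff=ba.sd_diff,
                ba_limits=ba.limits,
                verdict="agreement" if tt.p >= alpha else "no_agreement",
            )
        )
    return results
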