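"""Poisson-regression comparisons of puncta counts between groups and over age.

Per-animal puncta counts are compared with a Poisson generalised linear model
with log link — the standard statistic for small-count microscopy data.  For
a two-group comparison the model is ``log mu = b0 + b1 * group`` and the
quantity of interest is the rate ratio ``exp(b1)``; its maximum-likelihood
estimate is exactly ``mean(group b) / mean(group a)``, which tests use as a
closed-form cross-check.  Inference is a Wald test on the group coefficient
by default, with a likelihood-ratio alternative behind a flag.

No multiple-testing correction is applied by default (per-comparison
significance tiers are reported); a Bonferroni flag exists on the age-trend
scan.  A group whose counts are all zero makes the log rate ratio undefined:
the result is returned flagged rather than silently pseudo-counted, with an
optional 0.5 continuity adjustment behind an explicit flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .bafa import ChangeCall

__all__ = [
    "RegressionResult",
    "poisson_rate_ratio",
    "age_trend_test",
    "change_call",
    "results_to_frame",
]


@dataclass(frozen=True)
class RegressionResult:
    """Two-group Poisson rate-ratio estimate with Wald (or LRT) inference."""

    log_rate_ratio: float
    stderr: float
    rate_ratio: float
    p_value: float
    n_per_group: tuple[int, int]
    undefined: bool = False


def _as_counts(x, name: str) -> np.ndarray:
    arr = np.asarray(x)
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr.astype(float))) or np.any(arr < 0):
        raise ValueError(f"{name} must contain non-negative finite counts")
    if not np.allclose(arr, np.round(arr.astype(float))):
        raise ValueError(f"{name} must contain integers")
    return arr.astype(float)


def poisson_rate_ratio(
    counts_a,
    counts_b,
    test: str = "wald",
    continuity: bool = False,
) -> RegressionResult:
    """Poisson GLM rate ratio of group b relative to group a.

    Parameters
    ----------
    counts_a, counts_b
        Non-negative integer counts (reference group first).
    test
        ``"wald"`` (default) or ``"lrt"`` for a likelihood-ratio test on the
        group coefficient.
    continuity
        When True, an all-zero group is rescued by adding 0.5 to each group
        total; when False (default) such input yields a flagged-undefined
        result, never an exception.
    """
    a = _as_counts(counts_a, "counts_a")
    b = _as_counts(counts_b, "counts_b")
    n = (int(a.size), int(b.size))
    sa, sb = float(a.sum()), float(b.sum())

    if (sa == 0 or sb == 0) and not continuity:
        log_rr = math.inf if sa == 0 and sb > 0 else (-math.inf if sb == 0 and sa > 0 else math.nan)
        return RegressionResult(
            log_rate_ratio=log_rr,
            stderr=math.nan,
            rate_ratio=math.exp(log_rr) if math.isfinite(log_rr) else (math.inf if log_rr > 0 else (0.0 if log_rr < 0 else math.nan)),
            p_value=math.nan,
            n_per_group=n,
            undefined=True,
        )
    if sa == 0 or sb == 0:
        # continuity-adjusted closed form (half an event added to each total)
        sa_c, sb_c = sa + 0.5, sb + 0.5
        log_rr = math.log(sb_c / n[1]) - math.log(sa_c / n[0])
        se = math.sqrt(1 / sa_c + 1 / sb_c)
        z = log_rr / se
        p = 2 * sps.norm.sf(abs(z))
        return RegressionResult(log_rr, se, math.exp(log_rr), float(p), n)

    y = np.concatenate([a, b])
    x = sm.add_constant(np.r_[np.zeros(n[0]), np.ones(n[1])])
    fit = sm.GLM(y, x, family=sm.families.Poisson()).fit()
    log_rr = float(fit.params[1])
    se = float(fit.bse[1])
    if test == "wald":
        p = float(fit.pvalues[1])
    elif test == "lrt":
        null = sm.GLM(y, np.ones((y.size, 1)), family=sm.families.Poisson()).fit()
        lr = 2 * (fit.llf - null.llf)
        p = float(sps.chi2.sf(max(lr, 0.0), df=1))
    else:
        raise ValueError(f"unknown test {test!r}; use 'wald' or 'lrt'")
    return RegressionResult(log_rr, se, math.exp(log_rr), p, n)


def age_trend_test(
    records: pd.DataFrame,
    reference_day: int = 1,
    test: str = "wald",
    bonferroni: bool = False,
) -> dict[int, RegressionResult]:
    """Day-vs-reference Poisson contrasts for one genotype/tissue/vesicle slice.

    Each non-reference day is compared against the reference day (adult Day 1
    by default).  For a Poisson GLM with a categorical day effect, the
    per-contrast estimate and Wald standard error coincide with those of the
    two-group model, so contrasts are computed pairwise.  With ``bonferroni``
    set, p-values are multiplied by the number of contrasts (capped at 1).
    """
    if "day" not in records.columns or "count" not in records.columns:
        raise ValueError("records must have 'day' and 'count' columns")
    days = sorted(records["day"].unique())
    if len(days) < 2:
        raise ValueError(f"need >= 2 distinct days, got {days}")
    if reference_day not in days:
        raise ValueError(
            f"reference day {reference_day} absent from data (days present: {days})"
        )
    ref = records.loc[records["day"] == reference_day, "count"].to_numpy()
    out: dict[int, RegressionResult] = {}
    m = len(days) - 1
    for day in days:
        if day == reference_day:
            continue
        res = poisson_rate_ratio(
            ref, records.loc[records["day"] == day, "count"].to_numpy(), test=test
        )
        if bonferroni and not res.undefined and math.isfinite(res.p_value):
            res = RegressionResult(
                res.log_rate_ratio,
                res.stderr,
                res.rate_ratio,
                min(1.0, res.p_value * m),
                res.n_per_group,
                res.undefined,
            )
        out[int(day)] = res
    return out


def change_call(result: RegressionResult, alpha: float = 0.01) -> ChangeCall:
    """Direction call from a rate-ratio test at significance level ``alpha``.

    ``none`` when the test is undefined or non-significant; otherwise the
    sign of the log rate ratio.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if result.undefined or not math.isfinite(result.p_value) or result.p_value >= alpha:
        direction = "none"
    elif result.log_rate_ratio > 0:
        direction = "increase"
    else:
        direction = "decrease"
    return ChangeCall(
        direction=direction, p_value=result.p_value, rate_ratio=result.rate_ratio
    )


def results_to_frame(results: dict[int, RegressionResult]) -> pd.DataFrame:
    """Tidy one-row-per-contrast frame from an age-trend result map."""
    rows = [
        {
            "day": day,
            "log_rate_ratio": r.log_rate_ratio,
            "stderr": r.stderr,
            "rate_ratio": r.rate_ratio,
            "p_value": r.p_value,
            "n_ref": r.n_per_group[0],
            "n_day": r.n_per_group[1],
            "undefined": r.undefined,
        }
        for day, r in sorted(results.items())
    ]
    return pd.DataFrame(rows)
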