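"""Cohort-level statistics.

The group test runs on per-subject *medians* of the per-bolus values
(robust to occasional outlying boli), compared across conditions with
a paired t test.  Display tables use per-subject means ± SEM; both
statistics are computed and labelled.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .types import BaroreflexError, BolusResponse, GroupResult, METRIC_BRS, METRIC_DSBP


def metric_values(responses: list[BolusResponse], metric: str) -> np.ndarray:
    """Valid per-bolus values of a metric.

    BRS uses only accepted regressions (r above threshold); ΔSBP uses
    every bolus with a valid baseline/peak pair even when the slope was
    rejected, so the two metrics may count different boli.
    """
    if metric == METRIC_BRS:
        vals = [r.brs_slope for r in responses if r.has_brs()]
    elif metric == METRIC_DSBP:
        vals = [r.delta_sbp for r in responses if r.has_pressor()]
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return np.asarray(vals, dtype=float)


def condition_statistic(
    responses: list[BolusResponse],
    metric: str,
    statistic: str = "median",
    *,
    subject_id: str = "?",
    condition: str = "?",
) -> tuple[float, float, int]:
    """Per-subject summary of one condition: ``(value, sem, n)``.

    ``statistic='median'`` is what feeds the paired group test;
    ``'mean'`` is the display statistic.  The SEM is sd/√n of the
    per-bolus values in either case (0 for a single value).
    """
    vals = metric_values(responses, metric)
    if vals.size == 0:
        raise BaroreflexError(
            f"subject {subject_id}, {condition}: no accepted boli for "
            f"metric {metric!r}"
        )
    if statistic == "median":
        value = float(np.median(vals))
    elif statistic == "mean":
        value = float(np.mean(vals))
    else:
        raise ValueError(f"statistic must be 'median' or 'mean', got {statistic!r}")
    sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
    return value, sem, int(vals.size)


def paired_group_test(
    per_subject_norm: np.ndarray,
    per_subject_hyp: np.ndarray,
    *,
    metric: str = "",
    subject_ids: list[str] | None = None,
    statistic: str = "median",
) -> GroupResult:
    """Paired t test of subject-aligned condition statistics.

    Differences are hypoxia − normoxia.  With identical vectors the
    statistic is 0 and p = 1; with a constant shift the SEM of the
    difference is 0 and p degenerates to 0.
    """
    x = np.asarray(per_subject_norm, dtype=float)
    y = np.asarray(per_subject_hyp, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise BaroreflexError(
            f"misaligned per-subject vectors: {x.shape} vs {y.shape}"
        )
    n = x.size
    if n < 2:
        raise BaroreflexError("paired test needs >= 2 subjects")
    if subject_ids is not None and len(subject_ids) != n:
        raise BaroreflexError("subject_ids length does not match data")
    d = y - x
    mean_d = float(np.mean(d))
    sd_d = float(np.std(d, ddof=1))
    sem_d = sd_d / math.sqrt(n)
    if sd_d == 0.0:
        t = 0.0 if mean_d == 0.0 else math.copysign(math.inf, mean_d)
        p = 1.0 if mean_d == 0.0 else 0.0
    else:
        t, p = stats.ttest_rel(y, x)
        t, p = float(t), float(p)
    return GroupResult(
        metric=metric,
        subject_ids=list(subject_ids) if subject_ids is not None else [str(i) for i in range(n)],
        per_subject_normoxia=x,
        per_subject_hypoxia=y,
        group_mean_norm=float(np.mean(x)),
        group_sem_norm=float(np.std(x, ddof=1) / math.sqrt(n)),
        group_mean_hyp=float(np.mean(y)),
        group_sem_hyp=float(np.std(y, ddof=1) / math.sqrt(n)),
        paired_t=t,
        df=n - 1,
        p_value=p,
        mean_paired_difference=mean_d,
        sem_paired_difference=sem_d,
        statistic=statistic,
    )


def correlate_changes(
    delta_brs: np.ndarray, delta_dsbp: np.ndarray
) -> tuple[float, float]:
    """Pearson correlation of per-subject BRS changes against pressor
    changes, with a two-sided p-value.

    Returns ``(nan, nan)`` when either change vector has zero variance.
    """
    x = np.asarray(delta_brs, dtype=float)
    y = np.asarray(delta_dsbp, dtype=float)
    if x.size != y.size:
        raise BaroreflexError("change vectors must be subject-aligned")
    if x.size < 3:
        raise BaroreflexError("correlation needs >= 3 subjects")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
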