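"""N-of-1 inference: does hypoxia change this subject's BRS or
pressor sensitivity?

The repeated boli within each condition serve as replicates; each
subject is tested with an unpaired two-sample t test (Welch by default,
pooled available).  ``welch_t_from_summary`` is a pure function of the
six summary numbers (mean, SEM, n per arm) so that published summary
rows can be re-tested directly.
"""

from __future__ import annotations

import math
from collections import Counter

import numpy as np
from scipy import stats

from .types import (
    CLASS_DECREASED,
    CLASS_INCREASED,
    CLASS_UNCHANGED,
    BaroreflexError,
    IndividualComparison,
    MetricSample,
)


def welch_t_from_summary(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
) -> tuple[float, float, float]:
    """Welch t test reconstructed from summary statistics.

    Returns ``(t, df, p)`` with Welch–Satterthwaite degrees of freedom
    and a two-sided p-value.  Degenerate inputs: if both SEMs are zero
    the statistic is 0 for equal means (p = 1) and signed infinity for
    unequal means (p = 0).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both samples")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be non-negative")
    v1, v2 = sem1 * sem1, sem2 * sem2
    se2 = v1 + v2
    diff = mean1 - mean2
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(n1 + n2 - 2), 1.0
        return math.copysign(math.inf, diff), float(n1 + n2 - 2), 0.0
    t = diff / math.sqrt(se2)
    df = se2 * se2 / (v1 * v1 / (n1 - 1) + v2 * v2 / (n2 - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return t, df, p


def pooled_t_from_summary(
    mean1: float, sem1: float, n1: int,
    mean2: float, sem2: float, n2: int,
) -> tuple[float, float, float]:
    """Classical equal-variance t test from summary statistics."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 in both samples")
    s1_sq = sem1 * sem1 * n1
    s2_sq = sem2 * sem2 * n2
    df = n1 + n2 - 2
    sp_sq = ((n1 - 1) * s1_sq + (n2 - 1) * s2_sq) / df
    diff = mean1 - mean2
    if sp_sq == 0.0:
        if diff == 0.0:
            return 0.0, float(df), 1.0
        return math.copysign(math.inf, diff), float(df), 0.0
    t = diff / math.sqrt(sp_sq * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


def _classify(p: float, difference: float, alpha: float) -> str:
    if p < alpha and difference < 0:
        return CLASS_DECREASED
    if p < alpha and difference > 0:
        return CLASS_INCREASED
    return CLASS_UNCHANGED


def compare_individual(
    sample_norm: MetricSample,
    sample_hyp: MetricSample,
    alpha: float = 0.05,
    *,
    equal_var: bool = False,
) -> IndividualComparison:
    """Test one subject's hypoxia-vs-normoxia difference for one metric.

    The difference and its 95% CI are on the hypoxia − normoxia scale
    (negative BRS difference = reduced reflex gain in hypoxia).  The
    comparison is classified ``decreased`` / ``increased`` when
    p < alpha, otherwise ``unchanged``.
    """
    if sample_norm.subject_id != sample_hyp.subject_id:
        raise BaroreflexError(
            f"samples from different subjects: {sample_norm.subject_id!r} "
            f"vs {sample_hyp.subject_id!r}"
        )
    if sample_norm.metric != sample_hyp.metric:
        raise BaroreflexError(
            f"samples for different metrics: {sample_norm.metric!r} vs "
            f"{sample_hyp.metric!r}"
        )
    for s in (sample_norm, sample_hyp):
        if s.n < 2:
            raise BaroreflexError(
                f"subject {s.subject_id}, metric {s.metric}, {s.condition}: "
                f"need >= 2 accepted boli, have {s.n}"
            )
    summary = pooled_t_from_summary if equal_var else welch_t_from_summary
    # sign convention: hypoxia first so t matches the difference's sign
    t, df, p = summary(
        sample_hyp.mean, sample_hyp.sem, sample_hyp.n,
        sample_norm.mean, sample_norm.sem, sample_norm.n,
    )
    diff = sample_hyp.mean - sample_norm.mean
    se = math.sqrt(sample_hyp.sem ** 2 + sample_norm.sem ** 2)
    if se > 0 and math.isfinite(t):
        half = float(stats.t.ppf(0.975, df)) * se
    else:
        half = 0.0
    return IndividualComparison(
        subject_id=sample_norm.subject_id,
        metric=sample_norm.metric,
        mean_normoxia=sample_norm.mean,
        mean_hypoxia=sample_hyp.mean,
        sem_normoxia=sample_norm.sem,
        sem_hypoxia=sample_hyp.sem,
        n_normoxia=sample_norm.n,
        n_hypoxia=sample_hyp.n,
        difference=diff,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        ci95_low=diff - half,
        ci95_high=diff + half,
        classification=_classify(p, diff, alpha),
    )


def comparison_from_summary(
    subject_id: str,
    metric: str,
    mean_norm: float, sem_norm: float, n_norm: int,
    mean_hyp: float, sem_hyp: float, n_hyp: int,
    alpha: float = 0.05,
    *,
    equal_var: bool = False,
) -> IndividualComparison:
    """Build an :class:`IndividualComparison` from printed summary rows."""
    summary = pooled_t_from_summary if equal_var else welch_t_from_summary
    t, df, p = summary(mean_hyp, sem_hyp, n_hyp, mean_norm, sem_norm, n_norm)
    diff = mean_hyp - mean_norm
    se = math.sqrt(sem_hyp ** 2 + sem_norm ** 2)
    half = float(stats.t.ppf(0.975, df)) * se if se > 0 and math.isfinite(t) else 0.0
    return IndividualComparison(
        subject_id=subject_id,
        metric=metric,
        mean_normoxia=mean_norm,
        mean_hypoxia=mean_hyp,
        sem_normoxia=sem_norm,
        sem_hypoxia=sem_hyp,
        n_normoxia=n_norm,
        n_hypoxia=n_hyp,
        difference=diff,
        t_statistic=t,
        degrees_of_freedom=df,
        p_value=p,
        ci95_low=diff - half,
        ci95_high=diff + half,
        classification=_classify(p, diff, alpha),
    )


def holm_adjust(comparisons: list[IndividualComparison], alpha: float = 0.05
                ) -> list[IndividualComparison]:
    """Optional Holm step-down correction across a family of N-of-1 tests.

    Returns new comparisons whose classification reflects the adjusted
    decisions; p-values themselves are left untouched.
    """
    order = np.argsort([c.p_value for c in comparisons])
    m = len(comparisons)
    rejected = np.zeros(m, dtype=bool)
    for rank, idx in enumerate(order):
        if comparisons[idx].p_value < alpha / (m - rank):
            rejected[idx] = True
        else:
            break
    out = []
    for c, rej in zip(comparisons, rejected):
        cls = _classify(0.0 if rej else 1.0, c.difference, alpha)
        out.append(
            IndividualComparison(**{**c.__dict__, "classification": cls})
        )
    return out


def classify_cohort(
    comparisons: list[IndividualComparison], metric: str
) -> dict[str, int]:
    """Tally decreased / increased / unchanged for one metric."""
    relevant = [c for c in comparisons if c.metric == metric]
    ids = [c.subject_id for c in relevant]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise BaroreflexError(f"duplicate subjects for {metric}: {dupes}")
    counts = Counter(c.classification for c in relevant)
    return {
        CLASS_DECREASED: counts.get(CLASS_DECREASED, 0),
        CLASS_INCREASED: counts.get(CLASS_INCREASED, 0),
        CLASS_UNCHANGED: counts.get(CLASS_UNCHANGED, 0),
    }
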