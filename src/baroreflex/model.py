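"""Model/Results interface for a repeated-bolus baroreflex study.

:class:`BaroreflexStudy` is built from per-subject recordings (beat
series + bolus events for both conditions), either loaded from files or
simulated.  ``fit()`` extracts every bolus, runs the N-of-1 layer per
subject, the paired group layer across subjects, and the BRS-change
versus pressor-change correlation, returning a
:class:`StudyResults` with tables, a ``summary()`` text report and
forest/correlation plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .extract import DEFAULT_SETTINGS, ExtractionSettings, extract_condition
from .group import condition_statistic, correlate_changes, metric_values, paired_group_test
from .io import comparisons_to_frame, group_to_frame, responses_to_frame
from .nof1 import classify_cohort, compare_individual, holm_adjust
from .types import (
    HYPOXIA,
    METRIC_BRS,
    METRIC_DSBP,
    METRICS,
    NORMOXIA,
    BaroreflexError,
    BeatSeries,
    BolusEvent,
    GroupResult,
    IndividualComparison,
    MetricSample,
)

_METRIC_LABEL = {METRIC_BRS: "BRS (ms/mmHg)", METRIC_DSBP: "dSBP (mmHg)"}


@dataclass
class SubjectData:
    """Input data of one subject: both conditions."""

    subject_id: str
    beats: dict[str, BeatSeries]
    events: dict[str, list[BolusEvent]]

    def __post_init__(self) -> None:
        if set(self.beats) != {NORMOXIA, HYPOXIA} or set(self.events) != {
            NORMOXIA,
            HYPOXIA,
        }:
            raise BaroreflexError(
                f"subject {self.subject_id}: need beats and events for both "
                f"conditions ({NORMOXIA}, {HYPOXIA})"
            )


class BaroreflexStudy:
    """N-of-1 baroreflex–chemoreflex interaction study.

    Parameters
    ----------
    subjects
        One :class:`SubjectData` per subject.
    settings
        Per-bolus extraction settings (windows, acceptance rule).
    alpha
        Per-subject significance level.
    equal_var
        Use the pooled instead of the Welch t test.
    holm
        Apply a Holm correction across subjects (per metric) before
        classifying; off by default.
    """

    def __init__(
        self,
        subjects: list[SubjectData],
        settings: ExtractionSettings = DEFAULT_SETTINGS,
        alpha: float = 0.05,
        *,
        equal_var: bool = False,
        holm: bool = False,
    ) -> None:
        ids = [s.subject_id for s in subjects]
        if len(set(ids)) != len(ids):
            raise BaroreflexError("duplicate subject ids")
        self.subjects = subjects
        self.settings = settings
        self.alpha = alpha
        self.equal_var = equal_var
        self.holm = holm

    # ------------------------------------------------------------------
    @classmethod
    def simulate(
        cls,
        cohort=None,
        seed: int = 0,
        settings: ExtractionSettings = DEFAULT_SETTINGS,
        alpha: float = 0.05,
        **kwargs,
    ) -> "BaroreflexStudy":
        """Build a study from the synthetic cohort (default: the bundled
        nine-subject cohort)."""
        from .simulate import default_cohort, simulate_cohort

        cohort = cohort if cohort is not None else default_cohort()
        recs = simulate_cohort(cohort, seed)
        subjects = [
            SubjectData(subject_id=r.subject_id, beats=r.beats, events=r.events)
            for r in recs
        ]
        study = cls(subjects, settings=settings, alpha=alpha, **kwargs)
        study.recordings = recs  # keeps truth for parameter-recovery checks
        return study

    @classmethod
    def from_responses(cls, *args, **kwargs):  # pragma: no cover - guidance
        raise NotImplementedError(
            "build results from a response table with "
            "StudyResults.from_response_frame instead"
        )

    # ------------------------------------------------------------------
    def fit(self) -> "StudyResults":
        """Extract all boli and run individual + group inference."""
        frames = []
        for subj in self.subjects:
            for cond in (NORMOXIA, HYPOXIA):
                responses = extract_condition(
                    subj.beats[cond], subj.events[cond], self.settings
                )
                frames.append(
                    (subj.subject_id, cond, responses)
                )
        return StudyResults._from_extraction(
            frames, alpha=self.alpha, equal_var=self.equal_var, holm=self.holm,
            model=self,
        )


@dataclass
class StudyResults:
    """Fitted study: per-bolus responses, N-of-1 and group inference."""

    responses: pd.DataFrame
    comparisons: list[IndividualComparison]
    group_results: dict[str, GroupResult]
    classification_counts: dict[str, dict[str, int]]
    change_correlation: tuple[float, float]
    subject_tables: pd.DataFrame
    alpha: float = 0.05
    model: BaroreflexStudy | None = field(default=None, repr=False)

    # -- construction ---------------------------------------------------
    @classmethod
    def _from_extraction(cls, frames, *, alpha, equal_var, holm, model=None):
        resp_frames = []
        samples: dict[tuple[str, str, str], MetricSample] = {}
        per_subject_rows = []
        subject_ids: list[str] = []
        for subject_id, cond, responses in frames:
            resp_frames.append(responses_to_frame(responses, subject_id, cond))
            if subject_id not in subject_ids:
                subject_ids.append(subject_id)
            for metric in METRICS:
                vals = metric_values(responses, metric)
                samples[(subject_id, cond, metric)] = MetricSample(
                    subject_id=subject_id, condition=cond, metric=metric, values=vals
                )
                med, sem, n = (
                    condition_statistic(
                        responses, metric, "median",
                        subject_id=subject_id, condition=cond,
                    )
                    if vals.size
                    else (np.nan, np.nan, 0)
                )
                mean = float(np.mean(vals)) if vals.size else np.nan
                per_subject_rows.append(
                    {
                        "subject": subject_id,
                        "condition": cond,
                        "metric": metric,
                        "mean": mean,
                        "sem": sem,
                        "median": med,
                        "n": n,
                    }
                )

        comparisons: list[IndividualComparison] = []
        for metric in METRICS:
            metric_comps = [
                compare_individual(
                    samples[(sid, NORMOXIA, metric)],
                    samples[(sid, HYPOXIA, metric)],
                    alpha=alpha,
                    equal_var=equal_var,
                )
                for sid in subject_ids
            ]
            if holm:
                metric_comps = holm_adjust(metric_comps, alpha)
            comparisons.extend(metric_comps)

        group_results: dict[str, GroupResult] = {}
        if len(subject_ids) >= 2:  # the paired layer needs a cohort
            for metric in METRICS:
                med_norm = [
                    samples[(sid, NORMOXIA, metric)].median for sid in subject_ids
                ]
                med_hyp = [
                    samples[(sid, HYPOXIA, metric)].median for sid in subject_ids
                ]
                group_results[metric] = paired_group_test(
                    np.asarray(med_norm),
                    np.asarray(med_hyp),
                    metric=metric,
                    subject_ids=subject_ids,
                    statistic="median",
                )

        counts = {m: classify_cohort(comparisons, m) for m in METRICS}

        by_subject = {c.subject_id: c for c in comparisons if c.metric == METRIC_BRS}
        d_brs = np.array([by_subject[sid].difference for sid in subject_ids])
        by_subject_d = {
            c.subject_id: c for c in comparisons if c.metric == METRIC_DSBP
        }
        d_dsbp = np.array([by_subject_d[sid].difference for sid in subject_ids])
        corr = correlate_changes(d_brs, d_dsbp) if len(subject_ids) >= 3 else (np.nan, np.nan)

        return cls(
            responses=pd.concat(resp_frames, ignore_index=True),
            comparisons=comparisons,
            group_results=group_results,
            classification_counts=counts,
            change_correlation=corr,
            subject_tables=pd.DataFrame(per_subject_rows),
            alpha=alpha,
            model=model,
        )

    # -- views ----------------------------------------------------------
    @property
    def comparison_frame(self) -> pd.DataFrame:
        return comparisons_to_frame(self.comparisons)

    @property
    def group_frame(self) -> pd.DataFrame:
        return group_to_frame(self.group_results.values())

    def comparisons_for(self, metric: str) -> list[IndividualComparison]:
        return [c for c in self.comparisons if c.metric == metric]

    def summary(self) -> str:
        """Plain-text report in the style of a fitted-model summary."""
        lines = []
        lines.append("Baroreflex-chemoreflex N-of-1 study")
        lines.append("=" * 74)
        n_subj = self.subject_tables["subject"].nunique()
        lines.append(
            f"Subjects: {n_subj}    alpha: {self.alpha}    "
            f"boli analyzed: {len(self.responses)}"
        )
        for metric in METRICS:
            lines.append("")
            lines.append(f"[{_METRIC_LABEL[metric]}] individual comparisons "
                         "(difference = hypoxia - normoxia)")
            lines.append("-" * 74)
            lines.append(
                f"{'subject':>8} {'normoxia':>14} {'hypoxia':>14} "
                f"{'diff':>7} {'t':>7} {'p':>8}  class"
            )
            for c in self.comparisons_for(metric):
                lines.append(
                    f"{c.subject_id:>8} "
                    f"{c.mean_normoxia:7.2f} ± {c.sem_normoxia:4.2f} "
                    f"{c.mean_hypoxia:7.2f} ± {c.sem_hypoxia:4.2f} "
                    f"{c.difference:7.2f} {c.t_statistic:7.3f} "
                    f"{c.p_value:8.4f}  {c.classification}"
                )
            g = self.group_results.get(metric)
            counts = self.classification_counts[metric]
            if g is not None:
                lines.append(
                    f"group ({g.statistic}s of boli): "
                    f"{g.group_mean_norm:.2f} ± {g.group_sem_norm:.2f} vs "
                    f"{g.group_mean_hyp:.2f} ± {g.group_sem_hyp:.2f}, "
                    f"paired t={g.paired_t:.3f}, df={g.df}, p={g.p_value:.4f}"
                )
            lines.append(
                f"classified: {counts['decreased']} decreased, "
                f"{counts['increased']} increased, "
                f"{counts['unchanged']} unchanged"
            )
        r, p = self.change_correlation
        lines.append("")
        lines.append(
            f"BRS change vs pressor change: r={r:.3f}, p={p:.3f}"
            if np.isfinite(r)
            else "BRS change vs pressor change: undefined"
        )
        return "\n".join(lines)

    # -- plots ----------------------------------------------------------
    def plot_forest(self, metric: str, ax=None):
        """Forest plot of per-subject differences (hypoxia − normoxia)
        with 95% CIs."""
        import matplotlib.pyplot as plt

        comps = self.comparisons_for(metric)
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 0.5 * len(comps) + 1.5))
        ys = np.arange(len(comps))[::-1]
        for y, c in zip(ys, comps):
            color = "tab:red" if c.significant else "tab:gray"
            ax.errorbar(
                c.difference, y,
                xerr=[[c.difference - c.ci95_low], [c.ci95_high - c.difference]],
                fmt="o", color=color, capsize=3,
            )
            ax.annotate(f"p={c.p_value:.3f}", (c.ci95_high, y),
                        textcoords="offset points", xytext=(6, -3), fontsize=8)
        ax.axvline(0.0, color="k", lw=0.8)
        ax.set_yticks(ys)
        ax.set_yticklabels([c.subject_id for c in comps])
        ax.set_xlabel(f"hypoxia - normoxia difference, {_METRIC_LABEL[metric]}")
        ax.set_title(f"Individual changes in {_METRIC_LABEL[metric]}")
        return ax

    def plot_change_correlation(self, ax=None):
        """Per-subject BRS change against pressor change."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        brs = {c.subject_id: c.difference for c in self.comparisons_for(METRIC_BRS)}
        dsbp = {c.subject_id: c.difference for c in self.comparisons_for(METRIC_DSBP)}
        sids = sorted(brs)
        x = [brs[s] for s in sids]
        y = [dsbp[s] for s in sids]
        ax.scatter(x, y)
        for s in sids:
            ax.annotate(s, (brs[s], dsbp[s]), fontsize=8,
                        textcoords="offset points", xytext=(4, 2))
        r, p = self.change_correlation
        ax.set_xlabel("BRS change (ms/mmHg)")
        ax.set_ylabel("pressor change (mmHg)")
        ax.set_title(f"r={r:.3f}, p={p:.3f}")
        return ax

    def plot_group(self, metric: str, ax=None):
        """Per-subject condition lines (normoxia → hypoxia)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        g = self.group_results[metric]
        for sid, a, b in zip(
            g.subject_ids, g.per_subject_normoxia, g.per_subject_hypoxia
        ):
            ax.plot([0, 1], [a, b], "-o", color="tab:blue", alpha=0.6)
        ax.set_xticks([0, 1])
        ax.set_xticklabels([NORMOXIA, HYPOXIA])
        ax.set_ylabel(_METRIC_LABEL[metric])
        ax.set_title(f"p={g.p_value:.4f} (paired, {g.statistic}s)")
        return ax
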