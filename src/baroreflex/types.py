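"""Core containers for beat-to-beat baroreflex analysis.

A recording is represented as a :class:`BeatSeries` (one subject, one
condition) plus a list of :class:`BolusEvent`.  Extraction turns each
bolus into a :class:`BolusResponse`; the inference layers consume
:class:`MetricSample`, :class:`IndividualComparison` and
:class:`GroupResult`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

# Physiological plausibility bounds enforced on every BeatSeries.
RRI_MIN_MS = 300.0
RRI_MAX_MS = 2000.0
SBP_MIN_MMHG = 50.0
SBP_MAX_MMHG = 300.0
MIN_BEATS = 12

NORMOXIA = "normoxia"
HYPOXIA = "hypoxia"
CONDITIONS = (NORMOXIA, HYPOXIA)

METRIC_BRS = "brs"
METRIC_DSBP = "delta_sbp"
METRICS = (METRIC_BRS, METRIC_DSBP)


class BaroreflexError(Exception):
    """Base class for errors raised by this package."""


class BeatSeriesError(BaroreflexError):
    """A beat series violates a structural or physiological invariant."""


class BolusWindowError(BaroreflexError):
    """A bolus lacks the beats required for its analysis window."""


class ScheduleError(BaroreflexError):
    """A bolus schedule is inconsistent with the recording duration."""


@dataclass
class BeatSeries:
    """Beat-indexed record of one subject under one condition.

    Parameters
    ----------
    time_s
        Time of each beat in seconds, strictly increasing.
    rri_ms
        RR interval *ending* at each beat, in milliseconds.
    sbp_mmhg
        Systolic blood pressure of each beat, in mmHg.
    """

    subject_id: str
    condition: str
    time_s: np.ndarray
    rri_ms: np.ndarray
    sbp_mmhg: np.ndarray

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.rri_ms = np.asarray(self.rri_ms, dtype=float)
        self.sbp_mmhg = np.asarray(self.sbp_mmhg, dtype=float)

    def __len__(self) -> int:
        return self.time_s.size

    @property
    def n_beats(self) -> int:
        return self.time_s.size

    def validate(self) -> None:
        """Raise :class:`BeatSeriesError` listing every offending beat."""
        n = self.n_beats
        if not (self.rri_ms.size == n and self.sbp_mmhg.size == n):
            raise BeatSeriesError(
                f"{self.subject_id}/{self.condition}: column lengths differ "
                f"(time {n}, rri {self.rri_ms.size}, sbp {self.sbp_mmhg.size})"
            )
        if n < MIN_BEATS:
            raise BeatSeriesError(
                f"{self.subject_id}/{self.condition}: only {n} beats, "
                f"need at least {MIN_BEATS}"
            )
        problems: list[str] = []
        bad_t = np.flatnonzero(np.diff(self.time_s) <= 0)
        if bad_t.size:
            problems.append(f"non-increasing time at beats {_fmt(bad_t + 1)}")
        bad_r = np.flatnonzero(
            (self.rri_ms < RRI_MIN_MS) | (self.rri_ms > RRI_MAX_MS)
        )
        if bad_r.size:
            problems.append(
                f"RRI outside [{RRI_MIN_MS:.0f}, {RRI_MAX_MS:.0f}] ms "
                f"at beats {_fmt(bad_r)}"
            )
        bad_s = np.flatnonzero(
            (self.sbp_mmhg < SBP_MIN_MMHG) | (self.sbp_mmhg > SBP_MAX_MMHG)
        )
        if bad_s.size:
            problems.append(
                f"SBP outside [{SBP_MIN_MMHG:.0f}, {SBP_MAX_MMHG:.0f}] mmHg "
                f"at beats {_fmt(bad_s)}"
            )
        if problems:
            raise BeatSeriesError(
                f"{self.subject_id}/{self.condition}: " + "; ".join(problems)
            )


def _fmt(idx: np.ndarray, limit: int = 8) -> str:
    vals = ", ".join(str(int(i)) for i in idx[:limit])
    return vals + (", ..." if idx.size > limit else "")


@dataclass(frozen=True)
class BolusEvent:
    """One phenylephrine administration (injection start time)."""

    bolus_index: int
    time_s: float
    dose_ug: float = float("nan")
    condition: str | None = None


@dataclass
class BolusResponse:
    """Per-bolus features: pressor response and cardiovagal BRS.

    ``accepted`` refers to the BRS slope only (Pearson r > threshold,
    strict).  A rejected bolus is carried, not dropped, so the number of
    analyzable boli can differ between the BRS and the pressor metric.
    """

    bolus_index: int
    sbp_baseline: float
    sbp_peak: float | None = None
    delta_sbp: float | None = None
    peak_time_s: float | None = None
    brs_slope: float | None = None
    brs_intercept: float | None = None
    pearson_r: float | None = None
    n_beats_regression: int = 0
    accepted: bool = False
    reject_reason: str | None = None

    def has_pressor(self) -> bool:
        return self.delta_sbp is not None and math.isfinite(self.delta_sbp)

    def has_brs(self) -> bool:
        return self.brs_slope is not None and self.accepted


@dataclass
class MetricSample:
    """Accepted per-bolus values of one metric for one subject-condition."""

    subject_id: str
    condition: str
    metric: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        if self.n < 2:
            return 0.0
        return float(np.std(self.values, ddof=1) / math.sqrt(self.n))

    @property
    def median(self) -> float:
        return float(np.median(self.values))


CLASS_DECREASED = "decreased"
CLASS_INCREASED = "increased"
CLASS_UNCHANGED = "unchanged"


@dataclass
class IndividualComparison:
    """N-of-1 result for one subject and one metric.

    ``difference`` is hypoxia − normoxia, so a negative BRS difference
    means the reflex gain fell under hypoxic chemoreflex stimulation.
    """

    subject_id: str
    metric: str
    mean_normoxia: float
    mean_hypoxia: float
    sem_normoxia: float
    sem_hypoxia: float
    n_normoxia: int
    n_hypoxia: int
    difference: float
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    ci95_low: float
    ci95_high: float
    classification: str

    @property
    def significant(self) -> bool:
        return self.classification != CLASS_UNCHANGED


@dataclass
class GroupResult:
    """Cohort-level summary of one metric across paired conditions."""

    metric: str
    subject_ids: Sequence[str]
    per_subject_normoxia: np.ndarray
    per_subject_hypoxia: np.ndarray
    group_mean_norm: float
    group_sem_norm: float
    group_mean_hyp: float
    group_sem_hyp: float
    paired_t: float
    df: int
    p_value: float
    mean_paired_difference: float
    sem_paired_difference: float
    statistic: str = "median"

    def __post_init__(self) -> None:
        self.per_subject_normoxia = np.asarray(self.per_subject_normoxia, float)
        self.per_subject_hypoxia = np.asarray(self.per_subject_hypoxia, float)


@dataclass
class RespiratorySummary:
    """Per-subject ventilation summary and chemoreflex response.

    ``chemoreflex_response`` is on the study's printed scale:
    100 × ΔVe / ΔSpO2 (see :mod:`baroreflex.respiratory`).
    """

    subject_id: str
    rr_normoxia: float
    rr_hypoxia: float
    vt_normoxia: float
    vt_hypoxia: float
    ve_normoxia: float
    ve_hypoxia: float
    delta_spo2: float
    chemoreflex_response: float = field(default=float("nan"))
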