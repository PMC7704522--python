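"""Per-bolus feature extraction: pressor response (ΔSBP) and
cardiovagal baroreflex sensitivity (BRS).

The estimators follow the pharmacological (Oxford-style) convention:

* baseline SBP = mean of the ten beats immediately before the bolus;
* peak SBP = maximal mean of three *consecutive* beats within 60 s of
  the injection (ties go to the earliest window);
* ΔSBP = peak − baseline;
* BRS = OLS slope of RRI(i+lag) on SBP(i) over the pressure-rise beats,
  accepted only when Pearson r exceeds 0.5 (strict inequality).

The rise phase is defined objectively: from the first post-bolus beat
whose SBP exceeds baseline + 2×SD(pre-bolus SBP) up to and including
the central beat of the peak window.  Boli that fail the slope
preconditions are carried with ``accepted=False`` and a recorded
reason, never silently dropped, so the number of analyzable boli can
differ between the BRS and the ΔSBP metric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .types import BeatSeries, BolusEvent, BolusResponse, BolusWindowError


@dataclass(frozen=True)
class ExtractionSettings:
    """Window and acceptance settings for per-bolus extraction."""

    baseline_beats: int = 10
    peak_window_s: float = 60.0
    peak_run_length: int = 3
    r_threshold: float = 0.5
    min_pairs: int = 5
    lag: int = 1
    onset_sd_multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.baseline_beats < 2:
            raise ValueError("baseline_beats must be >= 2")
        if self.peak_window_s <= 0:
            raise ValueError("peak_window_s must be positive")
        if self.peak_run_length < 1:
            raise ValueError("peak_run_length must be >= 1")
        if self.min_pairs < 2:
            raise ValueError("min_pairs must be >= 2")
        if self.lag not in (0, 1, 2):
            raise ValueError("lag must be 0, 1 or 2")


DEFAULT_SETTINGS = ExtractionSettings()


def _pre_bolus_indices(
    beats: BeatSeries, bolus: BolusEvent, n: int
) -> np.ndarray:
    stop = int(np.searchsorted(beats.time_s, bolus.time_s, side="left"))
    if stop < n:
        raise BolusWindowError(
            f"bolus {bolus.bolus_index} at t={bolus.time_s:.1f} s has only "
            f"{stop} preceding beats, need {n}"
        )
    return np.arange(stop - n, stop)


def _post_bolus_indices(
    beats: BeatSeries, bolus: BolusEvent, window_s: float
) -> np.ndarray:
    lo = int(np.searchsorted(beats.time_s, bolus.time_s, side="right"))
    hi = int(np.searchsorted(beats.time_s, bolus.time_s + window_s, side="right"))
    return np.arange(lo, hi)


def baseline_sbp(
    beats: BeatSeries,
    bolus: BolusEvent,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> float:
    """Mean SBP of the ``baseline_beats`` beats immediately pre-bolus."""
    idx = _pre_bolus_indices(beats, bolus, settings.baseline_beats)
    return float(np.mean(beats.sbp_mmhg[idx]))


def peak_sbp(
    beats: BeatSeries,
    bolus: BolusEvent,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> tuple[float, float]:
    """Maximal mean of ``peak_run_length`` consecutive SBP values within
    the post-bolus window.

    Returns ``(peak_mmhg, time_of_central_beat_s)``.  Ties are broken
    by the earliest window.
    """
    idx = _post_bolus_indices(beats, bolus, settings.peak_window_s)
    run = settings.peak_run_length
    if idx.size < run:
        raise BolusWindowError(
            f"bolus {bolus.bolus_index}: only {idx.size} beats within "
            f"{settings.peak_window_s:.0f} s, need {run}"
        )
    sbp = beats.sbp_mmhg[idx]
    window_means = np.convolve(sbp, np.ones(run) / run, mode="valid")
    best = int(np.argmax(window_means))  # argmax returns the first maximum
    center = idx[best + run // 2]
    return float(window_means[best]), float(beats.time_s[center])


def estimate_brs(
    beats: BeatSeries,
    bolus: BolusEvent,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> tuple[float, float, float, int] | None:
    """OLS slope of the following RR interval on SBP over the rise phase.

    Returns ``(slope_ms_per_mmhg, intercept_ms, pearson_r, n_pairs)``,
    or ``None`` when the bolus yields no usable regression (< min_pairs
    rise beats after lagging, or zero SBP variance).
    """
    base = baseline_sbp(beats, bolus, settings)
    pre_idx = _pre_bolus_indices(beats, bolus, settings.baseline_beats)
    pre_sd = float(np.std(beats.sbp_mmhg[pre_idx], ddof=1))
    _, peak_time = peak_sbp(beats, bolus, settings)

    post_idx = _post_bolus_indices(beats, bolus, settings.peak_window_s)
    threshold = base + settings.onset_sd_multiplier * pre_sd
    above = beats.sbp_mmhg[post_idx] > threshold
    if not above.any():
        return None
    onset = post_idx[int(np.argmax(above))]
    center = int(np.searchsorted(beats.time_s, peak_time, side="left"))
    if center < onset:
        return None
    rise = np.arange(onset, center + 1)
    rise = rise[rise + settings.lag < beats.n_beats]
    if rise.size < settings.min_pairs:
        return None
    x = beats.sbp_mmhg[rise]
    y = beats.rri_ms[rise + settings.lag]
    if np.ptp(x) == 0.0:
        return None
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue), int(rise.size)


def extract_bolus_response(
    beats: BeatSeries,
    bolus: BolusEvent,
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> BolusResponse:
    """Assemble ΔSBP and BRS for one bolus.

    ``accepted`` is True iff the regression exists and r > r_threshold
    (strict).  Raises :class:`BolusWindowError` when even the ΔSBP
    preconditions (10 pre-bolus beats, 3 post-bolus beats) fail.
    """
    base = baseline_sbp(beats, bolus, settings)
    peak, peak_time = peak_sbp(beats, bolus, settings)
    resp = BolusResponse(
        bolus_index=bolus.bolus_index,
        sbp_baseline=base,
        sbp_peak=peak,
        delta_sbp=peak - base,
        peak_time_s=peak_time,
    )
    fit = estimate_brs(beats, bolus, settings)
    if fit is None:
        resp.reject_reason = "no usable rise-phase regression"
        return resp
    slope, intercept, r, n = fit
    resp.brs_slope = slope
    resp.brs_intercept = intercept
    resp.pearson_r = r
    resp.n_beats_regression = n
    if r > settings.r_threshold:
        resp.accepted = True
    else:
        resp.reject_reason = f"r={r:.3f} <= {settings.r_threshold}"
    return resp


def extract_condition(
    beats: BeatSeries,
    events: list[BolusEvent],
    settings: ExtractionSettings = DEFAULT_SETTINGS,
) -> list[BolusResponse]:
    """Extract every bolus of one condition.

    Raises :class:`BolusWindowError` when the analysis windows of
    consecutive boli overlap: the earliest of the baseline beats of
    bolus k+1 must fall after the 60 s peak window of bolus k.
    """
    events = sorted(events, key=lambda e: e.time_s)
    for prev, nxt in zip(events, events[1:]):
        first_baseline_idx = _pre_bolus_indices(beats, nxt, settings.baseline_beats)[0]
        if beats.time_s[first_baseline_idx] <= prev.time_s + settings.peak_window_s:
            raise BolusWindowError(
                f"baseline window of bolus {nxt.bolus_index} overlaps the "
                f"{settings.peak_window_s:.0f} s peak window of bolus "
                f"{prev.bolus_index}"
            )
    return [extract_bolus_response(beats, ev, settings) for ev in events]
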