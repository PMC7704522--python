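"""Per-bolus estimators against hand-computed and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import baroreflex as bx
from baroreflex.extract import ExtractionSettings
from baroreflex.types import BeatSeries, BolusEvent, BolusWindowError


def series(sbp, rri=None, dt=1.0):
    sbp = np.asarray(sbp, dtype=float)
    n = sbp.size
    rri = np.full(n, 1000.0) if rri is None else np.asarray(rri, dtype=float)
    return BeatSeries("t", "normoxia", np.arange(n) * dt, rri, sbp)


def bolus(t):
    return BolusEvent(bolus_index=0, time_s=t)


class TestBaselineSbp:
    def test_constant_pressure(self):
        s = series([120.0] * 15)
        assert bx.baseline_sbp(s, bolus(14.5)) == 120.0

    def test_mean_of_last_ten_readings(self):
        # 4 ignored beats then SBP 121..130 immediately pre-bolus
        s = series([99, 99, 99, 99] + list(range(121, 131)) + [140, 150])
        assert bx.baseline_sbp(s, bolus(13.5)) == pytest.approx(125.5)

    def test_too_few_pre_bolus_beats_errors(self):
        s = series([120.0] * 15)
        with pytest.raises(BolusWindowError, match="bolus 0"):
            bx.baseline_sbp(s, bolus(5.5))


class TestPeakSbp:
    def test_max_three_beat_window(self):
        sbp = [120.0] * 10 + [130, 131, 135, 140, 139, 132] + [120.0] * 3
        s = series(sbp)
        peak, t_peak = bx.peak_sbp(s, bolus(9.5))
        assert peak == pytest.approx((135 + 140 + 139) / 3)
        assert t_peak == 13.0  # the beat carrying 140

    def test_plateau(self):
        sbp = [120.0] * 10 + [130, 150, 150, 150, 140]
        s = series(sbp)
        peak, _ = bx.peak_sbp(s, bolus(9.5))
        assert peak == pytest.approx(150.0)

    def test_tie_broken_by_earliest_window(self):
        sbp = [120.0] * 10 + [140, 140, 140, 100, 140, 140, 140]
        s = series(sbp)
        _, t_peak = bx.peak_sbp(s, bolus(9.5))
        assert t_peak == 11.0

    def test_window_limited_to_sixty_seconds(self):
        # big values arrive after the 60 s window: they must be ignored
        sbp = [120.0] * 10 + [125.0] * 60 + [200.0] * 10
        s = series(sbp)
        peak, _ = bx.peak_sbp(s, bolus(9.5))
        assert peak == pytest.approx(125.0)

    def test_fewer_than_three_beats_errors(self):
        s = series([120.0] * 12, dt=40.0)
        with pytest.raises(BolusWindowError):
            bx.peak_sbp(s, bolus(9.5 * 40))

    def test_matches_bruteforce_enumeration(self, rng):
        for _ in range(25):
            sbp = 130 + rng.normal(0, 5, size=80)
            s = series(np.concatenate([[125.0] * 10, sbp]))
            peak, _ = bx.peak_sbp(s, bolus(9.5))
            idx = np.arange(10, 10 + 60)  # beats inside (9.5, 69.5]
            brute = max(
                np.mean(s.sbp_mmhg[i : i + 3]) for i in idx[: idx.size - 2]
            )
            assert peak == pytest.approx(brute, abs=1e-12)


def _linear_series(slope, n_rise=20):
    """Baseline then a clean SBP ramp with RRI(i+1) = 800 + slope*(SBP_i-120)."""
    sbp = np.concatenate([np.full(10, 120.0), 120.0 + np.arange(1, n_rise + 1),
                          np.full(5, 120.0)])
    rri = np.full(sbp.size, 800.0)
    rri[1:] = 800.0 + slope * (sbp[:-1] - 120.0)
    return series(sbp, rri)


class TestEstimateBrs:
    def test_exact_linear_coupling(self):
        s = _linear_series(20.0)
        slope, intercept, r, n = bx.estimate_brs(s, bolus(9.5))
        assert slope == pytest.approx(20.0, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-12)
        assert n >= 5

    def test_matches_closed_form_least_squares(self, rng):
        settings = ExtractionSettings(min_pairs=5)
        for _ in range(25):
            n_rise = int(rng.integers(8, 30))
            s = _linear_series(float(rng.uniform(2, 30)), n_rise)
            s.rri_ms = s.rri_ms + rng.normal(0, 30, s.rri_ms.size)
            fit = bx.estimate_brs(s, bolus(9.5), settings)
            assert fit is not None
            slope, intercept, r, n = fit
            # independent closed-form oracle on the same pairs
            peak, t_peak = bx.peak_sbp(s, bolus(9.5), settings)
            center = int(np.searchsorted(s.time_s, t_peak))
            onset = 10  # first post-bolus beat exceeds baseline immediately
            idx = np.arange(onset, center + 1)
            idx = idx[idx + 1 < len(s.time_s)]
            x, y = s.sbp_mmhg[idx], s.rri_ms[idx + 1]
            sxx = np.sum((x - x.mean()) ** 2)
            sxy = np.sum((x - x.mean()) * (y - y.mean()))
            syy = np.sum((y - y.mean()) ** 2)
            assert slope == pytest.approx(sxy / sxx, rel=1e-9)
            assert intercept == pytest.approx(y.mean() - sxy / sxx * x.mean(), rel=1e-9)
            assert r == pytest.approx(sxy / np.sqrt(sxx * syy), rel=1e-9)
            assert n == idx.size

    def test_null_coupling_is_usually_rejected(self, rng):
        """SBP rises, RRI is pure noise: |r| stays <= 0.5 for most boli."""
        rejected = 0
        reps = 120
        for _ in range(reps):
            sbp = np.concatenate([np.full(10, 120.0),
                                  120.0 + np.arange(1, 16.0),
                                  np.full(4, 120.0)])
            rri = 900.0 + rng.normal(0, 40, sbp.size)
            fit = bx.estimate_brs(series(sbp, rri), bolus(9.5))
            assert fit is not None
            rejected += abs(fit[2]) <= 0.5
        assert rejected >= 0.85 * reps

    def test_too_few_rise_pairs_returns_none(self):
        s = _linear_series(20.0, n_rise=3)
        assert bx.estimate_brs(s, bolus(9.5)) is None

    def test_flat_series_with_no_rise_returns_none(self):
        assert bx.estimate_brs(series(np.full(30, 120.0)), bolus(9.5)) is None

    @given(shift=st.floats(-300, 300), scale=st.floats(0.25, 4.0))
    def test_rri_shift_and_sbp_scale_equivariance(self, shift, scale):
        s = _linear_series(12.0, n_rise=15)
        base = bx.estimate_brs(s, bolus(9.5))
        shifted = series(s.sbp_mmhg, s.rri_ms + shift)
        slope, intercept, r, _ = bx.estimate_brs(shifted, bolus(9.5))
        assert slope == pytest.approx(base[0], rel=1e-9)
        assert intercept == pytest.approx(base[1] + shift, rel=1e-7, abs=1e-7)
        assert r == pytest.approx(base[2], rel=1e-9)
        # scaling SBP deviations about the baseline divides the slope
        scaled = series(120.0 + (s.sbp_mmhg - 120.0) * scale, s.rri_ms)
        slope_s, _, r_s, _ = bx.estimate_brs(scaled, bolus(9.5))
        assert slope_s == pytest.approx(base[0] / scale, rel=1e-9)
        assert r_s == pytest.approx(base[2], rel=1e-9)


class TestExtractBolusResponse:
    def test_r_exactly_at_threshold_is_rejected(self):
        """Pairs engineered so Pearson r is exactly 0.5: strict > fails."""
        settings = ExtractionSettings(min_pairs=3, lag=0)
        sbp = np.array([120.0] * 10 + [121, 122, 123, 122.5, 119, 118, 118])
        rri = np.full(sbp.size, 1000.0)
        rri[10:13] = [800.0, 798.0, 802.0]
        resp = bx.extract_bolus_response(series(sbp, rri), bolus(9.5), settings)
        assert resp.pearson_r == 0.5
        assert not resp.accepted
        assert resp.brs_slope is not None  # slope still reported

    def test_delta_is_peak_minus_baseline_and_rejects_carry_values(
        self, noise_free_recording
    ):
        _, _, beats, events = noise_free_recording
        resp = bx.extract_bolus_response(beats, events[0])
        assert resp.delta_sbp == pytest.approx(resp.sbp_peak - resp.sbp_baseline)
        assert resp.accepted and resp.reject_reason is None


class TestExtractCondition:
    def test_twenty_boli_yield_twenty_responses(self):
        p = bx.ConditionParams(label="normoxia", brs_bolus_sd=0, dsbp_bolus_sd=0,
                               rri_noise_sd=5, sbp_noise_sd=1)
        sch = bx.BolusSchedule(n_boli=20)
        beats, events = bx.simulate_beats(p, sch, sch.duration_needed_s(), seed=1)
        resp = bx.extract_condition(beats, events)
        assert len(resp) == 20
        assert [r.bolus_index for r in resp] == list(range(20))

    def test_empty_event_list(self, noise_free_recording):
        _, _, beats, _ = noise_free_recording
        assert bx.extract_condition(beats, []) == []

    def test_boli_too_close_together_raise_overlap_error(self):
        # 69 s apart at 1 s beats: the 10-beat baseline window of the
        # second bolus reaches into the 60 s peak window of the first
        sbp = 130 + np.zeros(200)
        s = series(sbp)
        events = [BolusEvent(0, 20.5), BolusEvent(1, 89.5)]
        with pytest.raises(BolusWindowError, match="overlap"):
            bx.extract_condition(s, events)
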