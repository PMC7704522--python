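"""Generator contracts: determinism, beat-time bookkeeping, exact
noise-free coupling, and noise monotonicity."""

import numpy as np
import pytest

import baroreflex as bx
from baroreflex.types import HYPOXIA, NORMOXIA, BaroreflexError, ScheduleError


def _params(**kw):
    base = dict(
        label="normoxia", sbp_baseline=133.0, hr_baseline=63.0,
        brs_true=20.0, dsbp_true=22.0, brs_bolus_sd=0.0, dsbp_bolus_sd=0.0,
        rri_noise_sd=0.0, sbp_noise_sd=0.0,
    )
    base.update(kw)
    return bx.ConditionParams(**base)


SCHEDULE = bx.BolusSchedule(n_boli=3, interval_s=240.0, first_bolus_s=120.0)


def test_identical_seed_gives_bit_identical_series():
    p = _params(rri_noise_sd=15.0, sbp_noise_sd=3.0, brs_bolus_sd=4.0,
                dsbp_bolus_sd=5.0)
    a, ev_a = bx.simulate_beats(p, SCHEDULE, 1000.0, seed=42)
    b, ev_b = bx.simulate_beats(p, SCHEDULE, 1000.0, seed=42)
    assert np.array_equal(a.time_s, b.time_s)
    assert np.array_equal(a.rri_ms, b.rri_ms)
    assert np.array_equal(a.sbp_mmhg, b.sbp_mmhg)
    assert [e.time_s for e in ev_a] == [e.time_s for e in ev_b]
    c, _ = bx.simulate_beats(p, SCHEDULE, 1000.0, seed=43)
    assert not np.array_equal(a.sbp_mmhg, c.sbp_mmhg)


def test_beat_times_advance_by_the_interval_ending_at_each_beat():
    p = _params(rri_noise_sd=20.0, sbp_noise_sd=3.0)
    beats, _ = bx.simulate_beats(p, SCHEDULE, 1000.0, seed=3)
    np.testing.assert_allclose(
        np.diff(beats.time_s), beats.rri_ms[1:] / 1000.0, rtol=0, atol=1e-9
    )


def test_noise_free_extraction_recovers_slope_exactly(noise_free_recording):
    _, _, beats, events = noise_free_recording
    for ev in events:
        slope, _, r, n = bx.estimate_brs(beats, ev)
        assert slope == pytest.approx(20.0, abs=1e-9)
        assert r == pytest.approx(1.0, abs=1e-9)
        assert n >= 5


def test_noise_free_delta_sbp_matches_injected_amplitude(noise_free_recording):
    _, _, beats, events = noise_free_recording
    for ev in events:
        resp = bx.extract_bolus_response(beats, ev)
        assert resp.accepted
        # amplitude 25; 3-beat window averaging sits just under the peak
        assert resp.delta_sbp == pytest.approx(25.0, abs=0.2)


def test_zero_brs_keeps_rri_constant_through_the_pressor_rise():
    p = _params(brs_true=0.0)
    beats, _ = bx.simulate_beats(p, SCHEDULE, 1000.0, seed=5)
    np.testing.assert_allclose(beats.rri_ms, 60000.0 / 63.0, rtol=0, atol=1e-9)
    assert np.ptp(beats.sbp_mmhg) > 15  # the pressor transient is there


def test_mean_regression_r_does_not_improve_with_more_rri_noise():
    mean_r = []
    for noise in (0.0, 15.0, 60.0, 150.0):
        rs = []
        for seed in range(5):
            p = _params(rri_noise_sd=noise, sbp_noise_sd=2.0)
            beats, events = bx.simulate_beats(p, SCHEDULE, 1000.0, seed=seed)
            for ev in events:
                fit = bx.estimate_brs(beats, ev)
                if fit is not None:
                    rs.append(fit[2])
        mean_r.append(np.mean(rs))
    assert all(a >= b - 1e-12 for a, b in zip(mean_r, mean_r[1:]))


def test_schedule_not_covered_by_duration_names_first_offending_bolus():
    with pytest.raises(ScheduleError, match="bolus 2"):
        bx.simulate_beats(_params(), SCHEDULE, 630.0, seed=0)


def test_extracted_mean_delta_sbp_calibrated_to_truth_over_replicates():
    """Monte-Carlo: the per-bolus mean ΔSBP stays within 2 per-bolus SEM
    of the generator's true amplitude despite the max-window bias."""
    p = _params(dsbp_bolus_sd=5.0, sbp_noise_sd=2.0, rri_noise_sd=10.0,
                brs_bolus_sd=4.0, brs_true=19.9)
    sch = bx.BolusSchedule(n_boli=20)
    means = []
    for seed in range(50):
        beats, events = bx.simulate_beats(p, sch, sch.duration_needed_s(), seed=seed)
        resp = bx.extract_condition(beats, events)
        means.append(np.mean([r.delta_sbp for r in resp]))
    sem = 5.0 / np.sqrt(20)
    assert abs(np.mean(means) - p.dsbp_true) < 2 * sem


def test_cohort_has_nine_subjects_two_conditions_twenty_boli():
    recs = bx.simulate_cohort(bx.default_cohort(), seed=2)
    assert len(recs) == 9
    for rec in recs:
        assert set(rec.beats) == {NORMOXIA, HYPOXIA}
        assert all(len(rec.events[c]) == 20 for c in rec.events)
        assert set(rec.condition_order) == {NORMOXIA, HYPOXIA}
        for c, beats in rec.beats.items():
            beats.validate()
            ev_t = [e.time_s for e in rec.events[c]]
            assert min(ev_t) > beats.time_s[0]
            assert max(ev_t) < beats.time_s[-1]


def test_reordering_the_cohort_leaves_each_subject_unchanged():
    cohort = bx.default_cohort()
    recs_fwd = bx.simulate_cohort(cohort, seed=9)
    recs_rev = bx.simulate_cohort(cohort[::-1], seed=9)
    by_id = {r.subject_id: r for r in recs_rev}
    for rec in recs_fwd:
        other = by_id[rec.subject_id]
        for c in rec.beats:
            assert np.array_equal(rec.beats[c].sbp_mmhg, other.beats[c].sbp_mmhg)


def test_duplicate_subject_ids_rejected():
    cohort = bx.default_cohort()
    with pytest.raises(BaroreflexError, match="duplicate"):
        bx.simulate_cohort(cohort + [cohort[0]], seed=0)


def test_identical_conditions_classified_unchanged_at_type_one_rate():
    """Null subject (same truth in both conditions): the N-of-1 layer
    calls 'unchanged' at roughly 1 - alpha."""
    par = dict(
        sbp_baseline=133.0, hr_baseline=63.0, brs_true=18.0, dsbp_true=22.0,
        brs_bolus_sd=5.0, dsbp_bolus_sd=5.0, rri_noise_sd=10.0, sbp_noise_sd=2.0,
    )
    spec = bx.SubjectSpec(
        subject_id="null",
        normoxia=bx.ConditionParams(label="normoxia", **par),
        hypoxia=bx.ConditionParams(label="hypoxia", **par),
        schedule=bx.BolusSchedule(n_boli=10),
    )
    unchanged = 0
    n_seeds = 40
    for seed in range(n_seeds):
        rec = bx.simulate_cohort([spec], seed=seed)[0]
        study = bx.BaroreflexStudy(
            [bx.SubjectData(rec.subject_id, rec.beats, rec.events)]
        )
        res = study.fit()
        comps = res.comparisons_for("brs")
        unchanged += comps[0].classification == "unchanged"
    assert unchanged >= 0.85 * n_seeds


def test_invalid_condition_params_rejected():
    with pytest.raises(ValueError):
        bx.ConditionParams(label="normoxia", hr_baseline=250.0)
    with pytest.raises(ValueError):
        bx.ConditionParams(label="normoxia", brs_true=-1.0)
    with pytest.raises(ValueError):
        bx.BolusSchedule(interval_s=60.0)
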