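"""N-of-1 layer: summary-statistic Welch test, classification, tallies."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import baroreflex as bx
from baroreflex.nof1 import holm_adjust, pooled_t_from_summary
from baroreflex.types import BaroreflexError, MetricSample


def sample(values, subject="s1", cond="normoxia", metric="brs"):
    return MetricSample(subject, cond, metric, np.asarray(values, float))


class TestWelchFromSummary:
    def test_identical_groups(self):
        t, df, p = bx.welch_t_from_summary(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_degenerate_zero_sems(self):
        t, _, p = bx.welch_t_from_summary(5.0, 0.0, 10, 5.0, 0.0, 10)
        assert t == 0.0 and p == 1.0
        t, _, p = bx.welch_t_from_summary(6.0, 0.0, 10, 5.0, 0.0, 10)
        assert math.isinf(t) and t > 0 and p == 0.0

    def test_antisymmetry(self):
        t1, df1, p1 = bx.welch_t_from_summary(14.4, 0.8, 20, 8.3, 0.8, 20)
        t2, df2, p2 = bx.welch_t_from_summary(8.3, 0.8, 20, 14.4, 0.8, 20)
        assert t1 == -t2 and df1 == df2 and p1 == p2

    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=25),
        st.lists(st.floats(-50, 50), min_size=3, max_size=25),
    )
    def test_matches_raw_value_welch_test(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        sa = float(np.std(a, ddof=1)) / math.sqrt(len(a))
        sb = float(np.std(b, ddof=1)) / math.sqrt(len(b))
        t, df, p = bx.welch_t_from_summary(a.mean(), sa, len(a), b.mean(), sb, len(b))
        ref = stats.ttest_ind(a, b, equal_var=False)
        if math.isfinite(t) and sa + sb > 0:
            assert t == pytest.approx(ref.statistic, rel=1e-9, abs=1e-9)
            assert p == pytest.approx(ref.pvalue, rel=1e-9, abs=1e-9)

    def test_pooled_variant_matches_scipy(self, rng):
        a = rng.normal(10, 3, 12)
        b = rng.normal(8, 5, 17)
        sa = a.std(ddof=1) / math.sqrt(a.size)
        sb = b.std(ddof=1) / math.sqrt(b.size)
        t, df, p = pooled_t_from_summary(a.mean(), sa, a.size, b.mean(), sb, b.size)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert t == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert df == a.size + b.size - 2

    def test_rejects_tiny_samples(self):
        with pytest.raises(ValueError):
            bx.welch_t_from_summary(1.0, 0.5, 1, 2.0, 0.5, 10)


class TestCompareIndividual:
    def test_equals_scipy_welch_on_raw_values(self, rng):
        a = rng.normal(20, 5, 18)
        b = rng.normal(14, 6, 15)
        comp = bx.compare_individual(sample(a), sample(b, cond="hypoxia"))
        ref = stats.ttest_ind(b, a, equal_var=False)
        assert comp.t_statistic == pytest.approx(ref.statistic, rel=1e-9)
        assert comp.p_value == pytest.approx(ref.pvalue, rel=1e-9)
        assert comp.difference == pytest.approx(b.mean() - a.mean())

    def test_ci_covers_the_difference_and_matches_decision(self, rng):
        for _ in range(20):
            a = rng.normal(20, 5, 15)
            b = rng.normal(16, 5, 15)
            c = bx.compare_individual(sample(a), sample(b, cond="hypoxia"))
            assert c.ci95_low <= c.difference <= c.ci95_high
            # p < 0.05 iff the 95% CI excludes zero
            excludes = c.ci95_low > 0 or c.ci95_high < 0
            assert (c.p_value < 0.05) == excludes

    def test_noise_free_distinct_constants(self):
        c = bx.compare_individual(
            sample([10.0] * 5), sample([12.0] * 5, cond="hypoxia")
        )
        assert math.isinf(c.t_statistic) and c.p_value == 0.0
        assert c.classification == "increased"

    def test_classification_sign_convention(self):
        c = bx.compare_individual(
            sample([20, 21, 19, 20, 22]), sample([10, 11, 9, 10, 12], cond="hypoxia")
        )
        assert c.difference < 0 and c.classification == "decreased"

    def test_type_one_rate_close_to_alpha(self, rng):
        hits = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(15, 4, 17)
            b = rng.normal(15, 4, 17)
            c = bx.compare_individual(sample(a), sample(b, cond="hypoxia"))
            hits += c.classification != "unchanged"
        assert 0.02 <= hits / reps <= 0.08

    def test_mismatched_subject_or_metric_errors(self):
        with pytest.raises(BaroreflexError):
            bx.compare_individual(sample([1, 2]), sample([1, 2], subject="s2"))
        with pytest.raises(BaroreflexError, match="metric"):
            bx.compare_individual(
                sample([1, 2]), sample([1, 2], metric="delta_sbp")
            )
        with pytest.raises(BaroreflexError, match="boli"):
            bx.compare_individual(sample([1.0]), sample([1, 2], cond="hypoxia"))


class TestClassifyCohort:
    def _comps(self, pattern):
        comps = []
        for i, cls in enumerate(pattern):
            diff = {"decreased": -5.0, "increased": 5.0, "unchanged": 0.5}[cls]
            p = 0.01 if cls != "unchanged" else 0.5
            comps.append(
                bx.comparison_from_summary(
                    f"s{i}", "brs", 20.0, 1.0, 10, 20.0 + diff,
                    1.0 if cls != "unchanged" else 10.0, 10,
                )
            )
        return comps

    def test_counts(self):
        comps = self._comps(["decreased", "decreased", "increased", "unchanged"])
        counts = bx.classify_cohort(comps, "brs")
        assert counts == {"decreased": 2, "increased": 1, "unchanged": 1}

    def test_duplicate_subject_errors(self):
        comps = self._comps(["decreased", "unchanged"])
        comps[1].subject_id = comps[0].subject_id
        with pytest.raises(BaroreflexError, match="duplicate"):
            bx.classify_cohort(comps, "brs")


def test_holm_correction_is_more_conservative():
    comps = [
        bx.comparison_from_summary(f"s{i}", "brs", 20, 1.0, 10, m, 1.0, 10)
        for i, m in enumerate([14.0, 16.5, 17.0, 19.5, 20.5])
    ]
    plain = bx.classify_cohort(comps, "brs")
    adjusted = bx.classify_cohort(holm_adjust(comps), "brs")
    assert adjusted["unchanged"] >= plain["unchanged"]
    # the strongest effect survives correction
    assert [c for c in holm_adjust(comps) if c.subject_id == "s0"][0].significant
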