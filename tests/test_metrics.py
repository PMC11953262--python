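"""Figures of merit and method-comparison statistics.

Hand-computed oracles, brute-force definitional recomputation on random
vectors, and the published summary-statistics tables recomputed to
printed precision.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import spectracal as sc
from spectracal.exceptions import DomainError

finite_vec = st.lists(st.floats(-50, 50), min_size=2, max_size=12).map(np.asarray)


class TestRrmse:
    def test_perfect_prediction_is_zero(self):
        assert sc.rrmse([2, 6, 10], [2, 6, 10]) == 0

    def test_hand_oracle(self):
        # errors (1,0,-1): RMSE = sqrt(2/3); mean ref = 6
        assert sc.rrmse([3, 6, 9], [2, 6, 10]) == pytest.approx(100 * np.sqrt(2 / 3) / 6,
                                                               abs=1e-9)
        assert sc.rrmse([3, 6, 9], [2, 6, 10]) == pytest.approx(13.608, abs=1e-3)

    def test_scale_invariance(self):
        a = sc.rrmse([3, 6, 9], [2, 6, 10])
        b = sc.rrmse([30, 60, 90], [20, 60, 100])
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_mean_reference_rejected(self):
        with pytest.raises(DomainError):
            sc.rrmse([1, -1], [1, -1])

    def test_baseline_predictor_identity(self):
        """Predicting the mean gives RRMSE = 100 * SD_pop(y) / mean(y)."""
        y = np.array([2.0, 4, 6, 8, 10, 3])
        pred = np.full_like(y, y.mean())
        assert sc.rrmse(pred, y) == pytest.approx(100 * y.std() / y.mean(), rel=1e-12)

    @settings(deadline=None, max_examples=80)
    @given(err=finite_vec, base=st.floats(1, 20))
    def test_matches_brute_force_definition(self, err, base):
        ref = base + np.abs(err) + 1.0
        pred = ref + err
        expected = 100 * np.sqrt(np.sum((pred - ref) ** 2) / len(ref)) / np.mean(ref)
        assert sc.rrmse(pred, ref) == pytest.approx(expected, rel=1e-9)


class TestBiasCorrectedRrmsep:
    def test_pure_bias_removed(self):
        assert sc.bias_corrected_rrmsep([2.5, 6.5, 10.5], [2, 6, 10]) == pytest.approx(0, abs=1e-9)

    def test_hand_oracle(self):
        # errors (1,0,-1), bias 0, SEP = sqrt(2/2) = 1, mean ref 6
        assert sc.bias_corrected_rrmsep([3, 6, 9], [2, 6, 10]) == pytest.approx(100 / 6,
                                                                               abs=1e-9)

    @settings(deadline=None, max_examples=80)
    @given(err=finite_vec, base=st.floats(1, 20))
    def test_matches_brute_force_definition(self, err, base):
        ref = base + np.abs(err) + 1.0
        pred = ref + err
        e = pred - ref
        expected = 100 * np.sqrt(np.sum((e - e.mean()) ** 2) / (len(e) - 1)) / ref.mean()
        assert sc.bias_corrected_rrmsep(pred, ref) == pytest.approx(expected, rel=1e-9)


class TestRegressionAndLimits:
    def test_identity_line(self):
        assert sc.regression_fit([2, 6, 10], [2, 6, 10]) == pytest.approx((1, 0, 1))

    def test_exact_affine_fit(self):
        slope, intercept, r2 = sc.regression_fit([5, 13, 21], [2, 6, 10])
        assert (slope, intercept, r2) == pytest.approx((2, 1, 1))

    def test_constant_reference_rejected(self):
        with pytest.raises(DomainError):
            sc.regression_fit([1, 2, 3], [5, 5, 5])

    def test_perfect_prediction_gives_zero_limits(self):
        assert sc.lod_loq([2, 6, 10], [2, 6, 10]) == pytest.approx((0, 0), abs=1e-12)

    def test_loq_lod_ratio_is_ten_over_threethree(self):
        rng = np.random.default_rng(0)
        ref = np.tile([2.0, 4, 6, 8, 10], 4)
        pred = ref + rng.normal(0, 0.1, ref.size)
        lod, loq = sc.lod_loq(pred, ref)
        assert loq / lod == pytest.approx(10 / 3.3, rel=1e-12)

    def test_published_rosuvastatin_loq_from_lod(self):
        """LOD 0.1413 ug/mL forces LOQ 0.4282 under the 3.3/10 convention."""
        assert (10 / 3.3) * 0.1413 == pytest.approx(0.4282, abs=5e-5)


class TestSimpleRatios:
    @pytest.mark.parametrize("pred,nominal,expected", [(10.05, 10, 100.5), (6, 6, 100.0)])
    def test_recovery(self, pred, nominal, expected):
        assert sc.recovery_pct(pred, nominal) == pytest.approx(expected)

    def test_recovery_domain(self):
        with pytest.raises(DomainError):
            sc.recovery_pct(5, 0)

    def test_rsd(self):
        assert sc.rsd_pct([9, 10, 11]) == pytest.approx(10.0)
        assert sc.rsd_pct([5, 5, 5]) == 0
        assert sc.rsd_pct([18, 20, 22]) == pytest.approx(sc.rsd_pct([9, 10, 11]), rel=1e-12)

    @pytest.mark.parametrize("base,spiked,added,expected", [
        (4.0, 8.0, 4.0, 100.0),
        (4.0, 7.9, 4.0, 97.5),
    ])
    def test_standard_addition(self, base, spiked, added, expected):
        assert sc.standard_addition_recovery(base, spiked, added) == pytest.approx(expected)


# published Table-3-style summary statistics: (mean, SD) proposed vs reference,
# n = 5 determinations each
TABLE3 = {
    "propranolol": ((100.63, 2.114), (99.70, 1.698)),
    "rosuvastatin": ((100.13, 1.184), (99.16, 2.055)),
    "valsartan": ((100.99, 1.71), (99.67, 1.444)),
}
TABLE3_VARS = {
    "propranolol": (4.468, 2.884),
    "rosuvastatin": (1.403, 4.222),
    "valsartan": (2.923, 2.085),
}


class TestMethodComparison:
    def test_equal_means_give_t_zero(self):
        t, df, p = sc.pooled_t_test(100, 1.0, 5, 100, 2.0, 5)
        assert t == 0 and p == pytest.approx(1.0)

    def test_published_propranolol_t(self):
        (ma, sa), (mb, sb) = TABLE3["propranolol"]
        t, df, p = sc.pooled_t_test(ma, sa, 5, mb, sb, 5)
        assert df == 8
        assert t == pytest.approx(0.767, abs=5e-4)
        assert p == pytest.approx(0.466, abs=5e-3)

    def test_critical_value_for_df8(self):
        assert stats.t.ppf(0.975, 8) == pytest.approx(2.306, abs=5e-4)

    def test_symmetry(self):
        a = sc.pooled_t_test(100.63, 2.114, 5, 99.70, 1.698, 5)
        b = sc.pooled_t_test(99.70, 1.698, 5, 100.63, 2.114, 5)
        assert a == pytest.approx(b)

    def test_zero_pooled_variance(self):
        assert sc.pooled_t_test(5, 0, 3, 5, 0, 3) == (0.0, 4, 1.0)
        with pytest.raises(DomainError):
            sc.pooled_t_test(5, 0, 3, 6, 0, 3)

    @pytest.mark.parametrize("drug,expected", [
        ("propranolol", 1.549), ("rosuvastatin", 3.009), ("valsartan", 1.402),
    ])
    def test_published_f_values(self, drug, expected):
        va, vb = TABLE3_VARS[drug]
        f, df1, df2, _ = sc.variance_f_test(va, 5, vb, 5)
        assert (df1, df2) == (4, 4)
        assert f == pytest.approx(expected, abs=5e-4)

    def test_f_at_least_one_and_symmetric(self):
        a = sc.variance_f_test(2.0, 5, 8.0, 7)
        b = sc.variance_f_test(8.0, 7, 2.0, 5)
        assert a == b and a[0] >= 1

    def test_equal_variances(self):
        f, _, _, p = sc.variance_f_test(3.0, 5, 3.0, 5)
        assert f == 1.0 and p == pytest.approx(1.0)

    def test_f_critical_value_df4_4(self):
        """The one-tailed 5% critical value for (4,4) df is 6.39 — the basis
        of the tabulated comparison threshold."""
        assert stats.f.ppf(0.95, 4, 4) == pytest.approx(6.388, abs=5e-3)

    def test_compare_methods_from_raw_values(self):
        rng = np.random.default_rng(4)
        a = 100 + rng.normal(0, 2, 5)
        b = 99.5 + rng.normal(0, 1.5, 5)
        res = sc.compare_methods(a, b)
        t, df, p = sc.pooled_t_test(a.mean(), a.std(ddof=1), 5, b.mean(), b.std(ddof=1), 5)
        assert res.t_stat == pytest.approx(t) and res.t_df == df
        assert res.var_a == pytest.approx(res.sd_a**2, rel=1e-12)
        assert res.f_stat >= 1


def test_validation_report_roundtrip(tmp_path):
    rng = np.random.default_rng(1)
    ref = np.tile([2.0, 6, 10], 5)
    pred = ref + rng.normal(0, 0.05, ref.size)
    report = sc.build_validation_report("demo", pred, ref, pred, ref,
                                        intraday_values=[6.0, 6.02, 5.98])
    assert report.loq_ugml == pytest.approx(report.lod_ugml * 10 / 3.3, rel=1e-12)
    assert 0 <= report.r_squared <= 1
    text = report.to_json(tmp_path / "r.json")
    assert '"analyte"' in text
    md = report.to_markdown()
    assert "LOD" in md and "demo" in md
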