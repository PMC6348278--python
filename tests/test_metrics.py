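"""CoV, cumulative series, per-segment stats, peri-turn normalization,
paired t-tests and density histograms."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import gaitvar as gv
from gaitvar.metrics import UndefinedStatisticError

from conftest import segmented


class TestCoV:
    def test_hand_computed_example(self):
        # sample SD of [1,2,3] is 1 (n-1 denominator), mean 2 -> 50%
        assert gv.coefficient_of_variation([1, 2, 3]) == pytest.approx(50.0)

    def test_zero_variance(self):
        assert gv.coefficient_of_variation([5, 5, 5]) == 0.0

    @given(st.lists(st.floats(min_value=0.1, max_value=100), min_size=2,
                    max_size=50),
           st.floats(min_value=0.01, max_value=1000))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, values, c):
        base = gv.coefficient_of_variation(values)
        scaled = gv.coefficient_of_variation([c * v for v in values])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)

    @pytest.mark.parametrize("bad", [[1.0], [-1.0, -2.0, -3.0]])
    def test_degenerate_inputs_raise(self, bad):
        with pytest.raises(UndefinedStatisticError):
            gv.coefficient_of_variation(bad)


class TestCumulativeSeries:
    def test_constant_series_has_zero_cov_everywhere(self):
        cs = gv.cumulative_series([7.0] * 40, n_max=40)
        assert (cs.cum_cov == 0).all()
        assert (cs.cum_mean == 7.0).all()

    def test_endpoint_matches_whole_window_statistics(self, rng):
        values = rng.normal(80, 2, 40)
        cs = gv.cumulative_series(values, n_max=40)
        assert cs.at(40, "cum_cov") == gv.coefficient_of_variation(values)
        assert cs.at(40, "cum_mean") == pytest.approx(values.mean())

    def test_matches_direct_computation_per_n(self, rng):
        values = rng.normal(1.0, 0.03, 40)
        cs = gv.cumulative_series(values, n_max=40)
        for n in (3, 10, 25, 40):
            assert cs.at(n, "cum_mean") == pytest.approx(values[:n].mean())
            assert cs.at(n, "cum_cov") == pytest.approx(
                gv.coefficient_of_variation(values[:n]), rel=1e-10)

    def test_outlier_causes_jump_then_decay(self):
        values = np.full(40, 80.0) + np.linspace(0, 0.1, 40)
        values[19] = 40.0  # one drastically short stride at position 20
        cs = gv.cumulative_series(values, n_max=40)
        assert cs.at(20, "cum_cov") > 5 * cs.at(19, "cum_cov")
        after = cs.cum_cov[cs.n_values >= 20]
        assert (np.diff(after) < 0).all()

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            gv.cumulative_series([1.0] * 30, n_max=40)


class TestPerSegmentStats:
    def test_identical_segments_have_zero_range(self):
        from test_turns import make_trial
        pattern = [1.0, 1.1, 0.9, 1.0]
        trial = make_trial(pattern * 3, gaps_after={3, 7})
        st_ = gv.per_segment_stats(segmented(trial), "ST")
        assert len(st_.seg_covs) == 3
        assert st_.cov_range == pytest.approx(0.0, abs=1e-9)

    def test_hand_computed_segment_cov(self):
        from test_turns import make_trial
        trial = make_trial([1.0] * 6, gaps_after={2},
                           lengths=[1, 2, 3, 10, 10, 10])
        st_ = gv.per_segment_stats(segmented(trial), "SL")
        assert st_.seg_covs[0] == pytest.approx(50.0)
        assert st_.seg_covs[1] == 0.0
        assert st_.cov_range == pytest.approx(50.0)

    def test_short_segments_skipped_and_all_short_raises(self):
        from test_turns import make_trial
        trial = make_trial([1.0] * 5, gaps_after={1})
        st_ = gv.per_segment_stats(segmented(trial), "ST")
        assert len(st_.seg_covs) == 1  # 2-stride segment skipped
        tiny = make_trial([1.0, 1.0], gaps_after={0})
        with pytest.raises(UndefinedStatisticError):
            gv.per_segment_stats(segmented(tiny), "ST")


class TestPeriTurnNormalization:
    def test_stride_at_reference_maps_to_100(self, he_trial):
        sets = gv.extract_periturn_strides([segmented(he_trial)])
        ps = sets[0]
        rel = gv.normalize_periturn(ps, "SL")
        expected = 100 * ps.after[0].length_pct_stature / ps.ref_mean_sl
        assert rel["after"][0] == pytest.approx(expected)

    def test_generated_delta_recovered_in_relative_means(self):
        """After-turn relative stride length ~ 97.2% when generated with a
        2.8% shortening."""
        trials = [gv.generate_trial(gv.TABLE_PROFILES["PD"], gv.md_config(), s)
                  for s in range(60)]
        sets = gv.extract_periturn_strides([segmented(t) for t in trials])
        cmp_res = gv.compare_periturn(sets, "after", "SL")
        assert cmp_res.mean_relative_pct == pytest.approx(97.2, abs=0.3)
        cmp_t = gv.compare_periturn(sets, "after", "ST")
        assert cmp_t.mean_relative_pct == pytest.approx(103.2, abs=0.3)

    def test_empty_set_rejected(self):
        ps = gv.PeriTurnSet(subject_id="s", group="PD")
        with pytest.raises(UndefinedStatisticError):
            gv.normalize_periturn(ps, "SL")


class TestPairedT:
    def test_hand_computed_example(self):
        # mean 2, SD 1 -> t = 2 / (1/sqrt(3)) = 3.464, df = 2
        res = gv.paired_t_test([1, 2, 3])
        assert res.t == pytest.approx(3.4641016, rel=1e-6)
        assert res.df == 2

    def test_matches_scipy_one_sample(self, rng):
        d = rng.normal(0.5, 1.0, 30)
        res = gv.paired_t_test(d)
        ref = stats.ttest_1samp(d, 0.0)
        assert res.t == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_sign_symmetry(self, rng):
        d = rng.normal(1, 2, 20)
        a, b = gv.paired_t_test(d), gv.paired_t_test(-d)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)

    def test_zero_variance_raises(self):
        with pytest.raises(UndefinedStatisticError):
            gv.paired_t_test([0.0, 0.0, 0.0])

    def test_periturn_effect_detected_in_most_replicates(self):
        """Paired t on after-turn relative lengths rejects at p < 0.01 in
        >= 95% of seeded replicates (>= 100 pooled turns each)."""
        rejections = 0
        n_rep = 20
        for rep in range(n_rep):
            trials = [gv.generate_trial(gv.TABLE_PROFILES["PD"],
                                        gv.md_config(), 1000 * rep + s)
                      for s in range(25)]
            sets = gv.extract_periturn_strides([segmented(t) for t in trials])
            res = gv.compare_periturn(sets, "after", "SL")
            assert res.n == 100
            if res.test.p < 0.01:
                rejections += 1
        assert rejections >= 0.95 * n_rep


class TestDensityHistogram:
    def test_densities_integrate_to_one(self, rng):
        h = gv.density_histogram(rng.normal(size=500))
        widths = np.diff(h.bin_edges)
        assert (h.densities * widths).sum() == pytest.approx(1.0, abs=1e-9)

    def test_fit_recovers_standard_normal(self, rng):
        h = gv.density_histogram(rng.standard_normal(10_000))
        assert abs(h.fit_mean) < 0.05
        assert abs(h.fit_sd - 1.0) < 0.05

    def test_different_sample_sizes_comparable(self, rng):
        ha = gv.density_histogram(rng.normal(size=248))
        hb = gv.density_histogram(rng.normal(size=648))
        for h in (ha, hb):
            assert (h.densities * np.diff(h.bin_edges)).sum() == \
                pytest.approx(1.0, abs=1e-9)

    def test_degenerate_sample_single_spike(self):
        h = gv.density_histogram([3.0, 3.0, 3.0])
        assert h.fit_sd == 0.0 and len(h.densities) == 1
        with pytest.raises(UndefinedStatisticError):
            h.pdf([3.0])
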