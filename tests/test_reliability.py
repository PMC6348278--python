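"""ICC(2,1), interpretation bands, convergence profiles, required stride
count and the 2.6% CoV classification."""

import numpy as np
import pandas as pd
import pytest

import gaitvar as gv
from gaitvar.metrics import UndefinedStatisticError


def icc21_oracle(x):
    """Brute-force ICC(2,1) from explicit sums of squares over all cells.

    Independent of the implementation under test: loops over cells and
    forms the ANOVA decomposition from first principles.
    """
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ss_rows = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
    ss_cols = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
    ss_tot = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    @pytest.mark.parametrize("n,k,seed", [(6, 3, 0), (10, 5, 1), (50, 5, 2),
                                          (4, 2, 3), (30, 3, 4)])
    def test_matches_sums_of_squares_oracle(self, n, k, seed):
        x = np.random.default_rng(seed).normal(size=(n, k))
        res = gv.icc_two_way_random_single(x)
        assert res.icc == pytest.approx(icc21_oracle(x), abs=1e-10)

    def test_matches_pingouin_icc2(self, rng):
        pg = pytest.importorskip("pingouin")
        x = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1)) * 2
        res = gv.icc_two_way_random_single(x)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(12), 4),
            "rater": np.tile(np.arange(4), 12),
            "score": x.ravel(),
        })
        ref = pg.intraclass_corr(long, targets="subject", raters="rater",
                                 ratings="score")
        icc2 = float(ref.loc[ref["Type"].isin(["ICC2", "ICC(A,1)"]),
                             "ICC"].iloc[0])
        assert res.icc == pytest.approx(icc2, abs=1e-8)

    def test_identical_columns_give_perfect_agreement(self):
        col = np.array([1.0, 2.0, 5.0, 3.0])
        x = np.column_stack([col, col, col])
        res = gv.icc_two_way_random_single(x)
        assert res.icc == pytest.approx(1.0)
        assert res.band == "excellent"

    def test_constant_matrix_degenerate(self):
        with pytest.raises(UndefinedStatisticError):
            gv.icc_two_way_random_single(np.full((5, 3), 2.0))

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[1, 2] = np.nan
        with pytest.raises(ValueError):
            gv.icc_two_way_random_single(x)

    def test_growing_noise_drives_icc_toward_zero(self, rng):
        """Adding i.i.d. noise of growing SD to identical columns erodes
        agreement monotonically (checked on one seeded sequence)."""
        col = rng.normal(0, 1, 30)
        base = np.column_stack([col] * 4)
        iccs = []
        for sd in (0.1, 0.5, 1.0, 2.0, 5.0, 20.0):
            noise = np.random.default_rng(7).normal(0, 1, base.shape)
            iccs.append(gv.icc_two_way_random_single(base + sd * noise).icc)
        assert all(a > b for a, b in zip(iccs, iccs[1:]))
        assert iccs[-1] < 0.1

    def test_deflation_with_low_between_subject_spread(self):
        """Shrinking the between-subject spread of true values lowers ICC
        at fixed within-subject noise — the deflation that makes segment
        CoVs look unreliable in homogeneous groups."""
        rng_ = np.random.default_rng(21)
        subj_wide = rng_.normal(0, 2.0, 40)
        subj_narrow = subj_wide * 0.1
        noise = rng_.normal(0, 0.5, (40, 4))
        icc_wide = gv.icc_two_way_random_single(subj_wide[:, None] + noise).icc
        icc_narrow = gv.icc_two_way_random_single(
            subj_narrow[:, None] + noise).icc
        assert icc_narrow < icc_wide


class TestBands:
    @pytest.mark.parametrize("icc,band", [
        (0.3, "poor"), (0.39999, "poor"),
        (0.4, "fair_to_good"), (0.6, "fair_to_good"),
        (0.8, "fair_to_good"),  # 0.4-0.8 inclusive at both ends
        (0.80001, "excellent"), (0.95, "excellent"),
    ])
    def test_banding_rule(self, icc, band):
        assert gv.icc_band(icc) == band


def make_series(matrix, n_min=3, parameter="SL", statistic="cum_cov"):
    """Wrap a subjects x n matrix of cumulative values into series objects."""
    ns = np.arange(n_min, n_min + matrix.shape[1])
    other = np.ones_like(matrix[0])
    out = []
    for row in matrix:
        kw = {statistic: row,
              ("cum_mean" if statistic == "cum_cov" else "cum_cov"): other}
        out.append(gv.CumulativeSeries(parameter=parameter, n_values=ns,
                                       cum_mean=kw["cum_mean"],
                                       cum_cov=kw["cum_cov"]))
    return out


class TestConvergence:
    def test_constant_in_n_gives_r_one_everywhere(self):
        mat = np.tile(np.array([[1.0], [2.0], [3.0], [5.0]]), (1, 8))
        prof = gv.convergence_profile(make_series(mat), "cum_cov")
        assert np.allclose(prof.r_by_n, 1.0)

    def test_r_at_final_n_is_exactly_one(self, rng):
        mat = rng.normal(2, 0.5, (10, 12))
        prof = gv.convergence_profile(make_series(mat), "cum_cov")
        assert prof.r_by_n[-1] == 1.0

    def test_matches_numpy_corrcoef(self, rng):
        mat = rng.normal(2, 0.5, (10, 12))
        prof = gv.convergence_profile(make_series(mat), "cum_cov")
        for j in range(11):
            ref = np.corrcoef(mat[:, j], mat[:, -1])[0, 1]
            assert prof.r_by_n[j] == pytest.approx(ref, rel=1e-12)

    def test_zero_variance_at_final_raises(self):
        mat = np.ones((5, 6))
        mat[:, 0] = [1, 2, 3, 4, 5]
        with pytest.raises(UndefinedStatisticError):
            gv.convergence_profile(make_series(mat), "cum_cov")

    def test_mismatched_grids_rejected(self, rng):
        a = make_series(rng.normal(size=(2, 8)))
        b = make_series(rng.normal(size=(1, 8)), n_min=4)
        with pytest.raises(ValueError):
            gv.convergence_profile(a + b, "cum_cov")

    def test_convergence_r_nondecreasing_on_average(self):
        """On unperturbed synthetic cohorts the mean correlation profile of
        the cumulative mean rises with n (averaged over replicates)."""
        profiles = []
        for rep in range(100):
            trials = [gv.generate_trial(
                gv.TABLE_PROFILES["HE"],
                gv.he_config(periturn_delta_len_pct=0.0,
                             periturn_delta_time_pct=0.0),
                10_000 * rep + s) for s in range(12)]
            series = [gv.cumulative_series(t.lengths[:40], n_max=40,
                                           parameter="SL") for t in trials]
            profiles.append(gv.convergence_profile(series, "cum_mean").r_by_n)
        mean_r = np.mean(profiles, axis=0)
        assert (np.diff(mean_r) > -1e-3).all()
        assert mean_r[0] > 0.9


class TestRequiredStrideCount:
    def test_first_crossing_wins_despite_later_dip(self):
        r = np.array([0.5, 0.7, 0.85, 0.79, 0.9, 0.95, 1.0])
        res = gv.ConvergenceResult("SL", "cum_cov",
                                   np.arange(3, 10), r)
        assert gv.required_stride_count(res, 0.8) == 5

    def test_sustained_mode_waits_out_the_dip(self):
        r = np.array([0.5, 0.7, 0.85, 0.79, 0.9, 0.95, 1.0])
        res = gv.ConvergenceResult("SL", "cum_cov", np.arange(3, 10), r)
        assert gv.required_stride_count(res, 0.8, sustained=True) == 7

    def test_immediate_crossing(self):
        res = gv.ConvergenceResult("SL", "cum_mean", np.arange(3, 8),
                                   np.array([0.92, 0.95, 0.97, 0.99, 1.0]))
        assert gv.required_stride_count(res, 0.8) == 3

    def test_result_never_exceeds_n_max(self, rng):
        # final R is 1 by construction, so the requirement always exists
        r = np.concatenate([rng.uniform(-1, 0.5, 9), [1.0]])
        res = gv.ConvergenceResult("ST", "cum_cov", np.arange(3, 13), r)
        assert gv.required_stride_count(res, 0.8) == 12


class TestCutoffClassification:
    @pytest.mark.parametrize("values,expected", [
        ([2.7], 1),
        ([2.6], 0),       # strictly greater than the cut-off
        ([], 0),
        ([1.0, 2.61, 5.0, 2.59], 2),
    ])
    def test_counting_rule(self, values, expected):
        count, frac = gv.classify_above_cutoff(values, 2.6)
        assert count == expected
        if values:
            assert frac == pytest.approx(expected / len(values))
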