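"""Descriptive, rmcorr, Bland-Altman, TOST, effect sizes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sst

import respirad as rr
from respirad.stats import EquivalenceBounds, METRICS, run_validation


class TestDescriptive:
    def test_constant_series(self):
        d = rr.descriptive_stats({"radar": np.full(10, 3.3)})
        assert d.loc["radar", "sd"] == 0 and d.loc["radar", "se"] == 0

    def test_small_sample(self):
        d = rr.descriptive_stats({"x": np.array([1.0, 2.0, 3.0])})
        assert d.loc["x", "mean"] == 2.0
        assert d.loc["x", "sd"] == pytest.approx(1.0)  # ddof=1
        assert d.loc["x", "se"] == pytest.approx(1 / np.sqrt(3))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rr.descriptive_stats({"x": np.array([])})


class TestRmCorr:
    def test_perfect_within_subject_lines(self):
        subj = np.repeat([0, 1], 5)
        x = np.tile(np.arange(5.0), 2)
        y = np.concatenate([2 * np.arange(5.0) + 1, 2 * np.arange(5.0) - 4])
        res = rr.repeated_measures_correlation(subj, x, y)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)

    def test_sign_follows_common_slope(self):
        subj = np.repeat([0, 1], 4)
        x = np.tile(np.arange(4.0), 2)
        y = -x + np.repeat([0.0, 10.0], 4)
        assert rr.repeated_measures_correlation(subj, x, y).r == pytest.approx(-1.0)

    def test_null_data_gives_small_r_large_p(self):
        rng = np.random.default_rng(7)
        subj = np.repeat(np.arange(20), 50)
        res = rr.repeated_measures_correlation(
            subj, rng.normal(size=1000), rng.normal(size=1000)
        )
        assert abs(res.r) < 0.1
        assert res.p > 0.05

    def test_dof_is_n_minus_k_minus_1(self):
        rng = np.random.default_rng(0)
        subj = np.repeat(np.arange(3), 5)
        res = rr.repeated_measures_correlation(
            subj, rng.normal(size=15), rng.normal(size=15)
        )
        assert res.dof == 15 - 3 - 1

    def test_matches_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(5)
        df = pd.DataFrame(
            {"s": np.repeat([0, 1, 2], 5),
             "x": rng.normal(size=15), "y": rng.normal(size=15)}
        )
        mine = rr.repeated_measures_correlation(df.s, df.x, df.y)
        ref = pg.rm_corr(data=df, x="x", y="y", subject="s").iloc[0]
        assert mine.r == pytest.approx(ref["r"], abs=1e-10)
        assert mine.dof == ref["dof"]
        assert mine.p == pytest.approx(ref["pval"], abs=1e-10)

    def test_all_constant_rejected(self):
        subj = np.repeat([0, 1], 3)
        with pytest.raises(ValueError, match="constant"):
            rr.repeated_measures_correlation(subj, np.ones(6), np.arange(6.0))

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError, match="2 subjects"):
            rr.repeated_measures_correlation(np.zeros(6), np.arange(6.0), np.arange(6.0))


class TestBlandAltman:
    def test_zero_differences(self):
        r = rr.bland_altman_modified(
            np.arange(5.0), np.arange(5.0), bounds=EquivalenceBounds(-1, 1)
        )
        assert r.bias_mu == 0 and r.loa_sigma == 0
        assert r.fraction_within_bounds == 1.0 and r.fraction_within_loa == 1.0

    def test_three_point_example(self):
        r = rr.bland_altman_modified(np.array([-1.0, 0.0, 1.0]), np.zeros(3))
        assert r.bias_mu == 0
        assert r.loa_sigma == pytest.approx(1.0)
        assert r.loa_upper == pytest.approx(1.96)
        assert r.loa_lower == pytest.approx(-1.96)

    def test_ci_formulas(self):
        rng = np.random.default_rng(2)
        d = rng.normal(0.5, 2.0, 50)
        r = rr.bland_altman_modified(d, np.zeros(50))
        t = sst.t.ppf(0.975, 49)
        assert r.bias_ci[1] - r.bias_ci[0] == pytest.approx(2 * t * r.loa_sigma / np.sqrt(50))
        assert r.loa_upper_ci[1] - r.loa_upper_ci[0] == pytest.approx(
            2 * t * r.loa_sigma * np.sqrt(3 / 50)
        )

    def test_rr_panel_magnitudes(self):
        """Differences drawn with the bias/spread of the radar-vs-reference
        respiratory-rate comparison (mu 0.06, LoA half-width 1.37 brpm)."""
        rng = np.random.default_rng(42)
        d = rng.normal(0.06, 1.37 / 1.96, 532)
        r = rr.bland_altman_modified(d, np.zeros(532), bounds=EquivalenceBounds(-2, 2))
        assert 1.96 * r.loa_sigma == pytest.approx(1.37, abs=0.1)
        assert r.fraction_within_bounds >= 0.97
        assert r.fraction_within_loa == pytest.approx(0.95, abs=0.02)

    def test_fraction_invariant_to_ordering(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=40), rng.normal(size=40)
        perm = rng.permutation(40)
        r1 = rr.bland_altman_modified(a, b, bounds=EquivalenceBounds(-1, 1))
        r2 = rr.bland_altman_modified(a[perm], b[perm], bounds=EquivalenceBounds(-1, 1))
        assert r1.fraction_within_bounds == r2.fraction_within_bounds
        assert r1.bias_mu == pytest.approx(r2.bias_mu)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError, match="3"):
            rr.bland_altman_modified([1.0, 2.0], [0.0, 0.0])


class TestTost:
    def test_zero_differences_equivalent(self):
        r = rr.tost_paired(np.zeros(20), bounds=EquivalenceBounds(-0.3, 0.3))
        assert r.equivalent and r.overall_p == pytest.approx(0.0, abs=1e-12)

    def test_mean_outside_bound_not_equivalent(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0.25, 0.1, 10)
        r = rr.tost_paired(d, bounds=EquivalenceBounds(-0.2, 0.2))
        assert not r.equivalent
        assert r.p_upper > 0.05

    def test_zero_width_bounds_impossible(self):
        with pytest.raises(ValueError):
            EquivalenceBounds(0.0, 0.0)

    def test_degenerate_zero_variance(self):
        inside = rr.tost_paired(np.full(10, 0.1), bounds=EquivalenceBounds(-0.3, 0.3))
        assert inside.equivalent and inside.overall_p == 0.0
        outside = rr.tost_paired(np.full(10, 0.5), bounds=EquivalenceBounds(-0.3, 0.3))
        assert not outside.equivalent and outside.overall_p == 1.0

    def test_one_sided_orientation(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.0, 1.0, 200)
        r = rr.tost_paired(d, bounds=EquivalenceBounds(-0.5, 0.5))
        assert r.t_lower > 0 > r.t_upper

    @settings(derandomize=True, max_examples=200)
    @given(
        mu=st.floats(-1, 1), sigma=st.floats(0.05, 2), n=st.integers(4, 200),
        bound=st.floats(0.05, 1.5), seed=st.integers(0, 10_000),
    )
    def test_decision_equals_ci_inside_bounds(self, mu, sigma, n, bound, seed):
        d = np.random.default_rng(seed).normal(mu, sigma, n)
        b = EquivalenceBounds(-bound, bound)
        r = rr.tost_paired(d, bounds=b)
        ci_inside = b.lower < r.raw_effect_ci[0] and r.raw_effect_ci[1] < b.upper
        assert r.equivalent == ci_inside


class TestCohensDz:
    def test_hand_computed_example(self):
        d = np.array([1.0, 1, 1, 3, 3, 3])
        dz, lo, hi = rr.cohens_dz(d)
        assert dz == pytest.approx(2 / 1.0954451, rel=1e-6)
        assert lo < dz < hi

    def test_zero_mean(self):
        d = np.array([-1.0, 0.0, 1.0, -0.5, 0.5])
        dz, lo, hi = rr.cohens_dz(d)
        assert dz == 0.0
        assert lo < 0 < hi

    def test_ci_coverage_against_scipy_nct(self):
        rng = np.random.default_rng(9)
        d = rng.normal(0.3, 1.0, 40)
        dz, lo, hi = rr.cohens_dz(d, ci=0.90)
        t_obs = dz * np.sqrt(40)
        # by construction: cdf at the returned noncentralities hits 95% / 5%
        assert sst.nct.cdf(t_obs, 39, lo * np.sqrt(40)) == pytest.approx(0.95, abs=1e-9)
        assert sst.nct.cdf(t_obs, 39, hi * np.sqrt(40)) == pytest.approx(0.05, abs=1e-9)


class TestRunValidation:
    @staticmethod
    def paired_cohort(bias=0.0, noise=0.01, n_subj=4, n_win=8, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        centers = {"RR": 12.0, "TI": 2.4, "TE": 2.9, "IE": 0.85}
        for s in range(n_subj):
            for w in range(n_win):
                for m in METRICS:
                    ref = centers[m] + rng.normal(0, 0.3)
                    rows.append(
                        dict(subject=f"s{s}", metric=m, window_start_s=30.0 * w,
                             radar=ref + (bias if m == "TE" else 0.0)
                             + rng.normal(0, noise),
                             reference=ref)
                    )
        return pd.DataFrame(rows)

    def test_zero_error_cohort_all_equivalent(self):
        res = run_validation(self.paired_cohort(noise=1e-6))
        for m in METRICS:
            assert res[m].tost.equivalent
            assert res[m].concordance.r_rm == pytest.approx(1.0, abs=1e-3)

    def test_injected_te_bias_recovered(self):
        res = run_validation(self.paired_cohort(bias=-0.12))
        lo, hi = res["TE"].tost.raw_effect_ci
        assert lo < -0.12 < hi or abs(res["TE"].tost.mean_diff + 0.12) < 0.01
        assert res["TE"].tost.mean_diff < 0

    def test_zero_width_bounds_nothing_equivalent(self):
        tiny = {m: EquivalenceBounds(-1e-9, 1e-9) for m in METRICS}
        res = run_validation(self.paired_cohort(noise=0.05), bounds=tiny)
        assert not any(res[m].tost.equivalent for m in METRICS)

    def test_report_files_written(self, tmp_path):
        run_validation(self.paired_cohort(), outdir=tmp_path, make_figures=True)
        for name in ("metrics_summary.csv", "concordance.csv", "tost.csv",
                     "concordance.json", "rr_concordance.svg"):
            assert (tmp_path / name).exists()

    def test_missing_metric_rejected(self):
        df = self.paired_cohort()
        with pytest.raises(ValueError, match="lacks"):
            run_validation(df[df.metric != "IE"])
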