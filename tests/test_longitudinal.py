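"""Follow-up series fitting, slope tests, consistency, clinical trends."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from normorph import longitudinal as lg
from normorph.exceptions import InsufficientDataError, ValidationError


class TestFitSeries:
    def test_perfect_line(self):
        a, x0, S2 = lg.fit_series([0, 1, 2], [0, 1, 2])
        assert (a, x0, S2) == (pytest.approx(1.0), pytest.approx(0.0), pytest.approx(0.0))

    def test_three_point_closed_form(self):
        # OLS through (0,0),(1,2),(2,0): slope 0, intercept 2/3, RSS 8/3
        a, x0, S2 = lg.fit_series([0, 1, 2], [0, 2, 0])
        assert a == pytest.approx(0.0, abs=1e-12)
        assert x0 == pytest.approx(2 / 3)
        assert S2 == pytest.approx(8 / 9)

    def test_constant_series(self):
        a, x0, _ = lg.fit_series([0, 1, 2, 3], [5.0] * 4)
        assert a == pytest.approx(0.0, abs=1e-12)
        assert x0 == pytest.approx(5.0)

    def test_too_short_or_degenerate(self):
        with pytest.raises(InsufficientDataError):
            lg.fit_series([0, 1], [0, 1])
        with pytest.raises(ValidationError):
            lg.fit_series([1, 1, 1], [0, 1, 2])


class TestSlopeUncertainty:
    def test_zero_residual_variance(self):
        assert lg.slope_uncertainty(0.0, 1.0, 5) == 0.0

    def test_three_point_example(self):
        # S2=8/9, sigma_t^2=2/3, n=3 -> sqrt(8/9)/sqrt(2/3) = 2/sqrt(3)
        da = lg.slope_uncertainty(8 / 9, np.sqrt(2 / 3), 3)
        assert da == pytest.approx(2 / np.sqrt(3), abs=1e-9)
        assert da == pytest.approx(1.1547, abs=1e-4)

    def test_doubling_time_spacing_halves_uncertainty(self):
        da1 = lg.slope_uncertainty(1.0, np.std([0, 1, 2, 3]), 4)
        da2 = lg.slope_uncertainty(1.0, np.std([0, 2, 4, 6]), 4)
        assert da2 == pytest.approx(da1 / 2)

    @given(
        n=st.integers(4, 12),
        seed=st.integers(0, 10_000),
    )
    @settings(max_examples=80, deadline=None)
    def test_equals_textbook_ols_slope_se(self, n, seed):
        # oracle: sqrt( (RSS/(n-2)) / sum (t - tbar)^2 ) from a brute-force fit
        r = np.random.default_rng(seed)
        t = np.sort(r.uniform(0, 5, size=n))
        if np.ptp(t) < 1e-3:
            return
        x = r.normal(size=n) + r.normal() * t
        a, x0, S2 = lg.fit_series(t, x)
        da = lg.slope_uncertainty(S2, float(np.std(t)), n)
        rss = ((x - (a * t + x0)) ** 2).sum()
        se_oracle = np.sqrt((rss / (n - 2)) / ((t - t.mean()) ** 2).sum())
        assert da == pytest.approx(se_oracle, rel=1e-9)


class TestConsistencyChi2:
    def test_zero_residual_variance_is_consistent(self):
        assert lg.consistency_chi2(0.0, 1.0, 5) == pytest.approx(1.0)

    def test_chi2_upper_five_percent_point(self):
        # n=12 -> df=10; RSS = 18.307 sigma^2 is the 5% critical point
        S2 = 18.307 / 12
        assert lg.consistency_chi2(S2, 1.0, 12) == pytest.approx(0.05, abs=2e-4)

    def test_null_calibration_uniform(self, rng):
        ps = []
        t = np.arange(8.0)
        for _ in range(2000):
            x = rng.normal(0, 1.0, size=8) + 0.3 * t
            _, _, S2 = lg.fit_series(t, x)
            ps.append(lg.consistency_chi2(S2, 1.0, 8))
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestSlopeTest:
    def test_zero_slope(self):
        assert lg.slope_test(0.0, 1.0) == pytest.approx(1.0)

    def test_196_sigma(self):
        assert lg.slope_test(1.96, 1.0) == pytest.approx(0.05, abs=1e-3)

    def test_noiseless_trend(self):
        assert lg.slope_test(-2.0, 0.0) == 0.0

    def test_invariance_under_shifts(self, rng):
        t = np.sort(rng.uniform(0, 5, size=8))
        x = rng.normal(size=8)
        a1, x01, S21 = lg.fit_series(t, x)
        a2, x02, S22 = lg.fit_series(t + 7.0, x + 3.0)
        assert a2 == pytest.approx(a1)
        assert S22 == pytest.approx(S21)
        da1 = lg.slope_uncertainty(S21, float(np.std(t)), 8)
        da2 = lg.slope_uncertainty(S22, float(np.std(t + 7.0)), 8)
        assert da2 == pytest.approx(da1)


class TestWelch:
    def test_identical_groups(self):
        assert lg.mean_position_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]) == 1.0

    def test_separated_groups(self):
        a = [0.0, 0.0, 0.0, 0.0]
        b = [5.0, 5.001, 4.999, 5.0]
        assert lg.mean_position_test(a, b) < 1e-3

    def test_type_one_error_calibrated(self, rng):
        hits = 0
        n_sim = 5000
        for _ in range(n_sim):
            a = rng.normal(size=6)
            b = rng.normal(size=30)
            if lg.mean_position_test(a, b) < 0.05:
                hits += 1
        rate = hits / n_sim
        assert abs(rate - 0.05) < 0.012


class TestSeriesOutlierRejection:
    def test_clean_series_all_kept(self):
        kept = lg.series_outlier_rejection([0, 1, 2, 3], [0.1, 0.0, -0.1, 0.05])
        assert list(kept) == [0, 1, 2, 3]

    def test_gross_outlier_rejected(self):
        kept = lg.series_outlier_rejection([0, 1, 2, 3], [0.1, 0.0, -0.1, 50.0])
        assert list(kept) == [0, 1, 2]

    def test_manual_exclusion_honored(self):
        kept = lg.series_outlier_rejection(
            [0, 1, 2, 3], [0.1, 0.0, -0.1, 0.05], manual_exclude=[3]
        )
        assert 3 not in kept

    def test_too_few_survivors(self):
        with pytest.raises(InsufficientDataError):
            lg.series_outlier_rejection([0, 1, 2], [0.0, 0.1, np.nan])


class TestClinicalTrend:
    def test_strictly_increasing_scores(self):
        _, _, rho, _ = lg.clinical_trend([0, 1, 2, 3], [1.0, 1.5, 2.0, 3.0])
        assert rho == pytest.approx(1.0)

    def test_constant_scores(self):
        rate, p_rate, rho, p_s = lg.clinical_trend([0, 1, 2, 3], [2.0] * 4)
        assert rate == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(rho) and np.isnan(p_s)

    def test_spearman_matches_bruteforce_permutation(self):
        times = [0.0, 0.5, 1.0, 1.5, 2.0, 2.5]
        scores = [2, 2, 2, 3, 3, 4]
        _, _, rho, p = lg.clinical_trend(times, scores)
        # oracle: enumerate all orderings of the score ranks
        xr = stats.rankdata(times)
        yr = stats.rankdata(scores)
        rho_obs = np.corrcoef(xr, yr)[0, 1]
        count = 0
        total = 0
        for perm in itertools.permutations(yr):
            r = np.corrcoef(xr, perm)[0, 1]
            count += abs(r) >= abs(rho_obs) - 1e-12
            total += 1
        assert rho == pytest.approx(rho_obs)
        assert p == pytest.approx(count / total)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValidationError):
            lg.clinical_trend([0, 0, 1], [1, 2, 3])


class TestAssessSeries:
    def test_injected_slope_detected_only_in_injected_keys(
        self, small_cohort, small_db
    ):
        from normorph import synthetic, table, db as dbm

        cfg, _, _ = small_cohort
        slopes = {k.as_string(): 0.0 for k in cfg.keys}
        injected = "insula|left|thickness_mean|raw"
        slopes[injected] = -0.05           # strong thinning vs sigma_meas 0.005
        pcfg = synthetic.PatientSeriesConfig(
            subject_id="pat2", baseline_age=40.0, n_visits=10, interval=0.55,
            slope_true=slopes, offset_true=0.0, sigma_meas_true=0.005,
            sex="F", scanner_model="Verio", sequence="MDEFT", seed=21,
        )
        ptab, pmeta, _ = synthetic.simulate_patient_series(pcfg, cfg)
        joined = table.join_metadata(ptab, pmeta)
        factors = next(
            (e.contrast_factors for e in small_db.entries.values() if e.contrast_factors),
            {},
        )
        augmented = dbm.derive_variants_with_reference(
            joined, small_db.etiv_ref, factors
        )
        res = lg.assess_series(small_db, augmented, alpha=0.05)
        flagged = set(res.loc[res["fdr_significant"], "key"])
        # the raw injected key and its derived siblings may flag; others must not
        assert injected in flagged
        assert all("insula|left|thickness_mean" in k or "insula|bilateral|thickness_mean" in k
                   for k in flagged)

    def test_manual_exclusion_reflected_in_counts(self, small_db, patient_series):
        _, augmented = patient_series
        key = "insula|left|thickness_mean|raw"
        res = lg.assess_series(
            small_db, augmented, manual_exclusions={key: ["v03"]}
        )
        row = res[res["key"] == key].iloc[0]
        other = res[res["key"] == "insula|right|thickness_mean|raw"].iloc[0]
        assert row["n_used"] <= other["n_used"] + 1  # exclusion plus possible IQR hits
        assert row["n_excluded"] >= 1

    def test_too_few_visits_rejected(self, small_db, patient_series):
        _, augmented = patient_series
        short = augmented.subset(augmented.frame["visit_id"].isin(["v01", "v02"]))
        with pytest.raises(ValidationError, match="single-visit"):
            lg.assess_series(small_db, short)
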