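"""Matched-subset scoring, p-value calibration, FDR, feature vectors."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from normorph import anomaly, db
from normorph.exceptions import InsufficientControlsError, ValidationError
from normorph.keys import SubjectMeta


def _meta(sex="F", scanner="Verio", sequence="MDEFT"):
    return SubjectMeta("p", "v1", 30.0, sex, scanner, sequence, 1.5e6, "patient")


class TestMatchControls:
    def test_exact_categorical_match(self, small_db):
        key = sorted(small_db.entries)[0]
        entry = small_db.entries[key]
        meta = _meta()
        subset = anomaly.match_controls(meta, entry, n_min=5)
        r = entry.residues
        expect = (
            (r["sex"] == "F") & (r["scanner_model"] == "Verio") & (r["sequence"] == "MDEFT")
        ).sum()
        assert subset.n_matched == expect
        assert subset.n_matched < len(r)   # non-matching controls exist

    def test_no_matching_sequence_raises(self, small_db):
        entry = small_db.entries[sorted(small_db.entries)[0]]
        with pytest.raises(InsufficientControlsError, match="n_min"):
            anomaly.match_controls(_meta(sequence="FLASH"), entry, n_min=5)

    def test_all_matching_returns_full_set(self, small_db):
        entry = small_db.entries[sorted(small_db.entries)[0]]
        r = entry.residues.copy()
        entry2 = type(entry)(**{**entry.__dict__})
        entry2.residues = r.assign(sex="F", scanner_model="Verio", sequence="MDEFT")
        subset = anomaly.match_controls(_meta(), entry2, n_min=5)
        assert subset.n_matched == len(r)


class TestVisitPvalue:
    def test_directional_tail_at_mean_is_half(self):
        assert anomaly.directional_tail_p(0.0, 0.0, 1.0) == pytest.approx(0.5)

    def test_directional_three_four_five(self):
        # sigma_norm 3, sigma_meas 4 -> combined sigma 5; one z above the mean
        p = anomaly.directional_tail_p(5.0, 0.0, 3.0, 4.0)
        assert p == pytest.approx(1 - stats.norm.cdf(1.0), abs=1e-9)
        assert p == pytest.approx(0.1587, abs=2e-4)

    def test_directional_five_percent_quantile(self):
        p = anomaly.directional_tail_p(-1.6449, 0.0, 1.0)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_two_sided_at_mean_is_one(self):
        assert anomaly.visit_pvalue(0.0, 0.0, 1.0) == pytest.approx(1.0)

    def test_two_sided_doubles_the_tail(self):
        assert anomaly.visit_pvalue(5.0, 0.0, 3.0, 4.0) == pytest.approx(
            2 * stats.norm.sf(1.0)
        )

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValidationError):
            anomaly.visit_pvalue(1.0, 0.0, 0.0)

    def test_tail_reflection_identities(self):
        # CDF-complement symmetry: upper-tail mass at +delta plus at -delta is 1,
        # and the directional p is reflection-symmetric about the normative mean
        for delta in (0.3, 1.1, 2.7):
            up_plus = stats.norm.sf(delta)
            up_minus = stats.norm.sf(-delta)
            assert up_plus + up_minus == pytest.approx(1.0)
            assert anomaly.directional_tail_p(delta, 0.0, 1.0) == pytest.approx(
                anomaly.directional_tail_p(-delta, 0.0, 1.0)
            )

    def test_null_pvalues_uniform(self, rng):
        # healthy-like draws from the matched normative distribution with
        # measurement noise: p_ucor must be Uniform(0,1)
        sigma_norm, sigma_meas = 1.0, 0.5
        x = rng.normal(0.0, np.hypot(sigma_norm, sigma_meas), size=10_000)
        p = [anomaly.visit_pvalue(v, 0.0, sigma_norm, sigma_meas) for v in x]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_more_measurement_error_weakens_evidence(self):
        x = 2.0
        p_dir = [anomaly.directional_tail_p(x, 0.0, 1.0, sm) for sm in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(p_dir, p_dir[1:]))
        assert all(p < 0.5 for p in p_dir)
        p_two = [anomaly.visit_pvalue(x, 0.0, 1.0, sm) for sm in (0.0, 0.5, 1.0, 2.0)]
        assert all(a < b for a, b in zip(p_two, p_two[1:]))


class TestFeatureVector:
    @pytest.mark.parametrize(
        "p,direction,expect",
        [(0.01, 1.0, 2.0), (1.0, 1.0, 0.0), (0.001, -1.0, -3.0), (1.0, 0.0, 0.0)],
    )
    def test_signed_log10(self, p, direction, expect):
        assert anomaly.feature_value(p, direction) == pytest.approx(expect)

    def test_reflection_negates_feature(self, rng):
        for _ in range(50):
            delta = rng.uniform(0.1, 3.0)
            p = anomaly.visit_pvalue(delta, 0.0, 1.0)
            lp = anomaly.feature_value(p, np.sign(delta))
            lm = anomaly.feature_value(anomaly.visit_pvalue(-delta, 0.0, 1.0), -1.0)
            assert lm == pytest.approx(-lp)


class TestFdrAndHighlight:
    def test_bh_worked_example(self):
        # thresholds i*alpha/m = 0.0125, 0.025, 0.0375, 0.05 -> all flagged
        flags = anomaly.fdr_flags([0.001, 0.02, 0.03, 0.04], alpha=0.05)
        assert flags.all()

    def test_flat_half_pvalues_unflagged(self):
        assert not anomaly.fdr_flags([0.5] * 6, alpha=0.05).any()

    def test_single_small_p_flagged(self):
        assert anomaly.fdr_flags([0.04], alpha=0.05).all()

    def test_nan_carried_as_unflagged(self):
        flags = anomaly.fdr_flags([0.001, np.nan, 0.7], alpha=0.05)
        assert list(flags) == [True, False, False]

    @pytest.mark.parametrize(
        "p,fdr,alpha,expect",
        [
            (0.2, False, 0.05, "none"),
            (0.004, False, 0.01, "yellow"),
            (0.004, True, 0.01, "red"),
            (np.nan, False, 0.05, "none"),
        ],
    )
    def test_highlight_levels(self, p, fdr, alpha, expect):
        assert anomaly.highlight_level(p, fdr, alpha) == expect


class TestFeatureCorrelation:
    def test_self_and_negated(self, rng):
        v = pd.Series(rng.normal(size=100))
        m = anomaly.feature_correlation_matrix(pd.DataFrame({"a": v, "b": -v}))
        assert m.loc["a", "a"] == pytest.approx(1.0)
        assert m.loc["a", "b"] == pytest.approx(-1.0)

    def test_too_few_shared_entries_missing(self, rng):
        a = pd.Series([1.0, 2.0, np.nan, np.nan, np.nan])
        b = pd.Series([np.nan, 2.0, 1.0, np.nan, np.nan])
        m = anomaly.feature_correlation_matrix(pd.DataFrame({"a": a, "b": b}))
        assert np.isnan(m.loc["a", "b"])

    def test_null_mean_absolute_correlation(self, rng):
        # independent standard-normal vectors of the full feature length:
        # E|r| = sqrt(2/pi)/sqrt(n) ~ 0.0146 at n = 2976
        n, m = 2976, 100
        vecs = pd.DataFrame(rng.standard_normal((n, m)))
        corr = anomaly.feature_correlation_matrix(vecs).to_numpy()
        off = corr[~np.eye(m, dtype=bool)]
        assert np.mean(np.abs(off)) == pytest.approx(np.sqrt(2 / np.pi) / np.sqrt(n), rel=0.1)


class TestAssessVisit:
    def test_healthy_like_visit_mostly_unremarkable(self, small_db, patient_series):
        _, augmented = patient_series
        one = augmented.subset(augmented.frame["visit_id"] == "v01")
        res = anomaly.assess_visit(small_db, one, alpha=0.05)
        assert len(res) == 20
        assert (res["skip_reason"] != "").sum() == 0
        assert (res["highlight"] == "red").sum() == 0

    def test_injected_extreme_value_goes_red(self, small_db, patient_series):
        _, augmented = patient_series
        one = augmented.subset(augmented.frame["visit_id"] == "v01")
        f = one.frame.copy()
        key = "insula|left|thickness_mean|raw"
        hit = (
            (f["region"] == "insula") & (f["hemisphere"] == "left")
            & (f["parameter"] == "thickness_mean") & (f["variant"] == "raw")
        )
        entry = small_db.entries[
            [k for k in small_db.entries if k.as_string() == key][0]
        ]
        f.loc[hit, "value"] += 8 * entry.sigma_norm_all
        res = anomaly.assess_visit(small_db, type(one)(f), alpha=0.05)
        row = res[res["key"] == key].iloc[0]
        assert row["highlight"] == "red"
        assert row["L"] > 4

    def test_empty_table_rejected(self, small_db, patient_series):
        _, augmented = patient_series
        empty = augmented.subset(augmented.frame["visit_id"] == "nope")
        with pytest.raises(ValidationError):
            anomaly.assess_visit(small_db, empty)
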