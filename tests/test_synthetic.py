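"""Generator determinism, moment recovery, and known-truth identities."""

import numpy as np
import pandas as pd
import pytest

from normorph import synthetic, table
from normorph.exceptions import ValidationError
from normorph.keys import MeasurementKey


def _cfg(**kw):
    base = dict(
        n_subjects=60,
        keys=synthetic.default_keys(3),
        sigma_norm_true=1.0,
        sigma_meas_true=0.2,
        artifact_fraction=0.0,
        artifact_sigma_true=5.0,
        n_repeat_subjects=10,
        seed=5,
    )
    base.update(kw)
    return synthetic.CohortConfig(**base)


class TestCohort:
    def test_same_seed_bit_identical(self):
        t1, m1, _ = synthetic.simulate_cohort(_cfg())
        t2, m2, _ = synthetic.simulate_cohort(_cfg())
        pd.testing.assert_frame_equal(t1.frame, t2.frame)
        pd.testing.assert_frame_equal(m1, m2)

    def test_different_seed_differs(self):
        t1, _, _ = synthetic.simulate_cohort(_cfg())
        t2, _, _ = synthetic.simulate_cohort(_cfg(seed=6))
        assert not t1.frame["value"].equals(t2.frame["value"])

    def test_noiseless_repeats_share_subject_effect(self):
        # constant trend, no measurement noise: a subject's repeat visits
        # must produce identical values
        cfg = _cfg(
            sigma_meas_true=0.0,
            trend_coeffs={k.as_string(): [5.0] for k in synthetic.default_keys(3)},
        )
        tab, meta, _ = synthetic.simulate_cohort(cfg)
        j = table.join_metadata(tab, meta).frame
        for (_, _), grp in j.groupby(["subject_id", "region"]):
            assert grp["value"].nunique() == 1

    def test_residue_sd_matches_configured(self):
        cfg = _cfg(n_subjects=2000, sigma_meas_true=0.0, n_repeat_subjects=0,
                   keys=synthetic.default_keys(1),
                   trend_coeffs={"region_0000|none|volume|raw": [5.0]})
        tab, _, truth = synthetic.simulate_cohort(cfg)
        sd = tab.frame["value"].std(ddof=1)
        assert sd == pytest.approx(1.0, rel=0.05)

    def test_repeat_pair_within_sd_converges(self):
        cfg = _cfg(n_subjects=600, n_repeat_subjects=600, sigma_meas_true=0.5)
        tab, meta, _ = synthetic.simulate_cohort(cfg)
        j = table.join_metadata(tab, meta).frame
        one = j[j["region"] == "region_0000"].sort_values(["subject_id", "visit_id"])
        wide = one.pivot(index="subject_id", columns="visit_id", values="value").dropna()
        diffs = wide["v02"] - wide["v01"]
        # trend is linear in age with small slope; difference SD ~ sqrt(2)*sigma_meas
        within_sd = diffs.std(ddof=1) / np.sqrt(2)
        assert within_sd == pytest.approx(0.5, rel=0.08)

    def test_artifact_measurements_have_wide_marginal_sd(self):
        cfg = _cfg(n_subjects=3000, artifact_fraction=0.2, artifact_sigma_true=5.0,
                   n_repeat_subjects=0, keys=synthetic.default_keys(1),
                   trend_coeffs={"region_0000|none|volume|raw": [0.0]})
        tab, _, truth = synthetic.simulate_cohort(cfg)
        flags = truth.artifact_flags.set_index(["subject_id", "visit_id"])["is_artifact"]
        f = tab.frame.set_index(["subject_id", "visit_id"])
        art = f.loc[flags[flags].index, "value"]
        ok = f.loc[flags[~flags].index, "value"]
        assert art.std(ddof=1) == pytest.approx(5.0, rel=0.1)
        assert ok.std(ddof=1) == pytest.approx(np.hypot(1.0, 0.2), rel=0.1)

    def test_degenerate_age_range_rejected(self):
        with pytest.raises(ValidationError):
            _cfg(age_range=(30.0, 30.0))

    def test_artifact_fraction_bounds(self):
        with pytest.raises(ValidationError):
            _cfg(artifact_fraction=0.6)


class TestPatientSeries:
    def test_noiseless_zero_slope_recovered_exactly(self):
        cfg = _cfg()
        pcfg = synthetic.PatientSeriesConfig(
            n_visits=10, slope_true=0.0, sigma_meas_true=0.0, seed=1
        )
        tab, meta, _ = synthetic.simulate_patient_series(pcfg, cfg)
        one = tab.frame[tab.frame["region"] == "region_0000"]
        ages = meta["age"].to_numpy()
        truth = np.polynomial.polynomial.polyval(
            ages, np.asarray(cfg.trend_coeffs["region_0000|none|volume|raw"])
        )
        resid = one["value"].to_numpy() - truth
        slope = np.polyfit(ages, resid, 1)[0]
        assert slope == pytest.approx(0.0, abs=1e-10)

    def test_noiseless_injected_slope_recovered_exactly(self):
        cfg = _cfg()
        pcfg = synthetic.PatientSeriesConfig(
            n_visits=10, slope_true=-2.0, sigma_meas_true=0.0, seed=1
        )
        tab, meta, _ = synthetic.simulate_patient_series(pcfg, cfg)
        one = tab.frame[tab.frame["region"] == "region_0000"]
        t = np.arange(10) * pcfg.interval
        truth = np.polynomial.polynomial.polyval(
            meta["age"].to_numpy(),
            np.asarray(cfg.trend_coeffs["region_0000|none|volume|raw"]),
        )
        resid = one["value"].to_numpy() - truth
        slope = np.polyfit(t, resid, 1)[0]
        assert slope == pytest.approx(-2.0, abs=1e-10)

    def test_noisy_slope_estimator_unbiased(self):
        # parameter recovery: mean fitted slope over many seeds within the
        # standard error band of the true slope
        cfg = _cfg(keys=synthetic.default_keys(1),
                   trend_coeffs={"region_0000|none|volume|raw": [5.0]})
        slopes = []
        n_runs = 200
        for seed in range(n_runs):
            pcfg = synthetic.PatientSeriesConfig(
                n_visits=10, slope_true=-2.0, sigma_meas_true=1.0, seed=seed
            )
            tab, meta, _ = synthetic.simulate_patient_series(pcfg, cfg)
            t = np.arange(10) * pcfg.interval
            resid = tab.frame["value"].to_numpy() - 5.0
            slopes.append(np.polyfit(t, resid, 1)[0])
        t = np.arange(10) * 0.55
        se_single = 1.0 / np.sqrt(((t - t.mean()) ** 2).sum())
        assert np.mean(slopes) == pytest.approx(-2.0, abs=3 * se_single / np.sqrt(n_runs))

    def test_too_few_visits_rejected(self):
        with pytest.raises(ValidationError):
            synthetic.PatientSeriesConfig(n_visits=2)


class TestConfigIO:
    def test_yaml_roundtrip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text(
            "n_subjects: 40\n"
            "seed: 9\n"
            "keys: ['hippo|left|volume|raw']\n"
            "trend_coeffs:\n  'hippo|left|volume|raw': [4000.0, -5.0]\n"
            "sigma_norm_true: 150.0\n"
            "scanner_sequence_mix:\n  'Verio||MDEFT': 1.0\n"
        )
        cfg = synthetic.load_cohort_config(p)
        assert cfg.n_subjects == 40
        assert cfg.keys == [MeasurementKey("hippo", "left", "volume", "raw")]
        tab, _, _ = synthetic.simulate_cohort(cfg)
        assert len(tab) > 0

    def test_snapshot_is_json_serializable(self):
        import json

        snap = synthetic.config_snapshot(_cfg())
        json.dumps(snap)
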