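"""Shared fixtures: small synthetic cohorts and a prebuilt normative database."""

import numpy as np
import pytest

from normorph import synthetic, table, db
from normorph.keys import MeasurementKey


@pytest.fixture(scope="session")
def paired_keys():
    """Left/right thickness and contrast keys for two cortical regions."""
    keys = []
    for region in ("superiorfrontal", "insula"):
        for hemi in ("left", "right"):
            keys.append(MeasurementKey(region, hemi, "thickness_mean", "raw"))
            keys.append(MeasurementKey(region, hemi, "gw_contrast", "raw"))
    return keys


@pytest.fixture(scope="session")
def small_cohort(paired_keys):
    """150-subject cohort with repeats, mild artifacts, and paired keys."""
    cfg = synthetic.CohortConfig(
        n_subjects=150,
        keys=list(paired_keys),
        trend_coeffs={
            k.as_string(): ([2.5, -0.003] if k.parameter == "thickness_mean" else [20.0, -0.01])
            for k in paired_keys
        },
        sigma_norm_true=0.1,
        sigma_meas_true=0.02,
        artifact_fraction=0.01,
        artifact_sigma_true=1.0,
        n_repeat_subjects=20,
        seed=7,
    )
    tab, meta, truth = synthetic.simulate_cohort(cfg)
    joined = table.join_metadata(tab, meta)
    return cfg, joined, truth


@pytest.fixture(scope="session")
def small_db(small_cohort):
    cfg, joined, _ = small_cohort
    return db.build_normative_db(joined, seed=cfg.seed)


@pytest.fixture(scope="session")
def patient_series(small_cohort, small_db):
    """Noiseless-trend patient with a 10-visit follow-up series, joined + variants."""
    cfg, _, _ = small_cohort
    pcfg = synthetic.PatientSeriesConfig(
        subject_id="pat", baseline_age=35.0, n_visits=10, interval=0.55,
        slope_true=0.0, offset_true=0.0, sigma_meas_true=0.02,
        sex="F", scanner_model="Verio", sequence="MDEFT", seed=9,
    )
    ptab, pmeta, ptruth = synthetic.simulate_patient_series(pcfg, cfg)
    joined = table.join_metadata(ptab, pmeta)
    factors = next(
        (e.contrast_factors for e in small_db.entries.values() if e.contrast_factors), {}
    )
    augmented = db.derive_variants_with_reference(joined, small_db.etiv_ref, factors)
    return pcfg, augmented


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
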