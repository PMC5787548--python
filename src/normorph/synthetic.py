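"""Synthetic normative cohorts and patient follow-up series with known truth.

The generator emulates the statistical structure the pipeline assumes:

* per-key polynomial age trends with additive sex and scanner-sequence
  offsets;
* a Gaussian between-subject effect (shared across a subject's visits, so
  repeat scans estimate measurement error rather than population spread)
  plus Gaussian within-subject measurement noise;
* a wide-Gaussian artifact component: with probability ``artifact_fraction``
  a measurement's residue is *replaced* by a zero-centered draw of width
  ``artifact_sigma_true`` (artifacts can occur at any magnitude, including
  inconspicuous ones inside the outlier fences);
* a subset of subjects rescanned within two years, feeding the
  scan-rescan reliability estimator;
* patient follow-up series as normative trend + baseline offset + linear
  slope deviation + noise.

Ages are uniform over the configured range — calibration tests need age
coverage, not demographic realism — and keys are generated independently
(no inter-regional correlation).  Identical config + seed gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import ValidationError
from .keys import MeasurementKey
from .table import VALUE_COLS, MorphTable

#: default scanner-sequence site mix (two scanners, three sequences)
DEFAULT_SCANNER_MIX = {
    ("Verio", "MDEFT"): 0.30,
    ("Verio", "MPRAGE_vdK"): 0.22,
    ("Trio", "MDEFT"): 0.23,
    ("Trio", "MPRAGE_ADNI"): 0.25,
}


@dataclass
class CohortConfig:
    """Generating conditions of a normative cohort.

    Defaults mirror a single-site normative database: 323 subjects aged
    7-79, 56% female, 31 subjects rescanned within two years, and a small
    wide-Gaussian artifact contamination.
    """

    n_subjects: int = 323
    age_range: tuple[float, float] = (7.0, 79.0)
    sex_ratio: float = 0.563          # female fraction
    scanner_sequence_mix: dict = field(default_factory=lambda: dict(DEFAULT_SCANNER_MIX))
    keys: list[MeasurementKey] = field(default_factory=list)
    trend_coeffs: dict = field(default_factory=dict)   # key string -> [c0, c1, ...]
    sigma_norm_true: float | dict = 1.0
    sigma_meas_true: float | dict = 0.3
    artifact_fraction: float = 0.015
    artifact_sigma_true: float | dict = 6.0
    sex_offset: float | dict = 0.0     # added for male subjects
    scanner_offsets: dict = field(default_factory=dict)  # (scanner, seq) -> offset
    n_repeat_subjects: int = 31
    repeat_separation: tuple[float, float] = (0.25, 1.75)
    etiv_mean: float = 1.55e6          # mm^3
    etiv_sd: float = 1.3e5
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.age_range
        if hi <= lo:
            raise ValidationError("degenerate age range")
        if not 0.0 <= self.artifact_fraction < 0.5:
            raise ValidationError("artifact_fraction must be in [0, 0.5)")
        if not self.keys:
            self.keys = default_keys(4)
        for k in self.keys:
            ks = k.as_string()
            self.trend_coeffs.setdefault(ks, [10.0, 0.05])
        for name in ("sigma_norm_true", "sigma_meas_true", "artifact_sigma_true"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, dict) else [v]
            if any(x < 0 for x in vals) or (
                name != "sigma_meas_true" and any(x <= 0 for x in vals)
            ):
                raise ValidationError(f"{name} must be positive")

    def per_key(self, attr: str, key: MeasurementKey) -> float:
        v = getattr(self, attr)
        return float(v[key.as_string()]) if isinstance(v, dict) else float(v)


@dataclass
class PatientSeriesConfig:
    """Generating conditions of one patient's follow-up series."""

    subject_id: str = "patient"
    baseline_age: float = 30.0
    n_visits: int = 10
    interval: float = 0.55            # years between scans
    slope_true: float | dict = 0.0    # units/year deviation from the normative trend
    offset_true: float | dict = 0.0   # baseline residue
    sigma_meas_true: float | dict = 0.0
    sex: str = "F"
    scanner_model: str = "Verio"
    sequence: str = "MPRAGE_vdK"
    etiv: float = 1.5e6
    seed: int = 0

    def __post_init__(self):
        if self.n_visits < 3:
            raise ValidationError("follow-up series needs n_visits >= 3")
        if self.interval <= 0:
            raise ValidationError("interval must be positive")


@dataclass
class GroundTruth:
    """Per-measurement generating truth for downstream recovery checks."""

    trend_coeffs: dict
    sigma_norm_true: dict
    sigma_meas_true: dict
    artifact_flags: pd.DataFrame      # subject_id, visit_id, key, is_artifact
    subject_effects: pd.DataFrame     # subject_id, key, effect
    slopes_true: dict = field(default_factory=dict)
    offsets_true: dict = field(default_factory=dict)


def default_keys(n: int, parameter: str = "volume") -> list[MeasurementKey]:
    """n independent synthetic region keys (volume parameter, no hemisphere)."""
    return [
        MeasurementKey(f"region_{i:04d}", "none", parameter, "raw") for i in range(n)
    ]


def _poly(coeffs, age):
    return np.polynomial.polynomial.polyval(age, np.asarray(coeffs, dtype=float))


def simulate_cohort(config: CohortConfig):
    """Generate (MorphTable, metadata frame, GroundTruth) for a control cohort."""
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    lo, hi = config.age_range

    subject_ids = np.array([f"hc{i:04d}" for i in range(n)])
    ages = rng.uniform(lo, hi, size=n)
    sexes = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    combos = list(config.scanner_sequence_mix)
    weights = np.array([config.scanner_sequence_mix[c] for c in combos], dtype=float)
    weights = weights / weights.sum()
    combo_idx = rng.choice(len(combos), size=n, p=weights)
    etiv = np.abs(rng.normal(config.etiv_mean, config.etiv_sd, size=n)) + 1.0

    # visit layout: everyone has visit v01; the first n_repeat_subjects get v02
    n_rep = min(config.n_repeat_subjects, n)
    sep = rng.uniform(*config.repeat_separation, size=n_rep)
    vis_subject, vis_id, vis_age = [], [], []
    for i in range(n):
        vis_subject.append(i), vis_id.append("v01"), vis_age.append(ages[i])
        if i < n_rep:
            vis_subject.append(i), vis_id.append("v02"), vis_age.append(ages[i] + sep[i])
    vis_subject = np.array(vis_subject)
    vis_age = np.array(vis_age)
    n_vis = vis_subject.size

    meta = pd.DataFrame(
        {
            "subject_id": subject_ids[vis_subject],
            "visit_id": vis_id,
            "age": vis_age,
            "sex": sexes[vis_subject],
            "scanner_model": [combos[j][0] for j in combo_idx[vis_subject]],
            "sequence": [combos[j][1] for j in combo_idx[vis_subject]],
            "etiv": etiv[vis_subject],
            "group": "control",
        }
    )

    male = (sexes == "M").astype(float)
    frames = []
    art_frames = []
    eff_frames = []
    tc, sn, sm = {}, {}, {}
    for key in config.keys:
        ks = key.as_string()
        coeffs = config.trend_coeffs[ks]
        s_norm = config.per_key("sigma_norm_true", key)
        s_meas = config.per_key("sigma_meas_true", key)
        s_art = config.per_key("artifact_sigma_true", key)
        tc[ks], sn[ks], sm[ks] = list(coeffs), s_norm, s_meas

        subj_eff = rng.normal(0.0, s_norm, size=n)
        noise = rng.normal(0.0, s_meas, size=n_vis) if s_meas > 0 else np.zeros(n_vis)
        is_art = rng.random(n_vis) < config.artifact_fraction
        art_draw = rng.normal(0.0, s_art, size=n_vis)

        sex_off = config.per_key("sex_offset", key) * male[vis_subject]
        sc_off = np.array(
            [
                config.scanner_offsets.get(combos[j], 0.0)
                for j in combo_idx[vis_subject]
            ]
        )
        trend = _poly(coeffs, vis_age)
        resid = np.where(is_art, art_draw, subj_eff[vis_subject] + noise)
        values = trend + sex_off + sc_off + resid

        frames.append(
            pd.DataFrame(
                {
                    "subject_id": meta["subject_id"],
                    "visit_id": meta["visit_id"],
                    "region": key.region,
                    "hemisphere": key.hemisphere,
                    "parameter": key.parameter,
                    "variant": key.variant,
                    "value": values,
                }
            )
        )
        art_frames.append(
            pd.DataFrame(
                {
                    "subject_id": meta["subject_id"],
                    "visit_id": meta["visit_id"],
                    "key": ks,
                    "is_artifact": is_art,
                }
            )
        )
        eff_frames.append(
            pd.DataFrame({"subject_id": subject_ids, "key": ks, "effect": subj_eff})
        )

    table = MorphTable(pd.concat(frames, ignore_index=True)[VALUE_COLS])
    truth = GroundTruth(
        trend_coeffs=tc,
        sigma_norm_true=sn,
        sigma_meas_true=sm,
        artifact_flags=pd.concat(art_frames, ignore_index=True),
        subject_effects=pd.concat(eff_frames, ignore_index=True),
    )
    return table, meta, truth


def simulate_patient_series(config: PatientSeriesConfig, cohort_config: CohortConfig):
    """Generate one patient's follow-up series on top of the cohort's trends."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_visits) * config.interval
    ages = config.baseline_age + t
    visit_ids = [f"v{i + 1:02d}" for i in range(config.n_visits)]

    meta = pd.DataFrame(
        {
            "subject_id": config.subject_id,
            "visit_id": visit_ids,
            "age": ages,
            "sex": config.sex,
            "scanner_model": config.scanner_model,
            "sequence": config.sequence,
            "etiv": config.etiv,
            "group": "patient",
        }
    )
    frames = []
    slopes, offsets = {}, {}
    for key in cohort_config.keys:
        ks = key.as_string()
        coeffs = cohort_config.trend_coeffs[ks]
        slope = (
            float(config.slope_true[ks])
            if isinstance(config.slope_true, dict)
            else float(config.slope_true)
        )
        offset = (
            float(config.offset_true[ks])
            if isinstance(config.offset_true, dict)
            else float(config.offset_true)
        )
        s_meas = (
            float(config.sigma_meas_true[ks])
            if isinstance(config.sigma_meas_true, dict)
            else float(config.sigma_meas_true)
        )
        slopes[ks], offsets[ks] = slope, offset
        noise = rng.normal(0.0, s_meas, size=config.n_visits) if s_meas > 0 else 0.0
        values = _poly(coeffs, ages) + offset + slope * t + noise
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": config.subject_id,
                    "visit_id": visit_ids,
                    "region": key.region,
                    "hemisphere": key.hemisphere,
                    "parameter": key.parameter,
                    "variant": key.variant,
                    "value": values,
                }
            )
        )
    table = MorphTable(pd.concat(frames, ignore_index=True)[VALUE_COLS])
    truth = GroundTruth(
        trend_coeffs={k: list(v) for k, v in cohort_config.trend_coeffs.items()},
        sigma_norm_true={},
        sigma_meas_true={},
        artifact_flags=pd.DataFrame(
            columns=["subject_id", "visit_id", "key", "is_artifact"]
        ),
        subject_effects=pd.DataFrame(columns=["subject_id", "key", "effect"]),
        slopes_true=slopes,
        offsets_true=offsets,
    )
    return table, meta, truth


def realistic_cohort_config(
    n_keys: int,
    seed: int,
    n_subjects: int = 323,
    sigma_meas_true: float = 0.3,
    artifact_fraction: float = 0.015,
    single_site: bool = False,
) -> CohortConfig:
    """A cohort config with a mix of constant, linear and quadratic age trends.

    Trend shapes rotate deterministically over keys; amplitudes are chosen so
    the trend spans a few normative SDs over the age range, as regional
    morphometry does.  ``single_site`` collapses the scanner-sequence mix to
    one combination (maximal matched-control counts for calibration studies).
    """
    keys = default_keys(n_keys)
    trends = {}
    for i, k in enumerate(keys):
        shape = i % 3
        if shape == 0:
            trends[k.as_string()] = [10.0]
        elif shape == 1:
            trends[k.as_string()] = [12.0, -0.04]            # ~3 SD drop over 72 y
        else:
            # rise-then-decline: linear + concave parts both a few SD strong,
            # as cortical measures behave (monotone segments, no pure parabola)
            trends[k.as_string()] = [6.0, 0.18, -0.0018]
    mix = {("Verio", "MPRAGE_vdK"): 1.0} if single_site else dict(DEFAULT_SCANNER_MIX)
    return CohortConfig(
        n_subjects=n_subjects,
        keys=keys,
        trend_coeffs=trends,
        sigma_norm_true=1.0,
        sigma_meas_true=sigma_meas_true,
        artifact_fraction=artifact_fraction,
        artifact_sigma_true=6.0,
        scanner_sequence_mix=mix,
        seed=seed,
    )


# ------------------------------------------------------------------ config IO

def load_cohort_config(path) -> CohortConfig:
    """Read a flat YAML cohort config; keys listed as strings are parsed."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if "keys" in raw:
        raw["keys"] = [MeasurementKey.from_string(s) for s in raw["keys"]]
    if "age_range" in raw:
        raw["age_range"] = tuple(raw["age_range"])
    if "scanner_sequence_mix" in raw:
        raw["scanner_sequence_mix"] = {
            tuple(k.split("||")): v for k, v in raw["scanner_sequence_mix"].items()
        }
    return CohortConfig(**raw)


def config_snapshot(config) -> dict:
    """JSON-serializable snapshot of a config dataclass for provenance."""
    d = asdict(config)
    for k, v in list(d.items()):
        if k == "keys":
            d[k] = [
                "|".join((x["region"], x["hemisphere"], x["parameter"], x["variant"]))
                if isinstance(x, dict) else str(x)
                for x in v
            ]
        elif isinstance(v, dict):
            d[k] = {("||".join(kk) if isinstance(kk, tuple) else str(kk)): vv
                    for kk, vv in v.items()}
        elif isinstance(v, tuple):
            d[k] = list(v)
    return d
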