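"""The normative database: per-key age models, residues, reliability, artifacts.

Building the database from a joined healthy-control table performs, per
measurement key: two-pass IQR outlier rejection with polynomial age-trend
fitting (degree chosen by Bonferroni-corrected nested F-tests), storage of
the kept residues with their visit metadata, pooled measurement-error
estimation from short-interval repeat scans, and the artifact model
(sigma_out, p_out, p_art, odds) derived from the rejected outliers.

Variant augmentation happens before fitting: every eligible raw key gains a
``normalized`` sibling (eTIV-scaled, or scanner-sequence mean-equalized for
the gray-white contrast) and every left/right pair a bilateral
``asymmetry`` sibling.

Persistence is a single JSON archive (schema-versioned manifest plus
tabular payloads).  Python's shortest-repr float serialization makes the
round trip bit-exact.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import age_model, normalization, reliability
from .exceptions import (
    InsufficientDataError,
    IntegrityError,
    SchemaVersionError,
    ValidationError,
)
from .keys import MeasurementKey
from .table import META_COLS, MorphTable

logger = logging.getLogger(__name__)

SCHEMA_VERSION = "normorph-db-1"

_RESIDUE_COLS = [
    "subject_id", "visit_id", "age", "sex", "scanner_model", "sequence",
    "residue", "trunc_lower", "trunc_upper",
]


@dataclass
class NormativeEntry:
    """Everything the pipeline knows about one measurement key."""

    key: MeasurementKey
    model: age_model.PolynomialModel
    raw_bounds: age_model.OutlierBounds
    resid_bounds: age_model.OutlierBounds
    n_kept: int
    n_rejected_raw: int
    n_rejected_residual: int
    sigma_norm_all: float
    sigma_norm_corrected: float
    age_min: float
    age_max: float
    residues: pd.DataFrame            # kept-HC residues with visit metadata
    rel: reliability.ReliabilityEstimate
    art: reliability.ArtifactModel
    contrast_factors: dict[str, float] | None = None

    def predict(self, age):
        return self.model.predict(age)


@dataclass
class NormativeDB:
    entries: dict[MeasurementKey, NormativeEntry]
    etiv_ref: float
    n_hc_subjects: int
    n_hc_visits: int
    seed: int | None = None
    alpha_fit: float = 0.05
    config_snapshot: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def __getitem__(self, key: MeasurementKey) -> NormativeEntry:
        return self.entries[key]

    def __len__(self) -> int:
        return len(self.entries)


def derive_variants(table: MorphTable) -> MorphTable:
    """Append normalized and asymmetry variant records to a joined table.

    eTIV reference is the mean eTIV over the control visits of the table;
    contrast factors are likewise derived from controls only and applied to
    every record (patients are scaled by their own group's HC factor).
    """
    if not table.has_metadata:
        raise ValidationError("variant derivation requires joined metadata")
    f = table.frame
    raw = f[f["variant"] == "raw"]
    hc = raw[raw["group"] == "control"]
    if hc.empty:
        raise ValidationError("no control records to derive normalization references from")
    etiv_ref = float(hc.drop_duplicates(["subject_id", "visit_id"])["etiv"].mean())

    pieces = [f]

    # ---- eTIV-normalized / contrast-normalized variant
    norm = raw.copy()
    expo = norm["parameter"].map(
        {p: (float(e) if e is not None else np.nan)
         for p, e in normalization.SCALING_EXPONENTS.items()}
    )
    with np.errstate(invalid="ignore"):
        scaled = norm["value"].to_numpy() * (
            etiv_ref / norm["etiv"].to_numpy()
        ) ** expo.to_numpy()
    is_contrast = (norm["parameter"] == "gw_contrast").to_numpy()
    if is_contrast.any():
        labels = normalization.scanner_sequence_label(
            norm["scanner_model"], norm["sequence"]
        ).to_numpy()
        hc_con = norm[(norm["parameter"] == "gw_contrast")]
        hc_mask = (hc_con["group"] == "control").to_numpy()
        factors = normalization.contrast_factors(
            hc_con["value"].to_numpy()[hc_mask],
            normalization.scanner_sequence_label(
                hc_con["scanner_model"], hc_con["sequence"]
            ).to_numpy()[hc_mask],
        )
        fac = np.array(
            [factors.get(g, np.nan) if m else 1.0 for g, m in zip(labels, is_contrast)]
        )
        unmatched = is_contrast & np.isnan(fac) & np.isfinite(norm["value"].to_numpy())
        if unmatched.any():
            combos = sorted(set(labels[unmatched]))
            raise ValidationError(
                f"scanner-sequence combination(s) {combos} absent from the control set"
            )
        scaled = np.where(is_contrast, norm["value"].to_numpy() * fac, scaled)
    else:
        factors = {}
    norm["value"] = scaled
    norm["variant"] = "normalized"
    pieces.append(norm[f.columns])

    # ---- asymmetry variant from raw left/right pairs
    sided = raw[raw["hemisphere"].isin(["left", "right"])]
    if not sided.empty:
        wide = sided.pivot_table(
            index=["subject_id", "visit_id", "region", "parameter"],
            columns="hemisphere", values="value", aggfunc="first", dropna=False,
        )
        if "left" in wide.columns and "right" in wide.columns:
            both = wide.dropna(how="all").reset_index()
            ai = normalization.asymmetry_index(
                both["right"].to_numpy(), both["left"].to_numpy()
            )
            asym = both[["subject_id", "visit_id", "region", "parameter"]].copy()
            asym["hemisphere"] = "bilateral"
            asym["variant"] = "asymmetry"
            asym["value"] = ai
            meta = f.drop_duplicates(["subject_id", "visit_id"])[
                ["subject_id", "visit_id"] + META_COLS
            ]
            asym = asym.merge(meta, on=["subject_id", "visit_id"], how="left")
            pieces.append(asym[f.columns])

    out = MorphTable(pd.concat(pieces, ignore_index=True))
    out.etiv_ref = etiv_ref           # reference frozen at derivation time
    out.contrast_factors = factors
    return out


def derive_variants_with_reference(
    table: MorphTable, etiv_ref: float, contrast_factors: dict[str, float]
) -> MorphTable:
    """Variant augmentation for patient tables using DB-frozen references.

    Unlike :func:`derive_variants`, the eTIV reference and the contrast
    factors come from the normative database, so a patient never influences
    their own normalization.
    """
    if not table.has_metadata:
        raise ValidationError("variant derivation requires joined metadata")
    f = table.frame
    raw = f[f["variant"] == "raw"]
    pieces = [f]

    norm = raw.copy()
    expo = norm["parameter"].map(
        {p: (float(e) if e is not None else np.nan)
         for p, e in normalization.SCALING_EXPONENTS.items()}
    )
    with np.errstate(invalid="ignore"):
        scaled = norm["value"].to_numpy() * (
            etiv_ref / norm["etiv"].to_numpy()
        ) ** expo.to_numpy()
    is_contrast = (norm["parameter"] == "gw_contrast").to_numpy()
    if is_contrast.any():
        labels = normalization.scanner_sequence_label(
            norm["scanner_model"], norm["sequence"]
        ).to_numpy()
        fac = np.ones(len(norm))
        for i in np.flatnonzero(is_contrast):
            if np.isfinite(norm["value"].to_numpy()[i]):
                fac[i] = normalization.apply_contrast_factor(
                    1.0, labels[i], contrast_factors or {}
                )
        scaled = np.where(is_contrast, norm["value"].to_numpy() * fac, scaled)
    norm["value"] = scaled
    norm["variant"] = "normalized"
    pieces.append(norm[f.columns])

    sided = raw[raw["hemisphere"].isin(["left", "right"])]
    if not sided.empty:
        wide = sided.pivot_table(
            index=["subject_id", "visit_id", "region", "parameter"],
            columns="hemisphere", values="value", aggfunc="first", dropna=False,
        )
        if "left" in wide.columns and "right" in wide.columns:
            both = wide.dropna(how="all").reset_index()
            ai = normalization.asymmetry_index(
                both["right"].to_numpy(), both["left"].to_numpy()
            )
            asym = both[["subject_id", "visit_id", "region", "parameter"]].copy()
            asym["hemisphere"] = "bilateral"
            asym["variant"] = "asymmetry"
            asym["value"] = ai
            meta = f.drop_duplicates(["subject_id", "visit_id"])[
                ["subject_id", "visit_id"] + META_COLS
            ]
            asym = asym.merge(meta, on=["subject_id", "visit_id"], how="left")
            pieces.append(asym[f.columns])

    return MorphTable(pd.concat(pieces, ignore_index=True))


def build_normative_db(
    table: MorphTable,
    alpha_fit: float = 0.05,
    seed: int | None = None,
    with_variants: bool = True,
    config_snapshot: dict | None = None,
) -> NormativeDB:
    """Fit the full normative database from a metadata-joined control table."""
    if not table.has_metadata:
        raise ValidationError("build_normative_db requires joined metadata")
    hc = table.subset(table.frame["group"] == "control")
    if len(hc) == 0:
        raise ValidationError("no control records in input table")
    if with_variants:
        hc = derive_variants(hc)
        etiv_ref = hc.etiv_ref
        factors = hc.contrast_factors
    else:
        raw = hc.frame
        etiv_ref = float(
            raw.drop_duplicates(["subject_id", "visit_id"])["etiv"].mean()
        )
        factors = {}

    frame = hc.frame
    keystr = hc.key_strings()
    entries: dict[MeasurementKey, NormativeEntry] = {}
    skipped = 0
    for ks, sub in frame.groupby(keystr.to_numpy(), sort=True):
        key = MeasurementKey.from_string(ks)
        try:
            fit = age_model.fit_age_trend(
                sub["age"].to_numpy(), sub["value"].to_numpy(), alpha_fit
            )
        except InsufficientDataError as exc:
            logger.warning("key %s skipped: %s", ks, exc)
            skipped += 1
            continue
        kept = sub.iloc[fit.kept]
        residues = kept[["subject_id", "visit_id", "age", "sex",
                         "scanner_model", "sequence"]].copy()
        residues["residue"] = fit.residues
        residues["trunc_lower"] = fit.trunc_lower
        residues["trunc_upper"] = fit.trunc_upper
        rel = reliability.estimate_sigma_meas(
            residues["subject_id"].to_numpy(),
            residues["age"].to_numpy(),
            residues["residue"].to_numpy(),
        )
        art = reliability.build_artifact_model(
            fit.rejected_residues,
            fit.resid_bounds.lower,
            fit.resid_bounds.upper,
            n_total=int(np.isfinite(sub["value"].to_numpy()).sum()),
        )
        entries[key] = NormativeEntry(
            key=key,
            model=fit.model,
            raw_bounds=fit.raw_bounds,
            resid_bounds=fit.resid_bounds,
            n_kept=fit.n_kept,
            n_rejected_raw=int(fit.rejected_raw.size),
            n_rejected_residual=int(fit.rejected_residual.size),
            sigma_norm_all=fit.sigma_norm_all,
            sigma_norm_corrected=fit.sigma_norm_corrected,
            age_min=fit.age_min,
            age_max=fit.age_max,
            residues=residues.reset_index(drop=True),
            rel=rel,
            art=art,
            contrast_factors=(factors if key.parameter == "gw_contrast" else None),
        )
        logger.debug(
            "key %s: degree %d, kept %d, rejected %d+%d",
            ks, fit.model.degree, fit.n_kept,
            fit.rejected_raw.size, fit.rejected_residual.size,
        )
    if skipped:
        logger.warning("%d key(s) skipped for insufficient data", skipped)

    meta = table.frame[table.frame["group"] == "control"]
    visits = meta.drop_duplicates(["subject_id", "visit_id"])
    return NormativeDB(
        entries=entries,
        etiv_ref=etiv_ref,
        n_hc_subjects=int(visits["subject_id"].nunique()),
        n_hc_visits=int(len(visits)),
        seed=seed,
        alpha_fit=alpha_fit,
        config_snapshot=config_snapshot or {},
    )


# --------------------------------------------------------------- persistence

def _entry_payload(e: NormativeEntry) -> dict:
    return {
        "key": e.key.as_string(),
        "model": {
            "degree": e.model.degree,
            "coeffs": e.model.coeffs.tolist(),
            "scaled_coeffs": e.model.scaled_coeffs.tolist(),
            "age_lo": e.model.age_lo,
            "age_hi": e.model.age_hi,
            "cov_scaled": e.model.cov_scaled.tolist(),
            "rss": e.model.rss,
            "n": e.model.n,
        },
        "raw_bounds": [e.raw_bounds.lower, e.raw_bounds.upper],
        "resid_bounds": [e.resid_bounds.lower, e.resid_bounds.upper],
        "n_kept": e.n_kept,
        "n_rejected_raw": e.n_rejected_raw,
        "n_rejected_residual": e.n_rejected_residual,
        "sigma_norm_all": e.sigma_norm_all,
        "sigma_norm_corrected": e.sigma_norm_corrected,
        "age_min": e.age_min,
        "age_max": e.age_max,
        "residues": {c: e.residues[c].tolist() for c in _RESIDUE_COLS},
        "reliability": {
            "sigma_meas": e.rel.sigma_meas,
            "n_repeat_subjects": e.rel.n_repeat_subjects,
            "n_repeat_visits": e.rel.n_repeat_visits,
            "has_reliability_data": e.rel.has_reliability_data,
        },
        "artifact": {
            "sigma_out": e.art.sigma_out,
            "p_out": e.art.p_out,
            "n_out": e.art.n_out,
            "p_art": e.art.p_art,
            "odds": e.art.odds,
            "lower_limit": e.art.lower_limit,
        },
        "contrast_factors": e.contrast_factors,
    }


def _entry_from_payload(d: dict) -> NormativeEntry:
    m = d["model"]
    model = age_model.PolynomialModel(
        degree=int(m["degree"]),
        coeffs=np.asarray(m["coeffs"], dtype=float),
        scaled_coeffs=np.asarray(m["scaled_coeffs"], dtype=float),
        age_lo=float(m["age_lo"]),
        age_hi=float(m["age_hi"]),
        cov_scaled=np.asarray(m["cov_scaled"], dtype=float),
        rss=float(m["rss"]),
        n=int(m["n"]),
    )
    rel = reliability.ReliabilityEstimate(
        sigma_meas=d["reliability"]["sigma_meas"],
        n_repeat_subjects=d["reliability"]["n_repeat_subjects"],
        n_repeat_visits=d["reliability"]["n_repeat_visits"],
        has_reliability_data=d["reliability"]["has_reliability_data"],
    )
    art = reliability.ArtifactModel(
        sigma_out=d["artifact"]["sigma_out"],
        p_out=d["artifact"]["p_out"],
        n_out=d["artifact"]["n_out"],
        p_art=d["artifact"]["p_art"],
        odds=d["artifact"]["odds"],
        lower_limit=d["artifact"]["lower_limit"],
    )
    residues = pd.DataFrame({c: d["residues"][c] for c in _RESIDUE_COLS})
    return NormativeEntry(
        key=MeasurementKey.from_string(d["key"]),
        model=model,
        raw_bounds=age_model.OutlierBounds(*d["raw_bounds"]),
        resid_bounds=age_model.OutlierBounds(*d["resid_bounds"]),
        n_kept=int(d["n_kept"]),
        n_rejected_raw=int(d["n_rejected_raw"]),
        n_rejected_residual=int(d["n_rejected_residual"]),
        sigma_norm_all=float(d["sigma_norm_all"]),
        sigma_norm_corrected=float(d["sigma_norm_corrected"]),
        age_min=float(d["age_min"]),
        age_max=float(d["age_max"]),
        residues=residues,
        rel=rel,
        art=art,
        contrast_factors=d.get("contrast_factors"),
    )


def _json_default(o):
    if isinstance(o, np.integer):
        return int(o)
    if isinstance(o, np.floating):
        return float(o)
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def save_db(db: NormativeDB, path) -> None:
    """Persist the database as a single schema-versioned JSON archive."""
    payload = {
        "manifest": {
            "schema_version": db.schema_version,
            "etiv_ref": db.etiv_ref,
            "n_hc_subjects": db.n_hc_subjects,
            "n_hc_visits": db.n_hc_visits,
            "seed": db.seed,
            "alpha_fit": db.alpha_fit,
            "config_snapshot": db.config_snapshot,
            "n_entries": len(db.entries),
        },
        "entries": [_entry_payload(db.entries[k]) for k in sorted(db.entries)],
    }
    Path(path).write_text(json.dumps(payload, default=_json_default), encoding="utf-8")


def load_db(path) -> NormativeDB:
    """Load a persisted database, refusing incompatible schema versions."""
    text = Path(path).read_text(encoding="utf-8")
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise IntegrityError(f"{path}: truncated or corrupt database: {exc}") from exc
    manifest = payload.get("manifest", {})
    version = manifest.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: schema version {version!r} incompatible with {SCHEMA_VERSION!r}"
        )
    entries_raw = payload.get("entries")
    if entries_raw is None or len(entries_raw) != manifest.get("n_entries"):
        raise IntegrityError(f"{path}: entry count does not match manifest")
    entries = {}
    for d in entries_raw:
        e = _entry_from_payload(d)
        entries[e.key] = e
    return NormativeDB(
        entries=entries,
        etiv_ref=float(manifest["etiv_ref"]),
        n_hc_subjects=int(manifest["n_hc_subjects"]),
        n_hc_visits=int(manifest["n_hc_visits"]),
        seed=manifest.get("seed"),
        alpha_fit=float(manifest.get("alpha_fit", 0.05)),
        config_snapshot=manifest.get("config_snapshot", {}),
        schema_version=version,
    )
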