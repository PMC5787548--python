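"""Readers and writers for morphometric tables and visit metadata.

Two table dialects are supported:

``long_csv``
    The canonical long layout: columns
    ``subject_id,visit_id,region,hemisphere,parameter[,variant],value``.

``freesurfer_wide_tsv``
    One row per scan, first column an identifier, remaining columns named in
    the FreeSurfer table-exporter style — ``lh_<region>_<measure>`` /
    ``rh_<region>_<measure>`` for aparc exports and ``Left-<Region>`` /
    ``Right-<Region>`` / ``<Region>`` for aseg volume exports.  Unknown
    columns are collected and reported, never silently dropped.

``"NA"``/empty cells become explicit missing values (NaN), never zero.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .keys import SEXES, GROUPS
from .table import META_COLS, VALUE_COLS, MorphTable

_NA_TOKENS = {"", "na", "nan", "n/a", "none", "null"}

#: aparc measure suffix -> parameter name.
_APARC_MEASURES = {
    "thickness": "thickness_mean",
    "thicknessstd": "thickness_sd",
    "area": "surface_area",
    "volume": "gm_volume",
    "meancurv": "curvature_mean",
    "gauscurv": "curvature_gaussian",
    "curvind": "curvature_index",
    "foldind": "folding_index",
    "contrast": "gw_contrast",
    "pctmean": "gw_contrast",
}


class UnknownColumnWarning(UserWarning):
    """Emitted when a wide-table column cannot be mapped to a measurement key."""


def _parse_value(raw, path, row, col) -> float:
    if isinstance(raw, float):
        return raw
    s = str(raw).strip()
    if s.lower() in _NA_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise ParseError(
            f"{path}: non-numeric value {raw!r} in column {col!r}, row {row}"
        ) from None


def read_stats_table(path, dialect: str = "long_csv", visit_sep: str | None = "::") -> MorphTable:
    """Read a morphometric table in the given dialect into a :class:`MorphTable`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "long_csv":
        return _read_long_csv(path)
    if dialect == "freesurfer_wide_tsv":
        return _read_freesurfer_wide(path, visit_sep)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_long_csv(path: Path) -> MorphTable:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    required = [c for c in VALUE_COLS if c != "variant"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: malformed header, missing column(s) {missing}")
    if "variant" not in df.columns:
        df["variant"] = "raw"
    extra = [c for c in df.columns if c not in VALUE_COLS]
    if extra:
        warnings.warn(
            f"{path}: ignoring unknown column(s) {extra}", UnknownColumnWarning, stacklevel=2
        )
    values = [
        _parse_value(v, path, i + 2, "value") for i, v in enumerate(df["value"].tolist())
    ]
    out = df[[c for c in VALUE_COLS if c != "value"]].copy()
    out["value"] = np.asarray(values, dtype=float)
    return MorphTable(out[VALUE_COLS])


def _classify_wide_column(col: str):
    """Map a wide-table column name to (region, hemisphere, parameter) or None."""
    low = col.lower()
    for prefix, hemi in (("lh_", "left"), ("rh_", "right")):
        if low.startswith(prefix):
            body = col[3:]
            for suffix, parameter in _APARC_MEASURES.items():
                if body.lower().endswith("_" + suffix):
                    region = body[: -(len(suffix) + 1)]
                    return region, hemi, parameter
            return None
    for prefix, hemi in (("left-", "left"), ("right-", "right")):
        if low.startswith(prefix):
            return col[len(prefix):], hemi, "volume"
    # aseg midline/global structures: plain region name measured as a volume
    if col.replace("-", "").replace("_", "").replace(".", "").isalnum():
        return col, "none", "volume"
    return None


def _read_freesurfer_wide(path: Path, visit_sep: str | None) -> MorphTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: malformed header, expected id column plus measures")
    id_col = df.columns[0]
    mapped, unknown = {}, []
    for col in df.columns[1:]:
        spec = _classify_wide_column(col)
        if spec is None:
            unknown.append(col)
        else:
            mapped[col] = spec
    if unknown:
        warnings.warn(
            f"{path}: unmapped column(s) {unknown}", UnknownColumnWarning, stacklevel=2
        )
    rows = []
    for i in range(len(df)):
        ident = str(df.iloc[i, 0])
        if visit_sep and visit_sep in ident:
            subject_id, visit_id = ident.split(visit_sep, 1)
        else:
            subject_id = visit_id = ident
        for col, (region, hemi, parameter) in mapped.items():
            value = _parse_value(df.iloc[i][col], path, i + 2, col)
            rows.append((subject_id, visit_id, region, hemi, parameter, "raw", value))
    return MorphTable(pd.DataFrame(rows, columns=VALUE_COLS))


def write_long_csv(table: MorphTable, path) -> None:
    """Write the long dialect; floats use repr precision so round-trips are exact."""
    table.frame[VALUE_COLS].to_csv(path, index=False)


def read_metadata(path) -> pd.DataFrame:
    """Read and validate the visit metadata CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ["subject_id", "visit_id"] + META_COLS
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: metadata missing column(s) {missing}")
    for col in ("age", "etiv"):
        df[col] = [_parse_value(v, path, i + 2, col) for i, v in enumerate(df[col])]
    bad_sex = set(df["sex"]) - SEXES
    if bad_sex:
        raise ValidationError(f"{path}: invalid sex value(s) {sorted(bad_sex)}")
    bad_group = set(df["group"]) - GROUPS
    if bad_group:
        raise ValidationError(f"{path}: invalid group value(s) {sorted(bad_group)}")
    if not ((df["age"] > 0) & np.isfinite(df["age"])).all():
        raise ValidationError(f"{path}: ages must be finite and positive")
    if not ((df["etiv"] > 0) & np.isfinite(df["etiv"])).all():
        raise ValidationError(f"{path}: eTIV must be finite and positive")
    dup = df.duplicated(subset=["subject_id", "visit_id"])
    if dup.any():
        bad = df.loc[dup, ["subject_id", "visit_id"]].values.tolist()
        raise ValidationError(f"{path}: duplicate metadata rows for visits {bad}")
    return df[required]


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, index=False)
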