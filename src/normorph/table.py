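"""Long-format container of morphometric measurements.

The canonical in-memory representation is a long :class:`pandas.DataFrame`
with one row per (subject, visit, key) and an explicit ``value`` column;
missing measurements are carried as NaN and excluded per key at fit time,
never imputed.  Wide FreeSurfer-style exports are converted to this layout
on read.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .keys import PARAMETERS, HEMISPHERES, VARIANTS, MeasurementKey, SubjectMeta

#: Identity + key + value columns of the long layout.
VALUE_COLS = ["subject_id", "visit_id", "region", "hemisphere", "parameter", "variant", "value"]
#: Metadata columns attached by :func:`join_metadata`.
META_COLS = ["age", "sex", "scanner_model", "sequence", "etiv", "group"]


class MorphTable:
    """Long-format morphometric table, optionally joined to visit metadata."""

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in VALUE_COLS if c not in frame.columns]
        if missing:
            raise ValidationError(f"MorphTable frame lacks columns {missing}")
        frame = frame.reset_index(drop=True)
        bad_par = set(frame["parameter"].unique()) - PARAMETERS
        if bad_par:
            raise ValidationError(f"unknown parameter names {sorted(bad_par)}")
        bad_hemi = set(frame["hemisphere"].unique()) - HEMISPHERES
        if bad_hemi:
            raise ValidationError(f"unknown hemisphere labels {sorted(bad_hemi)}")
        bad_var = set(frame["variant"].unique()) - VARIANTS
        if bad_var:
            raise ValidationError(f"unknown variant labels {sorted(bad_var)}")
        dup = frame.duplicated(subset=VALUE_COLS[:-1])
        if dup.any():
            first = frame.loc[dup.idxmax(), VALUE_COLS[:-1]].tolist()
            raise ValidationError(
                f"duplicate (subject, visit, key) records, first duplicate: {first}"
            )
        values = frame["value"].to_numpy()
        finite_or_nan = np.isfinite(values) | np.isnan(values)
        if not finite_or_nan.all():
            i = int(np.flatnonzero(~finite_or_nan)[0])
            raise ValidationError(f"non-finite value that is not NaN at record {i}")
        self.frame = frame

    # ------------------------------------------------------------------ basic
    def __len__(self) -> int:
        return len(self.frame)

    @property
    def has_metadata(self) -> bool:
        return all(c in self.frame.columns for c in META_COLS)

    def keys(self) -> list[MeasurementKey]:
        """Distinct measurement keys, in sorted order."""
        kf = self.frame[["region", "hemisphere", "parameter", "variant"]].drop_duplicates()
        return sorted(MeasurementKey(*row) for row in kf.itertuples(index=False))

    def key_strings(self) -> pd.Series:
        f = self.frame
        return (
            f["region"].astype(str)
            + "|" + f["hemisphere"].astype(str)
            + "|" + f["parameter"].astype(str)
            + "|" + f["variant"].astype(str)
        )

    def subset(self, mask) -> "MorphTable":
        return MorphTable(self.frame.loc[mask].reset_index(drop=True))

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str, MeasurementKey, float]],
    ) -> "MorphTable":
        rows = [
            (s, v, k.region, k.hemisphere, k.parameter, k.variant, x)
            for s, v, k, x in records
        ]
        return cls(pd.DataFrame(rows, columns=VALUE_COLS))


def metadata_frame(metas: Sequence[SubjectMeta]) -> pd.DataFrame:
    """Collect validated :class:`SubjectMeta` records into a metadata table."""
    df = pd.DataFrame(
        [
            (m.subject_id, m.visit_id, m.age, m.sex, m.scanner_model, m.sequence, m.etiv, m.group)
            for m in metas
        ],
        columns=["subject_id", "visit_id"] + META_COLS,
    )
    dup = df.duplicated(subset=["subject_id", "visit_id"])
    if dup.any():
        bad = df.loc[dup, ["subject_id", "visit_id"]].values.tolist()
        raise ValidationError(f"duplicate metadata rows for visits {bad}")
    return df


def join_metadata(table: MorphTable, meta: pd.DataFrame | Sequence[SubjectMeta]) -> MorphTable:
    """Attach full visit metadata to every record.

    Every (subject, visit) in the table must appear exactly once in ``meta``;
    unmatched visits or duplicated metadata rows are hard errors so that no
    record is silently dropped.
    """
    if not isinstance(meta, pd.DataFrame):
        meta = metadata_frame(meta)
    dup = meta.duplicated(subset=["subject_id", "visit_id"])
    if dup.any():
        bad = meta.loc[dup, ["subject_id", "visit_id"]].values.tolist()
        raise ValidationError(f"duplicate metadata rows for visits {bad}")
    frame = table.frame[VALUE_COLS]
    joined = frame.merge(meta, on=["subject_id", "visit_id"], how="left", validate="m:1")
    if joined["group"].isna().any():
        missing = (
            joined.loc[joined["group"].isna(), ["subject_id", "visit_id"]]
            .drop_duplicates()
            .values.tolist()
        )
        raise ValidationError(f"visits missing from metadata: {missing}")
    if len(joined) != len(frame):  # pragma: no cover - guarded by validate='m:1'
        raise ValidationError("metadata join changed the record count")
    return MorphTable(joined)
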