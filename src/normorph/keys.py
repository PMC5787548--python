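"""Domain types identifying measured quantities and scan metadata.

A measurement is addressed by a :class:`MeasurementKey` — the atlas region,
the hemisphere, the morphometric parameter, and the variant (raw physical
units, head-size/scanner normalized, or interhemispheric asymmetry index).
The parameter taxonomy is closed: unknown parameter names are rejected at
load time so that typos never silently create new keys.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .exceptions import ValidationError

#: Closed taxonomy of morphometric parameters.  The nine surface-based
#: parameters come from cortical parcellations; volumes from segmentations;
#: pve_* are whole-brain partial volume estimates; lesion_volume and
#: clinical_score carry patient-only series (lesion load, EDSS and the like).
PARAMETERS = frozenset(
    {
        "volume",
        "thickness_mean",
        "thickness_sd",
        "surface_area",
        "gm_volume",
        "curvature_mean",
        "curvature_gaussian",
        "curvature_index",
        "folding_index",
        "gw_contrast",
        "pve_gm",
        "pve_wm",
        "pve_csf",
        "pve_brain",
        "lesion_volume",
        "clinical_score",
    }
)

HEMISPHERES = frozenset({"left", "right", "bilateral", "none"})
VARIANTS = frozenset({"raw", "normalized", "asymmetry"})
SEXES = frozenset({"F", "M"})
GROUPS = frozenset({"control", "patient"})

_KEY_SEP = "|"


@dataclass(frozen=True, order=True)
class MeasurementKey:
    """One measured quantity: region x hemisphere x parameter x variant."""

    region: str
    hemisphere: str
    parameter: str
    variant: str = "raw"

    def __post_init__(self) -> None:
        if self.parameter not in PARAMETERS:
            raise ValidationError(f"unknown parameter {self.parameter!r}")
        if self.hemisphere not in HEMISPHERES:
            raise ValidationError(f"unknown hemisphere {self.hemisphere!r}")
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.variant == "asymmetry" and self.hemisphere != "bilateral":
            raise ValidationError(
                "asymmetry variant requires hemisphere='bilateral' "
                f"(got {self.hemisphere!r} for region {self.region!r})"
            )

    def as_string(self) -> str:
        return _KEY_SEP.join((self.region, self.hemisphere, self.parameter, self.variant))

    @classmethod
    def from_string(cls, s: str) -> "MeasurementKey":
        parts = s.split(_KEY_SEP)
        if len(parts) != 4:
            raise ValidationError(f"malformed measurement key string {s!r}")
        return cls(*parts)

    def with_variant(self, variant: str) -> "MeasurementKey":
        return MeasurementKey(self.region, self.hemisphere, self.parameter, variant)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.as_string()


@dataclass(frozen=True)
class SubjectMeta:
    """Per-visit metadata: demographics, scanner provenance, head size, group."""

    subject_id: str
    visit_id: str
    age: float
    sex: str
    scanner_model: str
    sequence: str
    etiv: float
    group: str

    def __post_init__(self) -> None:
        if not (math.isfinite(self.age) and self.age > 0):
            raise ValidationError(
                f"age must be finite and positive, got {self.age!r} "
                f"for {self.subject_id}/{self.visit_id}"
            )
        if not (math.isfinite(self.etiv) and self.etiv > 0):
            raise ValidationError(
                f"etiv must be positive, got {self.etiv!r} "
                f"for {self.subject_id}/{self.visit_id}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"sex must be one of {sorted(SEXES)}, got {self.sex!r}")
        if self.group not in GROUPS:
            raise ValidationError(f"group must be one of {sorted(GROUPS)}, got {self.group!r}")
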