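"""Head-size, scanner and hemisphere normalization of morphometric values.

Geometric eTIV scaling: each parameter class carries the exponent expected
from dimensional analysis — volumes scale as eTIV^1, areas as eTIV^(2/3),
lengths (thicknesses) as eTIV^(1/3), and curvature-type quantities, being
functions of inverse radii, as eTIV^(-1/3) (mean curvature, curvature
index) or eTIV^(-2/3) (Gaussian curvature, folding index).  A value is
normalized to the reference head size by value * (etiv_ref / etiv)^n.

The gray-white contrast depends strongly on scanner and sequence rather
than head size, so it is rescaled multiplicatively so that every
scanner-sequence group of healthy controls has the same mean as the full
control group; patient values are rescaled by their own group's factor.

Interhemispheric asymmetry is (R - L) / (R + L) on raw values: 0 for
symmetry, +1/-1 for complete right/left dominance.  eTIV factors cancel
in the ratio for same-exponent pairs.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .keys import PARAMETERS

#: parameter -> geometric eTIV exponent; None marks group-mean normalization
SCALING_EXPONENTS: dict[str, Fraction | None] = {
    "volume": Fraction(1),
    "gm_volume": Fraction(1),
    "pve_gm": Fraction(1),
    "pve_wm": Fraction(1),
    "pve_csf": Fraction(1),
    "pve_brain": Fraction(1),
    "lesion_volume": Fraction(1),
    "surface_area": Fraction(2, 3),
    "thickness_mean": Fraction(1, 3),
    "thickness_sd": Fraction(1, 3),
    "curvature_mean": Fraction(-1, 3),
    "curvature_index": Fraction(-1, 3),
    "curvature_gaussian": Fraction(-2, 3),
    "folding_index": Fraction(-2, 3),
    "gw_contrast": None,
    "clinical_score": Fraction(0),
}
assert set(SCALING_EXPONENTS) == PARAMETERS


def scaling_exponent(parameter: str) -> Fraction | None:
    """Geometric eTIV exponent of a parameter; None for gw_contrast."""
    try:
        return SCALING_EXPONENTS[parameter]
    except KeyError:
        raise ValidationError(f"unknown parameter {parameter!r}") from None


def normalize_etiv(value, etiv_subject, etiv_ref, exponent) -> float:
    """Rescale a value to the reference head size with the given exponent."""
    etiv_subject = np.asarray(etiv_subject, dtype=float)
    if np.any(etiv_subject <= 0) or etiv_ref <= 0:
        raise ValidationError("eTIV values must be positive")
    return value * (etiv_ref / etiv_subject) ** float(exponent)


def contrast_factors(values: np.ndarray, group_labels: np.ndarray) -> dict[str, float]:
    """Multiplicative per scanner-sequence factors equalizing HC group means.

    factor_g = grand_mean / group_mean_g, so after multiplication every
    group's mean equals the grand mean of the full control set.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    ok = np.isfinite(values)
    values, group_labels = values[ok], group_labels[ok]
    if values.size == 0:
        raise ValidationError("no finite values to derive contrast factors from")
    grand = float(values.mean())
    factors = {}
    for g in np.unique(group_labels):
        gm = float(values[group_labels == g].mean())
        if gm == 0.0:
            raise ValidationError(f"scanner-sequence group {g!r} has zero mean contrast")
        factors[str(g)] = grand / gm
    return factors


def apply_contrast_factor(value, group_label: str, factors: dict[str, float]):
    """Rescale a value by its scanner-sequence group factor derived from HCs."""
    if group_label not in factors:
        raise ValidationError(
            f"scanner-sequence combination {group_label!r} absent from the control set"
        )
    return value * factors[group_label]


def asymmetry_index(right_value, left_value):
    """(R - L) / (R + L); NaN (missing) where the denominator vanishes."""
    r = np.asarray(right_value, dtype=float)
    l = np.asarray(left_value, dtype=float)
    denom = r + l
    with np.errstate(divide="ignore", invalid="ignore"):
        ai = np.where(denom == 0.0, np.nan, (r - l) / denom)
    if np.ndim(right_value) == 0 and np.ndim(left_value) == 0:
        return float(ai)
    return ai


def scanner_sequence_label(scanner_model, sequence) -> "pd.Series | str":
    """Canonical composite label of a scanner-sequence combination."""
    if isinstance(scanner_model, str):
        return f"{scanner_model}||{sequence}"
    return scanner_model.astype(str) + "||" + sequence.astype(str)
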