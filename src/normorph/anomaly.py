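"""Scoring a single patient visit against the matched normative subset.

For each measurement key, the patient's age-fit residue x is compared to
the residues of the healthy controls who match the patient exactly on sex,
scanner model and acquisition sequence.  With x_norm and sigma_norm the
mean and SD of the matched residues and sigma_meas the scan-rescan
measurement error, the variances add and the comparison uses a Gaussian
with

    sigma^2 = sigma_norm^2 * (1 + 1/n_matched) + sigma_meas^2,

where the 1/n term propagates the uncertainty of the matched-subset mean
and sigma_norm is the trim-bias-corrected normative SD.  The default
p-value is the calibrated two-sided one,

    p_ucor = 2 * (1 - Phi(|x - x_norm| / sigma)),

which is Uniform(0,1) for a healthy-like observation so that the fraction
of visits flagged at level alpha is alpha.  The directional single-tail
form (the probability mass beyond x on its own side of the normative mean)
is available as :func:`directional_tail_p` for reporting the deviation
direction.

Feature vectors are signed base-10 log p-values, L = -sign(x - x_norm) *
log10(p): large positive for abnormally increased values, large negative
for abnormally decreased ones.  Multiple testing across the >10^3 keys of
one dataset is handled by Benjamini-Hochberg FDR; uncorrected detections
are highlighted yellow, FDR-surviving ones red.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .age_model import trim_corrected_sigma_bounds
from .db import NormativeDB, NormativeEntry
from .exceptions import InsufficientControlsError, ValidationError
from .keys import MeasurementKey, SubjectMeta
from .table import MorphTable

#: minimum matched controls for a per-key comparison
DEFAULT_N_MIN = 10

_P_FLOOR = 1e-300  # keeps log10(p) finite


@dataclass(frozen=True)
class MatchedSubset:
    """Residues of HCs matching a patient on sex, scanner model and sequence."""

    x_norm: float
    sigma_norm: float             # sample SD of matched residues
    sigma_norm_corrected: float   # trim-bias corrected
    n_matched: int
    residues: np.ndarray


def match_controls(
    patient_meta: SubjectMeta,
    entry: NormativeEntry,
    n_min: int = DEFAULT_N_MIN,
) -> MatchedSubset:
    """Exact categorical match on sex, scanner model and sequence."""
    r = entry.residues
    mask = (
        (r["sex"] == patient_meta.sex)
        & (r["scanner_model"] == patient_meta.scanner_model)
        & (r["sequence"] == patient_meta.sequence)
    )
    x = r.loc[mask, "residue"].to_numpy(dtype=float)
    if x.size < n_min:
        raise InsufficientControlsError(
            f"{entry.key.as_string()}: {x.size} matched controls < n_min={n_min} "
            f"for sex={patient_meta.sex}, scanner={patient_meta.scanner_model}, "
            f"sequence={patient_meta.sequence}"
        )
    # subset residuals come from the global p-parameter fit: undo the
    # in-sample deflation before the truncation correction
    n_fit, n_par = entry.model.n, entry.model.degree + 1
    dof_factor = np.sqrt(n_fit / max(n_fit - n_par, 1))
    s = float(np.std(x, ddof=1))
    s_corr = trim_corrected_sigma_bounds(
        s * dof_factor,
        r.loc[mask, "trunc_lower"].to_numpy(dtype=float),
        r.loc[mask, "trunc_upper"].to_numpy(dtype=float),
        mu=float(x.mean()),
    )
    return MatchedSubset(
        x_norm=float(x.mean()),
        sigma_norm=s,
        sigma_norm_corrected=s_corr,
        n_matched=int(x.size),
        residues=x,
    )


def combined_sigma(
    sigma_norm: float,
    sigma_meas: float,
    n_norm: int | None = None,
    var_trend: float = 0.0,
    n_fit: int | None = None,
) -> float:
    """Predictive SD: normative spread (+ matched-mean uncertainty) +
    measurement error + age-trend fit error.

    The matched-subset mean of least-squares residuals has variance
    sigma_norm^2 (1/n_norm - 1/n_fit) because the fit constrains the
    overall residual mean to zero.
    """
    var = sigma_norm**2 + sigma_meas**2 + var_trend
    if n_norm:
        mean_term = 1.0 / n_norm - (1.0 / n_fit if n_fit else 0.0)
        var += sigma_norm**2 * max(mean_term, 0.0)
    return float(np.sqrt(var))


def _tail_sf(z: float, n_norm: int | None) -> float:
    """Upper-tail mass of the predictive reference distribution.

    With a known matched-subset size the reference is Student t with
    n_norm - 1 degrees of freedom — the exact predictive distribution of a
    standardized Gaussian observation against a sample mean and SD; the
    Gaussian is the large-sample limit used when n_norm is not given.
    """
    if n_norm and n_norm > 1:
        return float(stats.t.sf(z, n_norm - 1))
    return float(stats.norm.sf(z))


def visit_pvalue(
    x: float,
    x_norm: float,
    sigma_norm: float,
    sigma_meas: float = 0.0,
    n_norm: int | None = None,
    var_trend: float = 0.0,
    n_fit: int | None = None,
) -> float:
    """Calibrated two-sided p-value of one observation against the matched norm."""
    if sigma_norm <= 0:
        raise ValidationError("sigma_norm must be positive (degenerate normative spread)")
    if sigma_meas < 0:
        raise ValidationError("sigma_meas must be non-negative")
    sigma = combined_sigma(sigma_norm, sigma_meas, n_norm, var_trend, n_fit)
    return 2.0 * _tail_sf(abs(x - x_norm) / sigma, n_norm)


def directional_tail_p(
    x: float,
    x_norm: float,
    sigma_norm: float,
    sigma_meas: float = 0.0,
    n_norm: int | None = None,
    var_trend: float = 0.0,
    n_fit: int | None = None,
) -> float:
    """Single-tail probability toward the observation (0.5 at the normative mean)."""
    if sigma_norm <= 0:
        raise ValidationError("sigma_norm must be positive (degenerate normative spread)")
    sigma = combined_sigma(sigma_norm, sigma_meas, n_norm, var_trend, n_fit)
    z = abs(x - x_norm) / sigma
    return _tail_sf(z, n_norm)


def fdr_flags(pvalues, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up over one dataset's family of tests.

    NaN entries (skipped keys) are carried through as False.
    """
    p = np.asarray(pvalues, dtype=float)
    flags = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        flags[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return flags


def highlight_level(p_ucor: float, fdr_flag: bool, alpha: float = 0.05) -> str:
    """red = survives FDR; yellow = uncorrected p < alpha; none otherwise."""
    if fdr_flag:
        return "red"
    if np.isfinite(p_ucor) and p_ucor < alpha:
        return "yellow"
    return "none"


def feature_value(p: float, direction: float) -> float:
    """L = -sign(x - x_norm) * log10(p); 0 where p = 1 or the key was skipped."""
    if not np.isfinite(p):
        return np.nan
    return float(-np.sign(direction) * np.log10(max(p, _P_FLOOR)))


def feature_vector(assessment: pd.DataFrame) -> pd.Series:
    """Ordered feature vector L over a visit assessment (missing keys = NaN)."""
    out = pd.Series(
        [feature_value(p, d) for p, d in zip(assessment["p_ucor"], assessment["direction"])],
        index=assessment["key"].tolist(),
        dtype=float,
    )
    return out


def feature_correlation_matrix(vectors: pd.DataFrame, min_shared: int = 3) -> pd.DataFrame:
    """Pearson correlation matrix of feature vectors (columns = datasets).

    Pairwise-complete over non-missing entries; pairs sharing fewer than
    ``min_shared`` keys get a missing cell.
    """
    if vectors.shape[1] < 2:
        raise ValidationError("need >= 2 feature vectors")
    return vectors.corr(method="pearson", min_periods=min_shared)


def assess_visit(
    dbase: NormativeDB,
    visit_table: MorphTable,
    alpha: float = 0.05,
    n_min: int = DEFAULT_N_MIN,
) -> pd.DataFrame:
    """Assess every key of one patient visit against the normative database.

    ``visit_table`` must be metadata-joined and contain exactly one visit;
    variants should already be derived (see
    :func:`normorph.db.derive_variants_with_reference`).  Returns one row
    per key with residue, p_ucor, FDR flag, highlight, L and odds; keys
    without enough matched controls are reported with a skip reason.
    """
    f = visit_table.frame
    visits = f.drop_duplicates(["subject_id", "visit_id"])
    if len(visits) != 1:
        raise ValidationError(f"expected exactly one visit, got {len(visits)}")
    if len(f) == 0:
        raise ValidationError("empty patient table")
    vrow = visits.iloc[0]
    meta = SubjectMeta(
        subject_id=str(vrow["subject_id"]), visit_id=str(vrow["visit_id"]),
        age=float(vrow["age"]), sex=str(vrow["sex"]),
        scanner_model=str(vrow["scanner_model"]), sequence=str(vrow["sequence"]),
        etiv=float(vrow["etiv"]), group=str(vrow["group"]),
    )
    rows = []
    keystr = visit_table.key_strings()
    for ks, sub in f.groupby(keystr.to_numpy(), sort=True):
        key = MeasurementKey.from_string(ks)
        value = float(sub["value"].iloc[0])
        entry = dbase.entries.get(key)
        base = {
            "key": ks, "variant": key.variant, "value": value,
            "residue": np.nan, "p_ucor": np.nan, "direction": 0.0,
            "n_matched": 0, "odds": np.nan, "extrapolated": False, "skip_reason": "",
        }
        if entry is None:
            base["skip_reason"] = "key absent from normative database"
            rows.append(base)
            continue
        if not np.isfinite(value):
            base["skip_reason"] = "missing measurement"
            rows.append(base)
            continue
        expected, _, extrapolated = (
            entry.model.predict(meta.age),
            None,
            not (entry.age_min <= meta.age <= entry.age_max),
        )
        residue = value - float(expected)
        base.update(residue=residue, extrapolated=extrapolated, odds=entry.art.odds)
        try:
            subset = match_controls(meta, entry, n_min)
        except InsufficientControlsError as exc:
            base["skip_reason"] = str(exc)
            rows.append(base)
            continue
        if subset.sigma_norm_corrected <= 0:
            base["skip_reason"] = "degenerate normative spread"
            rows.append(base)
            continue
        p = visit_pvalue(
            residue, subset.x_norm, subset.sigma_norm_corrected,
            entry.rel.sigma_meas, subset.n_matched,
            var_trend=entry.model.predict_variance(meta.age),
            n_fit=entry.model.n,
        )
        base.update(
            p_ucor=p,
            direction=float(np.sign(residue - subset.x_norm)),
            n_matched=subset.n_matched,
        )
        rows.append(base)
    out = pd.DataFrame(rows)
    out["fdr_significant"] = fdr_flags(out["p_ucor"].to_numpy(), alpha)
    out["L"] = [feature_value(p, d) for p, d in zip(out["p_ucor"], out["direction"])]
    out["highlight"] = [
        highlight_level(p, flag, alpha)
        for p, flag in zip(out["p_ucor"], out["fdr_significant"])
    ]
    return out
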