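"""Linear trend statistics over a patient's follow-up series.

For each key, residues x (observed value minus the healthy-control age
trend) across >= 3 visits are fitted with x(t) = a*t + x_0 by ordinary
least squares.  Conventions: S^2 = RSS/n (maximum-likelihood residual
variance) and sigma_t^2 = population (divide-by-n) variance of the visit
times, under which the slope uncertainty

    delta_a = S / (sigma_t * sqrt(n - 2))

is algebraically identical to the textbook OLS slope standard error
sqrt( (RSS/(n-2)) / sum (t - tbar)^2 ).

Three tests accompany the fit: a chi-squared consistency test of S^2
against the scan-rescan measurement error (does a line describe the series
no worse than measurement noise allows?), a two-sided z-test of the slope
against zero (residues already subtract the normative age trend, so slope 0
means change consistent with cross-sectional aging), and a Welch two-sample
t-test of the mean residue position against the matched controls.

Clinical series (EDSS, lesion volume) get the same slope machinery plus a
Spearman rank correlation with age, with an exact permutation p-value for
short series (n <= 9) and the t-approximation otherwise.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import anomaly
from .age_model import iqr_bounds
from .db import NormativeDB
from .exceptions import InsufficientDataError, ValidationError
from .keys import MeasurementKey, SubjectMeta
from .table import MorphTable

EXACT_SPEARMAN_MAX_N = 9


def fit_series(times, residues):
    """OLS line fit; returns (slope a, intercept x_0, S2 = RSS/n)."""
    t = np.asarray(times, dtype=float)
    x = np.asarray(residues, dtype=float)
    n = t.size
    if n < 3:
        raise InsufficientDataError(f"series fit needs >= 3 points, got {n}")
    if np.ptp(t) == 0:
        raise ValidationError("zero time spread in series")
    a, x0 = np.polyfit(t, x, 1)
    rss = float(((x - (a * t + x0)) ** 2).sum())
    return float(a), float(x0), rss / n


def slope_uncertainty(S2: float, sigma_t: float, n: int) -> float:
    """delta_a = sqrt(S2) / (sigma_t * sqrt(n - 2)); sigma_t is the population SD of times."""
    if n < 3:
        raise InsufficientDataError("slope uncertainty undefined for n < 3")
    if sigma_t <= 0:
        raise ValidationError("sigma_t must be positive")
    return float(np.sqrt(S2) / (sigma_t * np.sqrt(n - 2)))


def consistency_chi2(S2: float, sigma_meas: float, n: int) -> float:
    """Upper-tail chi-squared test of RSS = n*S2 against measurement error, df = n - 2."""
    if sigma_meas <= 0:
        raise ValidationError("sigma_meas must be positive for the consistency test")
    statistic = n * S2 / sigma_meas**2
    return float(stats.chi2.sf(statistic, n - 2))


def slope_test(a: float, delta_a: float) -> float:
    """Two-sided z-test of the slope against zero."""
    if delta_a < 0:
        raise ValidationError("delta_a must be non-negative")
    if delta_a == 0:
        return 1.0 if a == 0 else 0.0
    return float(2.0 * stats.norm.sf(abs(a) / delta_a))


def mean_position_test(patient_residues, hc_residues) -> float:
    """Welch two-sample t-test (unequal sizes and variances), two-sided."""
    x = np.asarray(patient_residues, dtype=float)
    y = np.asarray(hc_residues, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("Welch test needs >= 2 values per group")
    if np.var(x) == 0 and np.var(y) == 0:
        return 1.0 if x.mean() == y.mean() else 0.0
    return float(stats.ttest_ind(x, y, equal_var=False).pvalue)


def series_outlier_rejection(times, residues, manual_exclude=()) -> np.ndarray:
    """Kept indices after per-series IQR rejection plus a manual exclusion list.

    Series too short for IQR fences (< 4 finite points) keep all finite
    points; fewer than 3 survivors is an error (no slope testing possible).
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(residues, dtype=float)
    keep = np.isfinite(x) & np.isfinite(t)
    keep[np.asarray(list(manual_exclude), dtype=int)] = False
    idx = np.flatnonzero(keep)
    if idx.size >= 4:
        b = iqr_bounds(x[idx])
        idx = idx[~b.outside(x[idx])]
    if idx.size < 3:
        raise InsufficientDataError(
            f"only {idx.size} visits survive exclusion; need >= 3"
        )
    return idx


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p by full enumeration of rank orderings."""
    n = xr.size
    perms = np.array(list(itertools.permutations(range(n))))
    yp = yr[perms]                                   # (n!, n)
    xc = xr - xr.mean()
    yc = yp - yp.mean(axis=1, keepdims=True)
    num = yc @ xc
    den = np.sqrt((xc @ xc) * (yc * yc).sum(axis=1))
    rhos = num / den
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def clinical_trend(times, scores):
    """Annual change rate and Spearman age correlation of a clinical series.

    Returns (rate, p_rate, rho, p_spearman); rho and its p are NaN for a
    constant series.
    """
    t = np.asarray(times, dtype=float)
    s = np.asarray(scores, dtype=float)
    if t.size < 3:
        raise InsufficientDataError("clinical series needs >= 3 points")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("clinical series times must be strictly increasing")
    a, _, S2 = fit_series(t, s)
    sigma_t = float(np.std(t))
    if S2 == 0.0:
        p_rate = 1.0 if a == 0 else 0.0
    else:
        p_rate = slope_test(a, slope_uncertainty(S2, sigma_t, t.size))
    if np.ptp(s) == 0:
        return a, p_rate, float("nan"), float("nan")
    xr = stats.rankdata(t)
    yr = stats.rankdata(s)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if t.size <= EXACT_SPEARMAN_MAX_N:
        p_s = _exact_spearman_p(xr, yr, rho)
    else:
        p_s = float(stats.spearmanr(t, s).pvalue)
    return a, p_rate, rho, p_s


def assess_series(
    dbase: NormativeDB,
    series_table: MorphTable,
    alpha: float = 0.05,
    n_min: int = anomaly.DEFAULT_N_MIN,
    manual_exclusions: dict[str, list[str]] | None = None,
) -> pd.DataFrame:
    """Per-key linear-trend assessment of one patient's follow-up series.

    ``series_table`` must be metadata-joined, single-subject, >= 3 visits,
    with variants already derived.  ``manual_exclusions`` maps key strings
    to visit_id lists excluded from the fit (the audited manual step after
    automatic rejection).  Slope-test p-values get BH/FDR flags across keys.
    """
    f = series_table.frame
    subjects = f["subject_id"].unique()
    if subjects.size != 1:
        raise ValidationError(f"expected one subject, got {subjects.size}")
    n_visits = f.drop_duplicates(["subject_id", "visit_id"]).shape[0]
    if n_visits < 3:
        raise ValidationError(
            f"{n_visits} visit(s): follow-up assessment needs >= 3 "
            "(use single-visit assessment instead)"
        )
    manual_exclusions = manual_exclusions or {}
    rows = []
    keystr = series_table.key_strings()
    for ks, sub in f.groupby(keystr.to_numpy(), sort=True):
        key = MeasurementKey.from_string(ks)
        entry = dbase.entries.get(key)
        base = {
            "key": ks, "variant": key.variant, "n_used": 0, "n_excluded": 0,
            "slope": np.nan, "intercept": np.nan, "S2": np.nan, "sigma_t": np.nan,
            "delta_a": np.nan, "p_chi2_consistency": np.nan, "p_slope": np.nan,
            "p_welch": np.nan, "skip_reason": "",
        }
        if entry is None:
            base["skip_reason"] = "key absent from normative database"
            rows.append(base)
            continue
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy(dtype=float)
        residues = sub["value"].to_numpy(dtype=float) - entry.model.predict(ages)
        excl_ids = set(manual_exclusions.get(ks, ()))
        manual_idx = [i for i, v in enumerate(sub["visit_id"]) if v in excl_ids]
        try:
            kept = series_outlier_rejection(ages, residues, manual_idx)
        except InsufficientDataError as exc:
            base["skip_reason"] = str(exc)
            rows.append(base)
            continue
        t, x = ages[kept], residues[kept]
        a, x0, S2 = fit_series(t, x)
        sigma_t = float(np.std(t))
        delta_a = slope_uncertainty(S2, sigma_t, t.size)
        p_slope = slope_test(a, delta_a)
        if entry.rel.sigma_meas > 0:
            p_chi2 = consistency_chi2(S2, entry.rel.sigma_meas, t.size)
        else:
            p_chi2 = np.nan   # no reliability data: consistency test skipped
        vrow = sub.iloc[0]
        meta = SubjectMeta(
            subject_id=str(vrow["subject_id"]), visit_id=str(vrow["visit_id"]),
            age=float(vrow["age"]), sex=str(vrow["sex"]),
            scanner_model=str(vrow["scanner_model"]), sequence=str(vrow["sequence"]),
            etiv=float(vrow["etiv"]), group=str(vrow["group"]),
        )
        try:
            subset = anomaly.match_controls(meta, entry, n_min)
            p_welch = mean_position_test(x, subset.residues)
        except (anomaly.InsufficientControlsError, InsufficientDataError):
            p_welch = np.nan
        base.update(
            n_used=int(t.size), n_excluded=int(ages.size - t.size),
            slope=a, intercept=x0, S2=S2, sigma_t=sigma_t, delta_a=delta_a,
            p_chi2_consistency=p_chi2, p_slope=p_slope, p_welch=p_welch,
        )
        rows.append(base)
    out = pd.DataFrame(rows)
    out["fdr_significant"] = anomaly.fdr_flags(out["p_slope"].to_numpy(), alpha)
    out["highlight"] = [
        anomaly.highlight_level(p, flag, alpha)
        for p, flag in zip(out["p_slope"], out["fdr_significant"])
    ]
    return out
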