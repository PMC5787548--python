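"""Outlier-robust polynomial age-trend modeling of normative data.

For every measurement key the healthy-control values are cleaned and fitted
in a fixed two-pass scheme:

1. reject raw values more than 1.5 interquartile ranges outside the 25%/75%
   percentiles of the full distribution;
2. fit a provisional polynomial age trend to the survivors and reject
   residues by the same 1.5 x IQR rule;
3. refit on the doubly cleaned data.

The polynomial degree is chosen stepwise from zero upward: degree d is
accepted over d-1 when the nested-model F statistic

    F = (RSS_{d-1} - RSS_d) / (RSS_d / (N - d - 1))

exceeds the upper alpha_fit/d quantile of F(1, N-d-1); the Bonferroni factor
d accounts for the d tests performed up to that step.  The search stops at
the first non-accepted degree; the upper limit is d_max = floor(N/20).

Because the IQR fences truncate the residue distribution at roughly
+-2.7 sigma, the sample SD of the kept residues underestimates the normative
spread by about 3%, which would inflate downstream anomaly rates above the
nominal level.  :func:`trim_corrected_sigma` removes this bias by
truncated-normal moment matching; both the plain (``sigma_norm_all``) and
the corrected SD are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError

IQR_FACTOR = 1.5
#: one fitted point per this many observations caps the polynomial degree
POINTS_PER_DEGREE = 20


@dataclass(frozen=True)
class OutlierBounds:
    """IQR fences; values strictly outside [lower, upper] are outliers."""

    lower: float
    upper: float

    def outside(self, values: np.ndarray) -> np.ndarray:
        return (values < self.lower) | (values > self.upper)


@dataclass
class PolynomialModel:
    """A fitted polynomial age trend with its uncertainty information.

    ``coeffs`` are in natural age units (ascending powers); the scaled-basis
    internals (age mapped to [-1, 1]) are kept for numerically stable
    evaluation of the confidence band.
    """

    degree: int
    coeffs: np.ndarray            # natural units, c_0 .. c_d
    scaled_coeffs: np.ndarray     # basis t = scale(age)
    age_lo: float                 # domain of the scaling map
    age_hi: float
    cov_scaled: np.ndarray        # coefficient covariance in the scaled basis
    rss: float
    n: int

    def _t(self, age):
        if self.age_hi == self.age_lo:
            return np.zeros_like(np.asarray(age, dtype=float))
        return 2.0 * (np.asarray(age, dtype=float) - self.age_lo) / (self.age_hi - self.age_lo) - 1.0

    def predict(self, age):
        return np.polynomial.polynomial.polyval(self._t(age), self.scaled_coeffs)

    def predict_variance(self, age):
        """Variance of the fitted trend value at an age (fit-error propagation)."""
        t = np.atleast_1d(self._t(age))
        V = np.vander(t, self.degree + 1, increasing=True)
        var = np.einsum("ij,jk,ik->i", V, self.cov_scaled, V)
        var = np.maximum(var, 0.0)
        return var if np.ndim(age) else float(var[0])

    def ci_halfwidth(self, age, level: float = 0.95):
        """Pointwise confidence half-width of the fitted trend."""
        var = np.atleast_1d(self.predict_variance(age))
        dof = max(self.n - (self.degree + 1), 1)
        q = stats.t.isf((1.0 - level) / 2.0, dof)
        out = q * np.sqrt(var)
        return out if np.ndim(age) else float(out[0])


@dataclass
class AgeTrendFit:
    """Result of the full two-pass rejection + degree-selected fit."""

    model: PolynomialModel
    raw_bounds: OutlierBounds
    resid_bounds: OutlierBounds
    kept: np.ndarray                  # indices (into the input) of kept points
    rejected_raw: np.ndarray          # indices rejected on raw values
    rejected_residual: np.ndarray     # indices rejected on provisional residues
    residues: np.ndarray              # x = X - X_poly for kept points
    rejected_residues: np.ndarray     # final-fit residues of all rejected points
    trunc_lower: np.ndarray           # per-kept-point effective truncation fences
    trunc_upper: np.ndarray           #   (residual scale, both rejection passes)
    sigma_norm_all: float             # sample SD of kept residues
    sigma_norm_corrected: float       # trim-bias corrected SD
    age_min: float                    # kept-HC age range (extrapolation guard)
    age_max: float

    @property
    def n_kept(self) -> int:
        return int(self.kept.size)


def iqr_bounds(values: np.ndarray) -> OutlierBounds:
    """1.5 x IQR fences around the quartiles (linear-interpolation quartiles)."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 4:
        raise InsufficientDataError(
            f"need >= 4 finite values for IQR fences, got {values.size}"
        )
    q25, q75 = np.percentile(values, [25.0, 75.0])
    iqr = q75 - q25
    return OutlierBounds(q25 - IQR_FACTOR * iqr, q75 + IQR_FACTOR * iqr)


def d_max_for(n: int) -> int:
    """Maximum admissible polynomial degree for n points (one per 20)."""
    return int(n) // POINTS_PER_DEGREE


@lru_cache(maxsize=16384)
def _f_crit(alpha: float, dfd: int) -> float:
    return float(stats.f.isf(alpha, 1, dfd))


def _design(t: np.ndarray, degree: int) -> np.ndarray:
    return np.vander(t, degree + 1, increasing=True)


def _fit_rss(t: np.ndarray, y: np.ndarray, degree: int):
    V = _design(t, degree)
    coef, _, _, _ = np.linalg.lstsq(V, y, rcond=None)
    resid = y - V @ coef
    return coef, float(resid @ resid)


def select_degree(
    ages: np.ndarray,
    values: np.ndarray,
    alpha_fit: float = 0.05,
    d_max: int | None = None,
) -> int:
    """Stepwise-up nested-model F-test selection of the polynomial degree."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.size
    if d_max is None:
        d_max = d_max_for(n)
    lo, hi = float(np.min(ages)), float(np.max(ages))
    t = np.zeros_like(ages) if hi == lo else 2.0 * (ages - lo) / (hi - lo) - 1.0
    if hi == lo:
        return 0
    ybar = values.mean()
    rss_prev = float((values - ybar) @ (values - ybar))
    degree = 0
    tiny = max(rss_prev, 1.0) * 1e-12
    for d in range(1, d_max + 1):
        dfd = n - d - 1
        if dfd < 1:
            break
        if rss_prev <= tiny:
            break  # lower degree already perfect
        _, rss_d = _fit_rss(t, values, d)
        if rss_d <= tiny:
            degree, rss_prev = d, rss_d
            continue
        F = (rss_prev - rss_d) / (rss_d / dfd)
        if F > _f_crit(alpha_fit / d, dfd):
            degree, rss_prev = d, rss_d
        else:
            break
    return degree


def fit_polynomial(ages: np.ndarray, values: np.ndarray, degree: int) -> PolynomialModel:
    """Least-squares polynomial fit on the [-1, 1]-scaled age axis."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < degree + 1:
        raise InsufficientDataError(f"{n} points cannot support degree {degree}")
    lo, hi = float(np.min(ages)), float(np.max(ages))
    t = np.zeros_like(ages) if hi == lo else 2.0 * (ages - lo) / (hi - lo) - 1.0
    coef, rss = _fit_rss(t, values, degree)
    V = _design(t, degree)
    dof = max(n - (degree + 1), 1)
    xtx_inv = np.linalg.pinv(V.T @ V)
    cov = (rss / dof) * xtx_inv
    # map scaled-basis coefficients back to natural age units
    if hi == lo:
        natural = coef.copy()
    else:
        p = np.polynomial.Polynomial(coef, domain=[lo, hi], window=[-1.0, 1.0])
        natural = p.convert().coef
        if natural.size < degree + 1:
            natural = np.pad(natural, (0, degree + 1 - natural.size))
    return PolynomialModel(
        degree=degree, coeffs=natural, scaled_coeffs=coef,
        age_lo=lo, age_hi=hi, cov_scaled=cov, rss=rss, n=n,
    )


def trim_corrected_sigma(
    s: float, lower: float, upper: float, mu: float = 0.0, iterations: int = 4
) -> float:
    """SD corrected for IQR-fence truncation by truncated-normal moment matching.

    Solves s^2 = sigma^2 * v(a, b) by fixed point, where v is the variance of
    a standard normal truncated to a = (lower-mu)/sigma, b = (upper-mu)/sigma.
    With no effective truncation (infinite fences) the input SD is returned.
    """
    if s <= 0 or not np.isfinite(s):
        return s
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)
    sigma = float(s)
    for _ in range(iterations):
        a = (lower - mu) / sigma
        b = (upper - mu) / sigma
        Z = 0.5 * (math.erf(b * inv_sqrt2) - math.erf(a * inv_sqrt2))
        if Z >= 1.0 - 1e-15:
            return float(s)
        if Z <= 1e-12:
            return sigma
        pa = inv_sqrt2pi * math.exp(-0.5 * a * a) if abs(a) < 40 else 0.0
        pb = inv_sqrt2pi * math.exp(-0.5 * b * b) if abs(b) < 40 else 0.0
        m = (pa - pb) / Z
        v = 1.0 + (a * pa - b * pb) / Z - m * m
        if not (0.0 < v <= 1.0):
            return sigma
        sigma = float(s) / math.sqrt(v)
    return sigma


def trim_corrected_sigma_bounds(
    s: float,
    lowers: np.ndarray,
    uppers: np.ndarray,
    mu: float = 0.0,
    iterations: int = 4,
) -> float:
    """Trim correction with per-point truncation fences.

    Each kept point survived its own effective interval (the residual fences
    intersected with the raw fences shifted by the trend at that point's
    age); moment matching uses the mean truncated-normal variance over
    points, s^2 = sigma^2 * mean_i v(a_i, b_i).
    """
    if s <= 0 or not np.isfinite(s):
        return s
    from scipy.special import erf

    lowers = np.asarray(lowers, dtype=float)
    uppers = np.asarray(uppers, dtype=float)
    inv_sqrt2 = 1.0 / math.sqrt(2.0)
    inv_sqrt2pi = 1.0 / math.sqrt(2.0 * math.pi)
    sigma = float(s)
    for _ in range(iterations):
        a = np.clip((lowers - mu) / sigma, -38.0, 38.0)
        b = np.clip((uppers - mu) / sigma, -38.0, 38.0)
        Z = 0.5 * (erf(b * inv_sqrt2) - erf(a * inv_sqrt2))
        pa = inv_sqrt2pi * np.exp(-0.5 * a * a)
        pb = inv_sqrt2pi * np.exp(-0.5 * b * b)
        ok = Z > 1e-12
        v = np.ones_like(Z)
        m = np.where(ok, (pa - pb) / np.where(ok, Z, 1.0), 0.0)
        v = np.where(
            ok, 1.0 + (a * pa - b * pb) / np.where(ok, Z, 1.0) - m * m, 1.0
        )
        vbar = float(np.clip(v, 1e-6, 1.0).mean())
        sigma = float(s) / math.sqrt(vbar)
    return sigma


def fit_age_trend(
    ages: np.ndarray, values: np.ndarray, alpha_fit: float = 0.05
) -> AgeTrendFit:
    """Two-pass IQR rejection with degree-selected polynomial age fits."""
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    finite = np.isfinite(values) & np.isfinite(ages)
    idx = np.flatnonzero(finite)
    if idx.size < 4:
        raise InsufficientDataError(
            f"need >= 4 finite (age, value) pairs, got {idx.size}"
        )
    a, v = ages[idx], values[idx]

    raw_b = iqr_bounds(v)
    out_raw = raw_b.outside(v)
    keep1 = ~out_raw
    if keep1.sum() < 4:
        raise InsufficientDataError("fewer than 4 points survive raw-value rejection")

    d_prov = select_degree(a[keep1], v[keep1], alpha_fit)
    prov = fit_polynomial(a[keep1], v[keep1], d_prov)
    res1 = v[keep1] - prov.predict(a[keep1])

    resid_b = iqr_bounds(res1)
    out_res = resid_b.outside(res1)
    keep1_idx = np.flatnonzero(keep1)
    keep_final_local = keep1_idx[~out_res]
    if keep_final_local.size < 4:
        raise InsufficientDataError("fewer than 4 points survive residual rejection")

    af, vf = a[keep_final_local], v[keep_final_local]
    d_final = select_degree(af, vf, alpha_fit)
    model = fit_polynomial(af, vf, d_final)
    residues = vf - model.predict(af)

    rejected_local = np.setdiff1d(np.arange(idx.size), keep_final_local)
    rej_res = v[rejected_local] - model.predict(a[rejected_local])

    # effective truncation interval per kept point: residual fences
    # intersected with the raw fences mapped into residual scale
    trend_kept = model.predict(af)
    t_lo = np.maximum(resid_b.lower, raw_b.lower - trend_kept)
    t_hi = np.minimum(resid_b.upper, raw_b.upper - trend_kept)

    s = float(np.std(residues, ddof=1)) if residues.size > 1 else 0.0
    # regression dof: p = d+1 fitted parameters absorb part of the spread
    n_par = model.degree + 1
    dof = max(residues.size - n_par, 1)
    s_dof = float(np.sqrt((residues @ residues) / dof))
    s_corr = trim_corrected_sigma_bounds(s_dof, t_lo, t_hi, mu=float(residues.mean()))
    return AgeTrendFit(
        model=model,
        raw_bounds=raw_b,
        resid_bounds=resid_b,
        kept=idx[keep_final_local],
        rejected_raw=idx[np.flatnonzero(out_raw)],
        rejected_residual=idx[keep1_idx[out_res]],
        residues=residues,
        rejected_residues=rej_res,
        trunc_lower=t_lo,
        trunc_upper=t_hi,
        sigma_norm_all=s,
        sigma_norm_corrected=s_corr,
        age_min=float(af.min()),
        age_max=float(af.max()),
    )


def evaluate_trend(model: PolynomialModel, age, age_min=None, age_max=None):
    """Evaluate the fitted trend at an age.

    Returns ``(value, ci_halfwidth, extrapolated)``; the flag marks ages
    outside the kept healthy-control range, where polynomial extrapolation
    loses reliability rapidly.
    """
    value = model.predict(age)
    hw = model.ci_halfwidth(age)
    lo = model.age_lo if age_min is None else age_min
    hi = model.age_hi if age_max is None else age_max
    extrapolated = bool(np.any((np.asarray(age) < lo) | (np.asarray(age) > hi)))
    if np.ndim(age) == 0:
        return float(value), float(hw), extrapolated
    return value, hw, extrapolated
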