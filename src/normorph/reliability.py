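"""Measurement error from short-interval repeat scans, and artifact modeling.

Measurement error sigma_meas is the pooled within-subject SD of age-fit
residues over healthy controls rescanned within two years — short enough
that true aging is negligible against scan-rescan variability.

Artifacts are modeled as a zero-centered Gaussian residue component of
width sigma_out, estimated as the mean absolute final-fit residue of the
rejected outliers.  The probability of an artifact being *detectable* as an
outlier given the empirical fences (x_lower, x_upper) is

    p_out = Phi(x_lower / sigma_out) + 1 - Phi(x_upper / sigma_out)

and scaling the observed outlier rate up by 1/p_out estimates the total
artifact probability p_art = (N_out / N) / p_out (capped at 1), from which
the odds for a valid measurement follow as odds = (1 - p_art) / p_art.
When no outliers were observed, p_art = 0 is only a lower limit of the true
artifact probability and the odds are reported as +inf with that flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

#: repeat scans qualify for reliability estimation below this separation
REPEAT_WINDOW_YEARS = 2.0


@dataclass(frozen=True)
class ReliabilityEstimate:
    sigma_meas: float
    n_repeat_subjects: int
    n_repeat_visits: int
    has_reliability_data: bool


@dataclass(frozen=True)
class ArtifactModel:
    sigma_out: float
    p_out: float
    n_out: int
    p_art: float
    odds: float            # +inf when p_art == 0
    lower_limit: bool      # True when no outliers were observed


def estimate_sigma_meas(
    subject_ids: np.ndarray,
    ages: np.ndarray,
    residues: np.ndarray,
    max_separation: float = REPEAT_WINDOW_YEARS,
) -> ReliabilityEstimate:
    """Pooled within-subject SD of residues from qualifying repeat scans.

    A subject qualifies with >= 2 visits whose ages span less than
    ``max_separation`` years.  The estimator is the unbiased pooled one,
    sqrt( sum_i sum_j (x_ij - mean_i)^2 / sum_i (k_i - 1) ).
    """
    subject_ids = np.asarray(subject_ids)
    ages = np.asarray(ages, dtype=float)
    residues = np.asarray(residues, dtype=float)
    order = np.argsort(subject_ids, kind="stable")
    sid, a, x = subject_ids[order], ages[order], residues[order]
    uniq, start = np.unique(sid, return_index=True)
    bounds = np.append(start, sid.size)
    ss = 0.0
    dof = 0
    n_subj = 0
    n_vis = 0
    for i in range(uniq.size):
        lo, hi = bounds[i], bounds[i + 1]
        k = hi - lo
        if k < 2:
            continue
        if a[lo:hi].max() - a[lo:hi].min() >= max_separation:
            continue
        xi = x[lo:hi]
        ss += float(((xi - xi.mean()) ** 2).sum())
        dof += k - 1
        n_subj += 1
        n_vis += k
    if dof == 0:
        return ReliabilityEstimate(0.0, 0, 0, False)
    return ReliabilityEstimate(float(np.sqrt(ss / dof)), n_subj, n_vis, True)


def estimate_sigma_out(outlier_residues: np.ndarray) -> float:
    """Width of the artifact Gaussian: mean absolute residue of the outliers."""
    outlier_residues = np.asarray(outlier_residues, dtype=float)
    outlier_residues = outlier_residues[np.isfinite(outlier_residues)]
    if outlier_residues.size == 0:
        raise InsufficientDataError("no rejected outliers to estimate sigma_out from")
    return float(np.mean(np.abs(outlier_residues)))


def artifact_p_out(x_lower: float, x_upper: float, sigma_out: float) -> float:
    """Probability that a zero-centered artifact of width sigma_out lands outside the fences."""
    if sigma_out <= 0:
        raise ValidationError("sigma_out must be positive")
    return float(
        stats.norm.cdf(x_lower / sigma_out) + stats.norm.sf(x_upper / sigma_out)
    )


def artifact_probability(n_out: int, n: int, p_out: float) -> tuple[float, float, bool]:
    """Scale the observed outlier rate by detectability: returns (p_art, odds, lower_limit)."""
    if not 0 <= n_out <= n or n <= 0:
        raise ValidationError(f"invalid outlier count {n_out} of {n}")
    if n_out == 0:
        return 0.0, float("inf"), True
    if p_out <= 0:
        raise ValidationError("p_out = 0 with observed outliers is inconsistent")
    p_art = min(1.0, (n_out / n) / p_out)
    odds = (1.0 - p_art) / p_art
    return p_art, odds, False


def build_artifact_model(
    rejected_residues: np.ndarray,
    resid_lower: float,
    resid_upper: float,
    n_total: int,
) -> ArtifactModel:
    """Assemble the full artifact model for one key from its fit diagnostics."""
    rejected_residues = np.asarray(rejected_residues, dtype=float)
    n_out = int(np.isfinite(rejected_residues).sum())
    if n_out == 0:
        return ArtifactModel(
            sigma_out=float("nan"), p_out=float("nan"), n_out=0,
            p_art=0.0, odds=float("inf"), lower_limit=True,
        )
    sigma_out = estimate_sigma_out(rejected_residues)
    p_out = artifact_p_out(resid_lower, resid_upper, sigma_out)
    p_art, odds, lower_limit = artifact_probability(n_out, n_total, p_out)
    return ArtifactModel(sigma_out, p_out, n_out, p_art, odds, lower_limit)
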