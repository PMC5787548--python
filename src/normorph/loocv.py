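"""Leave-one-out cross-validation of anomaly rates in healthy controls.

Holding out one control *subject* at a time — all their visits together, so
repeat scans can never match against themselves — the normative statistics
are rebuilt from scratch on the remainder (age-trend refit, outlier
rejection, measurement-error re-estimation) and every held-out visit is
scored exactly like a patient visit.  Aggregated over held-out visits and
keys, the fraction of uncorrected p-values below alpha estimates the
empirical anomaly rate, which for well-calibrated statistics equals alpha;
exact binomial tests compare the observed counts against the nominal level
and, optionally, against an empirical reference rate from a designated
reference run.

FDR-corrected counts apply Benjamini-Hochberg per held-out visit across
that visit's full key family, mirroring how a patient dataset is corrected.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .age_model import fit_age_trend, trim_corrected_sigma_bounds
from .anomaly import DEFAULT_N_MIN, fdr_flags
from .exceptions import InsufficientDataError, ValidationError
from .reliability import estimate_sigma_meas
from .table import MorphTable

logger = logging.getLogger(__name__)



@dataclass
class LoocvReport:
    """Anomaly counts and rates per variant and significance level."""

    summary: pd.DataFrame      # variant x alpha rows
    n_visits_tested: int
    n_subjects: int
    pvalues: pd.DataFrame | None = None   # per-test records when requested

    def with_empirical_reference(self, reference: "LoocvReport") -> "LoocvReport":
        """Add binomial tests against a reference run's empirical rates."""
        ref = reference.summary.set_index(["variant", "alpha"])
        rows = self.summary.copy()
        p_emp = []
        for _, r in rows.iterrows():
            try:
                rate0 = float(ref.loc[(r["variant"], r["alpha"]), "rate_uncorrected"])
            except KeyError:
                p_emp.append(np.nan)
                continue
            if not 0.0 < rate0 < 1.0:
                p_emp.append(np.nan)
                continue
            p_emp.append(
                binomial_rate_test(
                    int(r["count_uncorrected"]), int(r["test_count"]), rate0
                )
            )
        rows["p_binomial_empirical"] = p_emp
        return LoocvReport(rows, self.n_visits_tested, self.n_subjects, self.pvalues)


def binomial_rate_test(count: int, n_tests: int, rate0: float) -> float:
    """Exact two-sided binomial p (point-probability ordering)."""
    if not 0 <= count <= n_tests:
        raise ValidationError(f"count {count} outside [0, {n_tests}]")
    if not 0.0 < rate0 < 1.0:
        raise ValidationError("rate0 must be in (0, 1)")
    return float(stats.binomtest(count, n_tests, rate0).pvalue)


def null_calibration_study(
    n_keys: int,
    seed: int,
    n_test_subjects: int = 34,
    n_subjects: int = 323,
    alphas=(0.01, 0.05),
) -> LoocvReport:
    """LOOCV anomaly rates on an idealized Gaussian normative cohort.

    Simulates a single-site cohort (no artifacts, no measurement noise,
    Gaussian residues around realistic age trends), randomly selects
    ``n_test_subjects`` controls and runs subject-level LOOCV.  For
    well-calibrated statistics the uncorrected anomaly rate equals each
    nominal level.
    """
    from .synthetic import realistic_cohort_config, simulate_cohort
    from .table import join_metadata

    cfg = realistic_cohort_config(
        n_keys=n_keys, seed=seed, n_subjects=n_subjects,
        sigma_meas_true=0.0, artifact_fraction=0.0, single_site=True,
    )
    tab, meta, _ = simulate_cohort(cfg)
    joined = join_metadata(tab, meta)
    rng = np.random.default_rng([seed, 1])
    subjects = sorted(
        rng.choice(meta["subject_id"].unique(), size=n_test_subjects, replace=False)
    )
    return loocv_assess(joined, subjects, alphas=alphas)


def loocv_assess(
    table: MorphTable,
    test_subjects,
    alphas=(0.01, 0.05),
    alpha_fit: float = 0.05,
    n_min: int = DEFAULT_N_MIN,
    return_pvalues: bool = False,
) -> LoocvReport:
    """Score held-out control subjects against the refitted remainder.

    ``table`` is a metadata-joined control table (variants included if their
    rates are wanted).  For every subject in ``test_subjects`` the full
    normative machinery is rebuilt without that subject and each of their
    visits is scored per key.
    """
    if not table.has_metadata:
        raise ValidationError("loocv_assess requires joined metadata")
    f = table.frame
    hc_subjects = set(f.loc[f["group"] == "control", "subject_id"])
    missing = [s for s in test_subjects if s not in hc_subjects]
    if missing:
        raise ValidationError(f"test subjects not in the control set: {missing}")

    # ---- pre-split per key into flat arrays (reused across iterations)
    subj_codes, subj_uniques = pd.factorize(f["subject_id"])
    match_lbl = (
        f["sex"].astype(str) + "\x1f" + f["scanner_model"].astype(str)
        + "\x1f" + f["sequence"].astype(str)
    )
    match_codes, _ = pd.factorize(match_lbl)
    keystr = table.key_strings().to_numpy()
    ages_all = f["age"].to_numpy(dtype=float)
    values_all = f["value"].to_numpy(dtype=float)
    visit_lbl = (f["subject_id"].astype(str) + "\x1f" + f["visit_id"].astype(str)).to_numpy()

    order = np.argsort(keystr, kind="stable")
    key_sorted = keystr[order]
    key_names, key_starts = np.unique(key_sorted, return_index=True)
    key_bounds = np.append(key_starts, key_sorted.size)
    per_key = []
    for i, kname in enumerate(key_names):
        sel = order[key_bounds[i]:key_bounds[i + 1]]
        per_key.append(
            (
                kname,
                kname.split("|")[3],       # variant
                ages_all[sel],
                values_all[sel],
                subj_codes[sel],
                match_codes[sel],
                visit_lbl[sel],
            )
        )

    sub_code_of = {s: i for i, s in enumerate(subj_uniques)}
    records = []   # (visit label, variant, p)
    n_untested = 0
    tested_visits = set()

    for subject in test_subjects:
        s_code = sub_code_of[subject]
        for kname, variant, ages, values, scodes, mcodes, vlbls in per_key:
            held = scodes == s_code
            if not held.any():
                continue
            train = ~held
            try:
                fit = fit_age_trend(ages[train], values[train], alpha_fit)
            except InsufficientDataError:
                n_untested += int(np.isfinite(values[held]).sum())
                continue
            tr_idx = np.flatnonzero(train)
            kept_global = tr_idx[fit.kept]
            res = fit.residues
            rel = estimate_sigma_meas(scodes[kept_global], ages[kept_global], res)
            sigma_meas = rel.sigma_meas
            kept_match = mcodes[kept_global]
            n_fit = res.size
            n_par = fit.model.degree + 1
            dof_factor = math.sqrt(n_fit / max(n_fit - n_par, 1))
            for j in np.flatnonzero(held):
                if not np.isfinite(values[j]):
                    continue
                residue = float(values[j] - fit.model.predict(ages[j]))
                sel = kept_match == mcodes[j]
                nm = int(sel.sum())
                if nm < n_min:
                    n_untested += 1
                    continue
                x = res[sel]
                x_norm = float(x.mean())
                s = float(x.std(ddof=1))
                if s <= 0:
                    n_untested += 1
                    continue
                s_corr = trim_corrected_sigma_bounds(
                    s * dof_factor, fit.trunc_lower[sel], fit.trunc_upper[sel],
                    mu=x_norm,
                )
                var_trend = fit.model.predict_variance(ages[j])
                mean_term = max(1.0 / nm - 1.0 / n_fit, 0.0)
                sigma = math.sqrt(
                    s_corr * s_corr * (1.0 + mean_term)
                    + sigma_meas * sigma_meas + var_trend
                )
                z = abs(residue - x_norm) / sigma
                p = 2.0 * float(stats.t.sf(z, nm - 1))
                records.append((vlbls[j], variant, p))
                tested_visits.add(vlbls[j])

    rec = pd.DataFrame(records, columns=["visit", "variant", "p"])
    rows = []
    for variant in sorted(rec["variant"].unique()) if len(rec) else []:
        rv = rec[rec["variant"] == variant]
        for alpha in alphas:
            n_tests = len(rv)
            count_u = int((rv["p"] < alpha).sum())
            # BH per held-out visit over the visit's full key family
            count_f = 0
            for _, grp in rec.groupby("visit"):
                flags = fdr_flags(grp["p"].to_numpy(), alpha)
                count_f += int(flags[(grp["variant"] == variant).to_numpy()].sum())
            rows.append(
                {
                    "variant": variant,
                    "alpha": float(alpha),
                    "test_count": n_tests,
                    "count_uncorrected": count_u,
                    "count_fdr": count_f,
                    "rate_uncorrected": count_u / n_tests if n_tests else np.nan,
                    "rate_fdr": count_f / n_tests if n_tests else np.nan,
                    "p_binomial_nominal": (
                        binomial_rate_test(count_u, n_tests, float(alpha))
                        if n_tests else np.nan
                    ),
                    "n_untested": n_untested,
                }
            )
    summary = pd.DataFrame(rows)
    logger.info(
        "LOOCV: %d subjects, %d visits tested, %d tests, %d untested",
        len(list(test_subjects)), len(tested_visits), len(rec), n_untested,
    )
    return LoocvReport(
        summary=summary,
        n_visits_tested=len(tested_visits),
        n_subjects=len(list(test_subjects)),
        pvalues=rec if return_pvalues else None,
    )
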