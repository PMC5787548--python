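# Methods

`normorph` turns tables of region-wise brain morphometry (FreeSurfer-style
volumes, cortical thickness, surface area, curvature measures, gray–white
contrast, whole-brain partial volume estimates) into individual-level
statistics: *is this patient's measurement abnormal for their age, sex and
scanner?* and *is this patient's change over follow-up faster than normal
aging?*  All statistics are referenced to a normative database of healthy
controls (HCs) built once and persisted.

## Normative model

For every measurement key (region × hemisphere × parameter × variant) the
HC values `X` are modeled as a polynomial age trend plus residue:

    X = X_poly(age) + x,        x ~ N(0, sigma_norm)

with additive sex/scanner/sequence offsets handled not by regression but by
*exact matching*: patient statistics are computed against the subset of HC
residues whose sex, scanner model and acquisition sequence all equal the
patient's.  This avoids singular nuisance-parameter designs when the
"group" being compared is a single scan, at the cost of a smaller matched
sample.

### Outlier rejection and age-trend fitting

Per key, cleaning and fitting run in a fixed two-pass scheme:

1. values more than 1.5 interquartile ranges outside the 25 %/75 %
   percentiles (linear-interpolation quartiles) are rejected;
2. a provisional polynomial fit is made; residues are rejected by the same
   1.5×IQR rule;
3. the final fit is made on the doubly cleaned data.

The rejection runs exactly once (raw, then residual), not iterated.  The
polynomial degree is selected stepwise from 0 upward by nested-model
F-tests: degree d is accepted over d−1 when

    F = (RSS_{d−1} − RSS_d) / (RSS_d / (N − d − 1))

exceeds the upper `alpha_fit/d` quantile of F(1, N−d−1).  The Bonferroni
factor d is applied per step (d tests performed up to step d); the search
stops at the first rejection and is capped at d_max = floor(N/20) —
one degree per twenty observations (d_max = 16 at N = 323).  The
provisional fit uses the same selection procedure, so residual rejection is
not biased by an arbitrary provisional degree.  `alpha_fit` defaults
to 0.05.  Fitting is performed on the age axis mapped to [−1, 1] for
conditioning; coefficients are reported in natural age units.  Stepwise-up
selection cannot discover *pure even* curvature (a symmetric parabola makes
the linear step insignificant); empirically cortical aging trends are
monotone-with-curvature, for which selection is consistent.

### Measurement error

`sigma_meas` per key is the pooled unbiased within-subject SD of final-fit
residues over HCs rescanned within two years (short enough that true aging
is negligible):

    sigma_meas² = Σ_i Σ_j (x_ij − mean_i)² / Σ_i (k_i − 1).

Subjects qualify when ≥ 2 visits span < 2 years.  With no qualifying
repeats, sigma_meas = 0 is reported with an explicit "no reliability data"
flag and the series-consistency test is skipped.

### Artifact model and validity odds

Artifacts are modeled as a zero-centered Gaussian residue component of
width `sigma_out`, estimated as the mean absolute final-fit residue of the
rejected outliers (the literal "mean absolute" convention; not rescaled by
√(π/2) to a Gaussian SD — the estimator is switchable but the default
follows the definition above).  The probability that an artifact is
*detectable* as an outlier given the residual fences (x_<, x_>) is

    p_out = Φ(x_< / sigma_out) + 1 − Φ(x_> / sigma_out),

and the total artifact probability scales the observed outlier rate by the
detectability:

    p_art = (N_out / N) / p_out    (capped at 1),
    odds  = (1 − p_art) / p_art.

N_out counts both rejection passes.  With no observed outliers, p_art = 0
is reported as a *lower limit* (odds = +∞, flagged).  Two biases are worth
knowing: statistical outliers of the valid Gaussian (≈ 0.7 % per pass)
inflate N_out, so p_art mildly overestimates the true contamination — a
conservative direction for the odds; and Eq.-style upscaling can exceed 1
for tiny p_out, hence the cap.

## Single-visit assessment

The patient's residue x = X − X_poly(age) is compared to the matched HC
residues (mean x_norm, SD sigma_norm, size n_m; keys with fewer than
`n_min = 10` matched controls are skipped with a warning).  The predictive
variance adds all error sources:

    sigma² = sigma_norm²·(1 + 1/n_m − 1/n_fit) + sigma_meas² + var_trend(age)

where var_trend is the fit-error variance of the age trend at the
patient's age and the 1/n_m − 1/n_fit term propagates the matched-subset
mean uncertainty (least-squares residues are constrained to zero overall
mean, hence the −1/n_fit).  The reported p-value is the calibrated
two-sided one,

    p_ucor = 2 · T_{n_m−1}( |x − x_norm| / sigma ),

using the Student-t upper tail with n_m − 1 degrees of freedom — the exact
predictive reference for a Gaussian observation compared against a sample
mean and SD; the Gaussian CDF Φ is its large-sample limit.  Under the null
p_ucor is Uniform(0, 1), so the fraction of keys flagged at level α is α.
A *directional* single-tail probability (0.5 at the normative mean, small
in the direction of the deviation) is available for display purposes.

### Trim-bias correction

Because the 1.5×IQR fences truncate the residue distribution at roughly
±2.7 σ, the sample SD of kept residues underestimates the normative spread
by ≈ 3 %, which alone inflates anomaly rates by ~10–30 % relative.  The SD
entering the p-value is therefore corrected by truncated-normal moment
matching: solve s² = σ²·mean_i v(a_i, b_i) for σ, where v is the variance
of a standard normal truncated to each point's *effective* interval — the
residual fences intersected with the raw fences shifted by the trend at
that point's age (the raw pass truncates age-asymmetrically when a trend is
present).  The residual SD uses regression degrees of freedom
(RSS/(N − d − 1)) before correction.  The uncorrected ddof = 1 SD is kept
as `sigma_norm_all` for reporting.

### Multiple testing and highlighting

Benjamini–Hochberg FDR is applied per assessed dataset (one visit or one
series) across its full key family (typically > 10³ tests).  Highlights:
*yellow* = uncorrected p < α (secondary expert inspection advised), *red* =
significant after FDR.  Two levels, α = 0.05 and α = 0.01, are used
side by side.  Feature vectors are L = −sign(x − x_norm)·log10(p): large
positive = abnormally increased, large negative = abnormally decreased;
Pearson correlation matrices of feature vectors across scans quantify
their reproducibility.

## Normalization variants

Every raw key gains a `normalized` sibling: values rescaled to the mean HC
eTIV (frozen at database build) with the geometric exponent of the
parameter class — volumes n = 1, areas n = 2/3, thicknesses n = 1/3, mean
curvature and curvature index n = −1/3, Gaussian curvature and folding
index n = −2/3.  Gray–white contrast depends on scanner and sequence, not
head size, and is instead rescaled multiplicatively so every HC
scanner–sequence group has the grand HC mean; patients are rescaled by
their own group's HC-derived factor (a patient never influences the
factors).  The multiplicative choice reflects contrast being a positive
percentage-like quantity.  Left/right pairs gain a bilateral `asymmetry`
sibling, (R − L)/(R + L) on raw values (eTIV factors cancel): 0 =
symmetric, ±1 = fully lateralized; undefined when R + L = 0.

## Follow-up series

Per key, residues over ≥ 3 visits are cleaned by a per-series 1.5×IQR pass
(plus an audited manual exclusion list) and fitted with x(t) = a·t + x₀ by
OLS.  Conventions: S² = RSS/n and sigma_t = population SD of visit times,
under which the slope uncertainty

    Δa = S / (sigma_t · √(n − 2))

is algebraically identical to the textbook OLS slope standard error — this
resolves an otherwise odd-looking formula and is asserted against a
brute-force oracle in the tests.  Tests per key:

* **consistency**: chi-squared upper tail of RSS/sigma_meas² with n − 2 df
  — does a line describe the series no worse than measurement noise allows?
* **slope**: two-sided z-test of a against 0.  Residues already subtract
  the HC age trend, so slope 0 means change consistent with cross-sectional
  aging.  At n = 10 visits the z approximation inflates the nominal 5 %
  type-I rate to ≈ 8.6 % (t₈ vs normal); this is documented rather than
  silently re-derived, and the acceptance tests assert both the n = 10
  inflation and the near-nominal behavior of long series.
* **mean position**: Welch's two-sample t-test of the patient's residues
  against the matched HC residues.

Clinical series (EDSS, lesion volume) get the same slope machinery plus
Spearman's rank correlation with age — exact permutation p for n ≤ 9, the
t-approximation otherwise.

## Leave-one-out cross-validation

Calibration is validated by holding out one HC *subject* at a time (all
their visits together, so repeat scans never match against themselves),
rebuilding the full normative machinery on the remainder (age-trend refit,
rejection, sigma_meas re-estimation — the conservative full-refit
interpretation), and scoring each held-out visit like a patient.
Aggregated counts per variant and α are compared with the nominal rate and
optionally with an empirical reference run by exact two-sided binomial
tests (point-probability ordering).

## Synthetic cohorts

The generator emulates what the statistics assume: per-key polynomial age
trends with sex/scanner offsets; a Gaussian between-subject effect shared
across a subject's visits plus independent within-subject noise (so repeat
scans estimate measurement error, not population spread); artifacts as
*replacement* draws from a wide zero-centered Gaussian with probability
`artifact_fraction` (matching the zero-centered artifact residue model; not
offset shifts); a subset of subjects rescanned within two years; patient
series as trend + baseline offset + linear slope + noise.  Defaults mirror
a single-site normative database: 323 subjects aged 7–79 (uniform ages —
calibration needs age coverage, not the bimodal demographic histogram of a
real recruitment), 56 % female, 31 repeat subjects, artifact fraction
1.5 % with width 6 SD.  Keys are generated independently; real morphometry
has strong inter-regional correlation, so passing calibration tests here
says nothing about the *joint* distribution of anomalies across regions —
only about per-key rates.  Identical config + seed gives bit-identical
output.

## Problem sizes in the shipped checks

The calibration study used by `scripts/acceptance.py` runs 2,000
independent keys × 34 held-out subjects (≈ 68,000 tests, a few minutes on
one CPU); the test suite runs the same study at 600 keys (≈ 21,600 tests)
plus module-level Monte-Carlo checks at 10³–10⁵ draws.  These sizes give
binomial standard errors of ≈ 0.0004–0.0015 on the estimated rates, small
against the 99 % confidence bands they are compared to.

## Known limitations

* Extrapolating the polynomial trend outside the HC age range is unreliable
  and flagged, never silently accepted.
* p_art is biased upward by valid-tail outliers (conservative for odds);
  it is a lower limit where no outliers were observed.
* The z-based slope test is anticonservative for very short series (see
  above); the chi-squared consistency test depends on a nonzero sigma_meas
  estimate and is skipped without repeat-scan data.
* Matched subsets can be small for rare scanner–sequence combinations;
  keys below `n_min` are skipped loudly rather than silently pooled.
* HC repeats inform reliability only; longitudinal *aging trajectories* are
  cross-sectional by construction.
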