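# normorph

Normative modeling of regional brain morphometry for individual patients.

Radiological reading easily misses slow, regional tissue loss.  `normorph`
takes tables of region-wise morphometric parameters (FreeSurfer-style
volume segmentations and cortical parcellation measures: volumes, mean/SD
cortical thickness, surface area, curvature and folding indices,
gray–white contrast, whole-brain partial volume estimates) and answers two
clinical questions quantitatively, per region and parameter:

1. **Cross-sectional** — is this patient's measurement abnormal for their
   age, sex, scanner and sequence, given the measurement's own error bar
   and the probability that it is an artifact?
2. **Longitudinal** — over a follow-up series, is this patient changing
   faster than cross-sectional healthy aging predicts?

It is aimed at neuroimaging groups who maintain a healthy-control (HC)
database and want standardized, rater-independent per-patient reports.
Image processing itself (segmentation, parcellation, lesion filling) is
out of scope; the inputs are the exported statistics tables.

## The model in brief

Per measurement key, HC values are cleaned by a two-pass 1.5×IQR outlier
rejection and fitted with a polynomial age trend `X_poly(age)` whose degree
is chosen by Bonferroni-corrected nested F-tests (capped at
`d_max = N/20`).  All statistics run on the residues `x = X − X_poly(age)`.
From the HCs the pipeline also estimates, per key:

* `σ_meas` — scan–rescan measurement error, pooled within-subject SD over
  controls rescanned within 2 years;
* an artifact model: width `σ_out` of the artifact residue distribution,
  detectability `p_out = Φ(x_</σ_out) + 1 − Φ(x_>/σ_out)`, artifact
  probability `p_art = (N_out/N)/p_out` and validity odds
  `(1 − p_art)/p_art`.

A patient visit is scored against the HCs matching their sex, scanner and
sequence exactly: the variances add,

    σ² = σ_norm²·(1 + 1/n_m − 1/n_fit) + σ_meas² + var_trend(age),

and the two-sided p-value uses the Student-t predictive reference, which is
Uniform(0,1) for healthy-like visits — so the flag rate at level α is α.
σ_norm is corrected for the tail mass removed by the IQR fences
(truncated-normal moment matching).  Benjamini–Hochberg FDR across all
keys of a dataset separates *yellow* (uncorrected p < α) from *red*
(FDR-surviving) findings, and feature vectors
`L = −sign(x)·log₁₀(p)` summarize each scan.  Follow-up series get an OLS
line `x(t) = a·t + x₀` with slope uncertainty
`Δa = S/(σ_t·√(n−2))` (identical to the OLS slope SE), a chi-squared
consistency test against `σ_meas²`, a slope z-test and a Welch test against
the matched HCs.  Calibration of the whole machinery is validated by
subject-level leave-one-out cross-validation (LOOCV) in HCs.

## Worked example

Simulate a 200-subject single-site HC cohort for left/right hippocampal
volume (age trend 4400 − 6·age mm³, between-subject SD 250 mm³, scan–rescan
SD 60 mm³, 1.5 % artifacts), build the normative database, and assess one
visit:

```bash
normorph simulate --config cfg.yaml --out-dir sim
# wrote 450 records for 200 subjects to sim
normorph build-db --table sim/table.csv --metadata sim/metadata.csv --out normative.json
# normative database: 5 keys, 225 control visits (200 subjects), 20 outliers rejected -> normative.json
normorph assess-visit --db normative.json --table sim/table.csv \
    --metadata sim/metadata.csv --subject hc0007 --visit v01 --out-dir visit
# 5 keys assessed: 1 yellow, 0 red, 0 skipped -> visit
```

`visit/assessment.tsv` (abridged):

```
key                                        value    residue  p_ucor  n_matched    odds       L  highlight
hippocampus|bilateral|volume|asymmetry    0.0764     0.0662  0.2001        123  65.652  0.6989  none
hippocampus|left|volume|raw            4167.1839  -111.8420  0.6047        122  24.858 -0.2185  none
hippocampus|right|volume|normalized    5361.2738   936.1414  0.0474        121  39.273  1.3243  yellow
```

Reading the yellow row: this subject's eTIV-normalized right hippocampus
is 936 mm³ above the age-trend expectation of the 121 sex/scanner/sequence
matched controls; the chance of a healthy deviation this large is
p ≈ 0.047, worth a second look but not significant after FDR (the 5-key
family here is tiny; real runs correct over >10³ keys).  The odds of 39:1
say the measurement itself is unlikely to be an artifact.  The build
rejected 20 of 1125 control records (~1.8 %) as outliers, consistent with
the 1.5 % injected artifact rate plus Gaussian tails.

The database is a versioned JSON archive whose save/load round-trip is
bit-exact; `assess-series` produces the analogous per-key table for
follow-up trends, and `loocv` reports empirical anomaly rates with exact
binomial tests against the nominal level.

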