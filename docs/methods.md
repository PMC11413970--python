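# Methods

## Model and statistic

The screening problem: given per-analyte numerical values for diseased
cases and normal controls, find analytes associated with a *subtype* — a
subset of the cases whose values are shifted while the remaining cases
behave like controls. Mean- or median-based statistics dilute such signals
by construction; a subtype instead skews the case distribution or gives it
a second mode. The package therefore scores each analyte with the
difference in Sarle's bimodality coefficient between the groups,

    BC  = (s² + 1) / (k + 3·(n−1)²/((n−2)(n−3))),
    BCD = |BC(cases) − BC(controls)|,

with s the sample skewness and k the excess kurtosis. BC is scale- and
location-invariant and strictly inside (0, 1) — a consequence of the
Pearson inequality k ≥ s² − 2 combined with the finite-sample factor
exceeding 1 — with the asymptotic uniform value 5/9. High BC also responds
to strong unimodal skew, which is deliberate: skew different between
groups is equally a subtype signature. The absolute value in BCD protects
against controls being the more bimodal group (analytes that cycle within
healthy individuals, e.g. with time of sampling, can be bimodal in
controls).

### Estimator convention

Skewness and kurtosis use the plain moment estimators g1 = m3/m2^{3/2},
g2 = m4/m2² − 3 with central moments averaged over n. The bias-corrected
variants G1, G2 are available via `bias_corrected=True`; at the group
sizes this statistic is meant for (n ≳ 100) the two differ by well under
1% of the BC value, and the BC formula already carries its own explicit
n-correction. Moments are computed after centring on the sample mean to
avoid catastrophic cancellation when intensities are large relative to
their spread; samples whose variance underflows are treated as constant.
Constant samples and n < 4 raise typed errors rather than returning
sentinels, so the screening layer can count and report skipped analytes
by reason. Missing values are dropped per analyte per group before any
moment computation.

## Comparator metrics

* **log2FC** — |log2(center(cases)/center(controls))| on min/max-normalized
  values, median center by default. The median is the default rather than
  the mean because the mean chases the subtype mode and roughly doubles
  the statistic at a 50% subtype, which does not match how the benchmark's
  operating points behave; a `center="mean"` switch exists. Non-positive
  centers raise: fold change is undefined at or below the noise floor.
* **AUC** — the Mann–Whitney rank statistic with midrank tie handling:
  auc_raw = P(random case > random control), ties counting ½. The primary
  reported value is the *folded* AUC max(A, 1−A), which is what an
  in-sample fitted classifier effectively reports because the fit adapts
  its direction to the data; its null median is not 0.5 but
  0.5 + 0.6745·SE(AUC) (half-normal median), ≈ 0.509 at 1,000 + 1,000
  samples. An optional logistic-regression route (scikit-learn) exists for
  parity checking — a single-covariate logistic fit is monotone in the
  covariate, so its ROC area equals the rank AUC up to orientation — but
  the deterministic rank computation is the default.

## Winsorization

Outliers disproportionately inflate kurtosis and hence distort BC.
Values beyond Q1 − 3·IQR or Q3 + 3·IQR are clamped to the fence (not
deleted); quartiles use linear interpolation of order statistics (the
numpy default dialect; at the 3×IQR distance the fence is insensitive to
dialect for all but tiny samples, and the dialect is configurable).
Clamped sample identities are recorded because the upper-fence hits *are*
the candidate second mode and feed the covariate diagnostics.

**Fence scope.** Fences are computed on the pooled cases + controls values
per analyte, and the clamp applied to both groups ("pooled" scope, the
default). This keeps both groups on a common scale: per-group fences would
clamp a genuine case-only second mode much harder than the controls and
systematically shrink the group difference at large subtype fractions.
The pooled scope is the configuration under which the simulation
benchmark's operating points (below) hold; a per-group scope and an "off"
switch are provided for sensitivity analysis. Order of operations is
winsorize → (normalize, for FC only) → metric; BC is affine-invariant so
normalization placement only matters for fold change.

## Simulation benchmark

Each trial draws one pseudo-analyte: a fraction p of the 1,000 cases from
the subtype distribution N(0.40, 0.16), the remaining cases and all 1,000
controls from the background N(0.03, 0.04) (means and SDs chosen as a
realistic highly differentially-expressed analyte on a normalized
intensity scale). Seven scenarios sweep p over 0, 5, 10, 20, 30, 40, 50%;
1,000 trials per scenario; subtype count = round(p·n_cases). Scenario
summaries report median/min/max per metric.

Useful closed forms used as cross-checks: the expected raw AUC is
(1−p)/2 + p·Φ(0.37/√(0.04² + 0.16²)) ≈ 0.5 + 0.4876·p, and the folded
null median is 0.5 + 0.6745·√((n1+n2+1)/(12·n1·n2)). The BCD median rises
monotonically with p up to 40% and then dips at 50% — the case
distribution approaches symmetric bimodality while pooled winsorization
clamps its upper mode — and the test suite asserts this signature.

**Randomness.** One base seed; trial t of a scenario uses the substream
keyed by (seed, t), so trials are reproducible independently and in any
order, and identical specs give bit-identical metric streams.

## Matrix screening

Per analyte: pooled winsorization → BCD on winsorized groups, folded rank
AUC, and median log2FC on min/max-normalized winsorized values. Analytes
with fewer than 4 finite values in either group, or constant after
winsorization, are skipped and logged. Ranks (1 = largest) break ties by
analyte id so top-fraction extraction is deterministic; the top fraction
takes ⌈f·n⌉ analytes.

**Significance.** Case/control labels are permuted B times (configurable,
≥ 19); the null statistics are pooled across analytes and permutations and
p = (b + 1)/(B_total + 1) with b the number of pooled null values ≥ the
observed one. Pooling across analytes assumes the analytes are
exchangeable under the label-permutation null; on a homogeneous null
matrix the p-values calibrate to uniform (asserted at B = 99 on a
500-analyte fixture). The null 95th percentile of each metric is reported
as the α = 0.05 reference cutoff. **No multiple-testing correction is
applied** — the p-values are per-analyte screening quantities and every
output that contains them carries a banner saying so; hits need
validation in independent data.

**Fence diagnostics.** For a chosen analyte and covariate, the samples
clamped at the upper fence are cross-tabulated by covariate level per
group, next to the level's background proportion in that group; a level is
flagged enriched when its clamped proportion is at least twice background
(ratio configurable). A top-ranked analyte whose second mode is
concentrated in one covariate level that is rare overall indicates a
sampling confound (e.g. a tissue region with a strong case/control
imbalance), to be handled by excluding the stratum and re-screening.

## Synthetic fixtures

The fixture generator emits a genes × samples matrix shaped like a cortex
case/control expression study (defaults: 176 cases, 187 controls, a
4-level brain-region covariate in which region 4 holds 12.5% of cases but
only 4.8% of controls, and region 2 is similarly unbalanced). Null
analytes draw every sample from the background N(0.03, 0.04); planted
subtype analytes move a chosen fraction of cases to N(0.40, 0.16);
planted confounded analytes give all samples of one covariate level
far-outlier values (N(1.2, 0.05)), reproducing the spurious-second-mode
artifact end to end. What the fixtures deliberately do **not** emulate:
inter-analyte correlation, heteroscedastic intensity-dependent noise,
batch effects, or heavy-tailed measurement error — so passing tests
demonstrate the metric's behaviour under its own model, not robustness to
everything real expression data can do.

## Problem sizes in the test suite

The acceptance-level tests run the benchmark at its standard size
(7 × 1,000 trials of 1,000 + 1,000 samples; a few seconds in total).
Null-calibration uses a 500-analyte fixture at 99 permutations;
planted-subtype recovery uses 100 seeded repeats of a 50-analyte screen.

## Known limitations

* BC responds to skew as well as bimodality; BCD flags distributional
  difference generally, and top hits must be inspected (histograms,
  fence reports) before a "subtype" interpretation.
* BCD deliberately ignores location shifts: global biomarkers that move
  nearly all cases are better captured by FC or AUC.
* Small groups (n below ~50 per group) estimate kurtosis poorly; the
  typed-error floor is n = 4 but that is a formula constraint, not a
  power claim.
* The permutation null pools across analytes; with strongly heterogeneous
  analyte distributions the pooled cutoffs are only approximate
  (per-analyte nulls would need far more permutations).
* The command-line interface is a thin wrapper; the library functions are
  the primary surface.
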