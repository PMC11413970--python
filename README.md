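# bcd — Bimodality Coefficient Difference screening

Tools for finding **disease-subtype biomarkers** in case/control studies of
numerical analytes (gene expression, protein or metabolite levels, imaging
measurements). Conventional screening statistics — fold change (FC) and the
area under the ROC curve (AUC) — summarise a shift of the *whole* case
group, so a biomarker expressed by only a subset of the cases is diluted
away. The Bimodality Coefficient Difference looks at the *distribution* of
the values instead: a subtype biomarker leaves the controls unimodal while
giving the cases a second mode.

## The statistic

Sarle's bimodality coefficient of a sample of size *n* with skewness *s*
and excess kurtosis *k* is

```
BC = (s² + 1) / (k + 3·(n−1)² / ((n−2)(n−3)))
```

BC lies in (0, 1); the asymptotic value for a uniform distribution is
5/9 ≈ 0.556 and larger values indicate stronger bimodality or skew. The
screening statistic is the case/control difference

```
BCD = | BC(cases) − BC(controls) |
```

Large BCD flags analytes whose cases are distributed differently from the
controls — the signature of a subtype — even when group medians barely
move. The package also implements the two comparators as they are used in
practice (absolute log2 fold change of group medians on min/max-normalized
values, and the orientation-free "folded" rank AUC), pooled 3×IQR
winsorization with clamp-identity tracking, label-permutation significance,
and covariate diagnostics for the second mode.

## Worked example: the subtype simulation benchmark

Seven scenarios draw 1,000 cases and 1,000 controls per trial; a fraction
of the cases (0–50%) comes from a shifted subtype distribution
N(0.40, 0.16) and everything else from the background N(0.03, 0.04). Each
scenario runs 1,000 trials; each trial is winsorized (pooled 3×IQR fences)
and scored with all three metrics:

```
bcd simulate --seed 0 --out table.tsv
```

prints `wrote table.tsv (7 scenarios)` and the table contains (selected
columns, rounded):

```
               subtype_fraction  log2fc_median  auc_median  bcd_median  bcd_min  bcd_max
subtype_0pct               0.00          0.016       0.509       0.016    0.000    0.087
subtype_5pct               0.05          0.027       0.524       0.144    0.074    0.225
subtype_10pct              0.10          0.055       0.549       0.282    0.201    0.359
subtype_20pct              0.20          0.121       0.598       0.395    0.337    0.466
subtype_30pct              0.30          0.208       0.647       0.440    0.377    0.520
subtype_40pct              0.40          0.330       0.695       0.463    0.411    0.537
subtype_50pct              0.50          0.602       0.744       0.436    0.374    0.509
```

Read it this way: even with **half** the cases in a nearly ideal subtype,
the median |log2FC| is 0.60 — below the conventional log2FC > 1 cutoff in
every single trial — and the median AUC only reaches 0.74, the edge of the
usual "acceptable" band. BCD, by contrast, is already ≈ 0.28 at a 10%
subtype, far above its null level of 0.016, and stays high throughout.
The slight dip from 40% to 50% is expected: as the subtype approaches half
of the cases, the case distribution becomes *more* symmetric-bimodal but
the pooled winsorization clamps the subtype mode harder, and the case BC
peaks before 50%.

## Screening an expression matrix

```
bcd fixtures --n-analytes 100 --planted 7:0.3 --confound 9 --seed 0 --out-dir fix/
bcd screen --expr fix/expression.tsv --pheno fix/phenotype.tsv \
    --permutations 199 --top-frac 0.05 --seed 0 \
    --diagnose-covariate region --out-dir results/
```

`screen` accepts any tab-separated analytes × samples matrix plus a
phenotype table (`sample_id`, `status` = case/control, covariate columns).
It writes per-analyte scores with raw permutation p-values (no
multiple-testing correction is applied — the output banner says so), the
top-5% overlap between the three metrics, and a fence report
cross-tabulating the samples clamped at the upper winsorization fence
against a covariate. When the clamp set of a top-ranked analyte is
dominated by one covariate level that is rare in the background (e.g. a
brain region sampled almost only in cases), the signal is a sampling
confound: exclude the stratum with `--exclude-covariate region=2,4` and
re-screen.

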