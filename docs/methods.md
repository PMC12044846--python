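# Methods

This note documents the models, conventions and numerical choices behind
`evscore`, in the order the pipeline runs them, and what the synthetic-data
experiments do and do not demonstrate.

## Cross-cohort harmonization (MCQ)

Independent expression cohorts (log2 intensities, features × samples)
carry dataset-specific location and scale bias. The merge chain is:

1. **Quantile normalization** per dataset: every sample's sorted values are
   replaced by the row-wise means of the column-sorted matrix. Tied values
   receive the mean of the reference values spanning their tied ranks, the
   standard mean-of-order-statistics convention; within-column order is
   therefore preserved weakly (strict order can only collapse where the
   reference itself ties — e.g. the globally top-ranked gene becomes
   constant across samples, which also caps how large an expression effect
   can survive normalization for genes at the extreme of the distribution).
2. **Feature collapse**: features map to genes via an explicit table; for
   genes with several features the feature with the highest row mean is
   kept verbatim, ties broken toward the lexicographically smaller feature
   id (a fixed, documented convention).
3. **Median centering**: each gene row's median across the dataset's
   samples is subtracted, so dataset-level additive shifts vanish exactly.
4. **Pooled quantile scaling**: each dataset's matrix is flattened; a value
   with (average, tie-aware) rank r among n is mapped to the pooled
   distribution's quantile at r/(n+1), interpolating linearly between
   pooled order statistics at positions k/(N+1) (Weibull plotting positions
   on both sides). With matching conventions, datasets already drawn from
   identical distributions pass through numerically unchanged, which is the
   behavior the identity tests pin down.
5. **Join** on the intersection of gene ids (complete cases; downstream
   rank statistics need complete rows). Sample ids are prefixed with the
   dataset id, and per-sample provenance is kept.

The pooled distribution — rather than a designated reference cohort — is
the scaling target; the alternative was underdetermined and the pooled
choice treats cohorts symmetrically.

## Marker-selection funnel

Four etiology-based comparisons (HBV, HCV, ALD, MASLD): per gene, one-sided
Mann–Whitney (HCC > non-HCC of that etiology) with Benjamini–Hochberg
correction, plus a floor on the median log2 difference. A gene passes a
comparison iff q < `fdr_q` (default 0.05) and the median difference ≥
`min_log2fc` (default 1.0); the four passing sets are intersected —
"across four comparisons" is read as *all four*, which maximizes
specificity. Three reference filters follow, each comparing a gene's mean
expression to a quantile (type-7, linear interpolation) of all row means in
an auxiliary matrix: keep genes high in HCC cell lines (default quantile
0.75), drop genes high in immune cells (0.75), keep genes high in EVs
(0.50). A qPCR screen ranks survivors by the differential d = e(tumor
cells) − e(white blood cells) with expression proxy e = max(0, 40 − Ct)
(no amplification ⇒ e = 0; ties broken by gene id, making the ranking a
deterministic total order); the top-6 join a six-gene legacy panel, giving
a 12-candidate panel after deduplication. All thresholds are analysis
choices held in `SelectionParams`, not literature facts.

## Scoring

Copies are used as reported (per-mL-plasma equivalents), transformed as
log2(copies + 1). Gene weights are Golub signal-to-noise ratios,
(μ₁ − μ₀)/(σ₁ + σ₀ + ε), with sample SDs (n − 1) and guard ε = 1e−8 so
degenerate zero-variance groups yield large-but-finite weights. The
per-sample Digital Score is (1/m) Σ wᵢ·log2(cᵢ+1); the Δ score applies
the same form to gene-wise post − pre differences, making
Δ = DS(post) − DS(pre) an algebraic identity (tested to 1e−12). A missing
panel gene is scored as zero copies with a warning. The published
formulation divides by the panel size 6; the implementation generalizes the
divisor to m.

One source contradiction is left documented rather than resolved: the
narrative text describes Δ as "post subtracted from pre" while the printed
equation computes gene_post − gene_pre; the equation (post − pre) is
implemented.

## Treatment-response model

TR = β₀ + β_post·DS_post + β_Δ·ΔDS on the linear-predictor scale, with the
published instance (−8.132, 1.226, 1.146) and cutoff 0.76 frozen and
immutable. Two conventions the source leaves open: the cutoff is taken to
live on the linear-predictor scale (consistent with the printed formula's
scale; a probability output through the logistic link is provided as a
convenience), and the boundary case score = cutoff is classified viable
(the source only says scores "above" the cutoff suggest viable disease).

Refitting is maximum-likelihood logistic regression (statsmodels Logit;
convergence: relative log-likelihood change < 1e−8 or 100 iterations).
Separation — detected via the optimizer's separation diagnostics, a
coefficient-norm bound of 50, or non-convergence — triggers a minimal-ridge
fallback (L2 penalty 1e−4) and an explicit `penalized_separation_fallback`
flag, since unpenalized ML diverges on separable small cohorts. Fitted
models take their cutoff from the Youden-optimal threshold of in-sample
linear predictors.

Cross-validation uses hand-rolled stratified folds: per-class seeded
shuffle followed by a single round-robin deal across classes, so k = n
reduces exactly to leave-one-out (verified against brute-force refits). A
fold that loses a class is fitted anyway with a warning. The LASSO variant
standardizes predictors, walks 50 log-spaced penalties from the null point
(max |X'(y − ȳ)|/n) down four decades, picks the penalty by stratified
5-fold cross-validated deviance, and reports the AUROC of pooled held-out
linear predictors; the vanishing-penalty limit reproduces the unpenalized
fit to 1e−3.

## Evaluation machinery

- **AUROC**: Mann–Whitney pairwise concordance (ties credit 0.5); tested
  exhaustively against brute-force enumeration for n ≤ 50.
- **DeLong**: structural components via midranks; Wald CI on the AUROC
  scale clipped to [0, 1] (no logit transform — the source reports plain
  intervals); zero variance (perfect separation) degenerates to a flagged
  point interval. The paired test uses the component covariance between
  assays measured on the same subjects; zero difference-variance yields
  p = 1 with a flag.
- **Youden cutoff**: candidate thresholds are midpoints of adjacent
  distinct scores plus ±∞, positive call = score ≥ threshold; ties in J
  are broken by higher specificity, then lower threshold (an explicit
  convention).
- **Implied accuracy**: TP = round(sens·n_pos), TN = round(spec·n_neg)
  with half-up rounding — this reproduces reported training
  (81.8%/87.5% on 33/16 → 83.7%) and validation (76.5%/88.2% on 34/17 →
  80.4%) accuracies exactly.
- **Power**: Monte-Carlo, not closed-form, so the paired DeLong test is
  exercised end to end. Per replicate, case scores of the two assays are
  bivariate normal with unit variances and correlation ρ, shifted by
  δ = √2·Φ⁻¹(AUROC) per assay; controls share ρ with zero means. Power is
  the rejection fraction at two-sided α with its binomial SE. Under the
  stated design (0.86 vs 0.63, ρ = 0.5, 32/16, α = 0.05) the simulated
  power is ≈ 0.82–0.84, consistent with the nominal 80% sample-size claim;
  a null design rejects at ≈ α.
- **Linearity QC**: per-gene OLS of copies on spike-in level,
  R² = 1 − SS_res/SS_tot; noise-free series give R² = 1 exactly.

## Synthetic data: what it emulates, and what it does not

Defaults define the study conditions: 3 cohorts × 200 genes with 50
samples per (state, etiology) cell across the four-etiology cycle; batch
shift SD 2.0 (log2) and multiplicative scale SD 0.15; 10 planted markers
shifted +2 log2 units in HCC samples. dPCR copies are rounded log-normal
(location `copy_mu` = 4.6 ≈ 100 copies, SD 0.8 on the natural-log scale,
measurement noise SD 0.25) — chosen over a negative binomial because the
readout is a continuous-scale absolute-copy estimate and the parameters
stay interpretable. Inter-patient copy dispersion is uncharacterized in
the source; the log-normal is a stand-in.

A treated patient's copies are background + r × tumor component, with
residual fraction r = `viable_residual` (0.9) for viable and
1 − `response_drop` (0.1) for nonviable patients. Because r is
deterministic per group, synthetic TR cohorts separate almost perfectly
(AUROC ≈ 1.0 in the worked example); real cohorts mix treatment
modalities, tumor burdens and assay noise and sit near AUROC 0.9. Passing
tests on this generator demonstrate the *mechanics* (identities, ordering,
calibration, parameter recovery), not clinical performance.

For parameter-recovery experiments, setting `tr_coefficients` switches the
generator to a well-specified mode: r ~ Uniform(0, 1) per patient, and the
viability label is Bernoulli(logistic(β₀ + β_post·DS_post + β_Δ·ΔDS))
computed with known generating weights (all ones). Refitting at n = 5000
then recovers the generating coefficients within 10% median relative
error, which would be ill-defined under the label-first mechanistic mode.

The funnel's auxiliary references are labeled synthetic stand-ins: the
cell-line/EV matrices elevate the planted markers (plus filler genes up to
20% of the universe) by 4 log2 units, the immune matrix elevates a
disjoint 30% gene set; the fractions are placed on opposite sides of the
filters' default quantile tails so thresholds fall between the two
expression clusters and the discriminative content of the funnel test is
the four-comparison differential step.

All generators are driven by `numpy.random.default_rng` seeded from a
single integer; identical configurations are byte-reproducible.

## Known limitations

- No modeling of dPCR partition statistics, EV capture efficiency, or
  covariate-adjusted (age/sex/etiology) classifiers.
- The harmonization currently joins on complete gene intersections; union
  joins with missingness would require imputing into the rank machinery.
- DeLong Wald intervals without a logit transform can clip at [0, 1] for
  extreme AUROCs at small n; the flagged degenerate interval marks the
  perfectly separated case.
- Quantile normalization flattens genes pinned to the extreme rank in
  every sample (see above); markers at the very top of the expression
  distribution can lose their differential signal before selection.
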