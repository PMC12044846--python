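# evscore

A tested re-implementation of the computational chain behind an
extracellular-vesicle (EV) liquid-biopsy score for assessing treatment
response in hepatocellular carcinoma (HCC). Plasma EVs carry tumor-derived
mRNA; absolute copy numbers of a small gene panel, measured by RT-dPCR
before and after treatment, are combined into per-patient scores that
separate patients with viable residual tumor from complete responders.

The package is for computational biologists who want to exercise, test or
extend any stage of such a pipeline — cross-cohort transcriptome
harmonization, marker-panel selection, weighted digital scoring, the
treatment-response classifier, and its evaluation/power machinery — without
access to patient data: a synthetic-data module generates every input with
planted ground truth.

## The statistics at the core

**Digital Score.** For a plasma sample with copy numbers $c_i$ over a panel
of $m$ genes,

$$\mathrm{DS} = \frac{1}{m}\sum_{i=1}^{m} w_i \,\log_2(c_i + 1),$$

where the gene weight $w_i$ is the Golub signal-to-noise ratio
$(\mu_{\mathrm{HCC}} - \mu_{\mathrm{cirr}})/(\sigma_{\mathrm{HCC}} +
\sigma_{\mathrm{cirr}})$ estimated on $\log_2(c+1)$ values in a labeled
pilot cohort (HCC vs cirrhosis). The ΔDigital Score of a pre/post
treatment pair applies the same weighted sum to gene-wise post − pre
differences and is identically $\mathrm{DS}_{\mathrm{post}} -
\mathrm{DS}_{\mathrm{pre}}$.

**Treatment-response (TR) score.** The published two-covariate logistic
model, on the linear-predictor scale:

$$\mathrm{TR} = -8.132 + 1.226\cdot \mathrm{DS}_{\mathrm{post}} + 1.146\cdot \Delta\mathrm{DS},$$

with decision cutoff 0.76 (score ≥ 0.76 calls viable tumor). The package
ships this model frozen and can refit it, with leave-one-out / stratified
k-fold cross-validation and an L1 (LASSO) path as stability checks.

**Harmonization (MCQ).** Independent expression cohorts are merged by
per-dataset quantile normalization, collapse of redundant features to the
highest-mean row per gene, per-gene median centering, and quantile scaling
of each dataset's flattened values onto the pooled distribution.

**Evaluation.** Mann–Whitney AUROC, DeLong variance/CI and the paired
DeLong test, Youden-index cutoffs, and a Monte-Carlo power calculation for
comparing two correlated assays' AUROCs on the same subjects.

## Worked example

The numbered scripts under `analysis/` run the whole chain on synthetic
data (seed as optional argument) and write their tables under `results/`:

```bash
python analysis/01_simulate_inputs.py 0
python analysis/02_build_atlas.py
python analysis/03_select_markers.py
python analysis/04_pilot_scoring.py
python analysis/05_tr_study.py 0
python analysis/06_power_and_linearity.py 0
```

Output with seed 0:

```
merged 3 cohorts -> 200 genes x 1200 samples
  null-gene batch variance share: median 0.106 -> 0.001 (improved for 100.0% of genes)
  planted effects keep positive sign after merge: True (median shift 1.73 log2 units)
...
planted-marker recovery: 10/10; false discoveries: 0
...
pilot Digital Score AUROC 0.983 (95% CI 0.962-1.000); Youden cutoff 4.667: sens 0.943, spec 0.943
...
fitted TR model: -2.963 + 2.754*post + 19.446*delta; Youden cutoff 0.352
  train      AUROC 1.000 ...  validation AUROC 1.000 ...
paired DeLong power at the design (0.86 vs 0.63, corr 0.5, 32/16): 83.7% +- 0.5%
spike-in linearity over 12 genes, 7 levels, 5% CV noise: R^2 range 0.9987-0.9999
```

Reading the numbers: the harmonization removes essentially all
dataset-level variance from null genes while planted differential effects
survive with their sign; the selection funnel recovers all ten planted
markers with no false discoveries; the pilot Digital Score separates
synthetic HCC from cirrhosis almost perfectly (the planted effect is
strong); the refitted TR model separates viable from nonviable patients
completely, because the synthetic treatment effect is deterministic per
group — real cohorts are noisier (see `docs/methods.md`); the power of the
paired DeLong design matches its nominal 80% target; and noisy spike-in
series regress with R² > 0.99.

The same stages are available as a CLI (`evscore simulate | merge-atlas |
select-markers | weights | score | fit-tr | apply-tr | evaluate | power |
run-pilot | run-tr`); `evscore COMMAND --help` shows each contract.

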