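# sonotx

Radiotranscriptomic staging analysis for prostate cancer: joint analysis of
transrectal ultrasound radiomics, contrast-enhanced ultrasound (CEUS)
perfusion kinetics and RNA-seq expression to separate organ-confined (T2c)
from locally advanced (T3b) disease.

The package is aimed at imaging-genomics researchers who want a tested,
fully offline implementation of this analysis style. Because the clinical
cohorts behind such studies are rarely public, `sonotx` ships a first-class
synthetic-study generator that emulates the statistical structure every
stage assumes (stage-separable speckle textures, refill-shaped
time–intensity curves, negative-binomial expression with planted
stage-specific signals, cohort-matched clinical covariates), so the whole
pipeline is reproducible end to end from a single seed.

## What it computes

* **Texture radiomics** — from each grayscale image + ROI mask, a 368-entry
  feature vector: 6 global first-order features, 40 higher-order features
  from mask-aware GLCM / GLRLM / GLSZM / NGTDM count matrices, and the same
  46 features on each of 7 sub-bands (ch1, cv1, cd1, ca2, ch2, cv2, cd2) of
  a two-level Haar wavelet transform (7 × 46 = 322).
* **CEUS perfusion** — nonlinear least-squares fit of the
  destruction–replenishment refill model *I(t) = A(1 − e^(−βt))*, reported
  as RBV = A, RBF = A·β, β⁻¹ and RT = ln 10 / β (time to 90% of plateau).
* **Stepwise feature selection** — greedy relevance–redundancy selection
  against the 0/1 class: maximal |r(f, y)| primes; later steps maximize
  |r(f, y)| − mean |r(f, retained)| and stop when the monitoring score
  (mean redundancy + relevance) drops below a configurable fraction of the
  previous step's.
* **Differential expression** — log2(CPM+1) normalization, per-feature
  Welch t-tests with Benjamini–Hochberg correction, flags at p < 0.05 and
  linear fold change > 1.5; stage-specific Venn sets (DE vs healthy in one
  stage's comparison but not the other's); a six-biomarker panel filter
  (FZD4, RPS7, RPL29, miR-9-3p, miR-374c, miR-6510) with directions;
  hypergeometric gene-set enrichment for user-supplied GMT collections.
* **Integration** — per-stage Pearson correlation maps between radiomic
  features and biomarker expression (t-transform p-values, starred at
  0.05/0.01), and canonical correspondence analysis of the biomarker
  abundance table against the stage indicator.
* **Staging evaluation** — random forest, Gaussian naive Bayes and SVM over
  repeated stratified 70/30 splits on four feature sets (clinical,
  transcriptomic panel, radiomic, combined), with a self-contained
  Mann–Whitney rank AUC.
* **Regulatory network** — monotone trend filtering of group means along
  healthy → T2c → T3b, joined with a miRNA→target edge list into a
  bipartite graph ranked by hub out-degree.

## Worked example

Fit the refill model to one noisy CEUS time–intensity curve:

```python
import numpy as np
from sonotx import RefillModel, TICurve

rng = np.random.default_rng(7)
t = np.linspace(0.0, 12.0, 40)
true = 1.2 * (1 - np.exp(-0.6 * t))
tic = TICurve(t, true + rng.normal(0, 0.05, t.size), subject_id="T3B001")
print(RefillModel(tic).fit().summary())
```

```
Refill model: I(t) = A (1 - exp(-beta t))
subject:   T3B001
n points:  40
A (RBV):   1.17433
beta:      0.60916 1/s
beta_inv:  1.64161 s
RBF:       0.715351 /s
RT (90%):  3.77994 s
RSS:       0.0638334
R-squared: 0.980756
```

The plateau estimate Â = 1.174 and rate β̂ = 0.609 recover the true
(1.2, 0.6) to a few percent at 4% noise; RT says the ROI refills to 90% of
its plateau 3.8 s after the destruction flash.

Run the whole pipeline on a small synthetic cohort:

```python
from sonotx import PipelineConfig, StudyConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", seed=7, runs=5,
                     study=StudyConfig(n_healthy=6, n_T2c=10, n_T3b=8,
                                       image_size=64, n_mrna=200, n_mirna=80,
                                       n_planted_de=10))
report = run_pipeline(cfg)
```

The returned report (also written to `demo_run/report.json`) includes, for
this seed: `biomarkers_passing: 6` (all six planted biomarkers survive the
p < 0.05 & FC > 1.5 filter with their planted directions),
`grn: {n_hubs: 4, n_covered_genes: 9}` (the planted hub structure is
recovered exactly), `n_radiomic_features: 736` (368 per modality for B-mode
and CEUS-peak), and mean held-out AUCs per feature set and model — e.g.
`combined/svm: 1.0` versus `clinical/svm: 0.53` on this strongly separable
synthetic cohort.

The same stages are available from the shell:

```bash
sonotx simulate --seed 7 --out-dir study/
sonotx extract --images study/images --masks study/masks --out features.csv
sonotx perfusion --tics study/tics.csv --out perf.csv
sonotx run --seed 7 --out-dir pipeline_out/
```

## Documentation

`docs/methods.md` describes the models, conventions, numerical choices and
known limitations in detail, including exactly which aspects of real
ultrasound and RNA-seq data the synthetic generator does and does not
emulate.
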