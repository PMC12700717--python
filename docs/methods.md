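# Methods

This note documents the models, conventions, defaults and numerical
choices of `sonotx`, and what the synthetic-study design can and cannot
show about real data.

## Texture radiomics

**Quantization.** In-mask intensities are binned into `Ng` equal-width
levels spanning the in-mask `[min, max]` range (default `Ng = 32`; the
small-image test fixtures use 4–16). A constant region maps to level 1.
Equal-width binning over the in-mask range makes every higher-order feature
invariant to affine intensity changes applied before quantization, a
property the tests assert.

**Global features (6).** Population (not sample) mean, variance, skewness
and kurtosis of in-mask intensities; Shannon entropy (base 2) and energy of
the `Ng`-bin intensity histogram. Skewness and kurtosis of a constant
region are defined as 0.

**GLCM (9 features).** Co-occurrence counts aggregated by summing over
distance-1 offsets at 0°/45°/90°/135°, symmetrized; pairs with either pixel
outside the mask are excluded. Features: Energy (angular second moment),
Contrast, Correlation, Homogeneity (inverse difference moment), Entropy,
Variance, SumAverage, Dissimilarity, MaxProbability. Correlation of a
zero-variance matrix is defined as 0.

**GLRLM (13).** Runs are maximal colinear same-level segments lying
entirely inside the mask, counted over the four directions and summed into
one matrix. Standard run-length statistics (SRE, LRE, GLN, RLN, RP, LGRE,
HGRE, SRLGE, SRHGE, LRLGE, LRHGE, GLV, RLV). Run percentage is normalized
as `n_runs / (n_pixels × n_directions)` so it stays in (0, 1] after
direction aggregation; with a single direction this reduces to the textbook
definition.

**GLSZM (13).** Zones are 8-connected components of equal level inside the
mask (`scipy.ndimage.label`). Features mirror the run-length family with
zone size in place of run length (SZE, LZE, …, LZHGE, GLV, ZSV); e.g.
LZHGE = Σ p(i,z)·z²·i².

**NGTDM (5).** For each in-mask pixel with at least one in-mask 8-neighbor,
the absolute difference between its level and the mean level of its in-mask
neighbors is accumulated per level (`s_i`); the Amadasun–King coarseness,
contrast, busyness, complexity and strength follow. Degenerate cases:
coarseness is capped at 10⁶ when all `s_i` vanish; busyness and strength
are 0 when their denominators vanish.

All four matrix builders are vectorized but defined to agree exactly with
per-pixel enumeration; the test suite checks every feature against an
independent brute-force oracle on random masked images at 1e-10.

**Wavelet sub-bands.** Two-level separable DWT with the Haar wavelet and
periodic extension (orthonormal, hence energy-conserving — Parseval is
asserted to 1e-8 relative). Level-1 detail bands ch1/cv1/cd1 are retained;
the level-1 approximation is decomposed again into ca2/ch2/cv2/cd2. `ch`
responds to horizontal structure, `cv` to vertical, `cd` to diagonal. The
ROI mask is decimated alongside: a decimated cell is in-mask only when all
four contributing cells are (conservative — features never mix in- and
out-of-ROI coefficients). Sub-band features are computed on masked
coefficients; an empty decimated mask yields sentinel zeros with a warning.

**Inventory.** 6 global + 40 higher-order (9 GLCM + 13 GLRLM + 13 GLSZM +
5 NGTDM) native features, plus the same 46 on each of the 7 sub-bands:
368 total. The 9/13/13/5 split is this package's inventory choice; it uses
the standard Haralick / run-length / size-zone / Amadasun–King definitions
and contains every feature name the analysis style refers to (e.g.
`cv2-GLSZM-LZHGE`, `ca2-GLCM-Correlation`, `ch1-Global-Skewness`). Names
render as `<subband>-<family>-<feature>` (sub-band omitted for native
features) and parse back losslessly.

For CEUS, the frame to analyze is chosen as the one with maximal mean
in-mask intensity (the time–intensity peak); single frames bypass this.

## CEUS perfusion

The refill (destruction–replenishment) model is mono-exponential,
I(t) = A(1 − e^(−βt)). Fitting uses `scipy.optimize.curve_fit` with
positivity bounds and analytic initialization (A₀ = max intensity; β₀ from
a log-linear fit of 1 − I/A₀ against t with the plateau inflated by 5% to
keep the logarithm finite). Derived features are exact functions of the
estimates: RBV = A, RBF = A·β, β⁻¹, and RT = ln 10/β, the time to reach
90% of the plateau. Defining RT through the 90% criterion keeps it distinct
from β⁻¹ (the 63% time constant); both are module conventions, as is
leaving RBV/RBF in arbitrary intensity units (no calibration constant).
Non-convergence or a nonpositive parameter raises an explicit `FitFailure`;
`perfusion_table` flags failed subjects (`fit_ok = False`) rather than
dropping them silently. Monte-Carlo behaviour: at 5% plateau noise over 50
points spanning five time constants, the median relative error of both
estimates is below 5% (about 1% for A and 3% for β in the acceptance run).

## Stepwise feature selection

Relevance is |Pearson r| between a feature and the 0/1-encoded class;
zero-variance features score 0. The priming feature maximizes relevance.
Each later step selects the candidate maximizing
relevance − mean |r(candidate, retained)| — most related to the class,
least related to what is already kept. The monitoring score recorded at
every step is mean redundancy **plus** relevance; the procedure stops when
this score falls below `drop_ratio` (default 0.5) times the previous score,
or at `max_features` (default 20). The criterion subtracts redundancy while
the score adds it because the two play different roles: the selection rule
must penalize redundancy for the "least related" behaviour, whereas the
additive score is the literal stopping quantity; a `redundancy_sign="plus"`
variant exposes the fully additive criterion for comparison. "Dropped
sharply" is operationalized as a relative drop because it is scale-free and
needs a single parameter. Ties break lexicographically by feature name, so
the trace is a pure function of its input; the suite checks exact trace
equality against a brute-force greedy oracle.

## Differential expression

Counts are normalized to log2(CPM + 1). Each feature gets a Welch two-sample
t-test on the normalized values, with Benjamini–Hochberg correction across
features; a self-implemented, distribution-light test keeps the stage
calibrated and fully testable offline (the choice is config-visible, not a
claim that it is optimal for RNA-seq). Features with zero variance in both
groups and equal means get p = 1. The DE flag combines p < `p_cutoff`
(default 0.05) with a linear-scale fold-change criterion
max(FC, 1/FC) > `fc_cutoff` (default 1.5), where FC is the ratio of linear
CPM group means (with a 0.5 offset guarding zero means). Stage-specific
sets follow Venn logic: specific-to-T2c = flagged in T2c-vs-healthy but not
in T3b-vs-healthy, and symmetrically; the all-tumor comparison is recorded
for the Venn report but not used for subtraction, since specificity is
defined by exclusion of the other stage only. Enrichment is a one-sided
hypergeometric tail per gene set with BH across sets; set content (GMT) is
user-supplied.

Calibration: under the null generator the fraction of features with
p < 0.05 lies inside the 99% binomial band around 0.05 (asserted on 600
features), and the planted six-biomarker panel passes the filter with its
planted directions in the large majority of seeds at the default effect
size.

## Integration

Correlation maps are plain Pearson r with the t-transform two-sided p
(df = n − 2), computed within a stage's samples by default because pooled
correlations conflate stage effects; raw p-values are starred at 0.05/0.01
(BH is available but off by default, matching the starring convention of
this analysis style). Zero-variance columns give r = 0, p = 1.

CCA follows the classical correspondence-analysis form: the abundance table
(linear CPM of the biomarker panel — nonnegativity is required by the
chi-square standardization) is converted to relative frequencies, the
chi-square standardized residual matrix is regressed on the row-mass-
weighted, centered constraints, and the fitted matrix is decomposed by SVD.
Eigenvalues are the squared singular values; with a single binary stage
indicator there is exactly one constrained axis. Site and species scores
are the left/right singular vectors rescaled by inverse square-root row and
column masses. The implementation reproduces an independent reference
implementation's eigenvalues and total inertia on fixed toy tables to 1e-8
(values frozen into the tests).

## Staging evaluation

AUC is computed by the Mann–Whitney rank statistic with midranks, so tied
scores contribute ½; the suite asserts exact equality with exhaustive
positive–negative pair counting. Evaluation uses repeated stratified
shuffle splits (default 10 repeats, 70/30) — chosen for class-imbalance
safety at a 13-subject minority class — with the same partitions reused
across feature sets and models so comparisons are paired. Features are
z-scored with train-split statistics only. Classifiers are scikit-learn's
random forest, Gaussian naive Bayes and SVC at library defaults (logged in
the result object); scores are class-1 probabilities where available and
the decision function otherwise. Held-out AUC is the only reported metric.

## Regulatory network

Trend filtering keeps features whose group means are weakly monotone along
healthy → T2c → T3b (each step exceeding a margin δ, default 0): mRNAs
decreasing, miRNAs increasing. Weak monotonicity of means, not per-sample
monotonicity, is used because the latter is hopeless at a 13-sample group.
Filtering operates on normalized expression. The interaction table is a
plain miRNA→gene edge list file (the synthetic generator provides one), so
the stage is fully offline; duplicate edges collapse before degree
counting. Hubs are miRNAs with out-degree ≥ `hub_min_degree` (default 2),
ranked by descending degree with lexicographic tie-breaks.

## Synthetic study design

Defaults mirror the cohort the pipeline is designed around: 22 healthy
controls, 35 T2c and 13 T3b patients. Five seed-locked independent streams
drive the five generators, so every artifact is a pure function of
(config, seed) and reruns are bit-identical.

* **Images** (default 128×128 here; 64×64 in fast tests): a smooth Gaussian
  background field modulated by multiplicative gamma speckle (shape 4,
  unit mean). Inside a shared elliptical ROI (~18% of the frame; ≥ 100
  pixels enforced) the speckle correlation length and deviation gain grow
  with stage in proportion to `texture_contrast` (default 1.5; 0 gives an
  exact no-signal null). This produces ultrasound-like granularity whose
  coarseness separates stages — it is not an acoustic simulation: no
  point-spread physics, no attenuation, no anatomy, and the ROI is common
  to all subjects.
* **TICs**: 40 points over 12 s with stage-dependent true (A, β) — (0.8,
  0.40), (1.0, 0.50), (1.3, 0.70) for healthy/T2c/T3b, each jittered ±10%
  per subject — plus Gaussian noise with SD = `tic_noise_sd`·A (default
  5%). True parameters are returned for recovery testing.
* **Expression**: negative-binomial counts (dispersion 0.2) around
  lognormal baseline means with ±30% library-depth variation. Planted:
  `n_planted_de` T2c- and T3b-specific DE features (vs healthy) per stage
  in the mRNA matrix and a third as many in the miRNA matrix, at
  |log2FC| = `de_log2fc` (default 1.5, matching the ×1.5 fold-change
  filter's scale); the six-biomarker panel between T2c and T3b with fixed
  directions (FZD4, RPS7, RPL29, miR-9-3p up in T3b; miR-374c, miR-6510
  down); twelve monotonically decreasing mRNAs and six increasing miRNAs
  (half-effect per step). A truth table labels every planted effect.
* **Clinical covariates**: truncated-normal (at 0) draws from the published
  per-stage moments (e.g. T2c age 70.11 ± 7.90 y, T3b TRUS volume
  49.50 ± 19.86 mL); Gleason categories are sampled from the published
  per-stage counts. Healthy-control moments are not published and are this
  generator's own choices (age 64 ± 8 y, tPSA 1.5 ± 1.0 ng/mL, fPSA ratio
  0.25 ± 0.08, TRUS volume 30 ± 10 mL, PSA density 0.05 ± 0.03 ng/mL²).
* **Interactions**: the four planted hub miRNAs (drawn from the increasing
  set) cover the nine first decreasing genes with out-degrees (3, 2, 2, 2),
  plus degree-1 decoys from the remaining increasing miRNAs and ~30 random
  edges among generic features that trend filtering removes.

**What passing tests show — and do not.** Green tests demonstrate that each
stage implements its stated statistic correctly (oracle equivalence), that
the test machinery is calibrated under a true null, and that planted
signals of the configured size are recovered at the configured cohort
sizes. They do not demonstrate clinical performance: real ultrasound
texture, real RNA-seq dispersion structure, inter-subject ROI variability
and real miRNA-target biology are all richer than the generator, and the
near-perfect synthetic AUCs say nothing about AUCs on a real cohort.

## Problem sizes used by the shipped runs

The default test suite exercises images from 8×8 (oracle comparisons) to
256×256 (throughput), cohorts of 16–70 subjects, 150–800 expression
features, 200 Monte-Carlo refill fits and 10-seed replication of the AUC
ordering check. `scripts/acceptance.py` uses the full default cohort
(22/35/13) at 128×128 images with 600 mRNA + 200 miRNA features. These
sizes are the package's chosen balance between statistical resolution and
a laptop-friendly runtime.

## Known limitations

* The Group-2 inventory (9/13/13/5) is a defensible reconstruction of a
  40-feature set, not a canonical list; it is count-asserted and
  config-visible.
* Whether wavelet features should be computed on masked or whole-frame
  sub-bands is a genuine ambiguity; masked is implemented (with the
  conservative all-parents mask decimation).
* The Welch-on-log-CPM DE test is a calibrated stand-in for heavier count
  models; with very low counts or extreme dispersion a negative-binomial
  GLM would behave differently.
* The stepwise selector's stopping rule can terminate after one feature
  when the best remaining candidate is both weakly relevant and weakly
  redundant — a property of the score definition, visible in the trace.
* CCA site/species score scaling follows the chi-square metric convention;
  other packages expose several alternative scalings whose axes differ by
  constant factors (eigenvalues agree).
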