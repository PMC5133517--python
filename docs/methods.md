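# Methods

## Model and procedure

`ibdqt` maps a quantitative trait by relating pairwise identity-by-descent
(IBD) sharing to pairwise trait similarity in a cohort of nominally
unrelated individuals. The analysis chain is:

1. **Phenotype preparation.** The trait (diastolic blood pressure, mm Hg)
   is adjusted for antihypertensive treatment by adding 5 mm Hg to treated
   individuals, then residualized by ordinary least squares on an intercept,
   gender, age, smoking status and the principal-component scores supplied
   with the table (population-structure surrogates). All PC columns present
   are used; no model selection is performed, so non-significant covariates
   stay in the model. Rows with missing values are dropped listwise with a
   warning. The model always includes an intercept, so residuals are
   mean-centered — which is what makes the squared-sum statistic S
   interpretable as a spread measure.

2. **Sharing matrix.** Refined IBD segment calls (8-column tab-separated
   output; several runs with different seeds) are merged at the pair level:
   haplotype indices are ignored and overlapping or book-ended intervals
   (gap tolerance 0 bp, i.e. next start ≤ current end + 1 on 1-based
   inclusive coordinates) are coalesced. The binary matrix over all
   n(n−1)/2 unordered pairs × markers sets a cell to 1 when a merged
   segment of the pair covers the marker position, testing the **closed**
   interval [start_bp, end_bp]. Pairs that never share appear as all-zero
   rows; the matrix is stored sparse (chromosome-wide sharing rates are of
   order 10⁻³). Genetic positions come from a HapMap-style map by
   piecewise-linear interpolation, with constant-rate extrapolation beyond
   the terminal anchors.

3. **Marker scan.** At each marker, D = (rᵢ−rⱼ)² and S = (rᵢ+rⱼ)² are each
   regressed on the binary sharing indicator π̂. With a binary predictor the
   OLS slope is the difference of group means and the residual variance is
   RSS/(n_pairs−2); the scan therefore needs only four sparse matrix–vector
   products for the whole chromosome (O(nnz + markers), no per-marker
   solver). The two slopes are pooled by inverse-variance weighting and
   tested one-sided (alternative: pooled slope negative) against
   t(n_pairs − 2). Markers where π̂ is constant (nobody or everybody
   shares), or where a regression has zero residual variance, are flagged
   undefined and excluded from minimum-p summaries. The reported peak
   region is the maximal run of markers with p below a configurable
   reporting threshold (default 0.01) containing the minimum-p marker.

4. **Permutation calibration.** Pairs sharing an individual are dependent,
   so familywise significance is calibrated empirically: each permutation
   shuffles the residual-to-individual assignment (Fisher–Yates), recomputes
   D and S for all pairs, re-runs the scan and records the minimum defined
   p. The α-level chromosome-wide threshold is the k-th smallest null
   minimum p with k = floor(α·n_perm) — a deliberately conservative
   convention (for α·n_perm = 50 it is the 50th smallest of 1000).
   Individual-level (not pair-level) permutation is essential: it preserves
   the dependence structure of the pair statistics exactly under the null
   of no linkage. Defaults n_perm = 1000, α = 0.05.

5. **Sequence-region variants.** At a mapped region, variants are screened
   with literal boundary conventions: excluded if multi-allelic (>2
   alleles, removed before MAF is computed since dosage coding is undefined
   for them), monomorphic (MAF = 0 on non-missing genotypes), or missing
   rate strictly greater than 15 %. Retained variants with CADD scaled
   score strictly above 20 are classified deleterious. Marker-level GWAS QC
   applies, in order: missing ≥ 5 %, MAF ≤ 1 %, MAF ≤ 5 % together with
   missing ≥ 1 %, and exact Hardy–Weinberg p < 10⁻⁴ (conditional exact
   test, no mid-p). Deleterious genotypes, the adjusted trait and the
   covariates (gender, age, smoking, first 3 PCs) are exported aligned by
   individual for an external kernel association test (SKAT-O); the kernel
   test itself is deliberately out of scope.

## The sign question in the pooled slope

Under linkage the two component regressions point in opposite directions:
sharing pairs are more alike, so β̂_D < 0, but their residuals are
positively correlated (or jointly shifted), so β̂_S > 0. The pooled
estimator implemented by default enters β̂_S *with its own sign*, which can
attenuate or even invert a true signal when the S effect dominates — as it
does for a shared ancestral haplotype carrying a directional trait shift,
where carrier pairs' residual means add in S. On generator data with the
default planted effect, the minimum-p marker essentially never falls at the
planted locus under the default pooling (measured 0/100 replicates), while
`sign_corrected=True` (β̂_S negated before pooling, so both components point
toward linkage) localizes it in 98/100 replicates. The default is kept as
the package's primary definition of the statistic; the sign-corrected mode
is exposed everywhere (library, CLI, permutation) for sensitivity analysis.
Null calibration is unaffected by the choice, since the permutation
procedure calibrates whichever statistic is scanned.

A related interpretation choice: the weights use the *residual error
variances* of the two regressions. Because both regressions share the same
design matrix, weighting by residual variance is equivalent to
inverse-sampling-variance weighting of the slopes, which is what makes the
pooled estimator a proper precision-weighted average.

## Synthetic-data generator

The generator (`ibdqt.synthetic`) emulates the study conditions the
pipeline targets, with defaults chosen once to match them:

| parameter | default | meaning |
|---|---|---|
| `n_individuals` | 105 | unrelated cohort size |
| `chrom_length_cM` | 200 | one chromosome, 1 cM/Mb constant map |
| `background_rate` | 0.0029 | target mean pairwise sharing fraction |
| `min_seg_cM` | 1.0 | detection floor for segment length |
| `seg_tail_mean_cM` | 0.47 | exponential tail → mean length 1.47 cM |
| `qtl_position_cM` | 100 | planted causal locus |
| `carrier_freq` | 0.15 | ancestral-haplotype carrier fraction |
| `qtl_effect` | 14 mm Hg | trait shift per carrier (≈1.5 × noise SD) |
| `noise_sd` | 9.3 mm Hg | residual trait SD |
| `intercept` | 71.8 mm Hg | baseline trait mean |
| `treated_frac` | 22/105 | treated subgroup fraction |
| `sequenced_frac` | 71/105 | fraction with sequence data |

Background segments are an independent per-pair Poisson process: N ~
Poisson(background_rate · L / mean_length) intervals per pair, lengths
min_seg + Exp(tail), placed uniformly. This is the simplest process with
the right mean covered fraction and detection floor; it implies the
fraction of pairs with any sharing is 1 − e^(−λ) ≈ 33 % at the defaults
(real cohorts show clustering and can sit lower at the same mean rate).
Every carrier–carrier pair receives one segment covering both the QTL and
its nearest marker (lengths are inflated to the covering width if the
marker grid is sparse), so sharing at the QTL marker is observable by
construction. Covariates are drawn with realistic cohort moments (gender
Bernoulli(0.41), age Normal(56.6, 15.5), smoking Bernoulli(0.24), PCs
Normal(0, 0.05)); covariate effects default to zero except 18.2 mm Hg per
unit of PC1. Treatment is assigned independently of the trait and the
+5 mm Hg adjustment is applied downstream, keeping generator and phenotype
stages orthogonal.

The region-variant block plants known QC failures (5 % multi-allelic, 10 %
monomorphic, 10 % with missing rate > 15 %) and assigns CADD scaled scores
so that exactly `n_deleterious` clean variants exceed 20 — giving the
variant filter an enumerable ground truth.

What the generator does **not** emulate: linkage disequilibrium and
haplotype structure, clustered/overdispersed segment counts, segment-length
distributions beyond a shifted exponential, genotyping error, and relatedness
beyond the planted segments. Passing tests therefore demonstrate the
correctness and calibration of the statistics under the stated generative
model, not robustness to every feature of real cohort data.

## Numerical choices and degenerate inputs

- Same seed ⇒ byte-identical fixture files (fixed field formats: LOD 2
  decimals, phenotype floats 6 decimals, CADD 3 decimals).
- Binary-predictor regressions use group-mean identities; within-group sums
  of squares are clipped at zero to absorb round-off.
- Undefined markers (π̂ constant, or a zero residual variance) carry NaN
  statistics and a `defined = False` flag rather than raising.
- A degenerate permutation null (all residuals identical) returns a flagged
  result with NaN threshold and a warning.
- Rank-deficient covariate designs raise an error naming the collinear
  columns; duplicate ids raise; malformed segment lines raise with their
  line number.
- t reference distribution uses df = n_pairs − 2; nominal p-values are
  anyway calibrated by permutation.
- Marker-in-segment membership is closed-interval on physical coordinates;
  the merge gap tolerance is 0 bp (book-ended intervals coalesce).

## Problem sizes used in the shipped checks

The test suite runs the full 5460-pair × 52,216-marker scan once (it
completes in seconds thanks to the sparse formulation), null calibration
with 500 single-scan replicates at n = 105 × 500 markers plus 200 datasets
× 200 permutations at n = 60 × 500 markers, and 100 localization replicates
at n = 105 × 2000 markers. The acceptance script re-runs the study-scale
analysis (52,216 markers, 1000 permutations) plus 25 localization
replicates per pooling mode.

## Known limitations

- The default pooled slope attenuates directional-haplotype signals (see
  the sign discussion above); use the sign-corrected mode as a companion
  analysis.
- Only one chromosome is analysed at a time; no genome-wide thresholding.
- The exported kernel-test inputs assume an external SKAT-O implementation;
  no region-based association test is computed internally.
- MAF-based rules treat dosages 0/1/2 only; half-calls are not modelled.
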