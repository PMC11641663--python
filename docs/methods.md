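# Methods

`radgenmap` implements a radiogenomic association analysis for renal
masses: quantitative texture features extracted from segmented 3D
tumour volumes are correlated with cytoband-level copy-number features
derived from SNP-array B-allele-frequency (BAF) and log-R-ratio (LRR)
tracks, and the combined feature set feeds a cross-validated random
forest that separates chromophobe renal cell carcinoma (ChRCC, class
1) from renal oncocytoma (RO, class 0). Because the motivating
patient-level data are not publicly deposited, the package ships a
synthetic cohort generator with known ground truth; every stage is
exercised against that truth.

## Synthetic cohort model

The generator draws, per patient: a class label (Bernoulli, default
P(ChRCC) = 8/14, matching the pilot cohort's 6 RO / 8 ChRCC split),
demographics (age and tumour size from class-specific normal
distributions with the pilot cohort's means/SDs: age 63.5 ± 8.67 vs
61.40 ± 7.13 years, size 3.60 ± 1.47 vs 3.80 ± 1.09 cm; sex Bernoulli
at the pilot proportions), a tumour image, and a probe track.

**Imaging.** The tumour is an ellipsoid (semi-axes 0.35 × grid size)
inside a dark volume. Intensities inside the mask follow a smoothed
Gaussian random field: white noise blurred with an isotropic Gaussian
of width *granularity* voxels, rescaled to unit variance, then scaled
and shifted to the class's SD and mean. Granularity controls the
autocorrelation length, so the two classes differ in first-order and
texture statistics. Defaults — class 0: mean 40, SD 20, granularity
1.0; class 1: mean 52, SD 24, granularity 1.8, with per-patient jitter
(mean SD 8, SD SD 5, granularity SD 0.4) representing biological
variability. The separation is deliberately modest: the two tumour
types are difficult to distinguish on CT, and without patient-level
jitter all class-sensitive features become mutually correlated above
the 0.8 redundancy cut at small n, which no real radiomic cohort
exhibits to that degree.

**Genome and probe tracks.** A compact genome of two autosomes plus X
(50 Mb each) is tiled by probes every 25 kb and partitioned into
named p/q cytobands (five per arm, e.g. `1p2`, `Xq4`). Outside
aberrations, LRR ~ N(0, 0.15) and BAF clusters at {0, ½, 1} with a
heterozygous fraction of 0.30 and band noise SD 0.03 (clipped to
[0,1]). Implanted aberrations follow canonical Illumina-like shifts:
single-copy deletion LRR −0.45 with the heterozygous band removed;
single-copy gain +0.30 with heterozygotes split to {⅓, ⅔}; copy-neutral
LOH leaves LRR at 0 but removes heterozygotes. The default LRR noise
(0.15) sits below the 0.28 QC cut so generated samples pass quality
control. The default aberration profile implants one strongly
class-linked deletion at `1p2` (probability 0.85 in ChRCC-like vs 0.10
in RO-like patients) plus weakly-linked background events (`2q3` DUP
0.20/0.25, `Xp3` LOH 0.15/0.15).

What the generator does **not** model: GC waves, FFPE-vs-frozen noise
differences, haplotypes, subclonality, CT physics (beam hardening,
contrast phase), DICOM geometry. Passing tests therefore demonstrate
method correctness and recovery under idealised signal models, not
performance on clinical data.

## Radiomics

Features are computed on the masked ROI after an optional image
filter, discretized with a fixed bin width of 20 anchored at the ROI
minimum: level(x) = floor((x − min)/20) + 1.

Filter bank (defaults): original; Laplacian of Gaussian at σ = 2 and
3 mm (σ converted to voxels via the spacing; the truncated discrete
kernel's nonzero response to a constant image is removed by
subtracting the image mean times the kernel's response to ones);
single-level 3D separable Haar wavelet subbands LLL/LLH/LHL
(reconstructed to the original grid with the other subbands zeroed —
Haar is chosen so low-pass-of-constant is exactly the constant);
sign-preserving logarithm x ↦ sign(x)·log(1+|x|); and a simplified
3D local binary pattern (per-voxel count of 26-neighbours ≥ the
centre, a rotation-invariant statistic standing in for the full
spherical-harmonic LBP, which is deliberately out of scope).

Texture families follow the IBSI/PyRadiomics conventions on
26-connected neighbourhoods at distance 1:

- **GLCM** — symmetric co-occurrence matrices per direction; features
  (Imc2, joint entropy, contrast, joint energy) averaged over the 13
  unique direction pairs. Entropies use log2; Imc2 =
  √(1 − exp(−2(HXY2 − HXY)·ln 2)), clamped at 0, so a single-level ROI
  yields exactly 0.
- **GLRLM** — maximal equal-level runs per direction, features
  averaged over directions.
- **GLSZM** — 26-connected equal-level zones (one matrix).
- **GLDM** — dependence = number of equal-level masked 26-neighbours
  (gray-level tolerance 0, centre excluded), column j = dependence+1.

First-order features include minimum (equivariant to intensity shift)
and Fisher population skewness (shift-invariant; defined as 0 for
zero-variance input). Feature names follow
`<filter>_<family>_<Feature>`, e.g.
`wavelet-LHL_glszm_SmallAreaLowGrayLevelEmphasis`. Correctness is
checked against exhaustive-enumeration oracles (explicit run listing,
flood-filled zones, per-voxel neighbour counts) on random ROIs to
1e-10. Dice similarity 2|A∩B|/(|A|+|B|) is provided for segmentation
agreement; it errors on two empty masks (0/0).

No resampling, normalisation or outlier removal is applied before
extraction.

## CNV calling

Each probe emits (LRR, BAF); the model has six states — CN0, CN1
(loss), diploid CN2, copy-neutral CN2-LOH, CN3, CN4 (gain) — with
Gaussian LRR terms (means −2.0, −0.45, 0, 0, +0.30, +0.60) and BAF
mixtures over the genotype bands of each state, weighted by the
expected heterozygous fraction; boundary bands (means 0 or 1) use
truncated normals on [0,1]. Segmentation is Viterbi with a uniform
per-transition penalty (default 10 natural-log units; with a uniform
penalty the recursion only needs the per-step best predecessor).
Contiguous same-state runs become segments; non-normal runs are
emitted when they span ≥ 3 probes **and** their confidence — the
summed per-probe 10·log10 likelihood ratio against the diploid state —
is ≥ 35. The confidence statistic is this package's interpretation:
the upstream tool's threshold is published but its statistic is not.
Sample QC excludes tracks with LRR sample SD > 0.28. Raising the
confidence threshold can only remove segments (monotonicity is
tested). Segment coordinates are 1-based inclusive probe positions;
BED export converts to 0-based half-open.

The cohort share statistic CNV% (per patient and type) =
patient's segment count of that type / cohort total of that type ×
100, so each type column sums to 100 across patients whenever any
segment of the type exists.

## Cytobands, pathogenicity, association

Segments intersect cytobands with half-open interval arithmetic; the
patients × cytobands matrix holds the called copy number (largest
overlap wins conflicts; diploid baseline 2), with copy-neutral LOH
carried in separate 0/1 indicator columns because it does not change
the copy number. Numeric pathogenicity scores map to five classes by
fixed cut-offs, completed continuously so the map is total and
monotone: Benign ≤ −0.99 < Likely Benign ≤ −0.89 < VUS < 0.90 ≤
Likely Pathogenic < 0.99 ≤ Pathogenic.

Association analysis: per-column z-scores (population SD; columns
constant within float precision are dropped and logged); redundancy
filtering removes one member of every pair with |r| strictly above
0.8 (the member with the higher mean absolute correlation to the
rest; ties go against the lexicographically later name); consensus
selection runs four algorithms — cross-validated LASSO, RFE with a
logistic estimator, gradient boosting (200 depth-3 trees), random
forest (500 trees) — each contributing its top 14, keeping features
named at least twice. Cytobands are retained when |Pearson r| with
the binary labels exceeds 0.1; the radiomic × genomic association map
records the full Pearson matrix and the pairs exceeding |r| > 0.4 and
0.55. All correlation thresholds act on |r|, since strong negative
correlations are equally informative.

## Model evaluation

A random forest with 201 trees is evaluated by cross-validation —
leave-one-out by default (appropriate at cohort sizes of ~14),
stratified k-fold for larger cohorts — pooling out-of-fold class-1
probabilities into one confusion matrix (threshold 0.5) and one ROC.
AUC uses the Mann–Whitney formulation with ties counting ½. MCC uses
the 0 convention when a marginal is zero. Rates are reported both as
fractions and as percentages rounded to 2 decimals.

## Statistics

Two-sample t-tests are computed from printed per-group summaries
(pooled-variance Student by default, Welch optional — with rounded
published inputs both land within ±0.05 of the published p-values).
The 2×2 sex table uses Fisher's exact two-sided test by default (it
reproduces the published p = 1 exactly, which the chi-square variant
does not); chi-square is available. The two-proportion sample-size
formula Ni = (p1(1−p1) + p2(1−p2))/E² · Z² returns the raw per-group
value, its floor, and total = 2·floor — the flooring convention is
what reproduces the published total of 1254 at p1=0.286, p2=0.714,
E=0.05, Z=1.96.

## Problem sizes and numerical choices

Tests run cohorts of 12–16 patients at 8³–16³ voxels for unit-level
checks and one 200-patient cohort at 16³ with a reduced filter bank
(original + LoG 2 mm) for the end-to-end recovery check; the texture
oracle suite uses 50 random ROIs up to 6³ with ≤ 4 gray levels. These
sizes were chosen as the smallest at which the statistical assertions
(binomial bounds, recovery rates, AUC) are stable across seeds.
Degenerate inputs are defined explicitly: skewness of a constant ROI
is 0; Dice of two empty masks errors; an empty cohort type yields 0%
rows rather than division errors; single-probe tracks cannot be QC'd.

## Known limitations

- The feature set covers the named feature families, not full
  PyRadiomics parity (the published pipeline extracted 1875 features;
  that count is not reconstructable from the stated classes and is a
  non-goal).
- The LBP-3D filter is a simplified neighbour-count pattern, not the
  spherical-harmonic kurtosis variant.
- The CNV caller is a six-state model, not a port of the 14-scenario
  commercial tool; its confidence statistic is an interpretation.
- At pilot scale (n = 14) the redundancy filter can legitimately
  collapse the feature table to very few representatives; the
  pipeline then skips consensus voting and keeps the survivors,
  logging a warning.
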