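# Methods

`landcnn` implements a simulation-based model-selection workflow for
landscape genetics: candidate hypotheses about which landscape features
shape gene flow are expressed as resistance surfaces, converted into
migration matrices, used to simulate SNP datasets under a structured
coalescent, and discriminated by a convolutional classifier trained on
images of the simulated genotype matrices.

## The demographic model

An ancestral population of `N_anc` haploid individuals splits into
`n_demes` demes `T` generations before the present (defaults: 39 demes,
`T = 21,000`, one generation per year, so the split coincides with the
oldest landscape layer at 21 kyr).  Forward in time the demes exchange
migrants at per-generation rates given by a migration matrix that may change
at epoch boundaries.  Per-simulation parameters are drawn from uniform
priors:

| parameter            | prior            | units                 |
|----------------------|------------------|-----------------------|
| ancestral size       | U(20,000, 50,000)| haploid individuals   |
| per-deme size        | U(5, 100)        | haploid individuals   |
| landscape effect w_k | U(2, 5)          | dimensionless, per predictor in the model |
| dispersal d          | U(0.1, 0.3)      | dimensionless         |

Sizes are haploid everywhere; samples are haploid sequences, two per
diploid individual.  There is no recombination, selection, or growth within
demes; every SNP is an independent (unlinked) site.

## From landscape to migration

Five predictor kinds are supported.  `distance` is an all-ones raster (the
isolation-by-distance null).  `slope` and `rivers` are static;
`habitat_shifts` is a stack of 21 binary rasters covering 21–0 kyr in
1000-year epochs, and `niche_suitability` is a stack of 7 resistance
rasters (1 − suitability) on the named late-Quaternary climate periods:
Last Glacial Maximum (21 kyr), Heinrich Stadial 1 (17–14.7), Bølling–
Allerød (14.7–12.9), Younger Dryas (12.9–11.7), Greenlandian (11.7–8.326),
Northgrippian (8.326–4.2) and Meghalayan (4.2–0.3, extended to the present
so the epochs tile the whole window).

A model is a subset of {slope, rivers, habitat_shifts, niche_suitability};
the two climate-derived dynamic predictors never co-occur (they are built
from the same reconstructions and are not independent hypotheses).  The
twelve models are the cross of {∅, slope, rivers, slope+rivers} with
{∅, habitat_shifts, niche_suitability}, numbered in the standard order
(model 1 = distance only).

For one epoch the composite resistance surface is

    R(cell) = 1 + Σ_k w_k · L_k(cell),

where each layer `L_k` is on [0, 1] (layers already inside [0, 1] pass
through unchanged; anything else is min–max rescaled; the additive 1 is the
implicit distance layer, making IBD the exact `w → 0` limit of every IBR
model).  The resistance distance `x_ij` between demes i and j is the
least-cost path on the 8-connected grid graph with edge cost
`(R_a + R_b)/2 · step`, step = 1 for rook and √2 for diagonal moves, in
cell units.  Migration follows the cubic decay

    m_ij = d · (1 / x_ij)³,

symmetric, with zero diagonal.  A weaker (squared) decay leaves rates so
high that simulated datasets show no genetic structure, which motivates the
cubic form.  To keep per-generation emigration probabilities valid the
matrix is rescaled by a single factor whenever its largest row sum exceeds
0.5 (the cap preserves symmetry and the relative structure; it can be
disabled).  Dynamic models repeat the chain per epoch: 21 epochs of 1000
generations (habitat shifts) or 7 epochs at the climate-period boundaries
(niche suitability); static models use a single epoch spanning the full
21,000 generations.

## SNP simulation

Coalescent genealogies are generated with msprime (haploid sampling,
population sizes as haploid counts, epoch-wise migration-rate changes, all
demes merging into the ancestral population at the split).  Each unlinked
SNP comes from an independent marginal tree: one mutation is placed
uniformly at random on the branches that subtend between 1 and n−1 of the
sampled sequences.  This is exactly the infinite-sites distribution
conditional on the site being polymorphic in the sample, so a dataset
contains exactly `n_snps` polymorphic columns by construction, with no
ascertainment retries (equivalently: simulate sites, discard the
monomorphic ones and top up — without the loop).  Only demes flagged as
sampled contribute sequences.  There is no minor-allele-frequency filter;
the minor allele count can be 1.

## Image encoding

A genotype matrix (haploid sequences × SNPs, ancestral = 0 / derived = 1
from the simulator) becomes the classifier input by (i) recoding each
column so the major allele is 0 (ties leave 0 as major), (ii) stably
sorting columns by descending minor-allele frequency, and (iii) ordering
rows by (deme id, individual id, input order).  The encoding is idempotent
and deterministic; images are stored as 0/1 integer arrays ("black and
white" is purely a rendering concern).  Rows are haploid sequences rather
than diploid individuals, which avoids inventing a heterozygote pixel
value; the sampling-design experiments count sequences accordingly.

## The classifier

Architecture, in order: conv 3×1 (valid, stride 1) → max-pool 3×1 (stride =
pool size) → conv 3×1 → max-pool 3×1 → flatten → dense 100 → dense 40 →
dense `n_models` with softmax.  Hidden activations are ReLU.  Training uses
Adam (lr 10⁻³, β₁ 0.9, β₂ 0.999), categorical cross-entropy, mini-batches
of 100, exactly 10 epochs, no early stopping and no validation split beyond
the stratified 80/20 train/test partition.  Kernels span 3 rows (sequences)
× 1 column (SNP).  With pool stride equal to the pool window the minimum
admissible image height is 17 rows (17 → 15 → 5 → 3 → 1).

The engine is a compact numpy implementation (forward and hand-written
backward passes for the conv/pool/dense stack, verified against numerical
gradients in the test suite).  Weight initialization and shuffling are
driven by explicit seeded generators; a fit is fully determined by its
inputs and seed in single-threaded execution.  Default filter counts are
32 (conv1) and 64 (conv2), recorded in `ClassifierSpec`; the reduced-scale
experiments use 8/16 (`REDUCED_SPEC`) — filter counts are a free
architectural knob here, and the smaller network
keeps a full train/evaluate cycle at seconds on one CPU.

Evaluation reports the confusion matrix as row percentages, overall
accuracy as the count-weighted trace, and per-model precision TP/(TP+FP)
and recall TP/(TP+FN).  Calibration bins each test prediction's top softmax
probability into five 20%-wide classes and reports per-bin counts and
empirical accuracy (empty bins carry count 0 and an undefined accuracy).

## Summary statistics

Pairwise differentiation is Hudson's F_ST estimator in ratio-of-averages
form: per SNP, with sample frequencies p₁, p₂ and haploid sample sizes
n₁, n₂,

    N = (p₁ − p₂)² − p₁(1 − p₁)/(n₁ − 1) − p₂(1 − p₂)/(n₂ − 1)
    D = p₁(1 − p₂) + p₂(1 − p₁),      F_ST = ΣN / ΣD.

The estimator is unbiased, so small negative values are legitimate; demes
with fewer than two sequences get undefined (NaN) entries rather than
fabricated ones.  He is the sample-size-corrected expected heterozygosity
`n/(n−1) · 2p(1−p)` averaged over SNPs; Ho is the mean fraction of
heterozygous diploid individuals (consecutive sequence pairs).

The simulated-vs-observed plausibility check vectorizes the lower triangles
of simulated F_ST matrices, fits a 2-component PCA, projects the target
matrix, and declares a match when the projection falls inside the convex
hull of the simulated scores and within each component's min–max range
(with distances to the centroid and the nearest simulation reported; a
rank-deficient cloud is reported as degenerate, not an error).  This is an
explicit operationalization of what is usually an eyeball check.

## Synthetic landscapes

The generators emulate the structure of real predictor products rather
than their values: slope is the gradient magnitude of a Gaussian-smoothed
random surface (smoothing σ = 3 cells); rivers are random-walk channels
descending the grid with accumulation increasing downstream (2 channels by
default; 0 gives a barrier-free raster); the dynamic stacks are AR(1)
latent smooth fields (ρ = 0.85 between consecutive slices) thresholded to
binary habitat (closed fraction 0.5) or mapped to [0, 1] suitability.  All
layers are bit-reproducible under a fixed seed.  What these synthetic
layers do **not** capture: real spatial covariance between predictors
(elevation and climate are correlated in nature), anisotropy of real
drainage networks, and the empirical calibration of suitability models —
so passing tests demonstrate that the pipeline recovers the generating
model class under its own assumptions, not that it would recover the right
model for any particular empirical system.

## Problem sizes

The full-scale configuration is the empirical-mirror design: 39 demes on a
60×60 grid (9 sampled with the unbalanced 52-individual scheme
[18, 9, 7, 6, 4, 3, 2, 2, 1]; only the total, mean and range are known
per deme, so this fixed split is an approximation),
4364 SNPs, 2500 examples per model and the 80/20 split (24,000 train /
6,000 test).  The grid size keeps sampled localities several to tens of
cells apart, as they are on continental-scale rasters.

The reduced scale used by the test-suite experiments keeps the same
structure on a smaller problem: 12 demes on a 32×32 grid (6 sampled, 10
sequences each), 500 SNPs, and a 3-model contrast — distance vs. strong
slope vs. strong rivers, with effect weights drawn from U(4, 5), the top
of the full prior — at 100 training + 30 test examples per model.  The
sampling-design study runs the scheme grid scaled to this layout:
(9 demes, 2 seq), (9, 20), (12, 2), (12, 20), three models, 24 + 9
examples per model, 48 SNPs.  These sizes were chosen once so that every
experiment runs end to end on a single CPU in minutes.

## Numerical choices and degenerate inputs

- Least-cost edge costs use the mean-of-endpoints convention; distances are
  reported in cell units (multiply by the cell size for map units).
- Column-sort ties in the encoder preserve input order (stable sort); a
  50/50 column keeps its original polarity.
- A deme pair separated by nodata cells raises an unreachable error naming
  the pair; co-located demes (x = 0) raise a conversion error.
- Training on a single-class corpus aborts; non-finite training loss in the
  sampling study flags that scheme and the others continue.
- The cross-entropy adds 10⁻¹² inside the log; softmax subtracts the row
  max before exponentiation.
- Corpus construction retries a failed example with a fresh seed up to 5
  times and logs the attempt count in the manifest.

## Known limitations

- The coalescent approximation is coarse for demes of size 5–100 with
  migration rates up to the cap; any coalescent simulator of this design
  shares the regime.  Rates are interpreted as symmetric per-generation lineage
  movement probabilities.
- Migration matrices are symmetric by construction; real river systems
  induce asymmetric gene flow.
- The PCA match criterion with 2 components can declare a match for a
  target that deviates only in higher components.
- GeoTIFF I/O is not provided; rasters are exchanged as ESRI ASCII grids.
- The reduced-scale accuracy numbers are not comparable to the full-scale
  setting (fewer models, stronger effects, smaller corpora); only
  directions and orderings carry over.
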