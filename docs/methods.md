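# Methods

`fbrquant` quantifies the foreign-body reaction (FBR) that forms around
nerve conduits implanted in peripheral nerve: the fibrotic capsule at the
nerve edge, axon regeneration inside it, and the immune/expression changes
that accompany it. Because the raw micrographs and sequencing reads behind
such studies are rarely redistributable, every analysis stage is paired
with a synthetic generator that produces inputs with known ground truth,
and the test suite is built around recovering that truth.

## Depth-aligned capsule quantification

**Model.** The capsule is a ring of myofibroblasts (αSMA-positive) around
the edge of the nerve cross-section. Its extent is delineated by a human
tracing a closed polygon on the αSMA channel. To compare intensity across
capsules of irregular shape, each interior pixel is re-parameterized by its
*depth*: the Euclidean distance (μm) to the nearest point of the traced
edge. Depth is computed exactly — a vectorized point-to-segment minimum
over the polygon's edges, evaluated at pixel centers — rather than by a
grid distance transform, so the value at any pixel is the true geometric
distance; the depth field is 1-Lipschitz on the pixel grid by construction.
Pixel centers sit at integer coordinates, origin top-left, x rightward, y
downward, 0-based.

From the depth field:

- **Intensity profile** — mean stain intensity in contiguous depth bins
  `[b·w, (b+1)·w)` (default width 1 μm). Empty bins are reported as NaN,
  never zero, with per-bin pixel counts for auditing. Group summaries are
  subject-level: one profile per mouse, across-subject mean ± sample SD
  (ddof = 1; a single-subject group reports SD 0).
- **Near-edge mean** — the pixel-weighted mean over all pixels with depth
  ≤ *w*. The window is 25 μm by default; 50 μm is the convention for the
  macrophage marker CD68, which sits deeper in the tissue; 15 μm is also in
  use for αSMA panel summaries. All three are one parameter
  (`window_um`) — none is canonical, and results should state the window
  used. Per-subject means are normalized to the mean of a named control
  group, so the control's ratios average to exactly 1 and the ratio is
  invariant to any global intensity rescaling.
- **Capsule thickness** — requires two traced contours (outer and inner
  capsule boundary). At `n_positions` points spaced uniformly by arc
  length along the outer contour (default 360), thickness is the distance
  to the nearest point of the inner contour; the subject-level value is
  the mean over positions, matching the one-value-per-mouse convention
  used for group statistics. Nearest-point distance was chosen over a
  normal-ray intersection: it is well defined for any pair of
  non-crossing simple polygons and never misses on concave stretches.
  Contours that touch or cross are rejected.

## Axon density

Axons appear as puncta in the β3-tubulin channel. Density is estimated in
square counting frames — three randomly placed 100 × 100 μm boxes per
image by default — sampled uniformly over all positions where the box fits
inside the analysis region; boxes may overlap. Within a box the sub-image
is thresholded and 8-connected components with area ≥ `min_area_px`
(default 4 at 1 μm/px) are counted if their *centroid* lies inside the box
(the standard unbiased counting-frame simplification; a component is
attributed to exactly one box). Density = count / box area; per-image
means are averaged per mouse.

The default threshold is Otsu's criterion computed **exactly over the raw
pixel values** rather than over a 256-bin histogram. On punctum images the
foreground is <1 % of pixels and the background is near zero; a binned
histogram collapses the entire background (including its noise tail) into
one bin, the between-class criterion becomes flat, and the returned
threshold lands inside the noise, producing spurious small components. The
exact computation (an `O(n log n)` scan over sorted values) picks the
punctum/background split and is invariant to intensity rescaling. A fixed
numeric threshold can be supplied instead.

## Immune cell-type deconvolution

Bulk expression is modeled as a linear mixture of reference cell-type
profiles: given a signature matrix **S** (genes × types) and a mixture
**x**, fractions solve

    min ‖S f − x‖₂  subject to  f ≥ 0, Σf = 1.

The solver is an active-set quadratic program: the sum-to-one constraint
is kept in the working set with a Lagrange multiplier, non-negativity
bounds enter when a free coordinate goes negative and leave when their
dual multiplier (g_i + λ) is negative, to a stationarity tolerance of
1e-9. Genes are intersected case-insensitively between mixture and
signature (warning below 50 % overlap) and mixing is on the linear scale.
Rank-deficient signatures are solved but flagged as potentially
non-unique. Fractions over the default 25 hematopoietic fine types are
aggregated by summation into six major lineages (granulocytes, B cells,
T cells, NK cells, dendritic cells, mono/macrophages); the bundled
25-type table uses generic fine-type names — any signature TSV and
grouping table can be substituted, and no published signature is bundled.

## Expression statistics

- **Sample QC** keeps samples with RNA integrity number strictly above 3.
- **Size factors** are median-of-ratios: sf_j = median over genes (with a
  positive count in every sample) of count_gj / geometric-mean_g. The
  factors are reported rescaled to geometric mean 1; this leaves every
  between-sample ratio unchanged and makes normalization idempotent (the
  size factors of a normalized matrix are exactly 1), which is the
  property downstream code relies on.
- **The DE test is a stand-in**, not a negative-binomial model: per-gene
  Welch t on log2(normalized + 1), with the log2 fold change defined as
  the difference of group means on that scale and Benjamini–Hochberg
  adjustment across genes. Its contract is calibrated type-I error on
  simulated nulls (checked at 2000 genes × 20 seeds), not optimal power.
  Genes with zero variance in both groups get p = 1.
- **DEG filter**: |log2FC| ≥ 1 (twofold, inclusive at the boundary),
  base mean strictly above 3 normalized counts, adjusted p strictly below
  0.01. Boundary semantics follow the wording "a minimum of a twofold
  change", "above three", "below 0.01"; inclusivity of the fold-change
  boundary is configurable.
- **Top-k variable genes** for PCA are ranked by across-sample variance of
  log2(normalized + 1) (k = 500 by default), ties broken by gene id;
  variance ranking is the common default where no explicit ranking rule
  exists. PCA is plain centered SVD with samples as observations.
- **qPCR RQ**: ΔCt = Ct_gene − Ct_housekeeping per sample (machine offsets
  cancel here), averaged within group before differencing:
  ΔΔCt = mean ΔCt_group − mean ΔCt_reference, RQ = 2^(−ΔΔCt). The
  significance flag is the strict two-fold rule — RQ > 2 or < 0.5; RQ
  exactly 2 is *not* flagged.

## Group-comparison statistics

The experimental unit is the mouse; per-section/per-image values are
averaged per subject before testing. One-way ANOVA, Student's t and
Mann–Whitney U (exact null for groups of ≤ 8 without ties, otherwise the
tie-corrected normal approximation) are delegated to scipy. Dunnett's
many-to-one test is implemented in-package: with pooled error from all
groups (df = N − k), family-wise adjusted p-values are
P(max_i |T_i| ≥ |t_obs|) under the joint null, estimated by seeded Monte
Carlo over the multivariate-t distribution implied by the group sizes
(default 10⁵ draws; the `(hits + 1)/(draws + 1)` estimator avoids zero
p-values, and adjusted p is floored at the unadjusted t p, which Dunnett
adjustment can never undercut). This handles any k and any imbalance, and
is cross-checked in the tests against scipy's direct multivariate-t
integration. Tukey's HSD uses the studentized-range null; two-way ANOVA
uses Type II sums of squares, appropriate for the mildly unbalanced
layouts (e.g. 7 vs 8 mice) that arise in practice, and rejects designs
with empty cells by name.

## Synthetic generators

The image phantom is a circular nerve disk: the αSMA channel carries
`peak·exp(−depth/ℓ)` within the capsule thickness and zero beyond (the
exponential inward decay is a simulator choice — real profiles decay but
their form is not parameterized — with ℓ exposed as
`intensity_decay_um`, default 15 μm); axon puncta are disks placed
uniformly inside the inner boundary, rejection-sampled to be pairwise
disjoint so ground-truth counts are unambiguous; nuclei speckle is
analogous; additive Gaussian noise is clipped at zero. The generator
returns the exact outer/inner contours (256-gon approximations of the
circles; the polygonization error at this vertex count is < 0.01 px) and a
truth record with punctum centers and realized density. Defaults (1 μm/px,
800 axons/mm², 40 μm capsule) are in the range plausible for confocal
sections of mouse sciatic nerve; the pixel size is arbitrary since no
magnification convention exists for such data.

Count matrices are negative-binomial (variance μ + αμ², dispersion α
default 0.1) with log-uniform per-sample size factors and per-gene group
effects (N(0, lfc_sd), or exactly ±`lfc_fixed` for recovery tests); Ct
tables add per-sample machine offsets so downstream ΔCt must cancel them.
Every generator derives sub-streams from a single integer seed and is
bitwise reproducible.

**What the phantoms do not emulate:** optics (PSF, bleed-through,
vignetting), irregular capsule geometry, clustered or overlapping axons,
autofluorescence, 3-D structure. Passing recovery tests therefore
demonstrates that the measurement chain is unbiased and exact on clean
geometry, not that segmentation-free thresholding would survive real
tissue; on real images the traced contours and the threshold choice carry
that burden.

## Numerical choices and problem sizes

Depth maps are exact to float precision; profile bins are half-open with
NaN for empty bins; thickness positions are arc-length uniform with ties
in nearest-point search resolved by the exact polygon distance.
Acceptance-style checks run at deliberately modest sizes chosen to keep
the full suite fast while leaving the statistical bands meaningful:
256–360 px phantoms, 200 axon-recovery replicates, 100 deconvolution
seeds, 2000 genes × 20 seeds for DE calibration, 5000 replicates per null
rejection-rate estimate (binomial SE ≈ 0.003 at α = 0.05). The demo
pipeline (two groups × three mice, all stages) completes in well under a
minute on one CPU.

## Known limitations

- The DE stand-in has no dispersion shrinkage; at very low counts its
  power is below a negative-binomial model's, and its calibration is
  verified only at the simulated settings.
- Dunnett p-values carry Monte-Carlo error ~(p(1−p)/draws)^½; raise
  `mc_draws` for boundary decisions.
- Capsule thickness requires both boundaries to be traced; no automatic
  inner-edge detection is attempted.
- Deconvolution assumes linear mixing with a complete signature; missing
  cell types are absorbed into the nearest available columns rather than
  reported as unexplained mass (the residual norm is the only indicator).
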