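# Methods

## Scope

`serialstain` reimplements, as a tested pipeline, the quantitative core of a
serial-section multistain IHC workflow for the tumor microenvironment —
registration of single-marker serial sections onto a reference slide,
DAB-positive quantification, tile-based density/hotspot/colocalization
analysis over annotated compartments (tumor gland T, invasive front IF,
distal stroma S, lymphoid nodule LN) — together with the expression-side
statistics used alongside it: a cells-then-genes QC filter, the rank-based
p-EMT signature score with Wilcoxon comparison, the Wilcoxon + Bonferroni +
2-fold marker-gene rule, and normality-gated two-group fraction tests. A
synthetic-data module generates all inputs with known ground truth.
Normalization, clustering, embedding, trajectory inference, ligand–receptor
analysis and survival modeling are deliberately out of scope.

## Registration model

Each section is downsampled so its longest side is at most 500 px (aspect
preserved, antialiased; smaller images are never upsampled). Registration
runs at this working scale on *tissue-weighted grayscale* — the mean
Beer–Lambert optical density over RGB — because each serial section carries
a different chromogen and marker-dependent color must not drive alignment.

Pairwise registration is two-stage:

1. **Affine initialization** — SimpleITK multi-resolution (shrink 4/2/1,
   smoothing σ 2/1/0 px) affine registration, mean-squared-error metric by
   default (Mattes mutual information available via
   `RegistrationConfig(metric="mi")`), regular-step gradient descent with
   full (non-stochastic) metric sampling, moments-based centered
   initialization. Full sampling plus a deterministic optimizer makes the
   result bitwise reproducible.
2. **Dense nonrigid refinement** — fast symmetric-forces demons run
   coarse-to-fine (shrink 4/2/1, 100/60/30 iterations), with the
   displacement field Gaussian-smoothed (σ = 2 px) at every iteration as the
   regularizer. The demons field is composed with the affine transform into
   one dense pull-back field.

**Candidate selection / failure policy.** Identity, affine-only, and
affine+demons fields are scored by tissue-masked grayscale MSE; the best
scoring candidate is returned among those that do not lower the tissue-mask
Dice versus no registration. Dice alone is blind to interior-only
deformation, hence the MSE criterion; identity always qualifies, so a
worse-than-identity field is never returned, and the chosen stage is
recorded in the report.

**Field convention.** Fields are pull-back displacements in 0-based
(row, col) pixels: the aligned image samples the moving image at
`x + disp(x)`. Upsampling a field to full resolution bilinearly resamples
the grid *and* multiplies displacement components by the per-axis resize
factors, so the same physical deformation is expressed at the new
resolution. Stack registration maps every section onto the centroid
(middle; ties to the lower index) slide, upsamples each field to the
reference's full resolution, and warps with bilinear interpolation,
white-filling out-of-canvas samples.

Numerical field inversion (for round-trip checks) uses the fixed-point
iteration `e ← −d(x + e(x))`, which converges quickly for the smooth,
moderate-magnitude fields this pipeline targets.

## Stain model and positive detection

Brightfield composition follows Beer–Lambert: per-channel optical density
`OD = −ln(I/255)` is a nonnegative combination of unit stain vectors, with
the classic Ruifrok–Johnston hematoxylin (0.650, 0.704, 0.286) and DAB
(0.269, 0.568, 0.778) defaults. Deconvolution projects the per-pixel OD
vector onto the two stain vectors by least squares and clips negative
loadings. Because the synthetic renderer composes images in exactly this
space, deconvolution inverts it up to 8-bit quantization — which is what
makes detection testable without tuning.

The source study does not state how "marker-positive" was called. We
threshold the DAB channel at 0.15 OD and keep 8-connected components of at
least 20 px (both configurable); detection exposes *both* the positive-pixel
mask (for area claims) and object centroids (for cell-count claims).
Positive-area fractions are computed over region ∩ tissue pixels.

## Tiling, hotspots, colocalization

Annotated regions are dissected into 1000 × 1000-px tiles (half-open
intervals, grid anchored at the region bounding-box top-left). A tile is
valid when its region-and-tissue area is at least 5% of the tile area.
Densities are positive-pixel fraction of tile tissue (default) or object
count per tile; object counts are kept on every tile so they sum exactly to
the planted total.

**Hotspots.** The source describes hotspots as visually evident; we fix a
reproducible rule: valid tiles with density at or above the order-statistic
(`method="higher"`) 0.9-quantile of the *positive* valid densities.
Computing the threshold over positive tiles (and never calling a
zero-density tile a hotspot) keeps the rule sensible in sparse maps — a map
with one stained tile among a hundred empty ones yields exactly that tile —
and the order-statistic quantile makes the set invariant under any monotone
rescaling of densities.

**Colocalization.** Spearman correlation of two markers' densities over
jointly valid tiles, with a seeded permutation null: tile labels of the
second map are shuffled `n_perm` (default 1000) times and
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1)`, two-sided. The statistic is
rank-based because tile densities are heavy-tailed and the two markers'
scales are arbitrary. Permutation seeds are required inputs and logged in
the result.

## Expression statistics

* **QC filter** — cells with fewer than 400 expressed (value > 0) genes are
  dropped, then genes expressed in fewer than 4 of the remaining cells; one
  pass, cells-then-genes (the source states both rules without an order;
  the chosen order is recorded in `uns`). Re-running the filter is a no-op.
* **p-EMT score** — per cell, all genes in the matrix are ranked by
  expression (ascending, average ties); the score is the mean rank of the
  signature genes present divided by the number of ranked genes, so it lies
  in (0, 1] and is invariant under per-cell monotone transformations. The
  phrase "mean expression rank … in all cells" admits a second reading —
  ranking cells within each gene — which is exposed as
  `orientation="per_gene"`. The 97-gene list is supplied by the user as a
  text file, not hard-coded.
* **Rank-sum comparisons** — two-sided Wilcoxon rank-sum (Mann–Whitney U of
  the first group); exact when both groups are ≤ 50 and tie-free, otherwise
  the tie-corrected normal approximation *without* continuity correction,
  so exchangeable groups give p = 1 exactly.
* **Marker genes** — per gene, Wilcoxon target-vs-rest; Bonferroni over the
  genes actually tested (nonzero variance); keep `p_adj < 0.05` and raw-mean
  fold change > 2 (pseudocount 1e-9 guards a zero-mean rest); sorted by fold
  change.
* **Fraction tests** — Shapiro–Wilk (α = 0.05) on each group plus a
  two-sided F-ratio variance check gate the unpaired t test, falling back to
  Mann–Whitney; paired data gate the paired t on Shapiro of the differences,
  falling back to Wilcoxon signed-rank, with degenerate (constant)
  differences routed directly to the signed-rank/trivial branch. The gate
  outcome is recorded on every result.

## Synthetic data: what it emulates, and what it does not

The generator produces: a tissue slab (perturbed ellipse) containing disk
glands (T) ringed by invasive-front bands (IF, default width 4% of the
canvas) in a stroma (S), optionally with a lymphoid nodule (LN); per-marker
point processes — exact piecewise-homogeneous Poisson when markers are
independent, or a unit-mean log-Gaussian Cox modulation with a shared latent
field (loading √|ρ|) when cross-marker correlation is requested, so expected
counts are rate × area in both regimes; brightfield rendering in OD space
with flat DAB disks and a layout-seeded nuclei/texture pattern shared by all
sections of one tissue (serial sections of real tissue share structure — the
texture is what registration locks onto); and smooth random deformations
(Gaussian-smoothed white noise, correlation length `smoothness`, maximum
magnitude `max_disp`, plus an optional rigid part), generated on a coarse
grid and bicubically upsampled for long correlation lengths. Stored fields,
landmark pairs, planted densities and correlations serve as ground truth.

The expression simulator draws per-gene log-normal means and Poisson values,
boosting signature genes in one group by 1 + effect, so effect = 0 is an
exact null and the expected score shift is monotone in effect.

Not emulated: nuclear texture realism, scanner artifacts, stain variation
between scanners, multiplex (same-slide) staining, tissue tearing/folding,
section-to-section content loss, or the library-size and dropout structure
of real scRNA-seq. Passing tests therefore demonstrate correctness of the
*computations* under the stated models, not robustness to every artifact of
real slides or real dissociated-cell data.

## Problem sizes and default study conditions

The validation suite runs three ~2000 × 2000-px sections with smooth
deformations of 15 px maximum at the 500-px working scale (60 px at full
resolution, correlation length 300 px) — recovered with mean landmark TRE
≈ 0.12 px at the working scale and tissue Dice ≥ 0.998. Colocalization
calibration uses 500 independent 10 × 10 Poisson tile grids with 1000
permutations each (rejection ≈ 5% at α = 0.05) and 50 replicates of planted
ρ = 0.6 over 100 tiles for power. The compartment-gradient study plants
rates T 1 × 10⁻⁴ / IF 4 × 10⁻⁴ / S 1 × 10⁻³ points per px² (blob radius 4 px,
768² canvas, IF band 6% of the canvas, patient-level log-normal scaling with
σ = 0.15): these values were chosen by an a-priori power check so that every
compartment expects enough points for the planted ordering to be resolvable
against Poisson and blob-spill noise (ordering recovered in 60/60
independent trial seeds with fraction-ratio margins ≥ 1.4), and the S-vs-IF
paired test at 8 synthetic patients then carries an effect of ≈ 2–3
between-patient SDs.

## Known limitations

* The registration stack targets desk-scale images (≲ 4000 px per side); no
  pyramidal/tiled streaming of gigapixel WSIs.
* Demons + MSE assumes roughly consistent tissue appearance between
  sections after the OD-grayscale collapse; heavy necrosis or folds would
  require the MI metric and possibly masking.
* The hotspot rule and the colocalization statistic are reproducible
  stand-ins for analyses the source study performed by eye; only their
  construction, not any printed number, is reproduced.
* Two-stain unmixing only; no watershed splitting of touching positive
  cells, so object counts undercount merged clusters (the pixel-fraction
  mode is unaffected).
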