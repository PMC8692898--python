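# serialstain

Quantitative analysis of **serial-section multistain immunohistochemistry**
for tumor-microenvironment studies, plus the matching expression-side
statistics — built as a tested, reusable pipeline with a synthetic-data
module that provides exact ground truth for every stage.

In a serial-section multistain design, consecutive thin slices of one tissue
are each stained for a single marker (e.g. POSTN for extracellular-matrix
CAFs, CD163 for M2 macrophages, CD34, COL1A1, …). Because the slices come
from the same tissue, aligning them lets markers that can never share a
slide be compared spatially: which compartments (tumor gland **T**, invasive
front **IF**, distal stroma **S**, lymphoid nodule **LN**) each cell type
occupies, where its density hotspots sit, and whether two cell types
colocalize. The package is aimed at computational pathology / spatial
biology researchers who need these steps reproducible and testable rather
than read off heatmaps by eye.

## What it computes

**Registration.** Sections are downsampled to ≈500 px, registered onto the
centroid (middle) slide — multi-resolution affine, then regularized
demons-style nonrigid refinement on stain-independent optical-density
grayscale — and the recovered deformation field φ is upsampled to full
resolution (grid resampled, displacement magnitudes scaled) to warp the
original image: `aligned(x) = moving(x + φ(x))`.

**Stain quantification.** Beer–Lambert color deconvolution with
Ruifrok–Johnston H/DAB vectors; marker-positive = DAB optical density ≥ 0.15
over 8-connected components ≥ 20 px (both configurable); outputs both
positive-pixel masks and object centroids.

**Tile statistics.** Annotated regions are dissected into 1000×1000-px
tiles; per-tile densities (pixel fraction or object count) feed heatmaps,
top-decile hotspot calling, and cross-marker colocalization measured as the
tile-wise Spearman ρ with a seeded permutation p-value
`p = (1 + #{|ρ_perm| ≥ |ρ_obs|}) / (n_perm + 1)`.

**Expression statistics.** The QC filter (cells with < 400 expressed genes,
then genes expressed in < 4 cells), the p-EMT signature score — per cell,
the mean within-cell expression rank of the ~97 signature genes normalized
by the number of ranked genes, so score ∈ (0, 1] and is rank-invariant —
with two-sided Wilcoxon rank-sum group comparison; marker-gene selection
(Wilcoxon target-vs-rest, Bonferroni p < 0.05, fold change > 2); and
normality-gated group-fraction tests (Shapiro–Wilk + F-ratio gate choosing
between t test and Mann–Whitney / signed-rank).

**Synthetic data.** Tissue layouts with labeled compartments, planted
Poisson marker point processes (optionally correlated through a shared
log-Gaussian latent field), brightfield rendering composed in OD space so
deconvolution inverts it exactly, smooth known deformations with landmark
pairs, and expression matrices with planted signature shifts. Every
downstream claim is validated against these ground truths.

## Worked example

```python
import serialstain as ss

# two serial sections of one synthetic tissue, correlated markers,
# unknown smooth deformation on the non-reference section
rates = {"POSTN": {"T": 1e-4, "IF": 4e-4, "S": 1e-3},
         "CD163": {"T": 1e-4, "IF": 4e-4, "S": 1e-3}}
study = ss.make_serial_study(["POSTN", "CD163"], rates, size=(1200, 1200),
                             coloc_rho=0.8, max_disp=36.0, smoothness=200.0, seed=0)

fields, reports = ss.register_stack(study.sections, reference="centroid",
                                    landmarks=study.truth.landmarks)
aligned = [ss.warp(img, fld) for img, fld in zip(study.sections, fields)]
dets = {img.marker: ss.detect_positive(ss.deconvolve_hdab(img)) for img in aligned}

profile = ss.compartment_profile(dets, study.layout.annotation())
grid = ss.tile_region(study.layout.tissue_mask, study.layout.tissue_mask, tile_size=150)
maps = {m: ss.density_map(d, grid) for m, d in dets.items()}
coloc = ss.colocalize(maps["POSTN"], maps["CD163"], n_perm=1000, seed=7)
```

Output (exactly as printed by the example above):

```
section 1: affine+demons, tissue Dice 0.977 -> 0.999, TRE 0.30 px at working scale
compartment      IF       S       T
marker
CD163        0.0309  0.0644  0.0081
POSTN        0.0306  0.0573  0.0114
POSTN~CD163 tile Spearman rho = 0.39, permutation p = 0.0070 (44 tiles)
```

Registration recovered the planted deformation to 0.30 px at the 500-px
working scale and restored tissue overlap (Dice 0.999). Both markers show
the planted S > IF > T positive-area gradient, and the shared latent field
(ρ = 0.8) appears as significant tile-level colocalization (ρ = 0.39,
permutation p = 0.007 over 44 tiles).

On the expression side:

```python
sig = [f"G{i:04d}" for i in range(97)]
labels = ["normal"] * 200 + ["tumor"] * 200
adata = ss.simulate_expression(400, 2000, sig, labels, effect=2.0, seed=1)
adata = ss.qc_filter(adata)                       # <400 genes/cell, <4 cells/gene
score = ss.pemt_score(adata, sig)                 # normalized mean-rank score
test  = ss.compare_scores(score, adata.obs["group"].to_numpy())
```

```
p-EMT score: normal 0.485, tumor 0.715; Wilcoxon rank-sum p = 4.79e-67 (n = 200/200)
```

A `serialstain` console command wraps the same functions
(`serialstain simulate slides|expr`, `register`, `quantify`, `densitymap`,
`coloc`, `score-pemt`, `qc`, `find-markers`); run `serialstain --help`.

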