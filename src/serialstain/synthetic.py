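"""Synthetic serial-section IHC studies and expression matrices with known truth.

The generator emulates the data layout of a multistain serial-section
experiment: one tissue (a contiguous slab containing tumor glands ``T``,
invasive-front bands ``IF``, distal stroma ``S`` and optionally a lymphoid
nodule ``LN``), sectioned several times, each section stained for a single
marker whose positive cells are a planted point process, and each section
distorted by an unknown smooth deformation. Because the deformation fields,
point locations, per-compartment intensities and cross-marker correlations
are all stored, every downstream stage (registration, stain separation,
density mapping, colocalization, compartment statistics) can be tested
against exact ground truth.

The expression side generates nonnegative cell-by-gene matrices with a
multiplicative boost of the signature genes in one group, so the planted
signature-score shift between groups is known and tunable.

All functions are pure in their arguments: the same seed gives bitwise
identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import anndata as ad
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, map_coordinates
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage.draw import disk as _draw_disk

from .geometry import rasterize_geometry
from .stains import default_stain_vectors, od_to_rgb
from .types import DeformationField, RegionAnnotation, SlideImage


class SizingError(ValueError):
    """Raised when the requested structures cannot be packed into the canvas."""


# ---------------------------------------------------------------------------
# tissue layout
# ---------------------------------------------------------------------------


@dataclass
class TissueLayout:
    """A tissue slab with labeled compartments (shared by all serial sections)."""

    width: int
    height: int
    compartments: dict  # label -> shapely (Multi)Polygon, (x=col, y=row)
    tissue_mask: np.ndarray  # (H, W) bool
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.height, self.width

    def compartment_mask(self, label: str) -> np.ndarray:
        return rasterize_geometry(self.compartments[label], self.shape) & self.tissue_mask

    def annotation(self) -> RegionAnnotation:
        return RegionAnnotation(compartments=dict(self.compartments), tissue_mask=self.tissue_mask)


def make_tissue_layout(
    width: int,
    height: int,
    n_glands: int,
    seed: int,
    *,
    gland_radius_frac: tuple[float, float] = (0.06, 0.11),
    if_band_frac: float = 0.04,
    include_ln: bool = False,
) -> TissueLayout:
    """Build a tissue slab with ``n_glands`` tumor glands.

    The tissue is a smoothly perturbed ellipse filling most of the canvas.
    Each gland is a disk placed inside the tissue; an invasive-front band of
    width ``if_band_frac * min(width, height)`` rings each gland; the rest of
    the tissue is distal stroma. With ``include_ln`` a small lymphoid-nodule
    disk is carved out of the stroma.

    Raises :class:`SizingError` when the glands (with their bands) cannot be
    packed into the tissue.
    """
    if width < 256 or height < 256:
        raise SizingError("canvas must be at least 256x256 pixels")
    if n_glands < 1:
        raise ValueError("n_glands must be >= 1")
    rng = np.random.default_rng(seed)
    min_dim = min(width, height)
    cx, cy = width / 2.0, height / 2.0
    theta = np.linspace(0.0, 2.0 * np.pi, 181)[:-1]
    mod = np.zeros_like(theta)
    for k in range(2, 6):
        mod += rng.uniform(0.0, 0.03) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rx, ry = 0.42 * width, 0.42 * height
    ring = np.column_stack(
        [cx + rx * (1 + mod) * np.cos(theta), cy + ry * (1 + mod) * np.sin(theta)]
    )
    tissue_poly = Polygon(ring)

    band = if_band_frac * min_dim
    lo, hi = gland_radius_frac
    # quick infeasibility check before rejection sampling
    min_footprint = n_glands * math.pi * (lo * min_dim + band) ** 2
    if min_footprint > 0.6 * tissue_poly.area:
        raise SizingError(
            f"cannot place {n_glands} glands of radius >= {lo * min_dim:.0f} px "
            f"in a {width}x{height} canvas"
        )

    inner = tissue_poly.buffer(-2.0)
    glands: list[Polygon] = []
    attempts = 0
    while len(glands) < n_glands:
        attempts += 1
        if attempts > 5000:
            raise SizingError(f"failed to place {n_glands} non-overlapping glands")
        r = rng.uniform(lo, hi) * min_dim
        c = Point(rng.uniform(0, width), rng.uniform(0, height))
        footprint = c.buffer(r + band, quad_segs=24)
        if not inner.contains(footprint):
            continue
        if any(footprint.intersects(g.buffer(band)) for g in glands):
            continue
        glands.append(c.buffer(r, quad_segs=24))

    t_geom = unary_union(glands)
    banded = unary_union([g.buffer(band, quad_segs=24) for g in glands])
    if_geom = banded.difference(t_geom)
    s_geom = tissue_poly.difference(banded)

    compartments = {"T": t_geom, "IF": if_geom}
    if include_ln:
        ln = None
        for _ in range(2000):
            r = 0.05 * min_dim
            c = Point(rng.uniform(0, width), rng.uniform(0, height))
            cand = c.buffer(r, quad_segs=24)
            if inner.contains(cand) and not cand.intersects(banded):
                ln = cand
                break
        if ln is None:
            raise SizingError("failed to place the lymphoid nodule")
        compartments["LN"] = ln
        s_geom = s_geom.difference(ln)
    compartments["S"] = s_geom

    mask = rasterize_geometry(tissue_poly, (height, width))
    return TissueLayout(
        width=width, height=height, compartments=compartments, tissue_mask=mask, seed=seed
    )


# ---------------------------------------------------------------------------
# marker point processes
# ---------------------------------------------------------------------------


@dataclass
class MarkerPointSet:
    """Planted marker-positive cell locations for one marker."""

    marker: str
    points: np.ndarray  # (n, 2) float (row, col)
    compartment_of: list = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.points)


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    g = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    sd = g.std()
    if sd == 0:
        return np.zeros(shape)
    return (g - g.mean()) / sd


def plant_marker_points(
    layout: TissueLayout,
    rates: Mapping[str, Mapping[str, float]],
    coloc_rho: float = 0.0,
    seed: int = 0,
    *,
    latent_sigma: float = 40.0,
    latent_sd: float = 0.6,
) -> list[MarkerPointSet]:
    """Plant Poisson marker points with optional cross-marker correlation.

    ``rates`` maps marker -> compartment label -> intensity (points per px^2).
    With ``coloc_rho == 0`` each marker is an independent (piecewise
    homogeneous) Poisson process, so per-compartment counts are exactly
    Poisson with mean ``rate * area``. With ``coloc_rho != 0`` the intensity
    is modulated by a log-Gaussian field built from a latent component shared
    across markers with loading ``sqrt(|rho|)`` (negative rho flips the sign
    of the shared loading for all markers after the first). The modulation
    has unit mean, so expected counts are unchanged.
    """
    if not -1.0 <= coloc_rho <= 1.0:
        raise ValueError("coloc_rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    shape = layout.shape
    comp_masks = {lab: layout.compartment_mask(lab) for lab in layout.compartments}
    for marker, per_comp in rates.items():
        for lab, rate in per_comp.items():
            if lab not in comp_masks:
                raise KeyError(f"unknown compartment label {lab!r} in rates[{marker!r}]")
            if rate < 0:
                raise ValueError("rates must be nonnegative")

    shared = _smooth_unit_field(rng, shape, latent_sigma) if coloc_rho != 0 else None
    out: list[MarkerPointSet] = []
    comp_label_img = np.full(shape, "", dtype=object)
    for lab, m in comp_masks.items():
        comp_label_img[m] = lab

    for i, (marker, per_comp) in enumerate(rates.items()):
        lam = np.zeros(shape)
        for lab, rate in per_comp.items():
            lam[comp_masks[lab]] = rate
        if shared is not None:
            own = _smooth_unit_field(rng, shape, latent_sigma)
            loading = math.sqrt(abs(coloc_rho))
            sign = 1.0 if (i == 0 or coloc_rho > 0) else -1.0
            z = sign * loading * shared + math.sqrt(1.0 - abs(coloc_rho)) * own
            lam = lam * np.exp(latent_sd * z - 0.5 * latent_sd**2)
        total = lam.sum()
        if total <= 0:
            out.append(MarkerPointSet(marker=marker, points=np.empty((0, 2)), compartment_of=[]))
            continue
        n = rng.poisson(total)
        flat_idx = rng.choice(lam.size, size=n, p=(lam / total).ravel())
        rr, cc = np.unravel_index(flat_idx, shape)
        jitter = rng.uniform(-0.5, 0.5, size=(n, 2))
        pts = np.column_stack([rr + jitter[:, 0], cc + jitter[:, 1]])
        labels = [comp_label_img[r, c] for r, c in zip(rr, cc)]
        out.append(MarkerPointSet(marker=marker, points=pts, compartment_of=labels))
    return out


# ---------------------------------------------------------------------------
# IHC rendering
# ---------------------------------------------------------------------------


def render_ihc_image(
    layout: TissueLayout,
    points: MarkerPointSet,
    blob_radius: float = 5.0,
    dab_od: float = 0.8,
    seed: int = 0,
    *,
    base_hema_od: float = 0.35,
    nuclei_density: float = 1.5e-3,
    nuclei_od: float = 0.45,
    noise_od_sd: float = 0.0,
) -> SlideImage:
    """Render one serial section as an 8-bit RGB brightfield IHC image.

    The image is composed in optical-density space (Beer-Lambert): white
    background, hematoxylin-tinted tissue with a nuclei speckle texture that
    is a function of the *layout* seed (so all serial sections of one tissue
    share the same underlying structure, as real serial sections do), and
    flat DAB disks of radius ``blob_radius`` and density ``dab_od`` at the
    planted points. With ``noise_od_sd == 0`` (the default) the composition
    is exactly invertible by H-DAB color deconvolution up to 8-bit
    quantization.
    """
    if blob_radius < 1:
        raise ValueError("blob_radius must be >= 1")
    if dab_od <= 0:
        raise ValueError("dab_od must be positive")
    shape = layout.shape
    tex_rng = np.random.default_rng(layout.seed + 7777)

    hema = np.where(layout.tissue_mask, base_hema_od, 0.0)
    modulation = 1.0 + 0.25 * _smooth_unit_field(tex_rng, shape, 25.0)
    hema *= np.clip(modulation, 0.3, None)
    tissue_idx = np.flatnonzero(layout.tissue_mask)
    n_nuclei = int(round(nuclei_density * tissue_idx.size))
    if n_nuclei > 0:
        chosen = tex_rng.choice(tissue_idx, size=n_nuclei, replace=False)
        nrr, ncc = np.unravel_index(chosen, shape)
        nucleus_layer = np.zeros(shape, dtype=bool)
        for r, c in zip(nrr, ncc):
            dr, dc = _draw_disk((float(r), float(c)), 2.0, shape=shape)
            nucleus_layer[dr, dc] = True
        hema = np.where(nucleus_layer & layout.tissue_mask, hema + nuclei_od, hema)

    dab = np.zeros(shape)
    for r, c in np.asarray(points.points, dtype=float).reshape(-1, 2):
        dr, dc = _draw_disk((r, c), blob_radius, shape=shape)
        dab[dr, dc] = np.maximum(dab[dr, dc], dab_od)

    vecs = default_stain_vectors()
    od_rgb = hema[..., None] * vecs[0] + dab[..., None] * vecs[1]
    if noise_od_sd > 0:
        od_rgb = np.clip(
            od_rgb + np.random.default_rng(seed).normal(0.0, noise_od_sd, od_rgb.shape), 0.0, None
        )
    return SlideImage(pixels=od_to_rgb(od_rgb), marker=points.marker)


# ---------------------------------------------------------------------------
# deformation
# ---------------------------------------------------------------------------


def _sample_field(disp: np.ndarray, coords_rc: np.ndarray) -> np.ndarray:
    """Bilinear sample of an (H, W, 2) field at (n, 2) row/col positions."""
    pos = [coords_rc[:, 0], coords_rc[:, 1]]
    dr = map_coordinates(disp[..., 0], pos, order=1, mode="nearest")
    dc = map_coordinates(disp[..., 1], pos, order=1, mode="nearest")
    return np.column_stack([dr, dc])


def apply_deformation(
    image: SlideImage,
    max_disp: float,
    smoothness: float,
    rigid_part: tuple[float, tuple[float, float]] = (0.0, (0.0, 0.0)),
    seed: int = 0,
    *,
    n_landmarks: int = 25,
    tissue: Optional[np.ndarray] = None,
) -> tuple[SlideImage, DeformationField, np.ndarray]:
    """Warp a section by a known field: rigid motion plus smooth random bumps.

    The stored field uses the pull-back convention: the warped image samples
    the original at ``x + disp(x)``, i.e. the field maps warped-section
    coordinates to original (reference) coordinates. The random component is
    Gaussian-smoothed white noise (correlation length ``smoothness`` px)
    rescaled so its maximum magnitude equals ``max_disp``.

    Returns ``(warped_image, field, landmarks)`` where ``landmarks`` rows are
    ``(row_fixed, col_fixed, row_moving, col_moving)`` pairs sampled on a
    regular grid inside the warped tissue; each pair maps exactly under the
    stored field.
    """
    from .registration import warp  # deferred to avoid an import cycle

    if max_disp < 0:
        raise ValueError("max_disp must be nonnegative")
    if smoothness <= 0:
        raise ValueError("smoothness must be positive")
    h, w = image.shape
    rng = np.random.default_rng(seed)

    disp = np.zeros((h, w, 2))
    if max_disp > 0:
        # smooth random field, generated on a coarse grid for long correlation
        # lengths (identical model: Gaussian-smoothed white noise, bicubic grid)
        factor = max(1, int(round(smoothness / 10.0)))
        ch, cw = -(-h // factor), -(-w // factor)
        raw = np.stack(
            [
                gaussian_filter(rng.standard_normal((ch, cw)), smoothness / factor, mode="reflect")
                for _ in range(2)
            ],
            axis=-1,
        )
        if factor > 1:
            from skimage.transform import resize as _resize

            raw = _resize(raw, (h, w), order=3, anti_aliasing=False, preserve_range=True)
        mag = np.hypot(raw[..., 0], raw[..., 1])
        peak = mag.max()
        if peak > 0:
            disp += raw * (max_disp / peak)

    angle, (shift_r, shift_c) = rigid_part
    if angle != 0.0 or shift_r != 0.0 or shift_c != 0.0:
        cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        ca, sa = math.cos(angle), math.sin(angle)
        r0, c0 = rows - cr, cols - cc
        disp[..., 0] += ca * r0 - sa * c0 + cr + shift_r - rows
        disp[..., 1] += sa * r0 + ca * c0 + cc + shift_c - cols

    if tissue is None:
        tissue = np.any(image.pixels < 245, axis=2)
    if tissue.any():
        rr, cc = np.nonzero(tissue)
        margin = min(rr.min(), cc.min(), h - 1 - rr.max(), w - 1 - cc.max())
        if np.hypot(disp[..., 0], disp[..., 1]).max() > margin:
            raise ValueError(
                "deformation too large: tissue would leave the canvas "
                f"(max displacement {np.hypot(disp[...,0], disp[...,1]).max():.1f} px, "
                f"border margin {margin} px)"
            )

    fld = DeformationField(disp, scale=image.scale)
    warped = warp(image, fld)

    # landmarks: grid points q inside the warped tissue, paired with p = q + d(q)
    moving_tissue = (
        map_coordinates(
            tissue.astype(float),
            np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"))
            + np.moveaxis(disp, -1, 0),
            order=1,
            mode="constant",
        )
        > 0.5
    )
    pairs = None
    step = max(8, int(math.sqrt(moving_tissue.sum() / (4.0 * n_landmarks))))
    while step >= 4:
        gr = np.arange(step, h - step, step)
        gc = np.arange(step, w - step, step)
        qq = np.array([(r, c) for r in gr for c in gc if moving_tissue[r, c]])
        if len(qq) >= n_landmarks:
            pairs = qq
            break
        step //= 2
    if pairs is None:
        raise ValueError("could not sample enough landmarks inside tissue")
    d_at_q = disp[pairs[:, 0], pairs[:, 1]]
    fixed = pairs + d_at_q
    landmarks = np.column_stack([fixed, pairs.astype(float)])
    return warped, fld, landmarks


@dataclass
class GroundTruth:
    """Everything planted in one synthetic serial-section study."""

    fields: dict  # section index -> DeformationField (zero for the reference)
    landmarks: dict  # section index -> (n, 4) landmark pairs
    planted_densities: dict  # marker -> compartment -> intensity per px^2
    planted_coloc: float


@dataclass
class SerialStudy:
    """A full synthetic study: layout, planted points, rendered sections."""

    layout: TissueLayout
    point_sets: list  # MarkerPointSet per section
    sections: list  # SlideImage per section (deformed except the reference)
    reference_index: int
    truth: GroundTruth


def make_serial_study(
    markers: Sequence[str],
    rates: Mapping[str, Mapping[str, float]],
    *,
    size: tuple[int, int] = (1024, 1024),
    n_glands: int = 3,
    coloc_rho: float = 0.0,
    max_disp: float = 30.0,
    smoothness: float = 150.0,
    blob_radius: float = 5.0,
    dab_od: float = 0.8,
    seed: int = 0,
    include_ln: bool = False,
) -> SerialStudy:
    """Generate one tissue, one section per marker, and deform all but the
    centroid (middle) section, which serves as the registration reference."""
    h, w = size
    layout = make_tissue_layout(w, h, n_glands, seed=seed, include_ln=include_ln)
    point_sets = plant_marker_points(layout, rates, coloc_rho=coloc_rho, seed=seed + 1)
    ref = (len(markers) - 1) // 2
    sections: list[SlideImage] = []
    fields: dict[int, DeformationField] = {}
    landmark_map: dict[int, np.ndarray] = {}
    for i, marker in enumerate(markers):
        base = render_ihc_image(
            layout, point_sets[i], blob_radius=blob_radius, dab_od=dab_od, seed=seed + 10 + i
        )
        base.section_index = i
        if i == ref:
            sections.append(base)
            fields[i] = DeformationField.zero(layout.shape)
        else:
            warped, fld, lm = apply_deformation(
                base,
                max_disp=max_disp,
                smoothness=smoothness,
                seed=seed + 100 + i,
                tissue=layout.tissue_mask,
            )
            warped.marker = marker
            warped.section_index = i
            sections.append(warped)
            fields[i] = fld
            landmark_map[i] = lm
    truth = GroundTruth(
        fields=fields,
        landmarks=landmark_map,
        planted_densities={m: dict(rates.get(m, {})) for m in markers},
        planted_coloc=coloc_rho,
    )
    return SerialStudy(
        layout=layout, point_sets=point_sets, sections=sections, reference_index=ref, truth=truth
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def simulate_expression(
    n_cells: int,
    n_genes: int,
    signature: Sequence[str],
    group_labels: Sequence[str],
    effect: float,
    seed: int,
    *,
    elevated: Optional[str] = None,
    gene_names: Optional[Sequence[str]] = None,
    base_log_sd: float = 1.0,
) -> ad.AnnData:
    """Simulate a nonnegative cell-by-gene matrix with a planted signature shift.

    Per-gene baseline means are log-normal; values are Poisson draws around
    the mean, giving sparse nonnegative RPKM-like values. In the ``elevated``
    group (default: the lexicographically last group label) signature genes
    receive a multiplicative boost of ``1 + effect``, so the expected
    signature-score difference between groups grows monotonically with
    ``effect`` and ``effect == 0`` is an exact null.
    """
    if effect < 0:
        raise ValueError("effect must be nonnegative")
    rng = np.random.default_rng(seed)
    if gene_names is None:
        gene_names = [f"G{i:04d}" for i in range(n_genes)]
    gene_names = list(gene_names)
    if len(gene_names) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    name_to_idx = {g: i for i, g in enumerate(gene_names)}
    sig_idx = []
    for g in signature:
        if g not in name_to_idx:
            raise KeyError(f"signature gene {g!r} absent from gene names")
        sig_idx.append(name_to_idx[g])

    group_labels = list(group_labels)
    if n_cells == 0:
        return ad.AnnData(
            X=np.empty((0, n_genes)),
            obs=pd.DataFrame({"group": pd.Series([], dtype=str)}),
            var=pd.DataFrame(index=pd.Index(gene_names, name="gene")),
        )
    if len(group_labels) != n_cells:
        raise ValueError("group_labels length must equal n_cells")
    uniq = sorted(set(group_labels))
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    if elevated is None:
        elevated = uniq[-1]
    if elevated not in uniq:
        raise ValueError(f"elevated group {elevated!r} not among labels")

    means = rng.lognormal(mean=0.0, sigma=base_log_sd, size=n_genes)
    lam = np.tile(means, (n_cells, 1))
    elev_cells = np.array([g == elevated for g in group_labels])
    if sig_idx:
        lam[np.ix_(elev_cells, np.array(sig_idx))] *= 1.0 + effect
    X = rng.poisson(lam).astype(np.float64)
    obs = pd.DataFrame(
        {"group": group_labels}, index=pd.Index([f"cell{i:05d}" for i in range(n_cells)], name="cell")
    )
    var = pd.DataFrame(index=pd.Index(gene_names, name="gene"))
    return ad.AnnData(X=X, obs=obs, var=var)
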