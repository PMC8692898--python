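"""Tile-based marker density, hotspots, colocalization and compartment profiles.

After registration, every marker's detections live in the reference slide's
coordinate frame. Annotated regions are dissected into square tiles
(default 1000x1000 px at full resolution), and each tile carries a
marker-positive density: either the positive-pixel fraction of its tissue
area or the count of positive objects falling in it. Tiles sharing one grid
are directly comparable across markers, which makes hotspot calling and
cross-marker colocalization simple tile-level statistics.

Colocalization is quantified as the Spearman correlation of two markers'
tile densities over jointly valid tiles, with a seeded permutation null:
tile labels of the second map are shuffled ``n_perm`` times and the
two-sided p-value is ``(1 + #{|rho_perm| >= |rho_obs|}) / (n_perm + 1)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .geometry import rasterize_geometry
from .stains import PositiveDetection, positive_area_fraction
from .types import RegionAnnotation


@dataclass
class TileGrid:
    """Half-open square tiles covering a region's bounding box.

    Tile (i, j) spans rows ``[origin[0] + i*size, origin[0] + (i+1)*size)``
    and likewise for columns. ``tissue_px`` holds region-and-tissue pixels
    per tile; a tile is valid when its tissue fraction is at least
    ``min_tissue`` of the full tile area.
    """

    origin: tuple[int, int]
    tile_size: int
    n_rows: int
    n_cols: int
    tissue_px: np.ndarray  # (n_rows, n_cols) int
    valid: np.ndarray  # (n_rows, n_cols) bool
    region_tissue: np.ndarray  # full-frame bool mask (region AND tissue)

    @property
    def n_tiles(self) -> int:
        return self.n_rows * self.n_cols

    def tile_of(self, row: float, col: float) -> tuple[int, int]:
        """Tile index containing a point (half-open intervals)."""
        return (
            int(np.floor((row - self.origin[0]) / self.tile_size)),
            int(np.floor((col - self.origin[1]) / self.tile_size)),
        )


@dataclass
class DensityMap:
    """Per-tile marker-positive density on a :class:`TileGrid`."""

    marker: str
    grid: TileGrid
    values: np.ndarray  # (n_rows, n_cols) float; NaN on invalid tiles (pixel mode)
    valid: np.ndarray
    mode: str = "pixel_fraction"

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid & np.isfinite(self.values)]


@dataclass
class ColocResult:
    """Tile-wise Spearman colocalization with a permutation p-value."""

    marker_pair: tuple[str, str]
    statistic: float
    p_perm: float
    n_tiles: int
    n_perm: int
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.statistic <= 1.0 + 1e-9:
            raise ValueError("rho must lie in [-1, 1]")
        if not 0.0 < self.p_perm <= 1.0:
            raise ValueError("p must lie in (0, 1]")


def tile_region(
    region,
    tissue: np.ndarray,
    tile_size: int = 1000,
    min_tissue: float = 0.05,
) -> TileGrid:
    """Dissect a region into ``tile_size`` squares anchored at its bounding box.

    ``region`` may be a shapely polygon (GeoJSON axis order) or a boolean
    mask in the tissue frame. Tiles whose region-and-tissue area is below
    ``min_tissue`` of the tile area are marked invalid.
    """
    tissue = np.asarray(tissue, dtype=bool)
    region_mask = rasterize_geometry(region, tissue.shape)
    combined = region_mask & tissue
    if not combined.any():
        raise ValueError("region does not intersect tissue")
    rr, cc = np.nonzero(region_mask)
    r0, c0 = int(rr.min()), int(cc.min())
    r1, c1 = int(rr.max()), int(cc.max())
    n_rows = int(np.ceil((r1 - r0 + 1) / tile_size))
    n_cols = int(np.ceil((c1 - c0 + 1) / tile_size))
    tissue_px = np.zeros((n_rows, n_cols), dtype=int)
    for i in range(n_rows):
        for j in range(n_cols):
            rs, cs = r0 + i * tile_size, c0 + j * tile_size
            tissue_px[i, j] = combined[rs : rs + tile_size, cs : cs + tile_size].sum()
    valid = tissue_px >= min_tissue * tile_size * tile_size
    return TileGrid(
        origin=(r0, c0),
        tile_size=tile_size,
        n_rows=n_rows,
        n_cols=n_cols,
        tissue_px=tissue_px,
        valid=valid,
        region_tissue=combined,
    )


def density_map(det: PositiveDetection, grid: TileGrid, mode: str = "pixel_fraction") -> DensityMap:
    """Per-tile marker-positive density.

    ``pixel_fraction``: positive pixels / tissue pixels per tile (NaN where
    the tile holds no tissue). ``object_count``: number of detected object
    centroids falling in each tile (half-open boundary rule); counts are
    kept on every tile so they sum exactly to the number of objects whose
    centroid lies in the region's tissue.
    """
    if det.mask.shape != grid.region_tissue.shape:
        raise ValueError("detection and grid are in different frames (shape mismatch)")
    values = np.full((grid.n_rows, grid.n_cols), np.nan)
    r0, c0 = grid.origin
    ts = grid.tile_size
    if mode == "pixel_fraction":
        pos = det.mask & grid.region_tissue
        for i in range(grid.n_rows):
            for j in range(grid.n_cols):
                npx = grid.tissue_px[i, j]
                if npx > 0:
                    values[i, j] = pos[r0 + i * ts : r0 + (i + 1) * ts, c0 + j * ts : c0 + (j + 1) * ts].sum() / npx
    elif mode == "object_count":
        values[:] = 0.0
        for r, c, _a in det.objects.reshape(-1, 3):
            ri, ci = int(np.floor(r)), int(np.floor(c))
            if not (0 <= ri < det.mask.shape[0] and 0 <= ci < det.mask.shape[1]):
                continue
            if not grid.region_tissue[ri, ci]:
                continue
            i, j = grid.tile_of(r, c)
            if 0 <= i < grid.n_rows and 0 <= j < grid.n_cols:
                values[i, j] += 1
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return DensityMap(marker="", grid=grid, values=values, valid=grid.valid.copy(), mode=mode)


def hotspots(dmap: DensityMap, quantile: float = 0.9) -> set:
    """Tiles whose density reaches the given quantile of positive valid tiles.

    The threshold is the order-statistic quantile (``method="higher"``) of
    the *positive* valid densities, so the hotspot set is invariant under
    any monotone rescaling of densities and ties at the threshold are
    included. Zero-density tiles are never hotspots; an all-zero map yields
    an empty set.
    """
    finite = dmap.valid & np.isfinite(dmap.values)
    if not finite.any():
        raise ValueError("no valid tiles")
    vals = dmap.values[finite]
    pos = vals[vals > 0]
    if pos.size == 0:
        return set()
    thr = np.quantile(pos, quantile, method="higher")
    idx = np.argwhere(finite & (dmap.values >= thr) & (dmap.values > 0))
    return {(int(i), int(j)) for i, j in idx}


def _pearson_rows(za: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Correlation of standardized vector ``za`` against each row of ``B``."""
    Bc = B - B.mean(axis=1, keepdims=True)
    Bs = Bc.std(axis=1)
    Bs[Bs == 0] = np.nan
    return (Bc / Bs[:, None]) @ za / za.size


def colocalize(a: DensityMap, b: DensityMap, n_perm: int = 1000, seed: int = 0) -> ColocResult:
    """Spearman colocalization of two density maps on the same grid.

    Rank-based correlation over jointly valid tiles; the two-sided p-value
    comes from ``n_perm`` seeded shuffles of the second map's tile labels.
    """
    if a.values.shape != b.values.shape:
        raise ValueError("density maps are on different grids")
    joint = a.valid & b.valid & np.isfinite(a.values) & np.isfinite(b.values)
    va, vb = a.values[joint], b.values[joint]
    n = va.size
    if n < 3:
        raise ValueError("need at least 3 jointly valid tiles")
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("constant density map: colocalization undefined")
    ra, rb = rankdata(va), rankdata(vb)
    za = (ra - ra.mean()) / ra.std()
    zb = (rb - rb.mean()) / rb.std()
    rho = float(za @ zb / n)
    rng = np.random.default_rng(seed)
    perm = rng.permuted(np.tile(rb, (n_perm, 1)), axis=1)
    rho_perm = _pearson_rows(za, perm)
    exceed = np.sum(np.abs(rho_perm) >= abs(rho) - 1e-12)
    p = (1.0 + exceed) / (n_perm + 1.0)
    return ColocResult(
        marker_pair=(a.marker, b.marker),
        statistic=rho,
        p_perm=float(p),
        n_tiles=int(n),
        n_perm=n_perm,
        seed=seed,
    )


def render_heatmap(dmap: DensityMap, out) -> None:
    """Write a per-tile heatmap PNG plus an exact CSV twin of the values.

    Invalid tiles are rendered in a distinct hatch-gray; the CSV twin
    (same path with ``.csv``) round-trips the numeric values exactly.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out)
    shown = np.ma.masked_invalid(np.where(dmap.valid, dmap.values, np.nan))
    fig, ax = plt.subplots(figsize=(max(2, dmap.values.shape[1] / 2), max(2, dmap.values.shape[0] / 2)))
    cmap = plt.get_cmap("inferno").copy()
    cmap.set_bad("0.8")
    im = ax.imshow(shown, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=dmap.mode)
    ax.set_title(dmap.marker or "density")
    fig.savefig(out, dpi=100, bbox_inches="tight")
    plt.close(fig)
    rows = []
    for i in range(dmap.values.shape[0]):
        for j in range(dmap.values.shape[1]):
            rows.append(
                {
                    "tile_row": i,
                    "tile_col": j,
                    "density": dmap.values[i, j],
                    "tissue_px": int(dmap.grid.tissue_px[i, j]),
                    "valid": bool(dmap.valid[i, j]),
                }
            )
    pd.DataFrame(rows).to_csv(out.with_suffix(".csv"), index=False)


def compartment_profile(
    detections: Mapping[str, PositiveDetection],
    annotation: RegionAnnotation,
    section: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Positive-area fraction per (marker, compartment, section).

    ``detections`` maps marker name to its detection in reference
    coordinates; ``section`` optionally maps marker to a section index for
    bookkeeping. Compartments that do not intersect tissue are omitted with
    a warning.
    """
    rows = []
    for marker, det in detections.items():
        for label, geom in annotation.compartments.items():
            try:
                frac = positive_area_fraction(det, geom, annotation.tissue_mask)
            except ValueError:
                warnings.warn(f"compartment {label!r} has no tissue; omitted for {marker!r}")
                continue
            rows.append(
                {
                    "marker": marker,
                    "compartment": label,
                    "section": (section or {}).get(marker, 0),
                    "positive_area_fraction": frac,
                }
            )
    return pd.DataFrame(rows, columns=["marker", "compartment", "section", "positive_area_fraction"])
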