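"""Polygon rasterization helpers.

Annotations are shapely geometries in GeoJSON axis order (x=col, y=row);
rasters are (row, col) boolean masks. Pixels are treated as unit squares and
a pixel belongs to a polygon when its center lies inside.
"""

from __future__ import annotations

import numpy as np
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry
from skimage.draw import polygon as _draw_polygon


def _fill_ring(coords, shape: tuple[int, int]) -> np.ndarray:
    xy = np.asarray(coords, dtype=float)
    # shapely rings are (x, y) = (col, row)
    rr, cc = _draw_polygon(xy[:, 1], xy[:, 0], shape=shape)
    mask = np.zeros(shape, dtype=bool)
    mask[rr, cc] = True
    return mask


def rasterize_geometry(geom, shape: tuple[int, int]) -> np.ndarray:
    """Rasterize a shapely (Multi)Polygon or return a boolean mask unchanged."""
    if isinstance(geom, np.ndarray):
        if geom.shape != tuple(shape):
            raise ValueError("mask shape disagrees with target shape")
        return geom.astype(bool)
    if not isinstance(geom, BaseGeometry):
        raise TypeError(f"cannot rasterize object of type {type(geom)!r}")
    mask = np.zeros(shape, dtype=bool)
    if geom.is_empty:
        return mask
    if isinstance(geom, Polygon):
        parts = [geom]
    elif isinstance(geom, MultiPolygon):
        parts = list(geom.geoms)
    else:  # GeometryCollection etc.
        parts = [g for g in getattr(geom, "geoms", []) if isinstance(g, Polygon)]
    for poly in parts:
        part = _fill_ring(poly.exterior.coords, shape)
        for ring in poly.interiors:
            part &= ~_fill_ring(ring.coords, shape)
        mask |= part
    return mask


def translate_mask(mask: np.ndarray, d_row: int, d_col: int) -> np.ndarray:
    """Shift a boolean mask by whole pixels, zero-filling exposed borders."""
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs, cs = max(d_row, 0), max(d_col, 0)
    re, ce = h + min(d_row, 0), w + min(d_col, 0)
    out[rs:re, cs:ce] = mask[rs - d_row : re - d_row, cs - d_col : ce - d_col]
    return out
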