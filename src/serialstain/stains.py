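"""Hematoxylin/DAB stain separation and marker-positive detection.

Brightfield IHC obeys the Beer-Lambert law: the optical density of each RGB
channel is (to a good approximation) a nonnegative linear combination of the
per-stain absorption spectra. Separating stains is therefore a linear
unmixing of the per-pixel OD vector onto known stain vectors; the defaults
are the classic Ruifrok-Johnston hematoxylin and DAB vectors, the same ones
scikit-image uses for H-DAB separation.

"Marker-positive" is called by thresholding the DAB optical density and
keeping 8-connected components above a minimum area; both the positive-pixel
mask and the object centroids are retained, because density downstream is
reported either as a positive-pixel fraction (area claims) or an object
count (cell claims).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .geometry import rasterize_geometry
from .types import SlideImage

#: Ruifrok-Johnston absorption vectors (unit RGB-OD), rows = stains.
HEMATOXYLIN_RGB_OD = np.array([0.650, 0.704, 0.286])
DAB_RGB_OD = np.array([0.269, 0.568, 0.778])


def default_stain_vectors() -> np.ndarray:
    """Unit hematoxylin and DAB stain vectors, shape (2, 3)."""
    vecs = np.stack([HEMATOXYLIN_RGB_OD, DAB_RGB_OD])
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


@dataclass
class StainChannels:
    """Per-pixel optical densities after unmixing."""

    hema_od: np.ndarray
    dab_od: np.ndarray
    stain_vectors: np.ndarray

    def __post_init__(self) -> None:
        if self.hema_od.shape != self.dab_od.shape:
            raise ValueError("stain channel shapes disagree")


@dataclass
class PositiveDetection:
    """Thresholded DAB mask plus its connected components.

    ``objects`` rows are (centroid_row, centroid_col, area_px).
    """

    mask: np.ndarray
    objects: np.ndarray  # (n, 3) float
    threshold: float
    min_area: int

    @property
    def n_objects(self) -> int:
        return len(self.objects)

    @property
    def centroids(self) -> np.ndarray:
        return self.objects[:, :2] if len(self.objects) else np.empty((0, 2))


def rgb_to_od(pixels: np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density of 8-bit RGB: ``-ln(I / 255)``.

    Intensities are clipped to >= 1 so fully saturated pixels stay finite.
    """
    I = np.clip(np.asarray(pixels, dtype=np.float64), 1.0, 255.0)
    return -np.log(I / 255.0)


def od_to_rgb(od: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`, rounded to uint8."""
    return np.clip(np.round(255.0 * np.exp(-od)), 0, 255).astype(np.uint8)


def deconvolve_hdab(image, stain_vectors: np.ndarray | None = None) -> StainChannels:
    """Unmix an RGB IHC image into hematoxylin and DAB optical densities.

    The per-pixel OD vector is projected onto the two stain vectors by least
    squares (pseudoinverse of the 3x2 stain matrix); negative loadings are
    clipped to zero.
    """
    pixels = image.pixels if isinstance(image, SlideImage) else np.asarray(image)
    vecs = default_stain_vectors() if stain_vectors is None else np.asarray(stain_vectors, float)
    vecs = vecs[:2]
    norms = np.linalg.norm(vecs, axis=1)
    if np.any(norms == 0):
        raise ValueError("stain vectors must be nonzero")
    vecs = vecs / norms[:, None]
    if np.linalg.matrix_rank(vecs) < 2:
        raise ValueError("stain matrix is singular: vectors must be linearly independent")
    od = rgb_to_od(pixels)
    pinv = np.linalg.pinv(vecs.T)  # (2, 3)
    conc = od @ pinv.T
    conc = np.clip(conc, 0.0, None)
    return StainChannels(hema_od=conc[..., 0], dab_od=conc[..., 1], stain_vectors=vecs)


def detect_positive(
    channels: StainChannels, threshold: float = 0.15, min_area: int = 20
) -> PositiveDetection:
    """Threshold the DAB channel and extract positive objects.

    The mask keeps every pixel with ``dab_od >= threshold``; objects are
    8-connected components of the mask with area >= ``min_area``, located by
    their unweighted pixel-centroid.
    """
    dab = np.asarray(channels.dab_od, dtype=float)
    if not np.all(np.isfinite(dab)):
        raise ValueError("DAB channel contains non-finite values")
    mask = dab >= threshold
    labels = measure.label(mask, connectivity=2)
    rows = []
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            r, c = region.centroid
            rows.append((r, c, float(region.area)))
    objects = np.asarray(rows, dtype=float) if rows else np.empty((0, 3))
    return PositiveDetection(mask=mask, objects=objects, threshold=threshold, min_area=min_area)


def positive_area_fraction(det: PositiveDetection, region, tissue: np.ndarray) -> float:
    """Fraction of region-and-tissue pixels that are marker-positive.

    ``region`` may be a shapely polygon (GeoJSON axis order) or a boolean
    mask in the same frame as the detection.
    """
    tissue = np.asarray(tissue, dtype=bool)
    region_mask = rasterize_geometry(region, tissue.shape)
    denom_mask = region_mask & tissue
    denom = int(denom_mask.sum())
    if denom == 0:
        raise ValueError("region does not intersect tissue: fraction undefined")
    num = int((det.mask & denom_mask).sum())
    return num / denom
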