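"""Core containers shared across the registration and quantification stages.

Conventions used throughout the package:

* Image arrays are ``(H, W, 3)`` uint8 RGB; masks are ``(H, W)`` bool.
* Pixel coordinates are 0-based ``(row, col)`` floats.
* A :class:`DeformationField` stores pull-back displacements: to produce the
  aligned image, the moving image is sampled at ``x + disp(x)`` for every
  reference-grid coordinate ``x``.
* ``scale`` is the resolution of an object relative to the original slide
  (1.0 = full resolution; a 500-px working copy of a 2000-px slide has
  scale 0.25).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np


@dataclass
class SlideImage:
    """One serially sectioned, single-marker IHC slide."""

    pixels: np.ndarray  # (H, W, 3) uint8
    marker: str = ""
    section_index: int = 0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage expects an (H, W, 3) RGB array")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(np.round(self.pixels), 0, 255).astype(np.uint8)
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class DeformationField:
    """Dense pull-back displacement grid, ``disp[r, c] = (d_row, d_col)``.

    Displacements are expressed in pixels at the field's own resolution
    (``scale`` relative to the original slide).
    """

    disp: np.ndarray  # (H, W, 2) float
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.disp = np.asarray(self.disp, dtype=np.float64)
        if self.disp.ndim != 3 or self.disp.shape[2] != 2:
            raise ValueError("DeformationField expects an (H, W, 2) array")
        if not np.all(np.isfinite(self.disp)):
            raise ValueError("displacements must be finite")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.disp.shape[0], self.disp.shape[1]

    def magnitude(self) -> np.ndarray:
        return np.hypot(self.disp[..., 0], self.disp[..., 1])

    @classmethod
    def zero(cls, shape: tuple[int, int], scale: float = 1.0) -> "DeformationField":
        return cls(np.zeros((shape[0], shape[1], 2)), scale=scale)


@dataclass
class RegionAnnotation:
    """Labeled compartment polygons in reference-slide coordinates.

    ``compartments`` maps a label (``T``, ``IF``, ``S``, ``LN``) to a shapely
    (Multi)Polygon in (x=col, y=row) axis order, matching GeoJSON.
    """

    compartments: dict
    tissue_mask: np.ndarray  # (H, W) bool
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.tissue_mask = np.asarray(self.tissue_mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.tissue_mask.shape  # type: ignore[return-value]

    @property
    def labels(self) -> list[str]:
        return list(self.compartments)


@dataclass
class RegistrationReport:
    """Diagnostics for one registered section."""

    section_index: int
    dice_before: float
    dice_after: float
    method: str = "affine+demons"
    tre_px: Optional[float] = None  # mean landmark error, full-resolution px
    tre_px_working: Optional[float] = None  # same error at the working scale
    similarity_metric_trace: list = field(default_factory=list)
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("dice_before", "dice_after"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0 or np.isnan(v)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.tre_px is not None and self.tre_px < 0:
            raise ValueError("tre_px must be nonnegative")


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two boolean masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom
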