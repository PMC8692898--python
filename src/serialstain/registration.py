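"""Serial-section registration onto a reference (centroid) slide.

The pipeline mirrors standard practice for multistain serial sections:

1. downsample every section so its longest side is ~500 px,
2. register each moving section onto the reference at that working scale
   (multi-resolution affine initialization, then a regularized dense
   demons-style nonrigid refinement),
3. upsample the recovered deformation field to the original resolution
   (resampling the grid and scaling the displacement magnitudes), and
4. warp the full-resolution section with the upsampled field.

Registration runs on tissue-weighted grayscale (mean optical density), not
raw RGB, because each serial section carries a different stain and marker-
dependent color must not drive the alignment. The dissimilarity metric is
mean-squared error by default (mutual information is available as a config
option). The nonrigid step is never allowed to make things worse: if it
degrades the tissue-mask Dice relative to the affine result (or the affine
relative to identity), the better earlier stage is returned.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _field
from typing import Optional, Sequence

import numpy as np
import SimpleITK as sitk
from scipy.ndimage import binary_closing, binary_fill_holes, map_coordinates
from skimage import measure
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.transform import resize as _resize

from .stains import rgb_to_od
from .types import DeformationField, RegistrationReport, SlideImage, dice_coefficient


class RegistrationError(RuntimeError):
    """Raised when a pair or stack cannot be registered."""


@dataclass
class RegistrationConfig:
    """Knobs of the pairwise registration.

    metric: "mse" (mean squared error on tissue-weighted grayscale) or
        "mi" (Mattes mutual information).
    affine_only: skip the nonrigid refinement.
    affine_iterations / shrink_factors / smoothing_sigmas: multi-resolution
        schedule of the affine stage.
    demons_iterations: iterations per nonrigid pyramid level (coarse->fine).
    field_sigma: Gaussian smoothing (px) of the demons displacement field —
        the regularizer that keeps the recovered field smooth.
    """

    metric: str = "mse"
    affine_only: bool = False
    affine_iterations: int = 200
    shrink_factors: tuple = (4, 2, 1)
    smoothing_sigmas: tuple = (2.0, 1.0, 0.0)
    demons_levels: tuple = (4, 2, 1)
    demons_iterations: tuple = (100, 60, 30)
    field_sigma: float = 2.0


# ---------------------------------------------------------------------------
# basic image operations
# ---------------------------------------------------------------------------


def downsample(image: SlideImage, target: int = 500) -> tuple[SlideImage, float]:
    """Shrink so the longest side is <= ``target`` px, preserving aspect ratio.

    Antialiased; images already smaller than the target are returned
    unchanged with scale 1 (no upsampling). Returns (image, scale factor).
    """
    if target < 64:
        raise ValueError("target must be >= 64 px")
    h, w = image.shape
    longest = max(h, w)
    if longest <= target:
        out = SlideImage(
            image.pixels.copy(), marker=image.marker, section_index=image.section_index, scale=image.scale
        )
        return out, 1.0
    f = target / longest
    oh, ow = max(1, round(h * f)), max(1, round(w * f))
    resized = _resize(image.pixels, (oh, ow), anti_aliasing=True, preserve_range=True)
    factor = max(oh, ow) / longest
    out = SlideImage(
        np.clip(np.round(resized), 0, 255).astype(np.uint8),
        marker=image.marker,
        section_index=image.section_index,
        scale=image.scale * factor,
    )
    return out, factor


def tissue_mask(image: SlideImage) -> np.ndarray:
    """Foreground tissue via Otsu thresholding of inverted grayscale.

    Small specks are removed and only components at least 5% the size of the
    largest one are kept; holes are filled. A blank (near-white) slide gives
    an all-background mask.
    """
    gray = rgb2gray(image.pixels)  # in [0, 1]
    inv = 1.0 - gray
    if inv.max() - inv.min() < 5e-3 or inv.max() < 0.02:
        return np.zeros(image.shape, dtype=bool)
    thr = threshold_otsu(inv)
    mask = inv > thr
    labels = measure.label(mask, connectivity=2)
    if labels.max() == 0:
        return mask
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    keep = np.flatnonzero(sizes >= 0.05 * sizes.max())
    mask = np.isin(labels, keep)
    mask = binary_closing(mask, iterations=2)
    return binary_fill_holes(mask)


def registration_gray(image: SlideImage) -> np.ndarray:
    """Tissue-weighted grayscale used as the registration signal.

    Mean optical density over RGB, clipped; stain-specific hue is collapsed
    so alignment is driven by tissue structure rather than marker color.
    """
    od = rgb_to_od(image.pixels).mean(axis=2)
    return np.clip(od, 0.0, 2.0).astype(np.float32)


def warp(image: SlideImage, field: DeformationField) -> SlideImage:
    """Resample ``image`` through ``field`` (pull-back, bilinear).

    Output pixel x takes the value of the input at ``x + disp(x)``; samples
    falling outside the canvas are filled with background white.
    """
    if abs(image.scale - field.scale) > 1e-9:
        raise ValueError(f"scale mismatch: image {image.scale} vs field {field.scale}")
    h, w = image.shape
    if field.shape != (h, w):
        raise ValueError(f"shape mismatch: image {(h, w)} vs field {field.shape}")
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [rows + field.disp[..., 0], cols + field.disp[..., 1]]
    out = np.empty_like(image.pixels)
    for ch in range(3):
        out[..., ch] = np.clip(
            np.round(
                map_coordinates(
                    image.pixels[..., ch].astype(np.float64),
                    coords,
                    order=1,
                    mode="constant",
                    cval=255.0,
                )
            ),
            0,
            255,
        )
    return SlideImage(out, marker=image.marker, section_index=image.section_index, scale=image.scale)


def warp_mask(mask: np.ndarray, field: DeformationField) -> np.ndarray:
    """Pull a boolean mask through a field (bilinear then 0.5 threshold)."""
    h, w = mask.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    coords = [rows + field.disp[..., 0], cols + field.disp[..., 1]]
    return map_coordinates(mask.astype(np.float64), coords, order=1, mode="constant", cval=0.0) > 0.5


# ---------------------------------------------------------------------------
# deformation-field resampling
# ---------------------------------------------------------------------------


def resample_field(
    field: DeformationField, to_scale: float, out_shape: Optional[tuple[int, int]] = None
) -> DeformationField:
    """Resample a field to another resolution scale.

    The displacement grid is bilinearly resampled to the target size and the
    displacement magnitudes are multiplied by the per-axis resize factors
    (``to_scale / field.scale`` up to rounding), so the field expresses the
    same physical deformation at the new resolution.
    """
    if not np.all(np.isfinite(field.disp)):
        raise ValueError("field contains non-finite displacements")
    h, w = field.shape
    if out_shape is None:
        ratio = to_scale / field.scale
        out_shape = (max(1, round(h * ratio)), max(1, round(w * ratio)))
    oh, ow = out_shape
    if (oh, ow) == (h, w):
        return DeformationField(field.disp.copy(), scale=to_scale)
    fr, fc = oh / h, ow / w
    resized = _resize(field.disp, (oh, ow), order=1, anti_aliasing=False, preserve_range=True)
    out = np.empty_like(resized)
    out[..., 0] = resized[..., 0] * fr
    out[..., 1] = resized[..., 1] * fc
    return DeformationField(out, scale=to_scale)


def upsample_field(
    field: DeformationField, to_scale: float, out_shape: Optional[tuple[int, int]] = None
) -> DeformationField:
    """Upsample a working-scale field to a finer scale (e.g. full resolution)."""
    if to_scale < field.scale - 1e-12:
        raise ValueError("upsample_field cannot reduce the scale; use resample_field")
    return resample_field(field, to_scale, out_shape=out_shape)


def invert_field(field: DeformationField, n_iter: int = 40, tol: float = 1e-3) -> DeformationField:
    """Numerically invert a displacement field by fixed-point iteration.

    If ``d`` maps coordinates of image B to image A (pull-back), the inverse
    ``e`` satisfies ``e(x) = -d(x + e(x))`` and maps A-coordinates to B.
    """
    d = field.disp
    e = -d.copy()
    h, w = field.shape
    rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    for _ in range(n_iter):
        coords = [rows + e[..., 0], cols + e[..., 1]]
        d_at = np.stack(
            [map_coordinates(d[..., k], coords, order=1, mode="nearest") for k in range(2)], axis=-1
        )
        new = -d_at
        if np.abs(new - e).max() < tol:
            e = new
            break
        e = new
    return DeformationField(e, scale=field.scale)


# ---------------------------------------------------------------------------
# pairwise registration
# ---------------------------------------------------------------------------


def _composite_to_field(
    transform: sitk.Transform, reference: sitk.Image, scale: float
) -> DeformationField:
    filt = sitk.TransformToDisplacementFieldFilter()
    filt.SetReferenceImage(reference)
    filt.SetOutputPixelType(sitk.sitkVectorFloat64)
    disp_img = filt.Execute(transform)
    arr = sitk.GetArrayFromImage(disp_img)  # (H, W, 2) with (dx, dy)
    return DeformationField(np.stack([arr[..., 1], arr[..., 0]], axis=-1), scale=scale)


def register_pair(
    moving: SlideImage,
    fixed: SlideImage,
    config: Optional[RegistrationConfig] = None,
) -> tuple[DeformationField, RegistrationReport]:
    """Register ``moving`` onto ``fixed`` at their (shared) working scale.

    Returns the pull-back deformation field (sampling the moving image at
    ``x + disp(x)`` aligns it with the fixed image) and a report with tissue
    Dice before/after, the stage actually used, and the affine metric trace.
    """
    config = config or RegistrationConfig()
    fg = registration_gray(fixed)
    mg = registration_gray(moving)
    fixed_mask = tissue_mask(fixed)
    moving_mask = tissue_mask(moving)
    if not fixed_mask.any() or not moving_mask.any():
        raise RegistrationError("no tissue found in one of the images")
    dice_before = dice_coefficient(fixed_mask, moving_mask)

    f_img = sitk.GetImageFromArray(fg)
    m_img = sitk.GetImageFromArray(mg)

    trace: list[float] = []
    reg = sitk.ImageRegistrationMethod()
    if config.metric == "mse":
        reg.SetMetricAsMeanSquares()
    elif config.metric == "mi":
        reg.SetMetricAsMattesMutualInformation(numberOfHistogramBins=48)
    else:
        raise ValueError(f"unknown metric {config.metric!r}")
    reg.SetMetricSamplingStrategy(reg.NONE)
    reg.SetInterpolator(sitk.sitkLinear)
    reg.SetOptimizerAsRegularStepGradientDescent(
        learningRate=1.0,
        minStep=1e-4,
        numberOfIterations=config.affine_iterations,
        relaxationFactor=0.6,
        gradientMagnitudeTolerance=1e-6,
    )
    reg.SetOptimizerScalesFromPhysicalShift()
    shrinks = list(config.shrink_factors)
    reg.SetShrinkFactorsPerLevel(shrinks)
    reg.SetSmoothingSigmasPerLevel(list(config.smoothing_sigmas))
    initial = sitk.CenteredTransformInitializer(
        f_img, m_img, sitk.AffineTransform(2), sitk.CenteredTransformInitializerFilter.MOMENTS
    )
    reg.SetInitialTransform(initial, inPlace=False)
    reg.AddCommand(sitk.sitkIterationEvent, lambda: trace.append(reg.GetMetricValue()))
    try:
        affine = reg.Execute(f_img, m_img)
    except RuntimeError as exc:  # ITK failures (no overlap, non-finite metric)
        raise RegistrationError(f"affine stage failed: {exc}") from exc

    candidates: list[tuple[str, DeformationField]] = [
        ("identity", DeformationField.zero(fixed.shape, scale=fixed.scale)),
        ("affine", _composite_to_field(affine, f_img, fixed.scale)),
    ]

    if not config.affine_only:
        m_aff = sitk.Resample(m_img, f_img, affine, sitk.sitkLinear, 0.0)
        disp_total: Optional[sitk.Image] = None
        for level, iters in zip(config.demons_levels, config.demons_iterations):
            if level > 1:
                f_lvl = sitk.Shrink(f_img, [level, level])
                m_lvl = sitk.Shrink(m_aff, [level, level])
            else:
                f_lvl, m_lvl = f_img, m_aff
            demons = sitk.FastSymmetricForcesDemonsRegistrationFilter()
            demons.SetNumberOfIterations(iters)
            demons.SetSmoothDisplacementField(True)
            demons.SetStandardDeviations(config.field_sigma)
            if disp_total is None:
                disp_lvl = demons.Execute(f_lvl, m_lvl)
            else:
                init = sitk.Resample(
                    disp_total, f_lvl, sitk.Transform(), sitk.sitkLinear
                )
                disp_lvl = demons.Execute(f_lvl, m_lvl, init)
            disp_total = disp_lvl
        disp_full = sitk.Resample(disp_total, f_img, sitk.Transform(), sitk.sitkLinear)
        disp_full = sitk.Cast(disp_full, sitk.sitkVectorFloat64)
        composite = sitk.CompositeTransform(2)
        composite.AddTransform(affine)
        composite.AddTransform(sitk.DisplacementFieldTransform(disp_full))
        candidates.append(("affine+demons", _composite_to_field(composite, f_img, fixed.scale)))

    # pick the candidate with the lowest tissue-masked grayscale MSE, among
    # those that do not degrade the tissue-mask Dice (identity always
    # qualifies, so a worse-than-identity field is never returned)
    def _masked_mse(fld: DeformationField) -> float:
        h, w = fg.shape
        rows, cols = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
        warped = map_coordinates(
            mg.astype(np.float64),
            [rows + fld.disp[..., 0], cols + fld.disp[..., 1]],
            order=1,
            mode="constant",
            cval=0.0,
        )
        return float(((warped - fg) ** 2)[fixed_mask].mean())

    best_name, best_field, best_dice = "identity", candidates[0][1], dice_before
    best_mse = _masked_mse(candidates[0][1])
    for name, fld in candidates[1:]:
        if not np.all(np.isfinite(fld.disp)):
            continue
        d = dice_coefficient(fixed_mask, warp_mask(moving_mask, fld))
        if d < dice_before - 1e-9:
            continue
        mse = _masked_mse(fld)
        if mse < best_mse:
            best_name, best_field, best_dice, best_mse = name, fld, d, mse
    flags = []
    if best_name != ("affine" if config.affine_only else "affine+demons"):
        flags.append(f"fell back to {best_name}")
    report = RegistrationReport(
        section_index=moving.section_index,
        dice_before=dice_before,
        dice_after=best_dice,
        method=best_name,
        similarity_metric_trace=trace,
        flags=flags,
    )
    return best_field, report


# ---------------------------------------------------------------------------
# stack registration
# ---------------------------------------------------------------------------


def resolve_reference(n_sections: int, reference) -> int:
    """Map a reference selector to a section index; "centroid" = middle (ties low)."""
    if reference == "centroid":
        return (n_sections - 1) // 2
    idx = int(reference)
    if not 0 <= idx < n_sections:
        raise ValueError(f"reference index {idx} out of range for {n_sections} sections")
    return idx


def register_stack(
    images: Sequence[SlideImage],
    reference="centroid",
    config: Optional[RegistrationConfig] = None,
    target: int = 500,
    landmarks: Optional[dict] = None,
) -> tuple[list[DeformationField], list[RegistrationReport]]:
    """Register every section onto the reference slide.

    Sections are downsampled to the working scale, registered pairwise onto
    the downsampled reference, and each recovered field is upsampled to the
    reference section's full resolution. The reference receives a zero field.
    Optional ``landmarks`` maps section index to (n, 4) full-resolution
    correspondence rows (row_fixed, col_fixed, row_moving, col_moving) used
    to report target registration error.
    """
    if len(images) < 2:
        raise ValueError("need at least two sections")
    config = config or RegistrationConfig()
    ref_idx = resolve_reference(len(images), reference)
    ref_small, _ = downsample(images[ref_idx], target=target)
    fields: list[DeformationField] = []
    reports: list[RegistrationReport] = []
    for i, img in enumerate(images):
        if i == ref_idx:
            fields.append(DeformationField.zero(img.shape, scale=img.scale))
            reports.append(
                RegistrationReport(
                    section_index=i, dice_before=1.0, dice_after=1.0, method="reference"
                )
            )
            continue
        small, factor = downsample(img, target=target)
        try:
            fld, rep = register_pair(small, ref_small, config=config)
        except RegistrationError as exc:
            raise RegistrationError(f"section {i} failed to register: {exc}") from exc
        if rep.dice_after + 1e-9 < rep.dice_before:
            raise RegistrationError(
                f"section {i}: registration degraded tissue overlap "
                f"({rep.dice_before:.3f} -> {rep.dice_after:.3f})"
            )
        full = upsample_field(fld, to_scale=img.scale, out_shape=images[ref_idx].shape)
        if landmarks and i in landmarks:
            lm = np.asarray(landmarks[i], dtype=float)
            pred = lm[:, :2] + _sample_field_at(full.disp, lm[:, :2])
            err = np.linalg.norm(pred - lm[:, 2:4], axis=1)
            rep.tre_px = float(err.mean())
            rep.tre_px_working = float(err.mean() * fld.scale / img.scale)
        rep.section_index = i
        fields.append(full)
        reports.append(rep)
    return fields, reports


def _sample_field_at(disp: np.ndarray, coords_rc: np.ndarray) -> np.ndarray:
    pos = [coords_rc[:, 0], coords_rc[:, 1]]
    dr = map_coordinates(disp[..., 0], pos, order=1, mode="nearest")
    dc = map_coordinates(disp[..., 1], pos, order=1, mode="nearest")
    return np.column_stack([dr, dc])
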