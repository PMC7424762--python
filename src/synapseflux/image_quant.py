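"""Confocal-stack quantification: registration, projection, background, ROI means.

Reproduces the NMJ immunofluorescence measurement chain: optional rigid
integer-shift registration of a stack against its first slice, maximum
intensity projection over Z, harmonisation of background levels across
samples (so all images share background 0), and mean ROI fluorescence per
slice. Coordinates are (slice, row, column), 0-based; masks are 2-D and apply
to every slice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = [
    "ImageStack",
    "RoiMask",
    "RoiQuantResult",
    "register_frames",
    "max_intensity_projection",
    "background_level",
    "harmonize_background",
    "roi_mean_intensity",
]


@dataclass(frozen=True)
class ImageStack:
    """3-D stack of non-negative intensities, axes (slice, row, column)."""

    voxels: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        voxels = np.asarray(self.voxels, dtype=float)
        if voxels.ndim != 3 or voxels.shape[0] < 1:
            raise ParameterError("voxels must be 3-D with >= 1 slice")
        if np.any(voxels < 0):
            raise ParameterError("intensities must be non-negative")
        object.__setattr__(self, "voxels", voxels)

    @property
    def slice_count(self) -> int:
        return int(self.voxels.shape[0])


@dataclass(frozen=True)
class RoiMask:
    """Boolean region-of-interest mask applied to every slice of a stack."""

    mask: np.ndarray
    label: str = "roi"

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2 or not mask.any():
            raise ParameterError("mask must be 2-D with >= 1 true pixel")
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class RoiQuantResult:
    """Mean ROI fluorescence per slice and overall, after background removal."""

    label: str
    per_slice_means: tuple[float, ...]
    overall_mean: float
    background_level: float


def _as_voxels(stack: ImageStack | np.ndarray) -> np.ndarray:
    if isinstance(stack, ImageStack):
        return stack.voxels
    arr = np.asarray(stack, dtype=float)
    if arr.ndim != 3:
        raise ParameterError("stack must be 3-D (slice, row, column)")
    return arr


def _shift_image(img: np.ndarray, dy: int, dx: int) -> np.ndarray:
    """Integer translation with zero fill."""
    out = np.zeros_like(img)
    h, w = img.shape
    ys = slice(max(dy, 0), min(h, h + dy))
    xs = slice(max(dx, 0), min(w, w + dx))
    ys_src = slice(max(-dy, 0), min(h, h - dy))
    xs_src = slice(max(-dx, 0), min(w, w - dx))
    out[ys, xs] = img[ys_src, xs_src]
    return out


def register_frames(
    stack: ImageStack | np.ndarray, max_shift: int
) -> tuple[ImageStack, np.ndarray]:
    """Rigid integer-shift registration of every slice to the first slice.

    For each slice, the displacement (dy, dx) with |dy|, |dx| <= ``max_shift``
    maximising the cross-correlation with the first slice is estimated; the
    slice is translated by its negative (zero-filling vacated pixels). Ties
    prefer the smallest displacement, so identical slices report (0, 0).
    Returns the registered stack and the estimated per-slice displacements
    (first slice is the reference, displacement (0, 0)).
    """
    voxels = _as_voxels(stack)
    if max_shift < 0:
        raise ParameterError("max_shift must be >= 0")
    if max_shift >= min(voxels.shape[1], voxels.shape[2]):
        raise ParameterError("max_shift must be smaller than the image size")
    ref = voxels[0]
    n = voxels.shape[0]
    shifts = np.zeros((n, 2), dtype=int)
    registered = np.empty_like(voxels)
    registered[0] = ref
    # candidate displacements ordered by magnitude so ties keep the smallest
    candidates = sorted(
        (
            (dy, dx)
            for dy in range(-max_shift, max_shift + 1)
            for dx in range(-max_shift, max_shift + 1)
        ),
        key=lambda d: (d[0] * d[0] + d[1] * d[1], d[0], d[1]),
    )
    for s in range(1, n):
        best_score = -np.inf
        best = (0, 0)
        for dy, dx in candidates:
            shifted = _shift_image(voxels[s], -dy, -dx)
            score = float(np.dot(ref.ravel(), shifted.ravel()))
            if score > best_score:
                best_score = score
                best = (dy, dx)
        shifts[s] = best
        registered[s] = _shift_image(voxels[s], -best[0], -best[1])
    out = ImageStack(registered, stack.pixel_size_um if isinstance(stack, ImageStack) else None)
    return out, shifts


def max_intensity_projection(stack: ImageStack | np.ndarray) -> np.ndarray:
    """Pixelwise maximum across slices — the 2-D image shown for each Z-stack."""
    return _as_voxels(stack).max(axis=0)


def background_level(image: np.ndarray, percentile: float = 5.0) -> float:
    """Background estimate: a low percentile of the intensity histogram.

    The nearest-below order statistic is used (no interpolation) so the level
    is an actual pixel value; this makes background subtraction exactly
    idempotent.
    """
    if not 0.0 < percentile < 50.0:
        raise ParameterError("percentile must be in (0, 50)")
    return float(np.percentile(np.asarray(image, dtype=float), percentile, method="lower"))


def harmonize_background(
    images: list[np.ndarray], percentile: float = 5.0
) -> tuple[list[np.ndarray], list[float]]:
    """Equalise background across samples by subtracting each image's background.

    Each image (2-D or a whole 3-D stack) has its ``percentile`` intensity
    subtracted and is clipped at 0, so every output shares background level 0
    — the in-silico analogue of thresholding all samples to a common
    background. Returns (harmonised images, subtracted levels). Idempotent:
    re-harmonising returns the same images with level 0.
    """
    if not images:
        raise ParameterError("need >= 1 image")
    levels = [background_level(img, percentile) for img in images]
    out = [np.clip(np.asarray(img, dtype=float) - lvl, 0.0, None) for img, lvl in zip(images, levels)]
    return out, levels


def roi_mean_intensity(
    stack: ImageStack | np.ndarray,
    mask: RoiMask | np.ndarray,
    background: float = 0.0,
) -> RoiQuantResult:
    """Mean fluorescence of the masked region in each slice, and their average.

    ``background`` is recorded in the result as the level already removed from
    the stack (0 for raw input); it is not subtracted here.
    """
    voxels = _as_voxels(stack)
    roi = mask if isinstance(mask, RoiMask) else RoiMask(np.asarray(mask))
    if roi.mask.shape != voxels.shape[1:]:
        raise ParameterError("mask dimensions must match slice dimensions")
    per_slice = voxels[:, roi.mask].mean(axis=1)
    return RoiQuantResult(
        label=roi.label,
        per_slice_means=tuple(float(v) for v in per_slice),
        overall_mean=float(per_slice.mean()),
        background_level=float(background),
    )
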