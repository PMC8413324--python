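"""Reference segmentation of synthetic stacks and pixelwise validation.

Somata are darker than background in toluidine-blue-like images, so the
reference segmenter is the classical chain: Gaussian smoothing → global
(Otsu) threshold keeping dark voxels → morphological opening → per-section
hole filling.  It is meant for the controlled contrast of synthetic scenes;
masks from any external segmenter are equally accepted downstream as
:class:`~cortex3d.core.MaskStack`.

Validation metrics follow the usual confusion-matrix definitions:
sensitivity TP/(TP+FN), precision TP/(TP+FP) and their harmonic mean F1.
Reported values are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import ImageStack, MaskStack

__all__ = [
    "ConfusionCounts",
    "PixelMetrics",
    "reference_segment",
    "pixel_confusion",
    "classification_metrics",
    "round2",
]


def round2(value: float) -> float:
    """Round half-up to 2 decimals (reporting convention for metrics)."""
    return float(Decimal(repr(float(value))).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel- or object-wise confusion counts."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionCounts":
        """Counts with reference and prediction roles exchanged."""
        return ConfusionCounts(tp=self.tp, fp=self.fn, tn=self.tn,
                               fn=self.fp)


@dataclass(frozen=True)
class PixelMetrics:
    """Sensitivity, precision and F1-score, all in [0, 1]."""

    sensitivity: float
    precision: float
    f1: float

    def rounded(self) -> "PixelMetrics":
        return PixelMetrics(round2(self.sensitivity), round2(self.precision),
                            round2(self.f1))


class UndefinedMetricError(ZeroDivisionError):
    """A metric denominator (TP+FN or TP+FP) is zero."""


def reference_segment(stack: ImageStack, smooth_sigma: float = 0.5,
                      opening_radius: int = 1, min_size: int = 0,
                      min_contrast: float = 20.0) -> MaskStack:
    """Segment dark somata from a grayscale stack.

    Parameters
    ----------
    stack : ImageStack
        Grayscale stack; darker-than-background objects are extracted.
    smooth_sigma : float
        Gaussian smoothing scale in μm (anisotropy handled via the stack
        spacing).
    opening_radius : int
        In-plane radius (pixels) of the binary opening used to remove
        speckle; 0 disables it.
    min_size : int
        Remove connected components smaller than this voxel count.
    min_contrast : float
        Minimum separation (intensity units) between the Otsu foreground
        and background class means; below it the stack is treated as
        object-free (a global threshold on a unimodal histogram would
        otherwise split the noise).
    """
    img = np.asarray(stack.data, dtype=np.float32)
    if img.size == 0:
        raise ValueError("empty stack")
    dx, dy, dz = stack.spacing
    if smooth_sigma > 0:
        img = ndimage.gaussian_filter(
            img, sigma=(smooth_sigma / dz, smooth_sigma / dy,
                        smooth_sigma / dx))
    thresh = threshold_otsu(img)
    mask = img < thresh
    if not mask.any() or \
            img[~mask].mean() - img[mask].mean() < min_contrast:
        return MaskStack(np.zeros_like(mask, dtype=np.uint8), stack.spacing)
    if opening_radius > 0:
        r = int(opening_radius)
        yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
        disk = (yy**2 + xx**2 <= r**2)
        mask = ndimage.binary_opening(mask, structure=disk[None, :, :])
    for k in range(mask.shape[0]):
        mask[k] = ndimage.binary_fill_holes(mask[k])
    if min_size > 0:
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3), dtype=bool))
        counts = np.bincount(lab.ravel())
        small = np.flatnonzero(counts < min_size)
        mask &= ~np.isin(lab, small[small > 0])
    return MaskStack(mask.astype(np.uint8), stack.spacing)


def pixel_confusion(reference: MaskStack | np.ndarray,
                    predicted: MaskStack | np.ndarray) -> ConfusionCounts:
    """Exact per-pixel tally of TP/FP/TN/FN between two binary masks."""
    ref = reference.data if isinstance(reference, MaskStack) else \
        np.asarray(reference)
    pred = predicted.data if isinstance(predicted, MaskStack) else \
        np.asarray(predicted)
    if ref.shape != pred.shape:
        raise ValueError(f"shape mismatch: {ref.shape} vs {pred.shape}")
    ref = ref > 0
    pred = pred > 0
    tp = int(np.count_nonzero(ref & pred))
    fp = int(np.count_nonzero(~ref & pred))
    fn = int(np.count_nonzero(ref & ~pred))
    tn = int(ref.size - tp - fp - fn)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def classification_metrics(c: ConfusionCounts) -> PixelMetrics:
    """Sensitivity, precision and F1 from confusion counts.

    Raises :class:`UndefinedMetricError` when a denominator is zero rather
    than silently reporting 0.
    """
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: TP + FN == 0")
    if c.tp + c.fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP == 0")
    sens = c.tp / (c.tp + c.fn)
    prec = c.tp / (c.tp + c.fp)
    f1 = 2.0 * sens * prec / (sens + prec) if sens + prec > 0 else 0.0
    return PixelMetrics(sensitivity=sens, precision=prec, f1=f1)
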