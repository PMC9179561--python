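"""Densitometric percent-positive-area inside an ROI.

The staining-intensity readout: convert the grayscale micrograph to a
two-class binary image at an intensity cutoff, then report the percentage
of ROI pixels classified positive. DAB-positive signal is *dark* after
grayscale conversion, so the default polarity is ``positive-below``.

The cutoff can be fixed by the user or computed by Otsu's between-class
variance criterion; in either case the comparison is strict
(``<`` / ``>``), so pixels exactly at the cutoff go to background —
stated once here for bit-exact reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

from .errors import DegenerateHistogramError, ValidationError
from .io_roi import BinaryMask, GrayImage

POLARITIES = ("positive-below", "positive-above")


@dataclass
class ThresholdSpec:
    """How to binarize: ``fixed`` (explicit ``value``) or ``otsu``.

    ``polarity`` selects which side of the cutoff is foreground;
    ``positive-below`` marks pixels strictly darker than the cutoff.
    """

    mode: str = "otsu"
    value: float | None = None
    polarity: str = "positive-below"

    def __post_init__(self) -> None:
        if self.mode not in ("fixed", "otsu"):
            raise ValidationError(f"mode must be 'fixed' or 'otsu', got {self.mode!r}")
        if self.mode == "fixed":
            if self.value is None:
                raise ValidationError("fixed mode requires a cutoff value")
            if not (0 <= self.value <= 255):
                raise ValidationError(f"cutoff must lie in [0, 255], got {self.value}")
        if self.polarity not in POLARITIES:
            raise ValidationError(f"polarity must be one of {POLARITIES}")


def otsu_cutoff(values: np.ndarray) -> float:
    """Otsu's cutoff (between-class variance maximization) on raw intensities.

    The optimum is returned shifted half an intensity level above Otsu's
    bin so that the strict comparators reproduce the canonical split
    (lower class = values <= optimum) on integer-valued 8-bit data.
    """
    values = np.asarray(values).ravel()
    if values.size == 0:
        raise ValidationError("cannot threshold an empty pixel set")
    if np.all(values == values[0]):
        raise DegenerateHistogramError("constant-intensity region: Otsu is undefined")
    return float(threshold_otsu(values, nbins=256)) + 0.5


def binarize(
    img: GrayImage,
    spec: ThresholdSpec,
    roi_mask: BinaryMask | None = None,
) -> tuple[BinaryMask, float]:
    """Binarize an image; returns the mask and the cutoff actually used.

    In ``otsu`` mode the cutoff is computed from the histogram of ROI
    pixels only (when ``roi_mask`` is given), so staining outside the
    evaluated region cannot bias it; the resulting rule is then applied
    to the whole frame.
    """
    if spec.mode == "otsu":
        if roi_mask is not None:
            if roi_mask.shape != img.shape:
                raise ValidationError("roi_mask shape does not match image")
            sample = img.pixels[roi_mask.pixels]
            if sample.size == 0:
                raise ValidationError("empty ROI: nothing to threshold")
        else:
            sample = img.pixels
        cutoff = otsu_cutoff(sample)
    else:
        cutoff = float(spec.value)
    if spec.polarity == "positive-below":
        mask = img.pixels < cutoff
    else:
        mask = img.pixels > cutoff
    return BinaryMask(mask), cutoff


def percent_area(mask: BinaryMask, roi_mask: BinaryMask) -> float:
    """Percentage of ROI pixels that are positive: 100 * |mask & roi| / |roi|."""
    if mask.shape != roi_mask.shape:
        raise ValidationError("mask and roi_mask shapes differ")
    n_roi = roi_mask.count()
    if n_roi == 0:
        raise ValidationError("empty ROI mask")
    n_pos = int(np.logical_and(mask.pixels, roi_mask.pixels).sum())
    return 100.0 * n_pos / n_roi
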