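"""Cell detection by connected-component labeling and density in cells/mm^2.

An automated surrogate for manual counting: components of the thresholded
foreground are treated as cells, size-filtered in physical units, and
counted when their centroid falls inside the ROI. The centroid rule means
a cell straddling an ROI border is attributed to exactly one region, so
adjacent ROIs never double-count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.measure import label, regionprops

from .errors import ValidationError
from .io_roi import BinaryMask


@dataclass
class DetectionParams:
    """Component filters.

    ``min_area_um2`` rejects stain specks (default 20 um^2, well below a
    microglial soma); ``max_area_um2`` is unbounded by default.
    ``connectivity`` 8 keeps thin diagonal processes attached to somas.
    """

    min_area_um2: float = 20.0
    max_area_um2: float | None = None
    connectivity: int = 8

    def __post_init__(self) -> None:
        if not (self.min_area_um2 > 0):
            raise ValidationError("min_area_um2 must be > 0")
        if self.max_area_um2 is not None and not (self.max_area_um2 > self.min_area_um2):
            raise ValidationError("max_area_um2 must exceed min_area_um2")
        if self.connectivity not in (4, 8):
            raise ValidationError("connectivity must be 4 or 8")


@dataclass
class CellComponent:
    """One detected cell: its pixel set and centroid.

    ``pixels`` is an (N, 2) integer array of (row, col) indices;
    ``centroid`` is (x, y) in pixel-center coordinates (col + 0.5 averaged,
    row + 0.5 averaged).
    """

    pixels: np.ndarray
    centroid: tuple[float, float]

    @property
    def area_px(self) -> int:
        return len(self.pixels)

    def touches_border(self, shape: tuple[int, int]) -> bool:
        r, c = self.pixels[:, 0], self.pixels[:, 1]
        return bool(r.min() == 0 or c.min() == 0 or r.max() == shape[0] - 1 or c.max() == shape[1] - 1)


def detect_cells(
    mask: BinaryMask,
    roi_mask: BinaryMask,
    params: DetectionParams,
    pixel_size_um: float,
) -> list[CellComponent]:
    """Label the foreground and keep size-passing components centered in the ROI.

    A component is kept iff its pixel area in um^2 lies in
    ``[min_area_um2, max_area_um2]`` and the pixel containing its centroid
    is inside the ROI mask. An empty result is valid.
    """
    if mask.shape != roi_mask.shape:
        raise ValidationError("mask and roi_mask shapes differ")
    if not (pixel_size_um > 0):
        raise ValidationError("pixel_size_um must be > 0")
    skimage_conn = 1 if params.connectivity == 4 else 2
    labels = label(mask.pixels, connectivity=skimage_conn)
    px_area = pixel_size_um**2
    out: list[CellComponent] = []
    for rp in regionprops(labels):
        area_um2 = rp.area * px_area
        if area_um2 < params.min_area_um2:
            continue
        if params.max_area_um2 is not None and area_um2 > params.max_area_um2:
            continue
        crow, ccol = rp.centroid  # mean of pixel indices
        cx, cy = ccol + 0.5, crow + 0.5  # pixel-center coordinates
        # pixel containing the centroid
        irow = min(int(np.floor(cy)), mask.shape[0] - 1)
        icol = min(int(np.floor(cx)), mask.shape[1] - 1)
        if not roi_mask.pixels[irow, icol]:
            continue
        out.append(CellComponent(pixels=rp.coords.copy(), centroid=(cx, cy)))
    return out


def cells_per_mm2(count: int, roi_area_mm2: float) -> float:
    """Cell density: count / ROI area."""
    if not (roi_area_mm2 > 0):
        raise ValidationError(f"roi_area_mm2 must be > 0, got {roi_area_mm2}")
    if count < 0:
        raise ValidationError("count must be >= 0")
    return count / roi_area_mm2
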