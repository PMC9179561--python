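"""Raster and ROI input/output.

Conventions used throughout the package:

* pixel ``(0, 0)`` sits at the image top-left, ``x`` runs rightward along
  columns, ``y`` downward along rows;
* the *center* of pixel ``(row i, col j)`` is at ``(x, y) = (j + 0.5, i + 0.5)``;
* intensities follow the 8-bit convention, values in ``[0, 255]``;
* physical scale is carried as ``pixel_size_um``, the edge length of one
  pixel in micrometres.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
import tifffile
from PIL import Image
from shapely.geometry import Polygon

from .errors import ValidationError

#: ITU-R 601 luma weights, the standard weighted-grayscale option.
LUMINANCE_WEIGHTS = (0.299, 0.587, 0.114)

ROI_LABELS = ("corpus_callosum", "cortex", "hippocampus", "custom")


@dataclass
class GrayImage:
    """A 2-D grayscale micrograph with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities in ``[0, 255]``.
    pixel_size_um : float
        Edge length of one pixel in micrometres; must be positive.
    name : str
        Free-text identifier (file stem, animal id, ...).
    """

    pixels: np.ndarray
    pixel_size_um: float
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValidationError("GrayImage requires a non-empty 2-D array")
        if float(self.pixels.min()) < 0 or float(self.pixels.max()) > 255:
            raise ValidationError("intensities must lie in [0, 255]")
        if not (self.pixel_size_um > 0):
            raise ValidationError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class RoiPolygon:
    """Closed region-of-interest polygon in pixel coordinates.

    Vertices are an ordered list of ``(x, y)`` pairs, implicitly closed.
    The polygon must be simple (non-self-intersecting) and enclose a
    non-zero area.
    """

    vertices: np.ndarray
    label: str = "custom"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ValidationError("RoiPolygon requires >= 3 (x, y) vertices")
        if self.label not in ROI_LABELS:
            raise ValidationError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        poly = Polygon(self.vertices)
        if not poly.is_simple or not poly.is_valid:
            raise ValidationError("RoiPolygon must be simple (non-self-intersecting)")
        if poly.area == 0:
            raise ValidationError("RoiPolygon encloses zero area")

    def as_shapely(self) -> Polygon:
        return Polygon(self.vertices)


@dataclass
class BinaryMask:
    """Boolean foreground mask sharing the shape of its source image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.dtype != bool:
            raise ValidationError("BinaryMask pixels must be boolean")
        if self.pixels.ndim != 2:
            raise ValidationError("BinaryMask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def count(self) -> int:
        return int(self.pixels.sum())


def rgb_to_gray(rgb: np.ndarray, method: str = "luminance") -> np.ndarray:
    """Collapse a 3-channel raster to grayscale.

    ``luminance`` uses the 0.299/0.587/0.114 weighting; ``mean`` averages
    the channels (the ImageJ unweighted default). Output is rounded and
    clipped to ``[0, 255]``.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValidationError(f"expected a (H, W, 3) array, got shape {rgb.shape}")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValidationError("RGB values must lie in [0, 255]")
    if method == "luminance":
        w = np.asarray(LUMINANCE_WEIGHTS)
        gray = rgb @ w
    elif method == "mean":
        gray = rgb.mean(axis=2)
    else:
        raise ValidationError(f"unknown grayscale method {method!r}")
    return np.clip(np.round(gray), 0, 255).astype(np.uint8)


def read_image(path: str | Path, pixel_size_um: float, *, grayscale: str = "luminance") -> GrayImage:
    """Read an 8/16-bit, 1- or 3-channel TIFF or PNG into a :class:`GrayImage`.

    16-bit inputs are rescaled linearly by the dtype maximum (not the image
    maximum, so constant-illumination series stay comparable); 3-channel
    inputs go through :func:`rgb_to_gray`. The explicit ``pixel_size_um``
    always wins over any metadata stored in the file.
    """
    path = Path(path)
    if not (pixel_size_um > 0):
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if present
        arr = arr[:, :, :3]
    if arr.dtype == np.uint16:
        arr = np.round(arr.astype(float) * (255.0 / 65535.0)).astype(np.uint8)
    elif arr.dtype != np.uint8:
        raise IOError(f"unsupported dtype {arr.dtype} in {path}")
    if arr.ndim == 3:
        arr = rgb_to_gray(arr, method=grayscale)
    elif arr.ndim != 2:
        raise IOError(f"unsupported image shape {arr.shape} in {path}")
    return GrayImage(pixels=arr, pixel_size_um=pixel_size_um, name=path.stem)


def write_image(img: GrayImage, path: str | Path) -> None:
    """Write a GrayImage as an 8-bit single-channel PNG or TIFF."""
    path = Path(path)
    arr = np.asarray(np.round(img.pixels), dtype=np.uint8)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        Image.fromarray(arr, mode="L").save(path)


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Persist a binary mask as an 8-bit PNG with values {0, 255}."""
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(Path(path))


def rasterize_roi(roi: RoiPolygon, shape: tuple[int, int]) -> BinaryMask:
    """Rasterize an ROI polygon with the pixel-center-in-polygon rule.

    A pixel is foreground iff its center ``(j + 0.5, i + 0.5)`` lies inside
    the polygon; centers exactly on an edge are included.
    """
    h, w = shape
    poly = roi.as_shapely()
    ys, xs = np.mgrid[0:h, 0:w]
    cx = xs.ravel() + 0.5
    cy = ys.ravel() + 0.5
    # intersects == inside-or-on-boundary for point queries
    inside = shapely.intersects_xy(poly, cx, cy)
    return BinaryMask(inside.reshape(h, w))


def roi_area_mm2(roi: RoiPolygon, pixel_size_um: float) -> float:
    """Shoelace polygon area, converted to mm^2 (1 mm^2 = 1e6 um^2)."""
    if not (pixel_size_um > 0):
        raise ValidationError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    area_px2 = roi.as_shapely().area
    return area_px2 * pixel_size_um**2 * 1e-6


def read_roi(path: str | Path) -> tuple[RoiPolygon, float | None]:
    """Read an ROI JSON file: {"label", "pixel_size_um", "vertices"}.

    Returns the polygon and the pixel size recorded in the file (or None).
    """
    with open(path) as fh:
        obj = json.load(fh)
    roi = RoiPolygon(vertices=np.asarray(obj["vertices"], dtype=float), label=obj.get("label", "custom"))
    ps = obj.get("pixel_size_um")
    return roi, (float(ps) if ps is not None else None)


def read_roi_csv(path: str | Path, label: str = "custom") -> RoiPolygon:
    """Read a 2-column CSV of (x, y) vertices into an RoiPolygon."""
    verts = np.loadtxt(path, delimiter=",", ndmin=2)
    return RoiPolygon(vertices=verts, label=label)


def write_roi(roi: RoiPolygon, pixel_size_um: float, path: str | Path) -> None:
    obj = {
        "label": roi.label,
        "pixel_size_um": float(pixel_size_um),
        "vertices": [[float(x), float(y)] for x, y in roi.vertices],
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)
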