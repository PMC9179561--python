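"""Per-cell morphometry: cell area, convex-hull projection area, and the
ramification index.

The ramification index of a cell is

    RI = A_c / A_p

where ``A_c`` is the area of the stained silhouette itself and ``A_p`` is
the area of its convex hull — the territory spanned by the cell's most
prominent projections. A ramified (resting) microglia cell has long thin
processes, a large hull and therefore a small RI; an amoeboid (activated)
cell is nearly convex and its RI approaches 1.

Geometric convention: a foreground pixel ``(row i, col j)`` occupies the
closed unit square ``[j, j+1] x [i, i+1]`` in (x, y) coordinates. ``A_c``
counts pixel squares; ``A_p`` is the convex hull of all four corners of
every foreground square. Because that hull contains the union of the
squares, ``A_p >= A_c`` holds for every mask and ``RI <= 1`` is a provable
bound rather than an approximation (a hull over pixel *centers* can
violate it for thin cells). One-pixel-wide straight cells are not a
degenerate case: the hull of their squares is still a rectangle.

Cells are sampled for analysis by superimposing a rectangular grid with
uniform line spacing in X and Y and keeping every cell that crosses a
grid line — the unbiased systematic selection used when scoring cells
manually at the microscope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull

from .cell_detection import CellComponent, DetectionParams, detect_cells
from .densitometry import ThresholdSpec, binarize
from .errors import ValidationError
from .io_roi import BinaryMask, GrayImage, RoiPolygon, rasterize_roi


@dataclass
class CellMorphometry:
    """Per-cell record: areas in um^2 and the dimensionless RI in (0, 1]."""

    cell_id: int
    a_c_um2: float
    a_p_um2: float
    ri: float
    centroid: tuple[float, float] = (float("nan"), float("nan"))


@dataclass
class GridSpec:
    """Sampling grid: line spacing in pixels and the grid phase.

    Offsets ``None`` means "draw a random phase in [0, spacing) from the
    rng supplied at sampling time" — the default, mirroring random grid
    placement per section.
    """

    spacing_px: float
    offset_x: float | None = None
    offset_y: float | None = None

    def __post_init__(self) -> None:
        if not (self.spacing_px > 0):
            raise ValidationError("grid spacing must be > 0")
        for off in (self.offset_x, self.offset_y):
            if off is not None and not (0 <= off < self.spacing_px):
                raise ValidationError("grid offsets must lie in [0, spacing)")


def cell_area(pixels: np.ndarray, pixel_size_um: float) -> float:
    """A_c = number of foreground pixels x pixel area."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValidationError("empty pixel set has no area")
    if not (pixel_size_um > 0):
        raise ValidationError("pixel_size_um must be > 0")
    return len(pixels) * pixel_size_um**2


def _hull_area_px2(pixels: np.ndarray) -> float:
    """Convex-hull area (px^2) of the corner points of every pixel square."""
    rows = pixels[:, 0]
    cols = pixels[:, 1]
    # corners of square [j, j+1] x [i, i+1]
    xs = np.concatenate([cols, cols + 1, cols, cols + 1]).astype(float)
    ys = np.concatenate([rows, rows, rows + 1, rows + 1]).astype(float)
    pts = np.unique(np.column_stack([xs, ys]), axis=0)
    hull = ConvexHull(pts)
    return float(hull.volume)  # "volume" is area in 2-D


def projection_area(pixels: np.ndarray, pixel_size_um: float) -> float:
    """A_p = convex-hull area of the union of pixel squares, in um^2."""
    pixels = np.asarray(pixels)
    if pixels.size == 0:
        raise ValidationError("empty pixel set has no projection area")
    if not (pixel_size_um > 0):
        raise ValidationError("pixel_size_um must be > 0")
    return _hull_area_px2(pixels) * pixel_size_um**2


def ramification_index(a_c: float, a_p: float) -> float:
    """RI = A_c / A_p; 1 for convex silhouettes, smaller when ramified."""
    if not (a_c > 0):
        raise ValidationError("A_c must be > 0")
    if a_p < a_c:
        raise ValidationError(
            f"A_p ({a_p}) < A_c ({a_c}): inconsistent hull — this signals a hull bug"
        )
    return a_c / a_p


def measure_cell(pixels: np.ndarray, pixel_size_um: float, cell_id: int = 0) -> CellMorphometry:
    """Compute A_c, A_p and RI for one cell pixel set."""
    a_c = cell_area(pixels, pixel_size_um)
    a_p = projection_area(pixels, pixel_size_um)
    pixels = np.asarray(pixels)
    cx = float(pixels[:, 1].mean()) + 0.5
    cy = float(pixels[:, 0].mean()) + 0.5
    return CellMorphometry(cell_id=cell_id, a_c_um2=a_c, a_p_um2=a_p,
                           ri=ramification_index(a_c, a_p), centroid=(cx, cy))


def grid_sample_cells(
    cells: list[CellComponent],
    grid: GridSpec,
    image_shape: tuple[int, int],
    rng: np.random.Generator | None = None,
) -> list[CellComponent]:
    """Select the cells whose pixel set crosses any grid line.

    Vertical lines sit at ``x = offset_x + k * spacing`` and horizontal
    lines at ``y = offset_y + k * spacing`` for every integer ``k`` with
    the line inside the image. The pixel square ``[j, j+1) x [i, i+1)``
    intersects line ``x = c`` iff ``j <= c < j+1``, i.e. ``floor(c) == j``.
    """
    h, w = image_shape
    ox, oy = grid.offset_x, grid.offset_y
    if ox is None or oy is None:
        if rng is None:
            raise ValidationError("random grid phase requested but no rng supplied")
        if ox is None:
            ox = float(rng.uniform(0, grid.spacing_px))
        if oy is None:
            oy = float(rng.uniform(0, grid.spacing_px))
    s = grid.spacing_px
    line_cols = {int(np.floor(ox + k * s)) for k in range(int(np.ceil((w - ox) / s))) if 0 <= ox + k * s < w}
    line_rows = {int(np.floor(oy + k * s)) for k in range(int(np.ceil((h - oy) / s))) if 0 <= oy + k * s < h}
    selected = []
    for cell in cells:
        rows = cell.pixels[:, 0]
        cols = cell.pixels[:, 1]
        if np.isin(cols, list(line_cols)).any() or np.isin(rows, list(line_rows)).any():
            selected.append(cell)
    return selected


@dataclass
class MorphometryResult:
    """Morphometry of the grid-sampled cells of one image."""

    records: list[CellMorphometry]
    n_detected: int
    n_border_excluded: int
    grid_offsets: tuple[float, float] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.records)

    @property
    def mean_ri(self) -> float:
        if not self.records:
            return float("nan")
        return float(np.mean([r.ri for r in self.records]))

    @property
    def sd_ri(self) -> float:
        if len(self.records) < 2:
            return float("nan")
        return float(np.std([r.ri for r in self.records], ddof=1))


def analyze_cells(
    image: GrayImage | BinaryMask,
    roi: RoiPolygon | BinaryMask,
    detection: DetectionParams,
    grid: GridSpec,
    pixel_size_um: float,
    rng: np.random.Generator | None = None,
    threshold: ThresholdSpec | None = None,
) -> MorphometryResult:
    """Detect, grid-sample, and measure cells in one micrograph.

    GrayImage input is binarized first (default: ROI-restricted Otsu,
    positive-below). Cells touching the image border are excluded from
    morphometry because truncated silhouettes bias RI upward. An empty
    selection is a valid (empty) result, not an error.
    """
    if isinstance(roi, RoiPolygon):
        shape = image.shape
        roi_mask = rasterize_roi(roi, shape)
    else:
        roi_mask = roi
    if isinstance(image, GrayImage):
        mask, _ = binarize(image, threshold or ThresholdSpec(), roi_mask=roi_mask)
    else:
        mask = image
    cells = detect_cells(mask, roi_mask, detection, pixel_size_um)
    n_detected = len(cells)
    interior = [c for c in cells if not c.touches_border(mask.shape)]
    n_border = n_detected - len(interior)
    # resolve random grid phase once so it can be reported
    g = grid
    if g.offset_x is None or g.offset_y is None:
        if rng is None:
            raise ValidationError("random grid phase requested but no rng supplied")
        g = GridSpec(
            spacing_px=grid.spacing_px,
            offset_x=float(rng.uniform(0, grid.spacing_px)) if grid.offset_x is None else grid.offset_x,
            offset_y=float(rng.uniform(0, grid.spacing_px)) if grid.offset_y is None else grid.offset_y,
        )
    selected = grid_sample_cells(interior, g, mask.shape)
    records = [measure_cell(c.pixels, pixel_size_um, cell_id=i) for i, c in enumerate(selected)]
    return MorphometryResult(
        records=records,
        n_detected=n_detected,
        n_border_excluded=n_border,
        grid_offsets=(g.offset_x, g.offset_y),
    )


def default_grid(image_width: int) -> GridSpec:
    """Default sampling grid: spacing = image width / 8, random phase."""
    return GridSpec(spacing_px=image_width / 8.0)
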