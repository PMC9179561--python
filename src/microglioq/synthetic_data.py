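"""Synthetic DAB-like microglia fields with exact ground truth.

No raw micrographs accompany the study conditions this package targets, so
validation rests on simulation: fields of model microglia are rendered as
dark objects on a bright background (DAB signal is brown on a pale
counterstain; after grayscale conversion positive pixels are darker), with
known cell count, positive-pixel fraction and per-cell ramification index.

A model cell is a soma disk plus ramified processes drawn as discrete
random walks. A single ``retraction`` knob in [0, 1] morphs the shape
family from fully ramified (long thin processes, low RI) to fully
amoeboid (hypertrophic soma, retracted processes, RI near 1):

* soma radius grows as ``soma_radius_um * (1 + retraction)``;
* the process count shrinks as ``round(n_processes * (1 - 0.99 * retraction))``;
* the process length shrinks as ``process_length_um * (1 - retraction)``.

Because the printed group statistics are mean RIs, not retractions,
:func:`calibrate_retraction` inverts the (stochastic, monotone) map from
retraction to mean RI by bisection with common random numbers.

Cohorts mirror the 4-group design (control plus three intoxication
timepoints, n animals per group): per-animal targets are drawn Normal
around the group target, one scene is rendered per animal, and everything
is reproducible bit-for-bit from one root seed via a documented
``SeedSequence([seed, group_index, animal_index])`` splitting scheme, so
generation order cannot change the output.

Deliberate simplification: cells are placed with a minimum centroid
separation and mask-level overlap rejection, so connected-component
counting has unambiguous ground truth. Confluent microgliosis plaques,
uneven illumination and section artifacts are not emulated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.draw import disk as draw_disk
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import dilation as _dilation
from skimage.morphology import disk as disk_footprint

from shapely.geometry import Point

from .errors import CalibrationError, PlacementError, ValidationError
from .io_roi import BinaryMask, GrayImage, RoiPolygon, rasterize_roi, roi_area_mm2, write_image, write_roi
from .morphometry import measure_cell


@dataclass
class CellShapeParams:
    """Shape family of one model microglia.

    Defaults describe a resting cell: a 4 um-radius soma with six thin
    (1.5 um) processes of 25 um length, curvature noise ``wiggle`` (SD of
    the per-step heading change, radians per 1-um step).
    """

    soma_radius_um: float = 4.0
    n_processes: int = 6
    process_length_um: float = 25.0
    process_thickness_um: float = 1.5
    retraction: float = 0.0
    wiggle: float = 0.25

    def __post_init__(self) -> None:
        if not (self.soma_radius_um > 0):
            raise ValidationError("soma_radius_um must be > 0")
        if self.n_processes < 0:
            raise ValidationError("n_processes must be >= 0")
        if self.n_processes > 0 and not (self.process_thickness_um > 0):
            raise ValidationError("process_thickness_um must be > 0 when processes exist")
        if not (0 <= self.retraction <= 1):
            raise ValidationError("retraction must lie in [0, 1]")
        if self.wiggle < 0:
            raise ValidationError("wiggle must be >= 0")

    def max_extent_um(self) -> float:
        """Upper bound on the reach of the mask from the soma center."""
        return self.soma_radius_um * 2 + self.process_length_um + self.process_thickness_um + 2


@dataclass
class StainingModel:
    """Gaussian two-level intensity model: dark foreground, bright background."""

    mu_fg: float = 70.0
    mu_bg: float = 210.0
    sigma: float = 12.0

    def __post_init__(self) -> None:
        if not (self.mu_fg < self.mu_bg):
            raise ValidationError("mu_fg must be darker (smaller) than mu_bg")
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")


@dataclass
class SceneTruth:
    """Exact ground truth of one rendered field."""

    cell_centroids: list[tuple[float, float]]
    cell_masks: list[np.ndarray]  # (N, 2) arrays of (row, col)
    true_count: int
    true_density_cells_per_mm2: float
    true_positive_fraction_pct: float
    true_ri_per_cell: list[float]

    @property
    def true_mean_ri(self) -> float:
        if not self.true_ri_per_cell:
            return float("nan")
        return float(np.mean(self.true_ri_per_cell))


def _as_rng(rng_state: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _line_pixels_4conn(r0: int, c0: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham line with diagonal steps bridged to keep 4-connectivity."""
    rr, cc = draw_line(r0, c0, r1, c1)
    out_r, out_c = [rr[0]], [cc[0]]
    for i in range(1, len(rr)):
        if rr[i] != rr[i - 1] and cc[i] != cc[i - 1]:  # diagonal move
            out_r.append(rr[i - 1])
            out_c.append(cc[i])
        out_r.append(rr[i])
        out_c.append(cc[i])
    return np.asarray(out_r), np.asarray(out_c)


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    """floor(x) + Bernoulli(frac(x)): integer with expectation exactly x."""
    lo = int(np.floor(x))
    return lo + int(rng.random() < (x - lo))


def make_cell_mask(
    params: CellShapeParams,
    pixel_size_um: float,
    rng_state: np.random.Generator | int | None,
) -> np.ndarray:
    """Rasterize one model cell; returns (N, 2) (row, col) offsets from the soma center.

    The foreground is 4-connected: a soma disk of radius
    ``soma_radius_um * (1 + retraction)`` plus processes attached to the
    soma boundary at quasi-uniform angles, each a random walk of unit-um
    steps with heading perturbed by ``Normal(0, wiggle)`` per step and
    thickness applied by dilation with a disk of radius
    ``process_thickness_um / 2``.
    """
    rng = _as_rng(rng_state)
    ps = pixel_size_um
    if not (ps > 0):
        raise ValidationError("pixel_size_um must be > 0")
    soma_r_px = params.soma_radius_um * (1 + params.retraction) / ps
    if 2 * soma_r_px < 3:
        raise ValidationError(
            f"soma spans fewer than 3 px ({2 * soma_r_px:.2f}); use a finer pixel size"
        )
    # stochastic rounding keeps the population mean RI continuous in
    # retraction (a hard round makes it jump where the integer count flips,
    # leaving unreachable gaps for calibration)
    n_eff = _stochastic_round(params.n_processes * (1 - 0.99 * params.retraction), rng)
    eff_len_um = params.process_length_um * (1 - params.retraction)
    n_steps = _stochastic_round(eff_len_um, rng)
    r_th = int(round(params.process_thickness_um / (2 * ps)))

    half = int(np.ceil(soma_r_px + eff_len_um / ps + r_th + 3))
    size = 2 * half + 1
    soma = np.zeros((size, size), dtype=bool)
    rr, cc = draw_disk((half, half), soma_r_px, shape=soma.shape)
    soma[rr, cc] = True

    paths = np.zeros_like(soma)
    phi0 = rng.uniform(0, 2 * np.pi)
    step_px = 1.0 / ps
    for k in range(n_eff):
        theta = phi0 + 2 * np.pi * k / max(n_eff, 1) + rng.uniform(-0.5, 0.5) * np.pi / max(n_eff, 1)
        start_r = max(soma_r_px - 1.2, 0.0)
        pos = np.array([half + start_r * np.sin(theta), half + start_r * np.cos(theta)])
        prev = np.round(pos).astype(int)
        paths[prev[0], prev[1]] = True
        for _ in range(n_steps):
            theta += rng.normal(0.0, params.wiggle)
            pos = pos + step_px * np.array([np.sin(theta), np.cos(theta)])
            cur = np.round(pos).astype(int)
            lr, lc = _line_pixels_4conn(prev[0], prev[1], cur[0], cur[1])
            paths[lr, lc] = True
            prev = cur
    if r_th > 0 and paths.any():
        paths = _dilation(paths, disk_footprint(r_th))
    mask = soma | paths
    if not mask.any():
        raise ValidationError("cell parameters produced an empty mask")
    # connectivity is guaranteed by construction (processes start inside the
    # soma and walks are 4-bridged); verify defensively
    if cc_label(mask, connectivity=1).max() > 1:  # pragma: no cover
        mask = _dilation(mask, disk_footprint(1))
    pix = np.argwhere(mask)
    pix[:, 0] -= half
    pix[:, 1] -= half
    return pix


def oracle_ri(pixels: np.ndarray) -> float:
    """Ground-truth RI of a pixel set (same hull convention as morphometry)."""
    pix = np.asarray(pixels)
    shifted = pix - pix.min(axis=0)  # hull area is translation invariant
    return measure_cell(shifted, pixel_size_um=1.0).ri


def _mean_ri_at(
    retraction: float,
    base: CellShapeParams,
    pixel_size_um: float,
    child_seeds: list[int],
) -> float:
    params = dataclasses.replace(base, retraction=retraction)
    ris = [oracle_ri(make_cell_mask(params, pixel_size_um, s)) for s in child_seeds]
    return float(np.mean(ris))


def calibrate_retraction(
    target_mean_ri: float,
    base: CellShapeParams,
    pixel_size_um: float,
    n_cells: int = 40,
    rng_state: np.random.Generator | int | None = None,
    tol: float = 0.02,
    max_iter: int = 30,
    out_of_range: str = "raise",
) -> float:
    """Find the retraction whose mean cell RI matches ``target_mean_ri``.

    Bisection on retraction; each evaluation measures the mean RI of
    ``n_cells`` sampled cells drawn with *common random numbers* (the same
    per-cell seeds at every retraction), which makes the objective a
    deterministic, monotone function and lets bisection converge. When the
    target lies outside the range probed at retraction 0 and 1, either
    raises :class:`CalibrationError` naming the achievable interval
    (``out_of_range='raise'``, the default) or clips to the nearest
    endpoint (``'clip'``, used by the cohort generator so per-animal
    Normal draws are truncated to the family's valid range).
    """
    if not (0 < target_mean_ri <= 1):
        raise ValidationError("target_mean_ri must lie in (0, 1]")
    if out_of_range not in ("raise", "clip"):
        raise ValidationError("out_of_range must be 'raise' or 'clip'")
    rng = _as_rng(rng_state)
    root = int(rng.integers(2**31))
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in np.random.SeedSequence(root).spawn(n_cells)]
    f = lambda r: _mean_ri_at(r, base, pixel_size_um, child_seeds)
    lo, hi = 0.0, 1.0
    f_lo, f_hi = f(lo), f(hi)
    if target_mean_ri < f_lo - tol or target_mean_ri > f_hi + tol:
        if out_of_range == "clip":
            return 0.0 if target_mean_ri < f_lo else 1.0
        raise CalibrationError(
            f"target mean RI {target_mean_ri:.3f} outside the achievable interval "
            f"[{f_lo:.3f}, {f_hi:.3f}] of this shape family"
        )
    if abs(f_lo - target_mean_ri) <= tol and target_mean_ri <= f_lo:
        return lo
    if abs(f_hi - target_mean_ri) <= tol and target_mean_ri >= f_hi:
        return hi
    mid = 0.5
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if abs(fm - target_mean_ri) <= tol or hi - lo < 1e-4:
            return mid
        if fm < target_mean_ri:
            lo = mid
        else:
            hi = mid
    return mid


def place_cells(
    n: int,
    roi: RoiPolygon,
    min_separation_px: float,
    rng_state: np.random.Generator | int | None,
    max_attempts_per_cell: int = 400,
) -> list[tuple[float, float]]:
    """Poisson-disk (dart throwing) placement of cell centroids inside the ROI."""
    rng = _as_rng(rng_state)
    poly = roi.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    pts: list[tuple[float, float]] = []
    attempts = 0
    budget = max_attempts_per_cell * max(n, 1)
    while len(pts) < n:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(pts)}/{n} cells after {attempts} attempts; "
                "density infeasible at this minimum separation"
            )
        attempts += 1
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not poly.contains(Point(x, y)):
            continue
        ok = all((x - px) ** 2 + (y - py) ** 2 >= min_separation_px**2 for px, py in pts)
        if ok:
            pts.append((x, y))
    return pts


def _finalize_scene(
    centroids: list[tuple[float, float]],
    masks: list[np.ndarray],
    image_shape: tuple[int, int],
    pixel_size_um: float,
    roi: RoiPolygon,
    stain: StainingModel,
    rng: np.random.Generator,
    name: str,
) -> tuple[GrayImage, SceneTruth]:
    """Render intensities for placed masks and assemble the exact truth."""
    h, w = image_shape
    union = np.zeros((h, w), dtype=bool)
    for m in masks:
        union[m[:, 0], m[:, 1]] = True
    img = rng.normal(stain.mu_bg, stain.sigma, size=(h, w))
    img[union] = rng.normal(stain.mu_fg, stain.sigma, size=int(union.sum()))
    pixels = np.clip(np.round(img), 0, 255).astype(np.uint8)
    gray = GrayImage(pixels=pixels, pixel_size_um=pixel_size_um, name=name)

    roi_mask = rasterize_roi(roi, (h, w))
    area_mm2 = roi_area_mm2(roi, pixel_size_um)
    n_roi = roi_mask.count()
    pos_pct = 100.0 * np.logical_and(union, roi_mask.pixels).sum() / n_roi if n_roi else 0.0
    truth = SceneTruth(
        cell_centroids=list(centroids),
        cell_masks=masks,
        true_count=len(masks),
        true_density_cells_per_mm2=len(masks) / area_mm2,
        true_positive_fraction_pct=float(pos_pct),
        true_ri_per_cell=[oracle_ri(m) for m in masks],
    )
    return gray, truth


def _mark_blocked(blocked: np.ndarray, pix: np.ndarray) -> None:
    h, w = blocked.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            rr = np.clip(pix[:, 0] + dr, 0, h - 1)
            cc = np.clip(pix[:, 1] + dc, 0, w - 1)
            blocked[rr, cc] = True


def populate_scene(
    n: int,
    roi: RoiPolygon,
    params: CellShapeParams,
    image_shape: tuple[int, int],
    pixel_size_um: float,
    min_separation_px: float,
    rng_state: np.random.Generator | int | None,
    stain: StainingModel | None = None,
    name: str = "scene",
    max_attempts_per_cell: int = 400,
) -> tuple[GrayImage, SceneTruth]:
    """Place and draw ``n`` non-overlapping cells, then render the field.

    Unlike :func:`render_scene` (which takes placements as given and only
    redraws shapes), this resamples the *position* as well whenever a
    freshly drawn mask would touch an existing cell or the image border —
    robust at densities where fully ramified cells nearly tile the ROI.
    """
    rng = _as_rng(rng_state)
    stain = stain or StainingModel()
    h, w = image_shape
    poly = roi.as_shapely()
    minx, miny, maxx, maxy = poly.bounds
    blocked = np.zeros((h, w), dtype=bool)
    centroids: list[tuple[float, float]] = []
    masks: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_cell * max(n, 1)
    while len(masks) < n:
        if attempts >= budget:
            raise PlacementError(
                f"placed only {len(masks)}/{n} cells after {attempts} attempts; "
                "density infeasible at this minimum separation"
            )
        attempts += 1
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not poly.contains(Point(x, y)):
            continue
        if any((x - px) ** 2 + (y - py) ** 2 < min_separation_px**2 for px, py in centroids):
            continue
        offs = make_cell_mask(params, pixel_size_um, rng)
        pix = offs + np.array([int(y), int(x)])
        if pix[:, 0].min() < 0 or pix[:, 1].min() < 0 or pix[:, 0].max() >= h or pix[:, 1].max() >= w:
            continue
        if blocked[pix[:, 0], pix[:, 1]].any():
            continue
        _mark_blocked(blocked, pix)
        centroids.append((x, y))
        masks.append(pix)
    return _finalize_scene(centroids, masks, image_shape, pixel_size_um, roi, stain, rng, name)


def render_scene(
    centroids: list[tuple[float, float]],
    cell_params: list[CellShapeParams],
    image_shape: tuple[int, int],
    pixel_size_um: float,
    roi: RoiPolygon,
    stain: StainingModel | None = None,
    rng_state: np.random.Generator | int | None = None,
    name: str = "scene",
    max_redraws: int = 12,
) -> tuple[GrayImage, SceneTruth]:
    """Render placed cells into a noisy grayscale field with exact truth.

    Foreground pixels get ``Normal(mu_fg, sigma)`` intensities, background
    ``Normal(mu_bg, sigma)``, rounded and clipped to [0, 255]. A freshly
    drawn cell whose mask would touch (8-neighbourhood) an already placed
    one is redrawn with new shape randomness a bounded number of times, so
    every emitted cell is a distinct connected component.
    """
    if len(centroids) != len(cell_params):
        raise ValidationError("one CellShapeParams per centroid required")
    stain = stain or StainingModel()
    rng = _as_rng(rng_state)
    h, w = image_shape
    blocked = np.zeros((h, w), dtype=bool)  # union dilated by 1 (8-conn guard)
    masks: list[np.ndarray] = []
    for (cx, cy), params in zip(centroids, cell_params):
        r0, c0 = int(cy), int(cx)
        placed = False
        for _ in range(max_redraws):
            offs = make_cell_mask(params, pixel_size_um, rng)
            abs_pix = offs + np.array([r0, c0])
            if abs_pix[:, 0].min() < 0 or abs_pix[:, 1].min() < 0 \
                    or abs_pix[:, 0].max() >= h or abs_pix[:, 1].max() >= w:
                continue
            if blocked[abs_pix[:, 0], abs_pix[:, 1]].any():
                continue
            _mark_blocked(blocked, abs_pix)
            masks.append(abs_pix)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not draw a non-overlapping cell at ({cx:.0f}, {cy:.0f}) "
                f"after {max_redraws} redraws"
            )
    return _finalize_scene(list(centroids), masks, image_shape, pixel_size_um, roi, stain, rng, name)


@dataclass
class GroupSpec:
    """Targets for one cohort group; SDs are between-animal spreads."""

    label: str
    n_animals: int = 5
    target_density: float | None = None
    density_sd: float = 0.0
    target_mean_ri: float | None = None
    ri_sd: float = 0.0
    target_positive_pct: float | None = None
    pct_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ValidationError("n_animals must be >= 2")
        if self.target_density is None and self.target_positive_pct is None:
            raise ValidationError(f"group {self.label!r}: need target_density or target_positive_pct")
        if self.target_density is not None and not (self.target_density > 0):
            raise ValidationError("target_density must be > 0")
        if self.target_mean_ri is not None and not (0 < self.target_mean_ri <= 1):
            raise ValidationError("target_mean_ri must lie in (0, 1]")
        if self.target_positive_pct is not None and not (0 < self.target_positive_pct < 100):
            raise ValidationError("target_positive_pct must lie in (0, 100)")


@dataclass
class CohortSpec:
    """Full cohort design: groups, geometry, shape family, stain, root seed."""

    groups: list[GroupSpec]
    seed: int = 0
    image_size_px: int = 700
    pixel_size_um: float = 1.0
    roi_margin_px: int = 40
    base_shape: CellShapeParams = field(default_factory=CellShapeParams)
    stain: StainingModel = field(default_factory=StainingModel)
    min_separation_um: float | None = None  # default: soma radius + process length
    calibration_tol: float = 0.0075
    calibration_cells: int = 40

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("cohort needs at least one group")
        if self.image_size_px <= 2 * self.roi_margin_px:
            raise ValidationError("roi_margin_px too large for the image size")

    def resolved_min_separation_um(self) -> float:
        if self.min_separation_um is not None:
            return self.min_separation_um
        # 2 * (soma radius + process length) * 0.5
        return self.base_shape.soma_radius_um + self.base_shape.process_length_um


@dataclass
class AnimalScene:
    """One generated animal: image, ROI, truth, and the targets it was seeded with."""

    group: str
    animal: int
    image: GrayImage
    roi: RoiPolygon
    truth: SceneTruth
    seeded: dict[str, float]
    retraction: float | None


@dataclass
class CohortResult:
    scenes: list[AnimalScene]
    manifest: pd.DataFrame


def _draw_truncated(rng: np.random.Generator, mean: float, sd: float,
                    lo: float, hi: float) -> float:
    """Normal(mean, sd) truncated to (lo, hi) by redraw, clipped as last resort."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(100):
        v = rng.normal(mean, sd)
        if lo < v < hi:
            return float(v)
    return float(np.clip(v, lo + 1e-9, hi - 1e-9))


def _animal_scene(spec: CohortSpec, group: GroupSpec, g_idx: int, a_idx: int) -> AnimalScene:
    ss = np.random.SeedSequence([int(spec.seed), g_idx, a_idx])
    rng = np.random.default_rng(ss)
    size = spec.image_size_px
    m = spec.roi_margin_px
    roi = RoiPolygon(
        vertices=np.array([[m, m], [size - m, m], [size - m, size - m], [m, size - m]], dtype=float),
    )
    area_mm2 = roi_area_mm2(roi, spec.pixel_size_um)
    area_px = roi.as_shapely().area

    seeded: dict[str, float] = {}
    retr = None
    params = spec.base_shape
    if group.target_mean_ri is not None:
        ri_target = _draw_truncated(rng, group.target_mean_ri, group.ri_sd, 0.02, 1.0)
        seeded["mean_ri"] = ri_target
        retr = calibrate_retraction(
            ri_target, spec.base_shape, spec.pixel_size_um,
            n_cells=spec.calibration_cells, rng_state=rng, tol=spec.calibration_tol,
            out_of_range="clip",
        )
        params = dataclasses.replace(spec.base_shape, retraction=retr)

    if group.target_density is not None:
        d_target = _draw_truncated(rng, group.target_density, group.density_sd, 0.0, np.inf)
        seeded["density"] = d_target
        count = max(1, int(round(d_target * area_mm2)))
    else:
        pct_target = _draw_truncated(rng, group.target_positive_pct, group.pct_sd, 0.0, 99.0)
        seeded["percent_area"] = pct_target
        probe = [len(make_cell_mask(params, spec.pixel_size_um, rng)) for _ in range(30)]
        mean_area_px = float(np.mean(probe))
        count = max(1, int(round(pct_target / 100.0 * area_px / mean_area_px)))

    min_sep_px = spec.resolved_min_separation_um() / spec.pixel_size_um
    img, truth = populate_scene(
        count, roi, params, (size, size), spec.pixel_size_um, min_sep_px,
        rng, stain=spec.stain, name=f"{group.label}_a{a_idx}",
    )
    return AnimalScene(group=group.label, animal=a_idx, image=img, roi=roi,
                       truth=truth, seeded=seeded, retraction=retr)


def generate_cohort(spec: CohortSpec) -> CohortResult:
    """Generate every animal scene of the cohort plus the truth manifest."""
    scenes = []
    rows = []
    for g_idx, group in enumerate(spec.groups):
        for a_idx in range(group.n_animals):
            try:
                sc = _animal_scene(spec, group, g_idx, a_idx)
            except (PlacementError, CalibrationError) as exc:
                raise type(exc)(f"group {group.label!r}, animal {a_idx}: {exc}") from exc
            scenes.append(sc)
            rows.append({
                "group": sc.group,
                "animal": sc.animal,
                "file": f"{sc.image.name}.png",
                "roi_file": f"{sc.image.name}_roi.json",
                "true_count": sc.truth.true_count,
                "true_density": sc.truth.true_density_cells_per_mm2,
                "true_pct": sc.truth.true_positive_fraction_pct,
                "true_mean_ri": sc.truth.true_mean_ri,
            })
    return CohortResult(scenes=scenes, manifest=pd.DataFrame(rows))


def write_cohort(result: CohortResult, outdir: str | Path, pixel_size_um: float) -> None:
    """Emit PNG scenes, ROI JSON files, manifest.csv and truth_cells.csv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cell_rows = []
    for sc in result.scenes:
        write_image(sc.image, outdir / f"{sc.image.name}.png")
        write_roi(sc.roi, pixel_size_um, outdir / f"{sc.image.name}_roi.json")
        for i, (ri, cen) in enumerate(zip(sc.truth.true_ri_per_cell, sc.truth.cell_centroids)):
            cell_rows.append({
                "group": sc.group, "animal": sc.animal, "cell": i,
                "x": cen[0], "y": cen[1], "true_ri": ri,
                "true_area_px": len(sc.truth.cell_masks[i]),
            })
    result.manifest.to_csv(outdir / "manifest.csv", index=False)
    pd.DataFrame(cell_rows).to_csv(outdir / "truth_cells.csv", index=False)


def cohort_spec_from_yaml(path: str | Path) -> CohortSpec:
    """Load a CohortSpec from YAML mirroring the dataclass field-for-field."""
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    groups = [GroupSpec(**g) for g in obj.pop("groups")]
    shape = CellShapeParams(**obj.pop("base_shape")) if "base_shape" in obj else CellShapeParams()
    stain = StainingModel(**obj.pop("stain")) if "stain" in obj else StainingModel()
    return CohortSpec(groups=groups, base_shape=shape, stain=stain, **obj)
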