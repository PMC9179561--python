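"""End-to-end orchestration: simulate or load a cohort, run the three
quantification methods per animal, then the group statistics per metric,
and write a consolidated report bundle.

One root seed governs simulation, grid phases and any sampling; module
streams are split deterministically, so a rerun with the same config is
byte-identical. Reports use a fixed column order and 6-significant-digit
float formatting so diffs are meaningful.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cell_detection import DetectionParams, cells_per_mm2, detect_cells
from .densitometry import ThresholdSpec, binarize, percent_area
from .errors import ValidationError
from .io_roi import GrayImage, RoiPolygon, rasterize_roi, read_image, read_roi, roi_area_mm2
from .morphometry import GridSpec, analyze_cells, default_grid
from .group_stats import METRICS, run_group_analysis
from .synthetic_data import CohortResult, CohortSpec, cohort_spec_from_yaml, generate_cohort, write_cohort

log = logging.getLogger("microglioq")


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of ``simulation_spec`` / ``manifest``."""

    simulation_spec: str | Path | None = None
    manifest: str | Path | None = None
    seed: int = 0
    outdir: str | Path = "microglioq_out"
    control_label: str | None = None  # default: first group in order of appearance
    pixel_size_um: float | None = None  # required for manifest input
    threshold: ThresholdSpec = field(default_factory=ThresholdSpec)
    detection: DetectionParams = field(default_factory=DetectionParams)
    grid_spacing_px: float | None = None  # default: image width / 8
    alpha: float = 0.05
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.simulation_spec is None) == (self.manifest is None):
            raise ValidationError("provide exactly one of simulation_spec / manifest")


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_csv(df: pd.DataFrame, path: Path, columns: list[str]) -> None:
    df = df.reindex(columns=columns)
    out = df.copy()
    for c in out.columns:
        out[c] = out[c].map(_fmt)
    out.to_csv(path, index=False)


def analyze_scene(
    image: GrayImage,
    roi: RoiPolygon,
    pixel_size_um: float,
    threshold: ThresholdSpec,
    detection: DetectionParams,
    grid: GridSpec,
    rng: np.random.Generator,
) -> dict:
    """All three quantification methods on one (image, ROI) pair."""
    roi_mask = rasterize_roi(roi, image.shape)
    mask, cutoff = binarize(image, threshold, roi_mask=roi_mask)
    pct = percent_area(mask, roi_mask)
    cells = detect_cells(mask, roi_mask, detection, pixel_size_um)
    area = roi_area_mm2(roi, pixel_size_um)
    density = cells_per_mm2(len(cells), area)
    morpho = analyze_cells(mask, roi_mask, detection, grid, pixel_size_um, rng=rng)
    return {
        "cutoff": cutoff,
        "percent_area": pct,
        "count": len(cells),
        "roi_area_mm2": area,
        "cells_per_mm2": density,
        "morphometry": morpho,
    }


def _load_manifest(config: PipelineConfig) -> CohortResult:
    """Load pre-existing scenes listed in a manifest.csv (no ground truth)."""
    mpath = Path(config.manifest)
    base = mpath.parent
    man = pd.read_csv(mpath)
    if config.pixel_size_um is None:
        raise ValidationError("manifest input requires pixel_size_um")
    from .synthetic_data import AnimalScene, SceneTruth

    scenes = []
    for _, row in man.iterrows():
        img = read_image(base / row["file"], config.pixel_size_um)
        roi, _ = read_roi(base / row["roi_file"])
        truth = None
        if "true_count" in man.columns and not pd.isna(row.get("true_count", np.nan)):
            truth = SceneTruth(
                cell_centroids=[], cell_masks=[],
                true_count=int(row["true_count"]),
                true_density_cells_per_mm2=float(row["true_density"]),
                true_positive_fraction_pct=float(row["true_pct"]),
                true_ri_per_cell=[float(row["true_mean_ri"])] if not pd.isna(row["true_mean_ri"]) else [],
            )
        scenes.append(AnimalScene(group=str(row["group"]), animal=int(row["animal"]),
                                  image=img, roi=roi, truth=truth, seeded={}, retraction=None))
    return CohortResult(scenes=scenes, manifest=man)


def run_pipeline(config: PipelineConfig) -> dict:
    """Simulate/load -> analyze every animal -> group stats -> report bundle.

    Returns the report dict and writes summary.csv, stats.json, cells.csv,
    per_animal.csv, run.log (and recovery.csv when ground truth exists)
    under ``config.outdir``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        return _run(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict:
    log.info("pipeline start seed=%d", config.seed)
    if config.simulation_spec is not None:
        stage = "simulate"
        try:
            spec = cohort_spec_from_yaml(config.simulation_spec)
            spec = dataclasses.replace(spec, seed=config.seed)
            cohort = generate_cohort(spec)
            write_cohort(cohort, outdir / "scenes", spec.pixel_size_um)
            pixel_size = spec.pixel_size_um
        except Exception as exc:
            log.error("stage=%s failed: %s", stage, exc)
            raise
        log.info("simulated %d scenes", len(cohort.scenes))
    else:
        stage = "load"
        try:
            cohort = _load_manifest(config)
            pixel_size = config.pixel_size_um
        except Exception as exc:
            log.error("stage=%s failed: %s", stage, exc)
            raise

    per_animal_rows = []
    cell_rows = []
    for i, sc in enumerate(cohort.scenes):
        stage = f"analyze[{sc.group}/{sc.animal}]"
        try:
            grid = (GridSpec(spacing_px=config.grid_spacing_px)
                    if config.grid_spacing_px else default_grid(sc.image.shape[1]))
            rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 7, i]))
            res = analyze_scene(sc.image, sc.roi, pixel_size,
                                config.threshold, config.detection, grid, rng)
        except Exception as exc:
            log.error("stage=%s input=%s failed: %s", stage, sc.image.name, exc)
            raise
        morpho = res["morphometry"]
        per_animal_rows.append({
            "group": sc.group, "animal": sc.animal, "image": sc.image.name,
            "cutoff": res["cutoff"], "percent_area": res["percent_area"],
            "count": res["count"], "roi_area_mm2": res["roi_area_mm2"],
            "cells_per_mm2": res["cells_per_mm2"],
            "n_cells_morpho": morpho.n_cells, "mean_ri": morpho.mean_ri,
        })
        for r in morpho.records:
            cell_rows.append({
                "group": sc.group, "animal": sc.animal, "cell_id": r.cell_id,
                "centroid_x": r.centroid[0], "centroid_y": r.centroid[1],
                "area_um2": r.a_c_um2, "hull_area_um2": r.a_p_um2, "ri": r.ri,
            })
        log.info("analyzed %s: pct=%.4g density=%.5g mean_ri=%.4g n_morpho=%d",
                 sc.image.name, res["percent_area"], res["cells_per_mm2"],
                 morpho.mean_ri, morpho.n_cells)

    per_animal = pd.DataFrame(per_animal_rows)
    groups_in_order = list(dict.fromkeys(per_animal["group"]))
    control = config.control_label or groups_in_order[0]

    stats_out = {}
    summary_rows = []
    metric_cols = {"density": "cells_per_mm2", "percent_area": "percent_area", "mean_ri": "mean_ri"}
    if len(groups_in_order) >= 2:
        for metric, col in metric_cols.items():
            stage = f"stats[{metric}]"
            try:
                table = per_animal[["group", col]].rename(columns={col: "value"}).dropna()
                result = run_group_analysis(table, metric, control, alpha=config.alpha)
            except Exception as exc:
                log.error("stage=%s failed: %s", stage, exc)
                raise
            stats_out[metric] = {
                "H": result.H, "p_global": result.p_global,
                "comparisons": [dataclasses.asdict(c) for c in result.comparisons],
                "excluded_outliers": [
                    {"group": g, "value": v, "G": G} for g, v, G in result.excluded_outliers
                ],
            }
            summary_rows.extend(result.group_summaries)
    else:
        log.info("single group: skipping group statistics")
        for label in groups_in_order:
            for metric, col in metric_cols.items():
                vals = per_animal.loc[per_animal["group"] == label, col].dropna()
                if len(vals) >= 2:
                    summary_rows.append({"group": label, "metric": metric, "n": len(vals),
                                         "mean": float(vals.mean()), "sd": float(vals.std(ddof=1))})

    report = {
        "per_animal": per_animal,
        "cells": pd.DataFrame(cell_rows),
        "stats": stats_out,
        "summary": pd.DataFrame(summary_rows),
        "control": control,
    }

    has_truth = all(sc.truth is not None for sc in cohort.scenes) and cohort.scenes
    if has_truth:
        rec_rows = []
        seeded = {
            "density": float(np.mean([sc.truth.true_density_cells_per_mm2 for sc in cohort.scenes])),
            "percent_area": float(np.mean([sc.truth.true_positive_fraction_pct for sc in cohort.scenes])),
            "mean_ri": float(np.nanmean([sc.truth.true_mean_ri for sc in cohort.scenes])),
        }
        recovered = {
            "density": float(per_animal["cells_per_mm2"].mean()),
            "percent_area": float(per_animal["percent_area"].mean()),
            "mean_ri": float(per_animal["mean_ri"].mean()),
        }
        for metric in METRICS:
            s, r = seeded[metric], recovered[metric]
            rel = abs(r - s) / abs(s) if s else float("nan")
            rec_rows.append({"metric": metric, "seeded": s, "recovered": r, "relative_error": rel})
        report["recovery"] = pd.DataFrame(rec_rows)

    write_report(report, outdir)
    log.info("pipeline done; report in %s", outdir)
    return report


def write_report(report: dict, outdir: str | Path) -> None:
    """Write the consolidated CSV/JSON bundle with deterministic formatting."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _write_csv(report["per_animal"], outdir / "per_animal.csv",
               ["group", "animal", "image", "cutoff", "percent_area", "count",
                "roi_area_mm2", "cells_per_mm2", "n_cells_morpho", "mean_ri"])
    _write_csv(report["cells"], outdir / "cells.csv",
               ["group", "animal", "cell_id", "centroid_x", "centroid_y",
                "area_um2", "hull_area_um2", "ri"])
    _write_csv(report["summary"], outdir / "summary.csv",
               ["group", "metric", "n", "mean", "sd"])
    with open(outdir / "stats.json", "w") as fh:
        json.dump(report["stats"], fh, indent=1, sort_keys=True)
    if "recovery" in report:
        _write_csv(report["recovery"], outdir / "recovery.csv",
                   ["metric", "seeded", "recovered", "relative_error"])
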