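"""End-to-end orchestration: grid -> deconvolve -> measure -> stats -> report.

Each sample contributes one IHC-stained slide per stain plus a shared
hematoxylin-only negative control. Slides are analyzed independently (no
cross-stain registration): the grid comes from the stained slide's extent
and its exclusion annotations; nuclear morphometry and the chromatin
density ratio come from the negative control's hematoxylin channel; the
DAB score comes from the stained slide. Every run directory carries a
manifest recording the configuration, seeds, and package version before
any result file is interpreted.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .image import RgbImage, read_image, write_image
from .morphometry import (
    SegmentationParams,
    assemble_roi_table,
    compute_cdr,
    compute_dab_score,
    segment_nuclei,
)
from .stains import (
    IntensityThresholds,
    StainModel,
    classify_intensity,
    deconvolve,
    rgb_to_od,
    summarize_stain,
)
from .stats import run_analysis_suite
from .tiling import AnnotationSet, HeatmapSpec, RoiGrid, build_grid, grid_to_frame, render_heatmap

logger = logging.getLogger(__name__)


class StageFailure(RuntimeError):
    """A pipeline stage failed for an identified slide or file."""


@dataclass
class SlideEntry:
    """One stained slide + its negative control and annotations."""

    stain: str
    image: str
    control: str
    patient_id: str
    sample_id: str
    annotations: str | None = None


@dataclass
class PipelineConfig:
    slides: list[SlideEntry]
    cohort_csv: str | None = None
    output_dir: str = "run"
    microns_per_pixel: float | None = None  # fallback when tags are absent
    tile_size_mm: float = 0.25
    min_valid_fraction: float = 0.5
    thresholds: IntensityThresholds = field(default_factory=IntensityThresholds)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    n_boot: int = 2000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        slides = [SlideEntry(**s) for s in raw.pop("slides")]
        thr = IntensityThresholds(**raw.pop("thresholds", {}))
        seg = SegmentationParams(**raw.pop("segmentation", {}))
        return cls(slides=slides, thresholds=thr, segmentation=seg, **raw)

    def validate(self) -> list[str]:
        problems = []
        for s in self.slides:
            for p in (s.image, s.control, s.annotations):
                if p and not Path(p).exists():
                    problems.append(f"missing input: {p}")
        if self.cohort_csv and not Path(self.cohort_csv).exists():
            problems.append(f"missing input: {self.cohort_csv}")
        return problems


def measure_slide(
    stained: RgbImage,
    control: RgbImage,
    grid: RoiGrid,
    stain: str,
    model: StainModel | None = None,
    thresholds: IntensityThresholds = IntensityThresholds(),
    seg_params: SegmentationParams = SegmentationParams(),
    patient_id: str = "",
    sample_id: str = "",
) -> pd.DataFrame:
    """Measure every retained ROI of one stained/control slide pair.

    Per tile: segment nuclei on the control's hematoxylin concentration,
    stratify nuclear hematoxylin into intensity classes for the CDR, and
    summarize the stained slide's DAB channel for the expression score.
    """
    model = model or StainModel.hdab()
    conc_stained = deconvolve(rgb_to_od(stained, model.background), model)
    conc_control = deconvolve(rgb_to_od(control, model.background), model)
    hema_ctl = conc_control[..., 0]
    dab = conc_stained[..., 1]
    hema_classes = classify_intensity(hema_ctl, thresholds)
    dab_classes = classify_intensity(dab, thresholds)
    rows = []
    for tile in grid.tiles:
        sl = tile.slices()
        nuclei = segment_nuclei(
            hema_ctl[sl], control.microns_per_pixel, seg_params
        )
        cdr_res = compute_cdr(hema_classes[sl], nuclei.mask)
        dab_summary = summarize_stain(dab_classes[sl], dab[sl])
        rows.append(
            dict(
                roi_id=tile.roi_id,
                patient_id=patient_id,
                sample_id=sample_id,
                stain=stain,
                cdr=cdr_res.cdr,
                cdr_cumulative=cdr_res.cdr_cumulative,
                cdr_flag=cdr_res.flag,
                nuc_count=nuclei.count,
                avg_nuclear_size_um2=nuclei.mean_area_um2,
                dab_score=compute_dab_score(dab_summary),
                pct_weak=dab_summary.pct_weak,
                pct_medium=dab_summary.pct_medium,
                pct_strong=dab_summary.pct_strong,
                avg_od=dab_summary.avg_od,
                n_pixels=dab_summary.n_pixels,
            )
        )
    return assemble_roi_table(rows)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the run directory.

    The manifest is written before any analysis output. A failing slide is
    reported and skipped so the remaining slides still complete; the
    failure list is part of the manifest and a non-empty list raises
    :class:`StageFailure` at the end.
    """
    problems = config.validate()
    if problems:
        raise ValueError("invalid configuration:\n" + "\n".join(problems))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "config_hash": _config_hash(config),
        "version": __version__,
        "seed": config.seed,
        "failures": [],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))

    tables = []
    for entry in config.slides:
        t0 = time.time()
        try:
            stained = read_image(entry.image, config.microns_per_pixel)
            control = read_image(entry.control, config.microns_per_pixel)
            ann = AnnotationSet.from_geojson(entry.annotations) if entry.annotations else None
            grid = build_grid(
                stained, ann, config.tile_size_mm, config.min_valid_fraction
            )
            dropped = len(grid.all_tiles) - len(grid.tiles)
            if dropped:
                logger.warning(
                    "stage=grid slide=%s dropped=%d/%d tiles below min_valid_fraction",
                    entry.image, dropped, len(grid.all_tiles),
                )
            grid_to_frame(grid).to_csv(
                out / f"grid_{entry.sample_id}_{entry.stain}.csv", index=False
            )
            table = measure_slide(
                stained, control, grid, entry.stain,
                thresholds=config.thresholds, seg_params=config.segmentation,
                patient_id=entry.patient_id, sample_id=entry.sample_id,
            )
            table.to_csv(
                out / f"measurements_{entry.sample_id}_{entry.stain}.csv", index=False
            )
            heat = render_heatmap(
                grid, dict(zip(table["roi_id"], table["dab_score"])), HeatmapSpec()
            )
            write_image(out / f"heatmap_{entry.sample_id}_{entry.stain}.png", heat)
            tables.append(table)
            logger.info(
                "stage=measure slide=%s stain=%s rois=%d elapsed=%.1fs",
                entry.image, entry.stain, len(table), time.time() - t0,
            )
        except Exception as exc:  # noqa: BLE001 — isolate per-slide failures
            logger.error("stage=measure slide=%s FAILED: %s", entry.image, exc)
            manifest["failures"].append({"slide": entry.image, "error": str(exc)})

    if tables:
        measurements = pd.concat(tables, ignore_index=True)
        measurements.to_csv(out / "measurements.csv", index=False)
        wide = measurements_to_wide(measurements)
        if config.cohort_csv:
            cohort = pd.read_csv(config.cohort_csv)
            wide = wide.merge(
                cohort[["patient_id", "expression_set", "outcome"]].drop_duplicates(),
                on="patient_id", how="left",
            )
        stain_cols = tuple(
            c for c in wide.columns if c.startswith("dab_") and c != "dab_score"
        )
        try:
            results = run_analysis_suite(
                wide, stain_columns=stain_cols,
                n_boot=config.n_boot, seed=config.seed,
            )
            results.to_csv(out / "statistics.csv", index=False)
            (out / "report.txt").write_text(format_report(results, config))
        except ValueError as exc:
            logger.warning("stage=stats skipped: %s", exc)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    if manifest["failures"]:
        raise StageFailure(
            f"{len(manifest['failures'])} slide(s) failed; see manifest.json in {out}"
        )
    return out


def measurements_to_wide(measurements: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long per-stain table to one row per (sample, ROI).

    CDR, nuclear size and MTA come from the control slide and are shared
    across stains of a sample; ``dab_score`` pivots to ``dab_<stain>``.
    """
    keys = ["patient_id", "sample_id", "roi_id"]
    shared_cols = [c for c in ("cdr", "log_cdr", "avg_nuclear_size_um2",
                               "log_nuclear_size", "mta") if c in measurements]
    shared = measurements.groupby(keys, as_index=False)[shared_cols].first()
    dab = measurements.pivot_table(
        index=keys, columns="stain", values="dab_score"
    ).add_prefix("dab_").reset_index()
    out = shared.merge(dab, on=keys, how="left")
    if "mta" not in out.columns:
        out["mta"] = np.nan
    return out


def format_report(results: pd.DataFrame, config: PipelineConfig) -> str:
    lines = [
        "fibroquant analysis report",
        f"version {__version__}  seed {config.seed}  n_boot {config.n_boot}",
        "bootstrap: patient-cluster resampling, percentile CI, sign-flip p (unadjusted)",
        "GEE: Gaussian/identity, exchangeable working correlation, "
        "bias-reduced sandwich, t reference",
        "",
    ]
    for _, row in results.iterrows():
        if row["analysis"] == "correlation":
            lines.append(
                f"corr {row['xvar']} vs {row['yvar']}: r={row['estimate']:+.3f} "
                f"[{row['ci_low']:+.3f}, {row['ci_high']:+.3f}] p={row['p']:.4f} "
                f"(n={row['n']}, clusters={row['n_clusters']})"
            )
        else:
            lines.append(
                f"{row['analysis']} {row['yvar']} by {row['xvar']}: "
                f"diff={row['estimate']:+.3f} p={row['p']:.4f} "
                f"(n={row['n']}, clusters={row['n_clusters']})"
            )
    return "\n".join(lines) + "\n"
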