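"""Per-ROI nuclear morphometry, chromatin density ratio, and DAB score.

The biological quantities computed here per 0.25 mm tile:

* **Average nuclear size** — nuclei are segmented from the hematoxylin
  concentration map of a hematoxylin-only (negative control) image:
  threshold at the weak-positive cutoff, fill holes, split touching blobs
  by a distance-transform watershed, and drop components outside plausible
  nuclear area bounds. Mean per-nucleus area is reported in square microns.

* **Chromatin density ratio (CDR)** — within segmented nuclei, the ratio of
  the medium-density hematoxylin area (open, euchromatic, "active" nuclei)
  to the high-density area (condensed, heterochromatic, "inactive" nuclei).
  The numerator is the *exclusive* medium band (medium and not strong); a
  cumulative variant is carried alongside for sensitivity. A zero
  denominator yields a missing value, never infinity, because downstream
  analysis works on log CDR.

* **DAB expression score** — average DAB optical density of positive pixels
  times the percent of area staining positive (at the inclusive weak
  threshold), so tissue that is both darker and more extensively stained
  scores higher.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from .stains import (
    MEDIUM,
    STRONG,
    IntensityThresholds,
    StainSummary,
    concentration_cutoff,
)

NO_DENSE_CHROMATIN = "no-dense-chromatin"
NO_NUCLEAR_SIGNAL = "no-nuclear-signal"


@dataclass(frozen=True)
class SegmentationParams:
    """Nuclear segmentation settings.

    ``threshold_intensity`` is the transmission-scale cutoff (same scale as
    the weak positive-pixel threshold) above which hematoxylin is treated
    as nuclear. Area bounds are in square microns; components outside them
    are discarded. ``min_peak_distance_um`` spaces watershed markers: it
    must be below the typical center distance of touching nuclei and above
    the distance between spurious double peaks inside one nucleus.
    """

    threshold_intensity: float = 220.0
    min_area_um2: float = 8.0
    max_area_um2: float = 400.0
    min_peak_distance_um: float = 2.0
    smooth_sigma_px: float = 1.75
    fill_holes: bool = True


@dataclass(frozen=True)
class NucleusSet:
    """Labeled nuclei within an ROI."""

    labels: np.ndarray  # int label image, 0 = background
    areas_um2: np.ndarray  # per-nucleus area, index = label - 1

    @property
    def count(self) -> int:
        return len(self.areas_um2)

    @property
    def mean_area_um2(self) -> float:
        return float(np.mean(self.areas_um2)) if self.count else math.nan

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0


def segment_nuclei(
    hematoxylin: np.ndarray,
    microns_per_pixel: float,
    params: SegmentationParams = SegmentationParams(),
    mask: np.ndarray | None = None,
    background: float = 255.0,
) -> NucleusSet:
    """Segment nuclei from a hematoxylin concentration map.

    Empty input yields an empty set (count 0, mean area NaN), never an
    error: blank ROIs are a legitimate state.
    """
    hema = np.asarray(hematoxylin, dtype=float)
    c_min = concentration_cutoff(params.threshold_intensity, background)
    binary = hema >= c_min
    if mask is not None:
        binary &= np.asarray(mask, dtype=bool)
    if params.fill_holes:
        binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return NucleusSet(np.zeros(hema.shape, dtype=np.int32), np.empty(0))

    distance = ndi.distance_transform_edt(binary)
    smoothed = ndi.gaussian_filter(distance, params.smooth_sigma_px)
    min_dist_px = max(1, int(round(params.min_peak_distance_um / microns_per_pixel)))
    peaks = peak_local_max(
        smoothed, min_distance=min_dist_px, labels=binary, exclude_border=False
    )
    markers = np.zeros(hema.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    labels = watershed(-smoothed, markers, mask=binary)

    # area filter, then relabel densely
    px_area = microns_per_pixel**2
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    areas = counts * px_area
    keep = ids[(areas >= params.min_area_um2) & (areas <= params.max_area_um2)]
    lut = np.zeros(labels.max() + 1, dtype=np.int32)
    lut[keep] = np.arange(1, len(keep) + 1)
    labels = lut[labels]
    kept_areas = np.array(
        [areas[np.searchsorted(ids, k)] for k in keep], dtype=float
    )
    return NucleusSet(labels, kept_areas)


@dataclass(frozen=True)
class CdrResult:
    """Chromatin density ratio with its missingness state."""

    cdr: float  # NaN when undefined
    cdr_cumulative: float
    medium_px: int  # exclusive medium band
    strong_px: int
    flag: str | None = None


def compute_cdr(class_labels: np.ndarray, nuclear_mask: np.ndarray) -> CdrResult:
    """Ratio of medium-density to high-density nuclear hematoxylin area.

    ``class_labels`` is a negative/weak/medium/strong map restricted by
    ``nuclear_mask`` to segmented-nucleus pixels. Numerator: exclusive
    medium band; a cumulative variant (medium-or-darker over strong) is
    also returned. Zero strong area gives NaN, flagged.
    """
    lab = np.asarray(class_labels)[np.asarray(nuclear_mask, dtype=bool)]
    medium_excl = int(np.sum(lab == MEDIUM))
    strong = int(np.sum(lab == STRONG))
    if strong == 0:
        flag = NO_DENSE_CHROMATIN if medium_excl > 0 else NO_NUCLEAR_SIGNAL
        return CdrResult(math.nan, math.nan, medium_excl, strong, flag)
    return CdrResult(
        medium_excl / strong, (medium_excl + strong) / strong, medium_excl, strong
    )


def compute_dab_score(summary: StainSummary) -> float:
    """DAB expression score: mean positive OD times percent positive area."""
    return summary.avg_od * summary.pct_weak


def _safe_log(x: float) -> float:
    return math.log(x) if (x is not None and np.isfinite(x) and x > 0) else math.nan


def assemble_roi_table(
    rows: list[dict],
    mta: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Join per-ROI quantity dicts into the measurement table.

    Each input dict must carry ``roi_id``; duplicate ids are a hard error.
    Natural-log transforms of CDR and nuclear size are added; missing stays
    missing (NaN), never silently zero.
    """
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    if df["roi_id"].duplicated().any():
        dup = df.loc[df["roi_id"].duplicated(), "roi_id"].tolist()
        raise ValueError(f"duplicate roi_id(s): {dup}")
    if "cdr" in df:
        df["log_cdr"] = df["cdr"].map(_safe_log)
    if "avg_nuclear_size_um2" in df:
        df["log_nuclear_size"] = df["avg_nuclear_size_um2"].map(_safe_log)
    if mta is not None:
        bad = {k: v for k, v in mta.items() if v not in (1, 2, 3, 4)}
        if bad:
            raise ValueError(f"MTA scores must be in 1..4: {bad}")
        df["mta"] = df["roi_id"].map(mta)
    return df
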