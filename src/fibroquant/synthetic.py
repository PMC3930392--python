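"""Synthetic slides and cohort tables with known ground truth.

Real aggressive-fibromatosis sections are spatially heterogeneous: some
areas look "inactive" (sparse cells with thin, dark, heterochromatin-dense
nuclei in abundant collagen) and others "active" (denser, plump oval nuclei
with pale open chromatin and higher IHC staining). The generator encodes
that contrast through a smooth latent activity field a(x, y) in [0, 1]:

* nuclear density, nuclear plumpness/area, and DAB concentration increase
  with a;
* the fraction of nuclear pixels painted at the strong (condensed)
  hematoxylin level decreases with a, the remainder being medium (open);
* background collagen hematoxylin decreases with a.

Images are composed physically: per-stain concentrations are mixed along
unit stain vectors in optical-density space (Beer-Lambert), transmitted,
and quantized to 8-bit RGB. A hematoxylin-only negative control with the
identical nuclei accompanies every stained slide, mirroring how nuclear
morphometry is done on control sections. All randomness flows from one
seed; everything the pipeline later measures is recorded as ground truth.

The cohort generator is purely tabular: it draws the patient -> sample ->
ROI hierarchy with a latent activity per ROI and produces measurement
columns from configurable linear couplings, group shifts, and noise —
the substrate for calibrating and validating the cluster-aware statistics.
"""
from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from shapely.geometry import Point
from skimage.draw import ellipse as draw_ellipse

from .image import RgbImage, write_image
from .stains import MEDIUM, STRONG, StainModel, od_to_rgb
from .tiling import Annotation, AnnotationSet, RoiGrid


class PlacementError(RuntimeError):
    """Hard-core nucleus placement failed; lower the nuclear density."""


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of one synthetic slide.

    Defaults draw a 0.5 x 0.5 mm field at 0.5 um/px (a 2 x 2 lattice of
    0.25 mm ROIs). Nuclear geometry spans thin elongated nuclei
    (~17 um^2) at a=0 to plump ovals (~43 um^2) at a=1; densities span
    sparse (300 /mm^2) to cellular (1200 /mm^2). Hematoxylin OD levels for
    medium (open) and strong (condensed) chromatin sit mid-band relative to
    the default transmission cutoffs, and collagen stays below the weak
    cutoff so nuclei segment cleanly.
    """

    shape_px: tuple[int, int] = (1000, 1000)
    microns_per_pixel: float = 0.5
    # activity field
    correlation_length_um: float = 120.0
    uniform_activity: float | None = None
    # nuclei
    density_low: float = 300.0  # nuclei per mm^2 at a=0
    density_high: float = 1200.0  # at a=1
    major_um: tuple[float, float] = (4.5, 4.4)  # semi-major at a=0, a=1
    minor_um: tuple[float, float] = (1.2, 3.1)  # semi-minor at a=0, a=1
    size_jitter_sd: float = 0.10  # lognormal sd on the shared axis factor
    touching_fraction: float = 0.0  # fraction of nuclei given a touching twin
    # chromatin + stains (OD units)
    strong_fraction: tuple[float, float] = (0.85, 0.15)  # at a=0, a=1
    od_medium: float = 0.28
    od_strong: float = 0.65
    collagen_od: tuple[float, float] = (0.03, 0.01)  # at a=0, a=1
    dab_localization: str = "cytoplasmic"  # nuclear | cytoplasmic | both
    dab_base: float = 0.05
    dab_gain: float = 0.45
    cytoplasm_radius_um: float = 2.0
    noise_od_sigma: float = 0.01
    # artifacts to exercise annotation exclusion
    n_artifacts: int = 0
    artifact_radius_um: float = 40.0

    def __post_init__(self) -> None:
        if self.dab_localization not in ("nuclear", "cytoplasmic", "both"):
            raise ValueError("dab_localization must be nuclear|cytoplasmic|both")
        for name in ("od_medium", "od_strong", "dab_base", "dab_gain",
                     "noise_od_sigma", "density_low", "density_high"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.uniform_activity is not None and not 0 <= self.uniform_activity <= 1:
            raise ValueError("uniform_activity must lie in [0, 1]")


@dataclass
class SlideTruth:
    """Everything the generator knows about a slide."""

    activity: np.ndarray  # (H, W) in [0, 1]
    nuclei_labels: np.ndarray  # int32 label image, 0 background
    nucleus_areas_um2: np.ndarray  # painted areas, index = label - 1
    chromatin_class: np.ndarray  # 0 none, MEDIUM, STRONG per pixel
    hema_concentration: np.ndarray  # final (noisy) hematoxylin OD amount
    dab_concentration: np.ndarray  # final (noisy) DAB OD amount
    od: np.ndarray  # (H, W, 3) composed per-channel OD of the stained slide
    exclusions: AnnotationSet
    seed: int

    @property
    def n_nuclei(self) -> int:
        return len(self.nucleus_areas_um2)


def _activity_field(spec: SyntheticSlideSpec, rng: np.random.Generator) -> np.ndarray:
    h, w = spec.shape_px
    if spec.uniform_activity is not None:
        return np.full((h, w), float(spec.uniform_activity))
    sigma_px = spec.correlation_length_um / spec.microns_per_pixel
    noise = rng.standard_normal((h, w))
    smooth = ndi.gaussian_filter(noise, sigma_px, mode="reflect")
    # rank-normalize to a uniform [0, 1] marginal
    flat = smooth.ravel()
    ranks = np.empty_like(flat)
    ranks[np.argsort(flat, kind="stable")] = np.arange(flat.size)
    return (ranks / max(flat.size - 1, 1)).reshape(h, w)


def _place_nuclei(
    spec: SyntheticSlideSpec,
    activity: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[float, float, float, float, float, float]]:
    """Hard-core thinned Poisson placement.

    Returns (row, col, major_px, minor_px, rotation, a_local) per nucleus.
    Candidates are drawn at the maximum density and thinned by the local
    activity-dependent density; survivors must keep center distance above
    the sum of semi-majors (conservative no-overlap guarantee).
    """
    h, w = spec.shape_px
    mpp = spec.microns_per_pixel
    area_mm2 = h * w * mpp**2 / 1e6
    d_max = max(spec.density_low, spec.density_high)
    if d_max == 0:
        return []
    n_candidates = rng.poisson(d_max * area_mm2)
    placed: list[tuple[float, float, float, float, float, float]] = []
    centers = np.empty((0, 2))
    radii = np.empty(0)
    n_thinned = 0
    n_rejected = 0
    for _ in range(n_candidates):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        a_loc = float(activity[min(int(r), h - 1), min(int(c), w - 1)])
        dens = spec.density_low + (spec.density_high - spec.density_low) * a_loc
        if rng.uniform() * d_max > dens:
            continue
        n_thinned += 1
        jitter = math.exp(rng.normal(0.0, spec.size_jitter_sd))
        major = (spec.major_um[0] + (spec.major_um[1] - spec.major_um[0]) * a_loc) * jitter / mpp
        minor = (spec.minor_um[0] + (spec.minor_um[1] - spec.minor_um[0]) * a_loc) * jitter / mpp
        if len(centers):
            d2 = np.sum((centers - [r, c]) ** 2, axis=1)
            if np.any(d2 < (radii + major) ** 2):
                n_rejected += 1
                continue
        rot = rng.uniform(0, math.pi)
        placed.append((r, c, major, minor, rot, a_loc))
        centers = np.vstack([centers, [r, c]])
        radii = np.append(radii, major)
    if n_thinned >= 20 and len(placed) < 0.5 * n_thinned:
        raise PlacementError(
            "hard-core placement rejected most candidates; "
            "lower the nuclear density or nucleus size"
        )
    # optional touching twins, to exercise watershed splitting: the twin is
    # a parallel copy offset along the major axis (end-to-end contact),
    # which leaves a deep neck between the two lobes
    if spec.touching_fraction > 0:
        twins = []
        for (r, c, major, minor, rot, a_loc) in placed:
            if rng.uniform() >= spec.touching_fraction:
                continue
            gap = 1.7 * major
            tr = r + gap * math.cos(rot)
            tc = c + gap * math.sin(rot)
            if not (0 <= tr < h and 0 <= tc < w):
                continue
            clear = np.sum((centers - [tr, tc]) ** 2, axis=1) >= (radii + major) ** 2
            # contact with the primary (its own entry) is intended; require
            # clearance from every other nucleus
            if np.sum(~clear) <= 1:
                twins.append((tr, tc, major, minor, rot, a_loc))
        placed.extend(twins)
    return placed


def generate_slide(
    spec: SyntheticSlideSpec,
    seed: int,
    stain_model: StainModel | None = None,
) -> tuple[RgbImage, RgbImage, SlideTruth]:
    """Render one stained slide, its negative control, and the truth bundle."""
    model = stain_model or StainModel.hdab()
    rng = np.random.default_rng(seed)
    h, w = spec.shape_px
    mpp = spec.microns_per_pixel

    activity = _activity_field(spec, rng)
    nuclei = _place_nuclei(spec, activity, rng)

    labels = np.zeros((h, w), dtype=np.int32)
    chromatin = np.zeros((h, w), dtype=np.uint8)
    for i, (r, c, major, minor, rot, a_loc) in enumerate(nuclei, start=1):
        rr, cc = draw_ellipse(r, c, major, minor, shape=(h, w), rotation=rot)
        labels[rr, cc] = i
        f_strong = spec.strong_fraction[0] + (
            spec.strong_fraction[1] - spec.strong_fraction[0]
        ) * a_loc
        strong = rng.uniform(size=len(rr)) < f_strong
        chromatin[rr, cc] = np.where(strong, STRONG, MEDIUM).astype(np.uint8)
    # areas from painted pixels (twins may overwrite a few shared pixels)
    if nuclei:
        counts = np.bincount(labels.ravel(), minlength=len(nuclei) + 1)[1:]
        areas = counts.astype(float) * mpp**2
        keep = counts > 0
        areas = areas[keep]
    else:
        areas = np.empty(0)
    nuc_mask = labels > 0

    collagen = spec.collagen_od[0] + (spec.collagen_od[1] - spec.collagen_od[0]) * activity
    hema = collagen.copy()
    hema[chromatin == MEDIUM] = spec.od_medium
    hema[chromatin == STRONG] = spec.od_strong
    hema += rng.normal(0.0, spec.noise_od_sigma, size=(h, w))
    np.clip(hema, 0.0, None, out=hema)

    if spec.dab_localization == "nuclear":
        dab_mask = nuc_mask
    else:
        cyto_px = max(1, int(round(spec.cytoplasm_radius_um / mpp)))
        dilated = ndi.binary_dilation(nuc_mask, iterations=cyto_px)
        cyto = dilated & ~nuc_mask
        dab_mask = dilated if spec.dab_localization == "both" else cyto
    dab = np.zeros((h, w))
    dab[dab_mask] = spec.dab_base + spec.dab_gain * activity[dab_mask]
    dab[dab_mask] += rng.normal(0.0, spec.noise_od_sigma, size=int(dab_mask.sum()))
    np.clip(dab, 0.0, None, out=dab)

    exclusions: list[Annotation] = []
    artifact_extra = np.zeros((h, w))
    for _ in range(spec.n_artifacts):
        rad_px = spec.artifact_radius_um / mpp
        cr = rng.uniform(rad_px, h - rad_px)
        cc_ = rng.uniform(rad_px, w - rad_px)
        poly = Point(cc_ + 0.0, cr + 0.0).buffer(rad_px, quad_segs=16)
        exclusions.append(Annotation(poly, "exclude"))
        yy, xx = np.ogrid[:h, :w]
        inside = (yy - cr) ** 2 + (xx - cc_) ** 2 <= rad_px**2
        artifact_extra[inside] = 0.5  # dark tissue-fold artifact

    v_h, v_d = model.vectors[0], model.vectors[1]
    od_stained = hema[..., None] * v_h + dab[..., None] * v_d + artifact_extra[..., None]
    od_control = hema[..., None] * v_h + artifact_extra[..., None]
    stained = RgbImage(od_to_rgb(od_stained, model.background), mpp)
    control = RgbImage(od_to_rgb(od_control, model.background), mpp)
    truth = SlideTruth(
        activity=activity,
        nuclei_labels=labels,
        nucleus_areas_um2=areas,
        chromatin_class=chromatin,
        hema_concentration=hema,
        dab_concentration=dab,
        od=od_stained,
        exclusions=AnnotationSet(tuple(exclusions)),
        seed=seed,
    )
    return stained, control, truth


def truth_cdr(truth: SlideTruth, region: tuple[slice, slice] | None = None) -> float:
    """The generator's own CDR over a region: medium / strong painted area."""
    chrom = truth.chromatin_class if region is None else truth.chromatin_class[region]
    medium = int(np.sum(chrom == MEDIUM))
    strong = int(np.sum(chrom == STRONG))
    return medium / strong if strong else math.nan


def truth_by_tile(truth: SlideTruth, grid: RoiGrid) -> pd.DataFrame:
    """Per-tile ground truth: CDR, nuclear pixel count, mean nucleus area.

    A nucleus belongs to the tile containing its centroid.
    """
    cents = ndi.center_of_mass(
        truth.nuclei_labels > 0, truth.nuclei_labels,
        index=np.arange(1, truth.n_nuclei + 1),
    ) if truth.n_nuclei else []
    cents = np.asarray(cents).reshape(-1, 2)
    rows = []
    for tile in grid.tiles:
        sl = tile.slices()
        chrom = truth.chromatin_class[sl]
        medium = int(np.sum(chrom == MEDIUM))
        strong = int(np.sum(chrom == STRONG))
        in_tile = np.array(
            [tile.y0 <= r < tile.y1 and tile.x0 <= c < tile.x1 for r, c in cents],
            dtype=bool,
        ) if len(cents) else np.empty(0, dtype=bool)
        tile_areas = truth.nucleus_areas_um2[in_tile] if len(cents) else np.empty(0)
        rows.append(
            dict(
                roi_id=tile.roi_id,
                truth_cdr=medium / strong if strong else math.nan,
                truth_medium_px=medium,
                truth_strong_px=strong,
                truth_nuclear_px=medium + strong,
                truth_n_nuclei=int(in_tile.sum()) if len(cents) else 0,
                truth_mean_area_um2=float(tile_areas.mean()) if len(tile_areas) else math.nan,
                truth_mean_activity=float(truth.activity[sl].mean()),
                truth_mean_dab=float(truth.dab_concentration[sl].mean()),
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort generator (tabular)
# ---------------------------------------------------------------------------

DEFAULT_STAIN_GAINS = {
    "dab_fap": 12.0,
    "dab_adam12": 8.0,
    "dab_wisp1": 5.0,
    "dab_sox11": 1.5,
}
DEFAULT_OUTCOME_DELTAS = {
    "dab_adam12": 4.0,
    "dab_fap": 5.0,
    "dab_wisp1": 3.5,
    "dab_sox11": -2.5,
}


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Hierarchical cohort with latent per-ROI activity.

    The latent z for an ROI is patient + sample + ROI Gaussian effects; the
    activity is a = Phi(z / sd_total), giving a uniform [0, 1] marginal
    with Var(a) = 1/12, so analytic correlations of coupled measurements
    follow from the variance decomposition. Defaults mirror the real study
    design: 29 patients, ~11 ROIs per patient, a 5-vs-7 expression-set
    split among the first 12 patients, and 6 non-recurring vs 7 early-
    recurring patients among those with follow-up.
    """

    n_patients: int = 29
    samples_per_patient: int = 1
    rois_per_sample: int = 11
    patient_sd: float = 0.5
    sample_sd: float = 0.3
    roi_sd: float = 0.8
    # couplings to activity
    size_intercept: float = math.log(25.0)  # log um^2
    beta_size: float = 0.8
    size_noise_sd: float = 0.25
    cdr_intercept: float = math.log(0.35)
    beta_cdr: float = 2.0
    cdr_noise_sd: float = 0.5
    stain_base: float = 5.0
    stain_gains: dict = field(default_factory=lambda: dict(DEFAULT_STAIN_GAINS))
    stain_noise_sd: float = 4.0
    stain_patient_sd: float = 1.5
    mta_cutpoints: tuple[float, float, float] = (0.3, 0.5, 0.7)
    mta_noise_sd: float = 0.15
    # group structure
    n_set_a: int = 5
    n_set_b: int = 7
    set_b_wisp1_delta: float = 4.0
    n_no_recur: int = 6
    n_recur: int = 7
    outcome_deltas: dict = field(default_factory=lambda: dict(DEFAULT_OUTCOME_DELTAS))

    def __post_init__(self) -> None:
        for name in ("patient_sd", "sample_sd", "roi_sd", "size_noise_sd",
                     "cdr_noise_sd", "stain_noise_sd", "stain_patient_sd",
                     "mta_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_patients < 1 or self.samples_per_patient < 1 or self.rois_per_sample < 1:
            raise ValueError("group sizes must be >= 1")
        if self.n_set_a + self.n_set_b > self.n_patients:
            raise ValueError("expression sets exceed cohort size")
        if self.n_no_recur + self.n_recur > self.n_patients:
            raise ValueError("outcome groups exceed cohort size")

    @property
    def sd_total(self) -> float:
        return math.sqrt(self.patient_sd**2 + self.sample_sd**2 + self.roi_sd**2)

    def analytic_correlation(self, which: str = "size_cdr") -> float:
        """Expected marginal Pearson correlation implied by the couplings."""
        var_a = 1.0 / 12.0
        sd_size = math.sqrt(self.beta_size**2 * var_a + self.size_noise_sd**2)
        sd_cdr = math.sqrt(self.beta_cdr**2 * var_a + self.cdr_noise_sd**2)
        if which == "size_cdr":
            return self.beta_size * self.beta_cdr * var_a / (sd_size * sd_cdr)
        if which.startswith("dab_"):
            gain = self.stain_gains[which]
            # group shifts are independent of activity: they add variance
            # (Bernoulli mixture) but no covariance with log CDR
            p_recur = self.n_recur / self.n_patients
            extra = self.outcome_deltas.get(which, 0.0) ** 2 * p_recur * (1 - p_recur)
            if which == "dab_wisp1":
                p_b = self.n_set_b / self.n_patients
                extra += self.set_b_wisp1_delta**2 * p_b * (1 - p_b)
            sd_stain = math.sqrt(
                gain**2 * var_a + self.stain_noise_sd**2
                + self.stain_patient_sd**2 + extra
            )
            return gain * self.beta_cdr * var_a / (sd_stain * sd_cdr)
        raise ValueError(which)


def generate_cohort(spec: SyntheticCohortSpec, seed: int) -> pd.DataFrame:
    """Draw one cohort table (one row per ROI)."""
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    n_rows = spec.n_patients * spec.samples_per_patient * spec.rois_per_sample
    pat = np.repeat(np.arange(spec.n_patients),
                    spec.samples_per_patient * spec.rois_per_sample)
    samp = np.tile(
        np.repeat(np.arange(spec.samples_per_patient), spec.rois_per_sample),
        spec.n_patients,
    )
    z = (
        rng.normal(0, spec.patient_sd, spec.n_patients)[pat]
        + rng.normal(0, spec.sample_sd, spec.n_patients * spec.samples_per_patient)[
            pat * spec.samples_per_patient + samp
        ]
        + rng.normal(0, spec.roi_sd, n_rows)
    )
    a = norm.cdf(z / spec.sd_total)

    log_size = spec.size_intercept + spec.beta_size * a + rng.normal(0, spec.size_noise_sd, n_rows)
    log_cdr = spec.cdr_intercept + spec.beta_cdr * a + rng.normal(0, spec.cdr_noise_sd, n_rows)
    mta = 1 + np.sum(
        (a + rng.normal(0, spec.mta_noise_sd, n_rows))[:, None]
        > np.asarray(spec.mta_cutpoints)[None, :],
        axis=1,
    )

    # group labels (patient-level)
    perm = rng.permutation(spec.n_patients)
    expr = np.array([None] * spec.n_patients, dtype=object)
    expr[perm[: spec.n_set_a]] = "A"
    expr[perm[spec.n_set_a : spec.n_set_a + spec.n_set_b]] = "B"
    perm2 = rng.permutation(spec.n_patients)
    outcome = np.array(["unknown"] * spec.n_patients, dtype=object)
    outcome[perm2[: spec.n_no_recur]] = "no_recur_ge_5y"
    outcome[perm2[spec.n_no_recur : spec.n_no_recur + spec.n_recur]] = "recur_le_1y"

    df = pd.DataFrame(
        {
            "patient_id": [f"P{i + 1:02d}" for i in pat],
            "sample_id": [f"P{i + 1:02d}_S{j + 1}" for i, j in zip(pat, samp)],
            "roi_id": [f"roi{i:04d}" for i in range(n_rows)],
            "activity": a,
            "avg_nuclear_size_um2": np.exp(log_size),
            "log_nuclear_size": log_size,
            "cdr": np.exp(log_cdr),
            "log_cdr": log_cdr,
            "mta": mta.astype(int),
            "expression_set": expr[pat],
            "outcome": outcome[pat],
        }
    )
    recur = outcome[pat] == "recur_le_1y"
    for stain, gain in spec.stain_gains.items():
        pat_eff = rng.normal(0, spec.stain_patient_sd, spec.n_patients)[pat]
        val = (
            spec.stain_base
            + gain * a
            + pat_eff
            + rng.normal(0, spec.stain_noise_sd, n_rows)
        )
        val = val + spec.outcome_deltas.get(stain, 0.0) * recur
        if stain == "dab_wisp1":
            val = val + spec.set_b_wisp1_delta * (expr[pat] == "B")
        df[stain] = val
    return df


def recovery_cohort_spec() -> SyntheticCohortSpec:
    """Cohort used for the coupling-recovery experiment.

    Larger and less noisy than the study-sized default — 40 patients x 2
    samples x 6 ROIs with well-separated stain gains — chosen a priori so a
    single simulated cohort has the power to resolve the generated ordering
    of stain-CDR correlations and the sign pattern of outcome shifts.
    """
    return SyntheticCohortSpec(
        n_patients=40,
        samples_per_patient=2,
        rois_per_sample=6,
        cdr_noise_sd=0.3,
        stain_gains={"dab_fap": 14.0, "dab_adam12": 8.0,
                     "dab_wisp1": 4.5, "dab_sox11": 1.2},
        stain_noise_sd=2.5,
        stain_patient_sd=0.8,
        n_set_a=10,
        n_set_b=10,
        set_b_wisp1_delta=1.5,
        n_no_recur=20,
        n_recur=20,
        outcome_deltas={"dab_adam12": 2.0, "dab_fap": 2.5,
                        "dab_wisp1": 2.0, "dab_sox11": -1.5},
    )


# ---------------------------------------------------------------------------
# fixture writer
# ---------------------------------------------------------------------------

FIXTURE_SCALES = {
    "small": dict(shape_px=(1000, 1000), n_artifacts=1),
    "standard": dict(shape_px=(2000, 2500), n_artifacts=2),
}


def write_fixture_set(out_dir: str | Path, scale: str = "small", seed: int = 0) -> dict:
    """Write a complete on-disk fixture: slides, annotations, truth, cohort.

    Layout: ``<stain>.tif`` + ``<stain>_control.tif`` image pairs,
    ``<stain>_exclusions.geojson`` truth annotations, ``truth_tiles.csv``
    and ``truth_nuclei.csv`` tables, ``cohort.csv``, and ``manifest.json``
    recording the seed, the specs, and a content hash of every file.
    """
    if scale not in FIXTURE_SCALES:
        raise ValueError(f"scale must be one of {sorted(FIXTURE_SCALES)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    overrides = FIXTURE_SCALES[scale]
    stains = {"fap": "cytoplasmic", "sox11": "nuclear"}
    files: list[Path] = []
    specs: dict[str, dict] = {}
    from .tiling import build_grid

    nuclei_rows = []
    tile_rows = []
    for i, (stain, loc) in enumerate(stains.items()):
        spec = SyntheticSlideSpec(dab_localization=loc, **overrides)
        specs[stain] = asdict(spec)
        stained, control, truth = generate_slide(spec, seed=seed + i)
        for name, img in ((f"{stain}.tif", stained), (f"{stain}_control.tif", control)):
            write_image(out / name, img)
            files.append(out / name)
        geo = out / f"{stain}_exclusions.geojson"
        truth.exclusions.to_geojson(geo)
        files.append(geo)
        grid = build_grid(stained, truth.exclusions)
        tt = truth_by_tile(truth, grid)
        tt.insert(0, "stain", stain)
        tile_rows.append(tt)
        nuclei_rows.append(
            pd.DataFrame(
                {
                    "stain": stain,
                    "label": np.arange(1, truth.n_nuclei + 1),
                    "area_um2": truth.nucleus_areas_um2,
                }
            )
        )
    pd.concat(tile_rows, ignore_index=True).to_csv(out / "truth_tiles.csv", index=False)
    pd.concat(nuclei_rows, ignore_index=True).to_csv(out / "truth_nuclei.csv", index=False)
    files += [out / "truth_tiles.csv", out / "truth_nuclei.csv"]
    cohort_spec = SyntheticCohortSpec()
    generate_cohort(cohort_spec, seed=seed + 100).to_csv(out / "cohort.csv", index=False)
    files.append(out / "cohort.csv")

    manifest = {
        "seed": seed,
        "scale": scale,
        "slide_specs": specs,
        "cohort_spec": asdict(cohort_spec),
        "files": {
            f.name: hashlib.sha256(f.read_bytes()).hexdigest() for f in sorted(files)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
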