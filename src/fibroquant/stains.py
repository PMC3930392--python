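"""H-DAB color deconvolution and intensity stratification.

Brightfield absorbance follows the Beer-Lambert law: for each RGB channel
the optical density is OD_c = log10(I0_c / I_c), and ODs of co-localized
stains add. A stain is a unit direction in OD space; an image of two stains
plus a residual is a per-pixel linear combination of three such directions.
Inverting that 3x3 mixing matrix recovers per-stain amounts
("concentrations", in OD units along the stain vector) even where the
stains overlap spatially.

Per-stain amounts are stratified into negative / weak / medium / strong
classes by three transmission-scale cutoffs, mimicking positive-pixel
counting as used in commercial IHC quantification: a pixel's stain amount c
is mapped back to the equivalent transmission I_eq = I0 * 10**(-c) and
compared against the cutoffs, ties going to the darker class. Strata are
cumulative (a strong pixel is also medium and weak).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import RgbImage

# Published H-DAB stain directions (per-channel OD absorbances, unit norm
# after normalization): hematoxylin, DAB. The residual completes the basis.
RUIFROK_HEMATOXYLIN = (0.650, 0.704, 0.286)
RUIFROK_DAB = (0.269, 0.568, 0.778)

NEGATIVE, WEAK, MEDIUM, STRONG = 0, 1, 2, 3
CLASS_NAMES = ("negative", "weak", "medium", "strong")

STAIN_NAMES = ("hematoxylin", "dab", "residual")


class DegenerateStainModelError(ValueError):
    """Stain matrix is singular or numerically unusable."""


class InvalidBackgroundError(ValueError):
    """Blank-field intensity contains a zero channel."""


class EmptyRegionError(ValueError):
    """A summary was requested over an empty pixel mask."""


@dataclass(frozen=True)
class StainModel:
    """Deconvolution basis: three unit OD direction vectors plus background.

    ``vectors`` rows are (hematoxylin, dab, residual); each row must have
    non-negative components and unit Euclidean norm, and the matrix must be
    invertible. ``background`` is the per-channel blank-field transmission.
    """

    vectors: np.ndarray
    background: np.ndarray = field(
        default_factory=lambda: np.array([255.0, 255.0, 255.0])
    )

    def __post_init__(self) -> None:
        v = np.asarray(self.vectors, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if v.shape != (3, 3):
            raise ValueError("vectors must be a 3x3 matrix (rows = stains)")
        # physical stains absorb in every channel; the residual completes
        # the basis orthogonally and may carry a negative component
        if np.any(v[:2] < -1e-12):
            raise ValueError("stain vector components must be non-negative")
        norms = np.linalg.norm(v, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("each stain vector must have unit norm (+/-1e-9)")
        if np.any(bg <= 0) or np.any(bg > 255):
            raise InvalidBackgroundError("background channels must be in (0, 255]")
        try:
            cond = np.linalg.cond(v)
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise DegenerateStainModelError(str(exc)) from exc
        if not np.isfinite(cond) or cond > 1e8:
            raise DegenerateStainModelError(
                f"stain matrix is (near-)singular, condition number {cond:.3g}"
            )
        object.__setattr__(self, "vectors", v)
        object.__setattr__(self, "background", bg)

    @classmethod
    def hdab(cls, background: float | tuple[float, float, float] = 255.0) -> "StainModel":
        """Standard hematoxylin + DAB basis with orthogonal residual."""
        h = np.array(RUIFROK_HEMATOXYLIN, dtype=float)
        d = np.array(RUIFROK_DAB, dtype=float)
        h /= np.linalg.norm(h)
        d /= np.linalg.norm(d)
        r = np.cross(h, d)
        r /= np.linalg.norm(r)
        bg = np.broadcast_to(np.asarray(background, dtype=float), (3,)).copy()
        return cls(np.stack([h, d, r]), bg)

    @property
    def inverse(self) -> np.ndarray:
        """Inverse of the mixing matrix, mapping OD -> concentrations."""
        return np.linalg.inv(self.vectors)


def rgb_to_od(
    image: RgbImage | np.ndarray,
    background: np.ndarray | tuple[float, float, float] = (255.0, 255.0, 255.0),
    i_min: float = 1.0,
) -> np.ndarray:
    """Convert 8-bit RGB transmission to per-channel optical density.

    ``od_c = log10(background_c / max(I_c, i_min))``, with negative values
    (pixels brighter than the blank field) clipped to zero. The intensity
    floor ``i_min`` bounds the OD of fully dark pixels.
    """
    px = image.pixels if isinstance(image, RgbImage) else np.asarray(image)
    bg = np.asarray(background, dtype=float)
    if np.any(bg <= 0):
        raise InvalidBackgroundError("background channels must be positive")
    od = np.log10(bg / np.maximum(px.astype(float), i_min))
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, background=(255.0, 255.0, 255.0)) -> np.ndarray:
    """Inverse Beer-Lambert: OD back to quantized 8-bit transmission."""
    bg = np.asarray(background, dtype=float)
    trans = bg * np.power(10.0, -np.asarray(od, dtype=float))
    return np.clip(np.rint(trans), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, model: StainModel, clip: bool = True) -> np.ndarray:
    """Separate an OD image into per-stain concentration maps.

    Solves, per pixel, the linear system ``od = conc @ model.vectors``.
    Returns an ``(H, W, 3)`` array ordered (hematoxylin, dab, residual).
    With ``clip=True`` (default) negative solutions — physically meaningless
    stain amounts produced by noise — are set to zero.
    """
    od = np.asarray(od, dtype=float)
    conc = od @ model.inverse
    if clip:
        conc = np.clip(conc, 0.0, None)
    return conc


def recompose(conc: np.ndarray, model: StainModel) -> np.ndarray:
    """Map concentration maps back to a per-channel OD image."""
    return np.asarray(conc, dtype=float) @ model.vectors


def quantization_od_bound(
    pixels: np.ndarray,
    background: np.ndarray | tuple[float, float, float] = (255.0, 255.0, 255.0),
    i_min: float = 1.0,
) -> np.ndarray:
    """Per-pixel, per-channel OD uncertainty induced by 8-bit quantization.

    A quantized channel value q constrains the pre-quantization intensity to
    [q - 0.5, q + 0.5], so the OD is known to within
    log10((q + 0.5) / max(q - 0.5, i_min)). Matrix-multiplying this bound by
    the absolute inverse stain matrix bounds the concentration error.
    """
    q = np.maximum(np.asarray(pixels, dtype=float), i_min)
    return np.log10((q + 0.5) / np.maximum(q - 0.5, i_min * 0.5))


@dataclass(frozen=True)
class IntensityThresholds:
    """Descending transmission cutoffs (0-255 scale) bounding the strata.

    A pixel with equivalent transmission I_eq is strong if I_eq <= strong,
    else medium if I_eq <= medium, else weak if I_eq <= weak, else negative.
    Defaults are the widely used positive-pixel values; real calibrations
    are stain- and scanner-dependent and should be overridden.
    """

    weak: float = 220.0
    medium: float = 175.0
    strong: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.strong < self.medium < self.weak <= 255):
            raise ValueError(
                "thresholds must satisfy 0 <= strong < medium < weak <= 255"
            )


def equivalent_transmission(conc: np.ndarray, background: float = 255.0) -> np.ndarray:
    """Transmission a pure stain at amount ``conc`` would produce."""
    return background * np.power(10.0, -np.asarray(conc, dtype=float))


def concentration_cutoff(transmission: float, background: float = 255.0) -> float:
    """Concentration equivalent of a transmission-scale cutoff."""
    return float(np.log10(background / transmission))


def classify_intensity(
    conc: np.ndarray,
    thresholds: IntensityThresholds,
    background: float = 255.0,
) -> np.ndarray:
    """Label each pixel's stain amount as negative/weak/medium/strong.

    Ties at a cutoff go to the darker (more positive) class. Labels are
    exhaustive and mutually exclusive; strata built from them downstream
    are cumulative. The comparison runs in concentration space (the cutoffs
    are converted, not the pixels) so a concentration computed from a
    transmission exactly at a cutoff lands in the darker class.
    """
    conc = np.asarray(conc, dtype=float)
    labels = np.full(conc.shape, NEGATIVE, dtype=np.uint8)
    labels[conc >= concentration_cutoff(thresholds.weak, background)] = WEAK
    labels[conc >= concentration_cutoff(thresholds.medium, background)] = MEDIUM
    labels[conc >= concentration_cutoff(thresholds.strong, background)] = STRONG
    return labels


@dataclass(frozen=True)
class StainSummary:
    """Per-region positive-pixel report for one stain.

    Percent strata are cumulative (strong subset of medium subset of weak);
    ``avg_od`` is the mean stain amount over positive (non-negative-class)
    pixels only, so it measures stain darkness independently of the
    positive-area fraction.
    """

    pct_weak: float
    pct_medium: float
    pct_strong: float
    avg_od: float
    n_pixels: int

    def __post_init__(self) -> None:
        if not (0 <= self.pct_strong <= self.pct_medium <= self.pct_weak <= 100):
            raise ValueError("strata must be cumulative percentages in [0, 100]")
        if self.avg_od < 0:
            raise ValueError("avg_od must be non-negative")

    @property
    def pct_medium_exclusive(self) -> float:
        """Percent in the medium-but-not-strong band."""
        return self.pct_medium - self.pct_strong

    @property
    def pct_weak_exclusive(self) -> float:
        return self.pct_weak - self.pct_medium


def summarize_stain(
    labels: np.ndarray,
    conc: np.ndarray,
    mask: np.ndarray | None = None,
) -> StainSummary:
    """Aggregate a label map + concentration map over a region mask."""
    labels = np.asarray(labels)
    conc = np.asarray(conc, dtype=float)
    if mask is None:
        mask = np.ones(labels.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise EmptyRegionError("cannot summarize an empty region")
    lab = labels[mask]
    positive = lab >= WEAK
    pct_weak = 100.0 * positive.mean()
    pct_medium = 100.0 * (lab >= MEDIUM).mean()
    pct_strong = 100.0 * (lab >= STRONG).mean()
    avg_od = float(conc[mask][positive].mean()) if positive.any() else 0.0
    return StainSummary(pct_weak, pct_medium, pct_strong, avg_od, n)
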