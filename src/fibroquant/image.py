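"""Brightfield image container and TIFF/PNG I/O.

Slides are plain single-plane 8-bit RGB images on a 0-255 transmission
scale. The physical pixel size (microns per pixel) travels with the array;
it is read from TIFF resolution tags when present and can always be
supplied explicitly.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image


@dataclass(frozen=True)
class RgbImage:
    """An 8-bit RGB brightfield image with a physical scale.

    Parameters
    ----------
    pixels
        ``(H, W, 3)`` uint8 array, 0-255 transmission scale.
    microns_per_pixel
        Physical edge length of one pixel in micrometers; must be > 0.
    """

    pixels: np.ndarray
    microns_per_pixel: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected (H, W, 3) array, got shape {px.shape}")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        object.__setattr__(self, "pixels", px.astype(np.uint8, copy=False))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def read_image(path: str | Path, microns_per_pixel: float | None = None) -> RgbImage:
    """Read an 8-bit RGB TIFF or PNG.

    For TIFF, the scale is taken from the XResolution tag (pixels per
    centimeter or inch) unless ``microns_per_pixel`` is given, which always
    wins. For PNG (or tag-less TIFF) the scale must be supplied.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            px = page.asarray()
            if microns_per_pixel is None:
                microns_per_pixel = _mpp_from_tags(page)
    else:
        px = np.asarray(Image.open(path).convert("RGB"))
    if microns_per_pixel is None:
        raise ValueError(
            f"{path}: no resolution metadata; pass microns_per_pixel explicitly"
        )
    return RgbImage(px, microns_per_pixel)


def _mpp_from_tags(page: "tifffile.TiffPage") -> float | None:
    tags = page.tags
    if "XResolution" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value if "ResolutionUnit" in tags else 2
    px_per_unit = num / den
    unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit))  # inch, cm
    if unit_um is None:
        return None
    return unit_um / px_per_unit


def write_image(path: str | Path, image: RgbImage) -> None:
    """Write TIFF (with resolution tags encoding the scale) or PNG."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        px_per_cm = 10000.0 / image.microns_per_pixel
        tifffile.imwrite(
            path,
            image.pixels,
            photometric="rgb",
            resolution=(px_per_cm, px_per_cm),
            resolutionunit="CENTIMETER",
        )
    else:
        Image.fromarray(image.pixels).save(path)
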