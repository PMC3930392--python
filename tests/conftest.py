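"""Shared fixtures: synthetic slides and their pipeline measurements.

Slides are generated once per session; nothing is read from disk except in
the fixture-set round-trip tests, which write to tmp dirs.
"""
from __future__ import annotations

import numpy as np
import pytest

from fibroquant.pipeline import measure_slide
from fibroquant.stains import StainModel
from fibroquant.synthetic import SyntheticSlideSpec, generate_slide, truth_by_tile
from fibroquant.tiling import build_grid


@pytest.fixture(scope="session")
def stain_model() -> StainModel:
    return StainModel.hdab()


@pytest.fixture(scope="session")
def small_slide():
    """Default 0.5 x 0.5 mm slide (4 ROIs), heterogeneous activity."""
    spec = SyntheticSlideSpec()
    stained, control, truth = generate_slide(spec, seed=1)
    return spec, stained, control, truth


@pytest.fixture(scope="session")
def standard_slide():
    """1.25 x 1.0 mm slide (20 ROIs) for recovery statistics."""
    spec = SyntheticSlideSpec(shape_px=(2000, 2500))
    stained, control, truth = generate_slide(spec, seed=101)
    return spec, stained, control, truth


@pytest.fixture(scope="session")
def measured_standard(standard_slide):
    """Per-ROI pipeline measurements merged with generator ground truth."""
    _, stained, control, truth = standard_slide
    grid = build_grid(stained)
    table = measure_slide(stained, control, grid, stain="fap")
    return table.merge(truth_by_tile(truth, grid), on="roi_id")


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
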