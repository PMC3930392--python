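"""Generator self-consistency, monotone emulation, and reproducibility."""
import json
import math

import numpy as np
import pandas as pd
import pytest

from fibroquant.morphometry import segment_nuclei
from fibroquant.pipeline import measure_slide
from fibroquant.stains import (
    MEDIUM,
    STRONG,
    StainModel,
    deconvolve,
    quantization_od_bound,
    rgb_to_od,
)
from fibroquant.synthetic import (
    PlacementError,
    SyntheticCohortSpec,
    SyntheticSlideSpec,
    generate_cohort,
    generate_slide,
    recovery_cohort_spec,
    truth_by_tile,
    truth_cdr,
    write_fixture_set,
)
from fibroquant.tiling import build_grid


class TestSlideGenerator:
    def test_zero_density_yields_blank_tissue(self):
        spec = SyntheticSlideSpec(density_low=0, density_high=0,
                                  shape_px=(300, 300))
        _, control, truth = generate_slide(spec, seed=0)
        assert truth.n_nuclei == 0
        model = StainModel.hdab()
        hema = deconvolve(rgb_to_od(control, model.background), model)[..., 0]
        assert segment_nuclei(hema, spec.microns_per_pixel).count == 0

    def test_activity_extremes_shape_nuclei_by_construction(self):
        lo = generate_slide(SyntheticSlideSpec(uniform_activity=0.0), seed=9)[2]
        hi = generate_slide(SyntheticSlideSpec(uniform_activity=1.0), seed=9)[2]
        assert hi.nucleus_areas_um2.mean() > 1.5 * lo.nucleus_areas_um2.mean()
        frac_strong = lambda t: np.sum(t.chromatin_class == STRONG) / np.sum(
            t.chromatin_class > 0
        )
        assert frac_strong(hi) < 0.3 < 0.7 < frac_strong(lo)
        assert hi.n_nuclei > lo.n_nuclei  # denser where active

    def test_truth_cdr_consistent_with_chromatin_classes(self, small_slide):
        """Re-aggregating the per-pixel classes reproduces the truth CDR."""
        _, stained, _, truth = small_slide
        grid = build_grid(stained)
        tt = truth_by_tile(truth, grid).set_index("roi_id")
        for tile in grid.tiles:
            chrom = truth.chromatin_class[tile.slices()]
            medium, strong = np.sum(chrom == MEDIUM), np.sum(chrom == STRONG)
            expect = medium / strong if strong else math.nan
            got = tt.loc[tile.roi_id, "truth_cdr"]
            assert got == pytest.approx(expect, nan_ok=True)
            assert truth_cdr(truth, tile.slices()) == pytest.approx(expect, nan_ok=True)

    def test_measured_od_within_quantization_bound_of_truth(self, small_slide):
        _, stained, _, truth = small_slide
        od = rgb_to_od(stained)
        bound = quantization_od_bound(stained.pixels)
        assert np.all(np.abs(od - truth.od) <= bound + 1e-12)

    def test_dab_gain_monotone_in_measured_score(self):
        """Raising the activity->DAB gain raises the measured DAB score."""
        scores = []
        for gain in (0.15, 0.45, 0.9):
            spec = SyntheticSlideSpec(
                shape_px=(500, 500), uniform_activity=0.6, dab_gain=gain
            )
            stained, control, _ = generate_slide(spec, seed=3)
            grid = build_grid(stained)
            table = measure_slide(stained, control, grid, "fap")
            scores.append(table["dab_score"].mean())
        assert scores[0] < scores[1] < scores[2]

    def test_touching_pairs_counted_after_watershed(self):
        spec = SyntheticSlideSpec(touching_fraction=0.3, uniform_activity=0.7)
        _, control, truth = generate_slide(spec, seed=5)
        model = StainModel.hdab()
        hema = deconvolve(rgb_to_od(control, model.background), model)[..., 0]
        ns = segment_nuclei(hema, spec.microns_per_pixel)
        assert ns.count == truth.n_nuclei

    def test_excessive_density_raises_placement_error(self):
        spec = SyntheticSlideSpec(
            shape_px=(300, 300), density_low=60000, density_high=60000
        )
        with pytest.raises(PlacementError, match="density"):
            generate_slide(spec, seed=0)

    def test_seed_reproducibility(self):
        spec = SyntheticSlideSpec(shape_px=(400, 400))
        a = generate_slide(spec, seed=8)
        b = generate_slide(spec, seed=8)
        c = generate_slide(spec, seed=9)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        assert np.array_equal(a[2].chromatin_class, b[2].chromatin_class)
        assert not np.array_equal(a[0].pixels, c[0].pixels)

    def test_artifact_exclusions_recorded_and_dark(self):
        spec = SyntheticSlideSpec(shape_px=(500, 500), n_artifacts=2)
        stained, _, truth = generate_slide(spec, seed=6)
        assert len(truth.exclusions.excludes) == 2
        poly = truth.exclusions.excludes[0]
        cx, cy = poly.centroid.x, poly.centroid.y
        inside = stained.pixels[int(cy), int(cx)].astype(int).sum()
        outside = int(np.median(stained.pixels.sum(axis=2)))
        assert inside < outside  # folds are darker than tissue


class TestCohortGenerator:
    def test_hierarchy_shape_and_labels(self):
        spec = SyntheticCohortSpec()
        df = generate_cohort(spec, seed=0)
        assert len(df) == 29 * 11
        assert df.patient_id.nunique() == 29
        assert set(df.mta.unique()) <= {1, 2, 3, 4}
        assert (df.groupby("patient_id")["outcome"].nunique() == 1).all()
        assert (df.outcome == "recur_le_1y").sum() == 7 * 11
        assert (df.expression_set == "B").sum() == 7 * 11

    def test_null_couplings_give_null_correlations(self):
        spec = SyntheticCohortSpec(
            beta_size=0.0, beta_cdr=0.0,
            stain_gains={"dab_fap": 0.0}, outcome_deltas={},
            set_b_wisp1_delta=0.0,
        )
        rs = []
        for s in range(50):
            df = generate_cohort(spec, seed=s)
            rs.append(np.corrcoef(df.log_nuclear_size, df.log_cdr)[0, 1])
        assert abs(np.mean(rs)) < 0.02

    def test_empirical_correlation_matches_variance_decomposition(self):
        """Mean sample correlation approaches the analytic value implied by
        the coupling coefficients and noise variances."""
        spec = SyntheticCohortSpec()
        target = spec.analytic_correlation("size_cdr")
        rs = [
            np.corrcoef(d.log_nuclear_size, d.log_cdr)[0, 1]
            for d in (generate_cohort(spec, seed=s) for s in range(30))
        ]
        assert np.mean(rs) == pytest.approx(target, abs=0.03)

    def test_stain_correlation_matches_analytic_target(self):
        spec = recovery_cohort_spec()
        for stain in ("dab_fap", "dab_sox11"):
            target = spec.analytic_correlation(stain)
            rs = [
                np.corrcoef(d[stain], d.log_cdr)[0, 1]
                for d in (generate_cohort(spec, seed=s) for s in range(20))
            ]
            assert np.mean(rs) == pytest.approx(target, abs=0.05)

    def test_gee_recovers_generated_group_shift(self):
        """The generated outcome-group shift is recovered within 2 robust
        SE in at least ~95% of replicate cohorts."""
        import warnings

        from fibroquant.stats import gee_group_compare

        spec = SyntheticCohortSpec()
        delta = spec.outcome_deltas["dab_fap"]
        hits = 0
        n_rep = 100
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in range(n_rep):
                df = generate_cohort(spec, seed=s)
                sub = df[df.outcome != "unknown"]
                res = gee_group_compare(sub, "dab_fap", "outcome")
                hits += abs(res.mean_difference - delta) <= 2 * res.robust_se
        assert hits / n_rep >= 0.90

    def test_seed_reproducibility(self):
        spec = SyntheticCohortSpec()
        pd.testing.assert_frame_equal(
            generate_cohort(spec, 3), generate_cohort(spec, 3)
        )

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            SyntheticCohortSpec(patient_sd=-1)
        with pytest.raises(ValueError):
            SyntheticCohortSpec(n_patients=5, n_no_recur=4, n_recur=4)
        with pytest.raises(ValueError):
            SyntheticSlideSpec(dab_localization="membranous")


class TestFixtureSet:
    @pytest.fixture(scope="class")
    def fixture_dir(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("fixture")
        manifest = write_fixture_set(out, scale="small", seed=7)
        return out, manifest

    def test_manifest_hashes_reproducible(self, fixture_dir, tmp_path):
        out, manifest = fixture_dir
        again = write_fixture_set(tmp_path / "again", scale="small", seed=7)
        assert manifest["files"] == again["files"]

    def test_fixture_readable_end_to_end(self, fixture_dir):
        from fibroquant.image import read_image
        from fibroquant.tiling import AnnotationSet

        out, manifest = fixture_dir
        img = read_image(out / "fap.tif")
        assert img.microns_per_pixel == pytest.approx(0.5, rel=1e-3)
        ann = AnnotationSet.from_geojson(out / "fap_exclusions.geojson")
        grid = build_grid(img, ann)
        assert len(grid.tiles) >= 1
        cohort = pd.read_csv(out / "cohort.csv")
        assert {"patient_id", "log_cdr", "mta"} <= set(cohort.columns)
        stored = json.loads((out / "manifest.json").read_text())
        assert stored["files"] == manifest["files"]
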