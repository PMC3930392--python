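"""Cluster bootstrap correlation and GEE group comparison."""
import warnings

import numpy as np
import pandas as pd
import pytest

from fibroquant.stats import (
    CannotBootstrapError,
    UndefinedCorrelationError,
    cluster_bootstrap_correlation,
    gee_group_compare,
    pearson_r,
    run_analysis_suite,
)
from fibroquant.synthetic import SyntheticCohortSpec, generate_cohort


def clustered_bivariate(rng, n_clusters=29, m=11, icc=0.2, rho=0.3):
    """Patient random effects + row noise with marginal correlation rho."""
    cov_u = np.array([[icc, rho * icc], [rho * icc, icc]])
    cov_e = np.array([[1 - icc, rho * (1 - icc)], [rho * (1 - icc), 1 - icc]])
    u = rng.multivariate_normal([0, 0], cov_u, n_clusters)
    e = rng.multivariate_normal([0, 0], cov_e, n_clusters * m)
    pat = np.repeat(np.arange(n_clusters), m)
    return pd.DataFrame(
        {"patient_id": pat, "x": u[pat, 0] + e[:, 0], "y": u[pat, 1] + e[:, 1]}
    )


class TestPearson:
    def test_perfect_positive_and_negative(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # oracle: explicit covariance / sd formula
        oracle = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert oracle == pytest.approx(0.6)
        assert pearson_r(x, y) == pytest.approx(0.6)

    def test_missing_pairs_dropped(self):
        x = [1, 2, 3, np.nan, 5]
        y = [2, 4, 6, 8, np.nan]
        assert pearson_r(x, y) == pytest.approx(1.0)

    def test_degenerate_inputs_signalled(self):
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 2], [3, 4])
        with pytest.raises(UndefinedCorrelationError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestClusterBootstrap:
    def test_perfectly_linear_data_gives_degenerate_ci(self):
        df = pd.DataFrame(
            {"patient_id": [0, 0, 1, 1, 2, 2, 3, 3], "x": range(8), "y": range(8)}
        )
        res = cluster_bootstrap_correlation(df, "x", "y", n_boot=100, seed=0)
        assert res.r == pytest.approx(1.0)
        assert (res.ci_low, res.ci_high) == (pytest.approx(1.0), pytest.approx(1.0))
        assert res.p == pytest.approx(2 / 100)

    def test_singleton_clusters_equal_ordinary_bootstrap(self, rng):
        """With one row per cluster the procedure must coincide with a
        plain case-resampling bootstrap run with the same seed discipline."""
        n = 40
        df = pd.DataFrame(
            {"patient_id": np.arange(n),
             "x": rng.normal(size=n),
             "y": rng.normal(size=n)}
        )
        res = cluster_bootstrap_correlation(
            df, "x", "y", n_boot=500, seed=11, ci_method="percentile"
        )
        # independent oracle: naive bootstrap with the identical rng pattern
        x, y = df["x"].to_numpy(), df["y"].to_numpy()
        oracle_rng = np.random.default_rng(11)
        reps = []
        for _ in range(500):
            idx = oracle_rng.integers(0, n, n)
            reps.append(np.corrcoef(x[idx], y[idx])[0, 1])
        lo, hi = np.percentile(reps, [2.5, 97.5])
        assert res.ci_low == pytest.approx(lo)
        assert res.ci_high == pytest.approx(hi)

    def test_seed_determinism(self, rng):
        df = clustered_bivariate(rng)
        a = cluster_bootstrap_correlation(df, "x", "y", n_boot=200, seed=5)
        b = cluster_bootstrap_correlation(df, "x", "y", n_boot=200, seed=5)
        c = cluster_bootstrap_correlation(df, "x", "y", n_boot=200, seed=6)
        assert a == b
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_too_few_clusters_rejected(self):
        df = pd.DataFrame({"patient_id": [0] * 5, "x": range(5), "y": range(5)})
        with pytest.raises(CannotBootstrapError):
            cluster_bootstrap_correlation(df, "x", "y")

    def test_ci_width_shrinks_with_more_clusters(self, rng):
        widths = []
        for k in (10, 40):
            w = []
            for _ in range(10):
                df = clustered_bivariate(rng, n_clusters=k)
                res = cluster_bootstrap_correlation(df, "x", "y", n_boot=300, seed=1)
                w.append(res.ci_high - res.ci_low)
            widths.append(np.mean(w))
        assert widths[1] < widths[0]

    def test_cluster_bootstrap_covers_where_naive_undercovers(self, rng):
        """On strongly clustered data the patient-level bootstrap keeps its
        nominal coverage while row-level resampling visibly loses it."""
        rho, n_rep = 0.5, 150
        cover_cluster = cover_naive = 0
        for _ in range(n_rep):
            df = clustered_bivariate(rng, n_clusters=12, m=15, icc=0.85, rho=rho)
            seed = int(rng.integers(2**31))
            res = cluster_bootstrap_correlation(df, "x", "y", n_boot=200, seed=seed)
            cover_cluster += res.ci_low <= rho <= res.ci_high
            naive = df.assign(patient_id=np.arange(len(df)))
            res_n = cluster_bootstrap_correlation(naive, "x", "y", n_boot=200, seed=seed)
            cover_naive += res_n.ci_low <= rho <= res_n.ci_high
        assert cover_naive / n_rep < 0.85
        assert cover_cluster / n_rep > 0.85
        assert cover_cluster - cover_naive > 0.1 * n_rep / n_rep


class TestGee:
    def two_groups(self, rng, delta=0.0, k1=6, k2=7, m=11, icc=0.5):
        rows = []
        for i in range(k1 + k2):
            grp = "g1" if i < k1 else "g2"
            u = rng.normal(0, np.sqrt(icc))
            for v in u + rng.normal(0, np.sqrt(1 - icc), m):
                rows.append(
                    {"patient_id": f"P{i}", "value": v + delta * (grp == "g2"),
                     "group": grp}
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_zero_difference_p_one(self):
        df = pd.DataFrame(
            {"patient_id": list("aabbccdd"), "value": [1.0] * 8,
             "group": ["g1"] * 4 + ["g2"] * 4}
        )
        res = gee_group_compare(df, "value", "group")
        assert res.mean_difference == pytest.approx(0.0)
        assert res.p == 1.0

    def test_singleton_clusters_match_sandwich_oracle(self, rng):
        """With one row per cluster the robust variance equals the HC0
        sandwich computed from first principles."""
        n = 30
        grp = np.array(["g1"] * 12 + ["g2"] * 18)
        y = rng.normal(size=n) + 0.8 * (grp == "g2")
        df = pd.DataFrame({"patient_id": np.arange(n), "value": y, "group": grp})
        res = gee_group_compare(df, "value", "group", cov_type="robust", use_t=False)
        # oracle: OLS + HC0 sandwich, written out longhand
        x = np.column_stack([np.ones(n), (grp == "g2").astype(float)])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        resid = y - x @ beta
        bread = np.linalg.inv(x.T @ x)
        meat = (x * resid[:, None] ** 2).T @ x
        v = bread @ meat @ bread
        assert res.mean_difference == pytest.approx(beta[1])
        assert res.robust_se == pytest.approx(np.sqrt(v[1, 1]), rel=1e-6)

    def test_balanced_clusters_estimate_is_difference_of_cluster_means(self, rng):
        df = self.two_groups(rng, delta=1.3, k1=5, k2=5, m=8)
        res = gee_group_compare(df, "value", "group")
        means = df.groupby(["group", "patient_id"])["value"].mean()
        oracle = means["g2"].mean() - means["g1"].mean()
        assert res.mean_difference == pytest.approx(oracle, abs=1e-8)

    def test_single_cluster_group_falls_back_to_ttest(self, rng):
        df = self.two_groups(rng, k1=1, k2=5)
        with pytest.warns(UserWarning, match="single cluster"):
            res = gee_group_compare(df, "value", "group")
        assert res.method == "cluster-mean-ttest"

    def test_type_i_error_calibrated_with_few_clusters(self, rng):
        """Null rejection rate stays near 5% at the study's 6-vs-7 design."""
        n_rep, rej = 300, 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for _ in range(n_rep):
                res = gee_group_compare(self.two_groups(rng), "value", "group")
                rej += res.p < 0.05
        tol = 3 * np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rej / n_rep - 0.05) < tol

    def test_recovers_generated_shift(self, rng):
        df = self.two_groups(rng, delta=2.0, k1=10, k2=10)
        res = gee_group_compare(df, "value", "group")
        assert res.mean_difference == pytest.approx(2.0, abs=3 * res.robust_se)
        assert res.p < 0.05


class TestAnalysisSuite:
    def test_missing_columns_enumerated(self):
        with pytest.raises(ValueError, match="mta"):
            run_analysis_suite(pd.DataFrame({"patient_id": [], "log_cdr": []}))

    def test_null_cohort_recovers_no_structure(self):
        spec = SyntheticCohortSpec(
            beta_size=0.0, beta_cdr=0.0,
            stain_gains={k: 0.0 for k in SyntheticCohortSpec().stain_gains},
            outcome_deltas={}, set_b_wisp1_delta=0.0,
        )
        df = generate_cohort(spec, seed=4)
        res = run_analysis_suite(df, n_boot=300, seed=4)
        corr = res[res.analysis == "correlation"]
        stain_rows = corr[corr.xvar.str.startswith("dab_")]
        assert stain_rows["estimate"].abs().max() < 0.25
        covers = (stain_rows.ci_low <= 0) & (0 <= stain_rows.ci_high)
        assert covers.mean() >= 0.75

    def test_coupled_cohort_recovers_structure(self):
        df = generate_cohort(SyntheticCohortSpec(), seed=12)
        res = run_analysis_suite(df, n_boot=300, seed=12)
        corr = res[res.analysis == "correlation"].set_index(["xvar", "yvar"])
        assert corr.loc[("log_nuclear_size", "log_cdr"), "estimate"] > 0.3
        assert corr.loc[("mta", "log_cdr"), "estimate"] > 0.3

    def test_report_deterministic(self, tmp_path):
        df = generate_cohort(SyntheticCohortSpec(), seed=2)
        paths = []
        for i in (1, 2):
            res = run_analysis_suite(df, n_boot=200, seed=9)
            p = tmp_path / f"out{i}.csv"
            res.to_csv(p, index=False)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
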