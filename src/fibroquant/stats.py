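"""Cluster-aware inference for patient -> sample -> ROI measurement tables.

Measurements from the same patient are correlated, so row-level standard
errors are too small. Two procedures respect the clustering:

* **Patient-resampling bootstrap** for Pearson correlations: patients
  (clusters) are resampled with replacement, every row of a sampled patient
  enters the replicate (duplicated clusters kept), and the correlation is
  recomputed per replicate. The 95% CI is the percentile interval; the
  two-sided p-value is twice the proportion of replicates whose correlation
  has the opposite sign to the point estimate, clipped to [2/B, 1].

* **GEE group comparison** with identity link and an exchangeable working
  correlation, clustered on patient. With as few as 6-7 clusters per group
  the conventional sandwich variance is anti-conservative, so the default
  uses the Mancl-DeRouen bias-reduced sandwich together with a
  t(n_clusters - 2) reference distribution; the plain robust sandwich is
  available via ``cov_type="robust"``.

All inference is deterministic given a seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


class UndefinedCorrelationError(ValueError):
    """Fewer than 3 complete pairs or zero variance."""


class CannotBootstrapError(ValueError):
    """Fewer than 2 clusters available."""


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation on complete pairs.

    Missing values are dropped pairwise. Raises on fewer than 3 complete
    pairs or zero variance in either variable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise UndefinedCorrelationError(f"only {len(x)} complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    n_pairs: int
    n_clusters: int
    n_boot: int
    seed: int
    n_failed: int = 0  # replicates with undefined correlation, skipped

    def __post_init__(self) -> None:
        if not (-1 - 1e-12 <= self.ci_low <= self.r + 1e-12
                and self.r - 1e-12 <= self.ci_high <= 1 + 1e-12):
            raise ValueError("CI must bracket the point estimate within [-1, 1]")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")


def cluster_bootstrap_correlation(
    table: pd.DataFrame,
    xvar: str,
    yvar: str,
    cluster: str = "patient_id",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
    ci_method: str = "expanded",
) -> CorrelationResult:
    """Pearson correlation with patient-cluster bootstrap CI and p-value.

    The default CI is the expanded percentile interval (Hesterberg 2015):
    the percentile levels are widened so the interval matches a t(K-1)
    rather than a normal reference, correcting the systematic narrowness
    of plain percentile intervals when the number of clusters K is small.
    ``ci_method="percentile"`` gives the unexpanded interval.

    Seed discipline: one ``numpy.random.default_rng(seed)`` stream; each
    replicate draws ``rng.integers(0, K, size=K)`` cluster indices in order,
    so results are exactly reproducible and, with singleton clusters,
    coincide with an ordinary case-resampling bootstrap run the same way.
    """
    if ci_method not in ("expanded", "percentile"):
        raise ValueError("ci_method must be 'expanded' or 'percentile'")
    df = table[[xvar, yvar, cluster]].dropna(subset=[xvar, yvar])
    clusters = df[cluster].unique()
    k = len(clusters)
    if k < 2:
        raise CannotBootstrapError(f"need >=2 clusters, have {k}")
    r_hat = pearson_r(df[xvar], df[yvar])

    x = df[xvar].to_numpy(float)
    y = df[yvar].to_numpy(float)
    # row indices per cluster, in first-appearance order
    codes = pd.Categorical(df[cluster], categories=clusters).codes
    order = np.argsort(codes, kind="stable")
    sorted_codes = codes[order]
    starts = np.searchsorted(sorted_codes, np.arange(k))
    ends = np.searchsorted(sorted_codes, np.arange(k), side="right")
    members = [order[s:e] for s, e in zip(starts, ends)]

    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    n_failed = 0
    for b in range(n_boot):
        pick = rng.integers(0, k, size=k)
        idx = np.concatenate([members[i] for i in pick])
        xb, yb = x[idx], y[idx]
        sx, sy = xb.std(), yb.std()
        if len(xb) < 3 or sx == 0 or sy == 0:
            reps[b] = np.nan
            n_failed += 1
            continue
        reps[b] = ((xb - xb.mean()) * (yb - yb.mean())).mean() / (sx * sy)
    valid = reps[np.isfinite(reps)]
    if len(valid) == 0:
        raise UndefinedCorrelationError("all bootstrap replicates undefined")
    alpha = 1 - ci_level
    if ci_method == "expanded":
        # widen tail levels so +/- z_{alpha'} matches sqrt(K/(K-1)) * t_{K-1}
        t_q = sps.t.ppf(1 - alpha / 2, k - 1)
        alpha = 2 * sps.norm.cdf(-math.sqrt(k / (k - 1)) * t_q)
    ci_low, ci_high = np.percentile(valid, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    ci_low = min(float(ci_low), r_hat)
    ci_high = max(float(ci_high), r_hat)
    n_valid = len(valid)
    opposite = np.sum(valid * r_hat < 0) / n_valid
    p = float(np.clip(2.0 * opposite, 2.0 / n_valid, 1.0))
    return CorrelationResult(
        r_hat, ci_low, ci_high, p, len(df), k, n_boot, seed, n_failed
    )


@dataclass(frozen=True)
class GroupComparisonResult:
    mean_difference: float
    robust_se: float
    p: float
    working_correlation: float
    n_clusters: dict = field(default_factory=dict)
    df: float = math.nan
    method: str = "gee"
    groups: tuple = ()


def gee_group_compare(
    table: pd.DataFrame,
    value_var: str,
    group_var: str,
    cluster: str = "patient_id",
    cov_type: str = "bias_reduced",
    use_t: bool = True,
) -> GroupComparisonResult:
    """Compare group means of a continuous measurement across two groups.

    GEE, Gaussian family with identity link, exchangeable working
    correlation, clustered on ``cluster``; the reported difference is
    group2 minus group1 (groups in sorted label order). If either group
    has a single cluster the model-free fallback is a Welch t-test on
    cluster means, flagged in ``method``.
    """
    df = table[[value_var, group_var, cluster]].dropna()
    groups = sorted(df[group_var].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, have {groups}")
    n_clusters = {
        g: df.loc[df[group_var] == g, cluster].nunique() for g in groups
    }
    if min(n_clusters.values()) < 2:
        import warnings

        warnings.warn(
            "a group has a single cluster; falling back to a cluster-mean t-test",
            stacklevel=2,
        )
        means = df.groupby([group_var, cluster])[value_var].mean()
        a = means[groups[0]].to_numpy()
        b = means[groups[1]].to_numpy()
        t, p = sps.ttest_ind(b, a, equal_var=False)
        se = abs((b.mean() - a.mean()) / t) if t != 0 else math.nan
        return GroupComparisonResult(
            float(b.mean() - a.mean()), float(se), float(p), math.nan,
            n_clusters, math.nan, "cluster-mean-ttest", tuple(groups),
        )

    y_all = df[value_var].to_numpy(float)
    if np.var(y_all) == 0:
        # constant response: the mean difference is exactly zero and no
        # sampling variability exists to weigh it against
        return GroupComparisonResult(
            0.0, 0.0, 1.0, 0.0, n_clusters,
            float(df[cluster].nunique() - 2), "gee-degenerate", tuple(groups),
        )
    indicator = (df[group_var] == groups[1]).astype(float)
    exog = sm.add_constant(indicator.to_numpy())
    model = sm.GEE(
        df[value_var].to_numpy(float),
        exog,
        groups=df[cluster].to_numpy(),
        family=sm.families.Gaussian(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit(cov_type=cov_type)
    diff = float(res.params[1])
    se = float(res.standard_errors(cov_type=cov_type)[1])
    k_total = int(df[cluster].nunique())
    dof = float(k_total - 2)
    if se == 0:
        p = 1.0
    else:
        stat = diff / se
        if use_t:
            p = float(2 * sps.t.sf(abs(stat), dof))
        else:
            p = float(2 * sps.norm.sf(abs(stat)))
    working = float(np.atleast_1d(res.cov_struct.dep_params)[0])
    return GroupComparisonResult(
        diff, se, p, working, n_clusters, dof, f"gee-{cov_type}", tuple(groups)
    )


REQUIRED_SUITE_COLUMNS = ("patient_id", "log_cdr", "log_nuclear_size", "mta")
DEFAULT_STAIN_COLUMNS = ("dab_adam12", "dab_fap", "dab_wisp1", "dab_sox11")


def run_analysis_suite(
    table: pd.DataFrame,
    stain_columns: tuple[str, ...] = DEFAULT_STAIN_COLUMNS,
    n_boot: int = 2000,
    seed: int = 0,
    outcome_levels: tuple[str, str] = ("no_recur_ge_5y", "recur_le_1y"),
) -> pd.DataFrame:
    """Run the full correlation / group-comparison battery.

    Emits one row per analysis: (a) log nuclear size vs log CDR; (b) MTA vs
    log CDR and vs log nuclear size; (c) each stain's DAB score vs log CDR;
    (d) GEE comparisons of each DAB score and of log CDR between expression
    sets A/B and between recurrence-outcome groups. p-values are raw
    (unadjusted); every row records n, clusters, replicate count and seed.
    """
    missing = [c for c in REQUIRED_SUITE_COLUMNS if c not in table.columns]
    missing += [c for c in stain_columns if c not in table.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    rows = []

    import logging

    logger = logging.getLogger(__name__)

    def corr(xvar: str, yvar: str, name: str, sub_seed: int) -> None:
        try:
            res = cluster_bootstrap_correlation(
                table, xvar, yvar, n_boot=n_boot, seed=sub_seed
            )
        except (UndefinedCorrelationError, CannotBootstrapError) as exc:
            logger.warning("skipping %s vs %s: %s", xvar, yvar, exc)
            return
        rows.append(
            dict(analysis=name, xvar=xvar, yvar=yvar, n=res.n_pairs,
                 n_clusters=res.n_clusters, estimate=res.r, ci_low=res.ci_low,
                 ci_high=res.ci_high, p=res.p, n_boot=n_boot, seed=sub_seed)
        )

    corr("log_nuclear_size", "log_cdr", "correlation", seed)
    corr("mta", "log_cdr", "correlation", seed + 1)
    corr("mta", "log_nuclear_size", "correlation", seed + 2)
    for i, stain in enumerate(stain_columns):
        corr(stain, "log_cdr", "correlation", seed + 3 + i)

    def compare(value_var: str, group_var: str, sub: pd.DataFrame, name: str) -> None:
        try:
            res = gee_group_compare(sub, value_var, group_var)
        except ValueError as exc:
            logger.warning("skipping %s by %s: %s", value_var, group_var, exc)
            return
        rows.append(
            dict(analysis=name, xvar=group_var, yvar=value_var,
                 n=len(sub.dropna(subset=[value_var, group_var])),
                 n_clusters=sum(res.n_clusters.values()),
                 estimate=res.mean_difference, ci_low=np.nan, ci_high=np.nan,
                 p=res.p, n_boot=0, seed=seed)
        )

    if "expression_set" in table.columns and table["expression_set"].notna().any():
        sub = table[table["expression_set"].isin(["A", "B"])]
        if sub["expression_set"].nunique() == 2:
            for stain in stain_columns:
                compare(stain, "expression_set", sub, "gee_expression_set")
            compare("log_cdr", "expression_set", sub, "gee_expression_set")
    if "outcome" in table.columns:
        sub = table[table["outcome"].isin(outcome_levels)]
        if sub["outcome"].nunique() == 2:
            for stain in stain_columns:
                compare(stain, "outcome", sub, "gee_outcome")
            compare("log_cdr", "outcome", sub, "gee_outcome")
    return pd.DataFrame(rows)
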