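"""Clinical metabotyping: impute, screen, scale, k-means, stability, profile.

The clustering substrate is the ten routinely available clinical variables
(age, ALT, AST, waist circumference, VLDL, LDL, triglycerides, HOMA2-IR, uric
acid, systolic blood pressure). The workflow is: median imputation of sparse
missingness, a single-pass >5-SD extreme-value screen, z-scaling, k-means
(Lloyd with k-means++ restarts), an index panel for choosing k, a permutation
null for cluster stability (independently permuting each column destroys row
structure while preserving marginals), and Table-1-style cluster profiling
with Kruskal-Wallis / Mann-Whitney / chi-squared / Fisher tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans as _SKKMeans
from sklearn.metrics import (
    calinski_harabasz_score,
    davies_bouldin_score,
    silhouette_samples,
)

__all__ = [
    "CLUSTERING_VARS",
    "ClusterModel",
    "StabilityReport",
    "ProfileReport",
    "KMetabotyper",
    "impute_median",
    "exclude_extreme",
    "zscore_scale",
    "kmeans",
    "silhouette",
    "select_k",
    "permutation_stability",
    "profile_clusters",
    "derive_vldl",
]

CLUSTERING_VARS = [
    "age", "alt", "ast", "wc", "vldl", "ldl", "tg", "homa2ir", "uric_acid", "sbp",
]

DEFAULT_K_GRID = tuple(range(2, 11))


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------


def impute_median(table: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Replace missing clustering-variable cells by the cohort median.

    Medians are computed over the observed values only; categorical and
    profiling columns are untouched. A fully missing column is an error.
    """
    variables = list(variables) if variables is not None else CLUSTERING_VARS
    out = table.copy()
    for var in variables:
        col = out[var]
        if col.isna().all():
            raise ValueError(f"column {var!r} is fully missing; cannot impute")
        out[var] = col.fillna(col.median())
    return out


def exclude_extreme(
    table: pd.DataFrame, threshold_sd: float = 5.0, variables=None
) -> tuple[pd.DataFrame, list[str]]:
    """Single-pass extreme-value screen on the raw clustering variables.

    A subject is excluded iff any clustering variable lies strictly more than
    ``threshold_sd`` sample SDs from the mean, with mean/SD computed once on
    the (post-imputation) input. Zero-variance variables are skipped with a
    warning. Returns the surviving table and the excluded subject ids.
    """
    variables = list(variables) if variables is not None else CLUSTERING_VARS
    if len(table) < 3:
        raise ValueError("need at least three subjects")
    mask = np.zeros(len(table), dtype=bool)
    for var in variables:
        col = table[var].to_numpy(float)
        mu = np.nanmean(col)
        sd = np.nanstd(col, ddof=1)
        if sd == 0:
            warnings.warn(f"zero-variance variable {var!r} skipped in extreme screen",
                          UserWarning, stacklevel=2)
            continue
        with np.errstate(invalid="ignore"):
            mask |= np.abs(col - mu) > threshold_sd * sd
    excluded = list(table.loc[mask, "subject_id"]) if "subject_id" in table else list(table.index[mask])
    return table.loc[~mask].reset_index(drop=True), excluded


def zscore_scale(matrix) -> tuple[np.ndarray, dict]:
    """Scale each column to mean 0 and sample SD 1 (denominator n-1)."""
    X = np.asarray(matrix, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        j = int(np.argmax(sd == 0))
        name = matrix.columns[j] if isinstance(matrix, pd.DataFrame) else j
        raise ValueError(f"constant column {name!r} cannot be z-scaled")
    return (X - mean) / sd, {"mean": mean, "sd": sd}


def derive_vldl(tg):
    """VLDL cholesterol estimated as triglycerides / 5 (mg/dL)."""
    tg = np.asarray(tg, dtype=float)
    if (tg < 0).any():
        raise ValueError("triglycerides must be non-negative")
    out = tg / 5.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# k-means
# ---------------------------------------------------------------------------


@dataclass
class ClusterModel:
    k: int
    centroids: np.ndarray
    assignments: np.ndarray
    wss: float
    mean_silhouette: float | None = None
    scaling_params: dict | None = None


class KMetabotyper(ClusterMixin, BaseEstimator):
    """k-means metabotyper: Lloyd iterations from k-means++ starts.

    sklearn-style estimator; ``n_start`` restarts are run and the solution
    with the lowest within-cluster sum of squares is kept. Deterministic for
    a fixed ``random_state``.
    """

    def __init__(self, k: int = 3, n_start: int = 25, max_iter: int = 1000,
                 random_state: int | None = None):
        self.k = k
        self.n_start = n_start
        self.max_iter = max_iter
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty input")
        if self.k < 1 or self.k > X.shape[0]:
            raise ValueError(f"k={self.k} invalid for n={X.shape[0]} points")
        km = _SKKMeans(
            n_clusters=self.k,
            init="k-means++",
            n_init=self.n_start,
            max_iter=self.max_iter,
            algorithm="lloyd",
            random_state=self.random_state,
        ).fit(X)
        self.cluster_centers_ = km.cluster_centers_
        self.labels_ = km.labels_
        self.wss_ = float(km.inertia_)
        if self.k >= 2 and len(np.unique(km.labels_)) >= 2:
            self.silhouette_samples_ = silhouette_samples(X, km.labels_)
            self.mean_silhouette_ = float(self.silhouette_samples_.mean())
        else:
            self.silhouette_samples_ = None
            self.mean_silhouette_ = None
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        d = ((X[:, None, :] - self.cluster_centers_[None]) ** 2).sum(axis=2)
        return d.argmin(axis=1)


def kmeans(matrix, k: int, n_start: int = 25, max_iter: int = 1000,
           seed: int | None = None, scaling_params: dict | None = None) -> ClusterModel:
    """Fit k-means and return the fitted partition as a :class:`ClusterModel`."""
    est = KMetabotyper(k=k, n_start=n_start, max_iter=max_iter, random_state=seed).fit(matrix)
    return ClusterModel(
        k=k,
        centroids=est.cluster_centers_,
        assignments=est.labels_,
        wss=est.wss_,
        mean_silhouette=est.mean_silhouette_,
        scaling_params=scaling_params,
    )


def silhouette(matrix, assignments) -> tuple[np.ndarray, float]:
    """Per-point silhouette widths s(i) = (b-a)/max(a,b) and their mean.

    Euclidean distance; a(i) is the mean intra-cluster distance excluding the
    point itself, b(i) the smallest mean distance to another cluster;
    singleton clusters score 0.
    """
    labels = np.asarray(assignments)
    if len(np.unique(labels)) < 2:
        raise ValueError("silhouette requires at least two clusters")
    s = silhouette_samples(np.asarray(matrix, dtype=float), labels)
    return s, float(s.mean())


# ---------------------------------------------------------------------------
# choosing k
# ---------------------------------------------------------------------------


@dataclass
class SelectKReport:
    table: pd.DataFrame  # per-k panel indices
    votes: dict[str, int]  # index name -> recommended k
    recommendation: int
    tie: bool


def _gap_statistic(X, k_grid, rng, n_refs: int = 50, n_start: int = 5):
    """Tibshirani gap statistic with uniform reference sets over the data box."""
    n, d = X.shape
    lo, hi = X.min(axis=0), X.max(axis=0)
    log_w = {}
    log_w_ref = {k: np.empty(n_refs) for k in k_grid}
    for k in k_grid:
        log_w[k] = np.log(
            _SKKMeans(k, n_init=n_start, random_state=int(rng.integers(2**31))).fit(X).inertia_
        )
    for b in range(n_refs):
        ref = rng.uniform(lo, hi, size=(n, d))
        for k in k_grid:
            log_w_ref[k][b] = np.log(
                _SKKMeans(k, n_init=n_start, random_state=int(rng.integers(2**31)))
                .fit(ref)
                .inertia_
            )
    gap = {k: log_w_ref[k].mean() - log_w[k] for k in k_grid}
    s = {k: log_w_ref[k].std(ddof=1) * np.sqrt(1 + 1 / n_refs) for k in k_grid}
    # smallest k with gap(k) >= gap(k+1) - s(k+1); fall back to argmax gap
    ks = list(k_grid)
    best = None
    for i, k in enumerate(ks[:-1]):
        if gap[k] >= gap[ks[i + 1]] - s[ks[i + 1]]:
            best = k
            break
    if best is None:
        best = max(ks, key=lambda k: gap[k])
    return gap, s, best


def select_k(matrix, k_grid=DEFAULT_K_GRID, seed: int | None = None,
             n_start: int = 25, n_gap_refs: int = 50) -> SelectKReport:
    """Recommend k by majority vote over a reduced clustering-index panel.

    Panel: mean silhouette (max), Calinski-Harabasz (max), Davies-Bouldin
    (min), gap statistic (first-rise rule), and the WSS elbow located at the
    maximum second difference of WSS over k (including k=1 as anchor). Ties go
    to the smallest k and are flagged.
    """
    X = np.asarray(matrix, dtype=float)
    ks = sorted(k_grid)
    if X.shape[0] <= max(ks):
        raise ValueError("need more rows than max(k_grid)")
    if np.allclose(X.var(axis=0), 0):
        raise ValueError("degenerate input: all rows identical")
    rng = np.random.default_rng(seed)

    rows = []
    fits = {}
    for k in ks:
        fit = KMetabotyper(k=k, n_start=n_start, random_state=int(rng.integers(2**31))).fit(X)
        fits[k] = fit
        rows.append(
            {
                "k": k,
                "wss": fit.wss_,
                "silhouette": fit.mean_silhouette_,
                "calinski_harabasz": calinski_harabasz_score(X, fit.labels_),
                "davies_bouldin": davies_bouldin_score(X, fit.labels_),
            }
        )
    table = pd.DataFrame(rows).set_index("k")

    gap, gap_s, gap_best = _gap_statistic(X, ks, rng, n_refs=n_gap_refs)
    table["gap"] = [gap[k] for k in ks]
    table["gap_se"] = [gap_s[k] for k in ks]

    # WSS elbow: maximum second difference over k, anchored at k=1 (total SS)
    wss1 = float(((X - X.mean(axis=0)) ** 2).sum())
    wss = {1: wss1, **{k: fits[k].wss_ for k in ks}}
    elbow_ks = [k for k in ks if (k - 1 in wss) and (k + 1 in wss)]
    second_diff = {k: wss[k - 1] - 2 * wss[k] + wss[k + 1] for k in elbow_ks}
    elbow_best = max(elbow_ks, key=lambda k: (second_diff[k], -k))

    votes = {
        "silhouette": int(table["silhouette"].idxmax()),
        "calinski_harabasz": int(table["calinski_harabasz"].idxmax()),
        "davies_bouldin": int(table["davies_bouldin"].idxmin()),
        "gap": int(gap_best),
        "wss_elbow": int(elbow_best),
    }
    counts: dict[int, int] = {}
    for k in votes.values():
        counts[k] = counts.get(k, 0) + 1
    top = max(counts.values())
    tied = sorted(k for k, c in counts.items() if c == top)
    return SelectKReport(
        table=table.reset_index(),
        votes=votes,
        recommendation=tied[0],
        tie=len(tied) > 1,
    )


# ---------------------------------------------------------------------------
# permutation stability
# ---------------------------------------------------------------------------


@dataclass
class StabilityReport:
    k_grid: tuple[int, ...]
    observed_silhouette: dict[int, float]
    permuted_silhouettes: np.ndarray  # B x |k_grid|
    empirical_p: dict[int, float]
    B: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": list(self.k_grid),
                "observed_silhouette": [self.observed_silhouette[k] for k in self.k_grid],
                "permuted_mean": self.permuted_silhouettes.mean(axis=0),
                "permuted_max": self.permuted_silhouettes.max(axis=0),
                "empirical_p": [self.empirical_p[k] for k in self.k_grid],
            }
        )


def permute_columns(X: np.ndarray, rng) -> np.ndarray:
    """Independently permute each column, preserving marginals exactly."""
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = X[rng.permutation(X.shape[0]), j]
    return out


def permutation_stability(matrix, B: int = 100, k_grid=DEFAULT_K_GRID,
                          seed: int | None = None, n_start: int = 25) -> StabilityReport:
    """Permutation null for cluster stability.

    For each of B randomized datasets (every column permuted independently,
    destroying row structure but preserving marginals) k-means is refit at
    every k and the mean silhouette recorded. The add-one-smoothed empirical
    p-value per k is (1 + #{permuted >= observed}) / (B + 1).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    X = np.asarray(matrix, dtype=float)
    ks = tuple(sorted(k_grid))
    rng = np.random.default_rng(seed)

    observed = {}
    for k in ks:
        fit = KMetabotyper(k=k, n_start=n_start, random_state=int(rng.integers(2**31))).fit(X)
        observed[k] = fit.mean_silhouette_

    perm = np.empty((B, len(ks)))
    for b in range(B):
        Xp = permute_columns(X, rng)
        for i, k in enumerate(ks):
            fit = KMetabotyper(k=k, n_start=n_start,
                               random_state=int(rng.integers(2**31))).fit(Xp)
            perm[b, i] = fit.mean_silhouette_

    pvals = {
        k: (1 + int((perm[:, i] >= observed[k]).sum())) / (B + 1)
        for i, k in enumerate(ks)
    }
    return StabilityReport(
        k_grid=ks,
        observed_silhouette=observed,
        permuted_silhouettes=perm,
        empirical_p=pvals,
        B=B,
    )


# ---------------------------------------------------------------------------
# cluster profiling
# ---------------------------------------------------------------------------


@dataclass
class ProfileReport:
    continuous_summary: pd.DataFrame  # variable x cluster medians/IQRs
    continuous_tests: pd.DataFrame  # Kruskal-Wallis omnibus
    continuous_pairwise: pd.DataFrame  # Mann-Whitney U per cluster pair
    categorical_summary: pd.DataFrame  # counts and percents
    categorical_tests: pd.DataFrame  # chi-squared / Fisher / Monte-Carlo
    categorical_pairwise: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def _mannwhitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration when both groups have at
    most 8 observations, tie/continuity-corrected normal approximation
    otherwise."""
    method = "exact" if (len(x) <= 8 and len(y) <= 8) else "asymptotic"
    try:
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    except ValueError:  # exact method refuses ties; fall back
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _categorical_test(table: np.ndarray, seed: int) -> tuple[str, float, float]:
    """Omnibus association test for a levels x clusters count table.

    Chi-squared when all expected counts reach 5; otherwise Fisher's exact
    (2x2, hypergeometric) or a Monte-Carlo chi-squared p over 10,000 random
    tables with fixed margins.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return "degenerate", np.nan, 1.0
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    if (expected >= 5).all():
        return "chi-squared", float(chi2), float(p)
    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
        return "fisher", np.nan, float(p)
    # Monte-Carlo chi-squared with fixed margins (Patefield sampler)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    draws = sampler.rvs(10000, random_state=rng)
    stat = ((draws - expected) ** 2 / expected).sum(axis=(1, 2))
    p_mc = (1 + int((stat >= chi2 - 1e-12).sum())) / (10000 + 1)
    return "chi-squared (Monte-Carlo)", float(chi2), float(p_mc)


def profile_clusters(table: pd.DataFrame, assignments, continuous=None,
                     categorical=None, seed: int = 0) -> ProfileReport:
    """Table-1-style cluster profiling.

    Continuous variables are summarized as median (IQR) per cluster with a
    tie-corrected Kruskal-Wallis omnibus test and pairwise Mann-Whitney U
    tests; categorical variables as counts (percent) with chi-squared /
    Fisher / Monte-Carlo tests. Pairwise p-values are reported unadjusted
    (flagged in ``metadata``).
    """
    labels = np.asarray(assignments)
    clusters = sorted(np.unique(labels))
    if len(clusters) < 2:
        raise ValueError("profiling needs at least two clusters")
    for c in clusters:
        if (labels == c).sum() < 2:
            raise ValueError(f"cluster {c} has fewer than two members")

    if continuous is None:
        continuous = [
            v for v in table.columns
            if v not in ("subject_id",) and pd.api.types.is_numeric_dtype(table[v])
            and table[v].nunique() > 8
        ]
    if categorical is None:
        categorical = [
            v for v in table.columns
            if v not in ("subject_id",) and v not in continuous
        ]

    cont_rows, kw_rows, mw_rows = [], [], []
    for var in continuous:
        groups = [table.loc[labels == c, var].dropna().to_numpy(float) for c in clusters]
        for c, g in zip(clusters, groups):
            q1, med, q3 = np.percentile(g, [25, 50, 75]) if len(g) else (np.nan,) * 3
            cont_rows.append({"variable": var, "cluster": c, "median": med, "q1": q1, "q3": q3})
        try:
            h, p = stats.kruskal(*groups)
        except ValueError:  # all values identical
            h, p = 0.0, 1.0
        kw_rows.append({"variable": var, "kw_h": float(h), "p": float(p)})
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                u, p2 = _mannwhitney(groups[i], groups[j])
                mw_rows.append(
                    {"variable": var, "cluster_a": clusters[i], "cluster_b": clusters[j],
                     "u": u, "p": p2}
                )

    cat_rows, cat_test_rows, cat_pair_rows = [], [], []
    for var in categorical:
        levels = sorted(table[var].dropna().unique(), key=str)
        counts = np.array(
            [[int(((labels == c) & (table[var] == lv)).sum()) for c in clusters] for lv in levels]
        )
        for li, lv in enumerate(levels):
            for ci, c in enumerate(clusters):
                total = counts[:, ci].sum()
                cat_rows.append(
                    {"variable": var, "level": lv, "cluster": c, "count": int(counts[li, ci]),
                     "percent": 100.0 * counts[li, ci] / total if total else np.nan}
                )
        name, stat, p = _categorical_test(counts, seed=seed)
        cat_test_rows.append({"variable": var, "test": name, "statistic": stat, "p": p})
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                sub = counts[:, [i, j]]
                name2, stat2, p2 = _categorical_test(sub, seed=seed + 1)
                cat_pair_rows.append(
                    {"variable": var, "cluster_a": clusters[i], "cluster_b": clusters[j],
                     "test": name2, "p": p2}
                )

    return ProfileReport(
        continuous_summary=pd.DataFrame(cont_rows),
        continuous_tests=pd.DataFrame(kw_rows),
        continuous_pairwise=pd.DataFrame(mw_rows),
        categorical_summary=pd.DataFrame(cat_rows),
        categorical_tests=pd.DataFrame(cat_test_rows),
        categorical_pairwise=pd.DataFrame(cat_pair_rows),
        metadata={"pairwise_adjustment": "none (reported unadjusted)"},
    )
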