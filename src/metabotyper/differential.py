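"""Per-feature differential analysis across metabotypes.

One-way ANOVA per feature with Benjamini-Hochberg FDR control, Tukey-Kramer
honest-significant-difference post-hoc comparisons (studentized-range
distribution) restricted to the FDR-significant features, PLS-DA / PCA score
export for ordination, and Spearman screening of every feature against
(square-root-transformed) histologic fibrosis stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DifferentialResult",
    "anova_per_feature",
    "bh_fdr",
    "tukey_hsd",
    "run_differential",
    "PLSDA",
    "plsda_scores",
    "spearman_fibrosis",
]


# ---------------------------------------------------------------------------
# ANOVA + FDR + Tukey
# ---------------------------------------------------------------------------


@dataclass
class DifferentialResult:
    """Feature-level ANOVA table plus pairwise Tukey p-values.

    ``table`` columns: feature, F, p, q, mean_<group>...; ``tukey`` columns:
    feature, group_a, group_b, q_stat, p_adj.
    """

    table: pd.DataFrame
    tukey: pd.DataFrame
    metadata: dict = field(default_factory=dict)


def anova_per_feature(matrix, groups) -> pd.DataFrame:
    """Classical one-way ANOVA for every feature column.

    F = MSB / MSW with (g-1, n-g) degrees of freedom. Features with zero
    between- and within-group variance get F = 0, p = 1; zero within-group
    variance with real group differences gives p = 0.
    """
    X = np.asarray(matrix, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    g, n = len(levels), X.shape[0]
    if g < 2:
        raise ValueError("need at least two groups")
    for lv in levels:
        if (groups == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has fewer than two samples")

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    means = {}
    for lv in levels:
        block = X[groups == lv]
        m = block.mean(axis=0)
        means[lv] = m
        ssb += len(block) * (m - grand) ** 2
        ssw += ((block - m) ** 2).sum(axis=0)
    msb = ssb / (g - 1)
    msw = ssw / (n - g)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = msb / msw
    p = np.empty_like(F)
    ok = msw > 0
    p[ok] = stats.f.sf(F[ok], g - 1, n - g)
    # degenerate: no within-group variance
    both_zero = (~ok) & (msb <= 1e-300)
    F[both_zero], p[both_zero] = 0.0, 1.0
    sep = (~ok) & (msb > 1e-300)
    F[sep], p[sep] = np.inf, 0.0

    cols = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    out = pd.DataFrame({"feature": cols, "F": F, "p": p})
    for lv in levels:
        out[f"mean_{lv}"] = means[lv]
    return out


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tukey_hsd(values, groups) -> pd.DataFrame:
    """Tukey-Kramer all-pairs comparisons for one feature.

    The pairwise statistic is q = |mean_i - mean_j| /
    sqrt(MSW/2 * (1/n_i + 1/n_j)); adjusted p-values come from the
    studentized-range distribution with k groups and n-g error df.
    """
    x = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    g, n = len(levels), len(x)
    if g < 2:
        raise ValueError("need at least two groups")
    means = {lv: x[groups == lv].mean() for lv in levels}
    ns = {lv: int((groups == lv).sum()) for lv in levels}
    ssw = sum(((x[groups == lv] - means[lv]) ** 2).sum() for lv in levels)
    df_err = n - g
    msw = ssw / df_err
    if msw <= 0:
        if all(means[a] == means[b] for a, b in combinations(levels, 2)):
            rows = [
                {"group_a": a, "group_b": b, "q_stat": 0.0, "p_adj": 1.0}
                for a, b in combinations(levels, 2)
            ]
            return pd.DataFrame(rows)
        raise ValueError("zero within-group variance with distinct means")
    rows = []
    for a, b in combinations(levels, 2):
        se = np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(means[a] - means[b]) / se
        p_adj = float(stats.studentized_range.sf(q, g, df_err))
        rows.append({"group_a": a, "group_b": b, "q_stat": float(q), "p_adj": min(p_adj, 1.0)})
    return pd.DataFrame(rows)


def run_differential(matrix, groups, alpha: float = 0.05) -> DifferentialResult:
    """ANOVA -> BH-FDR -> Tukey HSD on the FDR-significant features only."""
    table = anova_per_feature(matrix, groups)
    table["q"] = bh_fdr(table["p"].to_numpy())
    X = np.asarray(matrix, dtype=float)
    tukey_rows = []
    for idx, row in table.iterrows():
        if row["q"] < alpha:
            tk = tukey_hsd(X[:, idx], groups)
            tk.insert(0, "feature", row["feature"])
            tukey_rows.append(tk)
    tukey = (
        pd.concat(tukey_rows, ignore_index=True)
        if tukey_rows
        else pd.DataFrame(columns=["feature", "group_a", "group_b", "q_stat", "p_adj"])
    )
    return DifferentialResult(
        table=table,
        tukey=tukey,
        metadata={"fdr_alpha": alpha, "post_hoc": "Tukey-Kramer on q < alpha features"},
    )


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------


class PLSDA(BaseEstimator):
    """Partial least squares discriminant analysis.

    PLS against a one-hot class indicator matrix via iterative latent-variable
    extraction with deflation; successive X-scores are mutually orthogonal.
    Constant feature columns are dropped with a warning.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("need at least two classes")
        keep = X.std(axis=0) > 0
        if not keep.all():
            warnings.warn(f"dropping {int((~keep).sum())} constant column(s)",
                          UserWarning, stacklevel=2)
        X = X[:, keep]
        Y = (y[:, None] == classes[None, :]).astype(float)
        pls = PLSRegression(n_components=self.n_components, scale=False).fit(X, Y)
        self.classes_ = classes
        self.keep_ = keep
        self.x_scores_ = pls.x_scores_
        self.x_loadings_ = pls.x_loadings_
        total_var = (X - X.mean(axis=0)).var(axis=0).sum() * X.shape[0]
        comp_var = (self.x_scores_**2).sum(axis=0) * (self.x_loadings_**2).sum(axis=0)
        self.explained_variance_ratio_ = comp_var / max(total_var, 1e-300)
        self._pls = pls
        return self

    def transform(self, X):
        return self._pls.transform(np.asarray(X, dtype=float)[:, self.keep_])


def plsda_scores(X, labels, n_comp: int = 2):
    """(scores, loadings, explained variance ratio) of a PLS-DA fit."""
    est = PLSDA(n_components=n_comp).fit(X, labels)
    return est.x_scores_, est.x_loadings_, est.explained_variance_ratio_


# ---------------------------------------------------------------------------
# fibrosis correlation screen
# ---------------------------------------------------------------------------


def spearman_fibrosis(matrix, fibrosis_stage) -> pd.DataFrame:
    """Spearman correlation of every feature with sqrt(fibrosis stage).

    The stage (0-4) is square-root transformed (handles zeros; the transform
    is monotone, so rho itself is unchanged). Average ranks resolve ties; the
    two-sided p uses the t approximation with n-2 df. Output is sorted by p.
    """
    stage = np.asarray(fibrosis_stage, dtype=float)
    if np.unique(stage[~np.isnan(stage)]).size < 2:
        raise ValueError("fibrosis stage is constant")
    if ((stage < 0) | (stage > 4)).any():
        raise ValueError("fibrosis stage must lie in 0..4")
    y = np.sqrt(stage)
    X = np.asarray(matrix, dtype=float)
    n = X.shape[0]

    ry = stats.rankdata(y)
    rX = np.apply_along_axis(stats.rankdata, 0, X)
    ryc = ry - ry.mean()
    rXc = rX - rX.mean(axis=0)
    denom = np.sqrt((rXc**2).sum(axis=0) * (ryc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rXc * ryc[:, None]).sum(axis=0) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)

    cols = matrix.columns if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(X.shape[1])
    out = pd.DataFrame({"feature": cols, "rho": rho, "p": p})
    return out.sort_values("p", kind="stable").reset_index(drop=True)
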