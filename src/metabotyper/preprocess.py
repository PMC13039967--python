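"""Untargeted LC-MS feature-table preprocessing.

Takes per-study, per-mode feature tables (m/z x retention time x intensity,
with triplicate injections and batch labels) through quality control and
normalization: replicate summarization, replicate-CV filtering, empirical-Bayes
batch adjustment, cross-study feature matching, quantile normalization, log2
transformation, and Hotelling-T2 multivariate outlier screening.

The canonical processing order is::

    summarize_triplicates -> filter_by_cv -> adjust_batch_effects
        -> match_features -> quantile_normalize -> log2_transform
        -> hotelling_outliers

Intensity matrices are oriented samples (rows) x features (columns) once
replicates are collapsed; raw tables carry one row per injection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FeatureTable",
    "MergedFeatureTable",
    "QCReport",
    "summarize_triplicates",
    "filter_by_cv",
    "adjust_batch_effects",
    "BatchAdjuster",
    "match_features",
    "quantile_normalize",
    "QuantileNormalizer",
    "log2_transform",
    "Log2Transformer",
    "hotelling_outliers",
    "hotelling_limit",
    "HotellingOutlierDetector",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class FeatureTable:
    """One ionization mode's feature table for one source/study group.

    Parameters
    ----------
    mode : str
        Ionization/chromatography mode, e.g. ``"hilic_pos"`` or ``"c18_neg"``.
    features : pandas.DataFrame
        Columns ``feature_id`` (unique), ``mz`` (Da, > 0), ``rt`` (seconds, >= 0).
    intensities : pandas.DataFrame
        Injections (rows, indexed by injection id) x features (columns are
        feature ids); non-negative.
    sample_of : pandas.Series
        Maps injection id -> sample id. After replicate summarization this is
        the identity map.
    batch_of : pandas.Series
        Maps sample id -> batch/study label.
    """

    mode: str
    features: pd.DataFrame
    intensities: pd.DataFrame
    sample_of: pd.Series
    batch_of: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        feats = self.features
        for col in ("feature_id", "mz", "rt"):
            if col not in feats.columns:
                raise ValueError(f"features table missing column {col!r}")
        if feats["feature_id"].duplicated().any():
            dup = feats.loc[feats["feature_id"].duplicated(), "feature_id"].iloc[0]
            raise ValueError(f"duplicate feature_id {dup!r}")
        if (feats["mz"] <= 0).any():
            raise ValueError("all m/z values must be positive")
        if (feats["rt"] < 0).any():
            raise ValueError("retention times must be non-negative")
        if list(self.intensities.columns) != list(feats["feature_id"]):
            raise ValueError("intensity columns must equal features.feature_id in order")
        unknown = set(self.intensities.index) - set(self.sample_of.index)
        if unknown:
            raise ValueError(f"injections without a sample mapping: {sorted(unknown)[:3]}")
        unknown_s = set(self.sample_of.values) - set(self.batch_of.index)
        if unknown_s:
            raise ValueError(f"samples without a batch label: {sorted(unknown_s)[:3]}")

    @property
    def samples(self) -> list[str]:
        seen: dict[str, None] = {}
        for inj in self.intensities.index:
            seen.setdefault(self.sample_of[inj], None)
        return list(seen)

    # -- CSV round trip (features x injections, per the on-disk schema) -----

    def to_csv(self, path, samples_path) -> None:
        """Write the table (rows = features, columns = injections) plus the
        sample/batch sidecar CSV."""
        out = self.features[["feature_id", "mz", "rt"]].copy()
        out = out.rename(columns={"rt": "rt_seconds"})
        mat = self.intensities.T  # features x injections
        mat.index.name = "feature_id"
        out = out.set_index("feature_id").join(mat)
        out.to_csv(path)
        side = pd.DataFrame(
            {
                "injection": self.intensities.index,
                "sample": [self.sample_of[i] for i in self.intensities.index],
            }
        )
        side["batch"] = side["sample"].map(self.batch_of)
        side.to_csv(samples_path, index=False)

    @classmethod
    def from_csv(cls, path, samples_path, mode: str) -> "FeatureTable":
        raw = pd.read_csv(path)
        for col in ("feature_id", "mz", "rt_seconds"):
            if col not in raw.columns:
                raise ValueError(f"feature CSV missing column {col!r}")
        feats = raw[["feature_id", "mz", "rt_seconds"]].rename(columns={"rt_seconds": "rt"})
        inj_cols = [c for c in raw.columns if c not in ("feature_id", "mz", "rt_seconds")]
        inten = raw.set_index("feature_id")[inj_cols].T
        inten.columns.name = None
        side = pd.read_csv(samples_path)
        sample_of = pd.Series(side["sample"].values, index=side["injection"].values)
        batch_of = (
            side.drop_duplicates("sample").set_index("sample")["batch"]
        )
        return cls(mode=mode, features=feats.reset_index(drop=True),
                   intensities=inten, sample_of=sample_of, batch_of=batch_of)


@dataclass
class MergedFeatureTable:
    """Cross-source matched and merged feature table for one mode.

    ``features`` has columns merged_id, mz (consensus mean), rt, plus per-source
    mz_<src> / rt_<src>; ``intensities`` is samples x merged features across the
    concatenated sample sets; ``provenance`` maps merged_id -> source feature ids.
    """

    mode: str
    features: pd.DataFrame
    intensities: pd.DataFrame
    batch_of: pd.Series
    provenance: dict[str, dict[str, str]]


@dataclass
class QCReport:
    """Quality-control bookkeeping emitted by the preprocessing operations."""

    feature_cv: pd.Series | None = None
    sample_replicate_r: pd.Series | None = None
    dropped_features: dict[str, str] = field(default_factory=dict)
    flagged_samples: dict[str, str] = field(default_factory=dict)
    t2: pd.Series | None = None
    t2_limit: float | None = None
    notes: dict[str, object] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        d: dict[str, object] = {
            "dropped_features": self.dropped_features,
            "flagged_samples": self.flagged_samples,
            "notes": self.notes,
        }
        if self.feature_cv is not None:
            d["feature_cv"] = self.feature_cv.round(6).to_dict()
        if self.sample_replicate_r is not None:
            d["sample_replicate_r"] = self.sample_replicate_r.round(6).to_dict()
        if self.t2 is not None:
            d["t2"] = self.t2.round(6).to_dict()
            d["t2_limit"] = self.t2_limit
        return d


# ---------------------------------------------------------------------------
# replicate handling
# ---------------------------------------------------------------------------


def summarize_triplicates(table: FeatureTable, min_r: float = 0.7):
    """Collapse technical replicates to per-sample medians and QC them.

    For every sample, all pairwise Pearson correlations between its replicate
    intensity vectors are computed; samples whose *median* pairwise r is not
    strictly above ``min_r`` are flagged (but retained — removal is a pipeline
    policy decision). Samples with a zero-variance replicate vector, where the
    correlation is undefined, are flagged too.

    Returns
    -------
    (FeatureTable, QCReport)
        A new table with one row per sample (replicates median-summarized).
    """
    inj_by_sample: dict[str, list[str]] = {}
    for inj in table.intensities.index:
        inj_by_sample.setdefault(table.sample_of[inj], []).append(inj)
    if any(len(v) < 1 for v in inj_by_sample.values()):
        raise ValueError("every sample needs at least one injection")

    qc = QCReport()
    med_rows = {}
    rs = {}
    for sample, injs in inj_by_sample.items():
        block = table.intensities.loc[injs].to_numpy(float)
        med_rows[sample] = np.median(block, axis=0)
        if len(injs) < 2:
            rs[sample] = np.nan
            continue
        pair_r = []
        undefined = False
        for i in range(len(injs)):
            for j in range(i + 1, len(injs)):
                a, b = block[i], block[j]
                if a.std() == 0 or b.std() == 0:
                    undefined = True
                    continue
                pair_r.append(np.corrcoef(a, b)[0, 1])
        if undefined and not pair_r:
            rs[sample] = np.nan
            qc.flagged_samples[sample] = "zero-variance replicate vector"
            continue
        r_med = float(np.median(pair_r))
        rs[sample] = r_med
        if undefined:
            qc.flagged_samples[sample] = "zero-variance replicate vector"
        elif r_med <= min_r:
            qc.flagged_samples[sample] = f"median replicate r {r_med:.3f} <= {min_r}"

    samples = list(inj_by_sample)
    inten = pd.DataFrame(
        np.vstack([med_rows[s] for s in samples]),
        index=samples,
        columns=table.intensities.columns,
    )
    qc.sample_replicate_r = pd.Series(rs)
    out = FeatureTable(
        mode=table.mode,
        features=table.features.copy(),
        intensities=inten,
        sample_of=pd.Series(samples, index=samples),
        batch_of=table.batch_of.copy(),
    )
    return out, qc


def filter_by_cv(table: FeatureTable, max_cv: float = 0.75):
    """Drop features whose replicate coefficient of variation is too high.

    CV is computed on the raw intensity scale as SD/mean across technical
    replicates within each sample, then median-aggregated across samples; a
    feature is kept iff its median CV is strictly below ``max_cv``. Features
    whose CV is undefined everywhere (zero-mean in every sample) are dropped
    with a recorded reason.
    """
    inj_by_sample: dict[str, list[str]] = {}
    for inj in table.intensities.index:
        inj_by_sample.setdefault(table.sample_of[inj], []).append(inj)

    X = table.intensities.to_numpy(float)
    idx = {inj: i for i, inj in enumerate(table.intensities.index)}
    cvs = []
    for sample, injs in inj_by_sample.items():
        block = X[[idx[i] for i in injs]]
        mean = block.mean(axis=0)
        sd = block.std(axis=0, ddof=1) if len(injs) > 1 else np.zeros(block.shape[1])
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > 0, sd / mean, np.nan)
        cvs.append(cv)
    cv_mat = np.vstack(cvs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        med_cv = np.nanmedian(cv_mat, axis=0)

    qc = QCReport(feature_cv=pd.Series(med_cv, index=table.intensities.columns))
    keep = []
    for fid, cv in zip(table.intensities.columns, med_cv):
        if np.isnan(cv):
            qc.dropped_features[fid] = "CV undefined (zero mean intensity)"
        elif cv < max_cv:
            keep.append(fid)
        else:
            qc.dropped_features[fid] = f"median replicate CV {cv:.3f} >= {max_cv}"
    out = FeatureTable(
        mode=table.mode,
        features=table.features[table.features["feature_id"].isin(keep)].reset_index(drop=True),
        intensities=table.intensities[keep],
        sample_of=table.sample_of.copy(),
        batch_of=table.batch_of.copy(),
    )
    return out, qc


# ---------------------------------------------------------------------------
# batch adjustment (parametric empirical Bayes, ComBat-style)
# ---------------------------------------------------------------------------


class BatchAdjuster(TransformerMixin, BaseEstimator):
    """Parametric empirical-Bayes location/scale batch adjustment.

    Implements the classical two-stage procedure on log-scale intensities:
    per-feature standardization by the batch-size-weighted grand mean and
    pooled residual SD, per-batch location (gamma) and scale (delta^2)
    estimation, shrinkage of both toward cross-feature priors (normal prior on
    gamma, inverse-gamma on delta^2, moment-matched), and removal of the
    shrunken effects.

    Parameters
    ----------
    eb : bool, default True
        If False, skip shrinkage and remove the raw per-batch location/scale
        estimates (one-feature inputs always take this path, since the priors
        are estimated across features).
    """

    def __init__(self, eb: bool = True, tol: float = 1e-4, max_iter: int = 500):
        self.eb = eb
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, batches):
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        if X.ndim != 2:
            raise ValueError("X must be samples x features")
        levels, inv = np.unique(batches, return_inverse=True)
        if len(levels) < 2:
            raise ValueError("need at least two batches")
        counts = np.bincount(inv)
        if (counts < 2).any():
            bad = levels[counts < 2]
            raise ValueError(f"batch with fewer than two samples: {list(bad)}")
        n, p = X.shape
        batch_means = np.vstack([X[inv == i].mean(axis=0) for i in range(len(levels))])
        alpha = (counts[:, None] * batch_means).sum(axis=0) / n
        resid = X - batch_means[inv]
        var_pooled = (resid**2).sum(axis=0) / n
        var_pooled = np.where(var_pooled <= 0, 1e-12, var_pooled)
        Z = (X - alpha) / np.sqrt(var_pooled)

        gamma_hat = np.vstack([Z[inv == i].mean(axis=0) for i in range(len(levels))])
        # ddof=0 matches the pooled-variance denominator, making identical
        # batches an exact fixed point of the adjustment
        delta2_hat = np.vstack(
            [Z[inv == i].var(axis=0, ddof=0) for i in range(len(levels))]
        )
        delta2_hat = np.where(delta2_hat <= 0, 1e-12, delta2_hat)

        if self.eb and p > 1:
            gamma_star = np.empty_like(gamma_hat)
            delta2_star = np.empty_like(delta2_hat)
            for i, n_i in enumerate(counts):
                g, d2 = gamma_hat[i], delta2_hat[i]
                gamma_bar = g.mean()
                tau2 = g.var(ddof=1)
                vbar = d2.mean()
                s2 = d2.var(ddof=1)
                if s2 <= 0:
                    a_prior = b_prior = None  # degenerate prior: no scale shrinkage
                else:
                    a_prior = (2 * s2 + vbar**2) / s2
                    b_prior = (vbar * s2 + vbar**3) / s2
                g_new = g.copy()
                d_new = d2.copy()
                Zi = Z[inv == i]
                if tau2 <= 0 and a_prior is None:
                    gamma_star[i], delta2_star[i] = g, d2
                    continue
                for _ in range(self.max_iter):
                    g_old, d_old = g_new, d_new
                    if tau2 > 0:
                        g_new = (n_i * tau2 * g + d_old * gamma_bar) / (n_i * tau2 + d_old)
                    sum2 = ((Zi - g_new) ** 2).sum(axis=0)
                    if a_prior is not None:
                        d_new = (0.5 * sum2 + b_prior) / (n_i / 2.0 + a_prior - 1.0)
                    change = max(
                        np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                        np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
                    )
                    if change < self.tol:
                        break
                gamma_star[i], delta2_star[i] = g_new, d_new
        else:
            gamma_star, delta2_star = gamma_hat, delta2_hat

        self.batches_ = levels
        self.alpha_ = alpha
        self.var_pooled_ = var_pooled
        self.gamma_star_ = gamma_star
        self.delta2_star_ = np.where(delta2_star <= 0, 1e-12, delta2_star)
        return self

    def transform(self, X, batches):
        X = np.asarray(X, dtype=float)
        batches = np.asarray(batches)
        lookup = {b: i for i, b in enumerate(self.batches_)}
        inv = np.array([lookup[b] for b in batches])
        Z = (X - self.alpha_) / np.sqrt(self.var_pooled_)
        Z_adj = (Z - self.gamma_star_[inv]) / np.sqrt(self.delta2_star_[inv])
        return Z_adj * np.sqrt(self.var_pooled_) + self.alpha_


def adjust_batch_effects(matrix, batches, eb: bool = True):
    """Remove additive/multiplicative batch effects from a log-scale matrix.

    Thin wrapper over :class:`BatchAdjuster`; preserves pandas metadata when a
    DataFrame is passed.
    """
    adj = BatchAdjuster(eb=eb).fit(matrix, batches)
    out = adj.transform(matrix, batches)
    if isinstance(matrix, pd.DataFrame):
        out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


# ---------------------------------------------------------------------------
# cross-source feature matching
# ---------------------------------------------------------------------------


def match_features(
    a: FeatureTable,
    b: FeatureTable,
    ppm_tol: float = 5.0,
    rt_tol: float = 30.0,
) -> MergedFeatureTable:
    """Match and merge two same-mode feature tables on m/z and retention time.

    A candidate pair must satisfy ``|mz_a - mz_b| / mean(mz) * 1e6 <= ppm_tol``
    and ``|rt_a - rt_b| <= rt_tol`` (both inclusive). Candidates are resolved
    one-to-one greedily by ascending ppm difference, with RT difference then
    feature ids as deterministic tie-breaks. Unmatched features are excluded;
    merged intensities are the concatenated sample columns of both sources.
    """
    if a.mode != b.mode:
        raise ValueError(f"mode mismatch: {a.mode!r} vs {b.mode!r}")
    fa = a.features.reset_index(drop=True)
    fb = b.features.reset_index(drop=True)
    mza, rta = fa["mz"].to_numpy(), fa["rt"].to_numpy()
    mzb, rtb = fb["mz"].to_numpy(), fb["rt"].to_numpy()

    order_b = np.argsort(mzb)
    mzb_sorted = mzb[order_b]
    candidates = []
    for i in range(len(fa)):
        # widest possible absolute window at this mass
        w = mza[i] * ppm_tol * 1e-6 * 1.000001
        lo = np.searchsorted(mzb_sorted, mza[i] - 2 * w, side="left")
        hi = np.searchsorted(mzb_sorted, mza[i] + 2 * w, side="right")
        for jj in range(lo, hi):
            j = order_b[jj]
            mean_mz = 0.5 * (mza[i] + mzb[j])
            ppm = abs(mza[i] - mzb[j]) / mean_mz * 1e6
            drt = abs(rta[i] - rtb[j])
            if ppm <= ppm_tol and drt <= rt_tol:
                candidates.append((ppm, drt, fa["feature_id"][i], fb["feature_id"][j], i, j))
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for ppm, drt, fida, fidb, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))

    overlap = set(a.samples) & set(b.samples)
    if overlap:
        raise ValueError(f"sources share sample ids: {sorted(overlap)[:3]}")

    rows = []
    provenance: dict[str, dict[str, str]] = {}
    cols_a, cols_b = [], []
    for k, (i, j) in enumerate(pairs):
        mid = f"M{k:05d}"
        rows.append(
            {
                "merged_id": mid,
                "mz": 0.5 * (mza[i] + mzb[j]),
                "rt": 0.5 * (rta[i] + rtb[j]),
                "mz_a": mza[i],
                "mz_b": mzb[j],
                "rt_a": rta[i],
                "rt_b": rtb[j],
            }
        )
        provenance[mid] = {"a": fa["feature_id"][i], "b": fb["feature_id"][j]}
        cols_a.append(fa["feature_id"][i])
        cols_b.append(fb["feature_id"][j])

    feats = pd.DataFrame(rows, columns=["merged_id", "mz", "rt", "mz_a", "mz_b", "rt_a", "rt_b"])
    ids = list(feats["merged_id"])
    ia = a.intensities[cols_a]
    ia.columns = ids
    ib = b.intensities[cols_b]
    ib.columns = ids
    inten = pd.concat([ia, ib], axis=0)
    batch_of = pd.concat([a.batch_of, b.batch_of])
    batch_of = batch_of[~batch_of.index.duplicated()]
    return MergedFeatureTable(
        mode=a.mode, features=feats, intensities=inten, batch_of=batch_of, provenance=provenance
    )


# ---------------------------------------------------------------------------
# normalization and transformation
# ---------------------------------------------------------------------------


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Classical quantile normalization across samples (rows).

    Each sample's intensity distribution is replaced by the reference
    distribution formed by averaging the samples' order statistics; tied values
    within a sample receive the mean of their rank-range targets. Applying the
    transform twice equals applying it once.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.size == 0:
            raise ValueError("empty matrix")
        self.reference_ = np.sort(X, axis=1).mean(axis=0)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        ref = self.reference_
        out = np.empty_like(X)
        for i in range(X.shape[0]):
            row = X[i]
            order = np.argsort(row, kind="stable")
            sorted_vals = row[order]
            targets = np.empty_like(row)
            j = 0
            m = len(row)
            while j < m:
                k = j
                while k + 1 < m and sorted_vals[k + 1] == sorted_vals[j]:
                    k += 1
                targets[order[j : k + 1]] = ref[j : k + 1].mean()
                j = k + 1
            out[i] = targets
        return out


def quantile_normalize(matrix):
    """Quantile-normalize a samples x features matrix; see QuantileNormalizer."""
    qn = QuantileNormalizer().fit(matrix)
    out = qn.transform(matrix)
    if isinstance(matrix, pd.DataFrame):
        out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out


class Log2Transformer(TransformerMixin, BaseEstimator):
    """log2 transform with per-feature half-minimum replacement of zeros.

    Zeros in a feature are replaced by half of that feature's smallest positive
    value; features that are entirely zero are dropped with a warning.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if (X < 0).any():
            raise ValueError("negative intensities cannot be log-transformed")
        keep = []
        fill = []
        for j in range(X.shape[1]):
            col = X[:, j]
            pos = col[col > 0]
            if len(pos) == 0:
                continue
            keep.append(j)
            fill.append(0.5 * pos.min())
        if len(keep) < X.shape[1]:
            warnings.warn(
                f"dropping {X.shape[1] - len(keep)} all-zero feature(s) before log2",
                UserWarning,
                stacklevel=2,
            )
        self.keep_ = np.array(keep, dtype=int)
        self.fill_ = np.array(fill, dtype=float)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)[:, self.keep_]
        X = np.where(X == 0, self.fill_, X)
        return np.log2(X)


def log2_transform(matrix):
    """log2 with half-minimum zero replacement; drops all-zero features."""
    tr = Log2Transformer().fit(matrix)
    out = tr.transform(matrix)
    if isinstance(matrix, pd.DataFrame):
        out = pd.DataFrame(out, index=matrix.index, columns=matrix.columns[tr.keep_])
    return out


# ---------------------------------------------------------------------------
# multivariate outlier screen
# ---------------------------------------------------------------------------


def hotelling_limit(n: int, n_pcs: int, conf: float = 0.99) -> float:
    """F-based control limit for the Hotelling T2 of PCA scores."""
    return n_pcs * (n - 1) / (n - n_pcs) * stats.f.ppf(conf, n_pcs, n - n_pcs)


class HotellingOutlierDetector(BaseEstimator):
    """Flag multivariate outlier samples by Hotelling's T2 on PCA scores.

    PCA is computed by SVD of the column-centered matrix; per-sample
    T2 = sum over the first ``n_pcs`` components of score^2 / component
    variance, compared against the ``conf``-level F control limit
    ``n_pcs (n-1)/(n-n_pcs) * F_conf(n_pcs, n-n_pcs)``.
    """

    def __init__(self, n_pcs: int = 5, conf: float = 0.99):
        self.n_pcs = n_pcs
        self.conf = conf

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        if n <= self.n_pcs + 1:
            raise ValueError(f"need more than n_pcs + 1 = {self.n_pcs + 1} samples")
        Xc = X - X.mean(axis=0)
        U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
        if (S[: self.n_pcs] <= 1e-12 * max(S[0], 1.0)).any():
            raise ValueError(f"matrix rank below n_pcs={self.n_pcs}")
        # deterministic sign: largest-magnitude loading positive
        for h in range(self.n_pcs):
            j = np.argmax(np.abs(Vt[h]))
            if Vt[h, j] < 0:
                Vt[h] *= -1
                U[:, h] *= -1
        scores = U[:, : self.n_pcs] * S[: self.n_pcs]
        lam = S[: self.n_pcs] ** 2 / (n - 1)
        self.scores_ = scores
        self.t2_ = (scores**2 / lam).sum(axis=1)
        self.limit_ = hotelling_limit(n, self.n_pcs, self.conf)
        self.outlier_mask_ = self.t2_ > self.limit_
        return self


def hotelling_outliers(matrix, n_pcs: int = 5, conf: float = 0.99) -> QCReport:
    """Run the T2 screen on a samples x features matrix; flagged samples are
    recorded in the report (removal is applied by the pipeline)."""
    det = HotellingOutlierDetector(n_pcs=n_pcs, conf=conf).fit(matrix)
    index = matrix.index if isinstance(matrix, pd.DataFrame) else pd.RangeIndex(len(det.t2_))
    qc = QCReport(
        t2=pd.Series(det.t2_, index=index),
        t2_limit=float(det.limit_),
    )
    for s, bad, t2 in zip(index, det.outlier_mask_, det.t2_):
        if bad:
            qc.flagged_samples[str(s)] = f"T2 {t2:.2f} > limit {det.limit_:.2f}"
    return qc
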