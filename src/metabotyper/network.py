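"""Per-metabotype clinical-metabolite association networks.

For each metabotype, the clinical block (log-transformed skewed labs,
square-root fibrosis stage, z-scaled) and the metabolite block (significant
features) are related by two-block PLS in canonical mode. An association
score between clinical variable i and metabolite j sums, over components, the
product of their correlations with the averaged block variates; edges pass
|r| > 0.3 and Student-t p < 0.05. Communities come from multilevel (Louvain)
modularity maximization on |r| weights; node influence from max-normalized
eigenvector centrality via power iteration; features whose centrality shifts
by at least 0.025 between two metabotype networks are selected for pairwise
pathway enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.cross_decomposition import PLSCanonical as _SKPLSCanonical

__all__ = [
    "LOG_CLINICAL_VARS",
    "AssociationNetwork",
    "CentralityComparison",
    "prepare_clinical_block",
    "PLSCanonicalAssociation",
    "pls_canonical",
    "association_matrix",
    "build_network",
    "detect_communities",
    "eigenvector_centrality",
    "compare_centrality",
]

# right-skewed labs natural-log transformed before integration
LOG_CLINICAL_VARS = ("alt", "ast", "tg", "vldl", "ldl", "homa2ir")

DEFAULT_NETWORK_VARS = (
    "age", "alt", "ast", "wc", "vldl", "ldl", "tg", "homa2ir", "uric_acid",
    "sbp", "fibrosis_stage",
)


def prepare_clinical_block(table: pd.DataFrame, members=None, variables=DEFAULT_NETWORK_VARS) -> pd.DataFrame:
    """Clinical block for one metabotype: transform then z-scale.

    ALT, AST, TG, VLDL, LDL and HOMA2-IR are natural-log transformed (they
    must be positive); fibrosis stage is square-root transformed (stage 0 maps
    to 0); remaining variables enter untransformed. Every column is then
    scaled to mean 0 / sample SD 1.
    """
    sub = table if members is None else table[table["subject_id"].isin(members)]
    if len(sub) == 0:
        raise ValueError("empty metabotype membership")
    out = {}
    for var in variables:
        col = sub[var].to_numpy(float)
        if var in LOG_CLINICAL_VARS:
            if (col <= 0).any():
                raise ValueError(f"non-positive value in log-transformed column {var!r}")
            col = np.log(col)
        elif var == "fibrosis_stage":
            col = np.sqrt(col)
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(f"constant clinical column {var!r}")
        out[var] = (col - col.mean()) / sd
    index = sub["subject_id"] if "subject_id" in sub else sub.index
    return pd.DataFrame(out, index=index)


# ---------------------------------------------------------------------------
# two-block PLS, canonical mode
# ---------------------------------------------------------------------------


class PLSCanonicalAssociation(BaseEstimator):
    """Two-block PLS (canonical mode) with an association-score matrix.

    Canonical-mode deflation treats the blocks symmetrically: each block is
    deflated on its own scores/loadings, and within-block score vectors are
    mutually orthogonal. The association score between column i of X and
    column j of Y is

        r_ij = sum_h cor(X_i, z_h) * cor(Y_j, z_h),   z_h = (t_h + u_h) / 2

    clipped to [-1, 1], with a two-sided Student-t p-value on n-2 df.
    """

    def __init__(self, n_components: int = 3):
        self.n_components = n_components

    def fit(self, X, Y):
        X = np.asarray(X, dtype=float)
        Y = np.asarray(Y, dtype=float)
        if X.shape[0] != Y.shape[0]:
            raise ValueError("X and Y must share the row (sample) dimension")
        keep_x = X.std(axis=0) > 0
        keep_y = Y.std(axis=0) > 0
        if not keep_x.all() or not keep_y.all():
            warnings.warn(
                f"dropping {int((~keep_x).sum())} X / {int((~keep_y).sum())} Y constant column(s)",
                UserWarning, stacklevel=2,
            )
        X, Y = X[:, keep_x], Y[:, keep_y]
        max_comp = min(np.linalg.matrix_rank(X - X.mean(0)), np.linalg.matrix_rank(Y - Y.mean(0)))
        if self.n_components > max_comp:
            raise ValueError(f"n_components={self.n_components} exceeds usable rank {max_comp}")
        pls = _SKPLSCanonical(n_components=self.n_components, scale=False,
                              max_iter=1000, tol=1e-10).fit(X, Y)
        self.keep_x_, self.keep_y_ = keep_x, keep_y
        self.x_scores_, self.y_scores_ = pls.transform(X, Y)
        self.x_loadings_ = pls.x_loadings_
        self.y_loadings_ = pls.y_loadings_
        self.n_samples_ = X.shape[0]
        return self

    def association(self, X, Y):
        """(r matrix, p matrix) over the retained X and Y columns."""
        X = np.asarray(X, dtype=float)[:, self.keep_x_]
        Y = np.asarray(Y, dtype=float)[:, self.keep_y_]
        n = X.shape[0]
        if n < 4:
            raise ValueError("need at least four samples for association p-values")
        Z = 0.5 * (self.x_scores_ + self.y_scores_)

        def corr_with(block, z):
            bc = block - block.mean(axis=0)
            zc = z - z.mean()
            denom = np.sqrt((bc**2).sum(axis=0) * (zc**2).sum())
            if (denom == 0).any():
                raise ValueError("zero-variance column in association computation")
            return (bc * zc[:, None]).sum(axis=0) / denom

        R = np.zeros((X.shape[1], Y.shape[1]))
        for h in range(Z.shape[1]):
            cx = corr_with(X, Z[:, h])
            cy = corr_with(Y, Z[:, h])
            R += np.outer(cx, cy)
        R = np.clip(R, -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.abs(R) * np.sqrt((n - 2) / (1 - R**2))
        P = 2 * stats.t.sf(t, n - 2)
        P = np.where(np.abs(R) >= 1.0, 0.0, P)
        return R, P


def pls_canonical(X, Y, n_comp: int = 3) -> PLSCanonicalAssociation:
    """Fit two-block canonical-mode PLS; returns the fitted estimator."""
    return PLSCanonicalAssociation(n_components=n_comp).fit(X, Y)


def association_matrix(fit: PLSCanonicalAssociation, X, Y):
    """Association scores and p-values for a fitted two-block PLS."""
    return fit.association(X, Y)


# ---------------------------------------------------------------------------
# network construction and analysis
# ---------------------------------------------------------------------------


@dataclass
class AssociationNetwork:
    """One metabotype's clinical-metabolite association graph."""

    label: str
    graph: nx.Graph
    n_samples: int
    communities: dict = field(default_factory=dict)
    modularity: float | None = None
    centrality: dict = field(default_factory=dict)
    disconnected: bool = False


def build_network(
    r: np.ndarray,
    p: np.ndarray,
    clinical_names,
    metabolite_names,
    label: str = "",
    n_samples: int = 0,
    r_min: float = 0.3,
    alpha: float = 0.05,
) -> AssociationNetwork:
    """Keep edges with |r| strictly above ``r_min`` and p strictly below
    ``alpha``; signed scores are retained as edge attributes and |r| as the
    weight. Nodes without any edge are dropped."""
    r = np.asarray(r, dtype=float)
    p = np.asarray(p, dtype=float)
    if r.shape != p.shape:
        raise ValueError("r and p must have the same shape")
    G = nx.Graph()
    for i, cname in enumerate(clinical_names):
        for j, mname in enumerate(metabolite_names):
            if abs(r[i, j]) > r_min and p[i, j] < alpha:
                G.add_node(cname, kind="clinical")
                G.add_node(mname, kind="metabolite")
                G.add_edge(cname, mname, r=float(r[i, j]), p=float(p[i, j]),
                           weight=float(abs(r[i, j])))
    return AssociationNetwork(label=label, graph=G, n_samples=n_samples)


def detect_communities(network: AssociationNetwork, seed: int = 0, restarts: int = 10):
    """Multilevel (Louvain) modularity maximization on |r| edge weights.

    The best of ``restarts`` seeded runs by modularity is kept; the partition
    is stored on the network and as a node attribute.
    """
    G = network.graph
    if G.number_of_edges() == 0:
        raise ValueError("cannot detect communities in an empty network")
    best_part, best_q = None, -np.inf
    for s in range(restarts):
        part = nx.community.louvain_communities(G, weight="weight", resolution=1.0,
                                                seed=seed + s)
        q = nx.community.modularity(G, part, weight="weight")
        if q > best_q:
            best_part, best_q = part, q
    mapping = {}
    for cid, nodes in enumerate(sorted(best_part, key=lambda s: sorted(s)[0])):
        for node in nodes:
            mapping[node] = cid
    nx.set_node_attributes(G, mapping, "community")
    network.communities = mapping
    network.modularity = float(best_q)
    return mapping, float(best_q)


def eigenvector_centrality(network: AssociationNetwork, tol: float = 1e-10,
                           max_iter: int = 100000) -> dict:
    """Max-normalized eigenvector centrality by power iteration on |r| weights.

    Computed on the full (possibly disconnected) graph; with disconnection the
    mass concentrates on the dominant component, which is flagged on the
    network object.
    """
    G = network.graph
    if G.number_of_edges() == 0:
        raise ValueError("cannot compute centrality on an empty network")
    nodes = sorted(G.nodes)
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    x = np.ones(len(nodes))
    x /= x.max()
    # iterate on A + I: same dominant eigenvector, but aperiodic, so the
    # iteration converges on bipartite graphs where plain A@x oscillates
    for _ in range(max_iter):
        x_new = A @ x + x
        norm = x_new.max()
        if norm <= 0:
            raise RuntimeError("power iteration collapsed to zero vector")
        x_new /= norm
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations "
            f"(last change {np.abs(x_new - x).max():.2e})"
        )
    cent = dict(zip(nodes, x))
    nx.set_node_attributes(G, cent, "centrality")
    network.centrality = cent
    network.disconnected = not nx.is_connected(G)
    return cent


@dataclass
class CentralityComparison:
    """Node-level centrality differences between two metabotype networks."""

    pair: str
    table: pd.DataFrame  # node, kind, centrality_a, centrality_b, delta
    selected: list[str]  # metabolite nodes with delta >= threshold
    threshold: float


def compare_centrality(a: AssociationNetwork, b: AssociationNetwork,
                       threshold: float = 0.025) -> CentralityComparison:
    """Delta centrality between two networks; nodes absent from one network
    contribute centrality 0 there. Metabolite nodes with delta >= threshold
    (inclusive) are selected for pairwise pathway enrichment."""
    ca = a.centrality if a.centrality else eigenvector_centrality(a)
    cb = b.centrality if b.centrality else eigenvector_centrality(b)
    nodes = sorted(set(ca) | set(cb))
    kinds = {}
    for net in (a, b):
        for node, data in net.graph.nodes(data=True):
            kinds[node] = data.get("kind", "metabolite")
    rows = []
    selected = []
    for node in nodes:
        va, vb = ca.get(node, 0.0), cb.get(node, 0.0)
        delta = abs(va - vb)
        rows.append({"node": node, "kind": kinds.get(node, "metabolite"),
                     "centrality_a": va, "centrality_b": vb, "delta": delta})
        if delta >= threshold and kinds.get(node) == "metabolite":
            selected.append(node)
    return CentralityComparison(
        pair=f"{a.label}-vs-{b.label}",
        table=pd.DataFrame(rows),
        selected=selected,
        threshold=threshold,
    )
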