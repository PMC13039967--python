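"""File I/O: validated clinical CSV reading and GraphML network export."""

from __future__ import annotations

import networkx as nx
import pandas as pd

from .clustering import CLUSTERING_VARS
from .network import AssociationNetwork

__all__ = ["read_clinical_csv", "write_clinical_csv", "export_graphml", "import_graphml"]

_NUMERIC_CLINICAL = list(CLUSTERING_VARS) + [
    "bmi", "bmi_z", "hdl", "tc", "ggt", "glucose", "insulin", "dbp", "nas",
]
_ORDINAL = ["steatosis", "lobular_inflammation", "ballooning", "fibrosis_stage"]
_ORDINAL_MAX = {"steatosis": 3, "lobular_inflammation": 3, "ballooning": 2, "fibrosis_stage": 4}


def read_clinical_csv(path) -> pd.DataFrame:
    """Read and validate a clinical table; empty cells become missing.

    Errors name the offending column (and row, for unparseable values).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if "subject_id" not in df.columns:
        raise ValueError("clinical CSV missing mandatory column 'subject_id'")
    missing = [v for v in CLUSTERING_VARS if v not in df.columns]
    if missing:
        raise ValueError(f"clinical CSV missing mandatory column(s): {missing}")
    if df["subject_id"].duplicated().any():
        dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValueError(f"duplicate subject_id {dup!r}")

    for col in _NUMERIC_CLINICAL + _ORDINAL:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ValueError(
                f"unparseable value {df.loc[row, col]!r} at row {row}, column {col!r}"
            )
        df[col] = parsed
    for col, top in _ORDINAL_MAX.items():
        if col in df.columns:
            obs = df[col].dropna()
            if ((obs < 0) | (obs > top)).any():
                raise ValueError(f"column {col!r} outside 0..{top}")
    for col in CLUSTERING_VARS:
        obs = df[col].dropna()
        if (obs < 0).any():
            raise ValueError(f"negative value in column {col!r}")
    return df


def write_clinical_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def export_graphml(network: AssociationNetwork, path) -> None:
    """Write an association network as standards-conformant GraphML.

    Node attributes: kind, community, centrality; edge attributes: r, p.
    """
    G = network.graph.copy()
    for node in G.nodes:
        G.nodes[node].setdefault("kind", "metabolite")
        G.nodes[node]["community"] = int(network.communities.get(node, -1))
        G.nodes[node]["centrality"] = float(network.centrality.get(node, 0.0))
    for _, _, data in G.edges(data=True):
        data.pop("weight", None)  # |r| is derivable; keep the signed score
    G.graph["label"] = network.label
    G.graph["n_samples"] = network.n_samples
    nx.write_graphml(G, path)


def import_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
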