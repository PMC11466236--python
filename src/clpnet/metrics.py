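"""Centrality, bridge edges, display thresholding and network comparison.

Expected influence (EI) is the *signed* sum of a node's cross-lagged
edges: out-EI sums a node's outgoing weights, in-EI its incoming ones;
autoregressive (diagonal) edges are excluded from both.  Summing signed
weights — rather than absolute strength — preserves the distinction
between symptom-amplifying and symptom-dampening nodes, which matters
here because several NSSI edges are negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .catalog import SymptomCatalog
from .errors import InputError
from .estimator import CrossLaggedNetwork


def count_cross_lagged_edges(catalog: SymptomCatalog) -> int:
    """Number of assessed directed cross-lagged edges: n^2 - n."""
    p = len(catalog)
    if p == 0:
        raise InputError("empty catalog")
    return p * p - p


# ---------------------------------------------------------------------------
# expected influence
# ---------------------------------------------------------------------------

def expected_influence(
    net: CrossLaggedNetwork, absolute: bool = False
) -> pd.DataFrame:
    """Per-node out-EI and in-EI with rankings.

    ``absolute=True`` switches to summed absolute weights (a sensitivity
    variant); the default is the signed one-step expected influence.
    Columns: node_id, community, out_EI, in_EI, rank_out, rank_in
    (rank 1 = largest value).
    """
    W = np.abs(net.W) if absolute else net.W.copy()
    np.fill_diagonal(W, 0.0)
    out_ei = W.sum(axis=1)
    in_ei = W.sum(axis=0)
    df = pd.DataFrame(
        {
            "node_id": net.catalog.node_ids,
            "community": net.catalog.communities,
            "out_EI": out_ei,
            "in_EI": in_ei,
        }
    )
    df["rank_out"] = df["out_EI"].rank(ascending=False, method="min").astype(int)
    df["rank_in"] = df["in_EI"].rank(ascending=False, method="min").astype(int)
    return df


# alias matching the directional naming used in reports
out_expected_influence = expected_influence


# ---------------------------------------------------------------------------
# bridge edges and display thresholding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BridgeEdge:
    src: str
    dst: str
    weight: float
    src_community: str
    dst_community: str


def bridge_edges(
    net: CrossLaggedNetwork,
    from_communities: set[str] | list[str],
    to_communities: set[str] | list[str],
    top_k: int = 3,
) -> list[BridgeEdge]:
    """Strongest cross-community edges from one community set to another.

    Nonzero edges whose source community is in ``from_communities`` and
    destination community in ``to_communities`` (source != destination
    community), sorted by |weight| descending with lexicographic
    (src, dst) tie-breaking; the top ``top_k`` are returned.
    """
    from_set, to_set = set(from_communities), set(to_communities)
    cat = net.catalog
    known = set(cat.communities)
    if not from_set or not to_set:
        raise InputError("community selections must be non-empty")
    if not from_set <= known or not to_set <= known:
        raise InputError(f"unknown community in selection; catalog has {sorted(known)}")
    if top_k < 1:
        raise InputError("top_k must be >= 1")
    comms = cat.communities
    ids = cat.node_ids
    edges = []
    for i in range(len(cat)):
        if comms[i] not in from_set:
            continue
        for j in range(len(cat)):
            if i == j or comms[j] not in to_set or comms[j] == comms[i]:
                continue
            w = float(net.W[i, j])
            if w != 0.0:
                edges.append(BridgeEdge(ids[i], ids[j], w, comms[i], comms[j]))
    edges.sort(key=lambda e: (-abs(e.weight), e.src, e.dst))
    return edges[:top_k]


#: display threshold used for figure parity in reports
DISPLAY_THRESHOLD = 0.06


def threshold_edges(net: CrossLaggedNetwork, min_abs: float = DISPLAY_THRESHOLD) -> pd.DataFrame:
    """Edges with |weight| strictly greater than ``min_abs``.

    Returns a DataFrame (from, to, weight, edge_type) preserving sign and
    direction, ordered by |weight| descending then (from, to).
    """
    if min_abs < 0:
        raise InputError("min_abs must be >= 0")
    edges = net.edge_list()
    kept = edges[edges["weight"].abs() > min_abs].copy()
    kept = kept.sort_values(
        by=["weight", "from", "to"],
        key=lambda s: -s.abs() if s.name == "weight" else s,
    ).reset_index(drop=True)
    return kept


# ---------------------------------------------------------------------------
# network comparison
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NetworkComparison:
    """Similarity of two cross-lagged networks over the same catalog.

    ``jaccard`` treats a directed edge as shared when it is nonzero in
    both networks and (by default) carries the same sign.  Overlap
    percentages ignore sign.  When a network has no nonzero edges the
    overlap/jaccard entries are None (undefined).
    """

    edge_correlation: float
    overlap_pct_A_in_B: float | None
    overlap_pct_B_in_A: float | None
    jaccard: float | None
    n_nonzero_A: int
    n_nonzero_B: int

    def to_dict(self) -> dict:
        return {
            "edge_correlation": self.edge_correlation,
            "overlap_pct_A_in_B": self.overlap_pct_A_in_B,
            "overlap_pct_B_in_A": self.overlap_pct_B_in_A,
            "jaccard": self.jaccard,
            "n_nonzero_A": self.n_nonzero_A,
            "n_nonzero_B": self.n_nonzero_B,
        }


def compare_networks(
    netA: CrossLaggedNetwork,
    netB: CrossLaggedNetwork,
    sign_sensitive: bool = True,
) -> NetworkComparison:
    """Edge-weight correlation, mutual overlap and Jaccard similarity.

    All three indices are computed over the off-diagonal (cross-lagged)
    weight vectors.  ``sign_sensitive=False`` counts a shared edge by
    direction only, ignoring sign disagreement.
    """
    if netA.catalog.node_ids != netB.catalog.node_ids:
        raise InputError("networks use different catalogs")
    p = netA.n_nodes
    off = ~np.eye(p, dtype=bool)
    a, b = netA.W[off], netB.W[off]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        corr = float("nan")  # correlation undefined for a constant vector
    else:
        corr = float(stats.pearsonr(a, b).statistic)
    nza, nzb = a != 0, b != 0
    n_a, n_b = int(nza.sum()), int(nzb.sum())
    both = nza & nzb
    overlap_ab = 100.0 * both.sum() / n_a if n_a else None
    overlap_ba = 100.0 * both.sum() / n_b if n_b else None
    union = int((nza | nzb).sum())
    if union == 0:
        jac = None
    else:
        shared = both & (np.sign(a) == np.sign(b)) if sign_sensitive else both
        jac = float(shared.sum() / union)
    return NetworkComparison(
        edge_correlation=corr,
        overlap_pct_A_in_B=overlap_ab,
        overlap_pct_B_in_A=overlap_ba,
        jaccard=jac,
        n_nonzero_A=n_a,
        n_nonzero_B=n_b,
    )


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def centrality_csv(net: CrossLaggedNetwork, path: str | Path) -> Path:
    path = Path(path)
    expected_influence(net).to_csv(path, index=False)
    return path


def to_graphml(
    net: CrossLaggedNetwork, path: str | Path, min_abs: float = DISPLAY_THRESHOLD
) -> Path:
    """Export the thresholded directed network as GraphML with weight and
    sign attributes (negative edges flagged)."""
    G = nx.DiGraph()
    for node in net.catalog:
        G.add_node(node.node_id, label=node.label, community=node.community)
    for _, row in threshold_edges(net, min_abs).iterrows():
        G.add_edge(
            row["from"],
            row["to"],
            weight=float(row["weight"]),
            sign="negative" if row["weight"] < 0 else "positive",
            edge_type=row["edge_type"],
        )
    path = Path(path)
    nx.write_graphml(G, path)
    return path
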