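"""Correlation networks and hierarchical clustering of r-value profiles.

Significant correlations become an undirected graph: edge weight is the
absolute Pearson r, the sign of the correlation is carried separately,
and edge width encodes evidence as -log10(q).  Self-correlations never
form edges.  Centrality (degree, strength, betweenness), connected
components and a force-directed layout summarise network structure;
Ward.D2 hierarchical clustering of per-target r-value profiles groups
targets by the similarity of their co-dependency signatures.
"""

from __future__ import annotations

import math
from collections.abc import Sequence
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

DEFAULT_Q_THRESH = 0.05

#: width assigned when q underflows to exactly 0 (would be -log10(0))
_WIDTH_CAP = 320.0

BETWEENNESS_MODES = ("unweighted", "weight_as_cost", "inverse_weight")


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

def build_graph(table: pd.DataFrame, q_thresh: float = DEFAULT_Q_THRESH,
                ) -> nx.Graph:
    """Build the significance-filtered correlation network.

    Keeps records with ``q < q_thresh``; self-correlations are dropped so
    the graph has no self-loops.  When the same unordered pair appears in
    several target families, the record with the smaller q (strongest
    evidence) wins.  Every target in the table becomes a node (flagged
    ``is_target``) even if it retains no edge.

    Edge attributes: ``weight`` = |r|, ``sign`` in {"+", "-"},
    ``width`` = -log10(q) (capped if q underflows to 0).
    """
    g = nx.Graph()
    targets = pd.unique(table["target"])
    for t in targets:
        g.add_node(t, is_target=True)

    sig = table[
        (table["gene"] != table["target"]) & table["q"].notna()
        & (table["q"] < q_thresh) & table["r"].notna()
    ]
    for rec in sig.itertuples(index=False):
        u, v = rec.target, rec.gene
        if g.has_edge(u, v) and g.edges[u, v]["q"] <= rec.q:
            continue
        width = -math.log10(rec.q) if rec.q > 0 else _WIDTH_CAP
        g.add_edge(
            u, v,
            weight=abs(rec.r),
            sign="+" if rec.r >= 0 else "-",
            width=width,
            r=float(rec.r),
            q=float(rec.q),
            n=int(rec.n),
        )
        if "is_target" not in g.nodes[v]:
            g.nodes[v]["is_target"] = False
        if "is_target" not in g.nodes[u]:
            g.nodes[u]["is_target"] = False
    return g


def degree(graph: nx.Graph) -> dict:
    """Number of adjacent edges per vertex."""
    return dict(graph.degree())


def strength(graph: nx.Graph) -> dict:
    """Weighted vertex degree: sum of incident |r| edge weights."""
    return dict(graph.degree(weight="weight"))


def betweenness(graph: nx.Graph, mode: str = "weight_as_cost") -> dict:
    """Shortest-path betweenness centrality per vertex.

    Pair counting is over unordered pairs with fractional credit for tied
    shortest paths (so the centre of an unweighted 3-node path scores 1).

    Modes
    -----
    ``weight_as_cost``
        |r| is used directly as the edge length — replicating pipelines
        that store |r| in the weight attribute and call a centrality
        routine that treats weights as distances.  Note this makes
        strongly correlated pairs *far* apart.
    ``inverse_weight``
        Edge length 1/|r|: strong correlations are short, usually the
        intended semantics.
    ``unweighted``
        Hop counts only.
    """
    if mode not in BETWEENNESS_MODES:
        raise ValueError(
            f"mode must be one of {BETWEENNESS_MODES}, got {mode!r}"
        )
    if mode == "unweighted":
        return nx.betweenness_centrality(graph, normalized=False)
    if mode == "weight_as_cost":
        attr = "weight"
    else:
        attr = "_invw"
        for u, v, d in graph.edges(data=True):
            graph.edges[u, v][attr] = 1.0 / d["weight"]
    lengths = [d[attr] for _, _, d in graph.edges(data=True)]
    if any(w <= 0 for w in lengths):
        raise ValueError("betweenness requires positive edge lengths")
    result = nx.betweenness_centrality(graph, normalized=False, weight=attr)
    if attr == "_invw":
        for u, v in graph.edges():
            del graph.edges[u, v][attr]
    return result


def components(graph: nx.Graph) -> list:
    """Connected components as node sets, largest first (ties by min label)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), min(map(str, c))))


def fr_layout(graph: nx.Graph, seed: int = 42, iterations: int = 500) -> dict:
    """Fruchterman-Reingold force-directed layout, deterministic per seed.

    Edge weights (|r|) scale the attractive force, so strongly correlated
    pairs end up closer in expectation.  A single node is placed at the
    origin by convention.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if graph.number_of_nodes() == 0:
        return {}
    if graph.number_of_nodes() == 1:
        return {next(iter(graph.nodes)): np.zeros(2)}
    return nx.spring_layout(
        graph, weight="weight", iterations=iterations, seed=seed
    )


# ---------------------------------------------------------------------------
# hierarchical clustering (Ward.D2)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering result: linkage steps plus leaf labels.

    ``linkage`` is a standard (L-1) x 4 linkage matrix: each row merges
    two clusters (ids < L are leaves) at a given height.
    """

    linkage: np.ndarray
    labels: tuple

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cut(self, k: int) -> dict:
        """Partition the leaves into ``k`` flat clusters."""
        assign = hierarchy.fcluster(self.linkage, k, criterion="maxclust")
        return {lab: int(c) for lab, c in zip(self.labels, assign)}

    def leaf_order(self) -> list:
        """Leaf labels in dendrogram display order."""
        order = hierarchy.leaves_list(self.linkage)
        return [self.labels[i] for i in order]

    def to_newick(self) -> str:
        """Newick string with branch lengths from the merge heights.

        A child branch length is the parent merge height minus the
        child's own merge height (leaves sit at height 0).
        """
        tree = hierarchy.to_tree(self.linkage)

        def fmt(node, parent_height):
            bl = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{bl:.10g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{bl:.10g}"

        left = fmt(tree.left, tree.dist)
        right = fmt(tree.right, tree.dist)
        return f"({left},{right});"


def profile_matrix(
    table: pd.DataFrame,
    targets: Sequence | None = None,
    q_thresh: float = DEFAULT_Q_THRESH,
    fill: float = 0.0,
) -> pd.DataFrame:
    """r-value profiles (targets x genes) for clustering.

    Columns are the genes significant (``q < q_thresh``, self excluded)
    for at least one of the clustered targets; cells hold the r-value of
    (target, gene) — including the self-correlation r = 1 when a target
    gene is itself a column — with absent combinations set to ``fill``
    so the matrix is complete.
    """
    if targets is None:
        targets = list(pd.unique(table["target"]))
    else:
        targets = list(targets)
    sub = table[table["target"].isin(targets)]
    sig = sub[
        (sub["gene"] != sub["target"]) & sub["q"].notna()
        & (sub["q"] < q_thresh)
    ]
    genes = sorted(set(sig["gene"]))
    prof = pd.DataFrame(fill, index=pd.Index(targets, name="target"),
                        columns=pd.Index(genes, name="gene"), dtype=float)
    have = sub[sub["gene"].isin(set(genes)) & sub["r"].notna()]
    for rec in have.itertuples(index=False):
        prof.loc[rec.target, rec.gene] = rec.r
    return prof


def hcluster_ward(profiles, labels: Sequence | None = None) -> Dendrogram:
    """Ward.D2 agglomerative clustering of row profiles.

    Euclidean distances between rows are clustered under Ward's minimal
    increase of within-cluster sum of squares (the variant that squares
    distances inside the Lance-Williams update, so merge heights are on
    the original Euclidean scale).
    """
    if isinstance(profiles, pd.DataFrame):
        if labels is None:
            labels = list(profiles.index)
        X = profiles.to_numpy(dtype=float)
    else:
        X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("profiles must be a 2-D matrix with >= 2 rows")
    if np.isnan(X).any():
        raise ValueError(
            "profiles contain missing values; impute or drop incomplete "
            "columns before clustering (profile_matrix fills them)"
        )
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    if len(labels) != X.shape[0]:
        raise ValueError("label count must match row count")
    Z = hierarchy.linkage(pdist(X), method="ward")
    return Dendrogram(linkage=Z, labels=tuple(labels))


# ---------------------------------------------------------------------------
# exports
# ---------------------------------------------------------------------------

def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edgelist_tsv(graph: nx.Graph, path) -> None:
    """TSV edge list: u, v, weight, sign, width (sorted for reproducibility)."""
    rows = [
        (str(u), str(v), d["weight"], d["sign"], d["width"])
        for u, v, d in graph.edges(data=True)
    ]
    rows.sort()
    df = pd.DataFrame(rows, columns=["u", "v", "weight", "sign", "width"])
    df.to_csv(path, sep="\t", index=False)


def write_layout_tsv(layout: dict, path) -> None:
    """TSV of node coordinates: node, x, y."""
    rows = [(str(n), float(xy[0]), float(xy[1])) for n, xy in layout.items()]
    rows.sort()
    pd.DataFrame(rows, columns=["node", "x", "y"]).to_csv(
        path, sep="\t", index=False
    )
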