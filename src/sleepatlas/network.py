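"""Bipartite network metrics for the consolidated domain x pathway atlas.

Rows are sleep phenotype domains, columns metabolite pathways; an edge means
at least one significant association, with the association count as the edge
weight.  Metrics follow the ecological bipartite-network toolkit: the
"cluster coefficient" is connectance (realised / possible links), shared
partners are common-neighbour counts, nestedness is NODF (binary and its
weighted extension), and community structure is Barber's bipartite
modularity Q, maximised exactly by partition enumeration on small graphs and
by seeded label propagation with restarts otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class BipartiteGraph:
    """Weighted bipartite incidence with row/column node labels.

    ``weights`` holds nonnegative counts; the binary adjacency is
    ``weights > 0``.  Row nodes and column nodes are distinct classes; edges
    exist only between classes.
    """

    weights: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.weights.to_numpy() < 0).any():
            raise ValueError("edge weights must be nonnegative")
        if self.weights.index.has_duplicates or self.weights.columns.has_duplicates:
            raise ValueError("node labels must be unique")

    @property
    def adjacency(self) -> np.ndarray:
        return (self.weights.to_numpy() > 0).astype(int)

    @property
    def n_links(self) -> int:
        return int(self.adjacency.sum())

    @property
    def row_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def col_degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=0)

    def drop_empty(self) -> "BipartiteGraph":
        """Remove rows/columns with no links (isolated nodes)."""
        a = self.weights
        return BipartiteGraph(a.loc[a.sum(axis=1) > 0, a.columns[a.sum(axis=0) > 0]])


def connectance(graph: BipartiteGraph) -> float:
    """Realised links over possible links: L / (n_rows * n_cols)."""
    n_r, n_c = graph.weights.shape
    if n_r == 0 or n_c == 0:
        raise ValueError("connectance undefined for an empty node class")
    return graph.n_links / (n_r * n_c)


def links_per_node(graph: BipartiteGraph) -> float:
    """Mean number of links per node, L / (n_rows + n_cols)."""
    n_r, n_c = graph.weights.shape
    return graph.n_links / (n_r + n_c)


def mean_shared_partners(graph: BipartiteGraph, axis: str = "rows") -> float:
    """Mean common-neighbour count over unordered node pairs on one side."""
    A = graph.adjacency if axis == "rows" else graph.adjacency.T
    if axis not in ("rows", "cols"):
        raise ValueError("axis must be 'rows' or 'cols'")
    n = A.shape[0]
    if n < 2:
        raise ValueError("shared partners need >= 2 nodes on the chosen axis")
    shared = A @ A.T
    iu = np.triu_indices(n, k=1)
    return float(shared[iu].mean())


def nestedness(graph: BipartiteGraph, weighted: bool = False) -> float:
    """NODF nestedness in [0, 100]; weighted variant on the count matrix.

    For each ordered pair with strictly decreasing marginal totals, the
    binary version scores the percentage of the sparser node's links shared
    with the denser one; equal fills contribute zero (the decreasing-fill
    rule).  The weighted version scores the percentage of the sparser node's
    positive cells that are strictly smaller than the corresponding cell of
    the denser node.  Row and column pair scores are averaged together.
    """
    M = graph.weights.to_numpy(dtype=float)
    if not weighted:
        M = (M > 0).astype(float)
    if M.sum() == 0:
        raise ValueError("nestedness undefined for an all-zero matrix")

    def pair_scores(mat: np.ndarray) -> list[float]:
        totals = mat.sum(axis=1)
        # evaluate in decreasing-total order so "i denser than j" is explicit
        order = np.argsort(-totals, kind="stable")
        mat = mat[order]
        totals = totals[order]
        scores = []
        n = mat.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                if totals[i] <= totals[j] or totals[j] == 0:
                    scores.append(0.0)
                    continue
                lower_pos = mat[j] > 0
                if not weighted:
                    overlap = (mat[i][lower_pos] > 0).sum() / lower_pos.sum()
                else:
                    overlap = (mat[j][lower_pos] < mat[i][lower_pos]).sum() \
                        / lower_pos.sum()
                scores.append(100.0 * overlap)
        return scores

    scores = pair_scores(M) + pair_scores(M.T)
    if not scores:
        raise ValueError("nestedness needs >= 2 rows and >= 2 columns")
    return float(np.mean(scores))


def _modularity_value(B: np.ndarray, m: float, row_labels: np.ndarray,
                      col_labels: np.ndarray) -> float:
    same = row_labels[:, None] == col_labels[None, :]
    return float((B * same).sum() / m)


def _partitions(n: int):
    """All set partitions of range(n) as restricted-growth label strings."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, maxl: int):
        if i == n:
            yield labels.copy()
            return
        for lab in range(maxl + 1):
            labels[i] = lab
            yield from rec(i + 1, max(maxl, lab + 1))

    yield from rec(0, 0)


def _assign_cols(B: np.ndarray, row_labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Optimal column labels given row labels.

    Each column independently joins the row module maximising its summed
    modularity contribution, or a fresh singleton module (contribution 0)
    when every row module scores negative.  This conditional optimisation is
    exact, so enumerating row partitions alone suffices for a global optimum.
    """
    labs = np.unique(row_labels)
    contrib = np.vstack([B[row_labels == lab].sum(axis=0) for lab in labs])
    best = contrib.max(axis=0)
    col_labels = labs[contrib.argmax(axis=0)]
    fresh = best < 0
    col_labels = col_labels.copy()
    if fresh.any():
        col_labels[fresh] = labs.max() + 1 + np.arange(fresh.sum())
        best = np.where(fresh, 0.0, best)
    return float(best.sum()), col_labels


def barber_modularity(
    graph: BipartiteGraph,
    seed: int = 0,
    exact_below: int = 12,
    restarts: int = 50,
    method: str = "auto",
) -> tuple[float, dict[str, int]]:
    """Barber bipartite modularity Q and the best joint partition found.

    Q = (1/m) * sum_ij (a_ij - k_i d_j / m) * [g(row i) == g(col j)], with m
    the number of edges.  The exact search enumerates set partitions of the
    smaller node class and assigns the other class optimally per node, which
    is globally optimal; it is used when the graph is small enough (total
    nodes <= ``exact_below``, or a smaller side of <= 9 nodes).  Otherwise
    seeded greedy label moves from ``restarts`` random starts report the best
    Q found, which never exceeds the exact optimum.
    """
    g = graph.drop_empty()
    A = g.adjacency.astype(float)
    m = A.sum()
    if m == 0:
        raise ValueError("modularity undefined for a graph with no edges")
    k = A.sum(axis=1)
    d = A.sum(axis=0)
    B = A - np.outer(k, d) / m
    n_r, n_c = A.shape
    n = n_r + n_c

    transpose = n_c < n_r
    Bx = B.T if transpose else B
    n_small = min(n_r, n_c)

    if method == "auto":
        method = "exact" if (n <= exact_below or n_small <= 9) else "heuristic"

    if method == "exact":
        best_q, best_pair = -np.inf, None
        for labels in _partitions(n_small):
            score, other = _assign_cols(Bx, labels)
            q = score / m
            if q > best_q:
                best_q, best_pair = q, (labels.copy(), other)
        small_labels, other_labels = best_pair
    elif method == "heuristic":
        rng = np.random.default_rng(seed)
        best_q, best_pair = -np.inf, None
        for _ in range(restarts):
            labels = rng.integers(0, max(2, n_small), size=n_small)
            prev = -np.inf
            for _ in range(200):
                score, other = _assign_cols(Bx, labels)
                # given the other side, re-optimise the small side the same way
                score2, labels = _assign_cols(Bx.T, other)
                if score2 <= prev + 1e-12:
                    break
                prev = score2
            score, other = _assign_cols(Bx, labels)
            q = score / m
            if q > best_q:
                best_q, best_pair = q, (labels.copy(), other)
        small_labels, other_labels = best_pair
    else:
        raise ValueError("method must be 'auto', 'exact' or 'heuristic'")

    if transpose:
        row_labels, col_labels = other_labels, small_labels
    else:
        row_labels, col_labels = small_labels, other_labels
    nodes = list(g.weights.index) + list(g.weights.columns)
    labels_all = np.concatenate([row_labels, col_labels])
    partition = {node: int(lab) for node, lab in zip(nodes, labels_all)}
    return float(best_q), partition


def to_networkx(graph: BipartiteGraph):
    """Unipartite view of the bipartite graph as a networkx Graph."""
    import networkx as nx

    G = nx.Graph()
    G.add_nodes_from(graph.weights.index, bipartite=0)
    G.add_nodes_from(graph.weights.columns, bipartite=1)
    W = graph.weights
    for r in W.index:
        for c in W.columns:
            if W.loc[r, c] > 0:
                G.add_edge(r, c, weight=float(W.loc[r, c]))
    return G


def fr_layout(graph: BipartiteGraph, seed: int = 0) -> pd.DataFrame:
    """Seeded Fruchterman-Reingold coordinates; isolated nodes on a ring.

    A single node sits at the origin.  Deterministic for a given seed.
    """
    import networkx as nx

    G = to_networkx(graph)
    nodes = list(G.nodes)
    if len(nodes) == 1:
        return pd.DataFrame([[0.0, 0.0]], index=nodes, columns=["x", "y"])
    isolated = [v for v in nodes if G.degree(v) == 0]
    connected = [v for v in nodes if G.degree(v) > 0]
    pos = {}
    if connected:
        pos = nx.spring_layout(G.subgraph(connected), seed=seed)
    for i, v in enumerate(isolated):
        ang = 2 * np.pi * i / max(len(isolated), 1)
        pos[v] = np.array([1.5 * np.cos(ang), 1.5 * np.sin(ang)])
    coords = pd.DataFrame({v: pos[v] for v in nodes}).T
    coords.columns = ["x", "y"]
    return coords


def network_properties(graph: BipartiteGraph, seed: int = 0) -> dict[str, float]:
    """All scalar metrics for one (sub)graph; NaN where undefined."""
    g = graph.drop_empty()
    out: dict[str, float] = {}
    if g.n_links == 0:
        return {k: float("nan") for k in (
            "n_links", "links_per_node", "connectance",
            "shared_partners_rows", "shared_partners_cols",
            "nestedness", "weighted_nestedness", "modularity_q")}
    out["n_links"] = g.n_links
    out["links_per_node"] = links_per_node(g)
    out["connectance"] = connectance(g)
    for key, axis in (("shared_partners_rows", "rows"),
                      ("shared_partners_cols", "cols")):
        try:
            out[key] = mean_shared_partners(g, axis)
        except ValueError:
            out[key] = float("nan")
    try:
        out["nestedness"] = nestedness(g, weighted=False)
        out["weighted_nestedness"] = nestedness(g, weighted=True)
    except ValueError:
        out["nestedness"] = out["weighted_nestedness"] = float("nan")
    out["modularity_q"], _ = barber_modularity(g, seed=seed)
    return out


def properties_by_superpathway(
    domain_by_subpathway: pd.DataFrame,
    annotation: pd.DataFrame,
    seed: int = 0,
) -> pd.DataFrame:
    """Network metrics per superpathway subgraph plus an all-metabolites row.

    Columns of the consolidated matrix are restricted to each superpathway's
    subpathways in turn; superpathways with no significant links are flagged
    with NaN metrics.
    """
    sub2sup = (annotation.drop_duplicates("subpathway")
               .set_index("subpathway")["superpathway"])
    rows = {}
    full = BipartiteGraph(domain_by_subpathway)
    rows["all"] = network_properties(full, seed=seed)
    for sup in sorted(sub2sup.unique()):
        cols = [c for c in domain_by_subpathway.columns
                if sub2sup.get(c) == sup]
        if not cols:
            continue
        sub = BipartiteGraph(domain_by_subpathway[cols])
        rows[sup] = network_properties(sub, seed=seed)
    out = pd.DataFrame(rows).T
    out.index.name = "superpathway"
    return out
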