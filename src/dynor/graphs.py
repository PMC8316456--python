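"""Graph container, random-graph generators and metric constructions.

Edge weights carry *distance* semantics (``w``); the adjacency used by the
diffusion operator carries *similarity* semantics (``a``).  For unweighted
graphs both are identically 1 on edges, so the distinction vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, dijkstra, minimum_spanning_tree

__all__ = [
    "WeightedGraph",
    "GeodesicField",
    "PlantedPartition",
    "DisconnectedGraphError",
    "generate_sbm",
    "generate_ssbm",
    "generate_multiscale_sbm",
    "generate_canonical",
    "to_similarity",
    "geodesics",
    "jaccard_graph",
    "filter_features",
    "simple_sparsify",
]


class DisconnectedGraphError(ValueError):
    """Raised when an operation that needs a connected graph gets one that is not."""


@dataclass
class WeightedGraph:
    """Undirected weighted graph with dense integer node ids ``0..n-1``.

    Parameters
    ----------
    n_nodes:
        Number of nodes.
    edges:
        ``(m, 2)`` integer array with ``u < v`` per row; no self loops,
        no duplicates.
    w:
        ``(m,)`` positive edge weights with distance semantics.
    a:
        ``(m,)`` non-negative edge similarities (defaults to ``w`` copied
        as all-ones for unweighted graphs, see :func:`to_similarity`).
    node_ids:
        Optional original node labels, ``node_ids[i]`` is the label of
        dense id ``i``.
    """

    n_nodes: int
    edges: np.ndarray
    w: np.ndarray
    a: np.ndarray
    node_ids: list | None = None
    _adj: sp.csr_matrix | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.w = np.asarray(self.w, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        if len(self.w) != len(self.edges) or len(self.a) != len(self.edges):
            raise ValueError("edges, w and a must have matching lengths")
        if len(self.edges):
            u, v = self.edges[:, 0], self.edges[:, 1]
            if np.any(u == v):
                raise ValueError("self-loops are not allowed")
            if np.any(u > v):
                raise ValueError("edges must be stored with u < v")
            if self.edges.max() >= self.n_nodes or self.edges.min() < 0:
                raise ValueError("edge endpoint outside 0..n-1")
            if np.any(self.w <= 0):
                raise ValueError("all edge weights w must be positive")
            if np.any(self.a < 0):
                raise ValueError("similarities must be non-negative")

    # -- derived structure -------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def adjacency(self, values: str = "similarity") -> sp.csr_matrix:
        """Symmetric sparse adjacency with ``similarity`` or ``distance`` values."""
        if values == "similarity":
            if self._adj is None:
                self._adj = self._build_adj(self.a)
            return self._adj
        if values == "distance":
            return self._build_adj(self.w)
        raise ValueError(f"unknown values kind {values!r}")

    def _build_adj(self, vals: np.ndarray) -> sp.csr_matrix:
        u, v = self.edges[:, 0], self.edges[:, 1]
        m = sp.coo_matrix(
            (np.concatenate([vals, vals]), (np.concatenate([u, v]), np.concatenate([v, u]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return m.tocsr()

    @property
    def degrees(self) -> np.ndarray:
        """Similarity-weighted degrees ``K_ii = sum_j A_ij``."""
        return np.asarray(self.adjacency().sum(axis=1)).ravel()

    @property
    def is_connected(self) -> bool:
        if self.n_nodes == 0:
            return False
        if self.n_edges == 0:
            return self.n_nodes == 1
        ncomp, _ = connected_components(self.adjacency(), directed=False)
        return ncomp == 1

    def largest_component(self) -> tuple["WeightedGraph", np.ndarray]:
        """Return the subgraph induced by the largest connected component.

        Returns the subgraph (with dense relabelled ids) and the array of
        retained original node ids.
        """
        ncomp, labels = connected_components(self.adjacency(), directed=False)
        if ncomp == 1:
            return self, np.arange(self.n_nodes)
        keep = np.flatnonzero(labels == np.bincount(labels).argmax())
        return self.subgraph(keep), keep

    def subgraph(self, nodes: np.ndarray) -> "WeightedGraph":
        nodes = np.asarray(nodes)
        pos = -np.ones(self.n_nodes, dtype=np.int64)
        pos[nodes] = np.arange(len(nodes))
        mask = (pos[self.edges[:, 0]] >= 0) & (pos[self.edges[:, 1]] >= 0)
        edges = pos[self.edges[mask]]
        edges.sort(axis=1)
        ids = None
        if self.node_ids is not None:
            ids = [self.node_ids[i] for i in nodes]
        return WeightedGraph(len(nodes), edges, self.w[mask], self.a[mask], node_ids=ids)

    # -- conversions -------------------------------------------------------
    @classmethod
    def from_networkx(cls, g: nx.Graph, weight: str = "weight") -> "WeightedGraph":
        """Build from an undirected networkx graph; missing weights default to 1."""
        if g.is_directed() or g.is_multigraph():
            raise ValueError("only simple undirected graphs are supported")
        node_ids = list(g.nodes())
        index = {u: i for i, u in enumerate(node_ids)}
        edges, w = [], []
        for u, v, data in g.edges(data=True):
            if u == v:
                continue
            i, j = index[u], index[v]
            edges.append((min(i, j), max(i, j)))
            w.append(float(data.get(weight, 1.0)))
        edges = np.array(edges, dtype=np.int64).reshape(-1, 2)
        w = np.array(w)
        ids = node_ids if any(u != i for i, u in enumerate(node_ids)) else None
        return cls(g.number_of_nodes(), edges, w, np.ones_like(w), node_ids=ids)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for (u, v), wi, ai in zip(self.edges, self.w, self.a):
            g.add_edge(int(u), int(v), weight=float(wi), similarity=float(ai))
        return g


@dataclass
class GeodesicField:
    """All-pairs shortest-path distances under the edge weights ``w``."""

    d: np.ndarray  # (n, n) dense
    d0: float  # min over edges of d_ij


@dataclass
class PlantedPartition:
    """Ground-truth block structure of a generated SBM graph."""

    labels: np.ndarray
    block_sizes: list
    p_in: float | None = None
    p_out: float | None = None

    @property
    def n_blocks(self) -> int:
        return len(self.block_sizes)

    @property
    def k_bar(self) -> float | None:
        """Mean degree ``n (p_in + p_out) / 2`` of the symmetric two-block model."""
        if self.p_in is None or self.p_out is None:
            return None
        n = int(np.sum(self.block_sizes))
        return n * (self.p_in + self.p_out) / 2

    @property
    def r(self) -> float | None:
        """Edge-density ratio ``p_out / p_in``."""
        if self.p_in is None or self.p_out is None or self.p_in == 0:
            return None
        return self.p_out / self.p_in


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_sbm(block_sizes, P, seed=None):
    """Stochastic block model: each node pair drawn independently.

    Parameters
    ----------
    block_sizes:
        Positive block sizes.
    P:
        ``(B, B)`` symmetric matrix of block-pair edge probabilities.
    seed:
        Integer seed or :class:`numpy.random.Generator`.

    Returns
    -------
    (WeightedGraph, PlantedPartition)
    """
    block_sizes = [int(s) for s in block_sizes]
    if any(s <= 0 for s in block_sizes):
        raise ValueError("block sizes must be positive")
    P = np.asarray(P, dtype=float)
    if np.any(P < 0) or np.any(P > 1):
        raise ValueError("edge probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = sum(block_sizes)
    labels = np.repeat(np.arange(len(block_sizes)), block_sizes)
    # vectorised draw over the strict upper triangle
    iu, ju = np.triu_indices(n, k=1)
    probs = P[labels[iu], labels[ju]]
    mask = rng.random(len(iu)) < probs
    edges = np.column_stack([iu[mask], ju[mask]])
    w = np.ones(len(edges))
    graph = WeightedGraph(n, edges, w, w.copy())
    return graph, PlantedPartition(labels, block_sizes)


def generate_ssbm(n, p_in, p_out, seed=None):
    """Symmetric two-block SBM with equal block sizes ``n/2``."""
    if n % 2:
        raise ValueError("n must be even for the symmetric SBM")
    graph, part = generate_sbm([n // 2, n // 2], [[p_in, p_out], [p_out, p_in]], seed)
    part.p_in = float(p_in)
    part.p_out = float(p_out)
    return graph, part


#: block sizes and within-block edge probabilities of the two-scale SBM demo graph
MULTISCALE_SIZES = (30, 40, 35, 50)
MULTISCALE_P_IN = (0.7, 0.8, 0.9, 0.6)


def generate_multiscale_sbm(seed=None, strong_pairs=((0, 1), (2, 3)),
                            p_strong=0.1, p_weak=0.02):
    """Four-block SBM with a coarser two-superblock scale.

    Blocks of sizes 30, 40, 35, 50 with within-block probabilities
    0.7, 0.8, 0.9, 0.6.  Block pairs listed in ``strong_pairs`` are joined
    with probability ``p_strong`` (default 0.1), every other pair with
    ``p_weak`` (default 0.02), creating two superblocks at a coarse scale.

    Returns
    -------
    (WeightedGraph, PlantedPartition fine, PlantedPartition coarse)
    """
    P = np.full((4, 4), p_weak)
    for i, j in strong_pairs:
        P[i, j] = P[j, i] = p_strong
    np.fill_diagonal(P, MULTISCALE_P_IN)
    graph, fine = generate_sbm(MULTISCALE_SIZES, P, seed)
    # coarse labels: one superblock per strong pair, by membership
    coarse_of_block = np.arange(4)
    for s, (i, j) in enumerate(strong_pairs):
        coarse_of_block[i] = coarse_of_block[j] = s
    coarse = PlantedPartition(coarse_of_block[fine.labels],
                              [int(np.sum(coarse_of_block == s)) for s in np.unique(coarse_of_block)])
    return graph, fine, coarse


def generate_canonical(kind, seed=None, **params):
    """Canonical graphs used as curvature fixtures.

    ``kind`` is one of ``cycle, path, grid2d, clique, balanced_tree,
    barbell, erdos_renyi``; keyword parameters follow the corresponding
    networkx constructor (``n``; ``rows, cols``; ``branching, depth``;
    ``m1, m2``; ``n, p``).
    """
    builders = {
        "cycle": lambda: nx.cycle_graph(params["n"]),
        "path": lambda: nx.path_graph(params["n"]),
        "grid2d": lambda: nx.grid_2d_graph(params["rows"], params["cols"]),
        "clique": lambda: nx.complete_graph(params["n"]),
        "balanced_tree": lambda: nx.balanced_tree(params.get("branching", 2), params["depth"]),
        "barbell": lambda: nx.barbell_graph(params["m1"], params.get("m2", 0)),
        "erdos_renyi": lambda: nx.gnp_random_graph(
            params["n"], params["p"],
            seed=int(np.random.default_rng(seed).integers(2**31))),
    }
    if kind not in builders:
        raise ValueError(f"unknown canonical graph kind {kind!r}")
    try:
        g = builders[kind]()
    except KeyError as exc:
        raise ValueError(f"missing parameter {exc} for kind {kind!r}") from exc
    g = nx.convert_node_labels_to_integers(g, ordering="sorted")
    return WeightedGraph.from_networkx(g)


# ---------------------------------------------------------------------------
# weight-semantics conversions and metric structure
# ---------------------------------------------------------------------------

def to_similarity(w, mode="unit"):
    """Convert distance weights to non-negative similarities.

    ``shifted``: ``A_ij = max_uv w_uv - w_ij`` (zeroes the maximal edge);
    ``exponential``: ``A_ij = exp(-w_ij)``; ``unit``: ``A_ij = 1``.
    """
    w = np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("distance weights must be positive")
    if mode == "unit":
        return np.ones_like(w)
    if mode == "exponential":
        return np.exp(-w)
    if mode == "shifted":
        a = w.max() - w
        if np.any(a == 0):
            warnings.warn(
                "shifted similarity zeroes the maximal edge(s); nodes whose every "
                "edge is maximal end up with zero degree", stacklevel=2)
        return a
    raise ValueError(f"unknown similarity mode {mode!r}")


def geodesics(graph: WeightedGraph) -> GeodesicField:
    """All-pairs shortest paths with the distance weights as edge lengths."""
    if not graph.is_connected:
        raise DisconnectedGraphError("geodesics require a connected graph")
    d = dijkstra(graph.adjacency("distance"), directed=False)
    u, v = graph.edges[:, 0], graph.edges[:, 1]
    d0 = float(d[u, v].min()) if len(u) else 0.0
    return GeodesicField(d=d, d0=d0)


# ---------------------------------------------------------------------------
# feature-matrix constructions
# ---------------------------------------------------------------------------

def jaccard_graph(B, node_ids=None) -> WeightedGraph:
    """All-to-all graph weighted by Jaccard similarity of binary feature rows.

    The similarity ``|intersection| / |union|`` of the feature sets goes into
    ``a``; the geodesic distance weight is ``w = 1 - similarity``.  Pairs with
    zero similarity carry no edge, and identical rows (similarity 1, distance
    0) are joined with a small positive distance floor of 1e-12 to keep ``w``
    a valid edge length.
    """
    B = np.asarray(B)
    if not np.isin(B, (0, 1)).all():
        raise ValueError("feature matrix must be binary")
    counts = B.sum(axis=1)
    if np.any(counts == 0):
        raise ValueError("all-zero feature rows have undefined Jaccard similarity")
    inter = (B @ B.T).astype(float)
    union = counts[:, None] + counts[None, :] - inter
    sim = inter / union
    n = len(B)
    iu, ju = np.triu_indices(n, k=1)
    s = sim[iu, ju]
    mask = s > 0
    edges = np.column_stack([iu[mask], ju[mask]])
    a = s[mask]
    w = np.maximum(1.0 - a, 1e-12)
    return WeightedGraph(n, edges, w, a, node_ids=node_ids)


def filter_features(B, upper_frac=0.9):
    """Drop binary feature columns expressed in no rows or in more than
    ``upper_frac`` of the rows.

    Returns the reduced matrix and the retained column indices.
    """
    B = np.asarray(B)
    frac = B.mean(axis=0)
    keep = np.flatnonzero((frac > 0) & (frac <= upper_frac))
    if len(keep) == 0:
        raise ValueError("the filter removed every feature column")
    return B[:, keep], keep


def simple_sparsify(graph: WeightedGraph, gamma: float) -> WeightedGraph:
    """Keep a minimum spanning tree plus the highest-similarity extra edges.

    A plain connectivity-preserving sparsifier: the MST under the distance
    weights is always kept, then non-tree edges are added in decreasing
    similarity order until at most ``gamma * m`` edges in total (the MST may
    already exceed that budget, in which case only the tree is returned).
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not graph.is_connected:
        raise DisconnectedGraphError("sparsification requires a connected graph")
    m = graph.n_edges
    budget = int(np.floor(gamma * m))
    mst = minimum_spanning_tree(graph.adjacency("distance")).tocoo()
    tree_pairs = {(min(i, j), max(i, j)) for i, j in zip(mst.row, mst.col)}
    in_tree = np.array([(u, v) in tree_pairs for u, v in graph.edges])
    keep = in_tree.copy()
    n_extra = max(0, budget - int(in_tree.sum()))
    if n_extra:
        candidates = np.flatnonzero(~in_tree)
        order = candidates[np.argsort(-graph.a[candidates], kind="stable")]
        keep[order[:n_extra]] = True
    return WeightedGraph(graph.n_nodes, graph.edges[keep], graph.w[keep],
                         graph.a[keep], node_ids=graph.node_ids)
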