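"""Geometric modularity and multiscale community detection.

Geometric modularity scores a partition C at scale tau by

    Q_kappa(C, tau) = (1 / 2m_kappa) * sum_edges (kappa_ij(tau) - kappa0) * delta(C_i, C_j),

with ``2 m_kappa = sum_edges |kappa_ij|`` and ``kappa0`` the maximal edge
curvature at the smallest computed scale, which makes every edge weight
non-positive there.  No statistical null model is involved: communities
exist wherever the curvature deviates from its small-scale baseline.
Optimisation is a Louvain-style greedy scheme that works directly with the
signed edge weights ``kappa_ij - kappa0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .curvature import CurvatureField, curvature_field
from .diffusion import ScaleGrid
from .graphs import WeightedGraph

__all__ = [
    "Partition",
    "ModularityContext",
    "ScanResult",
    "geometric_modularity",
    "louvain_signed",
    "variation_of_information",
    "partition_agreement",
    "scale_scan",
    "robust_scales",
]


@dataclass
class Partition:
    """Community labels with dense ids ``0..k-1``."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = canonical_labels(self.labels)

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if len(self.labels) else 0


def canonical_labels(labels) -> np.ndarray:
    """Relabel community ids densely in order of first appearance."""
    labels = np.asarray(labels)
    _, inv = np.unique(labels, return_inverse=True)
    first = {}
    out = np.empty(len(labels), dtype=np.int64)
    nxt = 0
    for i, c in enumerate(inv):
        if c not in first:
            first[c] = nxt
            nxt += 1
        out[i] = first[c]
    return out


@dataclass
class ModularityContext:
    """One curvature slice prepared for modularity evaluation."""

    edges: np.ndarray
    kappa_slice: np.ndarray
    kappa0: float
    n_nodes: int

    @property
    def b(self) -> np.ndarray:
        """Signed gain weights ``kappa_ij - kappa0``."""
        return self.kappa_slice - self.kappa0

    @property
    def two_m_kappa(self) -> float:
        return float(np.abs(self.kappa_slice).sum())

    @classmethod
    def from_field(cls, field: CurvatureField, tau_index: int, n_nodes: int,
                   kappa0: float | None = None) -> "ModularityContext":
        if kappa0 is None:
            kappa0 = float(field.kappa[:, 0].max())
        return cls(edges=field.edges, kappa_slice=field.kappa[:, tau_index],
                   kappa0=kappa0, n_nodes=n_nodes)


def geometric_modularity(context: ModularityContext, partition) -> float:
    """Evaluate ``Q_kappa`` for a partition (labels array or Partition)."""
    labels = partition.labels if isinstance(partition, Partition) else np.asarray(partition)
    norm = context.two_m_kappa
    if norm == 0:
        raise ValueError("all curvatures are zero: modularity undefined")
    same = labels[context.edges[:, 0]] == labels[context.edges[:, 1]]
    return float(context.b[same].sum() / norm)


# ---------------------------------------------------------------------------
# signed Louvain
# ---------------------------------------------------------------------------

def _louvain_one_level(neigh_idx, neigh_w, n, rng):
    """Greedy node-move phase; returns labels (not canonical)."""
    labels = np.arange(n)
    order = rng.permutation(n)
    moved = True
    while moved:
        moved = False
        for u in order:
            cu = labels[u]
            nbrs = neigh_idx[u]
            if len(nbrs) == 0:
                continue
            # accumulate signed weight towards each neighbouring community
            gains: dict[int, float] = {}
            for v, wv in zip(nbrs, neigh_w[u]):
                gains[labels[v]] = gains.get(labels[v], 0.0) + wv
            stay = gains.get(cu, 0.0)
            # first-improvement: move to the first community that beats staying
            for c, g in gains.items():
                if c != cu and g > stay + 1e-12:
                    labels[u] = c
                    moved = True
                    break
    return labels


def _aggregate(edges, b, labels):
    """Collapse communities to meta-nodes, summing signed weights; drops
    self-loops (they are constant under further moves)."""
    labels = canonical_labels(labels)
    k = labels.max() + 1
    eu = labels[edges[:, 0]]
    ev = labels[edges[:, 1]]
    lo = np.minimum(eu, ev)
    hi = np.maximum(eu, ev)
    keep = lo != hi
    key = lo[keep] * k + hi[keep]
    uniq, inv = np.unique(key, return_inverse=True)
    w = np.zeros(len(uniq))
    np.add.at(w, inv, b[keep])
    new_edges = np.column_stack([uniq // k, uniq % k])
    return new_edges, w, int(k), labels


def _build_neighbors(edges, w, n):
    neigh_idx = [[] for _ in range(n)]
    neigh_w = [[] for _ in range(n)]
    for (u, v), wi in zip(edges, w):
        neigh_idx[u].append(v)
        neigh_w[u].append(wi)
        neigh_idx[v].append(u)
        neigh_w[v].append(wi)
    return ([np.array(a, dtype=np.int64) for a in neigh_idx],
            [np.array(a) for a in neigh_w])


def _louvain_single_run(edges, b, n, rng):
    mapping = np.arange(n)
    cur_edges, cur_b, cur_n = edges, b, n
    while True:
        neigh_idx, neigh_w = _build_neighbors(cur_edges, cur_b, cur_n)
        labels = _louvain_one_level(neigh_idx, neigh_w, cur_n, rng)
        cur_edges, cur_b, new_n, labels = _aggregate(cur_edges, cur_b, labels)
        mapping = labels[mapping]
        if new_n == cur_n:
            break
        cur_n = new_n
    return canonical_labels(mapping)


def louvain_signed(edges, b, n_nodes, seed=None, n_runs=100):
    """Maximise ``sum_edges b_ij delta(C_i, C_j)`` by multi-run greedy Louvain.

    Each run shuffles the node sweep order; moves are first-improvement with
    ties broken toward the current community, followed by graph aggregation
    until no move improves the objective.  Returns the best partition, the
    full list of sampled partitions, and their objectives.
    """
    edges = np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=float)
    if not np.isfinite(b).all():
        raise ValueError("gain weights must be finite")
    rng = np.random.default_rng(seed)
    partitions, objectives = [], []
    for _ in range(max(1, n_runs)):
        labels = _louvain_single_run(edges, b, n_nodes, rng)
        same = labels[edges[:, 0]] == labels[edges[:, 1]]
        partitions.append(labels)
        objectives.append(float(b[same].sum()))
    best = int(np.argmax(objectives))
    return Partition(partitions[best]), partitions, np.array(objectives)


# ---------------------------------------------------------------------------
# partition comparison
# ---------------------------------------------------------------------------

def variation_of_information(labels1, labels2) -> float:
    """VI(P1, P2) = H(P1) + H(P2) - 2 I(P1; P2), in nats."""
    l1 = np.asarray(labels1)
    l2 = np.asarray(labels2)
    if len(l1) != len(l2):
        raise ValueError("partitions must cover the same node set")
    n = len(l1)
    _, c1 = np.unique(l1, return_inverse=True)
    _, c2 = np.unique(l2, return_inverse=True)
    joint = c1 * (c2.max() + 1) + c2
    nij = np.bincount(joint).astype(float)
    nij = nij[nij > 0] / n
    ni = np.bincount(c1).astype(float) / n
    nj = np.bincount(c2).astype(float) / n
    h1 = -np.sum(ni * np.log(ni))
    h2 = -np.sum(nj * np.log(nj))
    hj = -np.sum(nij * np.log(nij))
    mi = h1 + h2 - hj
    return float(max(0.0, h1 + h2 - 2 * mi))


def partition_agreement(labels1, labels2) -> float:
    """Fraction of nodes on which the partitions agree under the best
    one-to-one matching of community ids (Hungarian assignment)."""
    from scipy.optimize import linear_sum_assignment

    l1 = canonical_labels(labels1)
    l2 = canonical_labels(labels2)
    k1, k2 = l1.max() + 1, l2.max() + 1
    cont = np.zeros((k1, k2))
    np.add.at(cont, (l1, l2), 1)
    rows, cols = linear_sum_assignment(-cont)
    return float(cont[rows, cols].sum() / len(l1))


# ---------------------------------------------------------------------------
# the multiscale scan
# ---------------------------------------------------------------------------

@dataclass
class ScanResult:
    grid: ScaleGrid
    best_partitions: list  # Partition per scale
    best_q: np.ndarray
    n_communities: np.ndarray
    vi_tau: np.ndarray
    vi_cross: np.ndarray  # (T, T)
    kappa0: float
    field: CurvatureField | None = None
    meta: dict = dc_field(default_factory=dict)

    def summary(self):
        import pandas as pd

        return pd.DataFrame({
            "tau": self.grid.taus,
            "q": self.best_q,
            "n_communities": self.n_communities,
            "vi_tau": self.vi_tau,
        })


def scale_scan(graph: WeightedGraph, grid: ScaleGrid | None = None,
               field: CurvatureField | None = None, n_runs: int = 100,
               n_vi: int = 50, seed=None, method: str = "auto",
               vi_mode: str = "best_vs_pool",
               **curvature_kwargs) -> ScanResult:
    """Optimise geometric modularity at every scale and collect stability
    statistics.

    Per scale: ``n_runs`` Louvain restarts sample the cluster landscape;
    the best-Q partition is kept, its mean VI against ``n_vi`` randomly
    chosen sampled partitions gives ``vi_tau`` (``vi_mode='pairwise'``
    instead averages VI over random pairs from the pool), and the VI
    between best partitions of all scale pairs fills ``vi_cross``.
    """
    if field is None:
        field = curvature_field(graph, grid, method=method, **curvature_kwargs)
    grid = field.grid
    rng = np.random.default_rng(seed)
    if n_runs < 2:
        import warnings

        warnings.warn("n_runs < 2 makes the stability statistics degenerate",
                      stacklevel=2)
    kappa0 = float(field.kappa[:, 0].max())
    T = len(grid)
    best_parts, best_q, n_comms, vi_tau = [], [], [], []
    for ti in range(T):
        ctx = ModularityContext.from_field(field, ti, graph.n_nodes, kappa0)
        best, pool, objs = louvain_signed(ctx.edges, ctx.b, graph.n_nodes,
                                          seed=rng.integers(2**31),
                                          n_runs=n_runs)
        norm = ctx.two_m_kappa
        best_parts.append(best)
        best_q.append(objs.max() / norm if norm > 0 else 0.0)
        n_comms.append(best.n_communities)
        if vi_mode == "best_vs_pool":
            take = rng.choice(len(pool), size=min(n_vi, len(pool)), replace=False)
            vi_tau.append(float(np.mean([
                variation_of_information(best.labels, pool[i]) for i in take])))
        elif vi_mode == "pairwise":
            pairs = rng.integers(0, len(pool), size=(min(n_vi, len(pool)), 2))
            vi_tau.append(float(np.mean([
                variation_of_information(pool[i], pool[j]) for i, j in pairs])))
        else:
            raise ValueError(f"unknown vi_mode {vi_mode!r}")
    vi_cross = np.zeros((T, T))
    for i in range(T):
        for j in range(i + 1, T):
            vi_cross[i, j] = vi_cross[j, i] = variation_of_information(
                best_parts[i].labels, best_parts[j].labels)
    return ScanResult(grid=grid, best_partitions=best_parts,
                      best_q=np.array(best_q), n_communities=np.array(n_comms),
                      vi_tau=np.array(vi_tau), vi_cross=vi_cross,
                      kappa0=kappa0, field=field,
                      meta={"n_runs": n_runs, "n_vi": n_vi, "vi_mode": vi_mode})


def robust_scales(scan: ScanResult, vi_tol: float | None = None,
                  plateau_len: int = 3, nontrivial: bool = True):
    """Contiguous low-VI plateaus of the scan and one partition per plateau.

    A scale is *stable* when its ``vi_tau`` stays below ``vi_tol`` (default
    ``0.05 * ln(n)``); a plateau is a maximal run of consecutive stable
    scales whose best partitions persist across the run (cross-scale VI
    between consecutive scales below ``vi_tol``) of length at least
    ``plateau_len`` grid points.  The representative partition of a plateau
    is its highest-Q scale.  With ``nontrivial`` (default) the two
    structureless end states -- all singletons (diffusions not yet mixed)
    and a single community (fully mixed) -- are not reported as community
    structure.  Returns a list of ``(tau, Partition, scale_indices)``.
    """
    n = len(scan.best_partitions[0].labels)
    if vi_tol is None:
        vi_tol = 0.05 * np.log(n)
    T = len(scan.grid)
    ok = np.array([
        scan.vi_tau[t] <= vi_tol
        and not (nontrivial and scan.n_communities[t] in (1, n))
        for t in range(T)
    ])
    plateaus = []
    t = 0
    while t < T:
        if ok[t]:
            start = t
            # extend while the next scale is stable and its best partition
            # persists (low cross-scale VI to the previous one)
            while t + 1 < T and ok[t + 1] and scan.vi_cross[t, t + 1] <= vi_tol:
                t += 1
            idx = np.arange(start, t + 1)
            if len(idx) >= plateau_len:
                rep = idx[np.argmax(scan.best_q[idx])]
                plateaus.append((float(scan.grid.taus[rep]),
                                 scan.best_partitions[rep], idx))
        t += 1
    return plateaus
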