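"""Sparsity-thresholded binary brain networks and topology metrics.

A weighted PLI matrix is binarized by *proportional* (global) sparsity
thresholding: at sparsity S the strongest ``round(S * n(n-1)/2)`` edges
are kept, so every subject's network has the same edge count and group
differences reflect topology, not overall connectivity strength. The
sweep covers S = 0.1 ... 0.5 in steps of 0.05 and each metric is
additionally summarised by its trapezoidal area under the curve (AUC)
over the sweep, the summary used for group statistics.

Metric conventions (they differ between metrics, deliberately):

* global efficiency  E_glob = mean over ordered pairs of 1/d(i, j),
  with 1/inf = 0 for disconnected pairs — always defined, in [0, 1];
* characteristic path length L = mean of the *finite* shortest-path
  distances over connected ordered pairs (disconnected pairs excluded,
  their count reported);
* nodal efficiency E_nodal(i) = mean over j != i of 1/d(i, j).

Under these conventions mean(E_nodal) = E_glob holds exactly on every
graph. Distances are unweighted shortest paths computed by per-source
breadth-first search.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import PLIMatrix

__all__ = [
    "AdjacencyMatrix",
    "NetworkMetrics",
    "binarize_by_sparsity",
    "global_efficiency",
    "characteristic_path_length",
    "nodal_efficiency",
    "sparsity_sweep",
]


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency matrix with its achieved sparsity."""

    a: np.ndarray
    sparsity: float

    def __post_init__(self) -> None:
        a = np.asarray(self.a)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops not allowed")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.a = a.astype(np.int8)

    @property
    def n(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum() // 2)


def binarize_by_sparsity(m: PLIMatrix | np.ndarray, s: float) -> AdjacencyMatrix:
    """Keep the top ``round(s * n(n-1)/2)`` strongest edges.

    Ties at the cutoff are broken by fixed lexicographic pair order
    (smaller ``(i, j)`` wins), making the result deterministic across
    runs for equal weights.
    """
    w = m.m if isinstance(m, PLIMatrix) else np.asarray(m, dtype=float)
    n = w.shape[0]
    if not 0.0 < s < 1.0:
        raise ValueError("sparsity must lie in (0, 1)")
    n_pairs = n * (n - 1) // 2
    k = int(round(s * n_pairs))
    if k < 1:
        raise ValueError(f"sparsity {s} keeps zero edges for n = {n}")
    iu, ju = np.triu_indices(n, k=1)
    weights = w[iu, ju]
    # primary key: descending weight; ties: ascending (i, j)
    order = np.lexsort((ju, iu, -weights))
    keep = order[:k]
    a = np.zeros((n, n), dtype=np.int8)
    a[iu[keep], ju[keep]] = 1
    a = a + a.T  # upper triangle only was set, so this symmetrizes
    return AdjacencyMatrix(a, k / n_pairs)


def _distances(adj: AdjacencyMatrix) -> np.ndarray:
    """All-pairs unweighted shortest-path distances (inf = disconnected)."""
    g = csr_matrix(adj.a)
    return shortest_path(g, method="D", unweighted=True, directed=False)


def global_efficiency(adj: AdjacencyMatrix,
                      _dist: np.ndarray | None = None) -> float:
    """Mean inverse shortest-path length over ordered node pairs.

    Disconnected pairs contribute 0 (1/inf). Equals 1 on a complete
    graph and 0 on an empty one.
    """
    if adj.n < 2:
        raise ValueError("need >= 2 nodes")
    d = _distances(adj) if _dist is None else _dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return float(inv.sum() / (adj.n * (adj.n - 1)))


def characteristic_path_length(adj: AdjacencyMatrix,
                               _dist: np.ndarray | None = None
                               ) -> tuple[float, int]:
    """Mean finite shortest-path distance over connected ordered pairs.

    Returns ``(L, n_excluded)`` where ``n_excluded`` counts the
    disconnected ordered pairs left out of the mean. Raises on a graph
    with no edges (every pair disconnected).
    """
    if adj.n_edges == 0:
        raise ValueError("graph has no edges: path length undefined")
    d = _distances(adj) if _dist is None else _dist
    off = ~np.eye(adj.n, dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int((off & ~finite).sum())
    return float(d[finite].mean()), n_excluded


def nodal_efficiency(adj: AdjacencyMatrix,
                     _dist: np.ndarray | None = None) -> np.ndarray:
    """Per-node mean inverse distance to every other node.

    Disconnected targets contribute 0; an isolated node scores 0. The
    mean of this vector equals :func:`global_efficiency` exactly.
    """
    if adj.n < 2:
        raise ValueError("need >= 2 nodes")
    d = _distances(adj) if _dist is None else _dist
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    np.fill_diagonal(inv, 0.0)
    inv[np.isinf(d)] = 0.0
    return inv.sum(axis=1) / (adj.n - 1)


@dataclass
class NetworkMetrics:
    """Topology metrics across a sparsity sweep, with AUC aggregates."""

    sparsities: np.ndarray
    e_global: np.ndarray          # per level
    char_path_length: np.ndarray  # per level (nan where undefined)
    n_excluded_pairs: np.ndarray  # disconnected ordered pairs per level
    e_nodal: np.ndarray           # (n_levels, n_nodes)
    auc: dict = field(default_factory=dict)
    channel_labels: list[str] = field(default_factory=list)
    condition: str | None = None
    subject_id: str | None = None
    group: str | None = None


def sparsity_sweep(m: PLIMatrix | np.ndarray, s_min: float = 0.1,
                   s_max: float = 0.5, step: float = 0.05) -> NetworkMetrics:
    """Compute all three metrics at each sparsity level plus AUCs.

    The AUC (trapezoidal integral of the metric over the sparsity
    range) is the per-subject summary used in group statistics.
    """
    if s_min >= s_max:
        raise ValueError("empty sparsity sweep")
    levels = np.round(np.arange(s_min, s_max + step / 2, step), 10)
    w = m.m if isinstance(m, PLIMatrix) else np.asarray(m, dtype=float)
    n = w.shape[0]
    e_glob, cpl, excl, e_nod = [], [], [], []
    for s in levels:
        adj = binarize_by_sparsity(w, float(s))
        d = _distances(adj)
        e_glob.append(global_efficiency(adj, _dist=d))
        L, nx_ = characteristic_path_length(adj, _dist=d)
        cpl.append(L)
        excl.append(nx_)
        e_nod.append(nodal_efficiency(adj, _dist=d))
    e_glob = np.asarray(e_glob)
    cpl = np.asarray(cpl)
    e_nod = np.asarray(e_nod)
    auc = {
        "e_global": float(np.trapezoid(e_glob, levels)),
        "char_path_length": float(np.trapezoid(cpl, levels)),
        "e_nodal": np.trapezoid(e_nod, levels, axis=0),
    }
    meta = {}
    if isinstance(m, PLIMatrix):
        meta = dict(channel_labels=list(m.channel_labels),
                    condition=m.condition, subject_id=m.subject_id,
                    group=m.group)
    return NetworkMetrics(levels, e_glob, cpl, np.asarray(excl), e_nod,
                          auc, **meta)
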