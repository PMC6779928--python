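"""Independent reference implementations (oracles) used by the tests.

These deliberately re-derive quantities with naive algorithms — explicit
loops, Floyd-Warshall, textbook sums of squares — and stay independent
of the vectorised package code paths they are checked against.
"""
import numpy as np


def naive_pli(phase: np.ndarray) -> np.ndarray:
    """Per-pair, per-sample PLI via explicit per-trial loops.

    ``phase`` is (n_channels, n_samples, n_trials); returns
    (n_pairs, n_samples) with pairs in (i < j) lexicographic order.
    """
    C, S, T = phase.shape
    rows = []
    for i in range(C):
        for j in range(i + 1, C):
            row = np.empty(S)
            for t in range(S):
                total = 0.0
                for n in range(T):
                    d = phase[i, t, n] - phase[j, t, n]
                    w = d % (2.0 * np.pi)
                    if w > np.pi:
                        w -= 2.0 * np.pi
                    total += float(w > 0) - float(w < 0)
                row[t] = abs(total / T)
            rows.append(row)
    return np.asarray(rows)


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by the classic triple loop (vectorised
    only over the matrix update)."""
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        d = np.minimum(d, d[:, k, None] + d[None, k, :])
    return d


def metrics_from_distances(d: np.ndarray):
    """(e_global, char_path_length, e_nodal) from a distance matrix,
    using the 1/inf = 0 and connected-pairs-only conventions."""
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isinf(d), 0.0, 1.0 / np.where(d == 0, np.inf, d))
    e_nodal = np.array([inv[i, off[i]].mean() for i in range(n)])
    e_global = inv[off].mean()
    finite = off & np.isfinite(d)
    cpl = d[finite].mean() if finite.any() else np.nan
    return e_global, cpl, e_nodal


def split_plot_anova(x: np.ndarray, groups: np.ndarray) -> dict:
    """Textbook mixed-design ANOVA F ratios via explicit summation."""
    levels = sorted(set(groups))
    N, C = x.shape
    g = len(levels)
    gm = x.mean()
    ss_group = 0.0
    for lev in levels:
        sel = np.asarray(groups) == lev
        ss_group += sel.sum() * C * (x[sel].mean() - gm) ** 2
    ss_bs = sum(C * (x[i].mean() - gm) ** 2 for i in range(N))
    ss_subj = ss_bs - ss_group
    ss_cond = sum(N * (x[:, c].mean() - gm) ** 2 for c in range(C))
    ss_cells = 0.0
    for lev in levels:
        sel = np.asarray(groups) == lev
        for c in range(C):
            ss_cells += sel.sum() * (x[sel, c].mean() - gm) ** 2
    ss_inter = ss_cells - ss_group - ss_cond
    ss_total = ((x - gm) ** 2).sum()
    ss_err = ss_total - ss_bs - ss_cond - ss_inter
    out = {"group": (ss_group / (g - 1)) / (ss_subj / (N - g))}
    if C > 1:
        ms_err = ss_err / ((C - 1) * (N - g))
        out["condition"] = (ss_cond / (C - 1)) / ms_err
        out["interaction"] = (ss_inter / ((g - 1) * (C - 1))) / ms_err
    return out


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric binary adjacency with edge probability ``p``."""
    u = rng.random((n, n)) < p
    a = np.triu(u, 1).astype(np.int8)
    return a + a.T
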