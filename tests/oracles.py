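"""Independent from-scratch oracles used by the unit and acceptance tests.

Each implements the textbook definition directly, with no reference to the
package's code paths (which go through scipy/statsmodels or vectorized
routines).
"""

from __future__ import annotations

import math

import numpy as np


def welch_t_oracle(a, b) -> tuple[float, float]:
    """Welch's t and two-sided p via the Welch–Satterthwaite formula."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    p = 2.0 * tdist.sf(abs(t), df)
    return t, p


def cohens_d_oracle(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    s_pooled = math.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    return (a.mean() - b.mean()) / s_pooled


def bh_oracle(p) -> np.ndarray:
    """Step-up BH by direct enumeration: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    running_min = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running_min = min(running_min, m * p[idx] / rank_from_top)
        q[idx] = min(running_min, 1.0)
    return q


def pearson_oracle(a, b) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    da = a - a.mean()
    db = b - b.mean()
    return float((da * db).sum() / math.sqrt((da**2).sum() * (db**2).sum()))


def hypergeom_tail_oracle(k: int, N: int, m: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, m, n) by exact combinatorial sum."""
    total = math.comb(N, n)
    upper = min(m, n)
    return sum(
        math.comb(m, i) * math.comb(N - m, n - i) for i in range(k, upper + 1)
    ) / total


def multisource_dijkstra_oracle(mask: np.ndarray, sources, spacing: float,
                                connectivity: int = 8) -> np.ndarray:
    """Brute-force multi-source shortest paths via networkx on an explicit
    edge list over the full grid graph."""
    import networkx as nx

    ny, nx_ = mask.shape
    g = nx.Graph()
    for y in range(ny):
        for x in range(nx_):
            g.add_node((y, x))
    diag = spacing * math.sqrt(2.0)
    for y in range(ny):
        for x in range(nx_):
            if x + 1 < nx_:
                g.add_edge((y, x), (y, x + 1), weight=spacing)
            if y + 1 < ny:
                g.add_edge((y, x), (y + 1, x), weight=spacing)
            if connectivity == 8:
                if x + 1 < nx_ and y + 1 < ny:
                    g.add_edge((y, x), (y + 1, x + 1), weight=diag)
                if x - 1 >= 0 and y + 1 < ny:
                    g.add_edge((y, x), (y + 1, x - 1), weight=diag)
    dist = nx.multi_source_dijkstra_path_length(g, [tuple(s) for s in sources])
    out = np.full((ny, nx_), np.inf)
    for (y, x), d in dist.items():
        out[y, x] = d
    return out


def upgmc_oracle(X: np.ndarray) -> list[tuple[frozenset, frozenset, float]]:
    """Naive centroid-linkage trace: repeatedly merge the closest centroid
    pair; returns (members_a, members_b, merge_height) per step."""
    X = np.asarray(X, float)
    clusters: dict[frozenset, np.ndarray] = {
        frozenset([i]): X[i] for i in range(len(X))
    }
    merges = []
    while len(clusters) > 1:
        keys = list(clusters)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                d = float(np.linalg.norm(clusters[keys[i]] - clusters[keys[j]]))
                if best is None or d < best[0]:
                    best = (d, keys[i], keys[j])
        d, ka, kb = best
        merged = ka | kb
        # unweighted centroid: mean over all member observations
        clusters[merged] = X[sorted(merged)].mean(axis=0)
        del clusters[ka], clusters[kb]
        merges.append((ka, kb, d))
    return merges
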