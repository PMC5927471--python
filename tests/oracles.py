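"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: plain dynamic programming,
dense eigendecompositions, Floyd-Warshall distances and exhaustive
enumeration.  None of it shares code with the package.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.sparse.csgraph import floyd_warshall
from scipy.stats import rankdata


def sw_affine_score(a: str, b: str, substitution, gap_open: float,
                    gap_extend: float) -> float:
    """Full-DP Smith-Waterman with affine gaps (Gotoh, three matrices).

    ``substitution`` is a callable (x, y) -> score.  ``gap_open`` is the
    score of the first gap position and ``gap_extend`` of each further
    position, matching the aligner's convention.  Returns the optimal
    local alignment score (0 if no positive alignment exists).
    """
    n, m = len(a), len(b)
    neg = -1e18
    M = np.zeros((n + 1, m + 1))
    Ix = np.full((n + 1, m + 1), neg)
    Iy = np.full((n + 1, m + 1), neg)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = substitution(a[i - 1], b[j - 1])
            M[i, j] = max(0.0,
                          max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                              Iy[i - 1, j - 1]) + s)
            Ix[i, j] = max(M[i - 1, j] + gap_open, Ix[i - 1, j] + gap_extend)
            Iy[i, j] = max(M[i, j - 1] + gap_open, Iy[i, j - 1] + gap_extend)
            best = max(best, M[i, j])
    return best


def graph_arrays(G, weighted: bool):
    nodes = sorted(G.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    A = np.zeros((len(nodes), len(nodes)))
    for u, v, d in G.edges(data=True):
        w = d.get("weight", 1.0) if weighted else 1.0
        A[index[u], index[v]] = A[index[v], index[u]] = w
    return nodes, A


def degree_centrality_oracle(G, weighted: bool = False) -> dict:
    nodes, A = graph_arrays(G, weighted)
    return dict(zip(nodes, A.sum(axis=1)))


def closeness_centrality_oracle(G, weighted: bool = False,
                                normalized: bool = False) -> dict:
    """(sum of shortest-path distances)^-1 via dense Floyd-Warshall."""
    nodes, A = graph_arrays(G, weighted)
    lengths = np.zeros_like(A)
    mask = A > 0
    lengths[mask] = 1.0 / A[mask] if weighted else 1.0
    D = floyd_warshall(lengths, directed=False, unweighted=False)
    out = {}
    for i, v in enumerate(nodes):
        finite = np.isfinite(D[i]) & (np.arange(len(nodes)) != i)
        total = D[i][finite].sum()
        if total <= 0:
            out[v] = 0.0
        elif normalized:
            out[v] = finite.sum() / total
        else:
            out[v] = 1.0 / total
    return out


def eigenvector_centrality_oracle(G, weighted: bool = False) -> dict:
    """Leading eigenvector of the largest component by dense eigh."""
    import networkx as nx
    comp = max(nx.connected_components(G), key=len)
    sub = G.subgraph(comp)
    nodes, A = graph_arrays(sub, weighted)
    if len(nodes) == 1:
        vec = {nodes[0]: 1.0}
    else:
        w, v = np.linalg.eigh(A)
        lead = np.abs(v[:, np.argmax(w)])
        lead = lead / lead.max()
        vec = dict(zip(nodes, lead))
    return {u: vec.get(u, 0.0) for u in G.nodes}


def centralization_oracle(G, kind: str) -> float:
    """From-scratch evaluation of sum(C_w - c(V_i)) / T (star normalizer)."""
    import networkx as nx
    oracle = {"degree": degree_centrality_oracle,
              "closeness": closeness_centrality_oracle,
              "eigenvector": eigenvector_centrality_oracle}[kind]
    cents = list(oracle(G).values())
    raw = sum(max(cents) - c for c in cents)
    star = nx.star_graph(G.number_of_nodes() - 1)
    star_cents = list(oracle(star).values())
    t = sum(max(star_cents) - c for c in star_cents)
    return raw / t if t > 0 else 0.0


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic / (n1 * n0), ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return float(wins) / (len(pos) * len(neg))


def wilcoxon_exact_enumeration(x, y) -> float:
    """Two-sided exact signed-rank p by enumerating all sign assignments."""
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.array(signs) @ ranks
          for signs in itertools.product((0, 1), repeat=len(d))]
    ws = np.asarray(ws)
    cdf = np.mean(ws <= w_obs + 1e-12)
    sf = np.mean(ws >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(cdf, sf))


def holm_oracle(pvals):
    """Hand-stepped Holm: sort, multiply by m..1, cumulative max, cap."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    m = len(p)
    stepped = []
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        stepped.append(min(1.0, running))
    out = np.empty(m)
    out[order] = stepped
    return out
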