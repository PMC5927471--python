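"""Centrality, centralization and graph-dissimilarity statistics.

For an undirected graph G(V, E) with n = |V| nodes and adjacency matrix
A (entries a_ij), the per-node centralities are:

closeness
    ``C_C(V_i) = (sum_j d(V_i, V_j))**-1`` with d the shortest-path
    distance (number of traversed edges; 1/weight edge lengths in the
    weighted variant).  On a disconnected graph it is computed per
    component.  A conventional normalized variant,
    ``(n-1) / sum_j d``, is available behind ``normalized=True``.
degree
    ``C_D(V_i) = sum_j a_ij`` (sum of incident edge weights when
    weighted).
eigenvector
    the i-th entry of the leading eigenvector of A (weighted adjacency
    when weighted), computed by power iteration on the largest connected
    component, max-normalized to 1; nodes outside that component get 0.

The graph-level **centralization** is
``C(G) = sum_i (C_w - c(V_i)) / T`` with C_w the maximum observed
centrality and T the same numerator evaluated on the maximally
centralized graph -- the star -- with the same number of vertices
(Freeman's convention), giving a value in [0, 1].

Two graphs are compared by the Bray-Curtis dissimilarity of the
centralities of their shared nodes:
``B(G_i, G_j) = 1 - 2*C_ij / (C_i + C_j)`` where C_ij sums the lesser
centrality of each shared vertex and C_i, C_j total each graph's
centralities (a vertex-count variant of the totals is selectable).
Weighted eigenvector centrality is the default signature, so B reflects
both community membership and abundance-weighted network position.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .network import WEIGHT_FUNCTIONS

logger = logging.getLogger("phagenet")

CENTRALITY_KINDS = ("degree", "closeness", "eigenvector")


# ---------------------------------------------------------------------------
# Centrality
# ---------------------------------------------------------------------------

def _distances(G: nx.Graph, weighted: bool) -> dict:
    if weighted:
        for _, _, d in G.edges(data=True):
            if d.get("weight", 1.0) <= 0:
                raise ValueError("weighted closeness needs positive weights")
        H = G.copy()
        for u, v, d in H.edges(data=True):
            d["distance"] = 1.0 / d.get("weight", 1.0)
        return dict(nx.shortest_path_length(H, weight="distance"))
    return dict(nx.shortest_path_length(G))


def centrality(G: nx.Graph, kind: str, weighted: bool = False,
               normalized: bool = False, tol: float = 1e-10,
               max_iter: int = 1000) -> dict:
    """Per-node centrality of the requested kind (see module docstring)."""
    if kind not in CENTRALITY_KINDS:
        raise ValueError(f"unknown centrality kind {kind!r}")
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(G.nodes)

    if kind == "degree":
        if weighted:
            return {v: float(sum(d.get("weight", 1.0)
                                 for _, _, d in G.edges(v, data=True)))
                    for v in nodes}
        return {v: float(G.degree(v)) for v in nodes}

    if kind == "closeness":
        if not nx.is_connected(G):
            logger.warning("closeness on a disconnected graph: computed "
                           "per connected component")
        dist = _distances(G, weighted)
        out = {}
        for v in nodes:
            total = sum(d for u, d in dist[v].items() if u != v)
            if total <= 0:  # isolated node
                out[v] = 0.0
            elif normalized:
                out[v] = (len(dist[v]) - 1) / total
            else:
                out[v] = 1.0 / total
        return out

    # eigenvector by power iteration on the largest component
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    comp = sorted(components[0])
    if len(comp) == 1:
        return {v: (1.0 if v in set(comp) else 0.0) for v in nodes}
    index = {v: i for i, v in enumerate(comp)}
    A = np.zeros((len(comp), len(comp)))
    for u, v, d in G.subgraph(comp).edges(data=True):
        w = d.get("weight", 1.0) if weighted else 1.0
        A[index[u], index[v]] = A[index[v], index[u]] = w
    if A.max() > 0:  # rescaling leaves the eigenvector unchanged but
        A = A / A.max()  # conditions the shifted iteration for tiny weights
    x = np.full(len(comp), 1.0 / math.sqrt(len(comp)))
    # iterate with (A + I): same eigenvectors, but breaks the +/-lambda
    # symmetry of bipartite spectra that stalls plain power iteration
    for it in range(max_iter):
        x_new = A @ x + x
        norm = np.linalg.norm(x_new)
        if norm == 0:
            raise ArithmeticError("eigenvector iteration collapsed to zero")
        x_new /= norm
        if np.abs(x_new - x).max() < tol:
            x = x_new
            break
        x = x_new
    else:
        resid = A @ x + x
        resid /= np.linalg.norm(resid)
        raise ArithmeticError(
            f"eigenvector centrality did not converge in {max_iter} "
            f"iterations (n={len(comp)}, residual="
            f"{np.abs(resid - x).max():.2e})")
    x = np.abs(x)
    x /= x.max()
    out = {v: 0.0 for v in nodes}
    out.update({v: float(x[i]) for v, i in index.items()})
    return out


# ---------------------------------------------------------------------------
# Centralization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CentralizationScore:
    value: float
    raw_sum: float
    t_max: float
    kind: str


def _centralization_numerator(cents: Mapping) -> float:
    cmax = max(cents.values())
    return float(sum(cmax - c for c in cents.values()))


def centralization(G: nx.Graph, kind: str,
                   weighted: bool = False) -> CentralizationScore:
    """Freeman centralization: sum of (C_w - c(V_i)) over the star maximum.

    The normalizer T evaluates the same numerator on the star graph with
    the same number of vertices -- the maximally centralized topology --
    using unweighted centralities, so the score is comparable across
    graphs of equal size.
    """
    n = G.number_of_nodes()
    if n < 2:
        raise ValueError("centralization needs >= 2 nodes")
    cents = centrality(G, kind, weighted=weighted)
    raw = _centralization_numerator(cents)
    star = nx.star_graph(n - 1)
    t_max = _centralization_numerator(centrality(star, kind, weighted=False))
    if t_max <= 0:
        # n = 2: the star has no centrality inequality, so T = 0 and the
        # graph's own numerator is 0 too; the score is defined as 0
        return CentralizationScore(value=0.0, raw_sum=raw, t_max=t_max,
                                   kind=kind)
    return CentralizationScore(value=raw / t_max, raw_sum=raw,
                               t_max=t_max, kind=kind)


# ---------------------------------------------------------------------------
# Graph dissimilarity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GraphDissimilarity:
    value: float
    shared_lesser_sum: float
    total_i: float
    total_j: float


def bray_curtis_centrality(c1: Mapping, c2: Mapping,
                           totals: str = "centrality") -> GraphDissimilarity:
    """Bray-Curtis dissimilarity between two centrality signatures.

    ``B = 1 - 2*C_ij / (C_i + C_j)`` with C_ij the sum over shared nodes
    of the lesser centrality.  ``totals="centrality"`` (default) sums
    each graph's centrality values -- the standard Bray-Curtis
    convention; ``totals="vertices"`` uses the vertex counts instead.
    """
    if not c1 and not c2:
        raise ValueError("dissimilarity of two empty graphs is undefined")
    shared = set(c1) & set(c2)
    c_ij = float(sum(min(c1[v], c2[v]) for v in shared))
    if totals == "centrality":
        c_i, c_j = float(sum(c1.values())), float(sum(c2.values()))
    elif totals == "vertices":
        c_i, c_j = float(len(c1)), float(len(c2))
    else:
        raise ValueError(f"unknown totals convention {totals!r}")
    if c_i + c_j <= 0:
        raise ValueError("degenerate totals: all centralities zero")
    value = 1.0 - 2.0 * c_ij / (c_i + c_j)
    return GraphDissimilarity(value=value, shared_lesser_sum=c_ij,
                              total_i=c_i, total_j=c_j)


def graph_dissimilarity(G1: nx.Graph, G2: nx.Graph,
                        kind: str = "eigenvector", weighted: bool = True,
                        totals: str = "centrality") -> GraphDissimilarity:
    """Bray-Curtis dissimilarity of two graphs' centrality signatures."""
    c1 = centrality(G1, kind, weighted=weighted) if G1.number_of_nodes() else {}
    c2 = centrality(G2, kind, weighted=weighted) if G2.number_of_nodes() else {}
    return bray_curtis_centrality(c1, c2, totals=totals)


def dissimilarity_matrix(sample_graphs: Mapping[str, nx.Graph],
                         kind: str = "eigenvector", weighted: bool = True,
                         totals: str = "centrality") -> pd.DataFrame:
    """All pairwise graph dissimilarities (symmetric, zero diagonal)."""
    ids = list(sample_graphs)
    if len(ids) < 2:
        raise ValueError("need >= 2 samples")
    cents = {s: centrality(sample_graphs[s], kind, weighted=weighted)
             for s in ids}
    mat = np.zeros((len(ids), len(ids)))
    for i, si in enumerate(ids):
        for j in range(i + 1, len(ids)):
            b = bray_curtis_centrality(cents[si], cents[ids[j]],
                                       totals=totals).value
            mat[i, j] = mat[j, i] = b
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Edge perturbation (noise tolerance)
# ---------------------------------------------------------------------------

def perturb_edges(G: nx.Graph, mode: str, keep_fraction: float = 1.0,
                  seed: int = 0, weight_fn: str | None = None) -> nx.Graph:
    """Perturb a sample graph's edge set, keeping its node set fixed.

    ``mode="remove"`` retains a uniform random sample of
    ``floor(keep_fraction * m)`` edges; ``mode="complete"`` connects
    every phage-bacterium pair, weighting new edges with ``weight_fn``
    (default: the graph's recorded weight function) on the current
    relative abundances.
    """
    if mode not in ("remove", "complete"):
        raise ValueError(f"unknown perturbation mode {mode!r}")
    H = G.copy()
    if mode == "remove":
        if not 0 < keep_fraction <= 1:
            raise ValueError("keep_fraction must be in (0, 1]")
        if keep_fraction == 1.0:
            return H
        rng = np.random.default_rng(seed)
        edges = sorted(H.edges)
        keep_n = int(math.floor(keep_fraction * len(edges)))
        kept = rng.choice(len(edges), size=keep_n, replace=False)
        kept_set = {edges[i] for i in kept}
        H.remove_edges_from([e for e in edges if e not in kept_set])
        return H
    wname = weight_fn or H.graph.get("weight_fn", "mean")
    wfn = WEIGHT_FUNCTIONS[wname]
    phages = [v for v, d in H.nodes(data=True) if d.get("role") == "phage"]
    bacts = [v for v, d in H.nodes(data=True) if d.get("role") == "bacterium"]
    for p in phages:
        for b in bacts:
            if not H.has_edge(p, b):
                H.add_edge(p, b, weight=wfn(
                    H.nodes[p].get("rel_abundance", 1.0),
                    H.nodes[b].get("rel_abundance", 1.0)))
    return H


def noise_sweep(sample_graphs: Mapping[str, nx.Graph],
                analysis_fn: Callable[[Mapping[str, nx.Graph]], float],
                fractions: Sequence[float], n_iter: int = 5,
                seed: int = 0, mode: str = "remove") -> pd.DataFrame:
    """Re-run a group contrast under repeated random edge perturbation.

    ``analysis_fn`` maps a dict of sample graphs to a p-value.  For each
    keep-fraction the contrast is recomputed ``n_iter`` times on freshly
    perturbed graphs; the table reports the mean and standard error of
    the resulting p-values per fraction.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        pvals = []
        for _ in range(n_iter):
            perturbed = {s: perturb_edges(g, mode, keep_fraction=frac,
                                          seed=int(rng.integers(2**31)))
                         for s, g in sample_graphs.items()}
            pvals.append(float(analysis_fn(perturbed)))
        arr = np.asarray(pvals)
        rows.append({"keep_fraction": frac, "mean_p": float(arr.mean()),
                     "se_p": float(arr.std(ddof=1) / math.sqrt(len(arr)))
                     if len(arr) > 1 else 0.0,
                     "n_iter": len(arr)})
    return pd.DataFrame(rows)
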