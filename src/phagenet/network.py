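"""Master interaction network assembly and per-sample subgraph extraction.

The master network collects every retained OGU as a node (phage or
bacterium) and every predicted positive interaction as an undirected
edge; it is strictly bipartite.  Node attributes carry per-sample OGU
abundances, and graph attributes carry the study metadata, so the whole
object round-trips through GraphML.

A sample graph is the induced subgraph on the OGUs present in one sample
(abundance > 0).  Relative abundance is normalized *within role* --
phage and bacterial libraries are extracted and sequenced separately, so
their read pools are not comparable -- and each surviving edge is
weighted by a function of its endpoints' relative abundances
(arithmetic mean by default; product and geometric mean selectable).
"""

from __future__ import annotations

import json
import logging
import math
from typing import Callable, Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger("phagenet")

WEIGHT_FUNCTIONS: dict[str, Callable[[float, float], float]] = {
    "mean": lambda r1, r2: 0.5 * (r1 + r2),
    "product": lambda r1, r2: r1 * r2,
    "geometric": lambda r1, r2: math.sqrt(r1 * r2),
}


def build_master_network(predictions: pd.DataFrame,
                         abundance: pd.DataFrame,
                         roles: Mapping[str, str],
                         metadata: pd.DataFrame | None = None) -> nx.Graph:
    """Assemble the bipartite master network.

    ``predictions`` needs columns phage_id, bacterium_id and prediction
    (only rows predicted positive become edges -- "interacts", "positive"
    or boolean truth are accepted); ``abundance`` has OGUs as rows and
    samples as columns; ``roles`` maps every OGU id to "phage" or
    "bacterium".  Degree-0 OGUs remain as nodes.
    """
    G = nx.Graph()
    samples = list(abundance.columns)
    G.graph["samples"] = json.dumps(samples)
    if metadata is not None:
        G.graph["metadata"] = metadata.to_json(orient="records")
    for ogu_id in abundance.index:
        if ogu_id not in roles:
            raise ValueError(f"no role for OGU {ogu_id!r}")
        ab = {s: float(abundance.loc[ogu_id, s]) for s in samples}
        G.add_node(ogu_id, role=roles[ogu_id], abundance=json.dumps(ab))
    positive = {"interacts", "positive", True, 1, "True", "1"}
    for row in predictions.itertuples(index=False):
        pred = getattr(row, "prediction", "interacts")
        if pred not in positive:
            continue
        p, b = row.phage_id, row.bacterium_id
        for node in (p, b):
            if node not in G:
                raise ValueError(f"prediction references unknown OGU {node!r}")
        if G.nodes[p]["role"] != "phage" or G.nodes[b]["role"] != "bacterium":
            raise ValueError(f"edge {p!r}-{b!r} is not phage-bacterium")
        G.add_edge(p, b)
    logger.info("master network: %d nodes (%d phages, %d bacteria), %d edges",
                G.number_of_nodes(),
                sum(1 for _, d in G.nodes(data=True) if d["role"] == "phage"),
                sum(1 for _, d in G.nodes(data=True)
                    if d["role"] == "bacterium"),
                G.number_of_edges())
    return G


def node_abundance(G: nx.Graph, node: str) -> dict[str, float]:
    return json.loads(G.nodes[node]["abundance"])


def extract_sample_graph(master: nx.Graph, sample_id: str,
                         weight_fn: str = "mean") -> nx.Graph:
    """Extract one sample's weighted bipartite graph.

    Keeps nodes with positive abundance in the sample, normalizes
    abundance to relative abundance within each role, keeps the master
    edges whose endpoints both survive, and weights each edge as
    ``weight_fn`` of the endpoint relative abundances.
    """
    samples = json.loads(master.graph.get("samples", "[]"))
    if samples and sample_id not in samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    try:
        wfn = WEIGHT_FUNCTIONS[weight_fn]
    except KeyError:
        raise ValueError(f"unknown weight function {weight_fn!r}") from None
    present = {}
    for node in master.nodes:
        ab = node_abundance(master, node).get(sample_id, 0.0)
        if ab > 0:
            present[node] = ab
    totals = {"phage": 0.0, "bacterium": 0.0}
    for node, ab in present.items():
        totals[master.nodes[node]["role"]] += ab
    G = nx.Graph(sample_id=sample_id, weight_fn=weight_fn)
    for node, ab in present.items():
        role = master.nodes[node]["role"]
        G.add_node(node, role=role, rel_abundance=ab / totals[role])
    for u, v in master.edges:
        if u in present and v in present:
            G.add_edge(u, v, weight=wfn(G.nodes[u]["rel_abundance"],
                                        G.nodes[v]["rel_abundance"]))
    return G


def graph_summary(G: nx.Graph) -> dict:
    """Node/edge counts, eccentricities and diameter.

    Eccentricity of a node is its unweighted shortest-path distance to
    the farthest node reachable from it; on a disconnected graph both
    eccentricities and the diameter are computed on the largest
    connected component and the disconnection is flagged.
    """
    if G.number_of_nodes() == 0:
        raise ValueError("empty graph")
    components = sorted(nx.connected_components(G), key=len, reverse=True)
    connected = len(components) == 1
    largest = G.subgraph(components[0])
    ecc = nx.eccentricity(largest)
    return {
        "n_nodes": G.number_of_nodes(),
        "n_edges": G.number_of_edges(),
        "diameter": max(ecc.values()) if ecc else 0,
        "eccentricity": dict(ecc),
        "connected": connected,
        "n_components": len(components),
    }


def summarize_samples(master: nx.Graph, sample_ids, weight_fn: str = "mean",
                      ) -> pd.DataFrame:
    """Per-sample (n, m, diameter) summary table."""
    rows = []
    for sid in sample_ids:
        G = extract_sample_graph(master, sid, weight_fn)
        s = graph_summary(G) if G.number_of_nodes() else \
            {"n_nodes": 0, "n_edges": 0, "diameter": 0, "connected": True,
             "n_components": 0}
        rows.append({"sample_id": sid, "n_nodes": s["n_nodes"],
                     "n_edges": s["n_edges"], "diameter": s["diameter"],
                     "connected": s["connected"]})
    return pd.DataFrame(rows)
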