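"""Integrated regulatory network: merge, centralities, key-element calling.

The TF->gene and miRNA->gene edge sets of a stage are merged into one
simple undirected graph (regulation direction is kept only as an edge
attribute).  Node importance is scored by degree and by betweenness
centrality normalized to [0, 1] — BC(v) is the fraction of pairwise
shortest paths passing through v, divided by (n-1)(n-2)/2 — matching the
undirected NetworkAnalyzer convention.  Nodes whose degree AND betweenness
z-scores both exceed 2 are called key elements (an ``either`` rule is also
provided, since a ranked-union reading of the z>2 rule is equally
defensible on published tables).
"""

from __future__ import annotations

from collections import deque

import networkx as nx
import numpy as np
import pandas as pd

from .correlation import EDGE_COLUMNS
from .simulate import entity_role

KEY_REPORT_COLUMNS = ["node", "role", "degree", "bc", "z_degree", "z_bc", "is_key"]


def build_network(
    tf_edges: pd.DataFrame,
    mirna_edges: pd.DataFrame,
    de_results: pd.DataFrame,
    stage: str,
) -> nx.Graph:
    """Merge TF and miRNA edge tables into one stage network.

    Duplicate (regulator, target) records keep the one with the largest
    |pcc|.  Nodes carry role and log2 fold change (from the stage's DE
    results); edges carry pcc, p, sign and weight.  Self-loops are
    rejected; every endpoint must have a DE annotation.
    """
    parts = [df for df in (tf_edges, mirna_edges) if not df.empty]
    edges = (
        pd.concat(parts, ignore_index=True)
        if parts
        else pd.DataFrame(columns=EDGE_COLUMNS)
    )
    lfc = de_results.set_index("entity")["lfc"]

    g = nx.Graph(stage=stage)
    if edges.empty:
        return g

    edges = (
        edges.sort_values("weight", kind="stable")
        .drop_duplicates(subset=["regulator", "target"], keep="last")
        .reset_index(drop=True)
    )
    for rec in edges.itertuples(index=False):
        if rec.regulator == rec.target:
            raise ValueError(f"self-loop on {rec.regulator!r}")
        for node in (rec.regulator, rec.target):
            if node not in g:
                if node not in lfc.index:
                    raise ValueError(f"node {node!r} has no DE annotation")
                g.add_node(node, role=entity_role(node), lfc=float(lfc[node]))
        prev = g.get_edge_data(rec.regulator, rec.target)
        if prev is not None and prev["weight"] >= rec.weight:
            continue
        g.add_edge(
            rec.regulator,
            rec.target,
            regulator=rec.regulator,
            pcc=float(rec.pcc),
            p_value=float(rec.p_value),
            sign=int(rec.sign),
            weight=float(rec.weight),
        )
    return g


def degree(g: nx.Graph) -> dict[str, int]:
    """Undirected degree per node."""
    return {n: d for n, d in g.degree()}


def betweenness(g: nx.Graph) -> dict[str, float]:
    """Normalized betweenness centrality in [0, 1] (Brandes accumulation).

    Unordered node pairs; pairs with no connecting path contribute 0;
    normalization by (n-1)(n-2)/2.  Graphs with fewer than 3 nodes are
    degenerate and get all-zero centralities.
    """
    if g.number_of_nodes() < 3:
        return {n: 0.0 for n in g.nodes}
    return nx.betweenness_centrality(g, normalized=True)


def betweenness_bruteforce(g: nx.Graph, max_nodes: int = 15) -> dict[str, float]:
    """Betweenness by explicit shortest-path enumeration (test oracle).

    BFS from every source counts, for each unordered pair (u, w), the
    number of shortest u-w paths and how many pass through each interior
    node.  Intended for small graphs only (guarded at ``max_nodes``).
    """
    n = g.number_of_nodes()
    if n > max_nodes:
        raise ValueError(f"brute-force betweenness limited to {max_nodes} nodes, got {n}")
    nodes = list(g.nodes)
    raw = {v: 0.0 for v in nodes}
    if n < 3:
        return raw

    for i, u in enumerate(nodes):
        dist, npaths = _bfs_counts(g, u)
        for w in nodes[i + 1 :]:
            if w not in dist or npaths[w] == 0:
                continue
            total = npaths[w]
            for v in nodes:
                if v in (u, w) or v not in dist:
                    continue
                raw[v] += _paths_through(g, u, w, v, dist, npaths) / total
    denom = (n - 1) * (n - 2) / 2.0
    return {v: raw[v] / denom for v in nodes}


def _bfs_counts(g: nx.Graph, source: str) -> tuple[dict, dict]:
    dist = {source: 0}
    npaths = {source: 1}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g.neighbors(u):
            if v not in dist:
                dist[v] = dist[u] + 1
                npaths[v] = npaths[u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                npaths[v] += npaths[u]
    return dist, npaths


def _paths_through(g, u, w, v, dist_u, npaths_u) -> float:
    # shortest u-w paths through v = (paths u->v) * (paths v->w), when
    # d(u,v) + d(v,w) = d(u,w)
    dist_v, npaths_v = _bfs_counts(g, v)
    if w not in dist_v:
        return 0.0
    if dist_u[v] + dist_v[w] != dist_u[w]:
        return 0.0
    return npaths_u[v] * npaths_v[w]


def key_elements(
    g: nx.Graph,
    z_threshold: float = 2.0,
    rule: str = "both",
) -> pd.DataFrame:
    """Per-node centrality report with z-scores and the key-element flag.

    z-scores use the population (n-denominator) standard deviation over
    all nodes; a metric with zero spread flags nothing.  ``rule`` is
    ``"both"`` (default: both z-scores must exceed the threshold) or
    ``"either"``.  The report is sorted by betweenness descending, then
    degree, then node id.
    """
    if rule not in ("both", "either"):
        raise ValueError(f"rule must be 'both' or 'either', got {rule!r}")
    nodes = list(g.nodes)
    deg = degree(g)
    bc = betweenness(g)
    deg_v = np.array([deg[n] for n in nodes], dtype=float)
    bc_v = np.array([bc[n] for n in nodes], dtype=float)

    z_deg = _population_z(deg_v)
    z_bc = _population_z(bc_v)
    above_deg = z_deg > z_threshold
    above_bc = z_bc > z_threshold
    if rule == "both":
        is_key = above_deg & above_bc
    else:
        is_key = above_deg | above_bc

    report = pd.DataFrame(
        {
            "node": nodes,
            "role": [g.nodes[n]["role"] for n in nodes],
            "degree": deg_v.astype(int),
            "bc": bc_v,
            "z_degree": z_deg,
            "z_bc": z_bc,
            "is_key": is_key,
        }
    )
    return report.sort_values(
        ["bc", "degree", "node"], ascending=[False, False, True], kind="stable"
    ).reset_index(drop=True)[KEY_REPORT_COLUMNS]


def _population_z(x: np.ndarray) -> np.ndarray:
    if x.size == 0:
        return x.copy()
    sd = x.std(ddof=0)
    if sd == 0:
        # no spread: the metric cannot single out any node
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def network_to_edge_table(g: nx.Graph) -> pd.DataFrame:
    rows = []
    for u, v, data in g.edges(data=True):
        reg = data.get("regulator", u)
        target = v if reg == u else u
        rows.append(
            (
                reg,
                g.nodes[reg]["role"],
                target,
                data["pcc"],
                data["p_value"],
                data["sign"],
                data["weight"],
            )
        )
    out = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    return out.sort_values(["regulator", "target"], kind="stable").reset_index(drop=True)


def export_network(g: nx.Graph, path: str, fmt: str = "tsv") -> None:
    """Write the network as an edge TSV, SIF or GraphML file.

    SIF lines read ``regulator <activates|represses> target``; GraphML
    carries node role/lfc and edge pcc/sign attributes and round-trips
    through :func:`read_graphml_network`.
    """
    if fmt == "tsv":
        network_to_edge_table(g).to_csv(path, sep="\t", index=False)
    elif fmt == "sif":
        lines = []
        for _, _, data in _sorted_edges(g):
            rel = "activates" if data["sign"] > 0 else "represses"
            reg = data["regulator"]
            lines.append(f"{reg}\t{rel}\t{data['target_id']}")
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown export format {fmt!r}")


def _sorted_edges(g: nx.Graph):
    items = []
    for u, v, data in g.edges(data=True):
        reg = data.get("regulator", u)
        target = v if reg == u else u
        d = dict(data)
        d["target_id"] = target
        items.append((reg, target, d))
    return sorted(items, key=lambda t: (t[0], t[1]))


def read_graphml_network(path: str) -> nx.Graph:
    g = nx.read_graphml(path)
    g = nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
    return g
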