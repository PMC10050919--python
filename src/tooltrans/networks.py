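"""Weighted association networks and per-individual metrics.

Association records — either simulator co-occupancy logs (``step, agent_a,
agent_b``, unordered pairs) or observational focal-follow proximity records
(``focal, partner[, count]``, directed) — are turned into a weighted graph
whose edge weights count how often two individuals were observed together.
Two node-level measures follow the study's analysis:

* **eigenvector centrality** (EV-centrality): the dominant eigenvector of
  the weighted adjacency, rescaled so the maximum is 1;
* **strength to tool users**: the summed weight of a node's connections to
  tool-using individuals.
"""

from __future__ import annotations

import warnings
from pathlib import Path
import networkx as nx
import numpy as np
import pandas as pd

SIM_COLUMNS = ("step", "agent_a", "agent_b")
OBS_COLUMNS = ("focal", "partner")


class RecordError(ValueError):
    """Raised when association records reference unknown individuals."""


def _pair_counts(records: pd.DataFrame) -> tuple[pd.DataFrame, bool]:
    """Collapse records to (a, b, count); returns (counts, is_directed_input)."""
    cols = set(records.columns)
    if {"agent_a", "agent_b"} <= cols:
        a, b = records["agent_a"].to_numpy(), records["agent_b"].to_numpy()
        lo, hi = np.minimum(a, b), np.maximum(a, b)
        counts = (
            pd.DataFrame({"a": lo, "b": hi})
            .value_counts()
            .rename("count")
            .reset_index()
        )
        return counts, False
    if set(OBS_COLUMNS) <= cols:
        df = records.rename(columns={"focal": "a", "partner": "b"})
        if "count" in cols:
            counts = df.groupby(["a", "b"], as_index=False)["count"].sum()
        else:
            counts = df.value_counts(["a", "b"]).rename("count").reset_index()
        return counts, True
    raise RecordError(
        "records must have columns (step, agent_a, agent_b) or (focal, partner[, count])"
    )


def build_network(
    records: pd.DataFrame,
    attributes: pd.DataFrame,
    directed: bool = False,
) -> nx.Graph | nx.DiGraph:
    """Build the weighted association network.

    Every id in ``attributes`` becomes a node (isolates included) carrying
    its attribute columns. Edge weights count the records for each pair.
    Simulator logs are unordered: when a directed graph is requested each
    pair is expanded to both directions with the pair's count. Observational
    records keep their recorded direction (focal/active forager -> partner);
    when an undirected graph is requested opposite directions are summed.
    """
    if "id" not in attributes.columns:
        raise RecordError("attribute table must have an 'id' column")
    counts, input_directed = _pair_counts(records)
    known = set(attributes["id"].tolist())
    unknown = (set(counts["a"]) | set(counts["b"])) - known
    if unknown:
        raise RecordError(f"records reference unknown ids: {sorted(unknown)[:5]}")

    G: nx.Graph | nx.DiGraph = nx.DiGraph() if directed else nx.Graph()
    for row in attributes.itertuples(index=False):
        d = row._asdict()
        G.add_node(d.pop("id"), **d)
    for a, b, w in counts[["a", "b", "count"]].itertuples(index=False):
        if a == b:
            continue
        w = int(w)
        if directed and not input_directed:
            G.add_edge(a, b, weight=w)
            G.add_edge(b, a, weight=w)
        elif directed:
            G.add_edge(a, b, weight=w)
        else:
            if G.has_edge(a, b):
                G[a][b]["weight"] += w
            else:
                G.add_edge(a, b, weight=w)
    return G


def _symmetric_adjacency(G: nx.Graph | nx.DiGraph, nodes: list) -> np.ndarray:
    A = nx.to_numpy_array(G, nodelist=nodes, weight="weight")
    if G.is_directed():
        A = A + A.T
    return A


def ev_centrality(
    G: nx.Graph | nx.DiGraph,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict:
    """Weighted eigenvector centrality, max-normalized to [0, 1].

    Computed by power iteration on the (symmetrized, for directed input)
    weighted adjacency of the largest connected component; nodes outside
    that component score 0. A network with no edges yields all zeros.
    """
    nodes = list(G.nodes)
    if not nodes:
        return {}
    scores = dict.fromkeys(nodes, 0.0)
    und = G.to_undirected(as_view=False) if G.is_directed() else G
    if und.number_of_edges() == 0:
        warnings.warn("network has no edges; all centralities are 0")
        return scores
    components = sorted(nx.connected_components(und), key=len, reverse=True)
    if len(components) > 1:
        warnings.warn(
            "network is disconnected; centrality computed on the largest "
            f"component ({len(components[0])} of {len(nodes)} nodes)"
        )
    comp = [n for n in nodes if n in components[0]]
    A = _symmetric_adjacency(G, comp)
    # small diagonal shift: keeps eigenvectors, breaks the +/-lambda tie on
    # bipartite components that would make plain power iteration oscillate
    sigma = 1e-2 * max(1.0, A.sum(axis=1).max())
    A = A + sigma * np.eye(len(comp))
    v = np.full(len(comp), 1.0 / np.sqrt(len(comp)))
    for _ in range(max_iter):
        w = A @ v
        norm = np.linalg.norm(w)
        if norm == 0:
            break
        w /= norm
        if np.abs(w - v).max() < tol:
            v = w
            break
        v = w
    v = np.abs(v)
    vmax = v.max()
    if vmax > 0:
        v = v / vmax
    scores.update(zip(comp, v.tolist()))
    return scores


def strength_to_tool_users(
    G: nx.Graph | nx.DiGraph,
    node=None,
    tool_attr: str = "tool_user",
) -> dict | float:
    """Summed edge weight between each node and its tool-using neighbours.

    Directed networks are symmetrized first (weights of the two directions
    summed) so each unordered neighbour relation is counted once, making
    simulator and observational inputs comparable. Isolated nodes score 0.
    With ``node`` given, returns that node's value alone.
    """
    tool = nx.get_node_attributes(G, tool_attr)
    missing = [n for n in G.nodes if n not in tool]
    if missing:
        raise RecordError(f"nodes missing {tool_attr!r} attribute: {missing[:5]}")
    if G.is_directed():
        H = nx.Graph()
        H.add_nodes_from(G.nodes)
        for a, b, d in G.edges(data=True):
            w = d.get("weight", 1)
            if H.has_edge(a, b):
                H[a][b]["weight"] += w
            else:
                H.add_edge(a, b, weight=w)
        G = H
    out = {}
    for n in G.nodes:
        out[n] = float(
            sum(d.get("weight", 1) for nb, d in G[n].items() if tool[nb])
        )
    return out if node is None else out[node]


def node_metrics(G: nx.Graph | nx.DiGraph) -> pd.DataFrame:
    """Per-individual metrics table: id, ev_centrality, strength_to_tool_users."""
    cent = ev_centrality(G)
    strength = strength_to_tool_users(G)
    return pd.DataFrame(
        {
            "id": list(G.nodes),
            "ev_centrality": [cent[n] for n in G.nodes],
            "strength_to_tool_users": [strength[n] for n in G.nodes],
        }
    )


def write_metrics(metrics: pd.DataFrame, path: str | Path) -> None:
    metrics.to_csv(path, index=False)


def write_graphml(G: nx.Graph | nx.DiGraph, path: str | Path) -> None:
    """GraphML export of the weighted network (attributes included)."""
    H = G.copy()
    for _, d in H.nodes(data=True):
        for k, v in list(d.items()):
            if pd.isna(v):
                d[k] = ""
            elif isinstance(v, (np.bool_, np.integer, np.floating)):
                d[k] = v.item()
    nx.write_graphml(H, path)
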