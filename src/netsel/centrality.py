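"""Interaction-network loading, filtering, and centrality metrics.

Networks are undirected simple graphs over gene/protein id strings, with
per-edge attributes: interaction_type (physical/genetic), evidence
(LTP/HTP for low-/high-throughput), and an optional 0-1000 confidence
score (the STRING convention, where "score >= 40%" means score >= 400).
Loading collapses (a, b)/(b, a) duplicates and removes self-interactions.

Three centralities, as commonly defined for unweighted PPI networks:

* degree — number of distinct interaction partners;
* betweenness — fraction of shortest paths between other protein pairs
  passing through the protein, normalized by (n-1)(n-2)/2 with n the node
  count of the graph, so values are dimensionless fractions;
* closeness — one over the mean shortest-path distance to the other
  members of the protein's connected component.

Distances are within-component by convention: cross-component pairs
contribute nothing to betweenness and are excluded from closeness means
(isolated nodes get closeness 0).  A largest-component-only mode is
available since published analyses differ on this point.  The heavy
metrics run on igraph's C core; graphs stay networkx on the API surface.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

EVIDENCE_TAGS = {"LTP", "HTP"}
INTERACTION_TYPES = {"physical", "genetic"}

EDGE_COLUMNS = ["node_a", "node_b", "interaction_type", "evidence", "score"]


def load_network(
    edge_table,
    physical_only: bool = True,
    dedupe: bool = True,
    min_score: float | None = None,
    evidence_subset: set[str] | None = None,
) -> nx.Graph:
    """Build a filtered interaction network from an edge table.

    `edge_table` is a DataFrame or a TSV path with columns node_a, node_b
    and optionally interaction_type, evidence, score.  `min_score` is a
    fraction in [0, 1] or percent in (1, 100] on the 0-1000 score scale
    (0.4 and 40 both mean score >= 400).  Nodes appearing only in dropped
    rows are kept as isolates, so "in the network but unconnected after
    filtering" stays representable.
    """
    if not isinstance(edge_table, pd.DataFrame):
        edge_table = read_edge_tsv(edge_table)
    df = edge_table.copy()
    if evidence_subset is not None:
        unknown = set(map(str, evidence_subset)) - EVIDENCE_TAGS
        if unknown:
            raise ValueError(f"unknown evidence tags: {sorted(unknown)}")
    g = nx.Graph()
    threshold = None
    if min_score is not None:
        threshold = 1000.0 * (min_score / 100.0 if min_score > 1 else min_score)
    for line_no, row in enumerate(df.itertuples(index=False), start=1):
        a, b = str(row.node_a), str(row.node_b)
        if not a or not b or a == "nan" or b == "nan":
            raise ValueError(f"malformed edge row at line {line_no}")
        itype = getattr(row, "interaction_type", "physical")
        evidence = getattr(row, "evidence", None)
        score = getattr(row, "score", None)
        if evidence is not None and not (isinstance(evidence, float) and np.isnan(evidence)):
            if str(evidence) not in EVIDENCE_TAGS:
                raise ValueError(f"unknown evidence tag {evidence!r} at line {line_no}")
        g.add_nodes_from((a, b))
        if a == b:
            continue
        if physical_only and str(itype) != "physical":
            continue
        if evidence_subset is not None and str(evidence) not in evidence_subset:
            continue
        if threshold is not None and (score is None or float(score) < threshold):
            continue
        if dedupe and g.has_edge(a, b):
            continue
        g.add_edge(a, b, interaction_type=str(itype), evidence=evidence, score=score)
    return g


def read_edge_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if "protein1" in cols:  # STRING-like dialect
        df = df.rename(columns={"protein1": "node_a", "protein2": "node_b", "combined_score": "score"})
        df["interaction_type"] = "physical"
        df["evidence"] = None
    missing = {"node_a", "node_b"} - set(df.columns)
    if missing:
        raise ValueError(f"edge table lacks columns: {sorted(missing)}")
    return df


def write_edge_tsv(network: nx.Graph, path) -> None:
    rows = [
        (a, b, d.get("interaction_type", "physical"), d.get("evidence", ""), d.get("score", ""))
        for a, b, d in sorted(network.edges(data=True))
    ]
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(path, sep="\t", index=False)


def largest_component(network: nx.Graph) -> nx.Graph:
    if network.number_of_nodes() == 0:
        return network.copy()
    comp = max(nx.connected_components(network), key=len)
    return network.subgraph(comp).copy()


def degree(network: nx.Graph) -> dict[str, int]:
    """Distinct-neighbor count per node (isolates have degree 0)."""
    return {n: int(d) for n, d in network.degree()}


def _to_igraph(network: nx.Graph):
    import igraph

    nodes = list(network.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[a], index[b]) for a, b in network.edges]
    g = igraph.Graph(n=len(nodes), edges=edges, directed=False)
    return g, nodes


def betweenness(network: nx.Graph) -> dict[str, float]:
    """Shortest-path betweenness as a fraction, normalized by (n-1)(n-2)/2."""
    n = network.number_of_nodes()
    if n < 3:
        return {v: 0.0 for v in network.nodes}
    g, nodes = _to_igraph(network)
    raw = g.betweenness(directed=False)  # pair counted once for undirected
    norm = (n - 1) * (n - 2) / 2.0
    return {v: float(b) / norm for v, b in zip(nodes, raw)}


def betweenness_raw(network: nx.Graph) -> dict[str, float]:
    """Unnormalized pair-dependency counts (each unordered pair once)."""
    g, nodes = _to_igraph(network)
    return {v: float(b) for v, b in zip(nodes, g.betweenness(directed=False))}


def closeness(network: nx.Graph) -> dict[str, float]:
    """1 / mean within-component distance; 0 for isolated nodes."""
    g, nodes = _to_igraph(network)
    out: dict[str, float] = {}
    for comp in g.connected_components():
        sub = g.induced_subgraph(comp)
        if len(comp) == 1:
            out[nodes[comp[0]]] = 0.0
            continue
        dmat = np.asarray(sub.distances())
        means = dmat.sum(axis=1) / (len(comp) - 1)
        for local, orig in enumerate(comp):
            out[nodes[orig]] = float(1.0 / means[local])
    return out


def centrality_table(network: nx.Graph, metrics=("degree", "betweenness", "closeness")) -> pd.DataFrame:
    """Per-node centrality records for the requested metrics."""
    data: dict[str, dict] = {"gene": {n: n for n in network.nodes}}
    if "degree" in metrics:
        data["degree"] = degree(network)
    if "betweenness" in metrics:
        data["betweenness"] = betweenness(network)
    if "closeness" in metrics:
        data["closeness"] = closeness(network)
    df = pd.DataFrame({k: pd.Series(v) for k, v in data.items()})
    return df.reset_index(drop=True).sort_values("gene").reset_index(drop=True)
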