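"""Shared-practice similarity network over societies.

Nodes are societies (isolated ones kept, so the node count always equals the
dataset size); an edge joins two societies iff their practice sets intersect,
weighted by the intersection size w_ij = |S_i ∩ S_j|.  The weight ties to the
Hamming dissimilarity exactly: 2 w_ij = |S_i| + |S_j| - d_H(i, j).
Geographic coordinates travel as node attributes so external tools can lay
the graph out on a map.
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from cultshare.data import SocietyDataset

__all__ = ["build_network", "export_network", "import_network", "edge_list"]


def build_network(dataset: SocietyDataset) -> nx.Graph:
    """Weighted shared-practice network; deterministic given the dataset."""
    g = nx.Graph()
    for s in dataset.societies:
        attrs = {"n_practices": len(s.practices)}
        if s.latitude is not None:
            attrs["latitude"] = float(s.latitude)
        if s.longitude is not None:
            attrs["longitude"] = float(s.longitude)
        g.add_node(s.name, **attrs)
    socs = dataset.societies
    for i in range(len(socs)):
        for j in range(i + 1, len(socs)):
            w = len(socs[i].practices & socs[j].practices)
            if w > 0:
                g.add_edge(socs[i].name, socs[j].name, weight=int(w))
    return g


def edge_list(net: nx.Graph) -> pd.DataFrame:
    """Edge list (a, b, weight) in deterministic node order."""
    rows = [
        {"a": a, "b": b, "weight": int(d["weight"])}
        for a, b, d in net.edges(data=True)
    ]
    return pd.DataFrame(rows, columns=["a", "b", "weight"])


def export_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML (typed attributes) or an edge-list CSV.

    The edge-list CSV drops isolated nodes by construction; GraphML preserves
    them.
    """
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edgelist_csv":
        edge_list(net).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def import_network(path, format: str = "graphml") -> nx.Graph:
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "edgelist_csv":
        frame = pd.read_csv(path)
        g = nx.Graph()
        for _, row in frame.iterrows():
            g.add_edge(str(row["a"]), str(row["b"]), weight=int(row["weight"]))
        return g
    raise ValueError(f"unknown format {format!r}")
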