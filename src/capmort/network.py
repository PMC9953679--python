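"""First-neighbor PPI subnetworks and hub ranking from a local edge list.

The module consumes a user-supplied protein-protein interaction edge list
(two or more whitespace/tab-separated columns; '#' comments ignored),
builds an undirected simple graph with uppercase-normalized gene symbols,
extracts the neighborhood of a seed gene list (e.g. the differentially
expressed genes), and ranks hub genes by degree with betweenness
centrality as the tie-break.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = ["load_edges", "seed_subnetwork", "rank_hubs"]


def load_edges(path: str | Path, provenance: str | None = None) -> nx.Graph:
    """Read an edge list into an undirected simple graph.

    Lines with fewer than two fields raise with their line number;
    self-loops are dropped and duplicate edges collapsed; symbols are
    uppercased.
    """
    g = nx.Graph()
    g.graph["provenance"] = provenance or str(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace("\t", " ").split()
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            a, b = fields[0].upper(), fields[1].upper()
            if a == b:
                continue
            g.add_edge(a, b)
    return g


def seed_subnetwork(network: nx.Graph, seeds, order: int = 1) -> nx.Graph:
    """Subnetwork around seed genes.

    ``order=0`` returns the seed-induced subgraph; ``order=1`` additionally
    keeps direct neighbors and every edge among the retained nodes.  Node
    attribute ``is_seed`` records seed membership.  If no seed is present
    in the network an empty graph is returned with a warning.
    """
    if order not in (0, 1):
        raise ValueError("order must be 0 or 1")
    seeds = {str(s).upper() for s in seeds}
    present = seeds & set(network.nodes)
    if not present:
        warnings.warn("no seed gene present in the network", UserWarning, stacklevel=2)
        return nx.Graph()
    keep = set(present)
    if order == 1:
        for s in present:
            keep.update(network.neighbors(s))
    sub = network.subgraph(keep).copy()
    nx.set_node_attributes(sub, {n: (n in seeds) for n in sub.nodes}, "is_seed")
    return sub


def rank_hubs(network: nx.Graph, k: int = 10) -> pd.DataFrame:
    """Top-k hub genes: degree descending, betweenness tie-break, then name.

    Returns a DataFrame indexed by gene with ``degree``, ``betweenness``
    and ``is_seed`` (False where the attribute is absent).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    degree = dict(network.degree())
    betweenness = nx.betweenness_centrality(network, normalized=True)
    nodes = sorted(
        network.nodes, key=lambda n: (-degree[n], -betweenness[n], n)
    )[:k]
    return pd.DataFrame(
        {
            "degree": [degree[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
            "is_seed": [bool(network.nodes[n].get("is_seed", False)) for n in nodes],
        },
        index=pd.Index(nodes, name="gene"),
    )
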