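"""Construction and export of the signature redundancy network.

Nodes are signatures, annotated with their category, informativeness,
conservation status, and gene count (the attributes a renderer maps to
node color, shape and size).  An edge is drawn between two signatures only
when their functional redundancy strictly exceeds a threshold (default
0.7); its weight is the average of the two redundancy measures (Jaccard
index and functional redundancy), and its class records whether the
compositional overlap is also significant ("functional-plus-JI", rendered
dark) or not ("functional-only", rendered light).

Layout is deliberately not computed here: graphs are exported with full
attributes (GraphML / SIF / JSON) and layout is delegated to the
visualization tool.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .conservation import ConservationResult
from .io import SignatureCollection
from .redundancy import RedundancyEdge
from .selection import InformativeCall

__all__ = ["build_graph", "connected_components", "export_graph"]

EDGE_FUNCTIONAL_ONLY = "functional-only"
EDGE_FUNCTIONAL_PLUS_JI = "functional-plus-JI"


def build_graph(
    edges: Sequence[RedundancyEdge],
    calls: Sequence[InformativeCall],
    conservation: Sequence[ConservationResult],
    collection: SignatureCollection,
    edge_threshold: float = 0.7,
) -> nx.Graph:
    """Build the redundancy network over the signatures named in ``calls``.

    Edge rule: functional_redundancy > edge_threshold (strict); weight =
    (jaccard + functional_redundancy) / 2; class from JI significance.
    Referencing a signature absent from ``calls`` is an error.
    """
    conserved = {c.signature_name: bool(c.conserved) for c in conservation}
    g = nx.Graph()
    for call in calls:
        sig = collection.get(call.signature_name)
        g.add_node(
            call.signature_name,
            category=sig.category,
            informative=bool(call.informative),
            conserved=conserved.get(call.signature_name, False),
            n_genes=len(sig),
        )
    for e in edges:
        for name in (e.sig_a, e.sig_b):
            if name not in g:
                raise ValueError(f"edge references unknown signature {name!r}")
        if e.functional_redundancy > edge_threshold:
            g.add_edge(
                e.sig_a,
                e.sig_b,
                weight=(e.jaccard + e.functional_redundancy) / 2.0,
                jaccard=e.jaccard,
                functional_redundancy=e.functional_redundancy,
                edge_class=(
                    EDGE_FUNCTIONAL_PLUS_JI if e.ji_significant else EDGE_FUNCTIONAL_ONLY
                ),
            )
    return g


def connected_components(graph: nx.Graph) -> list[set[str]]:
    """Connected components, sorted by size descending (ties by node names)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def _node_record(graph: nx.Graph, name: str) -> dict:
    rec = {"name": name}
    rec.update(graph.nodes[name])
    return rec


def export_graph(graph: nx.Graph, fmt: str, path: str | Path) -> None:
    """Export the network as ``graphml``, ``sif`` or ``json``.

    GraphML carries all node/edge attributes; SIF encodes the edge class
    as the interaction type (isolated nodes appear as bare names); JSON
    lists nodes and edges with their attributes, including any per-node
    differential scores attached by :func:`infosig.differential.score_map`.
    """
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(graph, path)
    elif fmt == "sif":
        with path.open("w", encoding="utf-8") as fh:
            covered = set()
            for a, b, data in sorted(graph.edges(data=True)):
                fh.write(f"{a}\t{data.get('edge_class', 'redundancy')}\t{b}\n")
                covered.update((a, b))
            for n in sorted(graph.nodes):
                if n not in covered:
                    fh.write(f"{n}\n")
    elif fmt == "json":
        doc = {
            "nodes": [_node_record(graph, n) for n in sorted(graph.nodes)],
            "edges": [
                {"source": a, "target": b, **data}
                for a, b, data in sorted(graph.edges(data=True))
            ],
        }
        with path.open("w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        raise ValueError(f"unknown export format {fmt!r} (graphml, sif, json)")
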