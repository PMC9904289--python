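"""Network serialization: canonical TSV tables and GraphML.

TSV is the canonical format: a node table keyed by a ``shared name`` column
(Cytoscape table dialect), an edge table, and a small metadata table, all
with sorted rows and fixed column order so byte-equality is a usable test
oracle.  Attribute values are JSON-encoded per cell, which preserves types
(int vs float vs string) across round-trips.  GraphML is a convenience
export built on networkx; ``write∘read`` is the identity on nodes, edges
and attributes in both formats.

A network saved under prefix ``P`` occupies ``P.nodes.tsv``,
``P.edges.tsv`` and ``P.meta.tsv`` (or ``P.graphml``).
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import networkx as nx

from .errors import ParseError
from .model import CHANNELS, Edge, EvidenceVector, Network, Node

def _part(prefix, part: str) -> Path:
    return Path(str(prefix) + "." + part)


_NODE_FIXED = ("shared name", "node_type", "species", "display_name")
_EDGE_FIXED = ("protein1", "protein2", "interaction_type", "source",
               "combined_score")


def _fmt(x: float) -> str:
    return repr(float(x))


def write_network_tsv(net: Network, prefix) -> None:
    prefix = Path(prefix)
    attr_keys = sorted({k for n in net.nodes.values() for k in n.attributes})
    with open(_part(prefix, "nodes.tsv"), "w", newline="") as fh:
        fh.write("\t".join(_NODE_FIXED + tuple(attr_keys)) + "\n")
        for nid in sorted(net.nodes):
            n = net.nodes[nid]
            cells = [nid, n.node_type,
                     "" if n.species is None else str(n.species),
                     n.display_name]
            for k in attr_keys:
                v = n.attributes.get(k)
                cells.append("" if v is None else json.dumps(v, sort_keys=True))
            fh.write("\t".join(cells) + "\n")
    with open(_part(prefix, "edges.tsv"), "w", newline="") as fh:
        fh.write("\t".join(_EDGE_FIXED + CHANNELS) + "\n")
        for key in sorted(net.edges):
            e = net.edges[key]
            cells = [e.endpoints[0], e.endpoints[1], e.interaction_type,
                     e.source, _fmt(e.combined_score)]
            cells += [_fmt(e.evidence[c]) if e.evidence[c] else "0"
                      for c in CHANNELS]
            fh.write("\t".join(cells) + "\n")
    with open(_part(prefix, "meta.tsv"), "w", newline="") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"network_type\t{net.network_type}\n")
        fh.write(f"cutoff\t{_fmt(net.cutoff)}\n")
        fh.write(f"prior\t{_fmt(net.prior)}\n")


def read_network_tsv(prefix) -> Network:
    prefix = Path(prefix)
    meta = {}
    meta_path = _part(prefix, "meta.tsv")
    if meta_path.exists():
        with open(meta_path, newline="") as fh:
            for rec in csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE):
                meta[rec["key"]] = rec["value"]
    net = Network(
        network_type=meta.get("network_type", "full"),
        cutoff=float(meta.get("cutoff", 0.4)),
        prior=float(meta.get("prior", 0.041)),
    )
    nodes_path = _part(prefix, "nodes.tsv")
    with open(nodes_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        if reader.fieldnames is None or "shared name" not in reader.fieldnames:
            raise ParseError(f"{nodes_path}: missing 'shared name' column")
        attr_keys = [c for c in reader.fieldnames if c not in _NODE_FIXED]
        for ln, rec in enumerate(reader, start=2):
            try:
                attrs = {
                    k: json.loads(rec[k]) for k in attr_keys if rec.get(k)
                }
                net.add_node(Node(
                    id=rec["shared name"],
                    node_type=rec["node_type"],
                    species=int(rec["species"]) if rec["species"] else None,
                    display_name=rec["display_name"],
                    attributes=attrs,
                ))
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{nodes_path}:{ln}: {exc}") from exc
    edges_path = _part(prefix, "edges.tsv")
    with open(edges_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        if reader.fieldnames is None or "protein1" not in reader.fieldnames:
            raise ParseError(f"{edges_path}: missing edge-table header")
        for ln, rec in enumerate(reader, start=2):
            try:
                a, b = rec["protein1"], rec["protein2"]
                for ep in (a, b):
                    if ep not in net.nodes:
                        raise ParseError(
                            f"{edges_path}:{ln}: edge endpoint {ep!r} "
                            f"not in node table"
                        )
                ev = EvidenceVector({
                    c: float(rec[c]) for c in CHANNELS if float(rec[c] or 0)
                })
                net.add_edge(Edge(
                    endpoints=(a, b),
                    interaction_type=rec["interaction_type"],
                    source=rec["source"],
                    combined_score=float(rec["combined_score"]),
                    evidence=ev,
                ))
            except ParseError:
                raise
            except (KeyError, ValueError) as exc:
                raise ParseError(f"{edges_path}:{ln}: {exc}") from exc
    return net


def write_network_graphml(net: Network, path) -> None:
    g = nx.Graph(network_type=net.network_type, cutoff=net.cutoff,
                 prior=net.prior)
    for nid in sorted(net.nodes):
        n = net.nodes[nid]
        data = {"node_type": n.node_type, "display_name": n.display_name,
                "attributes": json.dumps(n.attributes, sort_keys=True)}
        if n.species is not None:
            data["species"] = n.species
        g.add_node(nid, **data)
    for key in sorted(net.edges):
        e = net.edges[key]
        g.add_edge(
            *e.endpoints,
            interaction_type=e.interaction_type,
            source=e.source,
            combined_score=e.combined_score,
            evidence=json.dumps(dict(e.evidence.items()), sort_keys=True),
        )
    nx.write_graphml(g, str(path))


def read_network_graphml(path) -> Network:
    try:
        g = nx.read_graphml(str(path))
    except Exception as exc:  # malformed XML
        raise ParseError(f"{path}: {exc}") from exc
    net = Network(
        network_type=g.graph.get("network_type", "full"),
        cutoff=float(g.graph.get("cutoff", 0.4)),
        prior=float(g.graph.get("prior", 0.041)),
    )
    for nid, data in g.nodes(data=True):
        net.add_node(Node(
            id=nid,
            node_type=data.get("node_type", "protein"),
            species=int(data["species"]) if "species" in data else None,
            display_name=data.get("display_name", ""),
            attributes=json.loads(data.get("attributes", "{}")),
        ))
    for a, b, data in g.edges(data=True):
        net.add_edge(Edge(
            endpoints=(a, b),
            interaction_type=data.get("interaction_type", "association"),
            source=data.get("source", "store"),
            combined_score=float(data.get("combined_score", 0.0)),
            evidence=EvidenceVector(json.loads(data.get("evidence", "{}"))),
        ))
    return net


def write_network(net: Network, prefix, fmt: str = "tsv") -> None:
    """Write a network under a path prefix in the requested format."""
    if fmt == "tsv":
        write_network_tsv(net, prefix)
    elif fmt == "graphml":
        write_network_graphml(net, str(_part(prefix, "graphml")))
    else:
        raise ParseError(f"unknown network format {fmt!r}")


def read_network(prefix, fmt: str = "tsv") -> Network:
    """Read a network from a path prefix in the requested format."""
    if fmt == "tsv":
        return read_network_tsv(prefix)
    if fmt == "graphml":
        return read_network_graphml(str(_part(prefix, "graphml")))
    raise ParseError(f"unknown network format {fmt!r}")
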