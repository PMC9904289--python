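"""Node filtering by subcellular/tissue confidence and edge filtering by
evidence channel.

Localization confidences follow the 0-5 star scale used by the
COMPARTMENTS (subcellular) and TISSUES (tissue expression) resources and
live in node attributes under namespaced keys ``"compartment::<name>"`` and
``"tissue::<name>"``.  Filtering removes nodes/edges (there is no view
layer); both operations optionally report what was removed.
"""

from __future__ import annotations

import csv
import warnings
from typing import Optional

from .errors import InvalidArgumentError, ParseError
from .model import CHANNELS, Network

NAMESPACES = ("compartment", "tissue")


def localization_key(namespace: str, name: str) -> str:
    if namespace not in NAMESPACES:
        raise InvalidArgumentError(f"unknown localization namespace {namespace!r}")
    return f"{namespace}::{name}"


def attach_localization(network: Network, path) -> int:
    """Read a localization TSV (protein, namespace, name, score 0-5) and set
    the matching node attributes.  Returns the number of scores attached."""
    count = 0
    with open(path, newline="") as fh:
        for ln, rec in enumerate(csv.DictReader(fh, delimiter="\t"), start=2):
            try:
                key = localization_key(rec["namespace"], rec["name"])
                score = float(rec["score"])
            except (KeyError, InvalidArgumentError, ValueError) as exc:
                raise ParseError(f"{path}:{ln}: {exc}") from exc
            node = network.nodes.get(rec["protein"])
            if node is not None:
                node.attributes[key] = score
                count += 1
    return count


def filter_nodes_by_score(
    network: Network,
    namespace: str,
    name: str,
    min_score: float,
    keep_missing: bool = True,
    report: Optional[list] = None,
) -> Network:
    """Keep protein nodes whose localization score clears the threshold.

    Nodes lacking the annotation are kept iff ``keep_missing``; compound and
    term nodes are always kept.  Edges are induced on the surviving nodes.
    An unknown location name (absent from every node) triggers a warning,
    not an error.
    """
    if not 0.0 <= min_score <= 5.0:
        raise InvalidArgumentError(f"min score must be in [0, 5], got {min_score}")
    key = localization_key(namespace, name)
    if not any(key in n.attributes for n in network.nodes.values()):
        warnings.warn(f"location {key!r} not annotated on any node", stacklevel=2)

    net = network.copy()
    removed = []
    for nid, node in list(net.nodes.items()):
        if node.node_type != "protein":
            continue
        score = node.attributes.get(key)
        keep = keep_missing if score is None else score >= min_score
        if not keep:
            removed.append(nid)
            del net.nodes[nid]
    net.edges = {
        k: e
        for k, e in net.edges.items()
        if all(ep in net.nodes for ep in e.endpoints)
    }
    if report is not None:
        report.extend(removed)
    return net


def filter_edges_by_channel(
    network: Network,
    channel: str,
    min_score: float,
    report: Optional[list] = None,
) -> Network:
    """Keep association edges whose channel score clears the threshold.

    A channel absent from an edge scores 0.  User and enrichment edges are
    untouched; no node is removed.
    """
    if channel not in CHANNELS:
        raise InvalidArgumentError(f"unknown evidence channel {channel!r}")
    if not 0.0 <= min_score <= 1.0:
        raise InvalidArgumentError(f"min score must be in [0, 1], got {min_score}")
    net = network.copy()
    removed = []
    for k, e in list(net.edges.items()):
        if e.interaction_type == "association" and e.evidence[channel] < min_score:
            removed.append(k)
            del net.edges[k]
    if report is not None:
        report.extend(removed)
    return net
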