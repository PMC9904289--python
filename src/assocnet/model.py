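"""Core domain types: species, nodes, evidence vectors, edges, networks.

The data model mirrors the STRING ecosystem's conventions: protein nodes are
identified as ``"<taxid>.<accession>"``, association edges carry one
confidence score per evidence channel plus a combined score, and a network is
typed (``full`` functional associations or the ``physical`` subnetwork) and
carries the confidence cutoff it was built with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .errors import InvalidArgumentError

#: The fixed evidence channels, in canonical order.
CHANNELS: tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experiments",
    "database",
    "textmining",
)

#: Lineage ranks recognised by the taxonomy, most-specific first.
LINEAGE_RANKS: tuple[str, ...] = ("genus", "family", "order", "class")

NODE_TYPES = ("protein", "compound", "enriched_term")
INTERACTION_TYPES = ("association", "enrichment", "user")
EDGE_SOURCES = ("store", "transferred", "lifted")

#: Default prior probability that a random protein pair is associated.
DEFAULT_PRIOR = 0.041


@dataclass(frozen=True)
class Species:
    """One species with its (partial) taxonomic lineage.

    ``lineage`` maps rank name -> taxon name and must cover at least the
    ranks in :data:`LINEAGE_RANKS`; it is used to decide whether orthology
    transfer between two species is within taxonomic scope.
    """

    taxid: int
    name: str
    lineage: Mapping[str, str]

    def __post_init__(self):
        if self.taxid <= 0:
            raise InvalidArgumentError(f"taxid must be positive, got {self.taxid}")
        missing = [r for r in LINEAGE_RANKS if r not in self.lineage]
        if missing:
            raise InvalidArgumentError(
                f"species {self.taxid} lineage missing ranks: {missing}"
            )


class EvidenceVector(Mapping[str, float]):
    """Per-channel confidence scores in [0, 1]; an absent channel scores 0.

    Immutable mapping from channel name to score.  Only channels in
    :data:`CHANNELS` are accepted; zero scores are not stored.
    """

    __slots__ = ("_scores",)

    def __init__(self, scores: Optional[Mapping[str, float]] = None, **kw: float):
        merged: dict[str, float] = {}
        for src in (scores or {}), kw:
            for ch, s in src.items():
                if ch not in CHANNELS:
                    raise InvalidArgumentError(f"unknown evidence channel {ch!r}")
                s = float(s)
                if not 0.0 <= s <= 1.0:
                    raise InvalidArgumentError(
                        f"channel {ch!r} score {s} outside [0, 1]"
                    )
                if s > 0.0:
                    merged[ch] = s
        object.__setattr__(self, "_scores", merged)

    def __setattr__(self, *a):  # pragma: no cover - immutability guard
        raise AttributeError("EvidenceVector is immutable")

    def __copy__(self):
        return self

    def __deepcopy__(self, memo):
        return self

    def __reduce__(self):
        return (EvidenceVector, (dict(self._scores),))

    def __getitem__(self, ch: str) -> float:
        if ch not in CHANNELS:
            raise KeyError(ch)
        return self._scores.get(ch, 0.0)

    def get(self, ch: str, default: float = 0.0) -> float:
        return self._scores.get(ch, default)

    def __iter__(self):
        return iter(self._scores)

    def __len__(self):
        return len(self._scores)

    def __eq__(self, other):
        if isinstance(other, EvidenceVector):
            return self._scores == other._scores
        return NotImplemented

    def __hash__(self):
        return hash(frozenset(self._scores.items()))

    def __repr__(self):
        inner = ", ".join(f"{c}={self._scores[c]}" for c in CHANNELS if c in self._scores)
        return f"EvidenceVector({inner})"

    def is_empty(self) -> bool:
        return not self._scores


EMPTY_EVIDENCE = EvidenceVector()


def species_of(node_id: str) -> Optional[int]:
    """Parse the taxid prefix of a ``"<taxid>.<accession>"`` protein id.

    Returns None for ids that do not follow the convention (compounds,
    term nodes, unmapped user nodes).
    """
    head, _, tail = node_id.partition(".")
    if tail and head.isdigit():
        return int(head)
    return None


@dataclass
class Node:
    """A network node: protein, compound, or injected enriched term.

    ``attributes`` is an open key->value map holding localization scores
    (``"compartment::<name>"``, ``"tissue::<name>"``), group labels
    (``"group"``) and any attributes lifted from user networks.
    """

    id: str
    node_type: str = "protein"
    species: Optional[int] = None
    display_name: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.node_type not in NODE_TYPES:
            raise InvalidArgumentError(f"unknown node type {self.node_type!r}")
        if not self.display_name:
            self.display_name = self.id.partition(".")[2] or self.id
        if self.node_type == "protein" and self.species is None:
            self.species = species_of(self.id)


def edge_key(a: str, b: str) -> tuple[str, str]:
    """Canonical (lexicographically ordered) endpoint pair."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Edge:
    """An undirected edge with typed provenance.

    Association edges carry an :class:`EvidenceVector` and a combined score
    consistent with the channel-combination formula; enrichment and user
    edges carry no evidence.
    """

    endpoints: tuple[str, str]
    interaction_type: str = "association"
    evidence: EvidenceVector = EMPTY_EVIDENCE
    combined_score: float = 0.0
    source: str = "store"

    def __post_init__(self):
        a, b = self.endpoints
        if a == b:
            raise InvalidArgumentError(f"self-edge on {a!r}")
        self.endpoints = edge_key(a, b)
        if self.interaction_type not in INTERACTION_TYPES:
            raise InvalidArgumentError(
                f"unknown interaction type {self.interaction_type!r}"
            )
        if self.source not in EDGE_SOURCES:
            raise InvalidArgumentError(f"unknown edge source {self.source!r}")

    @property
    def key(self) -> tuple[tuple[str, str], str]:
        return (self.endpoints, self.interaction_type)

    def is_cross_species(self) -> bool:
        sa, sb = (species_of(e) for e in self.endpoints)
        return sa is not None and sb is not None and sa != sb


@dataclass
class Network:
    """Typed nodes plus scored edges, with a network type and cutoff."""

    nodes: dict[str, Node] = field(default_factory=dict)
    edges: dict[tuple, Edge] = field(default_factory=dict)
    network_type: str = "full"
    cutoff: float = 0.4
    prior: float = DEFAULT_PRIOR

    def add_node(self, node: Node) -> None:
        self.nodes[node.id] = node

    def add_edge(self, edge: Edge) -> None:
        self.edges[edge.key] = edge

    def association_edges(self) -> list[Edge]:
        return [e for e in self.edges.values() if e.interaction_type == "association"]

    def copy(self) -> "Network":
        import copy as _copy

        return _copy.deepcopy(self)


def validate(network: Network) -> list[str]:
    """Check every type invariant; return human-readable violations.

    Pure: never mutates, never raises for invariant violations.  An empty
    list means the network is well-formed.
    """
    from .evidence import combine_channels  # deferred: avoid import cycle

    violations: list[str] = []
    for nid, node in network.nodes.items():
        if nid != node.id:
            violations.append(f"node key {nid!r} differs from node id {node.id!r}")
        if node.node_type == "protein" and node.species is None:
            violations.append(f"protein node {nid!r} has null species")
    for edge in network.edges.values():
        a, b = edge.endpoints
        name = f"edge {a!r}--{b!r} ({edge.interaction_type})"
        if a == b:
            violations.append(f"{name}: self-edge")
        for ep in edge.endpoints:
            if ep not in network.nodes:
                violations.append(f"{name}: endpoint {ep!r} missing from nodes")
        if not 0.0 <= edge.combined_score <= 1.0:
            violations.append(
                f"{name}: combined score {edge.combined_score} outside [0, 1]"
            )
        if edge.interaction_type == "association":
            expected = combine_channels(edge.evidence, network.prior)
            if abs(expected - edge.combined_score) > 1e-9:
                violations.append(
                    f"{name}: combined score {edge.combined_score!r} inconsistent "
                    f"with evidence (expected {expected!r})"
                )
            if edge.source in ("store", "transferred") and (
                edge.combined_score < network.cutoff - 1e-12
            ):
                violations.append(
                    f"{name}: store-backed combined score {edge.combined_score} "
                    f"below cutoff {network.cutoff}"
                )
        else:
            if not edge.evidence.is_empty():
                violations.append(f"{name}: non-association edge carries evidence")
    return violations


def load_taxonomy(path) -> dict[int, Species]:
    """Read a taxonomy TSV (taxid, name, genus, family, order, class)."""
    import csv

    species: dict[int, Species] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            taxid = int(row["taxid"])
            species[taxid] = Species(
                taxid=taxid,
                name=row["name"],
                lineage={r: row[r] for r in LINEAGE_RANKS},
            )
    return species


def write_taxonomy(species: Iterable[Species], path) -> None:
    rows = sorted(species, key=lambda s: s.taxid)
    with open(path, "w") as fh:
        fh.write("taxid\tname\t" + "\t".join(LINEAGE_RANKS) + "\n")
        for sp in rows:
            fh.write(
                f"{sp.taxid}\t{sp.name}\t"
                + "\t".join(sp.lineage[r] for r in LINEAGE_RANKS)
                + "\n"
            )
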