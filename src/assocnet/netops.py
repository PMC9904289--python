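"""Network queries and manipulation.

Query semantics mirror the client behavior the score store was designed for:

* a *protein query* maps user identifiers to store ids and retrieves the
  interactions among them;
* a *ranked-entity query* (the generalization of disease/topic queries)
  first takes the top-N proteins associated with an entity, then their
  interactions;
* a *cross-species query* takes the interspecies interactions at the cutoff
  plus any intraspecies interactions among the same proteins;
* *expand* adds up to N new proteins (optionally species-restricted) ranked
  by connectivity to a selection;
* *set_confidence* deletes edges when the cutoff is raised but re-queries
  the store when it is lowered;
* *set_type* swaps all store edges between the full and physical stores;
* *stringify* converts an arbitrary user network into a store-mapped one,
  lifting the original edges at cutoff 1.0.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    EmptyQueryError,
    EmptyResultError,
    InvalidArgumentError,
    InvalidSelectionError,
    NotFoundError,
)
from .model import Edge, Network, Node, species_of
from .store import AliasTable, Row, ScoreStore


def _check_cutoff(cutoff: float) -> None:
    if not 0.0 <= cutoff <= 1.0:
        raise InvalidArgumentError(f"cutoff must be in [0, 1], got {cutoff}")


def _protein_node(pid: str, aliases: Optional[AliasTable] = None) -> Node:
    name = aliases.preferred_name(pid) if aliases is not None else None
    return Node(id=pid, node_type="protein", display_name=name or "")


def _edge_from_row(p1: str, p2: str, row: Row) -> Edge:
    return Edge(
        endpoints=(p1, p2),
        interaction_type="association",
        evidence=row.evidence,
        combined_score=row.combined,
        source="transferred" if row.transferred else "store",
    )


def _fill_edges(net: Network, store: ScoreStore, cutoff: float) -> None:
    for p1, p2, row in store.pair_scores(net.nodes.keys(), cutoff):
        net.add_edge(_edge_from_row(p1, p2, row))


def protein_query(
    ids: Sequence[str],
    species: int,
    store: ScoreStore,
    aliases: AliasTable,
    cutoff: float = 0.4,
) -> tuple[Network, dict]:
    """Map identifiers to store proteins and fetch interactions among them.

    Returns ``(network, report)``; the report lists the id->protein mapping
    and the identifiers that did not resolve (never silently dropped).
    """
    if not ids:
        raise EmptyQueryError("no query identifiers given")
    _check_cutoff(cutoff)
    mapped: dict[str, str] = {}
    unresolved: list[str] = []
    for ident in ids:
        pid = aliases.resolve(ident, species)
        if pid is None:
            unresolved.append(ident)
        else:
            mapped[ident] = pid
    if not mapped:
        raise EmptyQueryError(f"none of {len(ids)} identifiers resolved")
    net = Network(network_type=store.network_type, cutoff=cutoff, prior=store.prior)
    for pid in sorted(set(mapped.values())):
        net.add_node(_protein_node(pid, aliases))
    _fill_edges(net, store, cutoff)
    return net, {"mapped": mapped, "unresolved": unresolved}


def ranked_entity_query(
    entity: str,
    n_top: int,
    entity_links: Mapping[str, Sequence[tuple[str, float]]],
    store: ScoreStore,
    cutoff: float = 0.4,
    aliases: Optional[AliasTable] = None,
) -> Network:
    """Top-N proteins associated with an entity, plus their interactions.

    ``entity_links`` maps entity name -> [(protein id, association score)].
    Ranking is by score descending with lexicographic id tiebreak.
    """
    if n_top < 1:
        raise InvalidArgumentError("N must be >= 1")
    _check_cutoff(cutoff)
    if entity not in entity_links:
        raise NotFoundError(f"unknown entity {entity!r}")
    ranked = sorted(entity_links[entity], key=lambda t: (-t[1], t[0]))
    net = Network(network_type=store.network_type, cutoff=cutoff, prior=store.prior)
    for pid, score in ranked[:n_top]:
        node = _protein_node(pid, aliases)
        node.attributes["entity_score"] = score
        net.add_node(node)
    _fill_edges(net, store, cutoff)
    return net


def cross_species_query(
    species_a: int,
    species_b: int,
    store: ScoreStore,
    cutoff: float = 0.4,
    aliases: Optional[AliasTable] = None,
) -> Network:
    """Interspecies interactions at the cutoff plus intraspecies edges
    among the same proteins.

    Every node in the result touches at least one cross-species edge; the
    query fails with :class:`EmptyResultError` when the two species share no
    interaction at the cutoff.  Nodes carry a ``species_order`` attribute
    (1 for the first species in the query, 2 for the second).
    """
    if species_a == species_b:
        raise InvalidArgumentError("cross-species query needs two distinct taxids")
    _check_cutoff(cutoff)
    cross = [
        (p1, p2, row)
        for p1, p2, row in store.iter_cross_pairs(species_a, species_b)
        if row.combined >= cutoff
    ]
    if not cross:
        raise EmptyResultError(
            f"no cross-species interaction between {species_a} and {species_b} "
            f"at cutoff {cutoff}"
        )
    net = Network(network_type=store.network_type, cutoff=cutoff, prior=store.prior)
    for pa, pb, row in cross:
        for pid in (pa, pb):
            if pid not in net.nodes:
                node = _protein_node(pid, aliases)
                node.attributes["species_order"] = (
                    1 if species_of(pid) == species_a else 2
                )
                net.add_node(node)
        net.add_edge(_edge_from_row(pa, pb, row))
    # intraspecies edges among the cross-interacting proteins
    _fill_edges(net, store, cutoff)
    return net


def expand(
    network: Network,
    selection: Iterable[str],
    store: ScoreStore,
    max_added: int = 100,
    cutoff: float = 0.4,
    target_species: Optional[int] = None,
    aliases: Optional[AliasTable] = None,
) -> Network:
    """Add up to ``max_added`` proteins connected to the selection.

    Candidates are partners (at or above the cutoff) of the selected nodes,
    restricted to ``target_species`` when given, ranked by (number of
    selected neighbors, sum of those scores, id ascending).  After adding
    nodes, all store edges at the cutoff among the enlarged node set are
    fetched (inter- and intraspecies alike).
    """
    selection = list(selection)
    if not selection:
        raise InvalidSelectionError("selection is empty")
    missing = [s for s in selection if s not in network.nodes]
    if missing:
        raise InvalidSelectionError(f"selection ids not in network: {missing}")
    if max_added < 0:
        raise InvalidArgumentError("max_added must be >= 0")
    _check_cutoff(cutoff)
    net = network.copy()
    if max_added == 0:
        return net
    species = {target_species} if target_species is not None else None
    tally: dict[str, tuple[int, float]] = {}
    for sel in selection:
        for partner, score in store.neighbors(sel, species=species, cutoff=cutoff):
            if partner in net.nodes:
                continue
            n, tot = tally.get(partner, (0, 0.0))
            tally[partner] = (n + 1, tot + score)
    ranked = sorted(tally, key=lambda p: (-tally[p][0], -tally[p][1], p))
    for pid in ranked[:max_added]:
        net.add_node(_protein_node(pid, aliases))
    _fill_edges(net, store, cutoff)
    return net


def set_confidence(network: Network, new_cutoff: float, store: ScoreStore) -> Network:
    """Change the confidence cutoff.

    Raising it deletes store-backed association edges below the new cutoff
    (nodes are kept, possibly isolated); lowering it re-queries the store
    for all protein pairs in the network.  User and enrichment edges are
    untouched.
    """
    _check_cutoff(new_cutoff)
    net = network.copy()
    if new_cutoff > net.cutoff:
        net.edges = {
            k: e
            for k, e in net.edges.items()
            if e.interaction_type != "association"
            or e.source == "lifted"
            or e.combined_score >= new_cutoff
        }
    elif new_cutoff < net.cutoff:
        _fill_edges(net, store, new_cutoff)
    net.cutoff = new_cutoff
    return net


def set_type(
    network: Network,
    new_type: str,
    full_store: ScoreStore,
    physical_store: ScoreStore,
) -> Network:
    """Switch between the full and physical networks.

    Deletes every store-backed association edge and re-fetches edges of the
    chosen type at the current cutoff for all proteins in the network; user
    and enrichment edges (and the node set) are preserved.
    """
    if new_type not in ("full", "physical"):
        raise InvalidArgumentError(f"unknown network type {new_type!r}")
    store = full_store if new_type == "full" else physical_store
    net = network.copy()
    net.edges = {
        k: e
        for k, e in net.edges.items()
        if e.interaction_type != "association" or e.source == "lifted"
    }
    net.network_type = new_type
    _fill_edges(net, store, net.cutoff)
    return net


def stringify(
    user_network: Network,
    id_attribute: str,
    species: int,
    aliases: AliasTable,
    keep_unmapped: bool = True,
) -> tuple[Network, dict]:
    """Convert a non-store network into a store-mapped one.

    Each node's ``id_attribute`` value is resolved against the alias table;
    mapped nodes adopt the store protein id (original attributes are kept and
    the original id is recorded under ``"query term"``).  Unmapped nodes are
    kept as-is when ``keep_unmapped``.  All original edges are lifted over
    (interaction type ``user``, source ``lifted``); no store edges are
    retrieved, which is expressed by setting the cutoff to 1.0 — lowering it
    later adds store edges.

    When two user nodes map to the same store protein they are merged and
    their attribute values concatenated; the report records merges, the
    mapping, and dropped nodes.
    """
    mapping: dict[str, Optional[str]] = {}
    for nid, node in user_network.nodes.items():
        ident = node.attributes.get(id_attribute)
        mapping[nid] = (
            aliases.resolve(str(ident), species) if ident is not None else None
        )

    new_id: dict[str, str] = {}
    merged: dict[str, list[str]] = {}
    for nid in sorted(user_network.nodes):
        pid = mapping[nid]
        if pid is None:
            new_id[nid] = nid
        else:
            new_id[nid] = pid
            merged.setdefault(pid, []).append(nid)

    net = Network(network_type=user_network.network_type, cutoff=1.0,
                  prior=user_network.prior)
    dropped: list[str] = []
    for nid in sorted(user_network.nodes):
        node = user_network.nodes[nid]
        pid = mapping[nid]
        if pid is None:
            if not keep_unmapped:
                dropped.append(nid)
                continue
            copy = Node(
                id=nid, node_type=node.node_type, species=node.species,
                display_name=node.display_name, attributes=dict(node.attributes),
            )
            net.add_node(copy)
        elif pid in net.nodes:  # duplicate mapping: merge attributes
            tgt = net.nodes[pid]
            for k, v in node.attributes.items():
                if k in tgt.attributes and tgt.attributes[k] != v:
                    tgt.attributes[k] = f"{tgt.attributes[k]}|{v}"
                else:
                    tgt.attributes.setdefault(k, v)
            tgt.attributes["query term"] = (
                f"{tgt.attributes['query term']}|{nid}"
            )
        else:
            mapped = _protein_node(pid, aliases)
            mapped.attributes.update(node.attributes)
            mapped.attributes["query term"] = nid
            net.add_node(mapped)

    for edge in user_network.edges.values():
        a, b = (new_id[e] for e in edge.endpoints)
        if a == b:  # endpoints merged into one store node
            continue
        if a not in net.nodes or b not in net.nodes:
            continue
        net.add_edge(
            Edge(
                endpoints=(a, b),
                interaction_type="user",
                combined_score=edge.combined_score,
                source="lifted",
            )
        )
    report = {
        "mapping": mapping,
        "merged": {p: ns for p, ns in merged.items() if len(ns) > 1},
        "dropped": dropped,
    }
    return net, report
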