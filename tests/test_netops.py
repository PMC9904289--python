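"""Query and manipulation semantics against naive table-scan oracles."""

import pytest

from assocnet.errors import (
    EmptyQueryError,
    EmptyResultError,
    InvalidSelectionError,
    NotFoundError,
)
from assocnet.fixtures import apms_network, generate_apms_table
from assocnet.model import species_of, validate
from assocnet.netops import (
    cross_species_query,
    expand,
    protein_query,
    ranked_entity_query,
    set_confidence,
    set_type,
    stringify,
)


from oracles import scan_edges


class TestProteinQuery:
    def test_edges_match_scan_oracle(self, world, host_taxid):
        ids = world.protein_ids(host_taxid)[:5]
        net, report = protein_query(ids, host_taxid, world.full,
                                    world.aliases, cutoff=0.4)
        assert set(net.nodes) == set(ids)
        assert set(k[0] for k in net.edges) == \
            scan_edges(world.full, ids, 0.4)
        assert report["unresolved"] == []
        assert validate(net) == []

    def test_unresolved_ids_reported_not_dropped(self, world, host_taxid):
        ids = world.protein_ids(host_taxid)[:2] + ["NOT_A_GENE"]
        net, report = protein_query(ids, host_taxid, world.full,
                                    world.aliases)
        assert report["unresolved"] == ["NOT_A_GENE"]
        assert len(net.nodes) == 2

    def test_gene_name_aliases_resolve(self, world, host_taxid):
        net, report = protein_query(["hsg1", "HSG2"], host_taxid, world.full,
                                    world.aliases)
        assert len(net.nodes) == 2
        assert report["unresolved"] == []

    def test_single_id_gives_one_node_no_edges(self, world, host_taxid):
        net, _ = protein_query(world.protein_ids(host_taxid)[:1], host_taxid,
                               world.full, world.aliases)
        assert len(net.nodes) == 1 and len(net.edges) == 0

    def test_cutoff_one_gives_edgeless_network(self, world, host_taxid):
        ids = world.protein_ids(host_taxid)
        net, _ = protein_query(ids, host_taxid, world.full, world.aliases,
                               cutoff=1.0)
        assert len(net.edges) == 0

    def test_no_resolvable_id_raises(self, world, host_taxid):
        with pytest.raises(EmptyQueryError):
            protein_query(["XX1", "XX2"], host_taxid, world.full,
                          world.aliases)


class TestRankedEntityQuery:
    def test_top_n_by_score_then_id(self, world):
        links = {"d": [("9606.HSP0004", 0.9), ("9606.HSP0002", 0.8),
                       ("9606.HSP0001", 0.7), ("9606.HSP0003", 0.1)]}
        net = ranked_entity_query("d", 3, links, world.full)
        assert set(net.nodes) == {"9606.HSP0004", "9606.HSP0002",
                                  "9606.HSP0001"}

    def test_tie_at_rank_boundary_prefers_smaller_id(self, world):
        links = {"d": [("9606.HSP0002", 0.9), ("9606.HSP0001", 0.5),
                       ("9606.HSP0003", 0.5)]}
        net = ranked_entity_query("d", 2, links, world.full)
        assert set(net.nodes) == {"9606.HSP0002", "9606.HSP0001"}

    def test_n_larger_than_list_is_noop(self, world):
        net = ranked_entity_query("malaria", 999, world.entity_links,
                                  world.full)
        assert len(net.nodes) == len(world.entity_links["malaria"])

    def test_unknown_entity_raises(self, world):
        with pytest.raises(NotFoundError):
            ranked_entity_query("no-such-disease", 3, world.entity_links,
                                world.full)

    def test_edges_match_scan_oracle(self, world):
        net = ranked_entity_query("malaria", 6, world.entity_links,
                                  world.full, cutoff=0.4)
        assert set(k[0] for k in net.edges) == \
            scan_edges(world.full, net.nodes, 0.4)


class TestCrossSpeciesQuery:
    def _oracle(self, store, ta, tb, cutoff):
        cross = {
            (p1, p2)
            for p1, p2, row in store.iter_rows()
            if row.combined >= cutoff
            and {species_of(p1), species_of(p2)} == {ta, tb}
        }
        nodes = {p for pair in cross for p in pair}
        intra = {
            (p1, p2)
            for p1, p2, row in store.iter_rows()
            if p1 in nodes and p2 in nodes and row.combined >= cutoff
            and species_of(p1) == species_of(p2)
        }
        return nodes, cross | intra

    @pytest.mark.parametrize("cutoff", [0.4, 0.8])
    def test_matches_two_pass_scan_oracle(self, world, host_taxid,
                                          parasite_taxid, cutoff):
        net = cross_species_query(host_taxid, parasite_taxid, world.full,
                                  cutoff)
        nodes, edges = self._oracle(world.full, host_taxid, parasite_taxid,
                                    cutoff)
        assert set(net.nodes) == nodes
        assert set(k[0] for k in net.edges) == edges
        assert validate(net) == []

    def test_every_node_touches_a_cross_edge(self, world, host_taxid,
                                             parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        cross_endpoints = {
            p for e in net.edges.values() if e.is_cross_species()
            for p in e.endpoints
        }
        assert set(net.nodes) == cross_endpoints

    def test_species_order_attribute(self, world, host_taxid, parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        for nid, node in net.nodes.items():
            expected = 1 if species_of(nid) == host_taxid else 2
            assert node.attributes["species_order"] == expected

    def test_cutoff_above_all_scores_raises_empty_result(
        self, world, host_taxid, parasite_taxid
    ):
        with pytest.raises(EmptyResultError):
            cross_species_query(host_taxid, parasite_taxid, world.full, 0.9999)


class TestExpand:
    def test_noop_at_zero_budget(self, world, host_taxid, parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.8)
        out = expand(net, sorted(net.nodes), world.full, max_added=0)
        assert set(out.nodes) == set(net.nodes)
        assert set(out.edges) == set(net.edges)

    def test_adds_all_qualifying_candidates_when_budget_large(
        self, world, host_taxid, parasite_taxid, vector_taxid
    ):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.8)
        out = expand(net, sorted(net.nodes), world.full, max_added=100,
                     cutoff=0.8, target_species=vector_taxid)
        # oracle: vector proteins with >=1 edge >=0.8 to the selection
        candidates = {
            (p2 if p1 in net.nodes else p1)
            for p1, p2, row in world.full.iter_rows()
            if row.combined >= 0.8
            and ((p1 in net.nodes) != (p2 in net.nodes))
            and vector_taxid in (species_of(p1), species_of(p2))
            and species_of(p2 if p1 in net.nodes else p1) == vector_taxid
        }
        assert set(out.nodes) - set(net.nodes) == candidates
        # all inter- and intraspecies edges at the cutoff are added
        assert set(k[0] for k in out.edges) == \
            scan_edges(world.full, out.nodes, 0.8)
        assert validate(out) == []

    def test_budget_limits_additions_deterministically(
        self, world, host_taxid, parasite_taxid, vector_taxid
    ):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.8)
        full = expand(net, sorted(net.nodes), world.full, max_added=100,
                      cutoff=0.8, target_species=vector_taxid)
        n_all = len(full.nodes) - len(net.nodes)
        if n_all < 2:
            pytest.skip("fixture yields fewer than 2 expansion candidates")
        one = expand(net, sorted(net.nodes), world.full, max_added=1,
                     cutoff=0.8, target_species=vector_taxid)
        again = expand(net, sorted(net.nodes), world.full, max_added=1,
                       cutoff=0.8, target_species=vector_taxid)
        assert len(one.nodes) == len(net.nodes) + 1
        assert set(one.nodes) == set(again.nodes)

    def test_invalid_selection_raises(self, world, host_taxid, parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.8)
        with pytest.raises(InvalidSelectionError):
            expand(net, ["9606.NOPE"], world.full)


class TestSetConfidence:
    def test_same_cutoff_is_identity(self, world, host_taxid, parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        out = set_confidence(net, 0.4, world.full)
        assert set(out.edges) == set(net.edges)
        assert set(out.nodes) == set(net.nodes)

    def test_raise_filters_edges_keeps_nodes(self, world, host_taxid,
                                             parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        out = set_confidence(net, 0.8, world.full)
        assert set(out.nodes) == set(net.nodes)
        expected = {k for k, e in net.edges.items()
                    if e.combined_score >= 0.8}
        assert set(out.edges) == expected
        assert out.cutoff == 0.8
        assert validate(out) == []

    def test_raise_is_idempotent(self, world, host_taxid, parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        once = set_confidence(net, 0.8, world.full)
        twice = set_confidence(once, 0.8, world.full)
        assert set(once.edges) == set(twice.edges)

    def test_lower_requeries_store(self, world, host_taxid, parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.8)
        out = set_confidence(net, 0.4, world.full)
        assert set(k[0] for k in out.edges) == \
            scan_edges(world.full, net.nodes, 0.4)
        assert validate(out) == []


class TestSetType:
    def test_identity_when_type_unchanged(self, world, host_taxid,
                                          parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        out = set_type(net, "full", world.full, world.physical)
        assert set(out.edges) == set(net.edges)

    def test_switch_to_physical_matches_oracle(self, world, host_taxid,
                                               parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        out = set_type(net, "physical", world.full, world.physical)
        assert set(out.nodes) == set(net.nodes)
        assert set(k[0] for k in out.edges) == \
            scan_edges(world.physical, net.nodes, 0.4)
        assert out.network_type == "physical"

    def test_round_trip_restores_edge_set(self, world, host_taxid,
                                          parasite_taxid):
        net = cross_species_query(host_taxid, parasite_taxid, world.full, 0.4)
        phys = set_type(net, "physical", world.full, world.physical)
        back = set_type(phys, "full", world.full, world.physical)
        assert set(back.edges) == set(net.edges)


class TestStringify:
    @pytest.fixture()
    def user_net(self, world):
        return apms_network(generate_apms_table(world.spec, n_baits=2,
                                                preys_per_bait=5))

    def test_counts_preserved_with_keep_unmapped(self, world, user_net,
                                                 host_taxid):
        out, report = stringify(user_net, "name", host_taxid, world.aliases)
        assert len(out.nodes) == len(user_net.nodes)
        assert len(out.edges) == len(user_net.edges)
        assert out.cutoff == 1.0
        assert validate(out) == []

    def test_bait_nodes_kept_as_is(self, world, user_net, host_taxid):
        out, report = stringify(user_net, "name", host_taxid, world.aliases)
        baits = [nid for nid in user_net.nodes if nid.startswith("VP")]
        for bait in baits:
            assert bait in out.nodes
            assert report["mapping"][bait] is None

    def test_prey_attributes_lifted(self, world, user_net, host_taxid):
        out, _ = stringify(user_net, "name", host_taxid, world.aliases)
        mapped = [n for nid, n in out.nodes.items()
                  if species_of(nid) == host_taxid]
        assert mapped, "preys must map to store proteins"
        for node in mapped:
            assert "Bait_ID" in node.attributes
            assert "query term" in node.attributes

    def test_all_edges_lifted_as_user_edges(self, world, user_net, host_taxid):
        out, _ = stringify(user_net, "name", host_taxid, world.aliases)
        assert all(e.interaction_type == "user" and e.source == "lifted"
                   for e in out.edges.values())

    def test_drop_unmapped_removes_baits_and_their_edges(self, world,
                                                         user_net, host_taxid):
        out, report = stringify(user_net, "name", host_taxid, world.aliases,
                                keep_unmapped=False)
        assert all(species_of(nid) == host_taxid for nid in out.nodes)
        assert len(out.edges) == 0   # bait-prey edges all touch a bait
        assert sorted(report["dropped"]) == \
            sorted(nid for nid in user_net.nodes if nid.startswith("VP"))

    def test_zero_mappable_network_is_isomorphic_copy(self, world, host_taxid):
        rows = [{"bait": "VPa", "prey": "unknown-1", "Bait_ID": "VPa"},
                {"bait": "VPa", "prey": "unknown-2", "Bait_ID": "VPa"}]
        user = apms_network(rows)
        out, _ = stringify(user, "name", host_taxid, world.aliases)
        assert set(out.nodes) == set(user.nodes)
        assert len(out.edges) == len(user.edges)
        assert out.cutoff == 1.0

    def test_lowering_cutoff_adds_store_edges(self, world, user_net,
                                              host_taxid):
        from assocnet.netops import set_confidence

        out, _ = stringify(user_net, "name", host_taxid, world.aliases)
        lowered = set_confidence(out, 0.4, world.full)
        lifted = {k for k, e in lowered.edges.items()
                  if e.interaction_type == "user"}
        store_edges = {k[0] for k in lowered.edges} - {k[0] for k in lifted}
        assert store_edges == scan_edges(world.full, out.nodes, 0.4)
        assert len(lifted) == len(user_net.edges)
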