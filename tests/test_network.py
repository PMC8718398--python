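"""Bipartite assembly, linkage-pattern extraction and projection."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aonproj import (
    SHARED_DRUG,
    BipartiteNetwork,
    DrugEventAssociation,
    EventType,
    KERLink,
    LinkagePattern,
    PatternCollection,
    build_bipartite,
    extract_patterns,
    project_monopartite,
)
from helpers import brute_force_shared_edges, toy_network

DRUGS = [f"d{i}" for i in range(8)]
EVENTS = list("abcdefghij")

assignments_strategy = st.dictionaries(
    keys=st.sampled_from(DRUGS),
    values=st.frozensets(st.sampled_from(EVENTS), min_size=1, max_size=6),
    min_size=1,
    max_size=8,
)


def _net(assignments) -> BipartiteNetwork:
    return toy_network(assignments)


class TestBuildBipartite:
    def test_fig2_gb1_counts(self, gb1):
        assert gb1.n_drugs == 2
        assert gb1.n_events == 3
        assert gb1.n_assoc_edges == 5

    def test_single_record(self):
        net = _net({"d1": "a"})
        assert (net.n_drugs, net.n_events, net.n_assoc_edges) == (1, 1, 1)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_bipartite([])

    def test_duplicate_pairs_collapse(self):
        rec = DrugEventAssociation("d1", "a", EventType.MIE)
        net = build_bipartite([rec, rec, DrugEventAssociation("d1", "b", EventType.KE)])
        assert net.n_assoc_edges == 2

    def test_idempotent_on_deduplicated_input(self, gb1):
        records = [
            DrugEventAssociation(d, e, gb1.events[e]) for d, e in sorted(gb1.assoc_edges)
        ]
        rebuilt = build_bipartite(records)
        assert rebuilt.drugs == gb1.drugs
        assert rebuilt.events == gb1.events
        assert rebuilt.assoc_edges == gb1.assoc_edges

    def test_ker_enrichment_adds_new_endpoint(self):
        records = [
            DrugEventAssociation("d1", "a", EventType.MIE),
            DrugEventAssociation("d1", "b", EventType.MIE),
        ]
        kers = [KERLink("b", "x"), KERLink("y", "z")]
        net = build_bipartite(records, kers)
        assert "x" in net.events and net.events["x"] is EventType.KE
        assert ("b", "x") in net.ker_edges
        # a KER touching no known event is ignored entirely
        assert "y" not in net.events and "z" not in net.events
        assert ("y", "z") not in net.ker_edges

    def test_ker_self_loop_rejected(self):
        with pytest.raises(ValueError):
            KERLink("a", "a")

    def test_validate_catches_unregistered_endpoint(self, gb1):
        gb1.assoc_edges.add(("ghost_drug", "A"))
        with pytest.raises(ValueError):
            gb1.validate()


class TestExtractPatterns:
    @pytest.mark.parametrize(
        "assignments, expected",
        [
            ({"d1": "abc", "d2": "ab"}, {frozenset("abc"): 1, frozenset("ab"): 1}),
            (
                {"d1": "ab", "d2": "ab", "d3": "abcde"},
                {frozenset("ab"): 2, frozenset("abcde"): 1},
            ),
            ({"d1": "a"}, {frozenset("a"): 1}),
        ],
    )
    def test_profiles(self, assignments, expected):
        pc = extract_patterns(_net(assignments))
        assert pc.as_mapping() == expected

    def test_no_association_edges_rejected(self):
        with pytest.raises(ValueError):
            extract_patterns(BipartiteNetwork())

    def test_duplicate_patterns_rejected_in_collection(self):
        p = LinkagePattern(frozenset("ab"), 1)
        with pytest.raises(ValueError):
            PatternCollection([p, LinkagePattern(frozenset("ab"), 2)])

    @given(assignments_strategy)
    def test_occurrences_sum_to_drug_count(self, assignments):
        pc = extract_patterns(_net(assignments))
        assert pc.total_occurrences == len(assignments)

    @given(assignments_strategy)
    def test_probabilities_sum_to_one(self, assignments):
        pc = extract_patterns(_net(assignments))
        assert abs(sum(pc.probability(p) for p in pc) - 1.0) < 1e-12


class TestProjection:
    def test_gb1_projects_to_triangle(self, gm1):
        assert set(gm1.edges) == {("A", "B"), ("A", "C"), ("B", "C")}
        assert all(e.provenance == SHARED_DRUG for e in gm1.edges.values())

    def test_gb2_projects_to_k5_with_shared_counts(self, gm2):
        assert gm2.n_edges == 10
        assert gm2.edges[("A", "B")].shared_drug_count == 3
        assert gm2.edges[("C", "D")].shared_drug_count == 1

    def test_no_sharing_gives_empty_network(self):
        mono = project_monopartite(_net({"d1": "a", "d2": "b"}))
        assert mono.n_events == 0 and mono.n_edges == 0

    def test_isolated_events_kept_on_request(self):
        mono = project_monopartite(_net({"d1": "a", "d2": "b"}), drop_isolated=False)
        assert set(mono.events) == {"a", "b"} and mono.n_edges == 0

    def test_ker_pair_becomes_ker_only_edge_unless_shared(self):
        records = [
            DrugEventAssociation("d1", "a", EventType.MIE),
            DrugEventAssociation("d1", "b", EventType.MIE),
            DrugEventAssociation("d2", "c", EventType.KE),
        ]
        net = build_bipartite(records, [KERLink("a", "b"), KERLink("b", "c")])
        mono = project_monopartite(net)
        assert mono.edges[("a", "b")].provenance == SHARED_DRUG
        assert mono.edges[("b", "c")].provenance == "ker_only"

    @given(assignments_strategy)
    def test_matches_bruteforce_shared_neighbor_oracle(self, assignments):
        net = _net(assignments)
        mono = project_monopartite(net)
        expected = brute_force_shared_edges(net)
        got = {e.key: e.shared_drug_count for e in mono.shared_drug_edges()}
        assert got == expected

    @given(assignments_strategy)
    def test_every_shared_edge_has_a_covering_pattern_and_conversely(self, assignments):
        net = _net(assignments)
        pc = extract_patterns(net)
        mono = project_monopartite(net)
        shared = {e.key for e in mono.shared_drug_edges()}
        for v, w in shared:
            assert pc.containing_pair(v, w), (v, w)
        from itertools import combinations

        for pattern in pc:
            for v, w in combinations(sorted(pattern.events), 2):
                assert (v, w) in shared

    @given(assignments_strategy)
    def test_projection_invariants_hold(self, assignments):
        mono = project_monopartite(_net(assignments))
        mono.validate()
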