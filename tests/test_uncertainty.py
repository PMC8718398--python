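"""Entropy scores: H_before, maximal cliques, H_after, delta-H."""

from __future__ import annotations

import math
import random

import pytest
from hypothesis import given
from hypothesis import strategies as st

from aonproj import (
    EventType,
    LinkagePattern,
    MonoEdge,
    MonopartiteNetwork,
    PatternCollection,
    h_after_network,
    h_after_node,
    h_before_network,
    h_before_node,
    maximal_cliques,
    project_monopartite,
    score_uncertainty,
    extract_patterns,
)
from aonproj.uncertainty import CliqueSet
from helpers import brute_force_maximal_cliques

LN2 = math.log(2.0)


def pc_from(profile: dict[str, int]) -> PatternCollection:
    return PatternCollection(
        LinkagePattern(frozenset(events), n) for events, n in profile.items()
    )


def path_network(*chain: str) -> MonopartiteNetwork:
    events = {e: EventType.MIE for e in chain}
    edges = {}
    for a, b in zip(chain, chain[1:]):
        a, b = sorted((a, b))
        edges[(a, b)] = MonoEdge(a, b, "shared_drug", 1)
    return MonopartiteNetwork(events=dict(sorted(events.items())),
                              edges=dict(sorted(edges.items())))


class TestHBefore:
    @pytest.mark.parametrize(
        "profile, expected",
        [
            ({"ABC": 1, "AB": 1}, math.log(2)),                      # two equiprobable patterns
            ({"AB": 2, "ABCDE": 1},
             -(2 / 3) * math.log(2 / 3) - (1 / 3) * math.log(1 / 3)),
            ({"AQRSTV": 5}, 0.0),                                    # single pattern
        ],
    )
    def test_network_entropy(self, profile, expected):
        assert h_before_network(pc_from(profile)) == pytest.approx(expected, abs=1e-12)

    def test_fig2_value_rounds_to_published_069(self, gb1_patterns):
        assert round(h_before_network(gb1_patterns), 2) == 0.69

    def test_node_entropy_is_partial_sum(self, gb1_patterns):
        # C sits only in ABC (p = 1/2)
        assert h_before_node(gb1_patterns, "C") == pytest.approx(
            -0.5 * math.log(0.5), abs=1e-12
        )
        assert round(h_before_node(gb1_patterns, "C"), 2) == 0.35

    def test_node_in_every_pattern_equals_network(self, gb1_patterns):
        assert h_before_node(gb1_patterns, "A") == pytest.approx(
            h_before_network(gb1_patterns), abs=1e-12
        )

    def test_node_entropy_gb2(self, gb2_patterns):
        assert h_before_node(gb2_patterns, "C") == pytest.approx(
            -(1 / 3) * math.log(1 / 3), abs=1e-12
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            h_before_network(PatternCollection([]))
        with pytest.raises(KeyError):
            h_before_node(pc_from({"AB": 1}), "Z")

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=8))
    def test_equal_occurrences_maximize_at_ln_k(self, occurrences):
        k = len(occurrences)
        uniform = pc_from({f"E{i}": 1 for i in range(k)})
        arbitrary = pc_from({f"E{i}": n for i, n in enumerate(occurrences)})
        assert h_before_network(uniform) == pytest.approx(math.log(k), abs=1e-12)
        assert h_before_network(arbitrary) <= math.log(k) + 1e-12


class TestMaximalCliques:
    def test_triangle_has_single_clique_of_8_subcliques(self, gm1):
        cs = maximal_cliques(gm1)
        assert cs.cliques == (frozenset("ABC"),)
        assert cs.subclique_counts == (8,)

    def test_path_splits_into_two_edges(self):
        cs = maximal_cliques(path_network("a", "b", "c"))
        assert set(cs.cliques) == {frozenset("ab"), frozenset("bc")}

    def test_isolated_node_forms_singleton_clique(self):
        mono = MonopartiteNetwork(events={"x": EventType.AO}, edges={})
        # isolated nodes only arise when drop_isolated is disabled upstream
        cs = maximal_cliques(mono, include_ker=True)
        assert cs.cliques == (frozenset("x"),)

    @pytest.mark.parametrize("n, p, seed", [(8, 0.4, 0), (10, 0.3, 1), (12, 0.35, 2)])
    def test_matches_exhaustive_enumeration(self, n, p, seed):
        rng = random.Random(seed)
        nodes = [f"n{i:02d}" for i in range(n)]
        edges = [
            (a, b)
            for i, a in enumerate(nodes)
            for b in nodes[i + 1:]
            if rng.random() < p
        ]
        mono = MonopartiteNetwork(
            events={v: EventType.KE for v in nodes},
            edges={(a, b): MonoEdge(a, b, "shared_drug", 1) for a, b in edges},
        )
        cs = maximal_cliques(mono, include_ker=True)
        assert set(cs.cliques) == brute_force_maximal_cliques(nodes, edges)

    def test_ker_edges_excluded_by_default(self):
        from aonproj import KERLink, build_bipartite, DrugEventAssociation

        records = [
            DrugEventAssociation("d1", "a", EventType.MIE),
            DrugEventAssociation("d1", "b", EventType.MIE),
        ]
        bip = build_bipartite(records, [KERLink("b", "x")])
        mono = project_monopartite(bip)
        assert maximal_cliques(mono).cliques == (frozenset("ab"),)
        with_ker = maximal_cliques(mono, include_ker=True)
        assert frozenset("bx") in with_ker.cliques


class TestHAfter:
    @pytest.mark.parametrize(
        "sizes, expected",
        [((3,), math.log(8)), ((2,), math.log(4)), ((5,), math.log(32)),
         ((2, 2), math.log(8)), ((3, 2), math.log(12))],
    )
    def test_network_value_is_log_total_subcliques(self, sizes, expected):
        cs = CliqueSet(
            cliques=tuple(
                frozenset(f"v{i}_{j}" for j in range(k)) for i, k in enumerate(sizes)
            )
        )
        assert h_after_network(cs) == pytest.approx(expected, abs=1e-12)

    def test_fig2_value_rounds_to_published_208(self, gm1):
        assert round(h_after_network(maximal_cliques(gm1)), 2) == 2.08

    def test_node_value_uses_largest_containing_clique(self, gm1):
        cs = maximal_cliques(gm1)
        assert h_after_node(cs, "C") == pytest.approx(3 * LN2, abs=1e-12)
        path = maximal_cliques(path_network("a", "b", "c"))
        assert h_after_node(path, "b") == pytest.approx(2 * LN2, abs=1e-12)

    def test_errors(self):
        with pytest.raises(ValueError):
            h_after_network(CliqueSet(cliques=()))
        with pytest.raises(KeyError):
            h_after_node(maximal_cliques(path_network("a", "b")), "z")

    @pytest.mark.parametrize("k", range(1, 13))
    def test_single_clique_closed_form(self, k):
        cs = CliqueSet(cliques=(frozenset(f"v{i}" for i in range(k)),))
        assert abs(h_after_network(cs) - k * LN2) < 1e-12


class TestDeltaH:
    def test_fig2_network_and_node_deltas(self, gb1, gb1_patterns, gm1):
        scores = score_uncertainty(gb1_patterns, gm1)
        assert round(scores.delta_h_network, 2) == 1.39
        assert round(scores.delta_h_node["C"], 2) == 1.73

    def test_gb2_network_delta(self, gb2_patterns, gm2):
        scores = score_uncertainty(gb2_patterns, gm2)
        expected = math.log(32) - (
            -(2 / 3) * math.log(2 / 3) - (1 / 3) * math.log(1 / 3)
        )
        assert scores.delta_h_network == pytest.approx(expected, abs=1e-12)

    def test_node_scores_bounded_by_network_scores(self):
        from aonproj import GeneratorConfig, generate_random_bipartite

        for seed in range(5):
            net = generate_random_bipartite(GeneratorConfig(n_drugs=25, seed=seed))
            pc = extract_patterns(net)
            mono = project_monopartite(net)
            scores = score_uncertainty(pc, mono)
            for event, hb in scores.h_before_node.items():
                assert hb <= scores.h_before_network + 1e-12
                assert scores.h_after_node[event] <= scores.h_after_network + 1e-12
                assert hb >= 0 and scores.h_after_node[event] >= 0
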