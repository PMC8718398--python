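"""Increase-in-uncertainty scoring of a monopartite projection.

The entropy of the drug-side linkage patterns (``H_before``) is compared
with the entropy of a uniform distribution over the subcliques of the
projected event network (``H_after``).  Each maximal clique of size ``|c|``
is taken to stand for ``2^|c|`` subcliques (the empty subset included —
this is the deliberate approximation the scoring is built on), every
subclique is equally likely, and so ``H_after = ln(sum_j 2^|c_j|)``.  The
difference ``ΔH = H_after − H_before`` (in nats) grows with the information
lost when linkage patterns are collapsed into cliques.

Node-level variants restrict ``H_before`` to the patterns containing the
node (a partial, non-renormalised entropy) and ``H_after`` to the largest
maximal clique containing the node.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx

from .network import MonopartiteNetwork, PatternCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CliqueSet",
    "UncertaintyScores",
    "maximal_cliques",
    "h_before_network",
    "h_before_node",
    "h_after_network",
    "h_after_node",
    "score_uncertainty",
]

_LN2 = math.log(2.0)


@dataclass(frozen=True)
class CliqueSet:
    """Maximal cliques of the event network and their subclique budget.

    ``total_subcliques = sum_j 2^|c_j|``; overlapping subcliques are counted
    once per maximal clique that contains them — an accepted overcount that
    keeps the quantity computable on large networks.
    """

    cliques: tuple[frozenset[str], ...]

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.cliques)

    @property
    def subclique_counts(self) -> tuple[int, ...]:
        return tuple(2 ** len(c) for c in self.cliques)

    @property
    def total_subcliques(self) -> int:
        return sum(self.subclique_counts)

    def __len__(self) -> int:
        return len(self.cliques)

    def containing(self, event_id: str) -> tuple[frozenset[str], ...]:
        return tuple(c for c in self.cliques if event_id in c)

    def largest_containing(self, event_id: str) -> frozenset[str]:
        """The biggest maximal clique holding ``event_id`` (ties: any, since
        only the size enters the scores)."""
        best: frozenset[str] | None = None
        for c in self.cliques:
            if event_id in c and (best is None or len(c) > len(best)):
                best = c
        if best is None:
            raise KeyError(f"event {event_id!r} is in no maximal clique")
        return best

    def nodes(self) -> set[str]:
        out: set[str] = set()
        for c in self.cliques:
            out |= c
        return out


def maximal_cliques(mono: MonopartiteNetwork, include_ker: bool = False) -> CliqueSet:
    """Enumerate all maximal cliques of the event network.

    By default adjacency is restricted to shared-drug edges, matching the
    drug-derived linkage patterns the entropy is compared against; pass
    ``include_ker=True`` to let KER-only edges count as adjacency too.
    Cliques are returned in a deterministic (size, lexicographic) order.
    Isolated nodes, when present, form size-1 maximal cliques.
    """
    if mono.n_events == 0:
        raise ValueError("cannot enumerate cliques of an empty network")
    g = mono.to_networkx(include_ker=include_ker)
    cliques = [frozenset(c) for c in nx.find_cliques(g)] if g.number_of_nodes() else []
    cliques.sort(key=lambda c: (len(c), tuple(sorted(c))))
    return CliqueSet(cliques=tuple(cliques))


def h_before_network(pc: PatternCollection) -> float:
    """Shannon entropy of the linkage-pattern distribution, in nats."""
    if len(pc) == 0:
        raise ValueError("no linkage patterns: H_before is undefined")
    total = 0.0
    for pattern in pc:
        p = pc.probability(pattern)
        total -= p * math.log(p)
    return total


def h_before_node(pc: PatternCollection, event_id: str) -> float:
    """Partial entropy over the patterns containing ``event_id``.

    Pattern probabilities stay normalised against *all* patterns, so this is
    a partial sum of the network entropy, not a renormalised conditional
    entropy.  It is therefore always <= ``h_before_network``.
    """
    relevant = pc.containing(event_id)
    if not relevant:
        raise KeyError(f"event {event_id!r} appears in no linkage pattern")
    total = 0.0
    for pattern in relevant:
        p = pc.probability(pattern)
        total -= p * math.log(p)
    return total


def h_after_network(cs: CliqueSet) -> float:
    """Entropy of the uniform distribution over all counted subcliques.

    With ``N = sum_j 2^|c_j|`` and ``p = 1/N`` this is exactly ``ln N``.
    """
    if len(cs) == 0:
        raise ValueError("no cliques: H_after is undefined")
    return math.log(cs.total_subcliques)


def h_after_node(cs: CliqueSet, event_id: str) -> float:
    """``ln 2^|c*|`` for the largest maximal clique ``c*`` holding the node."""
    best = cs.largest_containing(event_id)
    return len(best) * _LN2


@dataclass
class UncertaintyScores:
    """Network- and node-level H_before / H_after / ΔH, all in nats."""

    h_before_network: float
    h_after_network: float
    h_before_node: dict[str, float] = field(default_factory=dict)
    h_after_node: dict[str, float] = field(default_factory=dict)

    @property
    def delta_h_network(self) -> float:
        return self.h_after_network - self.h_before_network

    @property
    def delta_h_node(self) -> dict[str, float]:
        return {
            e: self.h_after_node[e] - self.h_before_node[e]
            for e in self.h_after_node
            if e in self.h_before_node
        }


def score_uncertainty(
    pc: PatternCollection,
    mono: MonopartiteNetwork,
    include_ker_cliques: bool = False,
) -> UncertaintyScores:
    """Full uncertainty scoring of one bipartite -> monopartite projection.

    Node-level maps cover the events of the monopartite network that both
    appear in a linkage pattern and sit in at least one clique; events held
    in the network only by KER edges carry no drug information and are
    excluded (logged).
    """
    cs = maximal_cliques(mono, include_ker=include_ker_cliques)
    clique_nodes = cs.nodes()
    pattern_events = pc.events()

    h_before_map: dict[str, float] = {}
    h_after_map: dict[str, float] = {}
    skipped: list[str] = []
    for event in sorted(mono.events):
        if event not in clique_nodes or event not in pattern_events:
            skipped.append(event)
            continue
        h_before_map[event] = h_before_node(pc, event)
        h_after_map[event] = h_after_node(cs, event)
    if skipped:
        logger.info(
            "%d events carry no drug-derived linkage information and were "
            "excluded from node-level uncertainty: %s",
            len(skipped), ", ".join(skipped[:5]),
        )

    return UncertaintyScores(
        h_before_network=h_before_network(pc),
        h_after_network=h_after_network(cs),
        h_before_node=h_before_map,
        h_after_node=h_after_map,
    )
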