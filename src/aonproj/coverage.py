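"""Loss-of-coverage scoring for projected event-event edges and nodes.

A monopartite edge (v, w) compresses every linkage pattern containing both
events into a single link.  Its coverage is the occurrence-weighted mean of
``2 / |I_i|`` over exactly those patterns:

    COV(v, w) = sum_i n_i * (2 / |I_i|) / sum_i n_i

so an edge covered only by size-2 patterns has coverage 1 (nothing lost),
while patterns spanning many events dilute it.  The loss of coverage is
``¬COV = 1 − COV``; a node's loss is the arithmetic mean of the losses of
its incident shared-drug edges.

A loss of exactly 0 can also arise when a size-2 pattern occurs for several
drugs — the multiplicity collapses into one edge, so the zero understates
the loss; such edges are flagged in the report rather than adjusted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .network import SHARED_DRUG, MonopartiteNetwork, PatternCollection

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageScores",
    "cov_edge",
    "neg_cov_edge",
    "neg_cov_node",
    "score_coverage",
]


def cov_edge(pc: PatternCollection, v: str, w: str) -> float:
    """Edge coverage in (0, 1] from the patterns containing both events.

    Raises
    ------
    KeyError
        If no linkage pattern contains both ``v`` and ``w`` (such a pair is
        not a scorable shared-drug edge).
    """
    covering = pc.containing_pair(v, w)
    if not covering:
        raise KeyError(f"no linkage pattern contains both {v!r} and {w!r}")
    num = sum(p.occurrence * (2.0 / p.size) for p in covering)
    den = sum(p.occurrence for p in covering)
    return num / den


def neg_cov_edge(pc: PatternCollection, v: str, w: str) -> float:
    """Loss of coverage ``1 − COV(v, w)`` in [0, 1)."""
    return 1.0 - cov_edge(pc, v, w)


@dataclass
class CoverageScores:
    """Per-edge coverage / loss and per-node mean loss.

    Edge keys are lexicographically ordered event-id pairs.  ``ker_only``
    edges have no covering pattern, hence no defined coverage; they are
    listed in ``unscored_ker_edges`` instead of being forced to 0 or 1.
    ``zero_loss_edges`` flags the degenerate exact-zero losses (all covering
    patterns of size 2) that understate the true loss when the pattern's
    linkage profile exceeds 1.
    """

    cov_edge: dict[tuple[str, str], float] = field(default_factory=dict)
    neg_cov_edge: dict[tuple[str, str], float] = field(default_factory=dict)
    neg_cov_node: dict[str, float] = field(default_factory=dict)
    unscored_ker_edges: tuple[tuple[str, str], ...] = ()
    zero_loss_edges: tuple[tuple[str, str], ...] = ()


def neg_cov_node(scores: CoverageScores, mono: MonopartiteNetwork, event_id: str) -> float:
    """Mean loss of coverage over the node's incident shared-drug edges.

    Raises
    ------
    KeyError
        If the node has no incident scored edge (e.g. it is held in the
        network only by KER edges).
    """
    losses = [
        scores.neg_cov_edge[e.key]
        for e in mono.incident_edges(event_id)
        if e.provenance == SHARED_DRUG
    ]
    if not losses:
        raise KeyError(f"event {event_id!r} has no incident shared-drug edge")
    return sum(losses) / len(losses)


def score_coverage(pc: PatternCollection, mono: MonopartiteNetwork) -> CoverageScores:
    """Score every shared-drug edge and every node of the projection.

    Nodes whose every incident edge is KER-only are excluded from the node
    map (logged), since no drug-derived pattern covers them.
    """
    scores = CoverageScores()
    zero_flagged: list[tuple[str, str]] = []
    for edge in mono.shared_drug_edges():
        c = cov_edge(pc, edge.a, edge.b)
        scores.cov_edge[edge.key] = c
        scores.neg_cov_edge[edge.key] = 1.0 - c
        if c == 1.0:
            zero_flagged.append(edge.key)
    scores.zero_loss_edges = tuple(zero_flagged)
    scores.unscored_ker_edges = tuple(e.key for e in mono.ker_only_edges())

    skipped: list[str] = []
    for event in sorted(mono.events):
        try:
            scores.neg_cov_node[event] = neg_cov_node(scores, mono, event)
        except KeyError:
            skipped.append(event)
    if skipped:
        logger.info(
            "%d events have only KER-mediated edges and were excluded from "
            "node-level coverage: %s", len(skipped), ", ".join(skipped[:5]),
        )
    return scores
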