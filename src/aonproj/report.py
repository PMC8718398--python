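"""Aggregate information-loss scores into network / subgroup summaries.

The summary table carries one row for the whole network and one per event
stratum (AO, KE, MIE).  Subgroup node means average only the nodes of that
stratum; subgroup edge means include every scored edge with at least one
endpoint in the stratum, so a cross-stratum edge contributes to both rows.
Network-level entropies are meaningless per stratum and are left empty
there.
"""

from __future__ import annotations

import math
from typing import Literal, Mapping

import pandas as pd

from .coverage import CoverageScores
from .network import EventType, MonopartiteNetwork
from .uncertainty import UncertaintyScores

__all__ = ["SUMMARY_COLUMNS", "summarize", "rank_nodes"]

SUMMARY_COLUMNS = (
    "h_before_network",
    "h_before_nodes_mean",
    "h_after_network",
    "h_after_nodes_mean",
    "delta_h_network",
    "delta_h_nodes_mean",
    "neg_cov_edge_mean",
    "neg_cov_node_mean",
)


def _mean(values: list[float]) -> float:
    return sum(values) / len(values) if values else math.nan


def summarize(
    uncertainty: UncertaintyScores,
    coverage: CoverageScores,
    mono: MonopartiteNetwork,
) -> pd.DataFrame:
    """Build the network/AO/KE/MIE summary of all information-loss scores.

    Empty subgroups yield NaN cells; every mean is reproducible from the
    per-node and per-edge score maps.
    """
    delta_node = uncertainty.delta_h_node
    rows: dict[str, dict[str, float]] = {}

    rows["Network"] = {
        "h_before_network": uncertainty.h_before_network,
        "h_before_nodes_mean": _mean(list(uncertainty.h_before_node.values())),
        "h_after_network": uncertainty.h_after_network,
        "h_after_nodes_mean": _mean(list(uncertainty.h_after_node.values())),
        "delta_h_network": uncertainty.delta_h_network,
        "delta_h_nodes_mean": _mean(list(delta_node.values())),
        "neg_cov_edge_mean": _mean(list(coverage.neg_cov_edge.values())),
        "neg_cov_node_mean": _mean(list(coverage.neg_cov_node.values())),
    }

    for etype in (EventType.AO, EventType.KE, EventType.MIE):
        members = {e for e, t in mono.events.items() if t is etype}
        edge_losses = [
            loss for (a, b), loss in coverage.neg_cov_edge.items()
            if a in members or b in members
        ]
        rows[etype.value] = {
            "h_before_network": math.nan,
            "h_before_nodes_mean": _mean(
                [v for e, v in uncertainty.h_before_node.items() if e in members]),
            "h_after_network": math.nan,
            "h_after_nodes_mean": _mean(
                [v for e, v in uncertainty.h_after_node.items() if e in members]),
            "delta_h_network": math.nan,
            "delta_h_nodes_mean": _mean(
                [v for e, v in delta_node.items() if e in members]),
            "neg_cov_edge_mean": _mean(edge_losses),
            "neg_cov_node_mean": _mean(
                [v for e, v in coverage.neg_cov_node.items() if e in members]),
        }

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(SUMMARY_COLUMNS))
    df.index.name = "scope"
    return df


def rank_nodes(
    scores: Mapping[str, float],
    descending: bool = True,
) -> list[tuple[str, float]]:
    """Order nodes by a per-node score, ties broken by event id.

    Works for any node-keyed score map (ΔH, ¬COV, ...); the output is a
    permutation of the input keys and is stable across reruns.
    """
    sign = -1.0 if descending else 1.0
    return sorted(scores.items(), key=lambda kv: (sign * kv[1], kv[0]))
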