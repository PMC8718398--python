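"""One-call pipeline: associations -> projection -> information-loss scores."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .coverage import CoverageScores, score_coverage
from .network import (
    BipartiteNetwork,
    DrugEventAssociation,
    KERLink,
    MonopartiteNetwork,
    PatternCollection,
    build_bipartite,
    extract_patterns,
    project_monopartite,
)
from .report import summarize
from .uncertainty import CliqueSet, UncertaintyScores, maximal_cliques, score_uncertainty

__all__ = ["ProjectionAnalysis", "analyze"]


@dataclass
class ProjectionAnalysis:
    """Every artifact of one bipartite -> monopartite analysis run."""

    bipartite: BipartiteNetwork
    patterns: PatternCollection
    monopartite: MonopartiteNetwork
    cliques: CliqueSet
    uncertainty: UncertaintyScores
    coverage: CoverageScores
    summary: pd.DataFrame


def analyze(
    associations: Sequence[DrugEventAssociation],
    kers: Sequence[KERLink] = (),
    include_ker_cliques: bool = False,
    drop_isolated: bool = True,
) -> ProjectionAnalysis:
    """Run the full pipeline on in-memory association / KER records.

    Builds the bipartite network (with KER enrichment), extracts linkage
    patterns, projects to the event-event network, and computes uncertainty
    and coverage scores plus the subgroup summary table.
    """
    bip = build_bipartite(associations, kers)
    pc = extract_patterns(bip)
    mono = project_monopartite(bip, drop_isolated=drop_isolated)
    cs = maximal_cliques(mono, include_ker=include_ker_cliques)
    unc = score_uncertainty(pc, mono, include_ker_cliques=include_ker_cliques)
    cov = score_coverage(pc, mono)
    summary = summarize(unc, cov, mono)
    return ProjectionAnalysis(
        bipartite=bip,
        patterns=pc,
        monopartite=mono,
        cliques=cs,
        uncertainty=unc,
        coverage=cov,
        summary=summary,
    )
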