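"""Readers and writers for association tables, Cytoscape files and reports.

Input tables are UTF-8 TSV/CSV with a header row; lines starting with ``#``
are skipped.  Identifiers are matched exactly after trimming whitespace and
case-folding, so ``" MIE:1181 "`` and ``"mie:1181"`` are the same event.
Malformed rows are collected (not silently dropped) and returned alongside
the parsed records.

Network exports target Cytoscape: SIF for the bare topology and GraphML for
full attribute fidelity (a GraphML written here reads back into an
identical :class:`~aonproj.network.MonopartiteNetwork`).  All writers emit
nodes and edges in lexicographic order, so output is byte-stable for a
fixed input.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import pandas as pd

from .coverage import CoverageScores
from .network import (
    KER_ONLY,
    SHARED_DRUG,
    BipartiteNetwork,
    DrugEventAssociation,
    EventType,
    KERLink,
    MonoEdge,
    MonopartiteNetwork,
)
from .pipeline import ProjectionAnalysis
from .uncertainty import UncertaintyScores

logger = logging.getLogger(__name__)

__all__ = [
    "RowError",
    "read_association_table",
    "read_ker_table",
    "write_association_table",
    "write_ker_table",
    "write_sif",
    "write_monopartite_graphml",
    "read_monopartite_graphml",
    "write_bipartite_graphml",
    "read_bipartite_graphml",
    "ExportBundle",
    "write_score_tables",
]

REQUIRED_ASSOC_COLUMNS = ("drug_id", "event_id", "event_type")
OPTIONAL_ASSOC_COLUMNS = ("drug_name", "cas", "source")
REQUIRED_KER_COLUMNS = ("upstream_event_id", "downstream_event_id")


@dataclass(frozen=True)
class RowError:
    """One rejected input row and the reason it was rejected."""

    line: int
    message: str


def _norm_id(value: str) -> str:
    return str(value).strip().casefold()


def _read_table(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    import csv as _csv

    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep=None, engine="python", comment="#", dtype=str,
            skip_blank_lines=True, encoding="utf-8",
        )
    except (pd.errors.EmptyDataError, _csv.Error):
        raise ValueError(f"{path}: file is empty or not a delimited table") from None
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    return df


def read_association_table(
    path: str | Path,
) -> tuple[list[DrugEventAssociation], list[RowError]]:
    """Parse a drug-event association table.

    Returns the validated records plus a list of row-level errors (unknown
    event types, blank identifiers).  Missing required columns or an empty
    file raise immediately.
    """
    df = _read_table(path, REQUIRED_ASSOC_COLUMNS)
    records: list[DrugEventAssociation] = []
    errors: list[RowError] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        drug = _norm_id(data.get("drug_id") or "")
        event = _norm_id(data.get("event_id") or "")
        if not drug or drug == "nan" or not event or event == "nan":
            errors.append(RowError(idx, "blank drug_id or event_id"))
            continue
        try:
            etype = EventType.parse(data.get("event_type") or "")
        except ValueError as exc:
            errors.append(RowError(idx, str(exc)))
            continue
        cas = data.get("cas")
        records.append(
            DrugEventAssociation(
                drug_id=drug,
                event_id=event,
                event_type=etype,
                drug_name=str(data.get("drug_name") or "").strip(),
                cas=None if cas is None or str(cas) == "nan" else str(cas).strip(),
                source=str(data.get("source") or "").strip(),
            )
        )
    for err in errors:
        logger.warning("%s line %d: %s", path, err.line, err.message)
    return records, errors


def read_ker_table(path: str | Path) -> tuple[list[KERLink], list[RowError]]:
    """Parse a key-event-relationship table (upstream, downstream[, aop])."""
    df = _read_table(path, REQUIRED_KER_COLUMNS)
    links: list[KERLink] = []
    errors: list[RowError] = []
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        data = dict(zip(df.columns, row))
        up = _norm_id(data.get("upstream_event_id") or "")
        down = _norm_id(data.get("downstream_event_id") or "")
        if not up or up == "nan" or not down or down == "nan":
            errors.append(RowError(idx, "blank upstream or downstream event id"))
            continue
        if up == down:
            errors.append(RowError(idx, f"KER self-loop on {up!r}"))
            continue
        aop = data.get("aop_id")
        links.append(
            KERLink(
                upstream_event_id=up,
                downstream_event_id=down,
                aop_id=None if aop is None or str(aop) == "nan" else str(aop).strip(),
            )
        )
    for err in errors:
        logger.warning("%s line %d: %s", path, err.line, err.message)
    return links, errors


def write_association_table(
    records: Sequence[DrugEventAssociation], path: str | Path
) -> None:
    """Write association records as the standard ingestion TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(REQUIRED_ASSOC_COLUMNS) + list(OPTIONAL_ASSOC_COLUMNS))
        for r in sorted(records, key=lambda r: (r.drug_id, r.event_id)):
            writer.writerow(
                [r.drug_id, r.event_id, r.event_type.value,
                 r.drug_name, r.cas or "", r.source]
            )


def write_ker_table(links: Sequence[KERLink], path: str | Path) -> None:
    """Write KER links as the standard ingestion TSV."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(list(REQUIRED_KER_COLUMNS) + ["aop_id"])
        for k in sorted(links, key=lambda k: (k.upstream_event_id, k.downstream_event_id)):
            writer.writerow([k.upstream_event_id, k.downstream_event_id, k.aop_id or ""])


def write_sif(mono: MonopartiteNetwork, path: str | Path) -> None:
    """Write the event network as Cytoscape SIF, one edge per line.

    The relation column is ``shared_drug`` or ``ker``; line count equals the
    edge count.
    """
    path = Path(path)
    lines = []
    for _, e in sorted(mono.edges.items()):
        relation = "ker" if e.provenance == KER_ONLY else SHARED_DRUG
        lines.append(f"{e.a}\t{relation}\t{e.b}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_monopartite_graphml(
    mono: MonopartiteNetwork,
    path: str | Path,
    uncertainty: UncertaintyScores | None = None,
    coverage: CoverageScores | None = None,
) -> None:
    """Write the event network as GraphML, optionally with score attributes.

    Scores are attached as double-typed node attributes (``h_before``,
    ``h_after``, ``delta_h``, ``neg_cov_node``) and edge attributes
    (``cov_edge``, ``neg_cov_edge``) wherever defined.
    """
    g = mono.to_networkx(include_ker=True)
    if uncertainty is not None:
        delta = uncertainty.delta_h_node
        for node in g.nodes:
            if node in uncertainty.h_before_node:
                g.nodes[node]["h_before"] = float(uncertainty.h_before_node[node])
                g.nodes[node]["h_after"] = float(uncertainty.h_after_node[node])
                g.nodes[node]["delta_h"] = float(delta[node])
    if coverage is not None:
        for node in g.nodes:
            if node in coverage.neg_cov_node:
                g.nodes[node]["neg_cov_node"] = float(coverage.neg_cov_node[node])
        for key, value in coverage.cov_edge.items():
            if g.has_edge(*key):
                g.edges[key]["cov_edge"] = float(value)
                g.edges[key]["neg_cov_edge"] = float(coverage.neg_cov_edge[key])
    nx.write_graphml(g, str(path), named_key_ids=True, edge_id_from_attribute=None)


def read_monopartite_graphml(path: str | Path) -> MonopartiteNetwork:
    """Reconstruct a monopartite network from a GraphML written here."""
    g = nx.read_graphml(str(path))
    events = {
        str(n): EventType.parse(data["event_type"]) for n, data in g.nodes(data=True)
    }
    edges: dict[tuple[str, str], MonoEdge] = {}
    for u, v, data in g.edges(data=True):
        a, b = sorted((str(u), str(v)))
        edges[(a, b)] = MonoEdge(
            a, b,
            provenance=str(data.get("provenance", SHARED_DRUG)),
            shared_drug_count=int(data.get("shared_drug_count", 0)),
        )
    return MonopartiteNetwork(events=dict(sorted(events.items())),
                              edges=dict(sorted(edges.items())))


def write_bipartite_graphml(net: BipartiteNetwork, path: str | Path) -> None:
    """Write the drug-event network as GraphML (``node_class`` drug/event,
    ``edge_class`` association/ker)."""
    nx.write_graphml(net.to_networkx(), str(path), named_key_ids=True)


def read_bipartite_graphml(path: str | Path) -> BipartiteNetwork:
    """Reconstruct a bipartite network from a GraphML written here."""
    g = nx.read_graphml(str(path))
    net = BipartiteNetwork()
    for n, data in g.nodes(data=True):
        n = str(n)
        if data.get("node_class") == "drug":
            net.drugs.add(n)
        else:
            net.events[n] = EventType.parse(data["event_type"])
    for u, v, data in g.edges(data=True):
        u, v = str(u), str(v)
        if data.get("edge_class") == "ker":
            net.ker_edges.add((u, v))
        else:
            net.assoc_edges.add((u, v))
    net.validate()
    return net


@dataclass(frozen=True)
class ExportBundle:
    """Paths of one complete export (networks, score tables, JSON report)."""

    sif: Path
    monopartite_graphml: Path
    bipartite_graphml: Path
    uncertainty_nodes: Path
    coverage_nodes: Path
    edges: Path
    summary: Path
    report: Path


def _round(value: float, ndigits: int | None) -> float:
    return value if ndigits is None else round(value, ndigits)


def write_score_tables(
    analysis: ProjectionAnalysis,
    outdir: str | Path,
    rounding: int | None = 2,
) -> ExportBundle:
    """Write all artifacts of an analysis run into ``outdir``.

    Tables are rounded to ``rounding`` decimals (None = full precision);
    the JSON report always carries full float precision.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unc, cov, mono = analysis.uncertainty, analysis.coverage, analysis.monopartite
    delta = unc.delta_h_node

    bundle = ExportBundle(
        sif=outdir / "monopartite.sif",
        monopartite_graphml=outdir / "monopartite.graphml",
        bipartite_graphml=outdir / "bipartite.graphml",
        uncertainty_nodes=outdir / "uncertainty_nodes.tsv",
        coverage_nodes=outdir / "coverage_nodes.tsv",
        edges=outdir / "edges.tsv",
        summary=outdir / "summary.tsv",
        report=outdir / "report.json",
    )

    write_sif(mono, bundle.sif)
    write_monopartite_graphml(mono, bundle.monopartite_graphml, unc, cov)
    write_bipartite_graphml(analysis.bipartite, bundle.bipartite_graphml)

    with bundle.uncertainty_nodes.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_id", "event_type", "h_before", "h_after", "delta_h"])
        for event in sorted(unc.h_before_node):
            w.writerow([
                event, mono.events[event].value,
                _round(unc.h_before_node[event], rounding),
                _round(unc.h_after_node[event], rounding),
                _round(delta[event], rounding),
            ])

    with bundle.coverage_nodes.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_id", "event_type", "neg_cov_node"])
        for event in sorted(cov.neg_cov_node):
            w.writerow([event, mono.events[event].value,
                        _round(cov.neg_cov_node[event], rounding)])

    with bundle.edges.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["event_a", "event_b", "provenance", "shared_drug_count",
                    "cov_edge", "neg_cov_edge"])
        for key, e in sorted(mono.edges.items()):
            if key in cov.cov_edge:
                covv = _round(cov.cov_edge[key], rounding)
                negv = _round(cov.neg_cov_edge[key], rounding)
            else:  # ker_only: coverage undefined, not forced to 0 or 1
                covv = negv = ""
            w.writerow([e.a, e.b, e.provenance, e.shared_drug_count, covv, negv])

    summary = analysis.summary if rounding is None else analysis.summary.round(rounding)
    summary.to_csv(bundle.summary, sep="\t", na_rep="")

    report = {
        "network": {
            "n_drugs": analysis.bipartite.n_drugs,
            "n_events_bipartite": analysis.bipartite.n_events,
            "n_assoc_edges": analysis.bipartite.n_assoc_edges,
            "n_events_monopartite": mono.n_events,
            "n_edges_monopartite": mono.n_edges,
            "n_maximal_cliques": len(analysis.cliques),
            "total_subcliques": analysis.cliques.total_subcliques,
        },
        "uncertainty": {
            "h_before_network": unc.h_before_network,
            "h_after_network": unc.h_after_network,
            "delta_h_network": unc.delta_h_network,
        },
        "coverage": {
            "mean_neg_cov_edge": (
                sum(cov.neg_cov_edge.values()) / len(cov.neg_cov_edge)
                if cov.neg_cov_edge else None
            ),
            "mean_neg_cov_node": (
                sum(cov.neg_cov_node.values()) / len(cov.neg_cov_node)
                if cov.neg_cov_node else None
            ),
            "zero_loss_edges": sorted(map(list, cov.zero_loss_edges)),
            "unscored_ker_edges": sorted(map(list, cov.unscored_ker_edges)),
        },
    }
    bundle.report.write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return bundle
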