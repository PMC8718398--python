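"""Core graph types for mapping stressors (drugs) into AOP event space.

An adverse outcome pathway (AOP) chains biological events — a molecular
initiating event (MIE), intermediate key events (KE) and an adverse outcome
(AO) — linked by key event relationships (KER).  Drugs associated with those
events form a bipartite graph; projecting it onto the event side ("guilt by
association": two events are linked whenever at least one drug hits both)
yields an event-event monopartite network whose information loss the
:mod:`aonproj.uncertainty` and :mod:`aonproj.coverage` modules quantify.

This module holds the domain types and the three structural operations:
:func:`build_bipartite`, :func:`extract_patterns` and
:func:`project_monopartite`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from itertools import combinations
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "EventType",
    "DrugEventAssociation",
    "KERLink",
    "BipartiteNetwork",
    "LinkagePattern",
    "PatternCollection",
    "MonoEdge",
    "MonopartiteNetwork",
    "SHARED_DRUG",
    "KER_ONLY",
    "build_bipartite",
    "extract_patterns",
    "project_monopartite",
]

#: provenance tag for monopartite edges created by a shared drug
SHARED_DRUG = "shared_drug"
#: provenance tag for monopartite edges present only as a curated KER
KER_ONLY = "ker_only"


class EventType(str, Enum):
    """Stratum of a biological event inside an adverse outcome pathway."""

    MIE = "MIE"
    KE = "KE"
    AO = "AO"

    @classmethod
    def parse(cls, value: str) -> "EventType":
        """Parse a raw string (any case, surrounding whitespace) into a type.

        Raises
        ------
        ValueError
            If the trimmed, upper-cased value is not MIE, KE or AO.
        """
        key = str(value).strip().upper()
        try:
            return cls[key]
        except KeyError:
            raise ValueError(f"unknown event_type {value!r}; expected MIE, KE or AO") from None


@dataclass(frozen=True)
class DrugEventAssociation:
    """One curated drug -> event association with its provenance."""

    drug_id: str
    event_id: str
    event_type: EventType
    drug_name: str = ""
    cas: Optional[str] = None
    source: str = ""


@dataclass(frozen=True)
class KERLink:
    """A directed key event relationship (upstream causes downstream)."""

    upstream_event_id: str
    downstream_event_id: str
    aop_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.upstream_event_id == self.downstream_event_id:
            raise ValueError(f"KER self-loop on {self.upstream_event_id!r}")


@dataclass
class BipartiteNetwork:
    """Drug and event nodes joined by association edges, plus KER edges.

    ``assoc_edges`` always connect a drug to an event; ``ker_edges`` always
    connect two events (directed upstream -> downstream).
    """

    drugs: set[str] = field(default_factory=set)
    events: dict[str, EventType] = field(default_factory=dict)
    assoc_edges: set[tuple[str, str]] = field(default_factory=set)
    ker_edges: set[tuple[str, str]] = field(default_factory=set)

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_assoc_edges(self) -> int:
        return len(self.assoc_edges)

    def event_counts(self) -> dict[EventType, int]:
        """Number of events per stratum (MIE / KE / AO)."""
        out = {t: 0 for t in EventType}
        for t in self.events.values():
            out[t] += 1
        return out

    def drug_neighborhoods(self) -> dict[str, frozenset[str]]:
        """Event set of every drug that carries at least one association."""
        nb: dict[str, set[str]] = {}
        for drug, event in self.assoc_edges:
            nb.setdefault(drug, set()).add(event)
        return {d: frozenset(s) for d, s in nb.items()}

    def validate(self) -> None:
        """Check endpoint registration and the bipartite edge-class rules."""
        for drug, event in self.assoc_edges:
            if drug not in self.drugs:
                raise ValueError(f"association references unregistered drug {drug!r}")
            if event not in self.events:
                raise ValueError(f"association references unregistered event {event!r}")
        for up, down in self.ker_edges:
            if up not in self.events or down not in self.events:
                raise ValueError(f"KER edge ({up!r}, {down!r}) has an unregistered endpoint")
            if up == down:
                raise ValueError(f"KER self-loop on {up!r}")
        overlap = self.drugs & set(self.events)
        if overlap:
            raise ValueError(f"identifiers used both as drug and event: {sorted(overlap)[:5]}")

    def to_networkx(self) -> nx.DiGraph:
        """Directed graph view: drug->event association edges, KER edges.

        Nodes carry ``node_class`` ("drug"/"event") and events an
        ``event_type`` attribute; edges carry ``edge_class``
        ("association"/"ker").  Insertion is lexicographic so downstream
        serialisation is byte-stable.
        """
        g = nx.DiGraph()
        for drug in sorted(self.drugs):
            g.add_node(drug, node_class="drug")
        for event in sorted(self.events):
            g.add_node(event, node_class="event", event_type=self.events[event].value)
        for drug, event in sorted(self.assoc_edges):
            g.add_edge(drug, event, edge_class="association")
        for up, down in sorted(self.ker_edges):
            g.add_edge(up, down, edge_class="ker")
        return g


@dataclass(frozen=True)
class LinkagePattern:
    """The event set of one drug neighbourhood and how often it occurs.

    ``events`` is the pattern itself (the set of events a drug is associated
    with); ``occurrence`` is its linkage profile — the number of drugs whose
    neighbourhood equals exactly this set.
    """

    events: frozenset[str]
    occurrence: int

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("a linkage pattern must contain at least one event")
        if self.occurrence < 1:
            raise ValueError("linkage profile (occurrence) must be >= 1")

    @property
    def size(self) -> int:
        return len(self.events)

    def contains(self, event_id: str) -> bool:
        return event_id in self.events

    def contains_pair(self, v: str, w: str) -> bool:
        return v in self.events and w in self.events


class PatternCollection:
    """All distinct linkage patterns of a bipartite network.

    Pattern probabilities are occurrence-weighted:
    ``p(I_i) = n_i / sum_j n_j``.
    """

    def __init__(self, patterns: Iterable[LinkagePattern]):
        pats = sorted(patterns, key=lambda p: (p.size, tuple(sorted(p.events))))
        seen: set[frozenset[str]] = set()
        for p in pats:
            if p.events in seen:
                raise ValueError(f"duplicate linkage pattern {sorted(p.events)}")
            seen.add(p.events)
        self._patterns: tuple[LinkagePattern, ...] = tuple(pats)
        self.total_occurrences: int = sum(p.occurrence for p in pats)

    def __len__(self) -> int:
        return len(self._patterns)

    def __iter__(self) -> Iterator[LinkagePattern]:
        return iter(self._patterns)

    @property
    def patterns(self) -> tuple[LinkagePattern, ...]:
        return self._patterns

    def probability(self, pattern: LinkagePattern) -> float:
        return pattern.occurrence / self.total_occurrences

    def containing(self, event_id: str) -> tuple[LinkagePattern, ...]:
        """Patterns whose event set includes ``event_id``."""
        return tuple(p for p in self._patterns if p.contains(event_id))

    def containing_pair(self, v: str, w: str) -> tuple[LinkagePattern, ...]:
        """Patterns whose event set includes both ``v`` and ``w``."""
        return tuple(p for p in self._patterns if p.contains_pair(v, w))

    def events(self) -> set[str]:
        out: set[str] = set()
        for p in self._patterns:
            out |= p.events
        return out

    def as_mapping(self) -> dict[frozenset[str], int]:
        return {p.events: p.occurrence for p in self._patterns}


@dataclass(frozen=True)
class MonoEdge:
    """An undirected event-event edge of the monopartite network.

    ``provenance`` is ``shared_drug`` when at least one drug is associated
    with both endpoints (``shared_drug_count`` counts those drugs) and
    ``ker_only`` when the pair exists only as a curated KER.
    """

    a: str
    b: str
    provenance: str
    shared_drug_count: int = 0

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError(f"self-loop on {self.a!r}")
        if self.a > self.b:
            raise ValueError("MonoEdge endpoints must be lexicographically ordered")
        if self.provenance == SHARED_DRUG and self.shared_drug_count < 1:
            raise ValueError("shared_drug edge requires shared_drug_count >= 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.a, self.b)


def _edge_key(v: str, w: str) -> tuple[str, str]:
    return (v, w) if v <= w else (w, v)


@dataclass
class MonopartiteNetwork:
    """Undirected event-event network obtained by projection."""

    events: dict[str, EventType] = field(default_factory=dict)
    edges: dict[tuple[str, str], MonoEdge] = field(default_factory=dict)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def shared_drug_edges(self) -> list[MonoEdge]:
        return [e for _, e in sorted(self.edges.items()) if e.provenance == SHARED_DRUG]

    def ker_only_edges(self) -> list[MonoEdge]:
        return [e for _, e in sorted(self.edges.items()) if e.provenance == KER_ONLY]

    def incident_edges(self, event_id: str) -> list[MonoEdge]:
        return [e for _, e in sorted(self.edges.items()) if event_id in (e.a, e.b)]

    def validate(self) -> None:
        for key, e in self.edges.items():
            if key != e.key:
                raise ValueError(f"edge stored under wrong key {key}")
            if e.a not in self.events or e.b not in self.events:
                raise ValueError(f"edge ({e.a!r}, {e.b!r}) has an unregistered endpoint")
        degree: Counter[str] = Counter()
        for e in self.edges.values():
            degree[e.a] += 1
            degree[e.b] += 1
        isolated = set(self.events) - set(degree)
        if isolated:
            raise ValueError(f"isolated events present: {sorted(isolated)[:5]}")

    def to_networkx(self, include_ker: bool = True) -> nx.Graph:
        """Undirected view with typed node/edge attributes.

        ``include_ker=False`` restricts to shared-drug edges and drops nodes
        whose every incident edge is KER-only.
        """
        g = nx.Graph()
        edges = [e for _, e in sorted(self.edges.items())
                 if include_ker or e.provenance == SHARED_DRUG]
        if include_ker:
            keep = set(self.events)
        else:
            # shared-drug view: keep shared-edge endpoints plus truly
            # isolated events (size-1 cliques); drop KER-only-attached nodes
            keep = {n for e in edges for n in (e.a, e.b)}
            attached = {n for e in self.edges.values() for n in (e.a, e.b)}
            keep |= set(self.events) - attached
        for event in sorted(keep):
            g.add_node(event, event_type=self.events[event].value)
        for e in edges:
            g.add_edge(e.a, e.b, provenance=e.provenance,
                       shared_drug_count=e.shared_drug_count)
        return g


def build_bipartite(
    associations: Sequence[DrugEventAssociation],
    kers: Sequence[KERLink] = (),
) -> BipartiteNetwork:
    """Assemble the drug-event bipartite network, with KER enrichment.

    Duplicate ``(drug_id, event_id)`` pairs are collapsed (the collapse is
    logged).  A KER is kept only when at least one of its endpoints already
    occurs among the association events; its other endpoint is then added to
    the event set, typed KE when the association table never typed it.  KERs
    touching no known event are ignored.

    Raises
    ------
    ValueError
        If ``associations`` is empty.
    """
    if not associations:
        raise ValueError("cannot build a bipartite network from an empty association list")

    net = BipartiteNetwork()
    n_dupes = 0
    for rec in associations:
        pair = (rec.drug_id, rec.event_id)
        if pair in net.assoc_edges:
            n_dupes += 1
            continue
        known = net.events.get(rec.event_id)
        if known is not None and known is not rec.event_type:
            logger.warning(
                "event %s seen with types %s and %s; keeping %s",
                rec.event_id, known.value, rec.event_type.value, known.value,
            )
        else:
            net.events[rec.event_id] = known or rec.event_type
        net.drugs.add(rec.drug_id)
        net.assoc_edges.add(pair)
    if n_dupes:
        logger.info("collapsed %d duplicate drug-event pairs", n_dupes)

    assoc_events = set(net.events)
    n_skipped = 0
    for ker in kers:
        up, down = ker.upstream_event_id, ker.downstream_event_id
        if up not in assoc_events and down not in assoc_events:
            n_skipped += 1
            continue
        # enrichment: the unseen endpoint joins the event set as a KE
        for endpoint in (up, down):
            if endpoint not in net.events:
                net.events[endpoint] = EventType.KE
        net.ker_edges.add((up, down))
    if n_skipped:
        logger.info("ignored %d KERs with no endpoint in the association events", n_skipped)

    net.validate()
    return net


def extract_patterns(net: BipartiteNetwork) -> PatternCollection:
    """Group drugs by identical event neighbourhoods into linkage patterns.

    KER edges play no role here: a pattern is purely the set of events a drug
    is associated with, and its occurrence (linkage profile) is the number of
    drugs sharing exactly that set.

    Raises
    ------
    ValueError
        If the network carries no association edge.
    """
    neighborhoods = net.drug_neighborhoods()
    if not neighborhoods:
        raise ValueError("network has no association edges; no linkage patterns exist")
    counts: Counter[frozenset[str]] = Counter(neighborhoods.values())
    return PatternCollection(
        LinkagePattern(events=events, occurrence=n) for events, n in counts.items()
    )


def project_monopartite(
    net: BipartiteNetwork,
    drop_isolated: bool = True,
) -> MonopartiteNetwork:
    """Project the bipartite network onto its event side.

    Guilt by association: events ``v`` and ``w`` are joined by a
    ``shared_drug`` edge iff at least one drug is associated with both, with
    ``shared_drug_count`` the number of such drugs.  Each KER pair not
    already linked that way becomes a ``ker_only`` edge.  With
    ``drop_isolated`` (the default) events left without any incident edge
    are removed from the result, mirroring how single-drug leaf events fall
    out of the projected network.
    """
    shared: Counter[tuple[str, str]] = Counter()
    for events in net.drug_neighborhoods().values():
        for v, w in combinations(sorted(events), 2):
            shared[(v, w)] += 1

    edges: dict[tuple[str, str], MonoEdge] = {}
    for (v, w), count in shared.items():
        edges[(v, w)] = MonoEdge(v, w, SHARED_DRUG, shared_drug_count=count)
    for up, down in net.ker_edges:
        key = _edge_key(up, down)
        if key not in edges:
            edges[key] = MonoEdge(key[0], key[1], KER_ONLY, shared_drug_count=0)

    connected: set[str] = set()
    for v, w in edges:
        connected.add(v)
        connected.add(w)
    if drop_isolated:
        kept = {e: t for e, t in net.events.items() if e in connected}
        n_dropped = len(net.events) - len(kept)
        if n_dropped:
            logger.info("dropped %d isolated events during projection", n_dropped)
    else:
        kept = dict(net.events)

    mono = MonopartiteNetwork(
        events=dict(sorted(kept.items())),
        edges=dict(sorted(edges.items())),
    )
    if drop_isolated:
        mono.validate()
    return mono
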