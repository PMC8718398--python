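"""Independent oracles and small builders shared by the test modules.

Everything here is deliberately naive — literal re-summation, exhaustive
subset enumeration — so it can serve as an independent check on the
package's implementations.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterable, Mapping, Sequence

from aonproj import BipartiteNetwork, DrugEventAssociation, EventType, build_bipartite


def toy_network(assignments: Mapping[str, Iterable[str]],
                types: Mapping[str, EventType] | None = None) -> BipartiteNetwork:
    """Build a bipartite network from {drug: iterable-of-event-ids}."""
    records = [
        DrugEventAssociation(drug_id=d, event_id=e,
                             event_type=(types or {}).get(e, EventType.MIE))
        for d, events in assignments.items()
        for e in events
    ]
    return build_bipartite(records)


def brute_force_shared_edges(net: BipartiteNetwork) -> dict[tuple[str, str], int]:
    """All-pairs shared-neighbour check: (v, w) -> number of common drugs."""
    adj: dict[str, set[str]] = {e: set() for e in net.events}
    for drug, event in net.assoc_edges:
        adj[event].add(drug)
    out: dict[tuple[str, str], int] = {}
    for v, w in combinations(sorted(net.events), 2):
        n = len(adj[v] & adj[w])
        if n:
            out[(v, w)] = n
    return out


def brute_force_maximal_cliques(
    nodes: Sequence[str], edges: Iterable[tuple[str, str]]
) -> set[frozenset[str]]:
    """Exhaustive-subset maximal-clique enumeration (small graphs only)."""
    adjacency: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)

    def is_clique(subset: tuple[str, ...]) -> bool:
        return all(b in adjacency[a] for a, b in combinations(subset, 2))

    cliques: set[frozenset[str]] = set()
    node_list = sorted(nodes)
    for k in range(1, len(node_list) + 1):
        for subset in combinations(node_list, k):
            if is_clique(subset):
                cliques.add(frozenset(subset))
    maximal = set()
    for c in cliques:
        extendable = any(
            c | {n} in cliques for n in node_list if n not in c
        )
        if not extendable:
            maximal.add(c)
    return maximal


def literal_cov_edge(neighborhoods: Iterable[frozenset[str]], v: str, w: str) -> float:
    """Coverage of (v, w) recomputed from raw drug neighbourhoods."""
    profile = Counter(neighborhoods)
    num = den = 0.0
    for events, n in profile.items():
        if v in events and w in events:
            num += n * (2.0 / len(events))
            den += n
    if den == 0:
        raise KeyError((v, w))
    return num / den
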