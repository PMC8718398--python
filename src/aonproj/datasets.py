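"""Built-in toy networks and a seeded random bipartite-network generator.

The two toy networks are the canonical worked examples for the scoring
method: a pair of drugs sharing events A, B (and one also hitting C), and a
three-drug variant where the pattern AB occurs twice while a third drug
spans five events.  Both project onto cliques and every score on them can
be checked by hand.

The generator emulates the structure of curated drug-event tables: many
drugs, three event strata (MIE/KE/AO in roughly the 66:44:6 proportion seen
in compiled AOP resources), a heavy-tailed distribution of neighbourhood
sizes dominated by single-event drugs, some drugs repeating another drug's
exact event set (linkage profiles > 1), and sparse KER links between
events.  It makes no attempt to fit a real degree sequence — the
neighbourhood-size distribution is the knob that drives information loss.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .network import (
    BipartiteNetwork,
    DrugEventAssociation,
    EventType,
    KERLink,
    build_bipartite,
)

__all__ = [
    "make_fig2_gb1",
    "make_fig2_gb2",
    "GeneratorConfig",
    "generate_association_records",
    "generate_random_bipartite",
]

_TOY_TYPE = EventType.MIE  # the worked examples never distinguish strata


def _toy(assignments: Mapping[str, Sequence[str]],
         types: Mapping[str, EventType] | None = None) -> BipartiteNetwork:
    records = [
        DrugEventAssociation(
            drug_id=drug,
            event_id=event,
            event_type=(types or {}).get(event, _TOY_TYPE),
            source="toy",
        )
        for drug, events in assignments.items()
        for event in events
    ]
    return build_bipartite(records)


def make_fig2_gb1(types: Mapping[str, EventType] | None = None) -> BipartiteNetwork:
    """Toy network 1: drug1 -> {A, B, C}, drug2 -> {A, B}.

    Its linkage patterns are ABC (profile 1) and AB (profile 1); the
    projection is the triangle A-B-C.  ``types`` optionally overrides the
    default all-MIE event typing, e.g. to exercise subgroup summaries.
    """
    return _toy({"drug1": "ABC", "drug2": "AB"}, types)


def make_fig2_gb2(types: Mapping[str, EventType] | None = None) -> BipartiteNetwork:
    """Toy network 2: drugs 1 and 2 -> {A, B}, drug3 -> {A, B, C, D, E}.

    Pattern AB has linkage profile 2; ABCDE has profile 1.  The projection
    is the complete graph on the five events.
    """
    return _toy({"drug1": "AB", "drug2": "AB", "drug3": "ABCDE"}, types)


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the random drug-event network generator.

    ``pattern_size_probs`` maps neighbourhood size -> probability (must sum
    to 1); ``duplicate_profile_rate`` is the fraction of drugs copying an
    earlier drug's event set verbatim; ``ker_rate`` is the expected number
    of KER links per event.  The seed fully determines the output.
    """

    n_drugs: int = 60
    n_mie: int = 33
    n_ke: int = 22
    n_ao: int = 3
    pattern_size_probs: Mapping[int, float] = field(
        default_factory=lambda: {
            1: 0.45, 2: 0.20, 3: 0.12, 4: 0.08, 5: 0.06, 6: 0.04, 7: 0.03, 8: 0.02,
        }
    )
    duplicate_profile_rate: float = 0.15
    ker_rate: float = 0.15
    seed: int = 0

    @property
    def n_events(self) -> int:
        return self.n_mie + self.n_ke + self.n_ao

    def validate(self) -> None:
        if min(self.n_drugs, self.n_mie, self.n_ke, self.n_ao) < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.duplicate_profile_rate <= 1.0:
            raise ValueError("duplicate_profile_rate must lie in [0, 1]")
        if self.ker_rate < 0:
            raise ValueError("ker_rate must be non-negative")
        probs = dict(self.pattern_size_probs)
        if not probs or any(s < 1 for s in probs) or any(p < 0 for p in probs.values()):
            raise ValueError("pattern_size_probs needs sizes >= 1 and probabilities >= 0")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("pattern_size_probs must sum to 1")
        if max(probs) > self.n_events:
            raise ValueError(
                f"requested pattern size {max(probs)} exceeds the "
                f"{self.n_events} available events"
            )

    def with_uniform_sizes(self, max_size: int) -> "GeneratorConfig":
        """Same config but neighbourhood sizes uniform on {1, ..., max_size}."""
        if max_size < 1:
            raise ValueError("max_size must be >= 1")
        probs = {s: 1.0 / max_size for s in range(1, max_size + 1)}
        return replace(self, pattern_size_probs=probs)

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from YAML or JSON; keys mirror the field names."""
        path = Path(path)
        text = path.read_text(encoding="utf-8")
        raw = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: expected a mapping of generator parameters")
        if "pattern_size_probs" in raw:
            raw["pattern_size_probs"] = {
                int(k): float(v) for k, v in raw["pattern_size_probs"].items()
            }
        cfg = cls(**raw)
        cfg.validate()
        return cfg


def _event_ids(config: GeneratorConfig) -> dict[str, EventType]:
    events: dict[str, EventType] = {}
    for prefix, etype, count in (
        ("mie", EventType.MIE, config.n_mie),
        ("ke", EventType.KE, config.n_ke),
        ("ao", EventType.AO, config.n_ao),
    ):
        for i in range(count):
            events[f"{prefix}_{i + 1:03d}"] = etype
    return events


def generate_association_records(
    config: GeneratorConfig,
) -> tuple[list[DrugEventAssociation], list[KERLink]]:
    """Sample association and KER records under ``config``.

    Each non-duplicate drug draws a neighbourhood size from the configured
    distribution and samples that many distinct events uniformly; duplicate
    drugs copy a uniformly chosen earlier drug's event set.  KER links are
    Poisson in number (mean ``ker_rate * n_events``) over distinct ordered
    event pairs.  A single RNG stream seeded from ``config.seed`` makes the
    output reproducible byte for byte.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    events = _event_ids(config)
    event_list = sorted(events)
    sizes = sorted(config.pattern_size_probs)
    size_p = np.array([config.pattern_size_probs[s] for s in sizes], dtype=float)
    size_p = size_p / size_p.sum()

    neighborhoods: list[tuple[str, ...]] = []
    records: list[DrugEventAssociation] = []
    for i in range(config.n_drugs):
        drug = f"drug_{i + 1:04d}"
        if neighborhoods and rng.random() < config.duplicate_profile_rate:
            chosen = neighborhoods[rng.integers(len(neighborhoods))]
        else:
            k = int(rng.choice(sizes, p=size_p))
            chosen = tuple(sorted(rng.choice(event_list, size=k, replace=False)))
        neighborhoods.append(chosen)
        for event in chosen:
            records.append(
                DrugEventAssociation(
                    drug_id=drug,
                    event_id=event,
                    event_type=events[event],
                    source="simulated",
                )
            )

    kers: list[KERLink] = []
    if config.ker_rate > 0 and config.n_events >= 2:
        n_ker = int(rng.poisson(config.ker_rate * config.n_events))
        seen: set[tuple[str, str]] = set()
        for _ in range(n_ker):
            up, down = (event_list[j] for j in rng.choice(config.n_events, size=2, replace=False))
            if (up, down) in seen or (down, up) in seen:
                continue
            seen.add((up, down))
            kers.append(KERLink(upstream_event_id=up, downstream_event_id=down))
    return records, kers


def generate_random_bipartite(config: GeneratorConfig) -> BipartiteNetwork:
    """Sample records under ``config`` and assemble the bipartite network.

    Drugs without associations cannot occur (every drug draws size >= 1),
    but a zero-drug config yields an empty network rather than an error.
    """
    records, kers = generate_association_records(config)
    if not records:
        return BipartiteNetwork()
    return build_bipartite(records, kers)
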