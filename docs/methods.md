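# Methods

## The problem

Adverse outcome pathways (AOPs) describe toxicity as a causal chain of
biological events: a molecular initiating event (MIE), intermediate key
events (KE), and an adverse outcome (AO), linked by key event relationships
(KER). Because pathways share events, the curated AOP space is a network.
Associating stressors — here, drugs — to those events gives a bipartite
graph, and the natural way to study event–event structure in the drug
exposome is to project that graph onto its event side: two events become
linked whenever at least one drug is associated with both ("guilt by
association").

The projection is lossy. A drug associated with *k* events (its *linkage
pattern*, with a *linkage profile* counting how many drugs share exactly
that event set) collapses into a clique of `k(k-1)/2` undifferentiated
pairwise edges, and several patterns can collapse onto the same edge. This
package implements the projection together with two scores that quantify
the loss, so that edges of the projected network can be ranked by how much
drug-level evidence actually supports them.

## Increase in uncertainty (ΔH, nats)

Before projection, the linkage patterns `I_i` with profiles `n_i` define a
distribution `p(I_i) = n_i / Σ_j n_j`, and

    H_before = − Σ_i p(I_i) · ln p(I_i)

is its Shannon entropy. After projection the pattern identities are gone;
what remains is the clique structure. Each maximal clique of size `|c|` is
taken to stand for `2^|c|` subcliques — deliberately including the empty
subset, and deliberately counting a subclique once per maximal clique that
contains it. Both are approximations that keep the quantity computable on
large networks, and both are part of the method's definition: a lone
triangle counts 8 subcliques, not 7 and not the 4 distinct non-empty
cliques one could enumerate by hand. With `N = Σ_j 2^|c_j|` and a uniform
distribution over the counted subcliques,

    H_after = ln N,        ΔH = H_after − H_before.

Node-level variants: `H_before(v)` sums only the terms of patterns
containing `v`, with probabilities still normalised against **all**
patterns — a partial sum, not a renormalised conditional entropy, so it is
bounded by the network value. `H_after(v) = |c*| · ln 2` where `c*` is the
largest maximal clique containing `v` (ties are harmless; only the size
enters). All logarithms are natural; units are nats.

Maximal cliques are enumerated with the pivoting Bron–Kerbosch algorithm
(networkx `find_cliques`); the test suite pins its output to exhaustive
subset enumeration on small graphs. By default cliques are computed on the
shared-drug edge subgraph only, because the entropy is compared against
drug-derived patterns; `include_ker_cliques=True` widens adjacency to
KER-only edges. Isolated nodes, when retained, count as size-1 cliques
(`2^1 = 2` subcliques: the node and the empty set).

## Loss of coverage (¬COV)

For a projected edge `(v, w)`, let `L_vw` be the patterns containing both
endpoints. Each such pattern of size `|I_i|` devotes 2 of its `|I_i|`
events to this pair, so

    COV(v, w) = Σ_{i ∈ L_vw} n_i · (2 / |I_i|)  /  Σ_{i ∈ L_vw} n_i,
    ¬COV(v, w) = 1 − COV(v, w).

An edge covered only by size-2 patterns has `COV = 1` exactly; large
patterns dilute coverage toward 0. A node's loss is the unweighted mean of
`¬COV` over its incident shared-drug edges.

Two deliberate reporting choices:

* **KER-only edges are not scored.** No pattern covers them, so the
  formula's denominator is empty; forcing 0 or 1 would fabricate a value.
  They are listed separately in the JSON report, and nodes attached to the
  network only by KER edges are excluded from node-level scores (logged).
* **Degenerate zeros are flagged, not corrected.** When a size-2 pattern
  has profile > 1, its multiplicity collapses into one edge and
  `¬COV = 0` understates the loss. The report lists these edges under
  `zero_loss_edges`.

## Network assembly choices

* Duplicate `(drug, event)` pairs are collapsed silently (count logged);
  identifiers are matched exactly after trimming and case-folding at
  ingestion time.
* KER enrichment: a KER is kept iff at least one endpoint already appears
  among the association events; the other endpoint is then added as an
  event node. KERs carry no stratum information, so an endpoint never seen
  in the association table is typed KE — the conservative middle stratum
  and the one enrichment overwhelmingly adds in curated AOP data.
* If the association table types the same event inconsistently, the first
  seen type wins and a warning is logged.
* Events left with no incident edge after projection are removed by
  default (`drop_isolated=False` keeps them, e.g. to study singleton
  cliques). Removal happens *after* pattern extraction, so size-1 patterns
  still contribute to `H_before`.
* In the projected network an edge is `shared_drug` (with the count of
  common drugs) whenever at least one drug covers the pair, even if a KER
  links the pair too; `ker_only` otherwise. All entropy and coverage
  scoring uses shared-drug information only, since the scores are defined
  on drug-mediated patterns.
* Node ordering is lexicographic everywhere, making every export
  byte-stable for a fixed input.

## Subgroup summary

The summary table has one row for the network and one per stratum (AO, KE,
MIE). Node means average the nodes of that stratum. Edge means include
every scored edge with **at least one** endpoint in the stratum, so a
cross-stratum edge contributes to two rows; requiring both endpoints would
leave a small stratum (AO typically has a handful of events) nearly
edge-less. Means are unweighted; empty strata yield empty cells.

## Synthetic data generator

`GeneratorConfig` emulates the shape of curated drug–event tables without
fitting any real degree sequence:

| parameter | default | meaning |
|---|---|---|
| `n_drugs` | 60 | drugs |
| `n_mie / n_ke / n_ao` | 33 / 22 / 3 | events per stratum, roughly the 66:44:6 proportion of compiled AOP resources at half scale |
| `pattern_size_probs` | {1: .45, 2: .20, 3: .12, 4: .08, 5: .06, 6: .04, 7: .03, 8: .02} | drug neighbourhood-size distribution; mostly single-event drugs with a tail to 8, matching the curated picture where ~40% of drugs carry one association and the best-studied drug a dozen |
| `duplicate_profile_rate` | 0.15 | fraction of drugs copying an earlier drug's exact event set, creating linkage profiles > 1 |
| `ker_rate` | 0.15 | expected KER links per event (Poisson total, uniform distinct pairs) |
| `seed` | 0 | single RNG stream; fully determines the output |

Non-duplicate drugs draw a size then sample that many distinct events
uniformly. What the generator does **not** emulate: hub structure (real
MIEs like nuclear-receptor activations accumulate a hundred-plus drugs),
correlated event co-membership within an AOP, and literature-driven
sampling bias. Tests passing on generated data therefore validate the
algebra and the algorithms, not calibration against any real curated
network. The neighbourhood-size distribution is the one knob that drives
information loss: on 20 seeds per setting, mean network ΔH rises
monotonically as the maximum size grows from 2 to 8 (the suite asserts
this trend on averages, not per instance).

## Numerical notes

* `H_after` is computed as `ln(Σ 2^|c|)` on exact integers, so the single
  `k`-clique closed form `k·ln 2` holds to 1e-12 for `k` up to at least 12.
* Pattern probabilities are exact rationals evaluated in double precision;
  coverage sums are short and need no compensated summation.
* Human-readable tables round to 2 decimals (configurable); GraphML and
  the JSON report keep full precision.
* Degenerate inputs: an empty association list, a pattern-free network,
  entropy of an empty collection and coverage of an uncovered pair all
  raise informative errors rather than returning sentinels.

## Problem sizes used in the checks

The worked-example checks run on the built-in toy networks (2–3 drugs,
3–5 events). Oracle equivalence uses 100 generated networks with ≤ 10
drugs and 10 events plus dense random graphs up to 15 nodes for clique
enumeration; the coverage oracle uses 30 networks of 12 drugs; the
size-drives-loss trend uses 40 drugs × 56 events × 20 seeds per setting.
These sizes keep every check exhaustive or statistically stable while the
whole suite runs in seconds.

## Known limitations

* Counts such as "102 events / 515 edges" for the published curated
  network can only be reproduced from its supplementary association and
  KER tables, which are third-party data not redistributed here; the
  corresponding check looks for them under `data/sm2/`.
* The subclique count `2^|c|` double-counts overlaps between maximal
  cliques and includes the empty set; ΔH values are therefore comparable
  within a network but are upper-bound-flavoured approximations, not exact
  clique counts.
* Name-matching is exact (after normalisation); no CAS or synonym
  resolution is attempted.
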