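# Methods

## Model

A drug's pharmacodynamic footprint is modeled as the stationary
distribution of a random walk with restart (RWR) on the protein–protein
interaction (PPI) network. With *W* the row-stochastic degree-normalized
adjacency (entry (i, j) = 1/deg(i) on edges), the iteration

    p(t+1) = (1 − r) Wᵀ p(t) + r p(0)

is run from p(0) equal to the drug's target indicator vector until the L1
difference of successive iterates drops below the tolerance. Because *Wᵀ*
is column-stochastic, the entry sum of p(t) is invariant, so in the default
"unit" seeding (weight 1 per target) a profile's mass equals its target
count. The fixed point, p = r (I − (1 − r) Wᵀ)⁻¹ p(0), exists and is unique
for any r > 0; a dense solve of this system is kept as an exact test oracle
and is never used in production.

Two drugs are scored by the overlap of their profiles: per protein,
ProteinScoreᵢ = vᵢ(A)·vᵢ(B); per pair, DDIScore = Σᵢ ProteinScoreᵢ — the
inner product of the profiles. The score is symmetric, nonnegative, and
bounded by Cauchy–Schwarz: DDIScore(A,B) ≤ ‖v(A)‖·‖v(B)‖.

The comparator is the shortest-path average (SPA): S(p,q) = 1 at identity,
A·e^(−D(p,q)) otherwise with D the unweighted hop distance, and
SPA(A,B) the mean of S over the Cartesian product of the target sets.

## Parameters

| parameter | default | meaning |
|---|---|---|
| restart probability r | 0.7 | teleport-to-seed chance per step; larger keeps influence local. With r = 0.7 the residual contracts by ≈0.3 per iteration, so the walk converges in a few dozen steps. |
| L1 tolerance | 1·10⁻⁵ | stopping rule on successive iterates (absolute, full-vector). |
| max iterations | 10,000 | safety cap only; exhaustion sets an explicit truncation flag, never silent. |
| seeding mode | unit | 1 per target. The alternative `normalized` (1/\|T\|) differs only by the scalar \|T\|, leaving per-drug rankings unchanged but rescaling DDIScore by \|T(A)\|·\|T(B)\|. Unit seeding lets multi-target drugs carry proportionally more influence mass, which is the intended reading. |
| SPA amplitude A | 0.9·e | chosen so S = 0.9 at distance 1; S strictly decreases in distance and SPA stays in [0, 1]. Exposed as a constant because the alternative reading (A = 0.9, S(1) = 0.9/e) exists; rankings, and hence AUC, are unaffected since both are monotone in D. |
| unreachable target pairs | S = 0 | the D → ∞ limit, keeping SPA continuous on disconnected networks. |
| enrichment cut | n = ⌈fraction·N⌉ | deterministic after sorting by (−score, pair key). |
| empirical p-value | (1 + #{null ≥ x}) / (1 + R) | add-one permutation estimator; smallest attainable p is 1/(R+1), so the 10⁻⁴ significance threshold requires R ≥ 10⁴ and the API refuses unattainable α instead of returning an empty list. |

## Normalization and ordering conventions

- The network is loaded as a binary undirected graph; confidence columns
  may filter rows at ingest but never weight the walk.
- Self-loops are dropped by default (interaction screens report them as
  artifacts and they distort degree normalization).
- Node order is lexicographic over protein identifiers, fixed at load, so
  every vector, matrix, and output file is byte-reproducible across runs
  and platforms.
- Ranked pair output sorts by descending score with lexicographic
  tie-break, making top-fraction cuts well-defined.
- AUC is the Mann–Whitney rank statistic with midranks for ties; the
  threshold-swept ROC curve integrates to the same value (asserted in
  tests to 10⁻¹²).
- Gold-standard labeling: a known interaction is pharmacodynamic iff the
  drugs share a target or some single pathway contains a target of each.
  Pairs with unannotated drugs are skipped and counted.
- Single/multi stratification assigns a pair to "multi" if either drug is
  multi-target and "single" only when both are — exhaustive and disjoint.
  For general category labels (e.g. ATC letters) a pair belongs to every
  category both drugs share.

## Synthetic benchmarks

The generator stands in for a curated interactome, drug–target catalog,
and pathway collection. Defaults define the study conditions used
throughout the tests and the acceptance script:

- **Network**: 500-node preferential-attachment graph (m = 2), largest
  component; heavy-tailed degrees mimic real interactomes.
- **Drugs**: 40, with 1–4 targets each; with probability 0.8 each extra
  target is drawn from the 2-hop ball around the drug's anchor target,
  since real drug targets cluster in complexes and pathways.
- **Pathways**: 10 BFS balls of radius 2 around random centers, truncated
  to 40 closest members — pathway membership correlates with network
  proximity, as in curated collections, and no single pathway swallows a
  large share of the graph (a hub-centered untruncated ball can cover half
  of a 500-node network, which no real pathway does, and makes the
  cross-talk planting condition infeasible on some seeds).
- **Planted positives**: 60 pairs, by default in `cross_talk` mode:
  disjoint targets, no shared pathway, but minimum cross-target distance
  ≤ 2 hops. `shared_target` and `shared_pathway` modes plant pairs
  satisfying the respective gold-standard clause by construction.

Everything is reproducible from (config, seed); stage sub-seeds derive
from the bundle seed.

What the generator does **not** emulate: identifier namespaces and mapping
noise, confidence-scored edges, the size and degree distribution of a
12,000-protein interactome, drug chemistry, or pathway overlap structure
beyond proximity. Passing tests therefore demonstrate correctness of the
algorithms and the claimed orderings under controlled conditions, not
database-scale performance figures.

A deliberate property of cross-talk benchmarks: pairs that *do* share a
target are negatives there by construction, yet both scorers rank them at
the very top. This depresses top-5% fold enrichment toward 1 for both
methods while leaving AUC informative — the AUC comparison, not the
enrichment magnitude, is the benchmark's point.

## Problem sizes

Unit and property tests run on graphs of 2–300 nodes; solver–oracle
equivalence uses 20 random connected graphs up to 200 nodes at tolerance
10⁻¹⁰ against the dense solve. The end-to-end ordering check and the
acceptance script use ten 500-node bundles; permutation machinery is
exercised at 10⁴ replicates in tests and 10⁵ in the acceptance script.

## Known limitations

- Interaction polarity (synergistic / antagonistic / additive) is not
  classified; the score measures interference potential only.
- Pharmacokinetic interactions are out of scope by construction.
- No identifier mapping: all inputs must share one protein namespace.
- Edge confidences are filter-only; a weighted walk is not implemented.
- Truncated (non-converged) profiles are returned flagged rather than
  refused; downstream consumers should check the flag (the CLI offers
  `--strict`).
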