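# ddiwalk

Pharmacodynamic drug–drug interaction (PD DDI) prediction by signal
propagation on protein–protein interaction (PPI) networks.

A PD DDI arises when one drug interferes with another drug's mechanism of
action: at a shared target, within a shared pathway, or — the case most
methods miss — through cross-talking pathways far from either drug's
targets. `ddiwalk` models the signaling initiated at a drug's targets as a
random walk with restart (RWR) over the PPI network and scores a drug pair
by how much their propagated influence overlaps, anywhere on the network.

## The model

Let *W* be the row-stochastic (degree-normalized) adjacency of the PPI
network and *p*(0) the seed vector with 1 on each target protein of a drug.
The walk

&nbsp;&nbsp;&nbsp;&nbsp;*p*(t+1) = (1 − r) *Wᵀ p*(t) + r *p*(0)

is iterated (restart probability r = 0.7) until the L1 difference of
successive iterates falls below 1·10⁻⁵; the stationary entry *vᵢ*(Drug) is
the influence of the drug on protein *i*. For a drug pair,

&nbsp;&nbsp;&nbsp;&nbsp;ProteinScoreᵢ(A, B) = *vᵢ*(A) · *vᵢ*(B),&nbsp;&nbsp;&nbsp;&nbsp;DDIScore(A, B) = Σᵢ ProteinScoreᵢ(A, B),

i.e. the inner product of the two influence profiles. High DDIScore pairs
are PD-interaction candidates. The package also implements the classic
shortest-path-average (SPA) comparator, SPA(A,B) = mean over target pairs
of S(p,q) with S = 1 at identity and A·e^(−D(p,q)) otherwise (A = 0.9e), and
an evaluation battery: gold-standard labeling (drugs interact
pharmacodynamically iff they share a target or have targets in a common
pathway), ROC/AUC, top-fraction fold enrichment, side-effect Jaccard
similarity, and permutation-based empirical p-values for interaction scores
and the proteins driving them.

Everything runs on plain text inputs (edge-list TSV, drug-target TSV, GMT
pathways) and a built-in synthetic benchmark generator, so no database
downloads are needed to develop or test.

## Worked example

```python
from ddiwalk import (BundleConfig, generate_bundle, row_normalize,
                     propagate_all_drugs, score_pairs, spa_score_pairs, roc_auc)

bundle = generate_bundle(BundleConfig(seed=0))          # 500 proteins, 40 drugs,
                                                        # 60 planted cross-talk pairs
profiles = propagate_all_drugs(bundle.targets, row_normalize(bundle.network))
rwr = score_pairs(profiles)                             # 780 ranked pairs
spa = spa_score_pairs(bundle.targets, bundle.network)
print(f"RWR AUC = {roc_auc(rwr, bundle.gold).auc:.3f}")
print(f"SPA AUC = {roc_auc(spa, bundle.gold).auc:.3f}")
print(rwr[0])
```

prints

```
RWR AUC = 0.811
SPA AUC = 0.765
ScoredPair(drug_a='D06', drug_b='D17', score=1.1088773478943927, method='rwr')
```

The planted positives have disjoint targets in different pathways joined
only by short network paths — exactly the "distant interference" regime.
Propagation ranks them above matched negatives better than the
shortest-path baseline does (AUC 0.81 vs 0.77 here), because the walk
integrates every path between the two target neighbourhoods rather than
just the single shortest one. The top-ranked pair's score is the summed
per-protein overlap of the two influence profiles.

The same workflow is available from the shell:

```bash
ddiwalk simulate --seed 0 --out-dir bench/
ddiwalk propagate --network bench/edges.tsv --targets bench/targets.tsv --out-dir bench/profiles/
ddiwalk score --method both --profiles-dir bench/profiles/ \
    --network bench/edges.tsv --targets bench/targets.tsv --out bench/scores.tsv
ddiwalk evaluate --scores bench/scores.tsv --gold bench/gold.tsv --out-prefix bench/report
```

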