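"""Shortest-path-average (SPA) baseline for drug-pair similarity.

The comparator of Gottlieb et al.: target-target proximity is summarised
by a decaying function of unweighted shortest-path distance,

    S(p, q) = 1                    if p == q
            = A * exp(-D(p, q))    otherwise,

with A = 0.9e so that S equals 0.9 at distance 1, and a drug pair is
scored by the mean of S over the Cartesian product of the two target sets:

    SPA(A, B) = sum_{a in T(A)} sum_{b in T(B)} S(a, b) / (|T(A)| |T(B)|).

Target pairs in different connected components contribute S = 0 (the
D -> infinity limit). SPA sees only how close targets are; it is blind to
the multiplicity of paths and to influence converging beyond the shortest
route, which is exactly what the random-walk score captures.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence

import networkx as nx

from .network import DrugTargetMap, PPINetwork
from .scoring import ScoredPair

__all__ = ["SPA_A", "shortest_lengths_from", "pair_similarity", "spa_score", "spa_score_pairs"]

#: Decay amplitude: 0.9e, so similarity at distance 1 is exactly 0.9.
SPA_A = 0.9 * math.e

#: source protein -> {reachable protein -> hop count}
DistanceMap = Mapping[str, Mapping[str, int]]


def shortest_lengths_from(sources: Iterable[str], network: PPINetwork) -> dict[str, dict[str, int]]:
    """Unweighted BFS hop counts from each source to all reachable nodes.

    Unreachable targets are simply absent from a source's inner mapping.
    """
    g = network.to_networkx()
    out = {}
    for src in sorted(set(sources)):
        if src not in network:
            raise KeyError(f"source {src!r} is not a network node")
        out[src] = dict(nx.single_source_shortest_path_length(g, src))
    return out


def pair_similarity(p: str, q: str, distances: DistanceMap, A: float = SPA_A) -> float:
    """Decayed-distance similarity S(p, q); 0 when p and q are disconnected."""
    if p == q:
        return 1.0
    d = None
    if p in distances:
        d = distances[p].get(q)
    if d is None and q in distances:
        d = distances[q].get(p)
    if d is None:
        return 0.0
    return A * math.exp(-d)


def spa_score(
    drug_a: str,
    drug_b: str,
    targets: DrugTargetMap,
    network: PPINetwork,
    A: float = SPA_A,
    distances: DistanceMap | None = None,
) -> float:
    """Mean target-target similarity over the two drugs' target sets."""
    ta = targets.get(drug_a)
    tb = targets.get(drug_b)
    if not ta or not tb:
        missing = [d for d, t in ((drug_a, ta), (drug_b, tb)) if not t]
        raise ValueError(f"drugs without in-network targets: {missing}")
    if distances is None:
        distances = shortest_lengths_from(ta, network)
    total = 0.0
    # fixed summation order keeps scores bit-identical across interpreter runs
    for p in sorted(ta):
        for q in sorted(tb):
            total += pair_similarity(p, q, distances, A)
    return total / (len(ta) * len(tb))


def spa_score_pairs(
    targets: DrugTargetMap,
    network: PPINetwork,
    pairs: Sequence[tuple[str, str]] | None = None,
    A: float = SPA_A,
    sort: bool = True,
) -> list[ScoredPair]:
    """Score drug pairs by SPA, sharing one BFS per distinct target protein.

    Mirrors :func:`ddiwalk.scoring.score_pairs`: all unordered pairs when
    ``pairs`` is omitted, deterministic descending sort with lexicographic
    tie-break.
    """
    drugs = sorted(targets)
    if pairs is None:
        pairs = [(drugs[i], drugs[j]) for i in range(len(drugs)) for j in range(i + 1, len(drugs))]
    else:
        missing = sorted({d for p in pairs for d in p if d not in targets})
        if missing:
            raise KeyError(f"pairs reference drugs without targets: {missing}")
    all_targets = set()
    for a, b in pairs:
        all_targets |= targets[a]
    distances = shortest_lengths_from(all_targets, network)
    out = [
        ScoredPair(a, b, spa_score(a, b, targets, network, A, distances), "spa")
        for a, b in pairs
    ]
    if sort:
        out.sort(key=lambda sp: (-sp.score, sp.drug_a, sp.drug_b))
    return out
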