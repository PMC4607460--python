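"""Pairwise interaction scores from overlapping influence profiles.

For two drugs with influence profiles v(A) and v(B) on the same network,
the per-protein overlap is the elementwise product

    ProteinScore_i(A, B) = v_i(A) * v_i(B)

and the pair's interaction score is its sum over all proteins,

    DDIScore(A, B) = sum_i ProteinScore_i(A, B),

i.e. the inner product of the two profiles. A high DDIScore means the two
drugs' signaling, propagated from their respective target sets, lands on
the same proteins — the mechanism by which one drug can interfere with
another's action even when their targets are distinct and distant.
"""

from __future__ import annotations

from collections.abc import Mapping, Sequence
from dataclasses import dataclass

import numpy as np

from .propagation import PropagationProfile

__all__ = ["ScoredPair", "protein_scores", "ddi_score", "score_pairs"]


@dataclass(frozen=True)
class ScoredPair:
    """An unordered drug pair with its interaction score.

    ``drug_a``/``drug_b`` are stored in lexicographic order so the pair key
    is canonical; ``method`` tags the scorer ("rwr" or "spa").
    """

    drug_a: str
    drug_b: str
    score: float
    method: str = "rwr"

    def __post_init__(self):
        a, b = self.drug_a, self.drug_b
        if a > b:
            object.__setattr__(self, "drug_a", b)
            object.__setattr__(self, "drug_b", a)

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)


def protein_scores(profile_a: PropagationProfile, profile_b: PropagationProfile) -> np.ndarray:
    """Per-protein overlap of two influence profiles (elementwise product)."""
    va, vb = profile_a.vector, profile_b.vector
    if va.shape != vb.shape:
        raise ValueError(f"profile dimensions differ: {va.shape} vs {vb.shape}")
    return va * vb


def ddi_score(scores: np.ndarray) -> float:
    """Sum of per-protein overlap scores over all proteins."""
    return float(np.asarray(scores).sum())


def score_pairs(
    profiles: Mapping[str, PropagationProfile],
    pairs: Sequence[tuple[str, str]] | None = None,
    method: str = "rwr",
    sort: bool = True,
) -> list[ScoredPair]:
    """Score drug pairs by the inner product of their profiles.

    When ``pairs`` is omitted, all C(n, 2) unordered pairs of available
    drugs are scored. Output is sorted by descending score with ties broken
    lexicographically on the pair key, which makes ranked output (and hence
    top-fraction enrichment) fully deterministic; with ``sort=False`` the
    explicit input pair order is preserved.
    """
    drugs = sorted(profiles)
    if pairs is None:
        pairs = [(drugs[i], drugs[j]) for i in range(len(drugs)) for j in range(i + 1, len(drugs))]
    else:
        missing = sorted({d for p in pairs for d in p if d not in profiles})
        if missing:
            raise KeyError(f"pairs reference drugs without profiles: {missing}")
    out = [
        ScoredPair(a, b, float(profiles[a].vector @ profiles[b].vector), method)
        for a, b in pairs
    ]
    if sort:
        out.sort(key=lambda sp: (-sp.score, sp.drug_a, sp.drug_b))
    return out
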