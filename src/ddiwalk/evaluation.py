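"""Gold-standard construction, ROC/AUC, enrichment, and permutation tests.

A known drug-drug interaction is accepted as *pharmacodynamic* when the two
drugs share a target protein or have targets within a common pathway; those
pairs form the positive gold standard, every other scored candidate pair is
a negative. Rankings are evaluated by the area under the ROC curve (computed
from the Mann-Whitney rank statistic, ties by midranks) and by fold
enrichment of positives in the top-scored fraction:

    fold enrichment = (m / n) / (M / N)

with m positives among the n top-ranked pairs, M positives among all N
candidate pairs.

Statistical significance of individual scores is assessed against empirical
null distributions built by repeatedly sampling random proteins and random
drug pairs; the right-tailed p-value uses the add-one permutation estimator
(1 + #{null >= observed}) / (1 + replicates), so the smallest attainable
p-value is 1/(replicates + 1).
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

from .network import DrugTargetMap, PathwayCollection, _open_text
from .propagation import PropagationProfile
from .scoring import ScoredPair

logger = logging.getLogger(__name__)

__all__ = [
    "GoldStandard",
    "EmpiricalNull",
    "EvaluationReport",
    "label_pd_gold_standard",
    "roc_auc",
    "fold_enrichment",
    "side_effect_jaccard",
    "load_side_effects",
    "empirical_null",
    "empirical_pvalue",
    "significant_genes",
    "stratified_auc",
    "target_count_categories",
]

Pair = tuple[str, str]


def _canon(pair: Iterable[str]) -> Pair:
    a, b = pair
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class GoldStandard:
    """Positive pair labels over a candidate-pair universe."""

    positives: frozenset[Pair]
    universe: frozenset[Pair] = frozenset()
    provenance: str = ""

    def __post_init__(self):
        if self.universe and not self.positives <= self.universe:
            raise ValueError("positives must be a subset of the universe")

    def is_positive(self, pair: Iterable[str]) -> bool:
        return _canon(pair) in self.positives


def label_pd_gold_standard(
    known_ddis: Iterable[Pair],
    targets: DrugTargetMap,
    pathways: PathwayCollection,
) -> GoldStandard:
    """Filter known interactions down to the pharmacodynamic subset.

    A known interaction (a, b) is labeled positive iff the drugs share at
    least one target protein, or some single pathway contains a target of
    each. Pairs whose drugs lack target annotations are skipped (counted in
    the log); pairs failing the rule stay in the universe as candidates.
    The rule is symmetric in (a, b) and independent of input order.
    """
    pw_index = pathways.membership_index()
    universe: set[Pair] = set()
    positives: set[Pair] = set()
    skipped = 0
    for pair in known_ddis:
        a, b = _canon(pair)
        if a not in targets or b not in targets:
            skipped += 1
            continue
        universe.add((a, b))
        ta, tb = targets[a], targets[b]
        if ta & tb:
            positives.add((a, b))
            continue
        pws_a = frozenset().union(*(pw_index.get(p, frozenset()) for p in ta)) if ta else frozenset()
        for p in tb:
            if pw_index.get(p, frozenset()) & pws_a:
                positives.add((a, b))
                break
    if skipped:
        logger.info("gold standard: skipped %d pairs with unannotated drugs", skipped)
    logger.info(
        "gold standard: %d of %d known interactions labeled pharmacodynamic",
        len(positives), len(universe),
    )
    return GoldStandard(frozenset(positives), frozenset(universe), "labeled")


@dataclass
class EvaluationReport:
    """AUC, ROC curve, and optional enrichment for one ranking."""

    auc: float
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    n_positive: int
    n_negative: int
    fold_enrichment: float | None = None
    enrichment_counts: dict[str, int] | None = None
    stratum_auc: dict[str, float | None] = field(default_factory=dict)


def _labels(scores: Sequence[ScoredPair], gold: GoldStandard) -> np.ndarray:
    return np.array([gold.is_positive(sp.pair) for sp in scores], dtype=bool)


def _rank_auc(values: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with midranks for ties."""
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs at least one positive and one negative")
    ranks = rankdata(values)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_auc(scores: Sequence[ScoredPair], gold: GoldStandard) -> EvaluationReport:
    """ROC curve and AUC of a scored candidate list against the gold labels.

    The scored pairs themselves form the evaluation universe: every scored
    pair absent from the positive set is a negative. The AUC comes from the
    rank statistic; curve points come from a threshold sweep and integrate
    (trapezoid) to the same number.
    """
    if not scores:
        raise ValueError("no scored pairs")
    labels = _labels(scores, gold)
    values = np.array([sp.score for sp in scores])
    auc = _rank_auc(values, labels)
    fpr, tpr, _ = roc_curve(labels, values)
    return EvaluationReport(
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        n_positive=int(labels.sum()),
        n_negative=int((~labels).sum()),
    )


def fold_enrichment(
    scores: Sequence[ScoredPair],
    positives: Iterable[Pair] | GoldStandard,
    fraction: float = 0.05,
) -> float:
    """Enrichment of positives in the top-scored fraction of candidates.

    The top n = ceil(fraction * N) pairs are taken after re-sorting by
    descending score with lexicographic tie-break, so the cut is
    deterministic regardless of input order.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    if isinstance(positives, GoldStandard):
        pos = positives.positives
    else:
        pos = frozenset(_canon(p) for p in positives)
    ranked = sorted(scores, key=lambda sp: (-sp.score, sp.drug_a, sp.drug_b))
    N = len(ranked)
    if N == 0:
        raise ValueError("no scored pairs")
    M = sum(1 for sp in ranked if sp.pair in pos)
    if M == 0:
        raise ValueError("no positives among candidates: enrichment undefined")
    n = math.ceil(fraction * N)
    m = sum(1 for sp in ranked[:n] if sp.pair in pos)
    return (m / n) / (M / N)


def side_effect_jaccard(se_a: Iterable[str], se_b: Iterable[str]) -> float:
    """Jaccard index of two drugs' side-effect term sets."""
    sa, sb = set(se_a), set(se_b)
    if not sa and not sb:
        raise ValueError("both side-effect sets are empty (0/0)")
    return len(sa & sb) / len(sa | sb)


def load_side_effects(path) -> dict[str, frozenset[str]]:
    """Load per-drug side-effect terms from a TSV (drug_id, term).

    Upstream filtering (e.g. keeping only non-placebo, frequent effects) is
    the caller's responsibility at ingest.
    """
    out: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise ValueError(f"{path}: line {lineno}: expected drug and term")
            out.setdefault(fields[0].strip(), set()).add(fields[1].strip())
    return {d: frozenset(s) for d, s in out.items()}


@dataclass(frozen=True)
class EmpiricalNull:
    """Sorted null sample of a score statistic under random draws."""

    sample: np.ndarray
    replicates: int
    seed: int
    statistic: str  # "protein_score" | "ddi_score"

    def __post_init__(self):
        if self.sample.size != self.replicates:
            raise ValueError("sample size must equal replicate count")


def _profile_matrix(profiles: Mapping[str, PropagationProfile]) -> tuple[list[str], np.ndarray]:
    drugs = sorted(profiles)
    return drugs, np.vstack([profiles[d].vector for d in drugs])


def empirical_null(
    statistic: str,
    profiles: Mapping[str, PropagationProfile],
    replicates: int = 100_000,
    seed: int = 0,
) -> EmpiricalNull:
    """Sample a score's null distribution by random drug-pair draws.

    "protein_score": each replicate draws one uniform random protein and one
    uniform random unordered drug pair and records their per-protein overlap
    at that protein. "ddi_score": each replicate draws a uniform random
    unordered drug pair and records the pair's full interaction score.
    Fully reproducible from the seed.
    """
    if statistic not in ("protein_score", "ddi_score"):
        raise ValueError("statistic must be 'protein_score' or 'ddi_score'")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    drugs, V = _profile_matrix(profiles)
    n = len(drugs)
    if n < 2:
        raise ValueError("need at least two drugs to draw pairs")
    rng = np.random.default_rng(seed)
    i = rng.integers(0, n, size=replicates)
    j = rng.integers(0, n - 1, size=replicates)
    j = np.where(j >= i, j + 1, j)  # uniform over unordered pairs i != j
    if statistic == "protein_score":
        k = rng.integers(0, V.shape[1], size=replicates)
        sample = V[i, k] * V[j, k]
    else:
        gram = V @ V.T
        sample = gram[i, j]
    return EmpiricalNull(np.sort(sample), replicates, seed, statistic)


def empirical_pvalue(observed: float, null: EmpiricalNull) -> float:
    """Right-tailed p-value with the add-one permutation estimator."""
    ge = null.replicates - int(np.searchsorted(null.sample, observed, side="left"))
    return (1 + ge) / (1 + null.replicates)


def significant_genes(
    pair: Pair,
    profiles: Mapping[str, PropagationProfile],
    null: EmpiricalNull,
    nodes: Sequence[str],
    alpha: float = 1.0e-4,
) -> list[tuple[str, float]]:
    """Proteins whose per-protein overlap for a drug pair is null-significant.

    Returns (protein, p-value) sorted by ascending p then identifier. The
    smallest attainable p is 1/(replicates + 1); an ``alpha`` at or below it
    can never be met and raises, rather than silently returning nothing.
    """
    if null.statistic != "protein_score":
        raise ValueError("significant_genes requires a protein_score null")
    p_min = 1.0 / (1 + null.replicates)
    if alpha <= p_min:
        raise ValueError(
            f"alpha={alpha:g} is unattainable with {null.replicates} replicates "
            f"(smallest possible p-value is {p_min:g}); increase replicates"
        )
    a, b = pair
    ps = profiles[a].vector * profiles[b].vector
    ge = null.replicates - np.searchsorted(null.sample, ps, side="left")
    pvals = (1 + ge) / (1 + null.replicates)
    hits = [(nodes[idx], float(pvals[idx])) for idx in np.flatnonzero(pvals < alpha)]
    hits.sort(key=lambda t: (t[1], t[0]))
    return hits


def stratified_auc(
    scores: Sequence[ScoredPair],
    gold: GoldStandard,
    strata: Mapping[str, str | Iterable[str]],
) -> dict[str, float | None]:
    """Per-category AUC for pairs grouped by their drugs' categories.

    When the categories are exactly {"single", "multi"} (target-count
    strata) a pair is "multi" if either drug is multi-target and "single"
    only when both are — an exhaustive, disjoint split. For any other
    labeling (e.g. ATC letters, possibly several per drug) a pair belongs
    to every category both drugs share. Strata without at least one
    positive and one negative get ``None`` (undefined), never 0.
    """
    cats: dict[str, frozenset[str]] = {}
    for drug, c in strata.items():
        cats[drug] = frozenset([c]) if isinstance(c, str) else frozenset(c)
    flat = set().union(*cats.values()) if cats else set()
    single_multi = flat <= {"single", "multi"}

    groups: dict[str, list[ScoredPair]] = {}
    for sp in scores:
        ca = cats.get(sp.drug_a)
        cb = cats.get(sp.drug_b)
        if ca is None or cb is None:
            continue
        if single_multi:
            members = {"multi"} if ("multi" in ca or "multi" in cb) else {"single"}
        else:
            members = ca & cb
        for cat in members:
            groups.setdefault(cat, []).append(sp)

    out: dict[str, float | None] = {}
    for cat in sorted(groups):
        subset = groups[cat]
        labels = _labels(subset, gold)
        if labels.all() or not labels.any():
            out[cat] = None
            continue
        out[cat] = _rank_auc(np.array([sp.score for sp in subset]), labels)
    return out


def target_count_categories(targets: DrugTargetMap) -> dict[str, str]:
    """Label each drug "single" or "multi" by its number of targets."""
    return {d: ("single" if len(t) == 1 else "multi") for d, t in targets.items()}
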