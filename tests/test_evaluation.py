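import numpy as np
import pytest

from ddiwalk import (
    GoldStandard,
    PropagationProfile,
    RWRConfig,
    ScoredPair,
    empirical_null,
    empirical_pvalue,
    fold_enrichment,
    label_pd_gold_standard,
    roc_auc,
    side_effect_jaccard,
    significant_genes,
    stratified_auc,
    target_count_categories,
)
from ddiwalk.evaluation import _rank_auc
from ddiwalk.network import DrugTargetMap, PathwayCollection


def make_profile(vec, drug="D"):
    return PropagationProfile(drug, np.asarray(vec, dtype=float), 1, 0.0, True, RWRConfig())


def make_scores(values, labels):
    """ScoredPairs with synthetic drug ids; returns (scores, gold)."""
    scores = [ScoredPair(f"A{i:05d}", f"B{i:05d}", float(v)) for i, v in enumerate(values)]
    positives = frozenset(sp.pair for sp, lab in zip(scores, labels) if lab)
    return scores, GoldStandard(positives)


PATHWAYS = PathwayCollection({"pw1": {"P1", "P2"}, "pw2": {"P3", "P4"}})


class TestGoldStandard:
    def test_shared_target_is_positive(self):
        targets = DrugTargetMap({"a": {"P9"}, "b": {"P9", "P3"}})
        gold = label_pd_gold_standard([("a", "b")], targets, PATHWAYS)
        assert gold.is_positive(("a", "b"))

    def test_co_pathway_is_positive(self):
        targets = DrugTargetMap({"a": {"P1"}, "b": {"P2"}})
        gold = label_pd_gold_standard([("a", "b")], targets, PATHWAYS)
        assert gold.is_positive(("b", "a"))

    def test_disjoint_pathways_not_positive_but_kept_as_candidate(self):
        targets = DrugTargetMap({"a": {"P1"}, "b": {"P3"}})
        gold = label_pd_gold_standard([("a", "b")], targets, PATHWAYS)
        assert not gold.is_positive(("a", "b"))
        assert ("a", "b") in gold.universe

    def test_unannotated_drug_skipped(self):
        targets = DrugTargetMap({"a": {"P1"}})
        gold = label_pd_gold_standard([("a", "zzz")], targets, PATHWAYS)
        assert gold.universe == frozenset()

    def test_order_invariant_and_symmetric(self):
        targets = DrugTargetMap({"a": {"P1"}, "b": {"P2"}, "c": {"P3"}})
        pairs = [("a", "b"), ("b", "c")]
        g1 = label_pd_gold_standard(pairs, targets, PATHWAYS)
        g2 = label_pd_gold_standard([(b, a) for a, b in reversed(pairs)], targets, PATHWAYS)
        assert g1.positives == g2.positives
        assert g1.universe == g2.universe

    def test_positives_must_be_subset_of_universe(self):
        with pytest.raises(ValueError):
            GoldStandard(frozenset({("a", "b")}), frozenset({("c", "d")}))


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        scores, gold = make_scores([5, 4, 3, 2, 1], [1, 1, 0, 0, 0])
        assert roc_auc(scores, gold).auc == 1.0

    def test_reversed_separation_gives_zero(self):
        scores, gold = make_scores([1, 2, 3, 4, 5], [1, 1, 0, 0, 0])
        assert roc_auc(scores, gold).auc == 0.0

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(12)
        values = rng.random(4000)
        labels = rng.random(4000) < 0.3
        scores, gold = make_scores(values, labels)
        assert roc_auc(scores, gold).auc == pytest.approx(0.5, abs=0.03)

    def test_rank_auc_equals_trapezoid_of_curve_with_ties(self):
        rng = np.random.default_rng(3)
        values = rng.integers(0, 10, size=500).astype(float)  # heavy ties
        labels = rng.random(500) < 0.4
        scores, gold = make_scores(values, labels)
        rep = roc_auc(scores, gold)
        assert rep.auc == pytest.approx(np.trapezoid(rep.roc_tpr, rep.roc_fpr), abs=1e-12)

    def test_curve_endpoints(self):
        scores, gold = make_scores([3, 2, 1], [1, 0, 1])
        rep = roc_auc(scores, gold)
        assert (rep.roc_fpr[0], rep.roc_tpr[0]) == (0.0, 0.0)
        assert (rep.roc_fpr[-1], rep.roc_tpr[-1]) == (1.0, 1.0)

    def test_degenerate_labeling_rejected(self):
        scores, _ = make_scores([1, 2], [1, 1])
        all_pos = GoldStandard(frozenset(sp.pair for sp in scores))
        with pytest.raises(ValueError):
            roc_auc(scores, all_pos)
        with pytest.raises(ValueError):
            roc_auc(scores, GoldStandard(frozenset()))


class TestFoldEnrichment:
    def test_spec_arithmetic(self):
        # 1000 candidates, 50 positives, 5 of them in the top 10 -> 10.0
        labels = np.zeros(1000, dtype=bool)
        labels[:5] = True  # in top 10
        labels[500:545] = True  # the other 45 lower down
        scores, gold = make_scores(np.arange(1000, 0, -1), labels)
        assert fold_enrichment(scores, gold, fraction=0.01) == pytest.approx(10.0)

    def test_fraction_one_is_exactly_one(self):
        scores, gold = make_scores([4, 3, 2, 1], [1, 0, 1, 0])
        assert fold_enrichment(scores, gold, fraction=1.0) == 1.0

    def test_all_positives_on_top_reach_upper_bound(self):
        labels = [1] * 10 + [0] * 90
        scores, gold = make_scores(np.arange(100, 0, -1), labels)
        # m = M -> enrichment = N/n
        assert fold_enrichment(scores, gold, fraction=0.1) == pytest.approx(10.0)

    def test_scattered_positives_near_one(self):
        vals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            labels = rng.random(500) < 0.2
            scores, gold = make_scores(rng.random(500), labels)
            vals.append(fold_enrichment(scores, gold, fraction=0.2))
        assert np.mean(vals) == pytest.approx(1.0, abs=0.1)

    def test_no_positives_rejected(self):
        scores, _ = make_scores([2, 1], [0, 0])
        with pytest.raises(ValueError):
            fold_enrichment(scores, GoldStandard(frozenset()))

    def test_bad_fraction_rejected(self):
        scores, gold = make_scores([2, 1], [1, 0])
        with pytest.raises(ValueError):
            fold_enrichment(scores, gold, fraction=0.0)


class TestSideEffectJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"x", "y"}, {"x", "y"}, 1.0),
            ({"x"}, {"y"}, 0.0),
            ({"x", "y", "z"}, {"y", "z", "w"}, 0.5),
        ],
    )
    def test_values(self, a, b, expected):
        assert side_effect_jaccard(a, b) == expected

    def test_double_empty_rejected(self):
        with pytest.raises(ValueError):
            side_effect_jaccard(set(), set())


class TestEmpiricalNull:
    def test_seed_reproducible_to_the_byte(self, small_profiles):
        n1 = empirical_null("protein_score", small_profiles, replicates=500, seed=3)
        n2 = empirical_null("protein_score", small_profiles, replicates=500, seed=3)
        assert n1.sample.tobytes() == n2.sample.tobytes()
        assert n1.sample.size == 500

    def test_identical_profiles_enumerate_squares(self):
        # with all drugs sharing one profile the protein-score null can only
        # take the squared profile values
        vec = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        profiles = {d: make_profile(vec, d) for d in "abc"}
        null = empirical_null("protein_score", profiles, replicates=2000, seed=0)
        assert set(np.round(null.sample, 12)) <= set(np.round(vec**2, 12))

    def test_ddi_null_draws_pair_scores(self, small_profiles):
        null = empirical_null("ddi_score", small_profiles, replicates=300, seed=1)
        drugs = sorted(small_profiles)
        gram = {
            (a, b): float(small_profiles[a].vector @ small_profiles[b].vector)
            for a in drugs
            for b in drugs
            if a < b
        }
        allowed = np.round(sorted(gram.values()), 12)
        assert set(np.round(null.sample, 12)) <= set(allowed)

    def test_validation(self, small_profiles):
        with pytest.raises(ValueError):
            empirical_null("bogus", small_profiles)
        with pytest.raises(ValueError):
            empirical_null("ddi_score", small_profiles, replicates=0)
        one = {"a": make_profile([1.0])}
        with pytest.raises(ValueError):
            empirical_null("ddi_score", one, replicates=10)


class TestEmpiricalPvalue:
    def test_extremes(self, small_profiles):
        null = empirical_null("ddi_score", small_profiles, replicates=1000, seed=0)
        top = float(null.sample[-1]) + 1.0
        assert empirical_pvalue(top, null) == pytest.approx(1 / 1001)
        assert empirical_pvalue(float(null.sample[0]), null) == pytest.approx(1.0)

    def test_monotone_non_increasing(self, small_profiles):
        null = empirical_null("ddi_score", small_profiles, replicates=1000, seed=0)
        xs = np.linspace(float(null.sample[0]), float(null.sample[-1]), 50)
        ps = [empirical_pvalue(x, null) for x in xs]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_percentile_calibration(self):
        from ddiwalk.evaluation import EmpiricalNull

        rng = np.random.default_rng(8)
        sample = np.sort(rng.normal(size=20_000))
        null = EmpiricalNull(sample, 20_000, 8, "ddi_score")
        q95 = float(np.quantile(sample, 0.95))
        assert empirical_pvalue(q95, null) == pytest.approx(0.05, abs=0.005)

    def test_super_uniform_under_own_null(self, small_profiles):
        null = empirical_null("protein_score", small_profiles, replicates=5000, seed=0)
        fresh = empirical_null("protein_score", small_profiles, replicates=2000, seed=99)
        ps = np.array([empirical_pvalue(x, null) for x in fresh.sample])
        for alpha in (0.01, 0.05, 0.1):
            se = np.sqrt(alpha * (1 - alpha) / ps.size)
            assert (ps <= alpha).mean() <= alpha + 3 * se


class TestSignificantGenes:
    def test_zero_overlap_gives_empty_list(self):
        profiles = {
            "a": make_profile([1.0, 0.0, 0.0, 0.0], "a"),
            "b": make_profile([0.0, 0.0, 0.0, 1.0], "b"),
            "c": make_profile([0.5, 0.5, 0.0, 0.0], "c"),
        }
        null = empirical_null("protein_score", profiles, replicates=200, seed=0)
        out = significant_genes(("a", "b"), profiles, null, ("P1", "P2", "P3", "P4"), alpha=0.5)
        assert out == []

    def test_dominant_hub_detected(self, small_bundle, small_profiles):
        # the protein most co-influenced by the top-scoring pair must show up
        from ddiwalk import score_pairs

        top = score_pairs(small_profiles)[0]
        null = empirical_null("protein_score", small_profiles, replicates=20_000, seed=5)
        hits = significant_genes(
            top.pair, small_profiles, null, small_bundle.network.nodes, alpha=0.01
        )
        assert hits
        ps = small_profiles[top.drug_a].vector * small_profiles[top.drug_b].vector
        hub = small_bundle.network.nodes[int(np.argmax(ps))]
        assert hub in [g for g, _ in hits]
        pvals = [p for _, p in hits]
        assert pvals == sorted(pvals)

    def test_unattainable_alpha_rejected(self, small_profiles):
        null = empirical_null("protein_score", small_profiles, replicates=1000, seed=0)
        with pytest.raises(ValueError, match="unattainable"):
            significant_genes(
                ("x", "y"), small_profiles, null, (), alpha=1e-4
            )

    def test_requires_protein_score_null(self, small_profiles):
        null = empirical_null("ddi_score", small_profiles, replicates=100, seed=0)
        with pytest.raises(ValueError):
            significant_genes(("x", "y"), small_profiles, null, (), alpha=0.5)


class TestStratifiedAuc:
    def test_all_single_target_matches_global(self):
        scores, gold = make_scores([5, 4, 3, 2], [1, 0, 1, 0])
        strata = {d: "single" for sp in scores for d in sp.pair}
        out = stratified_auc(scores, gold, strata)
        assert set(out) == {"single"}
        assert out["single"] == roc_auc(scores, gold).auc

    def test_either_multi_rule(self):
        scores = [
            ScoredPair("a", "b", 3.0),
            ScoredPair("a", "c", 2.0),
            ScoredPair("b", "c", 1.0),
        ]
        gold = GoldStandard(frozenset({("a", "b"), ("a", "c")}))
        strata = {"a": "single", "b": "single", "c": "multi"}
        out = stratified_auc(scores, gold, strata)
        # (a,c) and (b,c) form the multi stratum, (a,b) alone is single
        assert out["single"] is None  # one pair only: no negative/positive mix
        assert out["multi"] == 1.0

    def test_stratum_without_positives_is_undefined(self):
        scores, _ = make_scores([2, 1], [0, 0])
        gold = GoldStandard(frozenset())
        strata = {d: "single" for sp in scores for d in sp.pair}
        assert stratified_auc(scores, gold, strata) == {"single": None}

    def test_category_pairs_share_letter(self):
        scores = [
            ScoredPair("a", "b", 3.0),
            ScoredPair("a", "c", 2.0),
            ScoredPair("b", "c", 1.0),
        ]
        gold = GoldStandard(frozenset({("a", "b")}))
        strata = {"a": {"N", "C"}, "b": {"N"}, "c": {"N", "C"}}
        out = stratified_auc(scores, gold, strata)
        # N stratum holds all three pairs, its positive ranks on top
        assert out["N"] == 1.0
        # C stratum holds only the negative pair (a,c): undefined
        assert out["C"] is None

    def test_planted_benchmark_both_strata_beat_chance(self, small_bundle, small_profiles):
        from ddiwalk import score_pairs

        scores = score_pairs(small_profiles)
        strata = target_count_categories(small_bundle.targets)
        out = stratified_auc(scores, small_bundle.gold, strata)
        defined = [v for v in out.values() if v is not None]
        assert defined and all(v > 0.5 for v in defined)

    def test_rank_auc_handles_ties_by_midranks(self):
        vals = np.array([1.0, 1.0, 0.0, 0.0])
        labels = np.array([True, False, True, False])
        assert _rank_auc(vals, labels) == 0.5


class TestTargetCountCategories:
    def test_split(self):
        tm = DrugTargetMap({"a": {"P1"}, "b": {"P1", "P2"}})
        assert target_count_categories(tm) == {"a": "single", "b": "multi"}
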