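import math
import warnings

import numpy as np
import pytest

from effectorank.functional import (
    AnnotationCategory,
    build_training_profile,
    category_similarity,
    empirical_pvalue,
    fisher_combine,
    read_quantitative_tsv,
    sample_null_genes,
    score_candidates_functional,
    write_quantitative_tsv,
)
from effectorank.geneset_io import GeneSet, ValidationError
from effectorank.overlap import intersect_and_partition
from effectorank.pipeline import prioritize_bundle
from effectorank.synthetic import SyntheticConfig, generate_bundle


def _categorical(name, **terms_by_gene):
    # Keys are uppercased to match GeneSet symbol normalization.
    return AnnotationCategory(
        name=name,
        kind="categorical",
        terms_by_gene={g.upper(): frozenset(t) for g, t in terms_by_gene.items()},
    )


class TestTrainingProfile:
    def test_term_weights_are_training_fractions(self):
        category = _categorical(
            "c", t1=["T"], t2=["T"], t3=["T", "U"], t4=["V"]
        )
        training = GeneSet.from_iterable("train", ["t1", "t2", "t3", "t4"])
        profile = build_training_profile(training, [category])
        weights = profile.categorical["c"].term_weights
        assert weights["T"] == pytest.approx(0.75)
        assert weights["U"] == pytest.approx(0.25)
        assert weights["V"] == pytest.approx(0.25)

    def test_quantitative_profile_is_mean(self):
        category = AnnotationCategory(
            "q",
            kind="quantitative",
            vectors={"T1": np.array([1.0, 2.0]), "T2": np.array([3.0, 4.0])},
        )
        training = GeneSet.from_iterable("train", ["t1", "t2"])
        profile = build_training_profile(training, [category])
        assert np.allclose(profile.quantitative["q"].mean_vector, [2.0, 3.0])

    def test_unannotating_category_dropped_with_warning(self):
        category = _categorical("c", other=["T"])
        training = GeneSet.from_iterable("train", ["t1"])
        with pytest.warns(UserWarning, match="annotates no training gene"):
            profile = build_training_profile(training, [category])
        assert "c" not in profile.categorical


class TestCategorySimilarity:
    def test_exact_profile_match_is_one(self):
        category = _categorical("c", t1=["A", "B"], t2=["A", "B"], cand=["A", "B"])
        training = GeneSet.from_iterable("train", ["t1", "t2"])
        profile = build_training_profile(training, [category])
        assert category_similarity("CAND", profile, category) == pytest.approx(1.0)

    def test_terms_absent_from_profile_score_zero(self):
        category = _categorical("c", t1=["A"], cand=["Z", "W"])
        training = GeneSet.from_iterable("train", ["t1"])
        profile = build_training_profile(training, [category])
        assert category_similarity("CAND", profile, category) == 0.0

    def test_pearson_of_profile_mean_is_one(self):
        category = AnnotationCategory(
            "q",
            kind="quantitative",
            vectors={
                "T1": np.array([1.0, 2.0, 5.0]),
                "CAND": np.array([1.0, 2.0, 5.0]),
            },
        )
        training = GeneSet.from_iterable("train", ["t1"])
        profile = build_training_profile(training, [category])
        assert category_similarity("CAND", profile, category) == pytest.approx(1.0)

    def test_zero_variance_vector_warns_and_scores_zero(self):
        category = AnnotationCategory(
            "q",
            kind="quantitative",
            vectors={"T1": np.array([1.0, 2.0]), "CAND": np.array([3.0, 3.0])},
        )
        training = GeneSet.from_iterable("train", ["t1"])
        profile = build_training_profile(training, [category])
        with pytest.warns(UserWarning, match="zero-variance"):
            assert category_similarity("CAND", profile, category) == 0.0

    def test_best_jaccard_alternative(self):
        category = _categorical("c", t1=["A", "B"], t2=["C"], cand=["A", "B"])
        training = GeneSet.from_iterable("train", ["t1", "t2"])
        profile = build_training_profile(training, [category])
        assert category_similarity("CAND", profile, category, method="best_jaccard") == 1.0


class TestEmpiricalPvalue:
    def test_add_one_floor(self):
        nulls = np.linspace(0.0, 0.5, 999)
        assert empirical_pvalue(0.9, nulls) == pytest.approx(1 / 1000)

    def test_boundary_all_nulls_tie_or_exceed(self):
        nulls = np.full(999, 0.0)
        assert empirical_pvalue(0.0, nulls) == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        universe = [f"g{i}" for i in range(200)]
        training = frozenset(universe[:50])
        a = sample_null_genes(universe, training, 99, np.random.default_rng(9))
        b = sample_null_genes(universe, training, 99, np.random.default_rng(9))
        assert a == b

    def test_small_universe_warns_and_samples_with_replacement(self):
        universe = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="replacement"):
            sampled = sample_null_genes(universe, frozenset(), 99, np.random.default_rng(0))
        assert len(sampled) == 99


class TestFisherCombine:
    def test_single_pvalue_identity(self):
        # chi-square(2) survival at -2 ln p is exactly p.
        _, p_fisher, s_combined = fisher_combine([0.05])
        assert p_fisher == pytest.approx(0.05, abs=1e-12)
        assert s_combined == pytest.approx(0.95, abs=1e-12)

    def test_all_ones_give_zero_score(self):
        statistic, _, s_combined = fisher_combine([1.0, 1.0, 1.0])
        assert statistic == 0.0
        assert s_combined == 0.0

    def test_two_categories_closed_form(self):
        statistic, p_fisher, s_combined = fisher_combine([0.1, 0.1])
        expected_x = -2 * (math.log(0.1) + math.log(0.1))
        expected_p = math.exp(-expected_x / 2) * (1 + expected_x / 2)
        assert statistic == pytest.approx(expected_x, abs=1e-12)
        assert p_fisher == pytest.approx(expected_p, abs=1e-10)
        assert s_combined == pytest.approx(1 - expected_p, abs=1e-10)

    def test_monotone_in_each_pvalue(self):
        base = [0.2, 0.5, 0.9]
        _, _, s_base = fisher_combine(base)
        for i in range(3):
            stronger = list(base)
            stronger[i] /= 10
            _, _, s_stronger = fisher_combine(stronger)
            assert s_stronger >= s_base

    def test_zero_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            _, _, s = fisher_combine([0.0, 0.5])
        # The clamped p is so extreme the chi-square survival underflows.
        assert 0.0 <= s <= 1.0


class TestScoreCandidates:
    def test_unannotated_candidate_gets_uninformative_p(self):
        category = _categorical("c", t1=["A"], known=["A"])
        training = GeneSet.from_iterable("train", ["t1"])
        scores = score_candidates_functional(
            ["known", "ghost"],
            training,
            [category],
            universe=["known", "ghost", "t1"] + [f"bg{i}" for i in range(150)],
            n_null_samples=99,
            rng=1,
        )
        by_gene = {s.gene: s for s in scores}
        assert by_gene["GHOST"].per_category_p["c"] == 1.0
        assert by_gene["GHOST"].per_category_similarity["c"] == 0.0
        assert by_gene["KNOWN"].per_category_p["c"] < 1.0

    def test_planted_effectors_outscore_background(self):
        """Planted effectors beat the non-planted candidate median S_combined
        in >= 95% of 50 default synthetic replicates."""
        wins = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(50):
                bundle = generate_bundle(SyntheticConfig(rng_seed=3000 + i))
                _, partition = intersect_and_partition(
                    bundle.aging_set, bundle.exercise_set
                )
                scores = score_candidates_functional(
                    partition.test.genes,
                    partition.training,
                    bundle.categories,
                    bundle.universe,
                    n_null_samples=199,
                    rng=i,
                )
                planted = set(bundle.truth["planted_effectors"])
                planted_scores = [s.s_combined for s in scores if s.gene in planted]
                background = [s.s_combined for s in scores if s.gene not in planted]
                wins += np.median(planted_scores) > np.median(background)
        assert wins >= 48  # 95% of 50, rounded up

    def test_round_trip_quantitative_tsv(self, tmp_path):
        category = AnnotationCategory(
            "q",
            kind="quantitative",
            vectors={"g1": np.array([0.5, -1.25]), "g2": np.array([2.0, 3.5])},
        )
        path = tmp_path / "q.tsv"
        write_quantitative_tsv(category, path)
        loaded = read_quantitative_tsv(path, name="q")
        assert set(loaded.vectors) == {"G1", "G2"}
        assert np.allclose(loaded.vectors["G2"], [2.0, 3.5])
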