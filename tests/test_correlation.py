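"""Correlation primitives against brute-force oracles; bootstrap, shuffle
null, and the stratified estimators."""

import math

import networkx as nx
import numpy as np
import pytest
import scipy.stats

from emocorr import (
    ConfigurationError,
    DegenerateSequenceError,
    EmotionVector,
    InsufficientDataError,
    bootstrap_corr,
    clustering_binned,
    degree_stratified,
    dominant_emotion,
    neighborhood_vector,
    pairwise_correlation,
    pearson,
    shuffle_null,
    spearman,
)
from emocorr.emotions import Emotion


def brute_pearson(x, y):
    """Textbook sum formula, independent of the implementation route."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    return (n * sxy - sx * sy) / math.sqrt((n * sxx - sx * sx) * (n * syy - sy * sy))


class TestPearson:
    def test_perfect_linear(self):
        assert pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson([1, 2, 3], [6, 4, 2]) == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        x = [0.1, 0.4, 0.3, 0.2]
        y = [0.2, 0.3, 0.5, 0.0]
        assert pearson(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_constant_sequence_raises(self):
        with pytest.raises(DegenerateSequenceError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_single_pair_raises(self):
        with pytest.raises(InsufficientDataError):
            pearson([1], [2])

    def test_thousand_random_pairs_match_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(2, 51))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert pearson(x, y) == pytest.approx(brute_pearson(x, y), abs=1e-12)

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=30)
            y = rng.normal(size=30)
            assert pearson(x, y) == pytest.approx(
                scipy.stats.pearsonr(x, y).statistic, abs=1e-12
            )


class TestSpearman:
    def test_rank_difference_formula_hand_value(self):
        # ranks differ by (0, 1, -1, 0): sum d^2 = 2, rho = 1 - 12/60
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_monotone_transform_gives_one(self):
        x = [0.3, 1.2, 5.0, 9.1]
        assert spearman(x, [math.exp(v) for v in x]) == pytest.approx(1.0)

    def test_tie_free_formula_equals_pearson_of_ranks(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            n = int(rng.integers(3, 51))
            x = rng.permutation(n).astype(float)  # tie-free by construction
            y = rng.permutation(n).astype(float)
            rx = scipy.stats.rankdata(x)
            ry = scipy.stats.rankdata(y)
            assert spearman(x, y) == pytest.approx(brute_pearson(rx, ry), abs=1e-12)

    def test_ties_use_average_ranks(self):
        x = [1, 1, 2, 3]
        y = [4, 5, 6, 7]
        assert spearman(x, y) == pytest.approx(
            scipy.stats.spearmanr(x, y).statistic, abs=1e-12
        )

    def test_constant_after_ranking_raises(self):
        with pytest.raises(DegenerateSequenceError):
            spearman([2, 2, 2], [1, 2, 3])


class TestBootstrap:
    def test_identical_sequences_give_unit_mean_zero_std(self):
        r_mean, r_std, _ = bootstrap_corr([1, 2, 3], [1, 2, 3], b=50, seed=0)
        assert r_mean == pytest.approx(1.0)
        assert r_std == pytest.approx(0.0)

    def test_fixed_seed_reproducible(self):
        x = np.random.default_rng(3).normal(size=40)
        y = x + np.random.default_rng(4).normal(size=40)
        assert bootstrap_corr(x, y, b=100, seed=9) == bootstrap_corr(x, y, b=100, seed=9)

    def test_degenerate_resamples_dropped_and_counted(self):
        # length-2 input: half the resamples repeat one index -> constant
        _, _, n_deg = bootstrap_corr([0.0, 1.0], [1.0, 0.0], b=200, seed=1)
        assert 50 < n_deg < 150

    def test_all_degenerate_raises(self):
        with pytest.raises(DegenerateSequenceError):
            bootstrap_corr([0.0, 1.0], [0.0, 1.0], b=1, seed=5)  # seed picks [0,0]

    def test_error_shrinks_with_sample_size(self):
        ratios = []
        for seed in range(3):
            rng = np.random.default_rng(seed)
            cov = [[1, 0.5], [0.5, 1]]
            big = rng.multivariate_normal([0, 0], cov, size=2000)
            small = rng.multivariate_normal([0, 0], cov, size=200)
            _, std_big, _ = bootstrap_corr(big[:, 0], big[:, 1], b=200, seed=seed)
            _, std_small, _ = bootstrap_corr(small[:, 0], small[:, 1], b=200, seed=seed)
            assert std_big < std_small
            ratios.append(std_small / std_big)
        # expected ratio sqrt(10) ~ 3.16; allow a factor of 2 either way
        assert 1.58 < np.mean(ratios) < 6.4

    def test_bootstrap_mean_converges_to_plain_estimate(self):
        rng = np.random.default_rng(11)
        data = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=2000)
        r_mean, _, _ = bootstrap_corr(data[:, 0], data[:, 1], b=1000, seed=2)
        assert abs(r_mean - pearson(data[:, 0], data[:, 1])) < 0.02


class TestShuffleNull:
    def test_breaks_strong_correlation(self):
        rng = np.random.default_rng(6)
        data = rng.multivariate_normal([0, 0], [[1, 0.6], [0.6, 1]], size=2000)
        assert pearson(data[:, 0], data[:, 1]) > 0.4
        assert abs(shuffle_null(data[:, 0], data[:, 1], seed=7)) < 0.05

    def test_length_two_gives_plus_or_minus_one(self):
        rs = {round(shuffle_null([0.0, 1.0], [0.0, 1.0], seed=s)) for s in range(20)}
        assert rs <= {-1, 1}

    def test_fixed_seed_reproducible(self):
        x = list(range(10))
        y = list(range(10))[::-1]
        assert shuffle_null(x, y, seed=3) == shuffle_null(x, y, seed=3)


def vec(a, j, s, d, count=10):
    return EmotionVector((a, j, s, d), count)


class TestPairwiseCorrelation:
    def test_two_node_mirror_pair(self):
        g = nx.Graph([("a", "b")])
        vectors = {"a": vec(1, 0, 0, 0), "b": vec(0, 1, 0, 0)}
        est = pairwise_correlation(g, vectors, 1, Emotion.ANGER, b=50, seed=0)
        assert est.n_pairs == 2
        assert est.r_mean == pytest.approx(-1.0)

    def test_identical_vectors_degenerate(self):
        g = nx.path_graph(["a", "b", "c"])
        vectors = {u: vec(0.25, 0.25, 0.25, 0.25) for u in g.nodes}
        with pytest.raises(DegenerateSequenceError):
            pairwise_correlation(g, vectors, 1, Emotion.JOY, b=10, seed=0)

    def test_orientation_symmetry(self, small_corpus):
        """Both orientations included: source/target relabeling is a no-op,
        so X and Y have identical multisets and equal means."""
        from emocorr import hop_pairs

        _, graph, truth, _, _ = small_corpus
        from conftest import truth_vectors

        vectors = truth_vectors(truth)
        pairs = hop_pairs(graph, 2)
        assert set(pairs) == {(t, s) for s, t in pairs}

    def test_independent_mixtures_give_null_correlation(self):
        from emocorr import GeneratorConfig, assign_emotions, generate_network
        from conftest import truth_vectors

        cfg = GeneratorConfig(n_users=500, assortativity_rho=0.0, seed=8)
        g = generate_network(cfg)
        vectors = truth_vectors(assign_emotions(g, cfg))
        for emotion in Emotion:
            est = pairwise_correlation(g, vectors, 1, emotion, b=100, seed=1)
            assert est.n_pairs >= 2000
            assert abs(est.r_mean) < 0.05


class TestNeighborhoodVector:
    def test_sums_raw_counts(self):
        g = nx.star_graph(["v", "n1", "n2"])
        counts = {"n1": [3, 1, 0, 0], "n2": [1, 3, 0, 0]}
        nv = neighborhood_vector(g, "v", counts)
        assert nv.fractions == pytest.approx((0.5, 0.5, 0, 0))

    def test_single_neighbor_equals_its_vector(self):
        g = nx.Graph([("v", "n1")])
        counts = {"n1": [2, 0, 6, 0]}
        assert neighborhood_vector(g, "v", counts).fractions == pytest.approx(
            (0.25, 0, 0.75, 0)
        )

    def test_count_sum_differs_from_fraction_average(self):
        # prolific neighbor dominates: (9 anger) + (1 joy) -> (0.9, 0.1)
        g = nx.star_graph(["v", "n1", "n2"])
        counts = {"n1": [9, 0, 0, 0], "n2": [0, 1, 0, 0]}
        nv = neighborhood_vector(g, "v", counts)
        assert nv.fractions == pytest.approx((0.9, 0.1, 0, 0))

    def test_neighborless_node_raises(self):
        g = nx.Graph()
        g.add_node("v")
        with pytest.raises(Exception):
            neighborhood_vector(g, "v", {})


class TestStratifiedEstimators:
    def test_min_group_filters_small_strata(self):
        g = nx.gnp_random_graph(10, 0.4, seed=0)
        vectors = {v: vec(*np.random.default_rng(v).dirichlet([1] * 4)) for v in g.nodes}
        counts = {v: np.array(vectors[v].fractions) * 10 for v in g.nodes}
        assert degree_stratified(g, vectors, counts, Emotion.ANGER,
                                 b=10, min_group=30, seed=0) == []

    def test_clustering_bin_assignment_half_open(self):
        # a node with clustering exactly 0.1 lands in bin index 1 for w=0.1
        g = nx.Graph()
        # 20 degree-5 nodes with exactly one neighbor tie: c = 2/(5*4) = 0.1
        rng = np.random.default_rng(0)
        for i in range(20):
            c = f"c{i}"
            leaves = [f"{c}_l{j}" for j in range(5)]
            g.add_edges_from((c, l) for l in leaves)
            g.add_edge(leaves[0], leaves[1])
        vectors = {}
        counts = {}
        for v in g.nodes:
            mix = rng.dirichlet([1] * 4)
            vectors[v] = EmotionVector(tuple(mix), 10)
            counts[v] = mix * 10
        ests = clustering_binned(g, vectors, counts, Emotion.ANGER,
                                 bin_width=0.1, b=10, min_group=10, seed=0)
        values = {e.stratum_value for e in ests}
        assert 0.1 in values  # the centers' bin is [0.1, 0.2)

    def test_single_bin_equals_all_nodes(self):
        g = nx.gnp_random_graph(40, 0.2, seed=2)
        rng = np.random.default_rng(3)
        vectors, counts = {}, {}
        for v in g.nodes:
            mix = rng.dirichlet([1] * 4)
            vectors[v] = EmotionVector(tuple(mix), 10)
            counts[v] = mix * 10
        ests = clustering_binned(g, vectors, counts, Emotion.JOY,
                                 bin_width=1.0, b=50, min_group=10, seed=4)
        assert len(ests) == 1
        assert ests[0].n_pairs == sum(1 for v in g.nodes if g.degree(v) >= 1)

    def test_tree_graph_all_in_bin_zero(self):
        g = nx.balanced_tree(2, 4)
        rng = np.random.default_rng(5)
        vectors, counts = {}, {}
        for v in g.nodes:
            mix = rng.dirichlet([1] * 4)
            vectors[v] = EmotionVector(tuple(mix), 10)
            counts[v] = mix * 10
        ests = clustering_binned(g, vectors, counts, Emotion.JOY,
                                 bin_width=0.1, b=20, min_group=5, seed=6)
        assert [e.stratum_value for e in ests] == [0.0]


class TestEmotionVector:
    def test_fractions_from_labels(self):
        # emoticon labels only: 2 anger, 1 joy, 1 sadness
        from emocorr import NaiveBayesModel, emotion_vector
        from conftest import tweet

        emap = {"EA": Emotion.ANGER, "EJ": Emotion.JOY, "ES": Emotion.SADNESS}
        model = NaiveBayesModel.train(
            [(("x",), Emotion.ANGER), (("y",), Emotion.JOY)]
        )
        tweets = [
            tweet(tid="1", emoticons=["EA"]),
            tweet(tid="2", emoticons=["EA"]),
            tweet(tid="3", emoticons=["EJ"]),
            tweet(tid="4", emoticons=["ES"]),
        ]
        v = emotion_vector(tweets, model, emap)
        assert v.fractions == pytest.approx((0.5, 0.25, 0.25, 0.0))
        assert v.tweet_count == 4

    def test_all_one_class(self):
        from emocorr import NaiveBayesModel, emotion_vector
        from conftest import tweet

        emap = {"EJ": Emotion.JOY}
        model = NaiveBayesModel.train([(("x",), Emotion.ANGER), (("y",), Emotion.JOY)])
        v = emotion_vector([tweet(tid=str(i), emoticons=["EJ"]) for i in range(5)],
                           model, emap)
        assert v.fractions == pytest.approx((0.0, 1.0, 0.0, 0.0))

    def test_zero_tweets_raises(self, tiny_model):
        from emocorr import emotion_vector

        with pytest.raises(Exception):
            emotion_vector([], tiny_model, {})

    def test_oracle_labeled_fractions_near_truth(self, small_corpus):
        """Empirical fractions from true latent labels concentrate around the
        user's true mixture (multinomial concentration at ~80 tweets)."""
        _, _, truth, tweets, latent = small_corpus
        by_user = {}
        for t in tweets:
            by_user.setdefault(t.user_id, []).append(latent[t.tweet_id])
        for uid in list(by_user)[:30]:
            labels = by_user[uid]
            emp = np.bincount([int(l) for l in labels], minlength=4) / len(labels)
            assert np.abs(emp - truth.mixtures[int(uid)]).max() <= 0.15


class TestDominantEmotion:
    @pytest.mark.parametrize(
        "fractions, expected",
        [
            ((0.5, 0.25, 0.25, 0.0), Emotion.ANGER),
            ((0.25, 0.25, 0.25, 0.25), Emotion.ANGER),  # canonical tie-break
            ((0.0, 1.0, 0.0, 0.0), Emotion.JOY),
            ((0.1, 0.2, 0.3, 0.4), Emotion.DISGUST),
        ],
    )
    def test_argmax_with_canonical_ties(self, fractions, expected):
        assert dominant_emotion(EmotionVector(fractions, 4)) is expected
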