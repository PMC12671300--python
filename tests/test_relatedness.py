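import math

import numpy as np
import pytest

from conftest import make_model
from oracles import brute_adjacency_segments, brute_cosine
from vftclust import (
    EmbeddingConfig,
    ThresholdConfig,
    default_grid,
    grid_search,
    identify_relatedness_clusters,
    load_word2vec_text,
    relatedness,
    save_word2vec_text,
    sequential_relatedness,
    sweep_thresholds,
    train_embeddings,
    toy_lexicon,
)
from vftclust.relatedness import THETA_GRID, evaluate_pair_scores, segment_scores


def chain_model(cosines: list[float]) -> tuple[list[str], object]:
    """2-D model where consecutive words w0..wn have the given cosines.

    In 2-D, placing each word at the cumulative angle makes adjacent
    cosines exact by construction.
    """
    angles = np.concatenate([[0.0], np.cumsum([math.acos(c) for c in cosines])])
    words = [f"w{i}" for i in range(len(angles))]
    return words, make_model(
        {w: [math.cos(a), math.sin(a)] for w, a in zip(words, angles)}
    )


class TestRelatedness:
    def test_self_relatedness_is_one(self, tiny_model):
        assert relatedness("a", "a", tiny_model).value == pytest.approx(1.0)

    def test_orthogonal_vectors_score_zero(self, tiny_model):
        assert relatedness("a", "b", tiny_model).value == pytest.approx(0.0)

    def test_45_degree_pair(self, tiny_model):
        assert relatedness("a", "c", tiny_model).value == pytest.approx(
            1 / math.sqrt(2)
        )

    def test_symmetric_exactly(self, tiny_model):
        assert relatedness("a", "c", tiny_model) == relatedness("c", "a", tiny_model)

    def test_oov_marker(self, tiny_model):
        s = relatedness("a", "zz", tiny_model)
        assert s.oov and s.value is None

    def test_capitalized_fallback_lookup(self):
        model = make_model({"Hund": [1.0, 0.0], "Katze": [0.5, 0.5]})
        assert not relatedness("hund", "katze", model).oov

    def test_matches_direct_cosine_arithmetic(self):
        rng = np.random.default_rng(5)
        vecs = {f"w{i}": rng.normal(size=7) for i in range(20)}
        model = make_model({w: list(v) for w, v in vecs.items()})
        for _ in range(100):
            a, b = rng.choice(20, size=2)
            got = relatedness(f"w{a}", f"w{b}", model).value
            assert got == pytest.approx(brute_cosine(vecs[f"w{a}"], vecs[f"w{b}"]))


class TestSequentialRelatedness:
    def test_two_words_one_score(self, tiny_model):
        assert len(sequential_relatedness(["a", "b"], tiny_model)) == 1

    def test_identical_words_all_ones(self, tiny_model):
        scores = sequential_relatedness(["a"] * 5, tiny_model)
        assert [s.value for s in scores] == pytest.approx([1.0] * 4)

    def test_oov_flags_neighbouring_pairs(self, tiny_model):
        scores = sequential_relatedness(["a", "zz", "b", "c"], tiny_model)
        assert [s.oov for s in scores] == [True, True, False]

    def test_fewer_than_two_words_rejected(self, tiny_model):
        with pytest.raises(ValueError):
            sequential_relatedness(["a"], tiny_model)


class TestThresholdClustering:
    def test_example_scan(self):
        words, model = chain_model([0.6, 0.2, 0.5])
        cl = identify_relatedness_clusters(words, model, ThresholdConfig(0.40))
        assert [(c.start, c.end) for c in cl.clusters] == [(0, 2), (2, 4)]
        assert cl.switches == 1

    def test_theta_above_all_scores_gives_singletons(self):
        words, model = chain_model([0.6, 0.7, 0.5])
        cl = identify_relatedness_clusters(words, model, ThresholdConfig(0.9))
        assert cl.n_clusters == 4 and cl.switches == 3

    def test_all_scores_above_theta_gives_one_cluster(self):
        words, model = chain_model([0.6, 0.7, 0.5])
        cl = identify_relatedness_clusters(words, model, ThresholdConfig(0.1))
        assert cl.sizes == [3]

    def test_strictly_greater_than_theta(self):
        cl = segment_scores([0.40, 0.41], 0.40)
        assert [(c.start, c.end) for c in cl.clusters] == [(0, 1), (1, 3)]

    def test_oov_pairs_never_join(self, tiny_model):
        cl = identify_relatedness_clusters(["a", "zz", "a"], tiny_model, ThresholdConfig(0.0))
        assert cl.n_clusters == 3

    def test_theta_one_gives_all_singletons(self):
        rng = np.random.default_rng(2)
        scores = list(rng.uniform(-1, 1, size=10))
        assert segment_scores(scores, 1.0).n_clusters == 11

    def test_monotone_in_theta(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            scores = list(rng.uniform(0, 1, size=rng.integers(1, 15)))
            prev_switches, prev_mean = -1, np.inf
            for theta in THETA_GRID:
                cl = segment_scores(scores, float(theta))
                mean_size = np.mean(cl.sizes)
                assert cl.switches >= prev_switches
                assert mean_size <= prev_mean
                prev_switches, prev_mean = cl.switches, mean_size

    def test_matches_threshold_scan_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            n = rng.integers(2, 9)
            cosines = list(np.round(rng.uniform(-0.9, 0.99, size=n - 1), 3))
            words, model = chain_model(cosines)
            theta = float(rng.uniform(0, 1))
            cl = identify_relatedness_clusters(words, model, ThresholdConfig(theta))
            join = [c > theta for c in cosines]
            assert [(c.start, c.end) for c in cl.clusters] == brute_adjacency_segments(join)


class TestSweepAndGrid:
    def test_separable_scores_recover_a_separating_theta(self):
        rng = np.random.default_rng(12)
        scores = list(rng.uniform(0.8, 1.0, 40)) + list(rng.uniform(0.0, 0.2, 60))
        labels = [True] * 40 + [False] * 60
        theta, score, table = sweep_thresholds(scores, labels)
        assert 0.20 < theta <= 0.80
        assert score == 1.0
        assert len(table) == 101

    def test_default_lattice_has_twelve_combinations(self):
        grid = default_grid()
        assert len(grid) == 12
        assert {g.dimensions for g in grid} == {200, 500, 1000}
        assert {g.window for g in grid} == {4, 10}
        assert {g.algorithm for g in grid} == {"cbow", "skipgram"}

    def test_single_combination_grid_returns_it(self):
        from vftclust import ToyCorpusSpec, gen_toy_corpus, toy_themes

        lex = toy_lexicon("en")
        corpus = gen_toy_corpus(
            ToyCorpusSpec(themes=toy_themes("en"), sentences_per_theme=30,
                          sentence_length=6, cross_theme_rate=0.05, seed=5)
        )
        cfg = EmbeddingConfig(dimensions=8, window=2, min_count=1, epochs=2)
        res = grid_search(corpus, lex, grid=[cfg], n_pairs=30, seed=3)
        assert res.best_config.dimensions == 8
        assert res.best_config.algorithm == "skipgram"
        assert len(res.table) == 101

    def test_oov_pairs_are_dropped_and_counted(self, tiny_model):
        pairs = [("a", "b", False), ("a", "zz", True), ("b", "c", True)]
        scores, labels, n_oov = evaluate_pair_scores(tiny_model, pairs)
        assert n_oov == 1 and len(scores) == 2 and labels == [False, True]


class TestTraining:
    def test_vocabulary_and_dimension_contract(self):
        corpus = [["a", "b", "c"], ["a", "b"], ["c", "a"]]
        cfg = EmbeddingConfig(dimensions=50, window=2, min_count=1, epochs=1)
        model = train_embeddings(corpus, cfg)
        assert set(model.vocab) == {"a", "b", "c"}
        assert model.vectors.shape == (3, 50)

    def test_min_count_prunes_rare_words(self):
        corpus = [["a", "a", "b"]] * 3 + [["rare", "a"]]
        cfg = EmbeddingConfig(dimensions=8, window=2, min_count=2, epochs=1)
        assert "rare" not in train_embeddings(corpus, cfg).vocab

    def test_same_seed_bitwise_identical(self):
        corpus = [["a", "b", "c", "d"], ["b", "d", "a"]] * 10
        cfg = EmbeddingConfig(dimensions=16, window=3, min_count=1, epochs=2, seed=99)
        m1, m2 = train_embeddings(corpus, cfg), train_embeddings(corpus, cfg)
        assert np.array_equal(m1.vectors, m2.vectors)
        assert m1.vocab == m2.vocab

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            train_embeddings([], EmbeddingConfig(dimensions=8))

    @pytest.mark.parametrize("algorithm", ["skipgram", "cbow"])
    def test_both_algorithms_train(self, algorithm):
        corpus = [["x", "y", "z"], ["y", "x"]] * 5
        cfg = EmbeddingConfig(dimensions=8, window=2, algorithm=algorithm,
                              min_count=1, epochs=1)
        assert train_embeddings(corpus, cfg).dim == 8


class TestWord2VecText:
    def test_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "m.vec"
        save_word2vec_text(tiny_model, path)
        loaded = load_word2vec_text(path)
        assert loaded.vocab == tiny_model.vocab
        assert np.array_equal(loaded.vectors, tiny_model.vectors)

    def test_gzip_round_trip(self, tmp_path, tiny_model):
        path = tmp_path / "m.vec.gz"
        save_word2vec_text(tiny_model, path)
        assert load_word2vec_text(path).vocab == tiny_model.vocab

    def test_arity_mismatch_names_line(self, tmp_path):
        path = tmp_path / "bad.vec"
        path.write_text("2 3\na 0.1 0.2 0.3\nb 0.1 0.2\n")
        with pytest.raises(ValueError, match="line 3"):
            load_word2vec_text(path)

    def test_bad_header_rejected(self, tmp_path):
        path = tmp_path / "bad.vec"
        path.write_text("nonsense\n")
        with pytest.raises(ValueError, match="header"):
            load_word2vec_text(path)
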