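import numpy as np
import pytest

from oracles import (
    brute_adjacency_segments,
    brute_first_two_letters,
    brute_one_vowel_difference,
    brute_rhyme,
)
from vftclust import (
    CategoryLexicon,
    PhonematicRuleConfig,
    WordToken,
    identify_list_clusters,
    identify_rule_clusters,
    rule_match,
    rule_usage_census,
)


class TestRuleMatch:
    @pytest.mark.parametrize(
        "w1,w2,rule",
        [
            ("summer", "sunday", "first_two_letters"),
            ("sand", "stand", "rhyme"),
            ("sat", "seat", "one_vowel_difference"),
        ],
    )
    def test_canonical_pairs(self, w1, w2, rule):
        assert rule in rule_match(w1, w2)

    def test_identical_word_matches_rule_one(self):
        assert "first_two_letters" in rule_match("sun", "sun")

    def test_one_letter_words_never_match_rule_one(self):
        assert "first_two_letters" not in rule_match("a", "a")

    def test_unrelated_words_match_nothing(self):
        assert rule_match("tiger", "sonne") == frozenset()

    def test_homonym_requires_both_indications(self):
        assert "homonym" not in rule_match("some", "sum")
        assert "homonym" in rule_match(
            "some", "sum", homonym_indicated=(True, True)
        )
        assert "homonym" not in rule_match(
            "some", "sum", homonym_indicated=(True, False)
        )

    def test_homonym_table_restricts_matches(self):
        cfg = PhonematicRuleConfig(homonym_table={"some": "sVm", "sum": "sVm", "son": "sOn"})
        assert "homonym" in rule_match("some", "sum", cfg, (True, True))
        assert "homonym" not in rule_match("some", "son", cfg, (True, True))

    def test_disabled_rules_never_fire(self):
        cfg = PhonematicRuleConfig(rules=frozenset({"rhyme"}))
        assert rule_match("summer", "sunday", cfg) == frozenset()

    def test_at_least_one_rule_required(self):
        with pytest.raises(ValueError):
            PhonematicRuleConfig(rules=frozenset())

    def test_rules_agree_with_independent_reimplementation(self):
        rng = np.random.default_rng(7)
        letters = list("sateionrd")
        for _ in range(300):
            w1 = "".join(rng.choice(letters, size=rng.integers(1, 7)))
            w2 = "".join(rng.choice(letters, size=rng.integers(1, 7)))
            got = rule_match(w1, w2)
            assert ("first_two_letters" in got) == brute_first_two_letters(w1, w2)
            assert ("rhyme" in got) == brute_rhyme(w1, w2)
            assert ("one_vowel_difference" in got) == brute_one_vowel_difference(w1, w2)


class TestRuleClusters:
    def test_shared_prefix_triplet_is_one_cluster(self):
        cl = identify_rule_clusters(["simple", "simulate", "silly"])
        assert cl.n_clusters == 1 and cl.sizes == [2] and cl.switches == 0

    def test_single_word_is_a_singleton(self):
        cl = identify_rule_clusters(["sun"])
        assert cl.sizes == [0] and cl.switches == 0

    def test_mixed_sequence_segments_correctly(self):
        cl = identify_rule_clusters(["summer", "sat", "seat", "tiger"])
        assert [(c.start, c.end) for c in cl.clusters] == [(0, 1), (1, 3), (3, 4)]

    def test_homonym_annotation_joins_tokens(self):
        toks = [
            WordToken("some", flags=frozenset({"homonym_indicated"})),
            WordToken("sum", flags=frozenset({"homonym_indicated"})),
        ]
        cl = identify_rule_clusters(toks)
        assert cl.n_clusters == 1 and "homonym" in cl.links[0]

    def test_partition_identities_hold(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            words = [
                "".join(rng.choice(list("saeto"), size=rng.integers(1, 6)))
                for _ in range(rng.integers(1, 12))
            ]
            cl = identify_rule_clusters(words)
            assert sum(s + 1 for s in cl.sizes) == cl.n_tokens == len(words)
            assert cl.switches == cl.n_clusters - 1

    def test_rule_one_only_equals_prefix_bigram_oracle(self):
        rng = np.random.default_rng(9)
        cfg = PhonematicRuleConfig(rules=frozenset({"first_two_letters"}))
        for _ in range(100):
            words = [
                "".join(rng.choice(list("sta"), size=rng.integers(2, 5)))
                for _ in range(rng.integers(1, 10))
            ]
            cl = identify_rule_clusters(words, cfg)
            join = [words[i][:2] == words[i + 1][:2] for i in range(len(words) - 1)]
            assert [(c.start, c.end) for c in cl.clusters] == brute_adjacency_segments(join)


class TestListClusters:
    def test_common_list_pair_forms_cluster(self, animal_lexicon):
        cl = identify_list_clusters(["dog", "parrot"], animal_lexicon)
        assert cl.n_clusters == 1 and cl.sizes == [1]

    def test_disjoint_categories_give_singletons(self, animal_lexicon):
        cl = identify_list_clusters(["dog", "lion", "shark"], animal_lexicon)
        assert cl.sizes == [0, 0, 0]

    def test_chaining_links_through_shared_member(self, animal_lexicon):
        # dog-parrot share pet, parrot-eagle share bird: chained into one
        cl = identify_list_clusters(["dog", "parrot", "eagle"], animal_lexicon)
        assert cl.n_clusters == 1 and cl.sizes == [2]

    def test_whole_cluster_reading_splits_the_chain(self, animal_lexicon):
        cl = identify_list_clusters(
            ["dog", "parrot", "eagle"], animal_lexicon, whole_cluster_common_list=True
        )
        assert [(c.start, c.end) for c in cl.clusters] == [(0, 2), (2, 3)]

    def test_single_shared_category_yields_one_cluster(self):
        lex = CategoryLexicon({w: {"all"} for w in ("a", "b", "c", "d")})
        cl = identify_list_clusters(["a", "b", "c", "d"], lex)
        assert cl.n_clusters == 1

    def test_empty_input_is_empty_clustering(self, animal_lexicon):
        cl = identify_list_clusters([], animal_lexicon)
        assert cl.n_tokens == 0 and cl.n_clusters == 0

    def test_matches_explicit_adjacency_oracle(self, animal_lexicon):
        rng = np.random.default_rng(21)
        vocab = animal_lexicon.words + ["unicorn"]
        for _ in range(100):
            words = [vocab[i] for i in rng.integers(0, len(vocab), size=rng.integers(1, 9))]
            cl = identify_list_clusters(words, animal_lexicon)
            join = [
                bool(animal_lexicon.get(words[i]) & animal_lexicon.get(words[i + 1]))
                for i in range(len(words) - 1)
            ]
            assert [(c.start, c.end) for c in cl.clusters] == brute_adjacency_segments(join)


class TestCensus:
    def test_counts_matched_pairs_per_rule(self):
        cls = [
            # three pairs joined by the first-two-letters rule only
            identify_rule_clusters(["summer", "sunday"]),
            identify_rule_clusters(["student", "stark"]),
            identify_rule_clusters(["tiger", "tinte"]),
            # one pair joined by the rhyme rule only
            identify_rule_clusters(["sand", "stand"]),
        ]
        counts = rule_usage_census(cls)
        assert counts["first_two_letters"] == 3
        assert counts["rhyme"] == 1
        assert counts["one_vowel_difference"] == 0
        assert counts["homonym"] == 0

    def test_corpus_without_matches_counts_zero(self):
        cls = [identify_rule_clusters(["tiger", "sonne"])]
        assert all(v == 0 for v in rule_usage_census(cls).values())

    def test_disjoint_rules_partition_joined_pairs(self):
        cls = [
            identify_rule_clusters(["summer", "sunday"]),
            identify_rule_clusters(["sand", "stand"]),
        ]
        counts = rule_usage_census(cls)
        joined = sum(1 for cl in cls for link in cl.links if link)
        assert sum(counts.values()) == joined

    def test_rejects_non_rule_based_clusterings(self, animal_lexicon):
        cl = identify_list_clusters(["dog"], animal_lexicon)
        with pytest.raises(ValueError):
            rule_usage_census([cl])
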