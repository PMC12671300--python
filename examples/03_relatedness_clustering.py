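"""Semantic relatedness clustering with a freshly trained toy model.

Trains skip-gram embeddings on a synthetic two-theme corpus (pets vs
African animals), then segments a word sequence wherever the cosine
relatedness of an adjacent pair drops to the task threshold (0.40 for
the semantic task) or below.
"""

from vftclust import (
    EmbeddingConfig,
    ThresholdConfig,
    ToyCorpusSpec,
    gen_toy_corpus,
    identify_relatedness_clusters,
    sequential_relatedness,
    toy_themes,
    train_embeddings,
)

themes = {k: v for k, v in toy_themes("en").items() if k in ("pets", "africa")}
corpus = gen_toy_corpus(ToyCorpusSpec(themes=themes, sentences_per_theme=400,
                                      sentence_length=8, cross_theme_rate=0.05,
                                      seed=3))
model = train_embeddings(
    corpus,
    EmbeddingConfig(dimensions=32, window=4, algorithm="skipgram",
                    min_count=1, epochs=3, seed=7),
)
print(f"trained {len(model.vocab)} words, {model.dim} dimensions")

words = ["dog", "cat", "hamster", "lion", "giraffe", "rabbit", "parrot"]
for (w1, w2), s in zip(zip(words, words[1:]),
                       sequential_relatedness(words, model)):
    print(f"  {w1:8s} - {w2:8s} relatedness {s.value:+.2f}")

clustering = identify_relatedness_clusters(words, model, ThresholdConfig(0.40))
print("clusters:", [words[c.start:c.end] for c in clustering.clusters])
print(f"switches: {clustering.switches}")
# Adjacent within-theme pairs score near +1 and chain into clusters; the
# pet->Africa and Africa->pet transitions fall below 0.40 and register
# as switches.
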