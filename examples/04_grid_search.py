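"""Hyperparameter grid search supervised by category-list membership.

Random word pairs are drawn from a category lexicon and labelled by
whether they share a list; for each hyperparameter combination a model
is trained and the relatedness threshold theta is swept from 0 to 1 in
steps of 0.01, scoring each theta by balanced accuracy of the
same-list-iff-relatedness-above-theta classifier.  No transcript data
enters model selection, which prevents overfitting to patients.
"""

from vftclust import (
    EmbeddingConfig,
    ToyCorpusSpec,
    default_grid,
    gen_toy_corpus,
    grid_search,
    toy_lexicon,
    toy_themes,
)

corpus = gen_toy_corpus(ToyCorpusSpec(themes=toy_themes("en"),
                                      sentences_per_theme=150,
                                      sentence_length=6, cross_theme_rate=0.05,
                                      seed=11))
print(f"default lattice: {len(default_grid())} combinations "
      "(dims 200/500/1000 x windows 4/10 x cbow/skip-gram)")

# a reduced lattice suits the toy corpus; the full default lattice is for
# real corpora
small_grid = [
    EmbeddingConfig(dimensions=d, window=4, algorithm=a, min_count=1, epochs=2)
    for d in (16, 32) for a in ("cbow", "skipgram")
]
result = grid_search(corpus, toy_lexicon("en"), grid=small_grid,
                     n_pairs=150, seed=5)
best = result.best_config
print(f"best: dim={best.dimensions} window={best.window} algo={best.algorithm}")
print(f"best theta={result.best_theta:.2f} "
      f"balanced accuracy={result.best_score:.3f} "
      f"({result.n_oov_pairs} OOV pairs dropped)")
# The sweep returns the threshold separating same-list from
# different-list pairs best; on this well-separated toy corpus the
# balanced accuracy approaches 1.
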