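# vftclust

Automated cluster analysis of verbal fluency task (VFT) transcripts.

In a VFT a person produces as many words as possible in 60 seconds for a
cue — a semantic category ("animals") or an initial letter ("S").
Beyond the total word count, the *clustering* of the produced sequence
carries clinical signal: people emit runs of related words (clusters)
and jump between them (switches), and switch counts track executive
function while cluster sizes relate to language function.  This package
computes those cluster characteristics for clinical-neuropsychology and
digital-biomarker research, three ways:

1. **List-based clustering** (semantic task): consecutive words that
   occur on at least one common thematic word list (e.g. *parrot* is on
   both the "pet" and "bird" lists) join a cluster.
2. **Rule-based clustering** (phonematic task): consecutive words that
   satisfy at least one of the four Troyer phonematic rules — same first
   two letters (*summer*/*Sunday*), rhyme (*sand*/*stand*), a single
   differing vowel sound (*sat*/*seat*), or indicated homonyms
   (*some*/*sum*).
3. **Semantic relatedness clustering** (both tasks): each word is a
   vector in a word2vec embedding space; the relatedness of words
   *w₁, w₂* is cos(v₁, v₂), and a cluster is a maximal run in which
   every sequential pair satisfies cos(vᵢ, vᵢ₊₁) > θ, with θ = 0.40 for
   the semantic and θ = 0.30 for the phonematic task by default.

For every clustering, cluster size = words in the cluster − 1
(singletons count, with size 0), switches = number of clusters − 1, and
mean cluster size therefore satisfies the identity
`mean_size = n_tokens / (switches + 1) − 1`.  Rule violations
(repetitions, same-stem words, proper names) stay in the clustered
sequence but are removed from the total word count; transcripts with
more than 25% violations, or no word within the first 10 seconds, are
excluded.  The package also measures automatic-speech-recognition error
as a word-level normalized Levenshtein distance, selects embedding
hyperparameters and θ by a grid search supervised only by category-list
membership of random word pairs (never by patient data), and relates
cluster characteristics to neuropsychological scores with Pearson /
Spearman correlations, Mann-Whitney U tests, and a filtered correlation
network.

Embedding training is a compact, single-threaded, bit-reproducible
word2vec implementation (skip-gram and CBOW with negative sampling);
pretrained vectors in the standard word2vec text format can be loaded
instead for corpus-scale models.

## Worked example

`examples/` contains one narrative script per capability.  For instance
`python examples/02_traditional_clustering.py` prints:

```
semantic clusters: [['dog', 'cat', 'parrot', 'eagle'], ['lion', 'giraffe']]
total=6 mean_cluster_size=2.00 switches=1
phonematic clusters: [['simple', 'simulate', 'silly'], ['sand', 'stand'], ['tiger']]
sand/stand matched by: ['rhyme']
```

dog–cat–parrot–eagle chain into one cluster of four words (size 3)
because each adjacent pair shares a list, lion–giraffe form a second
cluster (size 1), so the mean cluster size is 2.0 and one switch
occurred.  In the phonematic sequence, the first three words share
their first two letters, *sand*/*stand* rhyme, and *tiger* is a
singleton.  `examples/03_relatedness_clustering.py` trains a toy
embedding model and shows the per-pair cosines that drive the
threshold segmentation, and `examples/06_full_pipeline.py` runs the
whole QC → clustering → metrics pipeline with a manifest.

A thin command line mirrors the library:

```sh
vft simulate corpus --seed 1 -o corpus.txt
vft train-model --corpus corpus.txt --dim 32 --window 4 --min-count 1 -o model.vec
vft cluster transcripts.jsonl --method relatedness --model model.vec
vft run transcripts.jsonl --config run.yaml
```

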