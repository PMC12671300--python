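# Methods

## Transcript model and normalization

A transcript is an ordered sequence of word tokens with optional onset
times (seconds from task start) and annotation flags.  All lookups —
repetition detection, lexicon membership, embedding vocabulary — use a
single normalization policy: Unicode NFC, casefold, surrounding
whitespace stripped.  Umlauts are preserved because German lexicon and
embedding keys need them; casefold maps ß→ss, which is harmless for
matching.  Embedding lookup additionally tries a capitalized variant of
the normalized form before declaring a word out of vocabulary, because
German nouns are capitalized in typical training corpora.

## Rule violations and quality control

Task instructions disallow repetitions, words sharing a stem with an
earlier word, and proper names.  Repetitions are auto-detected by exact
recurrence of the normalized form.  Same-stem and proper-name detection
require external resources (a word→stem map, a name list); when absent,
those detectors are disabled and the package relies on pre-set flags,
replicating a manual-annotation pathway.  In phonematic transcripts,
words not starting with the cue letter are additionally flagged as
violations (`cue_mismatch`); this reading of "rule violation" is
configurable off because protocols differ on it.

A transcript is excluded when strictly more than 25% of its tokens are
violations (25.0% exactly is retained), when onsets are present but no
word starts before 10.0 s ("within the first ten seconds" is read as a
strict before; a first onset at exactly 10.0 s excludes), or when it is
empty.  When no onsets are recorded the 10-second rule is skipped and
logged.  QC depends only on flags and onsets, never on surfaces, and is
idempotent.

## Word-level error rate

The error rate of an automatic transcription against the corrected word
list is the word-level Levenshtein distance (unit-cost insertions,
deletions, substitutions on normalized tokens, computed by dynamic
programming with a backtrace to split the distance into operation
counts) divided by the length of the corrected list.  The normalized
value is 0 exactly when the lists match and can exceed 1 when the
automatic transcript is much longer than the corrected one.

## Clustering conventions shared by all methods

Cluster size is the number of words in the cluster minus one, so a
singleton has size 0 and contributes to the mean.  Switches equal the
number of clusters (singletons included) minus one.  Hence
`mean_cluster_size = n_tokens/(switches+1) − 1` holds exactly, and the
test suite enforces it as an invariant.  Violation tokens remain in the
clustered sequence (consistent with the Troyer protocol) but are
removed from the total word count; both conventions are enforced at the
metrics layer, so the clustering functions see the full sequence.
For an empty transcript, mean cluster size and switches are reported as
absent rather than 0, so summaries are not diluted by fake zeros.

Both traditional methods and the relatedness method join clusters by
**adjacent-pair chaining**: positions i and i+1 belong to one cluster
iff the pair satisfies the method's criterion, and maximal joined runs
form clusters.  For list-based clustering a stricter reading — one list
common to *all* words of the cluster — is available via
`whole_cluster_common_list=True`; chaining is the default because it
makes the three methods structurally identical and is the only reading
possible for the relatedness method.

## Phonematic rules and the grapheme phonetizer

Rule 1 compares the first two normalized characters (words shorter than
two characters never match).  Rules 2 and 3 are pronunciation-based in
the original protocol; automating them faithfully would require a
phonetic transcription backend, so the default here is a transparent
deterministic grapheme heuristic (with the backend pluggable for true
phonetics): vowel groups are maximal runs of {a, e, i, o, u, ä, ö, ü,
y}; two words rhyme when the suffixes starting at the onset of their
final vowel groups are identical (*sand*/*stand* → "and"); they differ
in one vowel when their consonant-run structures are identical and
exactly one vowel group differs (*sat*/*seat*).  The heuristic
over-accepts some orthographic rhymes that are not phonetic rhymes and
misses rhymes spelled differently; this is a documented trade-off for
exact, reproducible tests.  Rule 4 (homonyms) is annotation-driven: it
fires only when both tokens carry the `homonym_indicated` flag, and an
optional homonym table (word → pronunciation key) can further restrict
matches.  There is no automatic sense detection.

## Embedding training

`vftclust.word2vec` is a compact word2vec implementation: skip-gram and
CBOW objectives with negative sampling (5 negatives), a unigram^0.75
noise distribution, per-position dynamic window shrinking, and a
linearly decaying learning rate (0.025 → 1e-4).  It is single-threaded
on purpose: given a fixed seed, two runs produce bit-identical vectors,
which matters for auditable clinical pipelines (multi-worker word2vec
training is inherently non-deterministic).  Vocabulary ordering is by
descending frequency then alphabetical, so it is deterministic too.
The trainer is adequate for corpora up to a few hundred thousand
tokens; corpus-scale models (e.g. Wikipedia) should be trained
externally and loaded via the standard word2vec text format
(`load_word2vec_text`, gzip supported).

Defaults: 500 dimensions, window 10, skip-gram — the configuration
selected by grid search for both tasks.  `min_count` (5) and `epochs`
(5) follow common word2vec practice; both are configurable and recorded
in model metadata.

## Relatedness clustering and thresholds

Relatedness is the cosine of the two word vectors, in [−1, 1].  A pair
joins a cluster iff its score is defined and **strictly greater** than
θ; defaults θ = 0.40 (semantic task) and θ = 0.30 (phonematic task).
Out-of-vocabulary policy: OOV pairs never join, are excluded from the
mean sequential relatedness, and are counted and reported — scoring
them 0 would silently bias the mean downward.  The mean sequential
relatedness is the plain mean of the defined scores over all adjacent
pairs of the full sequence (violation words included).

## Grid search

Hyperparameters are chosen without touching transcript data: random
unordered word pairs are drawn uniformly without replacement from the
category lexicon and labelled by shared-list membership; for each
lattice cell (default 3 dimensionalities × 2 windows × 2 algorithms =
12 combinations) a model is trained and θ is swept over {0.00, 0.01,
…, 1.00}, classifying a pair as same-list iff score > θ.  The selection
metric is balanced accuracy by default (robust to the unbalanced class
counts random sampling produces; plain accuracy and F1 are available).
When several θ tie on the best score — a plateau, typical for
well-separated classes — the middle θ of the plateau is returned, since
a threshold deep inside the plateau transfers better to new pairs than
one at its edge.  Pair sampling is unbalanced by default, mirroring
plain random draws; a balanced mode exists.  Per-combination training
seeds are derived deterministically from the search seed.

## Association statistics

Pearson correlation (two-sided p from the t transform, n−2 df) is the
default; Spearman uses midranks; Mann-Whitney U uses exact enumeration
for tie-free samples of ≤8 per group and the tie-corrected normal
approximation otherwise.  All three delegate to scipy.stats behind the
module surface; independent brute-force implementations exist in the
test suite as oracles.  Missing scores are handled by pairwise-complete
deletion, so n varies per cell.  P values are unadjusted by default (an
optional Benjamini-Hochberg mode is provided).  The correlation network
keeps edges with p < α (default 0.05), never computes test-test edges,
drops tests with no surviving link to a cluster characteristic, and
keeps characteristic-characteristic edges unlabeled; edge weight is
|r|.

## Synthetic data: what it emulates and what it does not

The generators stand in for two things that cannot ship with the
package: a corpus-scale training text and patient recordings.

* `gen_toy_corpus` produces sentences drawn within one theme, with each
  token replaced by a word from another theme at a small cross-theme
  rate (default 0.05, so theme structure dominates but is not
  noise-free).  Defaults (500 sentences per theme, 8 tokens per
  sentence) give a corpus a 16–50-dimensional model separates cleanly
  within seconds.
* `gen_transcript` realizes a requested cluster-size sequence by
  drawing consecutive clusters from different themes (so adjacent
  planted clusters cannot accidentally merge), injects violations as
  repetitions of earlier words, and attaches onsets with word gaps
  uniform in 0.8–2.5 s starting near 1.5 s — roughly the pace of a
  fluent speaker.  The ground-truth clustering is returned alongside.
* `corrupt_asr` applies insertions/deletions/substitutions i.i.d. per
  word at a configurable rate.
* `gen_score_table` creates participant score tables; planted
  associations are generated as scaled driver plus Gaussian noise so a
  target correlation is recovered in expectation.

What passing tests on these fixtures shows: the machinery — QC
boundaries, segmentation logic, metric identities, threshold sweep,
training reproducibility, statistical plumbing — is correct.  What it
does not show: that real fluency transcripts separate as cleanly as the
toy themes (real corpora give graded cosines, not ±1), that the toy
thresholds transfer to corpus-scale embeddings, or anything about
clinical validity.  Patient-level results require real recordings and a
corpus-scale model.

## Numerical and size choices

Verification problem sizes (thousands of random instances for oracle
checks, 600 sentences/theme and 32 dimensions for the trained-model
checks) were chosen so the whole suite and the acceptance script each
run in well under a minute on one CPU while exercising every code path;
they are not statistical power choices.  Floating-point comparisons in
tests use absolute tolerances around 1e-9 where exact agreement is
expected from identical arithmetic, and exact equality for integer
quantities.  CSV outputs use `%.10g` float formatting so reruns are
byte-identical.

## Known limitations

* The grapheme phonetizer is orthographic, not phonetic; languages with
  deep orthographies will mis-rate some rhymes (pluggable backend).
* The built-in trainer is not meant for corpus-scale text; use
  externally trained vectors for that.
* Homonym clustering requires explicit annotation.
* The 10-second rule needs onsets; ASR exports without timestamps skip
  it.
* Mean sequential relatedness includes pairs involving violation words,
  consistent with computing it over all sequential pairs; protocols
  that strip violations first will differ slightly.
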