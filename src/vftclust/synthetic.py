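"""Synthetic data generation for end-to-end testing without downloads.

Real studies train the relatedness model on Wikipedia-scale text and
analyze patient recordings; neither is redistributable here.  This module
generates structurally analogous stand-ins: toy training corpora in which
words of one theme co-occur within sentences, fluency transcripts with a
planted cluster/switch structure plus injected rule violations, ASR-style
word corruption, and synthetic neuropsychological score tables.  Every
generator is a pure function of its spec and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clusters import Cluster, Clustering
from .lexicon import CategoryLexicon
from .transcripts import Transcript, WordToken

__all__ = [
    "ToyCorpusSpec",
    "PlantedTranscriptSpec",
    "toy_themes",
    "toy_lexicon",
    "gen_toy_corpus",
    "gen_transcript",
    "corrupt_asr",
    "gen_score_table",
]

# Small bilingual theme vocabularies so the German normalization path
# (umlauts, capitalization fallback) is exercised without external data.
_THEMES = {
    "en": {
        "pets": ["dog", "cat", "hamster", "parrot", "rabbit", "goldfish",
                 "guinea", "budgie", "kitten", "puppy"],
        "africa": ["lion", "elephant", "giraffe", "zebra", "hippo", "rhino",
                   "cheetah", "antelope", "hyena", "buffalo"],
        "birds": ["parrot", "eagle", "sparrow", "owl", "falcon", "stork",
                  "heron", "budgie", "crow", "swan"],
        "water": ["shark", "dolphin", "whale", "trout", "salmon", "seal",
                  "octopus", "crab", "goldfish", "herring"],
    },
    "de": {
        "haustiere": ["hund", "katze", "hamster", "papagei", "kaninchen",
                      "goldfisch", "meerschweinchen", "wellensittich",
                      "kätzchen", "welpe"],
        "afrika": ["löwe", "elefant", "giraffe", "zebra", "nilpferd",
                   "nashorn", "gepard", "antilope", "hyäne", "büffel"],
        "vögel": ["papagei", "adler", "spatz", "eule", "falke", "storch",
                  "reiher", "wellensittich", "krähe", "schwan"],
        "wasser": ["hai", "delfin", "wal", "forelle", "lachs", "robbe",
                   "krake", "krabbe", "goldfisch", "hering"],
    },
}


def toy_themes(language: str = "en") -> dict[str, list[str]]:
    """Built-in theme -> word-list map (``en`` or ``de``)."""
    return {k: list(v) for k, v in _THEMES[language].items()}


def toy_lexicon(language: str = "en") -> CategoryLexicon:
    """Category lexicon over the toy themes (shared words get both labels,
    like parrot in pets and birds)."""
    entries: dict[str, set[str]] = {}
    for cat, words in _THEMES[language].items():
        for w in words:
            entries.setdefault(w, set()).add(cat)
    return CategoryLexicon({w: frozenset(c) for w, c in entries.items()})


@dataclass(frozen=True)
class ToyCorpusSpec:
    themes: Mapping[str, Sequence[str]]
    sentences_per_theme: int = 500
    sentence_length: int = 8
    cross_theme_rate: float = 0.05
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.themes or any(not ws for ws in self.themes.values()):
            raise ValueError("themes must be non-empty word lists")
        if not 0.0 <= self.cross_theme_rate <= 1.0:
            raise ValueError("cross_theme_rate must lie in [0, 1]")


def gen_toy_corpus(spec: ToyCorpusSpec) -> list[list[str]]:
    """Sentences drawn within one theme, with each token replaced by a
    word from another theme with probability ``cross_theme_rate``."""
    rng = np.random.default_rng(spec.seed)
    names = sorted(spec.themes)
    pools = {t: list(spec.themes[t]) for t in names}
    sentences = []
    for theme in names:
        others = [w for t in names if t != theme for w in pools[t]]
        for _ in range(spec.sentences_per_theme):
            sent = []
            for _ in range(spec.sentence_length):
                if others and rng.random() < spec.cross_theme_rate:
                    sent.append(others[rng.integers(len(others))])
                else:
                    sent.append(pools[theme][rng.integers(len(pools[theme]))])
            sentences.append(sent)
    order = rng.permutation(len(sentences))
    return [sentences[i] for i in order]


@dataclass(frozen=True)
class PlantedTranscriptSpec:
    cluster_sizes: tuple[int, ...]  # words per planted cluster, each >= 1
    task: str = "semantic"
    cue: str = "animals"
    violation_rate: float = 0.0
    with_onsets: bool = True
    first_onset_s: float = 1.5
    seed: int = 1

    def __post_init__(self) -> None:
        if not self.cluster_sizes or any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster_sizes must be >= 1")
        if not 0.0 <= self.violation_rate <= 1.0:
            raise ValueError("violation_rate must lie in [0, 1]")


def gen_transcript(
    spec: PlantedTranscriptSpec,
    themes: Mapping[str, Sequence[str]],
) -> tuple[Transcript, Clustering]:
    """Generate a transcript realizing the planted cluster structure.

    Consecutive planted clusters draw from different themes, so adjacent
    clusters never accidentally merge under list- or theme-based
    clustering.  Violations are injected as repetitions of an earlier
    word (flagged in the returned transcript and ground truth).  Returns
    the transcript and the planted ground-truth clustering.
    """
    rng = np.random.default_rng(spec.seed)
    names = sorted(themes)
    if len(names) < 2 and len(spec.cluster_sizes) > 1:
        raise ValueError("need at least 2 themes to alternate between clusters")
    words: list[str] = []
    boundaries: list[int] = [0]
    prev_theme: str | None = None
    for size in spec.cluster_sizes:
        choices = [t for t in names if t != prev_theme]
        theme = choices[rng.integers(len(choices))]
        pool = [w for w in themes[theme] if w not in words]
        if len(pool) < size:
            raise ValueError(f"theme {theme!r} has too few unused words for size {size}")
        picks = rng.choice(len(pool), size=size, replace=False)
        words.extend(pool[int(i)] for i in picks)
        boundaries.append(len(words))
        prev_theme = theme

    flags: list[frozenset[str]] = [frozenset()] * len(words)
    if spec.violation_rate > 0 and len(words) > 1:
        for i in range(1, len(words)):
            if rng.random() < spec.violation_rate:
                words[i] = words[rng.integers(i)]
                flags[i] = frozenset({"repetition"})

    onsets: list[float | None]
    if spec.with_onsets:
        gaps = rng.uniform(0.8, 2.5, size=len(words))
        t = spec.first_onset_s
        onsets = []
        for g in gaps:
            onsets.append(round(t, 2))
            t += g
    else:
        onsets = [None] * len(words)

    tokens = tuple(
        WordToken(surface=w, onset_s=o, flags=f)
        for w, o, f in zip(words, onsets, flags)
    )
    transcript = Transcript(
        task=spec.task, cue=spec.cue, tokens=tokens,
        transcript_id=f"planted-{spec.seed}",
    )
    clusters = tuple(
        Cluster(a, b) for a, b in zip(boundaries, boundaries[1:])
    )
    truth = Clustering("planted", clusters, len(words))
    return transcript, truth


def corrupt_asr(
    words: Sequence[str],
    rate: float,
    seed: int,
    operations: Sequence[str] = ("insertion", "deletion", "substitution"),
    noise_vocab: Sequence[str] = ("blur", "noise", "hum", "static", "echo"),
) -> list[str]:
    """Apply ASR-style word errors i.i.d. at the given per-word rate."""
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    for w in words:
        if rng.random() < rate:
            op = operations[rng.integers(len(operations))]
            if op == "deletion":
                continue
            if op == "insertion":
                out.append(w)
                out.append(noise_vocab[rng.integers(len(noise_vocab))])
                continue
            out.append(noise_vocab[rng.integers(len(noise_vocab))])
        else:
            out.append(w)
    return out


DEFAULT_TESTS = ("MoCA", "FAB", "TMT_B", "BNT", "MWT")


def gen_score_table(
    n_participants: int,
    seed: int,
    tests: Sequence[str] = DEFAULT_TESTS,
    driver: Sequence[float] | None = None,
    planted: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Synthetic neuropsychological score table (wide, participant-indexed).

    With ``driver`` (one value per participant, e.g. a cluster metric) and
    ``planted`` (test name -> correlation strength in [-1, 1]), the named
    tests are generated as scaled driver plus noise so that planted
    associations are recoverable; other tests are independent noise.
    """
    rng = np.random.default_rng(seed)
    data = {}
    z = None
    if driver is not None:
        z = np.asarray(driver, dtype=float)
        z = (z - z.mean()) / (z.std() or 1.0)
    for t in tests:
        if planted and z is not None and t in planted:
            r = planted[t]
            noise_sd = np.sqrt(max(1.0 - r * r, 1e-12)) / max(abs(r), 1e-12)
            data[t] = np.sign(r) * z + rng.normal(0, noise_sd, n_participants)
        else:
            data[t] = rng.normal(0, 1, n_participants)
    idx = pd.Index([f"p{i:03d}" for i in range(n_participants)], name="participant_id")
    return pd.DataFrame(data, index=idx)
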