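import numpy as np
import pytest

from vftclust import CategoryLexicon, EmbeddingModel, Transcript, WordToken


@pytest.fixture
def animal_lexicon() -> CategoryLexicon:
    return CategoryLexicon(
        {
            "parrot": {"pet", "bird"},
            "dog": {"pet"},
            "cat": {"pet"},
            "eagle": {"bird"},
            "owl": {"bird"},
            "lion": {"africa"},
            "giraffe": {"africa"},
            "shark": {"water"},
        }
    )


def make_model(vectors: dict[str, list[float]]) -> EmbeddingModel:
    words = list(vectors)
    mat = np.array([vectors[w] for w in words], dtype=float)
    return EmbeddingModel({w: i for i, w in enumerate(words)}, mat)


@pytest.fixture
def tiny_model() -> EmbeddingModel:
    return make_model({"a": [1.0, 0.0], "b": [0.0, 1.0], "c": [1.0, 1.0]})


def transcript_of(words, task="semantic", cue="animals", onsets=None, flags=None):
    n = len(words)
    onsets = onsets if onsets is not None else [None] * n
    flags = flags if flags is not None else [frozenset()] * n
    toks = tuple(
        WordToken(surface=w, onset_s=o, flags=f)
        for w, o, f in zip(words, onsets, flags)
    )
    return Transcript(task=task, cue=cue, tokens=toks, transcript_id="fix")
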