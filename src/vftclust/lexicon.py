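"""Category lexicons: curated thematic word lists (e.g. pets, birds).

Traditional semantic-fluency clustering joins consecutive words that occur
on at least one common list; a word may belong to several lists (parrot is
both a pet and a bird).  The same lexicons supervise the hyperparameter
grid search: random word pairs are labelled by whether they share a list.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._normalize import normalize_word

__all__ = [
    "CategoryLexicon",
    "load_lexicon",
    "save_lexicon",
    "common_categories",
    "sample_supervision_pairs",
]


@dataclass
class CategoryLexicon:
    """Normalized word -> non-empty set of category labels."""

    entries: dict[str, frozenset[str]] = field(default_factory=dict)
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm: dict[str, frozenset[str]] = {}
        for word, cats in self.entries.items():
            cats = frozenset(cats)
            if not cats:
                raise ValueError(f"word {word!r} has no categories")
            norm[normalize_word(word)] = cats
        self.entries = norm

    def __contains__(self, word: str) -> bool:
        return normalize_word(word) in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, word: str) -> frozenset[str]:
        return self.entries.get(normalize_word(word), frozenset())

    @property
    def words(self) -> list[str]:
        return sorted(self.entries)


def common_categories(w1: str, w2: str, lex: CategoryLexicon) -> frozenset[str]:
    """Categories shared by two words; empty for out-of-lexicon words."""
    return lex.get(w1) & lex.get(w2)


def load_lexicon(path, format: str = "csv") -> CategoryLexicon:
    """Load a lexicon from ``word,category`` CSV rows or a ``{word: [cats]}``
    JSON object.  Duplicate rows for one word union their categories."""
    entries: dict[str, set[str]] = {}
    if format == "csv":
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh)
            header = next(reader, None)
            if header is not None and [h.strip().lower() for h in header[:2]] != ["word", "category"]:
                # headerless file: first row is data
                rows = [header]
            else:
                rows = []
            rows.extend(reader)
        for row in rows:
            if not row or not row[0].strip():
                continue
            if len(row) < 2 or not row[1].strip():
                raise ValueError(f"lexicon row {row!r} lacks a category")
            entries.setdefault(normalize_word(row[0]), set()).add(row[1].strip())
    elif format == "json":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        for word, cats in data.items():
            if not cats:
                raise ValueError(f"word {word!r} has no categories")
            entries.setdefault(normalize_word(word), set()).update(cats)
    else:
        raise ValueError(f"unknown format {format!r}")
    return CategoryLexicon({w: frozenset(c) for w, c in entries.items()})


def save_lexicon(lex: CategoryLexicon, path, format: str = "csv") -> None:
    if format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["word", "category"])
            for word in sorted(lex.entries):
                for cat in sorted(lex.entries[word]):
                    writer.writerow([word, cat])
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {w: sorted(c) for w, c in sorted(lex.entries.items())},
                fh, ensure_ascii=False, indent=1,
            )
    else:
        raise ValueError(f"unknown format {format!r}")


def sample_supervision_pairs(
    lex: CategoryLexicon,
    n_pairs: int,
    seed: int,
    balanced: bool = False,
) -> list[tuple[str, str, bool]]:
    """Draw random unordered word pairs labelled by shared list membership.

    Pairs are sampled uniformly without replacement from all distinct
    pairs; ``same_list`` is true when the two words share at least one
    category.  With ``balanced=True`` the positive and negative classes are
    subsampled to equal size (at most ``n_pairs`` total).
    """
    words = sorted(lex.entries)
    if len(words) < 2:
        raise ValueError("lexicon needs at least 2 words to sample pairs")
    total = math.comb(len(words), 2)
    if n_pairs > total:
        raise ValueError(f"requested {n_pairs} pairs but only {total} distinct pairs exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n_pairs, replace=False)
    pairs: list[tuple[str, str, bool]] = []
    for k in sorted(int(i) for i in idx):
        # unrank the k-th pair of the lexicographic pair ordering
        i = int((2 * len(words) - 1 - math.sqrt((2 * len(words) - 1) ** 2 - 8 * k)) // 2)
        j = k - i * (2 * len(words) - i - 1) // 2 + i + 1
        w1, w2 = words[i], words[j]
        pairs.append((w1, w2, bool(common_categories(w1, w2, lex))))
    if balanced:
        pos = [p for p in pairs if p[2]]
        neg = [p for p in pairs if not p[2]]
        m = min(len(pos), len(neg))
        pairs = sorted(pos[:m] + neg[:m])
    rng.shuffle(pairs)
    return pairs
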