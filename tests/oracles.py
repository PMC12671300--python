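"""Independent brute-force oracles used to cross-check the implementation.

These are deliberately written differently from the library code:
recursive edit distance, explicit adjacency scans, direct formula
arithmetic, and O(n*m) pair counting.
"""

from functools import lru_cache

import numpy as np


def brute_levenshtein(a: tuple, b: tuple) -> int:
    """Plain recursive word-level edit distance."""

    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
        )

    return rec(len(a), len(b))


def brute_adjacency_segments(join: list[bool]) -> list[tuple[int, int]]:
    """Explicit scan turning adjacent-pair join flags into [start, end) spans."""
    n = len(join) + 1
    spans = []
    start = 0
    for i, j in enumerate(join):
        if not j:
            spans.append((start, i + 1))
            start = i + 1
    spans.append((start, n))
    return spans


def brute_first_two_letters(w1: str, w2: str) -> bool:
    return len(w1) >= 2 and len(w2) >= 2 and w1[0] == w2[0] and w1[1] == w2[1]


_V = set("aeiouäöüy")


def brute_rhyme(w1: str, w2: str) -> bool:
    def suffix(w: str) -> str | None:
        # scan from the end: find the last vowel, then extend left over vowels
        k = len(w) - 1
        while k >= 0 and w[k] not in _V:
            k -= 1
        if k < 0:
            return None
        end = k
        while k >= 0 and w[k] in _V:
            k -= 1
        return w[k + 1 :]

    s1, s2 = suffix(w1), suffix(w2)
    return s1 is not None and s1 == s2


def brute_one_vowel_difference(w1: str, w2: str) -> bool:
    import re

    def parts(w: str) -> list[str]:
        return [p for p in re.split(f"([{''.join(sorted(_V))}]+)", w) if p]

    p1, p2 = parts(w1), parts(w2)
    if len(p1) != len(p2):
        return False
    diffs = 0
    for a, b in zip(p1, p2):
        av, bv = a[0] in _V, b[0] in _V
        if av != bv:
            return False
        if a != b:
            if not av:
                return False
            diffs += 1
    return diffs == 1


def brute_pearson(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def brute_midranks(x) -> np.ndarray:
    x = np.asarray(x, float)
    ranks = np.empty(len(x))
    for i, v in enumerate(x):
        less = np.sum(x < v)
        equal = np.sum(x == v)
        ranks[i] = less + (equal + 1) / 2.0
    return ranks


def brute_spearman(x, y) -> float:
    return brute_pearson(brute_midranks(x), brute_midranks(y))


def brute_mann_whitney_u(a, b) -> float:
    """U for group a = count of winning pairs plus half-ties."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


def brute_cosine(u, v) -> float:
    u, v = np.asarray(u, float), np.asarray(v, float)
    return float(np.dot(u, v) / (np.sqrt(np.dot(u, u)) * np.sqrt(np.dot(v, v))))
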