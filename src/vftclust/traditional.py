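"""Traditional fluency clustering: list-based (semantic) and rule-based
(phonematic), after Troyer's clustering-and-switching protocol.

List-based clustering joins consecutive words found on at least one common
thematic list.  Rule-based clustering joins consecutive words satisfying
at least one of four phonematic rules: (1) same first two letters,
(2) rhyme, (3) difference in exactly one vowel sound, (4) homonyms when
indicated by the test person.  Rules 2 and 3 are pronunciation-based in
the original protocol; the default backend here is a transparent grapheme
heuristic (documented in docs/methods.md) with a pluggable interface for
true phonetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

from ._normalize import normalize_word
from .clusters import Cluster, Clustering, segment_by_links
from .lexicon import CategoryLexicon, common_categories
from .transcripts import WordToken

__all__ = [
    "PhonematicRuleConfig",
    "ALL_RULES",
    "rule_match",
    "identify_rule_clusters",
    "identify_list_clusters",
    "rule_usage_census",
]

ALL_RULES = ("first_two_letters", "rhyme", "one_vowel_difference", "homonym")

_VOWELS = set("aeiouäöüy")


def _runs(word: str) -> list[tuple[bool, str]]:
    """Split a word into maximal (is_vowel_run, run) segments."""
    runs: list[tuple[bool, str]] = []
    for ch in word:
        is_v = ch in _VOWELS
        if runs and runs[-1][0] == is_v:
            runs[-1] = (is_v, runs[-1][1] + ch)
        else:
            runs.append((is_v, ch))
    return runs


def _rhyme_suffix(word: str) -> str | None:
    """Suffix of the word from the onset of its final vowel group."""
    runs = _runs(word)
    for k in range(len(runs) - 1, -1, -1):
        if runs[k][0]:
            return "".join(r for _, r in runs[k:])
    return None  # no vowels: no rhyme part


def grapheme_rhyme(w1: str, w2: str) -> bool:
    s1, s2 = _rhyme_suffix(w1), _rhyme_suffix(w2)
    return s1 is not None and s1 == s2


def grapheme_one_vowel_difference(w1: str, w2: str) -> bool:
    """True when the words have identical consonant structure and differ in
    exactly one vowel group."""
    r1, r2 = _runs(w1), _runs(w2)
    if len(r1) != len(r2):
        return False
    diffs = 0
    for (v1, s1), (v2, s2) in zip(r1, r2):
        if v1 != v2:
            return False
        if s1 != s2:
            if not v1:  # consonant runs must match exactly
                return False
            diffs += 1
    return diffs == 1


@dataclass(frozen=True)
class PhonematicRuleConfig:
    """Which phonematic rules are enabled and which phonetizer backend
    evaluates the pronunciation-based ones (rhyme, one-vowel-difference)."""

    rules: frozenset[str] = frozenset(ALL_RULES)
    rhyme_fn: Callable[[str, str], bool] = grapheme_rhyme
    vowel_fn: Callable[[str, str], bool] = grapheme_one_vowel_difference
    #: optional word -> pronunciation key; when given, the homonym rule
    #: additionally requires equal keys for the two indicated words
    homonym_table: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        unknown = set(self.rules) - set(ALL_RULES)
        if unknown:
            raise ValueError(f"unknown rules {sorted(unknown)}")
        if not self.rules:
            raise ValueError("at least one rule must be enabled")


def rule_match(
    w1: str,
    w2: str,
    cfg: PhonematicRuleConfig | None = None,
    homonym_indicated: tuple[bool, bool] = (False, False),
) -> frozenset[str]:
    """Return every enabled phonematic rule the word pair satisfies.

    Rule 1 compares the first two normalized characters (words shorter
    than 2 characters never match it).  The homonym rule is
    annotation-driven: it fires only when both tokens were indicated as
    homonyms by the test person.
    """
    cfg = cfg or PhonematicRuleConfig()
    a, b = normalize_word(w1), normalize_word(w2)
    matched = set()
    if "first_two_letters" in cfg.rules and len(a) >= 2 and a[:2] == b[:2]:
        matched.add("first_two_letters")
    if "rhyme" in cfg.rules and cfg.rhyme_fn(a, b):
        matched.add("rhyme")
    if "one_vowel_difference" in cfg.rules and cfg.vowel_fn(a, b):
        matched.add("one_vowel_difference")
    if "homonym" in cfg.rules and all(homonym_indicated):
        if cfg.homonym_table is None or (
            cfg.homonym_table.get(a) is not None
            and cfg.homonym_table.get(a) == cfg.homonym_table.get(b)
        ):
            matched.add("homonym")
    return frozenset(matched)


def _words_and_homonym_flags(
    words: Sequence[str | WordToken],
) -> tuple[list[str], list[bool]]:
    out_w, out_h = [], []
    for w in words:
        if isinstance(w, WordToken):
            out_w.append(w.normalized)
            out_h.append("homonym_indicated" in w.flags)
        else:
            out_w.append(normalize_word(w))
            out_h.append(False)
    return out_w, out_h


def identify_rule_clusters(
    words: Sequence[str | WordToken],
    cfg: PhonematicRuleConfig | None = None,
) -> Clustering:
    """Cluster a phonematic word sequence by adjacent-pair rule matching.

    Adjacent words join one cluster when they satisfy at least one enabled
    rule; maximal joined runs form clusters, the rest are singletons.
    Rule violations stay in the sequence, per the Troyer protocol.
    """
    cfg = cfg or PhonematicRuleConfig()
    ws, homs = _words_and_homonym_flags(words)
    links = [
        rule_match(ws[i], ws[i + 1], cfg, (homs[i], homs[i + 1]))
        for i in range(len(ws) - 1)
    ]
    return segment_by_links("rule_based", links, len(ws))


def identify_list_clusters(
    words: Sequence[str | WordToken],
    lex: CategoryLexicon,
    whole_cluster_common_list: bool = False,
) -> Clustering:
    """Cluster a semantic word sequence by shared thematic-list membership.

    By default adjacent words join when they occur on at least one common
    list and maximal runs are chained into clusters (a run dog, parrot,
    eagle is one cluster even if dog and eagle share no list).  With
    ``whole_cluster_common_list=True`` a cluster is grown only while one
    list is common to *all* its words — the stricter reading.
    """
    ws, _ = _words_and_homonym_flags(words)
    n = len(ws)
    links = [common_categories(ws[i], ws[i + 1], lex) for i in range(n - 1)]
    if not whole_cluster_common_list:
        return segment_by_links("list_based", links, n)
    # stricter reading: maintain the running intersection over the cluster
    clusters: list[Cluster] = []
    eff_links: list[frozenset] = []
    if n > 0:
        start = 0
        running = lex.get(ws[0])
        for i in range(n - 1):
            joint = running & lex.get(ws[i + 1])
            if joint:
                running = joint
                eff_links.append(joint)
            else:
                clusters.append(Cluster(start, i + 1))
                start = i + 1
                running = lex.get(ws[i + 1])
                eff_links.append(frozenset())
        clusters.append(Cluster(start, n))
    return Clustering("list_based", tuple(clusters), n, tuple(eff_links))


def rule_usage_census(clusterings: Sequence[Clustering]) -> dict[str, int]:
    """Count, per phonematic rule, the adjacent word pairs joined by it
    across a corpus of rule-based clusterings.

    A pair joined by several rules increments each matched rule's count.
    """
    counts = {r: 0 for r in ALL_RULES}
    for cl in clusterings:
        if cl.method != "rule_based":
            raise ValueError("census expects rule_based clusterings")
        for link in cl.links:
            for rule in link:
                counts[rule] += 1
    return counts
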