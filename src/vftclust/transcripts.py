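"""Verbal fluency transcript data model, QC and error-rate computation.

A verbal fluency task (VFT) transcript is an ordered list of produced
words, optionally with per-word onset times (seconds from task start) and
violation annotations.  Task instructions disallow word repetitions, words
sharing a stem with an earlier word, and proper names; such words are
*rule violations*.  Transcripts with more than 25% violations, or with no
word produced in the first 10 seconds, are excluded from analysis.

The module also computes the word-level error rate of an automatic
transcription against a manually corrected word list, as a normalized
Levenshtein distance (insertions + deletions + substitutions divided by
the length of the correct list).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from ._normalize import normalize_word

logger = logging.getLogger(__name__)

__all__ = [
    "WordToken",
    "Transcript",
    "QCResult",
    "ErrorRateResult",
    "VIOLATION_FLAGS",
    "mark_violations",
    "qc_transcript",
    "word_error_rate",
    "read_transcripts",
    "write_transcripts",
]

#: Flags that count as rule violations.  ``homonym_indicated`` is an
#: annotation used by phonematic rule 4 and is *not* a violation.
VIOLATION_FLAGS = frozenset({"repetition", "same_stem", "proper_name", "cue_mismatch"})

_KNOWN_FLAGS = VIOLATION_FLAGS | {"homonym_indicated"}


class TranscriptFormatError(ValueError):
    """Raised for malformed transcript files; carries line/field context."""


@dataclass(frozen=True)
class WordToken:
    """One produced word.

    ``normalized`` is derived from ``surface`` unless given explicitly;
    ``flags`` is a subset of the known annotation flags.
    """

    surface: str
    onset_s: float | None = None
    flags: frozenset[str] = frozenset()
    normalized: str = ""

    def __post_init__(self) -> None:
        if not self.normalized:
            object.__setattr__(self, "normalized", normalize_word(self.surface))
        if self.surface and not self.normalized:
            raise ValueError(f"token {self.surface!r} normalizes to empty string")
        if self.onset_s is not None and self.onset_s < 0:
            raise ValueError(f"negative onset {self.onset_s} for {self.surface!r}")
        unknown = set(self.flags) - _KNOWN_FLAGS
        if unknown:
            raise ValueError(f"unknown flags {sorted(unknown)} on {self.surface!r}")
        object.__setattr__(self, "flags", frozenset(self.flags))

    @property
    def is_violation(self) -> bool:
        return bool(self.flags & VIOLATION_FLAGS)


@dataclass(frozen=True)
class Transcript:
    """An ordered word sequence for one 60-second fluency task run."""

    task: str  # "semantic" or "phonematic"
    cue: str  # category name, or the initial letter for phonematic tasks
    tokens: tuple[WordToken, ...]
    duration_s: float = 60.0
    source: str = "manual"  # "asr" or "manual"
    transcript_id: str = ""

    def __post_init__(self) -> None:
        if self.task not in ("semantic", "phonematic"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.source not in ("asr", "manual"):
            raise ValueError(f"unknown source {self.source!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        object.__setattr__(self, "tokens", tuple(self.tokens))
        onsets = [t.onset_s for t in self.tokens if t.onset_s is not None]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("onset_s values must be non-decreasing")

    @property
    def words(self) -> list[str]:
        """Normalized word sequence (violations included)."""
        return [t.normalized for t in self.tokens]

    def __len__(self) -> int:
        return len(self.tokens)


@dataclass(frozen=True)
class QCResult:
    n_tokens: int
    n_violations: int
    violation_fraction: float
    excluded: bool
    reasons: tuple[str, ...]


@dataclass(frozen=True)
class ErrorRateResult:
    insertions: int
    deletions: int
    substitutions: int
    distance: int
    normalized: float


def mark_violations(
    transcript: Transcript,
    stem_lexicon: Mapping[str, str] | None = None,
    proper_names: Iterable[str] | None = None,
    flag_cue_mismatch: bool = True,
) -> Transcript:
    """Return a copy of *transcript* with violation flags populated.

    Repetitions are auto-detected by exact recurrence of the normalized
    form.  Same-stem violations are only detected when a word->stem map is
    supplied (the later of two tokens sharing a stem is flagged); proper
    names only when a name set is supplied.  Absent resources simply
    disable those detectors, mirroring a manual-annotation pathway where
    such flags arrive pre-set on the tokens.  Pre-existing flags are
    preserved.

    For phonematic transcripts, tokens whose normalized form does not
    start with the cue letter are flagged ``cue_mismatch`` (disable with
    ``flag_cue_mismatch=False``).
    """
    if stem_lexicon is None:
        logger.debug("no stem lexicon supplied; same_stem detection disabled")
    if proper_names is None:
        logger.debug("no proper-name list supplied; proper_name detection disabled")
    names = {normalize_word(w) for w in proper_names} if proper_names else set()
    cue_prefix = normalize_word(transcript.cue) if transcript.task == "phonematic" else ""

    seen_words: set[str] = set()
    seen_stems: set[str] = set()
    out: list[WordToken] = []
    for tok in transcript.tokens:
        flags = set(tok.flags)
        if tok.normalized in seen_words:
            flags.add("repetition")
        if stem_lexicon is not None:
            stem = stem_lexicon.get(tok.normalized)
            if stem is not None:
                if stem in seen_stems:
                    flags.add("same_stem")
                seen_stems.add(stem)
        if tok.normalized in names:
            flags.add("proper_name")
        if (
            flag_cue_mismatch
            and cue_prefix
            and not tok.normalized.startswith(cue_prefix)
        ):
            flags.add("cue_mismatch")
        seen_words.add(tok.normalized)
        out.append(replace(tok, flags=frozenset(flags)))
    return replace(transcript, tokens=tuple(out))


def qc_transcript(transcript: Transcript, first10_rule: bool = True) -> QCResult:
    """Apply the exclusion rules to a transcript with violations marked.

    A transcript is excluded when strictly more than 25% of its tokens are
    violations, when onsets are present but no word starts before 10.0 s
    ("within the first 10 seconds" read as strict-before), or when it is
    empty.  When no token carries an onset, the 10-second rule is skipped.
    """
    n = len(transcript.tokens)
    n_viol = sum(1 for t in transcript.tokens if t.is_violation)
    reasons: list[str] = []
    if n == 0:
        return QCResult(0, 0, 0.0, True, ("empty",))
    fraction = n_viol / n
    if fraction > 0.25:
        reasons.append("violation_rate_gt_25pct")
    onsets = [t.onset_s for t in transcript.tokens if t.onset_s is not None]
    if first10_rule and onsets:
        if not any(o < 10.0 for o in onsets):
            reasons.append("no_word_in_first_10s")
    elif first10_rule:
        logger.debug("no onsets present; 10-second rule skipped")
    return QCResult(n, n_viol, fraction, bool(reasons), tuple(reasons))


def word_error_rate(auto: Sequence[str], correct: Sequence[str]) -> ErrorRateResult:
    """Word-level Levenshtein distance, normalized by the correct list length.

    Tokens are compared on their normalized forms with unit costs for
    insertion, deletion and substitution.  An operation transforms *auto*
    into *correct*: an insertion adds a word missing from the automatic
    transcript, a deletion removes a spurious one.
    """
    if len(correct) == 0:
        raise ValueError("correct word list must be non-empty")
    a = [normalize_word(w) for w in auto]
    b = [normalize_word(w) for w in correct]
    n, m = len(a), len(b)
    # DP over (n+1) x (m+1); cell value = edit distance of prefixes.
    dist = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dist[i][0] = i
    for j in range(1, m + 1):
        dist[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = dist[i - 1][j - 1] + (a[i - 1] != b[j - 1])
            dele = dist[i - 1][j] + 1
            ins = dist[i][j - 1] + 1
            dist[i][j] = min(sub, dele, ins)
    # Backtrace to split the distance into operation counts.
    i, j = n, m
    n_ins = n_del = n_sub = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and dist[i][j] == dist[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
            if a[i - 1] != b[j - 1]:
                n_sub += 1
            i, j = i - 1, j - 1
        elif i > 0 and dist[i][j] == dist[i - 1][j] + 1:
            n_del += 1
            i -= 1
        else:
            n_ins += 1
            j -= 1
    d = dist[n][m]
    return ErrorRateResult(n_ins, n_del, n_sub, d, d / m)


# ---------------------------------------------------------------------------
# I/O: JSON-lines (one object per transcript) and long-format CSV.

def _token_to_dict(tok: WordToken) -> dict:
    d: dict = {"surface": tok.surface}
    if tok.onset_s is not None:
        d["onset_s"] = tok.onset_s
    if tok.flags:
        d["flags"] = sorted(tok.flags)
    return d


def _transcript_to_dict(tr: Transcript) -> dict:
    return {
        "transcript_id": tr.transcript_id,
        "task": tr.task,
        "cue": tr.cue,
        "duration_s": tr.duration_s,
        "source": tr.source,
        "tokens": [_token_to_dict(t) for t in tr.tokens],
    }


def _transcript_from_dict(d: dict, where: str) -> Transcript:
    try:
        tokens = tuple(
            WordToken(
                surface=t["surface"],
                onset_s=t.get("onset_s"),
                flags=frozenset(t.get("flags", ())),
            )
            for t in d["tokens"]
        )
        return Transcript(
            task=d["task"],
            cue=d["cue"],
            tokens=tokens,
            duration_s=d.get("duration_s", 60.0),
            source=d.get("source", "manual"),
            transcript_id=d.get("transcript_id", ""),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise TranscriptFormatError(f"{where}: {exc}") from exc


def write_transcripts(transcripts: Iterable[Transcript], path, format: str = "jsonl") -> None:
    transcripts = list(transcripts)
    if format == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for tr in transcripts:
                fh.write(json.dumps(_transcript_to_dict(tr), ensure_ascii=False) + "\n")
    elif format == "csv":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["transcript_id", "task", "cue", "duration_s", "source",
                 "position", "surface", "onset_s", "flags"]
            )
            for tr in transcripts:
                for pos, tok in enumerate(tr.tokens):
                    writer.writerow(
                        [tr.transcript_id, tr.task, tr.cue, tr.duration_s, tr.source,
                         pos, tok.surface,
                         "" if tok.onset_s is None else tok.onset_s,
                         ";".join(sorted(tok.flags))]
                    )
    else:
        raise ValueError(f"unknown format {format!r}")


def read_transcripts(path, format: str = "jsonl") -> list[Transcript]:
    if format == "jsonl":
        out = []
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    d = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise TranscriptFormatError(f"line {lineno}: invalid JSON") from exc
                out.append(_transcript_from_dict(d, f"line {lineno}"))
        return out
    if format == "csv":
        groups: dict[str, dict] = {}
        order: list[str] = []
        with open(path, encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                tid = row["transcript_id"]
                if tid not in groups:
                    groups[tid] = {
                        "transcript_id": tid,
                        "task": row["task"],
                        "cue": row["cue"],
                        "duration_s": float(row["duration_s"]),
                        "source": row["source"],
                        "tokens": [],
                    }
                    order.append(tid)
                onset = row.get("onset_s", "")
                tok = {
                    "surface": row["surface"],
                    "flags": [f for f in row.get("flags", "").split(";") if f],
                }
                if onset not in ("", None):
                    tok["onset_s"] = float(onset)
                groups[tid]["tokens"].append((int(row["position"]), lineno, tok))
        out = []
        for tid in order:
            g = groups[tid]
            g["tokens"] = [t for _, _, t in sorted(g["tokens"], key=lambda x: x[0])]
            out.append(_transcript_from_dict(g, f"transcript {tid!r}"))
        return out
    raise ValueError(f"unknown format {format!r}")
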