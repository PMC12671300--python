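"""Word normalization policy shared across the package.

Keys used for repetition detection, lexicon lookup and embedding lookup
must be deterministic: Unicode NFC, casefold, surrounding whitespace
stripped.  Umlauts are preserved (German lookups need them); casefold maps
"ß" to "ss", which is acceptable for matching purposes.
"""

from __future__ import annotations

import unicodedata

__all__ = ["normalize_word"]


def normalize_word(word: str) -> str:
    """Return the canonical lookup form of *word*."""
    return unicodedata.normalize("NFC", word).strip().casefold()
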