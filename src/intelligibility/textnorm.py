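"""Normalization of typed Hebrew and English transcripts.

Listener and ASR transcripts arrive as free-form typed text: mixed case,
stray punctuation, and (for Hebrew) optional niqqud/cantillation marks and
word-final letter forms.  Scoring compares transcripts to target words at
the level of whole normalized tokens, so everything orthographic that does
not change word identity is folded away first.

Word identity itself is exact match on normalized tokens, optionally
extended by an explicit :class:`EquivalenceLexicon` of spelling variants
declared phonemically identical (e.g. plene/defective Hebrew spellings).
No grapheme-to-phoneme conversion is attempted: the lexicon keeps the
correctness rule auditable.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "NormalizationConfig",
    "EquivalenceLexicon",
    "normalize_text",
    "words_match",
]

# Hebrew final forms -> regular forms (kaf, mem, nun, pe, tsadi)
_FINAL_FORMS = str.maketrans("ךםןףץ", "כמנפצ")

# Hebrew combining marks: niqqud, cantillation and related points all live
# in U+0591..U+05C7 and carry the Unicode combining-mark category.
_HEBREW_POINTS = range(0x0591, 0x05C8)


def _is_hebrew_point(ch: str) -> bool:
    return ord(ch) in _HEBREW_POINTS and unicodedata.category(ch).startswith("M")


def _is_punctuation(ch: str) -> bool:
    # Unicode punctuation/symbol categories, not an ASCII list: Hebrew
    # transcripts may carry geresh/gershayim or smart quotes, and stray
    # keyboard symbols (^, $, ~) are as meaningless as commas here.
    return unicodedata.category(ch)[0] in "PS"


@dataclass(frozen=True)
class NormalizationConfig:
    """Switches controlling transcript normalization.

    Parameters
    ----------
    language
        ``"hebrew"`` or ``"english"``.  The language does not change the
        mechanics of any individual switch; it selects sensible defaults
        via :meth:`for_language` and is recorded for provenance.
    lowercase
        Case-fold the text (no-op for Hebrew script).
    strip_punctuation
        Remove all characters in the Unicode punctuation category.
    strip_hebrew_points
        Remove niqqud and cantillation combining marks.
    fold_final_letters
        Map Hebrew final forms to their regular forms.
    collapse_whitespace
        Split on any whitespace run and drop empty tokens.
    """

    language: str = "english"
    lowercase: bool = True
    strip_punctuation: bool = True
    strip_hebrew_points: bool = True
    fold_final_letters: bool = True
    collapse_whitespace: bool = True

    def __post_init__(self) -> None:
        if self.language not in ("hebrew", "english"):
            raise ValueError(f"unknown language: {self.language!r}")

    @classmethod
    def for_language(cls, language: str) -> "NormalizationConfig":
        """Default configuration for a study language."""
        return cls(language=language)


def normalize_text(raw: str, config: NormalizationConfig) -> list[str]:
    """Normalize raw transcript text into a token sequence.

    Returns an ordered list of non-empty normalized tokens.  Empty input
    (or input that is entirely punctuation) normalizes to the empty list,
    which downstream scoring treats as an omission, not an error condition.
    The function is idempotent: normalizing already-normalized text is a
    no-op.
    """
    if not isinstance(raw, str):
        raise TypeError("transcript must be text")
    text = unicodedata.normalize("NFC", raw)
    if config.lowercase:
        text = text.casefold()
    if config.strip_hebrew_points:
        text = "".join(ch for ch in text if not _is_hebrew_point(ch))
    if config.fold_final_letters:
        text = text.translate(_FINAL_FORMS)
    if config.strip_punctuation:
        # Deleted, not blanked: word-internal marks (geresh/gershayim in
        # Hebrew acronyms, English apostrophes) must not split a token.
        text = "".join(ch for ch in text if not _is_punctuation(ch))
    if config.collapse_whitespace:
        tokens = text.split()
    else:
        tokens = [t for t in text.split(" ") if t]
    return tokens


@dataclass
class EquivalenceLexicon:
    """Unordered pairs of normalized forms declared phonemically identical.

    Matching is reflexive by construction (every token matches itself) and
    symmetric because pairs are stored as frozensets.  The default lexicon
    is empty: exact normalized-orthographic identity is then the whole rule.
    """

    entries: set[frozenset[str]] = field(default_factory=set)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "EquivalenceLexicon":
        return cls(entries={frozenset((a, b)) for a, b in pairs if a != b})

    @classmethod
    def from_file(cls, path: str | Path) -> "EquivalenceLexicon":
        """Load a two-column UTF-8 delimited lexicon file.

        Columns are separated by a tab or comma; lines starting with ``#``
        are comments.  Blank lines are ignored.
        """
        pairs: list[tuple[str, str]] = []
        for lineno, line in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in (line.split("\t") if "\t" in line else line.split(","))]
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def add(self, a: str, b: str) -> None:
        if a != b:
            self.entries.add(frozenset((a, b)))

    def matches(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self.entries


def words_match(
    hypothesis: str, target: str, lexicon: EquivalenceLexicon | None = None
) -> bool:
    """Decide word identity under the study's correctness rule.

    Both tokens must already be normalized.  A word counts as correct only
    when it is identical to the target (or declared equivalent in the
    lexicon); any partial mismatch — including omitted or substituted
    morphological elements — is an error.
    """
    if lexicon is None:
        return hypothesis == target
    return lexicon.matches(hypothesis, target)
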