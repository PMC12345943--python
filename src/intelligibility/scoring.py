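"""Per-speaker intelligibility scores and listener-vs-ASR agreement.

Every stimulus (a single word or a sentence) is transcribed by exactly
three naive listeners and once by an ASR system.  Word stimuli are scored
binary correct/incorrect per transcript; a speaker's listener word score
is the mean of the three listeners' proportions correct, and the ASR word
score is the ASR's proportion correct.  Listener-ASR *agreement* for words
is point-by-point: an item agrees when the ASR's outcome matches the
majority (at least two of three) listener outcome — by default the
correct/incorrect status, optionally the transcribed string itself.

Sentence stimuli are scored as percent words correct per sentence via a
minimum edit-distance token alignment against the target; the listener
sentence score averages across the three listeners and then across
sentences.  Sentence-level agreement is the proportion of "ASR successes":
sentences where the ASR's percent correct is at least the three-listener
average for that sentence.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import pandas as pd

from .errors import DataCompletenessError, SchemaError
from .textnorm import EquivalenceLexicon, NormalizationConfig, normalize_text, words_match

__all__ = [
    "LISTENER_SOURCES",
    "ASR_SOURCE",
    "TranscriptionRecord",
    "SpeakerWordResult",
    "SpeakerSentenceResult",
    "TokenAlignment",
    "score_word",
    "majority_status",
    "align_tokens",
    "sentence_percent_correct",
    "listener_word_scores",
    "word_agreement",
    "speaker_word_result",
    "speaker_sentence_result",
    "score_study",
]

LISTENER_SOURCES = ("listener_1", "listener_2", "listener_3")
ASR_SOURCE = "asr"
_SOURCES = LISTENER_SOURCES + (ASR_SOURCE,)

AgreementMode = Literal["status", "string"]


@dataclass(frozen=True)
class TranscriptionRecord:
    """One transcript of one stimulus by one source (a listener or the ASR)."""

    language: str
    group: str
    speaker_id: str
    stimulus_type: str  # "word" | "sentence"
    item_id: str
    target_text: str
    source: str  # listener_1 | listener_2 | listener_3 | asr
    transcript: str

    def __post_init__(self) -> None:
        if self.source not in _SOURCES:
            raise SchemaError(f"unknown source {self.source!r}")
        if self.stimulus_type not in ("word", "sentence"):
            raise SchemaError(f"unknown stimulus_type {self.stimulus_type!r}")
        if not self.target_text or not self.target_text.strip():
            raise SchemaError(
                f"empty target_text for speaker {self.speaker_id} item {self.item_id}"
            )


@dataclass(frozen=True)
class SpeakerWordResult:
    speaker_id: str
    language: str
    group: str
    listener_score: float  # mean of three listeners' proportions correct
    asr_score: float
    agreement: float  # proportion of items where ASR agrees with listener majority
    n_items: int


@dataclass(frozen=True)
class SpeakerSentenceResult:
    speaker_id: str
    language: str
    group: str
    listener_score: float  # mean over sentences of 3-listener mean percent correct
    asr_score: float  # mean over sentences of ASR percent correct
    asr_success: float  # proportion of sentences with ASR >= listener average
    n_sentences: int


@dataclass(frozen=True)
class TokenAlignment:
    """Counts from a minimum edit-distance monotone token alignment."""

    hits: int
    substitutions: int
    deletions: int
    insertions: int

    @property
    def n_reference(self) -> int:
        return self.hits + self.substitutions + self.deletions

    @property
    def cost(self) -> int:
        return self.substitutions + self.deletions + self.insertions


def score_word(
    transcript: str,
    target: str,
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None = None,
) -> bool:
    """Score a single-word transcript as correct (True) or incorrect.

    Correct iff the transcript normalizes to exactly one token that matches
    the (single-token) target; empty or multi-token transcripts are
    incorrect — an omission or an elaboration is an error either way.
    """
    target_tokens = normalize_text(target, norm)
    if len(target_tokens) != 1:
        raise SchemaError(f"word target must normalize to one token: {target!r}")
    hyp_tokens = normalize_text(transcript, norm)
    if len(hyp_tokens) != 1:
        return False
    return words_match(hyp_tokens[0], target_tokens[0], lexicon)


def majority_status(statuses: Sequence[bool]) -> bool:
    """Majority outcome of exactly three binary listener statuses."""
    if len(statuses) != 3:
        raise ValueError(f"expected exactly 3 statuses, got {len(statuses)}")
    return sum(bool(s) for s in statuses) >= 2


def align_tokens(
    hypothesis: Sequence[str],
    reference: Sequence[str],
    lexicon: EquivalenceLexicon | None = None,
) -> TokenAlignment:
    """Minimum edit-distance monotone alignment with unit costs.

    A hit is a matched pair under :func:`words_match` (cost 0); mismatched
    pairs are substitutions, unmatched reference tokens deletions, and
    unmatched hypothesis tokens insertions (cost 1 each).  Among
    minimum-cost alignments, ties are broken by preferring more hits, then
    more substitutions, then more deletions.
    """
    nh, nr = len(hypothesis), len(reference)
    # DP over (cost, -hits, -subs, -dels); lexicographic min realises the
    # tie-break order.
    prev = [(j, 0, 0, -j) for j in range(nr + 1)]
    for i in range(1, nh + 1):
        cur = [(prev[0][0] + 1, prev[0][1], prev[0][2], prev[0][3])]
        for j in range(1, nr + 1):
            diag = prev[j - 1]
            if words_match(hypothesis[i - 1], reference[j - 1], lexicon):
                best = (diag[0], diag[1] - 1, diag[2], diag[3])
            else:
                best = (diag[0] + 1, diag[1], diag[2] - 1, diag[3])
            up = prev[j]  # insertion of hypothesis[i-1]
            cand = (up[0] + 1, up[1], up[2], up[3])
            if cand < best:
                best = cand
            left = cur[j - 1]  # deletion of reference[j-1]
            cand = (left[0] + 1, left[1], left[2], left[3] - 1)
            if cand < best:
                best = cand
            cur.append(best)
        prev = cur
    cost, neg_hits, neg_subs, neg_dels = prev[nr]
    hits, subs, dels = -neg_hits, -neg_subs, -neg_dels
    ins = cost - subs - dels
    return TokenAlignment(hits=hits, substitutions=subs, deletions=dels, insertions=ins)


def sentence_percent_correct(
    transcript: str,
    target: str,
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None = None,
) -> float:
    """Proportion of target words correctly transcribed in a sentence.

    Hits from the minimum edit-distance alignment divided by the number of
    target tokens; insertions cannot push the score below zero, and the
    reference-length denominator keeps it in [0, 1].
    """
    ref = normalize_text(target, norm)
    if not ref:
        raise SchemaError(f"sentence target normalizes to nothing: {target!r}")
    hyp = normalize_text(transcript, norm)
    return align_tokens(hyp, ref, lexicon).hits / len(ref)


# ---------------------------------------------------------------------------
# per-speaker aggregation


def _group_by_item(
    records: Iterable[TranscriptionRecord],
) -> dict[str, dict[str, TranscriptionRecord]]:
    by_item: dict[str, dict[str, TranscriptionRecord]] = defaultdict(dict)
    for rec in records:
        if rec.source in by_item[rec.item_id]:
            raise SchemaError(
                f"duplicate record for speaker {rec.speaker_id}, "
                f"item {rec.item_id}, source {rec.source}"
            )
        by_item[rec.item_id][rec.source] = rec
    return by_item


def _check_complete(by_item: dict[str, dict[str, TranscriptionRecord]], speaker: str) -> None:
    bad = sorted(
        item
        for item, sources in by_item.items()
        if set(sources) != set(_SOURCES)
    )
    if bad:
        raise DataCompletenessError(
            f"speaker {speaker}: items missing listener or ASR transcripts: {bad}",
            items=bad,
        )


def listener_word_scores(
    records: Sequence[TranscriptionRecord],
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None = None,
) -> tuple[tuple[float, float, float], float]:
    """Per-listener proportions correct for one speaker's words, and their mean."""
    by_item = _group_by_item(records)
    speaker = records[0].speaker_id if records else "?"
    _check_complete(by_item, speaker)
    n = len(by_item)
    props = []
    for src in LISTENER_SOURCES:
        correct = sum(
            score_word(sources[src].transcript, sources[src].target_text, norm, lexicon)
            for sources in by_item.values()
        )
        props.append(correct / n)
    return (props[0], props[1], props[2]), sum(props) / 3.0


def _item_statuses(
    sources: dict[str, TranscriptionRecord],
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None,
) -> tuple[list[bool], bool]:
    listener = [
        score_word(sources[src].transcript, sources[src].target_text, norm, lexicon)
        for src in LISTENER_SOURCES
    ]
    asr = score_word(sources[ASR_SOURCE].transcript, sources[ASR_SOURCE].target_text, norm, lexicon)
    return listener, asr


def word_agreement(
    records: Sequence[TranscriptionRecord],
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None = None,
    mode: AgreementMode = "status",
) -> float:
    """Point-by-point proportion of listener-ASR agreement for one speaker.

    ``status`` mode (default): an item agrees when the ASR's
    correct/incorrect outcome equals the majority listener outcome.
    ``string`` mode: an item agrees when at least two listeners typed the
    same normalized transcript and the ASR's normalized transcript equals
    it; with no string majority the item does not agree.
    """
    by_item = _group_by_item(records)
    speaker = records[0].speaker_id if records else "?"
    _check_complete(by_item, speaker)
    n = len(by_item)
    agree = 0
    for sources in by_item.values():
        if mode == "status":
            listener, asr = _item_statuses(sources, norm, lexicon)
            agree += majority_status(listener) == asr
        elif mode == "string":
            texts = [
                tuple(normalize_text(sources[src].transcript, norm))
                for src in LISTENER_SOURCES
            ]
            asr_text = tuple(normalize_text(sources[ASR_SOURCE].transcript, norm))
            counts: dict[tuple, int] = defaultdict(int)
            for t in texts:
                counts[t] += 1
            majority = [t for t, c in counts.items() if c >= 2]
            agree += bool(majority) and asr_text == majority[0]
        else:
            raise ValueError(f"unknown agreement mode {mode!r}")
    return agree / n


def speaker_word_result(
    records: Sequence[TranscriptionRecord],
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None = None,
    mode: AgreementMode = "status",
) -> SpeakerWordResult:
    """Full word-level result for one speaker."""
    by_item = _group_by_item(records)
    speaker = records[0].speaker_id
    _check_complete(by_item, speaker)
    n = len(by_item)
    _, listener_score = listener_word_scores(records, norm, lexicon)
    asr_correct = sum(
        score_word(s[ASR_SOURCE].transcript, s[ASR_SOURCE].target_text, norm, lexicon)
        for s in by_item.values()
    )
    agreement = word_agreement(records, norm, lexicon, mode)
    return SpeakerWordResult(
        speaker_id=speaker,
        language=records[0].language,
        group=records[0].group,
        listener_score=listener_score,
        asr_score=asr_correct / n,
        agreement=agreement,
        n_items=n,
    )


def speaker_sentence_result(
    records: Sequence[TranscriptionRecord],
    norm: NormalizationConfig,
    lexicon: EquivalenceLexicon | None = None,
) -> SpeakerSentenceResult:
    """Sentence-level result for one speaker.

    Percent words correct is averaged across the three listeners and then
    across sentences; an "ASR success" is a sentence whose ASR percent
    correct is equal to or greater than the three-listener average.
    """
    by_item = _group_by_item(records)
    speaker = records[0].speaker_id
    _check_complete(by_item, speaker)
    listener_means, asr_scores, successes = [], [], []
    for sources in by_item.values():
        per_listener = [
            sentence_percent_correct(
                sources[src].transcript, sources[src].target_text, norm, lexicon
            )
            for src in LISTENER_SOURCES
        ]
        listener_mean = sum(per_listener) / 3.0
        asr = sentence_percent_correct(
            sources[ASR_SOURCE].transcript, sources[ASR_SOURCE].target_text, norm, lexicon
        )
        listener_means.append(listener_mean)
        asr_scores.append(asr)
        # "equal to or greater": guard the tie against float rounding
        successes.append(asr >= listener_mean - 1e-9)
    n = len(by_item)
    return SpeakerSentenceResult(
        speaker_id=speaker,
        language=records[0].language,
        group=records[0].group,
        listener_score=sum(listener_means) / n,
        asr_score=sum(asr_scores) / n,
        asr_success=sum(successes) / n,
        n_sentences=n,
    )


def score_study(
    records: Sequence[TranscriptionRecord],
    lexicon: EquivalenceLexicon | None = None,
    mode: AgreementMode = "status",
    norm_by_language: dict[str, NormalizationConfig] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score a whole study and return (word, sentence) per-speaker tables.

    Speakers without sentence stimuli simply do not appear in the sentence
    table (complete-case handling for each analysis happens downstream).
    """
    norms = norm_by_language or {}
    per_speaker: dict[tuple[str, str], list[TranscriptionRecord]] = defaultdict(list)
    for rec in records:
        per_speaker[(rec.speaker_id, rec.stimulus_type)].append(rec)
    word_rows, sent_rows = [], []
    for (speaker, stimulus_type), recs in sorted(per_speaker.items()):
        norm = norms.get(recs[0].language, NormalizationConfig.for_language(recs[0].language))
        if stimulus_type == "word":
            word_rows.append(speaker_word_result(recs, norm, lexicon, mode).__dict__)
        else:
            sent_rows.append(speaker_sentence_result(recs, norm, lexicon).__dict__)
    word_cols = [f.name for f in SpeakerWordResult.__dataclass_fields__.values()]
    sent_cols = [f.name for f in SpeakerSentenceResult.__dataclass_fields__.values()]
    return (
        pd.DataFrame(word_rows, columns=word_cols),
        pd.DataFrame(sent_rows, columns=sent_cols),
    )
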