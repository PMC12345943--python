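"""Synthetic transcription studies with the design the analysis assumes.

The real study's recordings are confidential, so this module generates
complete stand-in datasets with the same structure: two languages by two
speaker groups (Down syndrome and typically developing) with unbalanced
cell sizes, fixed word lists per language, short Hebrew sentence sets,
exactly three listener transcripts plus one ASR transcript per stimulus,
and group-dependent correctness probabilities.

The generative model is deliberately simple and inspectable.  Each speaker
has a latent intelligibility theta drawn from a per-cell Beta distribution;
each item has a latent difficulty d on the logit scale, shared by listeners
and the ASR (the sole coupling mechanism, which induces the positive
listener-ASR correlation seen in real data).  A listener transcribes a word
correctly with probability

    p_listener = invlogit(logit(s_L * theta) - d)

and the ASR with probability

    p_asr = invlogit(lambda * logit(theta) + delta - d)

where s_L is a listener scaling, lambda an ASR discrimination slope, and
delta an ASR accuracy offset (negative delta emulates an ASR that lags
naive listeners, as observed for Hebrew).  Incorrect transcripts are drawn
from a held-out confusion vocabulary, so agreement on a wrong string is
possible but rare.  Sentences are generated word by word under the same
model; no grammar is simulated because the analysis consumes only per-word
correctness.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .scoring import ASR_SOURCE, LISTENER_SOURCES, TranscriptionRecord

__all__ = [
    "CellConfig",
    "SimulationConfig",
    "SimulatedStudy",
    "ExpectedCellStats",
    "simulate_study",
    "expected_statistics",
    "majority_correct_probability",
]

_EPS = 1e-9


def _logit(p: float) -> float:
    p = min(max(p, _EPS), 1.0 - _EPS)
    return math.log(p / (1.0 - p))


def _invlogit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def majority_correct_probability(p: float) -> float:
    """P(at least 2 of 3 independent listeners correct), each correct w.p. p."""
    return p**3 + 3 * p**2 * (1 - p)


@dataclass(frozen=True)
class CellConfig:
    """One language-by-group cell: size and latent intelligibility Beta."""

    language: str
    group: str
    n_speakers: int
    theta_mean: float
    theta_sd: float

    def beta_params(self) -> tuple[float, float]:
        m, s = self.theta_mean, self.theta_sd
        if not 0 < m < 1:
            raise ConfigError(f"theta_mean must be in (0,1), got {m}")
        var = s * s
        if var >= m * (1 - m):
            raise ConfigError(f"theta_sd {s} too large for mean {m}")
        if var == 0:
            return (float("inf"), float("inf"))
        nu = m * (1 - m) / var - 1.0
        return (m * nu, (1 - m) * nu)


def _default_cells() -> list[CellConfig]:
    # Cell sizes and latent-intelligibility moments follow the study design:
    # 24/24 Hebrew DS/TD, 8/6 English DS/TD, with listener word-score
    # means (SDs) of 0.80 (0.10), 0.98 (0.02), 0.56 (0.24), 0.91 (0.06).
    return [
        CellConfig("hebrew", "DS", 24, 0.80, 0.10),
        CellConfig("hebrew", "TD", 24, 0.98, 0.02),
        CellConfig("english", "DS", 8, 0.56, 0.24),
        CellConfig("english", "TD", 6, 0.91, 0.06),
    ]


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic study generator."""

    cells: list[CellConfig] = field(default_factory=_default_cells)
    n_word_items: dict[str, int] = field(
        default_factory=lambda: {"hebrew": 46, "english": 78}
    )
    sentence_languages: tuple[str, ...] = ("hebrew",)
    n_sentences: int = 5
    words_per_sentence: tuple[int, ...] = (3, 4)  # drawn uniformly; mean 3.5
    n_sentence_missing_td: int = 2  # TD speakers with no sentence data
    n_sentence_missing_ds: int = 4  # DS speakers with no sentence data
    n_sentence_short_ds: int = 4  # DS speakers with one sentence fewer
    listener_slope: float = 1.0
    asr_slope: float = 1.0
    asr_offset: float = -0.75
    item_difficulty_sd: float = 0.5
    confusion_vocabulary: dict[str, list[str]] | None = None
    n_confusion_words: int = 200
    seed: int = 0

    def validate(self) -> None:
        if not self.cells:
            raise ConfigError("cells must be non-empty")
        for c in self.cells:
            c.beta_params()
        if self.item_difficulty_sd < 0:
            raise ConfigError("item_difficulty_sd must be >= 0")
        for lang in {c.language for c in self.cells}:
            if lang not in self.n_word_items:
                raise ConfigError(f"no word-item count for language {lang!r}")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class ExpectedCellStats:
    language: str
    group: str
    listener_score: float
    asr_score: float
    agreement: float  # expected status-mode listener-ASR agreement


@dataclass
class SimulatedStudy:
    """Records plus ground truth from one simulated study."""

    records: list[TranscriptionRecord]
    theta: dict[str, float]  # speaker -> latent intelligibility
    item_difficulty: dict[str, float]  # item_id -> logit difficulty
    correct: pd.DataFrame  # speaker_id, item_id, source, correct
    config: SimulationConfig


_HEBREW_LETTERS = "אבגדהוזחטיכלמנסעפצקרשת"
_ENGLISH_ONSETS = "bcdfghjklmnprstvwz"
_ENGLISH_VOWELS = "aeiou"


def _make_vocab(language: str, n: int, rng: np.random.Generator) -> list[str]:
    """Deterministic pool of distinct pronounceable-ish pseudo-words."""
    words: list[str] = []
    seen = set()
    while len(words) < n:
        if language == "hebrew":
            length = int(rng.integers(2, 5))
            w = "".join(rng.choice(list(_HEBREW_LETTERS), size=length))
        else:
            syll = int(rng.integers(1, 3))
            w = "".join(
                rng.choice(list(_ENGLISH_ONSETS))
                + rng.choice(list(_ENGLISH_VOWELS))
                + rng.choice(list(_ENGLISH_ONSETS))
                for _ in range(syll)
            )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def _p_listener(theta: float, d: float, slope: float) -> float:
    return float(_invlogit(_logit(min(slope * theta, 1.0 - _EPS)) - d))


def _p_asr(theta: float, d: float, lam: float, delta: float) -> float:
    return float(_invlogit(lam * _logit(theta) + delta - d))


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one complete synthetic study, deterministic under the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    languages = sorted({c.language for c in config.cells})

    # Fixed stimulus material per language: targets + held-out confusion pool.
    vocab_rng = np.random.default_rng(rng.integers(2**31))
    targets: dict[str, list[str]] = {}
    confusion: dict[str, list[str]] = {}
    for lang in languages:
        n_items = config.n_word_items[lang]
        n_sentence_words = config.n_sentences * max(config.words_per_sentence) + 8
        pool = _make_vocab(lang, n_items + n_sentence_words, vocab_rng)
        targets[lang] = pool
        if config.confusion_vocabulary and lang in config.confusion_vocabulary:
            confusion[lang] = list(config.confusion_vocabulary[lang])
        else:
            confusion[lang] = _make_vocab(lang, config.n_confusion_words, vocab_rng)
        overlap = set(targets[lang]) & set(confusion[lang])
        confusion[lang] = [w for w in confusion[lang] if w not in overlap]
        if not confusion[lang]:
            raise ConfigError(f"confusion vocabulary for {lang!r} is empty")

    # Per-word-item difficulty, shared by listeners and ASR.
    item_difficulty: dict[str, float] = {}
    for lang in languages:
        for i in range(config.n_word_items[lang]):
            item_difficulty[f"{lang}_w{i:03d}"] = float(
                rng.normal(0.0, config.item_difficulty_sd)
            )

    records: list[TranscriptionRecord] = []
    theta_by_speaker: dict[str, float] = {}
    correct_rows: list[tuple[str, str, str, bool]] = []

    def emit(rec: TranscriptionRecord, ok: bool) -> None:
        records.append(rec)
        correct_rows.append((rec.speaker_id, rec.item_id, rec.source, ok))

    def transcribe(lang: str, target: str, p: float) -> tuple[str, bool]:
        ok = bool(rng.random() < p)
        if ok:
            return target, True
        return str(rng.choice(confusion[lang])), False

    for cell in config.cells:
        a, b = cell.beta_params()
        do_sentences = cell.language in config.sentence_languages
        missing = (
            config.n_sentence_missing_td if cell.group == "TD" else config.n_sentence_missing_ds
        )
        short = config.n_sentence_short_ds if cell.group == "DS" else 0
        for idx in range(cell.n_speakers):
            speaker = f"{cell.language[:2]}_{cell.group}_{idx:02d}"
            theta = float(rng.beta(a, b)) if math.isfinite(a) else cell.theta_mean
            theta_by_speaker[speaker] = theta

            # words
            for i, target in enumerate(targets[cell.language][: config.n_word_items[cell.language]]):
                item = f"{cell.language}_w{i:03d}"
                d = item_difficulty[item]
                p_l = _p_listener(theta, d, config.listener_slope)
                p_a = _p_asr(theta, d, config.asr_slope, config.asr_offset)
                for src in LISTENER_SOURCES:
                    text, ok = transcribe(cell.language, target, p_l)
                    emit(
                        TranscriptionRecord(
                            cell.language, cell.group, speaker, "word", item, target, src, text
                        ),
                        ok,
                    )
                text, ok = transcribe(cell.language, target, p_a)
                emit(
                    TranscriptionRecord(
                        cell.language, cell.group, speaker, "word", item, target, ASR_SOURCE, text
                    ),
                    ok,
                )

            # sentences (study languages only; some speakers missing/short)
            if not do_sentences or idx < missing:
                continue
            n_sent = config.n_sentences - (1 if idx < missing + short else 0)
            sent_pool = targets[cell.language][config.n_word_items[cell.language]:]
            for s in range(n_sent):
                length = int(rng.choice(config.words_per_sentence))
                words = [str(w) for w in rng.choice(sent_pool, size=length, replace=False)]
                item = f"{speaker}_s{s}"
                ds = rng.normal(0.0, config.item_difficulty_sd, size=length)
                item_difficulty[item] = float(np.mean(ds))
                p_l = [_p_listener(theta, dw, config.listener_slope) for dw in ds]
                p_a = [_p_asr(theta, dw, config.asr_slope, config.asr_offset) for dw in ds]
                target_text = " ".join(words)

                def sentence_transcript(ps: list[float]) -> tuple[str, bool]:
                    out, all_ok = [], True
                    for w, p in zip(words, ps):
                        t, ok = transcribe(cell.language, w, p)
                        out.append(t)
                        all_ok = all_ok and ok
                    return " ".join(out), all_ok

                for src in LISTENER_SOURCES:
                    text, ok = sentence_transcript(p_l)
                    emit(
                        TranscriptionRecord(
                            cell.language, cell.group, speaker, "sentence", item,
                            target_text, src, text,
                        ),
                        ok,
                    )
                text, ok = sentence_transcript(p_a)
                emit(
                    TranscriptionRecord(
                        cell.language, cell.group, speaker, "sentence", item,
                        target_text, ASR_SOURCE, text,
                    ),
                    ok,
                )

    correct = pd.DataFrame(
        correct_rows, columns=["speaker_id", "item_id", "source", "correct"]
    )
    return SimulatedStudy(
        records=records,
        theta=theta_by_speaker,
        item_difficulty=item_difficulty,
        correct=correct,
        config=config,
    )


def expected_statistics(
    config: SimulationConfig, n_theta: int = 400, n_difficulty: int = 41
) -> list[ExpectedCellStats]:
    """Analytic expectations per cell under the generative model.

    Integrates over the speaker intelligibility Beta (quantile midpoint
    rule) and the item-difficulty normal (Gauss-Hermite), computing for
    word stimuli the expected listener score, ASR score, and status-mode
    listener-ASR agreement E[P(majority) p_asr + (1 - P(majority))(1 -
    p_asr)], with the three listeners conditionally independent given
    (theta, d).
    """
    from scipy import stats as sps

    config.validate()
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(n_difficulty)
    d_nodes = gh_x * config.item_difficulty_sd
    d_weights = gh_w / gh_w.sum()

    out = []
    for cell in config.cells:
        a, b = cell.beta_params()
        if math.isfinite(a):
            qs = (np.arange(n_theta) + 0.5) / n_theta
            thetas = sps.beta.ppf(qs, a, b)
        else:
            thetas = np.array([cell.theta_mean])
        t_weights = np.full(thetas.size, 1.0 / thetas.size)

        listener = asr = agree = 0.0
        for theta, tw in zip(thetas, t_weights):
            lt = _logit(min(config.listener_slope * theta, 1.0 - _EPS))
            at = config.asr_slope * _logit(theta) + config.asr_offset
            p_l = _invlogit(lt - d_nodes)
            p_a = _invlogit(at - d_nodes)
            p_maj = p_l**3 + 3 * p_l**2 * (1 - p_l)
            listener += tw * float(np.sum(d_weights * p_l))
            asr += tw * float(np.sum(d_weights * p_a))
            agree += tw * float(
                np.sum(d_weights * (p_maj * p_a + (1 - p_maj) * (1 - p_a)))
            )
        out.append(
            ExpectedCellStats(
                language=cell.language,
                group=cell.group,
                listener_score=listener,
                asr_score=asr,
                agreement=agree,
            )
        )
    return out
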