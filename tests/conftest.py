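import pytest

from intelligibility.scoring import ASR_SOURCE, LISTENER_SOURCES, TranscriptionRecord
from intelligibility.textnorm import NormalizationConfig


@pytest.fixture
def english_norm():
    return NormalizationConfig.for_language("english")


@pytest.fixture
def hebrew_norm():
    return NormalizationConfig.for_language("hebrew")


def make_word_records(
    item_matrix,
    speaker="s1",
    language="english",
    group="DS",
    target_prefix="t",
):
    """Build one speaker's word records from a correctness matrix.

    ``item_matrix`` is a list of 4-tuples of bools
    (listener_1, listener_2, listener_3, asr); a True transcript is the
    target word, a False one is a distinct wrong word.
    """
    records = []
    for i, outcomes in enumerate(item_matrix):
        target = f"{target_prefix}{i}"
        sources = list(LISTENER_SOURCES) + [ASR_SOURCE]
        for src, ok in zip(sources, outcomes):
            records.append(
                TranscriptionRecord(
                    language=language,
                    group=group,
                    speaker_id=speaker,
                    stimulus_type="word",
                    item_id=f"w{i}",
                    target_text=target,
                    source=src,
                    transcript=target if ok else f"wrong{i}{src}",
                )
            )
    return records


@pytest.fixture
def word_records_factory():
    return make_word_records
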