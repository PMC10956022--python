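import numpy as np
import pytest

from dyadlang.features import MatchCounter
from dyadlang.lexicons import builtin_lexicons
from dyadlang.transcripts import (
    Corpus,
    SessionMetadata,
    SessionTranscript,
    TalkTurn,
)


@pytest.fixture(scope="session")
def lexicons():
    return builtin_lexicons()


@pytest.fixture(scope="session")
def counter(lexicons):
    return MatchCounter(lexicons)


def make_turn(idx, speaker, start, end, text):
    return TalkTurn(turn_index=idx, speaker=speaker, start_s=float(start),
                    end_s=float(end), text=text)


def make_session(texts, session_id="S000", therapist_id="T000", patient_id="P000",
                 turn_s=10.0, gap_s=1.0, first_speaker="patient", **meta):
    """Build an alternating-session transcript from a list of texts."""
    roles = ["patient", "therapist"] if first_speaker == "patient" else [
        "therapist", "patient"]
    turns = []
    clock = 0.0
    for i, text in enumerate(texts):
        turns.append(make_turn(i, roles[i % 2], clock, clock + turn_s, text))
        clock += turn_s + gap_s
    md = SessionMetadata(session_id=session_id, therapist_id=therapist_id,
                         patient_id=patient_id, **meta)
    return SessionTranscript(metadata=md, turns=turns)


@pytest.fixture
def tiny_corpus():
    s1 = make_session(
        ["i never sleep", "it sounds like you are frustrated",
         "maybe i will remember", "that seems hurt and calm now"],
        session_id="S000", therapist_id="T000", patient_id="P000", phq9=7,
        diagnosis="depression",
    )
    s2 = make_session(
        ["we always talk", "i see you now", "they remember yesterday",
         "you sound calm"],
        session_id="S001", therapist_id="T001", patient_id="P001", phq9=12,
        diagnosis="eating_disorder",
    )
    return Corpus(sessions=[s1, s2])


@pytest.fixture
def rng():
    # function-scoped: every test sees the same fresh stream, so stochastic
    # checks are deterministic and independent of execution order
    return np.random.default_rng(20260924)
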