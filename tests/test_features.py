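import math

import numpy as np
import pytest

from dyadlang.features import (
    FEATURES,
    PER_SPEAKER_FEATURES,
    SECONDS_PER_TURN,
    SECONDS_PER_TURN_RATIO,
    WORDS_PER_SECOND,
    WORDS_PER_SECOND_RATIO,
    assign_quintile,
    build_utterance_series,
    session_signature,
    turn_features,
    window_features,
)
from dyadlang.lexicons import count_matches, tokenize
from dyadlang.transcripts import Corpus, SessionTranscript

from conftest import make_session, make_turn


class TestFeatureSpec:
    def test_eighteen_features_sixteen_per_speaker(self):
        assert len(FEATURES) == 18
        assert len(PER_SPEAKER_FEATURES) == 16
        assert set(FEATURES) - set(PER_SPEAKER_FEATURES) == {
            SECONDS_PER_TURN_RATIO, WORDS_PER_SECOND_RATIO}


class TestTurnFeatures:
    def test_words_per_second(self, counter):
        turn = make_turn(0, "therapist", 0, 15, " ".join(["word"] * 30))
        vals = turn_features(turn, counter)
        assert vals[WORDS_PER_SECOND] == pytest.approx(2.0)
        assert vals[SECONDS_PER_TURN] == pytest.approx(15.0)

    def test_lexicon_proportion(self, counter):
        text = "never never one two three four five six seven eight"
        turn = make_turn(0, "patient", 0, 5, text)
        assert turn_features(turn, counter)["Absolutist"] == pytest.approx(0.2)

    def test_empty_turn_policy(self, counter):
        turn = make_turn(0, "patient", 3, 8, "")
        vals = turn_features(turn, counter)
        assert all(vals[n] == 0.0 for n in PER_SPEAKER_FEATURES
                   if n != SECONDS_PER_TURN and n != WORDS_PER_SECOND)
        assert vals[SECONDS_PER_TURN] == pytest.approx(5.0)

    def test_zero_duration_turn_with_words_has_missing_rate(self, counter):
        turn = make_turn(0, "patient", 3, 3, "some words here")
        assert math.isnan(turn_features(turn, counter)[WORDS_PER_SECOND])


class TestWindowFeatures:
    def test_pooled_proportion_is_total_matches_over_total_words(self, counter):
        # therapist: 3 matches / 20 words then 1 match / 30 words -> 4/50
        t1 = "never always must " + " ".join(["pad"] * 17)
        t2 = "never " + " ".join(["pad"] * 29)
        s = make_session(["x", t1, "y", t2], turn_s=10)
        vals = window_features(s, "therapist", (0.0, s.duration_s), counter)
        assert vals["Absolutist"] == pytest.approx(4 / 50)

    def test_seconds_per_turn_ratio(self, counter):
        s = make_session(["a", "b"], turn_s=3.0)
        # stretch therapist turn to 6 s
        s.turns[1] = make_turn(1, "therapist", 4.0, 10.0, "b")
        vals = window_features(s, "therapist", (0.0, s.duration_s), counter)
        assert vals[SECONDS_PER_TURN_RATIO] == pytest.approx(2.0)

    def test_zero_patient_rate_gives_missing_ratio_not_inf(self, counter):
        s = make_session(["", "some words here"], turn_s=5.0)
        vals = window_features(s, "therapist", (0.0, s.duration_s), counter)
        assert math.isnan(vals[WORDS_PER_SECOND_RATIO])

    def test_no_turns_in_window_gives_missing(self, counter):
        s = make_session(["a", "b", "c", "d"], turn_s=10)
        vals = window_features(s, "therapist", (0.0, 5.0), counter)
        assert math.isnan(vals[SECONDS_PER_TURN])


class TestQuintiles:
    def test_midpoint_in_second_quintile(self):
        turn = make_turn(0, "patient", 11.5 * 60, 12.5 * 60, "x")
        assert assign_quintile(turn, 50 * 60) == 2

    def test_midpoint_at_duration_clamps_to_five(self):
        turn = make_turn(0, "patient", 100.0, 100.0, "x")
        assert assign_quintile(turn, 100.0) == 5

    def test_midpoint_zero_is_first_quintile(self):
        turn = make_turn(0, "patient", 0.0, 0.0, "x")
        assert assign_quintile(turn, 100.0) == 1

    def test_turn_outside_session_raises(self):
        turn = make_turn(0, "patient", 90.0, 130.0, "x")
        with pytest.raises(ValueError):
            assign_quintile(turn, 100.0)

    def test_quintile_words_partition_session_words(self, counter):
        texts = [f"word{i} never maybe i" for i in range(20)]
        s = make_session(texts, turn_s=7.0, gap_s=0.5)
        total = {}
        for role in ("therapist", "patient"):
            words = sum(
                tokenize(u.text).word_count
                for u in s.turns if u.speaker == role
            )
            per_q = 0
            for k in range(5):
                t0 = s.duration_s * k / 5
                t1 = s.duration_s * (k + 1) / 5
                per_q += sum(
                    tokenize(u.text).word_count
                    for u in s.turns
                    if u.speaker == role and (
                        t0 <= u.midpoint_s < t1
                        or (k == 4 and u.midpoint_s == t1))
                )
            assert per_q == words


class TestSignature:
    def test_signature_matches_direct_counting_oracle(self, counter, lexicons):
        s = make_session(
            ["i feel hurt", "it sounds like you feel hurt and calm",
             "we never talk", "maybe i see that now"],
            turn_s=8.0, gap_s=2.0,
        )
        sig = session_signature(s, counter)
        ther_turns = [u for u in s.turns if u.speaker == "therapist"]
        words = sum(tokenize(u.text).word_count for u in ther_turns)
        secs = sum(u.duration_s for u in ther_turns)
        for name in PER_SPEAKER_FEATURES:
            j = PER_SPEAKER_FEATURES.index(name)
            if name == SECONDS_PER_TURN:
                expected = secs / len(ther_turns)
            elif name == WORDS_PER_SECOND:
                expected = words / secs
            else:
                expected = sum(
                    count_matches(tokenize(u.text), lexicons[name])
                    for u in ther_turns
                ) / words
            assert sig[j] == pytest.approx(expected), name

    def test_signature_has_sixteen_components(self, counter):
        s = make_session(["a b", "c d", "e f", "g h"])
        assert session_signature(s, counter).shape == (16,)

    def test_doubling_text_preserves_proportions(self, counter):
        texts = ["i never hurt you", "it sounds like you feel calm"]
        s1 = make_session(texts * 2)
        s2 = make_session([t + " " + t for t in texts] * 2)
        sig1 = session_signature(s1, counter)
        sig2 = session_signature(s2, counter)
        for j, name in enumerate(PER_SPEAKER_FEATURES):
            if name in (SECONDS_PER_TURN, WORDS_PER_SECOND):
                continue
            assert sig1[j] == pytest.approx(sig2[j]), name

    def test_nested_pronoun_lexicons_order_feature_values(self, counter):
        s = make_session(["x", "you and they and i went with us and him"] * 2)
        vals = window_features(s, "therapist", (0.0, s.duration_s), counter)
        for sub in ('"You" Pronouns', '"They" Pronouns', '"I" Pronouns',
                    '"We" Pronouns'):
            assert vals["Personal Pronouns"] >= vals[sub]


class TestUtteranceSeries:
    def test_leading_therapist_turn_dropped(self, counter):
        s = make_session(["t0", "p1", "t1", "p2", "t2"],
                         first_speaker="therapist")
        us = build_utterance_series(s, counter)
        assert us.n_exchanges == 2

    def test_clean_patient_first_session_keeps_all(self, counter):
        s = make_session(["p1", "t1", "p2", "t2"])
        us = build_utterance_series(s, counter)
        assert us.n_exchanges == 2
        assert us.patient.shape == (2, 16) and us.therapist.shape == (2, 16)

    def test_non_alternating_session_raises(self, counter):
        s = make_session(["a", "b", "c"])
        s.turns[1] = make_turn(1, "patient", 11, 20, "b")
        with pytest.raises(ValueError, match="merge"):
            build_utterance_series(s, counter)

    def test_patient_turn_precedes_therapist_turn_per_exchange(self, counter):
        s = make_session(["p1 never", "t1", "p2", "t2 never never"])
        us = build_utterance_series(s, counter)
        j = PER_SPEAKER_FEATURES.index("Absolutist")
        assert us.patient[0, j] == pytest.approx(1 / 2)
        assert us.therapist[1, j] == pytest.approx(2 / 3)
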