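"""Language-feature extraction over talk turns, session quintiles and sessions.

Eighteen features in five groups are computed: five pronoun features, three
time-orientation features, two emotional-polarity features, four therapist-
tactic features (all fourteen lexicon-based, reported as proportions of words
spoken), and four paralinguistic features — seconds per talk turn, words per
second, and the two therapist-to-patient ratios thereof.

Sixteen of the eighteen are defined for a single speaker; the two ratio
features need both speakers and are therefore excluded from per-speaker
series and from therapist signatures.

Zero-denominator policy: proportions over zero words are 0; rates over zero
seconds are missing (NaN); windows containing no turns for a speaker yield
all-missing features.  Downstream stages treat missing as exclusion, never
as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .lexicons import Lexicon, TokenSequence, count_matches, tokenize
from .transcripts import PATIENT, THERAPIST, SessionTranscript, TalkTurn

SECONDS_PER_TURN = "Seconds per Talk Turn"
SECONDS_PER_TURN_RATIO = "Seconds per Talk Turn (Ratio)"
WORDS_PER_SECOND = "Words per Second"
WORDS_PER_SECOND_RATIO = "Words per Second (Ratio)"

LEXICAL_FEATURES: tuple[str, ...] = (
    '"You" Pronouns',
    '"They" Pronouns',
    "Personal Pronouns",
    '"I" Pronouns',
    '"We" Pronouns',
    "Past-Oriented",
    "Present-Oriented",
    "Future-Oriented",
    "Negative",
    "Positive",
    "Checking for Understanding",
    "Demonstrating Understanding",
    "Hedging",
    "Absolutist",
)

#: All 18 features, Table-of-features order.
FEATURES: tuple[str, ...] = LEXICAL_FEATURES + (
    SECONDS_PER_TURN,
    SECONDS_PER_TURN_RATIO,
    WORDS_PER_SECOND,
    WORDS_PER_SECOND_RATIO,
)

#: The 16 features defined for a single speaker (ratios excluded).
PER_SPEAKER_FEATURES: tuple[str, ...] = LEXICAL_FEATURES + (
    SECONDS_PER_TURN,
    WORDS_PER_SECOND,
)

FEATURE_GROUPS: dict[str, str] = {
    '"You" Pronouns': "Pronouns",
    '"They" Pronouns': "Pronouns",
    "Personal Pronouns": "Pronouns",
    '"I" Pronouns': "Pronouns",
    '"We" Pronouns': "Pronouns",
    "Past-Oriented": "Time Orientation",
    "Present-Oriented": "Time Orientation",
    "Future-Oriented": "Time Orientation",
    "Negative": "Emotional Polarity",
    "Positive": "Emotional Polarity",
    "Checking for Understanding": "Therapist Tactics",
    "Demonstrating Understanding": "Therapist Tactics",
    "Hedging": "Therapist Tactics",
    "Absolutist": "Therapist Tactics",
    SECONDS_PER_TURN: "Paralinguistic Style",
    SECONDS_PER_TURN_RATIO: "Paralinguistic Style",
    WORDS_PER_SECOND: "Paralinguistic Style",
    WORDS_PER_SECOND_RATIO: "Paralinguistic Style",
}

N_PER_SPEAKER = len(PER_SPEAKER_FEATURES)  # 16


class MatchCounter:
    """Counts matches for many lexicons in one pass over a token sequence.

    Token- and wildcard-mode lexicons are folded into a single token→features
    index; phrase-mode lexicons (few, short) are scanned individually.
    """

    def __init__(self, lexicons: Mapping[str, Lexicon]):
        self.names = [n for n in LEXICAL_FEATURES if n in lexicons]
        self._token_map: dict[str, list[str]] = {}
        self._prefixes: list[tuple[str, str]] = []  # (prefix, feature)
        self._phrase: list[Lexicon] = []
        for name in self.names:
            lex = lexicons[name]
            if lex.mode == "phrase":
                self._phrase.append(lex)
                continue
            for e in lex.entries:
                if lex.mode == "wildcard" and e.endswith("*"):
                    self._prefixes.append((e[:-1], name))
                else:
                    self._token_map.setdefault(e, []).append(name)

    def counts(self, tokens: TokenSequence) -> dict[str, int]:
        out = dict.fromkeys(self.names, 0)
        tmap = self._token_map
        for t in tokens.tokens:
            feats = tmap.get(t)
            if feats:
                for f in feats:
                    out[f] += 1
            if self._prefixes:
                for prefix, f in self._prefixes:
                    if t.startswith(prefix):
                        out[f] += 1
        for lex in self._phrase:
            out[lex.name] = count_matches(tokens, lex)
        return out


def _as_counter(lexicons) -> MatchCounter:
    return lexicons if isinstance(lexicons, MatchCounter) else MatchCounter(lexicons)


# ---------------------------------------------------------------------------
# per-turn features


def turn_features(
    turn: TalkTurn, lexicons: Mapping[str, Lexicon] | MatchCounter
) -> dict[str, float]:
    """The 16 per-speaker features of a single talk turn.

    Lexicon features are proportions matches/word_count (0 for an empty
    turn) so that turn length does not confound downstream responsiveness
    analysis; Seconds per Talk Turn is the turn duration; Words per Second is
    word_count/duration, missing for a zero-duration turn with words.
    """
    counter = _as_counter(lexicons)
    tokens = tokenize(turn.text)
    wc = tokens.word_count
    counts = counter.counts(tokens)
    vals: dict[str, float] = {}
    for name in counter.names:
        vals[name] = counts[name] / wc if wc else 0.0
    dur = turn.duration_s
    vals[SECONDS_PER_TURN] = dur
    if dur > 0:
        vals[WORDS_PER_SECOND] = wc / dur
    else:
        vals[WORDS_PER_SECOND] = math.nan if wc else 0.0
    return vals


# ---------------------------------------------------------------------------
# windows and quintiles


def assign_quintile(turn: TalkTurn, duration_s: float) -> int:
    """Quintile 1..5 of a turn, by its temporal midpoint.

    A turn belongs to exactly one quintile so its words and seconds are
    never fragmented; the midpoint decides membership and a midpoint exactly
    at session end clamps to quintile 5.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    mid = turn.midpoint_s
    if mid < 0 or mid > duration_s:
        raise ValueError(
            f"turn midpoint {mid} outside session [0, {duration_s}]"
        )
    return min(5, 1 + int(5 * mid / duration_s))


def _pooled(
    turns: Sequence[TalkTurn], counter: MatchCounter
) -> dict[str, float]:
    """Pooled per-speaker features over a set of turns (NaN if none)."""
    if not turns:
        return dict.fromkeys(PER_SPEAKER_FEATURES, math.nan)
    total_words = 0
    total_secs = 0.0
    agg = dict.fromkeys(counter.names, 0)
    for u in turns:
        tokens = tokenize(u.text)
        total_words += tokens.word_count
        total_secs += u.duration_s
        for k, v in counter.counts(tokens).items():
            agg[k] += v
    vals: dict[str, float] = {}
    for name in counter.names:
        vals[name] = agg[name] / total_words if total_words else 0.0
    vals[SECONDS_PER_TURN] = total_secs / len(turns)
    vals[WORDS_PER_SECOND] = total_words / total_secs if total_secs > 0 else math.nan
    return vals


def _ratio(t_val: float, p_val: float) -> float:
    if not (math.isfinite(t_val) and math.isfinite(p_val)) or p_val == 0:
        return math.nan
    return t_val / p_val


def window_features(
    session: SessionTranscript,
    speaker: str,
    window: tuple[float, float],
    lexicons: Mapping[str, Lexicon] | MatchCounter,
) -> dict[str, float]:
    """All 18 features over a time window; the 16 per-speaker ones for
    ``speaker``, the 2 ratios from both speakers.

    Lexicon features are pooled (total matches / total words in the window);
    Seconds per Talk Turn is the mean over the speaker's turns whose midpoint
    falls in the window; Words per Second is total words / total speaking
    seconds.  A ratio with a missing or zero patient value is missing, never
    infinite.
    """
    counter = _as_counter(lexicons)
    t0, t1 = window
    dur = session.duration_s
    closed_right = t1 >= dur  # final window includes its right edge

    def in_window(u: TalkTurn) -> bool:
        m = u.midpoint_s
        return t0 <= m < t1 or (closed_right and m == t1)

    by_role = {
        role: [u for u in session.turns if u.speaker == role and in_window(u)]
        for role in (THERAPIST, PATIENT)
    }
    per_role = {role: _pooled(turns, counter) for role, turns in by_role.items()}
    vals = dict(per_role[speaker])
    vals[SECONDS_PER_TURN_RATIO] = _ratio(
        per_role[THERAPIST][SECONDS_PER_TURN], per_role[PATIENT][SECONDS_PER_TURN]
    )
    vals[WORDS_PER_SECOND_RATIO] = _ratio(
        per_role[THERAPIST][WORDS_PER_SECOND], per_role[PATIENT][WORDS_PER_SECOND]
    )
    return vals


def quintile_windows(duration_s: float) -> list[tuple[float, float]]:
    edges = [duration_s * k / 5 for k in range(6)]
    return [(edges[k], edges[k + 1]) for k in range(5)]


def session_quintile_table(
    session: SessionTranscript, lexicons: Mapping[str, Lexicon] | MatchCounter
) -> pd.DataFrame:
    """Tidy quintile feature values: columns quintile, role, feature, value.

    Roles are therapist/patient for the 16 per-speaker features and ``dyad``
    for the two ratio features.
    """
    counter = _as_counter(lexicons)
    rows = []
    for k, win in enumerate(quintile_windows(session.duration_s), start=1):
        for role in (THERAPIST, PATIENT):
            vals = window_features(session, role, win, counter)
            for name in PER_SPEAKER_FEATURES:
                rows.append((k, role, name, vals[name]))
        for name in (SECONDS_PER_TURN_RATIO, WORDS_PER_SECOND_RATIO):
            rows.append((k, "dyad", name, vals[name]))
    return pd.DataFrame(rows, columns=["quintile", "role", "feature", "value"])


# ---------------------------------------------------------------------------
# signatures and utterance series


def session_signature(
    session: SessionTranscript, lexicons: Mapping[str, Lexicon] | MatchCounter
) -> np.ndarray:
    """The therapist's 16-dimensional linguistic signature for one session:
    whole-session per-speaker features in ``PER_SPEAKER_FEATURES`` order."""
    vals = window_features(session, THERAPIST, (0.0, session.duration_s), lexicons)
    return np.array([vals[name] for name in PER_SPEAKER_FEATURES], dtype=float)


@dataclass
class UtteranceSeries:
    """Aligned per-exchange feature series for one dyad.

    Exchange ``t`` pairs a patient turn with the therapist turn that follows
    it; the patient turn precedes the therapist turn in time, which is what
    licenses testing lag-0 patient→therapist dependence downstream.
    """

    session_id: str
    patient: np.ndarray  # (T, 16)
    therapist: np.ndarray  # (T, 16)
    feature_names: tuple[str, ...] = PER_SPEAKER_FEATURES

    @property
    def n_exchanges(self) -> int:
        return self.patient.shape[0]


def build_utterance_series(
    session: SessionTranscript, lexicons: Mapping[str, Lexicon] | MatchCounter
) -> UtteranceSeries:
    """Per-turn feature matrices aligned into (patient, therapist) exchanges.

    Requires a strictly alternating transcript (apply the same-speaker merge
    fix-up first).  A leading therapist turn and/or trailing patient turn is
    dropped so every exchange is complete.
    """
    counter = _as_counter(lexicons)
    turns = session.turns
    for a, b in zip(turns, turns[1:]):
        if a.speaker == b.speaker:
            raise ValueError(
                f"{session.session_id}: non-alternating turns "
                f"{a.turn_index},{b.turn_index}; merge same-speaker turns first"
            )
    if turns and turns[0].speaker == THERAPIST:
        turns = turns[1:]
    if turns and turns[-1].speaker == PATIENT:
        turns = turns[:-1]
    pairs = [(turns[i], turns[i + 1]) for i in range(0, len(turns) - 1, 2)]
    pat = np.empty((len(pairs), N_PER_SPEAKER))
    ther = np.empty((len(pairs), N_PER_SPEAKER))
    for t, (pu, tu) in enumerate(pairs):
        pv = turn_features(pu, counter)
        tv = turn_features(tu, counter)
        pat[t] = [pv[n] for n in PER_SPEAKER_FEATURES]
        ther[t] = [tv[n] for n in PER_SPEAKER_FEATURES]
    return UtteranceSeries(session_id=session.session_id, patient=pat, therapist=ther)


def feature_table(corpus, lexicons, include_turns: bool = False) -> pd.DataFrame:
    """Tidy feature export: session_id, speaker, window_type, window_index,
    feature, value — quintile and session windows, optionally per-turn."""
    counter = _as_counter(lexicons)
    frames = []
    for sess in corpus.sessions:
        qt = session_quintile_table(sess, counter)
        qt.insert(0, "session_id", sess.session_id)
        qt["window_type"] = "quintile"
        qt = qt.rename(columns={"quintile": "window_index", "role": "speaker"})
        frames.append(qt[["session_id", "speaker", "window_type", "window_index",
                          "feature", "value"]])
        rows = []
        for role in (THERAPIST, PATIENT):
            vals = window_features(sess, role, (0.0, sess.duration_s), counter)
            for name in PER_SPEAKER_FEATURES:
                rows.append((sess.session_id, role, "session", 0, name, vals[name]))
        for name in (SECONDS_PER_TURN_RATIO, WORDS_PER_SECOND_RATIO):
            rows.append((sess.session_id, "dyad", "session", 0, name, vals[name]))
        frames.append(pd.DataFrame(rows, columns=frames[-1].columns))
        if include_turns:
            rows = []
            for u in sess.turns:
                vals = turn_features(u, counter)
                for name in PER_SPEAKER_FEATURES:
                    rows.append(
                        (sess.session_id, u.speaker, "turn", u.turn_index, name,
                         vals[name])
                    )
            frames.append(pd.DataFrame(rows, columns=frames[-1].columns))
    return pd.concat(frames, ignore_index=True)
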