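"""Synthetic dyadic-transcript generator with known ground truth.

Real psychotherapy transcripts are never shareable, so every pipeline stage
is exercised against generated corpora in which the quantities of interest —
within-session trends, lagged patient→therapist dependencies, therapist
signature offsets, and label-linked signature shifts — are planted and
therefore recoverable.

The generative model works at the level of latent per-exchange intensities
and realizes actual word-level transcripts from them, so the full stack
(tokenization, lexicon matching, timing, feature extraction) is exercised
end to end rather than just the downstream statistics:

* latent dynamics, per session ``s`` and exchange ``t`` of ``T``:

  - patient:   ``x_t = a·x_{t−1} + m_p·(t/T) + ε``
  - therapist: ``y_t = a·y_{t−1} + Σ_links c·x_{src, t−lag} + δ + b_f(therapist)
    + m_t·(t/T) + ε``

  with AR coefficient ``a``, trend slopes ``m``, a fixed therapist-vs-patient
  baseline shift ``δ``, a per-therapist random signature offset ``b_f`` (plus
  a diagnosis-linked shift for one patient class), and Gaussian noise ε;

* realization, per turn: the word count is ``1 + Poisson`` with a rate
  modulated by the seconds-per-turn latent; each word slot emits a term of
  feature ``f``'s stand-in lexicon with probability
  ``base_f · logistic(latent_f)`` and a filler token otherwise; the turn
  duration is words divided by ``wps_base · exp(scale · latent_wps)``, so the
  observed words-per-second feature is an exact monotone readout of its
  latent.

Tokens emitted for the Personal Pronouns feature are restricted to the
third-person-singular terms so each latent drives a disjoint vocabulary;
the nested-lexicon invariant (Personal ≥ each subcategory) still holds at
match time because the subcategory tokens also match the Personal lexicon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as dc_replace
from typing import Mapping, Sequence

import numpy as np

from .features import (
    LEXICAL_FEATURES,
    PER_SPEAKER_FEATURES,
    SECONDS_PER_TURN,
    WORDS_PER_SECOND,
)
from .lexicons import builtin_lexicons
from .transcripts import (
    Corpus,
    PATIENT,
    SessionMetadata,
    SessionTranscript,
    TalkTurn,
    THERAPIST,
)

__all__ = [
    "SyntheticConfig",
    "SyntheticGroundTruth",
    "generate_corpus",
    "preset_paperlike",
    "null_config",
]

_FEAT_INDEX = {name: i for i, name in enumerate(PER_SPEAKER_FEATURES)}

#: Default per-token emission base rates for the 14 lexical features.
DEFAULT_BASE_RATES: dict[str, float] = {
    '"You" Pronouns': 0.10,
    '"They" Pronouns': 0.06,
    "Personal Pronouns": 0.06,
    '"I" Pronouns': 0.12,
    '"We" Pronouns': 0.04,
    "Past-Oriented": 0.05,
    "Present-Oriented": 0.12,
    "Future-Oriented": 0.04,
    "Negative": 0.05,
    "Positive": 0.06,
    "Checking for Understanding": 0.02,
    "Demonstrating Understanding": 0.02,
    "Hedging": 0.03,
    "Absolutist": 0.05,
}

# emission vocabularies: disjoint across features (Personal restricted to
# third-person singular); fillers collide with no lexicon term or phrase
_EMIT_OVERRIDES = {"Personal Pronouns": ("he", "she", "it")}
_FILLERS = (
    "um", "uh", "okay", "right", "so", "well", "just", "really", "kind",
    "going", "want", "feel", "talk", "about", "then", "some", "more", "time",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults mimic the shape of a college-
    counseling corpus: 78 primary sessions with unique dyads plus 20 second
    sessions from a subset of therapists, ~45-minute sessions."""

    n_primary: int = 78
    n_secondary: int = 20
    exchanges_per_session: float = 105.0
    exchanges_sd: float = 15.0
    min_exchanges: int = 40
    max_exchanges: int = 135
    word_rate: float = 22.0  # mean words per turn
    words_per_second: float = 2.0  # baseline speech rate
    turn_gap_s: float = 0.7
    ar_coeff: float = 0.3
    noise_sd: float = 0.4
    rate_scale: float = 0.25  # latent -> log-rate scale for paralinguistics
    # feature -> slope, or (patient slope, therapist slope)
    trend_slopes: Mapping[str, float | tuple[float, float]] = field(
        default_factory=dict
    )
    # feature -> fixed therapist-minus-patient latent baseline shift
    therapist_baseline_shift: Mapping[str, float] = field(default_factory=dict)
    # (patient feature, therapist feature, lag, coefficient)
    cross_links: Sequence[tuple[str, str, int, float]] = ()
    therapist_offset_sd: float = 0.0
    # feature -> latent shift added to therapist offsets when the patient's
    # diagnosis is depression
    diagnosis_effect: Mapping[str, float] = field(default_factory=dict)
    phq9_missing_rate: float = 0.10
    base_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_RATES)
    )
    seed: int = 0

    def __post_init__(self):
        if abs(self.ar_coeff) >= 1:
            raise ValueError("ar_coeff must satisfy |a| < 1")
        if self.noise_sd < 0 or self.therapist_offset_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        for src, tgt, lag, _ in self.cross_links:
            if lag < 0:
                raise ValueError("link lags must be >= 0")
            if src not in _FEAT_INDEX or tgt not in _FEAT_INDEX:
                raise ValueError(f"unknown link feature {src!r} or {tgt!r}")
        for f, r in self.base_rates.items():
            if r <= 0:
                raise ValueError(f"base rate for {f!r} must be positive")


@dataclass
class SyntheticGroundTruth:
    """Everything planted, sufficient to recompute every planted quantity."""

    config: SyntheticConfig
    therapist_offsets: dict[str, np.ndarray]  # therapist_id -> (16,)
    patient_slopes: np.ndarray  # (16,)
    therapist_slopes: np.ndarray  # (16,)
    links: list[tuple[str, str, int, float]]
    diagnosis: dict[str, str]  # session_id -> label
    phq9: dict[str, int | None]
    latent_patient: dict[str, np.ndarray]  # session_id -> (T, 16)
    latent_therapist: dict[str, np.ndarray]


def _slope_vectors(cfg: SyntheticConfig) -> tuple[np.ndarray, np.ndarray]:
    pat = np.zeros(len(PER_SPEAKER_FEATURES))
    ther = np.zeros(len(PER_SPEAKER_FEATURES))
    for name, slope in cfg.trend_slopes.items():
        j = _FEAT_INDEX[name]
        if isinstance(slope, (tuple, list)):
            pat[j], ther[j] = slope
        else:
            pat[j] = ther[j] = slope
    return pat, ther


def _emission_vocab() -> dict[str, list[tuple[str, ...]]]:
    """Per-feature list of emission units (tuples of tokens)."""
    lex = builtin_lexicons()
    vocab: dict[str, list[tuple[str, ...]]] = {}
    for name in LEXICAL_FEATURES:
        if name in _EMIT_OVERRIDES:
            entries = _EMIT_OVERRIDES[name]
        else:
            entries = sorted(lex[name].entries)
        vocab[name] = [tuple(e.split()) for e in entries]
    return vocab


def generate_corpus(
    cfg: SyntheticConfig,
) -> tuple[Corpus, SyntheticGroundTruth]:
    """Generate a corpus plus its ground truth; byte-identical per seed."""
    rng = np.random.default_rng(cfg.seed)
    nfeat = len(PER_SPEAKER_FEATURES)
    pat_slopes, ther_slopes = _slope_vectors(cfg)
    shift = np.zeros(nfeat)
    for name, v in cfg.therapist_baseline_shift.items():
        shift[_FEAT_INDEX[name]] = v
    link_spec = [
        (_FEAT_INDEX[s], _FEAT_INDEX[t], lag, c) for s, t, lag, c in cfg.cross_links
    ]
    base = np.array([cfg.base_rates[n] for n in LEXICAL_FEATURES])
    if np.sum(base) >= 1.0:
        raise ValueError("lexical base rates must sum to < 1")
    vocab = _emission_vocab()
    j_spt = _FEAT_INDEX[SECONDS_PER_TURN]
    j_wps = _FEAT_INDEX[WORDS_PER_SECOND]

    therapist_ids = [f"T{i:03d}" for i in range(cfg.n_primary)]
    offsets = {
        tid: rng.normal(0.0, cfg.therapist_offset_sd, size=nfeat)
        for tid in therapist_ids
    }
    diag_shift = np.zeros(nfeat)
    for name, v in cfg.diagnosis_effect.items():
        diag_shift[_FEAT_INDEX[name]] = v

    # session plan: primary dyads, then second sessions for the first
    # n_secondary therapists with fresh patients
    plan: list[tuple[str, str, str, str]] = []  # (sid, tid, pid, sample)
    for i, tid in enumerate(therapist_ids):
        plan.append((f"S{i:03d}", tid, f"P{i:03d}", "primary"))
    if cfg.n_secondary > cfg.n_primary:
        raise ValueError("n_secondary cannot exceed n_primary")
    for k in range(cfg.n_secondary):
        plan.append(
            (f"S{cfg.n_primary + k:03d}", therapist_ids[k],
             f"P{cfg.n_primary + k:03d}", "secondary")
        )

    n_sessions = len(plan)
    diagnoses = np.array(
        ["depression"] * (n_sessions - n_sessions // 2)
        + ["eating_disorder"] * (n_sessions // 2)
    )
    rng.shuffle(diagnoses)

    sessions: list[SessionTranscript] = []
    gt = SyntheticGroundTruth(
        config=cfg,
        therapist_offsets=offsets,
        patient_slopes=pat_slopes,
        therapist_slopes=ther_slopes,
        links=list(cfg.cross_links),
        diagnosis={},
        phq9={},
        latent_patient={},
        latent_therapist={},
    )
    stat_sd = cfg.noise_sd / math.sqrt(1.0 - cfg.ar_coeff**2)

    for idx, (sid, tid, pid, sample) in enumerate(plan):
        T = int(
            np.clip(
                round(rng.normal(cfg.exchanges_per_session, cfg.exchanges_sd)),
                cfg.min_exchanges,
                cfg.max_exchanges,
            )
        )
        diagnosis = str(diagnoses[idx])
        offset = offsets[tid] + (diag_shift if diagnosis == "depression" else 0.0)

        x = np.empty((T, nfeat))
        y = np.empty((T, nfeat))
        x_prev = rng.normal(0.0, stat_sd, size=nfeat)
        y_prev = rng.normal(0.0, stat_sd, size=nfeat)
        for t in range(T):
            frac = (t + 1) / T
            x[t] = (
                cfg.ar_coeff * x_prev
                + pat_slopes * frac
                + rng.normal(0.0, cfg.noise_sd, size=nfeat)
            )
            y[t] = (
                cfg.ar_coeff * y_prev
                + ther_slopes * frac
                + shift
                + offset
                + rng.normal(0.0, cfg.noise_sd, size=nfeat)
            )
            for js, jt, lag, c in link_spec:
                if t - lag >= 0:
                    y[t, jt] += c * x[t - lag, js]
            x_prev, y_prev = x[t], y[t]

        turns: list[TalkTurn] = []
        clock = 0.0
        for t in range(T):
            for role, lat in ((PATIENT, x[t]), (THERAPIST, y[t])):
                words, text = _realize_turn(rng, cfg, base, vocab, lat)
                wps = cfg.words_per_second * math.exp(cfg.rate_scale * lat[j_wps])
                dur = words / wps
                start = clock
                turns.append(
                    TalkTurn(
                        turn_index=len(turns),
                        speaker=role,
                        start_s=round(start, 3),
                        end_s=round(start + dur, 3),
                        text=text,
                    )
                )
                clock = start + dur + cfg.turn_gap_s * (0.6 + 0.8 * rng.random())

        sev = rng.normal(-1.0, 0.9)
        phq9: int | None = int(np.clip(round(27 / (1 + math.exp(-sev))), 0, 27))
        if rng.random() < cfg.phq9_missing_rate:
            phq9 = None
        md = SessionMetadata(
            session_id=sid,
            therapist_id=tid,
            patient_id=pid,
            diagnosis=diagnosis,
            phq9=phq9,
            sample=sample,
        )
        sessions.append(SessionTranscript(metadata=md, turns=turns))
        gt.diagnosis[sid] = diagnosis
        gt.phq9[sid] = phq9
        gt.latent_patient[sid] = x
        gt.latent_therapist[sid] = y

    return Corpus(sessions=sessions), gt


def _realize_turn(rng, cfg, base, vocab, lat) -> tuple[int, str]:
    """Realize one turn's text from its latent vector; returns (word count,
    text).  Word count is 1 + Poisson with a seconds-per-turn-modulated rate;
    phrase emissions expand to their full token tuples."""
    j_spt = _FEAT_INDEX[SECONDS_PER_TURN]
    rate = cfg.word_rate * math.exp(cfg.rate_scale * lat[j_spt])
    n_slots = 1 + rng.poisson(rate)
    probs = base / (1.0 + np.exp(-lat[: len(base)]))
    cum = np.cumsum(probs)
    u = rng.random(n_slots)
    slot_feat = np.searchsorted(cum, u)  # == len(base) -> filler
    tokens: list[str] = []
    nlex = len(base)
    for f in slot_feat:
        if f >= nlex:
            tokens.append(_FILLERS[rng.integers(len(_FILLERS))])
        else:
            units = vocab[LEXICAL_FEATURES[f]]
            tokens.extend(units[rng.integers(len(units))])
    return len(tokens), " ".join(tokens)


# ---------------------------------------------------------------------------
# presets


def preset_paperlike(seed: int = 0) -> SyntheticConfig:
    """Conditions shaped like the motivating corpus: 78 + 20 sessions,
    ~47-minute median duration, decreasing negative/past-oriented and
    increasing future-oriented/'we' language over the session, therapist
    negativity starting above the patient's and converging, a consistent
    per-therapist signature, and a few planted accommodation links
    concentrated on rate-of-speech features (the most frequent observed
    pattern, with a negative sign)."""
    return SyntheticConfig(
        trend_slopes={
            "Negative": (0.0, -1.0),
            "Past-Oriented": (-0.5, -0.9),
            "Present-Oriented": (0.4, 0.7),
            "Future-Oriented": (0.0, 0.9),
            '"We" Pronouns': (0.0, 0.9),
            '"I" Pronouns': (0.3, 0.6),
            SECONDS_PER_TURN: (0.0, 0.5),
        },
        therapist_baseline_shift={"Negative": 0.9, "Past-Oriented": 0.6},
        cross_links=[
            (WORDS_PER_SECOND, WORDS_PER_SECOND, 0, -0.5),
            (WORDS_PER_SECOND, "Personal Pronouns", 0, -0.35),
            ('"They" Pronouns', "Demonstrating Understanding", 1, 0.35),
        ],
        therapist_offset_sd=0.2,
        diagnosis_effect={
            "Positive": -0.5,
            '"You" Pronouns': 0.5,
            "Hedging": 0.4,
            "Absolutist": 0.4,
        },
        seed=seed,
    )


def null_config(seed: int = 0) -> SyntheticConfig:
    """The paperlike preset with every planted effect zeroed; used for
    type-I-error suites."""
    return dc_replace(
        preset_paperlike(seed),
        trend_slopes={},
        therapist_baseline_shift={},
        cross_links=(),
        therapist_offset_sd=0.0,
        diagnosis_effect={},
    )
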