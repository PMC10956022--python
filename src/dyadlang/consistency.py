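"""Therapist linguistic-signature consistency across sessions.

A therapist's signature is the 16-dimensional vector of whole-session
per-speaker features of their speech.  Consistency is assessed by comparing
two distributions of Pearson correlations between session signatures:

* *between*: all unordered pairs of primary-sample sessions (each primary
  session has a distinct therapist);
* *within*: each secondary session paired with the same therapist's primary
  session (same therapist, different patient).

Because the raw features live on incommensurate scales (proportions vs.
seconds vs. words/second), each feature column is z-scored across primary
sessions first — otherwise every vector correlation is dominated by the two
large-scale paralinguistic components.  Secondary sessions are transformed
with the primary-sample parameters so the two groups are commensurable.
The two correlation distributions are compared with Welch's unequal-variance
t-test (the groups differ in size by orders of magnitude).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import PER_SPEAKER_FEATURES, session_signature
from .transcripts import Corpus

__all__ = [
    "SignatureMatrix",
    "ConsistencyResult",
    "signature_matrix",
    "standardize_columns",
    "signature_correlations",
    "welch_t",
]


@dataclass
class SignatureMatrix:
    values: np.ndarray  # (n_sessions, 16)
    session_ids: list[str]
    therapist_ids: list[str]
    samples: list[str]  # "primary" | "secondary" per row
    standardized: bool = False
    feature_names: tuple[str, ...] = PER_SPEAKER_FEATURES

    def primary_mask(self) -> np.ndarray:
        return np.array([s == "primary" for s in self.samples])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "session_id", self.session_ids)
        df.insert(1, "therapist_id", self.therapist_ids)
        df.insert(2, "sample", self.samples)
        return df


def signature_matrix(corpus: Corpus, lexicons) -> SignatureMatrix:
    """Stack the therapist signature of every session in the corpus."""
    rows, sids, tids, samples = [], [], [], []
    for sess in corpus.sessions:
        rows.append(session_signature(sess, lexicons))
        sids.append(sess.session_id)
        tids.append(sess.metadata.therapist_id)
        samples.append(sess.metadata.sample)
    return SignatureMatrix(np.array(rows), sids, tids, samples)


def standardize_columns(m: SignatureMatrix) -> SignatureMatrix:
    """Z-score each feature column using primary-session mean and sample sd.

    Secondary sessions are transformed with the same parameters.  A
    zero-variance column over the primary sessions is an error naming the
    feature.  Idempotent up to floating point once standardized.
    """
    prim = m.values[m.primary_mask()]
    mean = prim.mean(axis=0)
    sd = prim.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if not np.isfinite(s) or s == 0:
            raise ValueError(
                f"feature {m.feature_names[j]!r} has zero variance over primary "
                "sessions; cannot standardize"
            )
    return SignatureMatrix(
        values=(m.values - mean) / sd,
        session_ids=list(m.session_ids),
        therapist_ids=list(m.therapist_ids),
        samples=list(m.samples),
        standardized=True,
        feature_names=m.feature_names,
    )


def welch_t(a, b) -> tuple[float, float, float]:
    """Welch unequal-variance t statistic, Welch–Satterthwaite df, two-sided p.

    Both samples constant with equal means → t = 0, p = 1 by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t needs at least 2 observations per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        return math.inf, float(a.size + b.size - 2), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class ConsistencyResult:
    between: np.ndarray  # correlations, one per distinct-therapist primary pair
    within: np.ndarray  # correlations, one per (primary, secondary) same-therapist pair
    between_pairs: list[tuple[str, str]]
    within_pairs: list[tuple[str, str]]
    skipped_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def mean_between(self) -> float:
        return float(self.between.mean())

    @property
    def mean_within(self) -> float:
        return float(self.within.mean())

    def ci_between(self) -> tuple[float, float]:
        return _normal_ci(self.between)

    def ci_within(self) -> tuple[float, float]:
        return _normal_ci(self.within)

    def t_test(self) -> tuple[float, float, float]:
        """Welch comparison of the within vs between correlation samples."""
        return welch_t(self.within, self.between)

    def summary(self) -> dict:
        t, df, p = self.t_test()
        return {
            "n_between": int(self.between.size),
            "n_within": int(self.within.size),
            "mean_between": self.mean_between,
            "ci_between": list(self.ci_between()),
            "mean_within": self.mean_within,
            "ci_within": list(self.ci_within()),
            "t": t,
            "df": df,
            "p": p,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"pair_type": "between", "session_a": a, "session_b": b, "correlation": r}
            for (a, b), r in zip(self.between_pairs, self.between)
        ] + [
            {"pair_type": "within", "session_a": a, "session_b": b, "correlation": r}
            for (a, b), r in zip(self.within_pairs, self.within)
        ]
        return pd.DataFrame(rows)


def _normal_ci(x: np.ndarray, z: float = 1.96) -> tuple[float, float]:
    se = x.std(ddof=1) / math.sqrt(x.size) if x.size > 1 else math.nan
    return float(x.mean() - z * se), float(x.mean() + z * se)


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    du = u - u.mean()
    dv = v - v.mean()
    denom = math.sqrt(float(du @ du) * float(dv @ dv))
    if denom == 0:
        return math.nan
    return float(du @ dv) / denom


def signature_correlations(m: SignatureMatrix) -> ConsistencyResult:
    """Between- and within-therapist signature correlation distributions.

    Correlations are Pearson across the 16 feature components of two session
    vectors of the standardized matrix.  Between pairs every pair of primary
    sessions with distinct therapists; within pairs every secondary session
    with its therapist's primary session.  Pairs involving a constant vector
    (undefined correlation) are skipped and reported.
    """
    if not m.standardized:
        m = standardize_columns(m)
    idx_primary = [i for i, s in enumerate(m.samples) if s == "primary"]
    idx_secondary = [i for i, s in enumerate(m.samples) if s == "secondary"]
    if len(idx_primary) < 2:
        raise ValueError("need at least 2 primary sessions")
    between, between_pairs, skipped = [], [], []
    for ai in range(len(idx_primary)):
        for bi in range(ai + 1, len(idx_primary)):
            i, j = idx_primary[ai], idx_primary[bi]
            if m.therapist_ids[i] == m.therapist_ids[j]:
                continue
            r = _pearson(m.values[i], m.values[j])
            pair = (m.session_ids[i], m.session_ids[j])
            if math.isnan(r):
                skipped.append(pair)
            else:
                between.append(r)
                between_pairs.append(pair)
    primary_by_therapist = {m.therapist_ids[i]: i for i in idx_primary}
    within, within_pairs = [], []
    for j in idx_secondary:
        i = primary_by_therapist.get(m.therapist_ids[j])
        if i is None:
            continue
        r = _pearson(m.values[i], m.values[j])
        pair = (m.session_ids[i], m.session_ids[j])
        if math.isnan(r):
            skipped.append(pair)
        else:
            within.append(r)
            within_pairs.append(pair)
    return ConsistencyResult(
        between=np.array(between),
        within=np.array(within),
        between_pairs=between_pairs,
        within_pairs=within_pairs,
        skipped_pairs=skipped,
    )
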