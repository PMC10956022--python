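"""Study-design arithmetic for dyadic corpora.

Small closed-form helpers that turn corpus design counts (sessions,
exclusions, features, discovered links) into the derived quantities reported
alongside the analyses: number of between-therapist signature pairs, number
of candidate lagged links, retention after screening, and link-rate
summaries.
"""

from __future__ import annotations

from math import comb

from .features import N_PER_SPEAKER


def between_pair_count(n_primary: int) -> int:
    """Number of unordered distinct-therapist signature pairs, C(n, 2)."""
    return comb(n_primary, 2)


def retained_session_count(
    n_sessions: int, n_nonstationary: int, n_zero_variance: int
) -> int:
    """Sessions surviving the responsiveness screen."""
    return n_sessions - n_nonstationary - n_zero_variance


def candidate_link_count(n_dyads: int, n_features: int = N_PER_SPEAKER) -> int:
    """Patient-feature × therapist-feature pairs tested across dyads."""
    return n_features * n_features * n_dyads


def significant_link_rate_percent(n_significant: int, n_candidates: int) -> float:
    """Share of candidate associations found significant, in percent."""
    return 100.0 * n_significant / n_candidates


def links_per_dyad(n_significant: int, n_dyads: int) -> float:
    """Mean number of significant links per dyad."""
    return n_significant / n_dyads


def design_summary(
    n_primary: int,
    n_nonstationary: int,
    n_zero_variance: int,
    n_significant: int,
    n_features: int = N_PER_SPEAKER,
) -> dict[str, float]:
    """All derived design quantities for one responsiveness run."""
    retained = retained_session_count(n_primary, n_nonstationary, n_zero_variance)
    candidates = candidate_link_count(retained, n_features)
    return {
        "between_pair_count": between_pair_count(n_primary),
        "retained_sessions": retained,
        "candidate_links": candidates,
        "significant_links": n_significant,
        "significant_link_rate_percent": significant_link_rate_percent(
            n_significant, candidates
        ),
        "links_per_dyad": links_per_dyad(n_significant, retained),
    }
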