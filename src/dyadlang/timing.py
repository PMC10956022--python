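"""Within-session timing dynamics of language features.

Sessions are cut into temporal quintiles; each feature's per-quintile value
(one observation per session) feeds three kinds of analysis:

* descriptive quintile curves, optionally smoothed with a natural cubic
  spline for plotting;
* first-vs-last-quintile contrasts per feature and role, via the
  Mann–Whitney U test;
* therapist-vs-patient contrasts within the first and within the last
  quintile, also Mann–Whitney.

All contrasts from one run form a single declared family for
Benjamini–Hochberg FDR control at level alpha.  The pattern of significance
of the therapist-vs-patient contrasts at the two ends of the session labels
each feature's alignment: significant early but not late → *convergent*;
not early but late → *divergent*; both → *parallel-distinct*; neither →
*indistinct*.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import CubicSpline
from statsmodels.stats.multitest import multipletests

from .features import (
    FEATURES,
    PER_SPEAKER_FEATURES,
    SECONDS_PER_TURN_RATIO,
    WORDS_PER_SECOND_RATIO,
    _as_counter,
    session_quintile_table,
)
from .transcripts import Corpus, PATIENT, THERAPIST

RATIO_FEATURES = (SECONDS_PER_TURN_RATIO, WORDS_PER_SECOND_RATIO)

# maximum pooled sample size for exact Mann-Whitney enumeration
_EXACT_N = 12


# ---------------------------------------------------------------------------
# statistical primitives


def mann_whitney_u(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Mann–Whitney U (for sample ``a``) with two-sided p-value.

    Ties contribute 1/2 to U.  When the pooled sample size is at most 12 the
    p-value is computed by exact enumeration of all group labelings (valid
    under ties); otherwise the normal approximation with tie-corrected
    variance and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(a, b)
    n = a.size + b.size
    if n <= _EXACT_N:
        p = _exact_p(a, b, u)
    else:
        _, p = stats.mannwhitneyu(a, b, alternative="two-sided",
                                  method="asymptotic", use_continuity=True)
    return float(u), float(p)


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([a, b]))
    r_a = ranks[: a.size].sum()
    return r_a - a.size * (a.size + 1) / 2


def _exact_p(a: np.ndarray, b: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p: P(|U - mu| >= |u_obs - mu|) over all labelings."""
    pooled = np.concatenate([a, b])
    n, n_a = pooled.size, a.size
    mu = n_a * b.size / 2
    ranks = stats.rankdata(pooled)
    extreme = 0
    total = 0
    offset = n_a * (n_a + 1) / 2
    for idx in itertools.combinations(range(n), n_a):
        u = ranks[list(idx)].sum() - offset
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return extreme / total


def bh_fdr(ps: Sequence[float], alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR control.

    Returns (reject flags, monotone adjusted values) for the declared family
    ``ps`` at level ``alpha``.
    """
    ps = np.asarray(ps, dtype=float)
    if ps.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((ps < 0) | (ps > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
    return reject, q


def natural_cubic_spline(xs: Sequence[float], ys: Sequence[float]) -> CubicSpline:
    """Interpolating natural cubic spline (zero second derivative at both
    ends); used to smooth the five quintile-aggregate points for display."""
    xs = np.asarray(xs, dtype=float)
    if np.any(np.diff(xs) <= 0):
        raise ValueError("xs must be strictly increasing")
    return CubicSpline(xs, np.asarray(ys, dtype=float), bc_type="natural")


# ---------------------------------------------------------------------------
# quintile curves


@dataclass
class QuintileCurve:
    feature: str
    role: str
    means: np.ndarray  # (5,)
    per_session: list[np.ndarray]  # 5 arrays of per-session values

    def normalized(self) -> np.ndarray:
        """Min-max over the five aggregate points, for plotting."""
        lo, hi = self.means.min(), self.means.max()
        if hi == lo:
            return np.full(5, 0.5)
        return (self.means - lo) / (hi - lo)


def quintile_curves(
    corpus: Corpus, lexicons, roles: tuple[str, ...] = (THERAPIST, PATIENT)
) -> dict[tuple[str, str], QuintileCurve]:
    """Per-(feature, role) five-point curves over the primary sample.

    The curve point for quintile k is the mean over sessions of that
    session's quintile-k value; sessions whose value is missing in a cell
    are excluded from that cell.  Ratio features appear under role "dyad".
    """
    counter = _as_counter(lexicons)
    tables = [
        session_quintile_table(s, counter) for s in corpus.primary_sessions
    ]
    stacked = pd.concat(tables, ignore_index=True)
    out: dict[tuple[str, str], QuintileCurve] = {}
    want_roles = set(roles) | {"dyad"}
    for (feature, role), grp in stacked.groupby(["feature", "role"], sort=False):
        if role not in want_roles:
            continue
        per_session = []
        means = np.empty(5)
        for k in range(1, 6):
            vals = grp.loc[grp["quintile"] == k, "value"].to_numpy()
            vals = vals[np.isfinite(vals)]
            per_session.append(vals)
            means[k - 1] = vals.mean() if vals.size else math.nan
        if not np.any(np.isfinite(means)):
            continue  # feature never observed: drop
        out[(feature, role)] = QuintileCurve(feature, role, means, per_session)
    return out


# ---------------------------------------------------------------------------
# contrasts


@dataclass
class ContrastResult:
    feature: str
    role: str  # therapist | patient | dyad for Q1-vs-Q5; quintile tag for T-vs-P
    contrast: str  # "Q1-vs-Q5" | "T-vs-P@Q1" | "T-vs-P@Q5"
    u_stat: float
    p: float
    q: float = math.nan
    significant: bool = False


@dataclass
class AlignmentLabel:
    feature: str
    label: str  # convergent | divergent | parallel-distinct | indistinct


def timing_contrasts(
    corpus: Corpus, lexicons, alpha: float = 0.05
) -> tuple[list[ContrastResult], list[AlignmentLabel]]:
    """All timing contrasts with FDR over the combined family.

    Families pooled into one BH family per run: (i) first-vs-last-quintile
    per feature for each role (ratio features under role "dyad"); (ii)
    therapist-vs-patient within quintile 1 and within quintile 5 per
    per-speaker feature.  Samples are per-session quintile values, sessions
    treated as independent.
    """
    curves = quintile_curves(corpus, lexicons)
    results: list[ContrastResult] = []

    def add(feature, role, contrast, a, b):
        if len(a) == 0 or len(b) == 0:
            return
        u, p = mann_whitney_u(a, b)
        results.append(ContrastResult(feature, role, contrast, u, p))

    for (feature, role), curve in curves.items():
        add(feature, role, "Q1-vs-Q5", curve.per_session[0], curve.per_session[4])
    for feature in PER_SPEAKER_FEATURES:
        ck_t = curves.get((feature, THERAPIST))
        ck_p = curves.get((feature, PATIENT))
        if ck_t is None or ck_p is None:
            continue
        add(feature, "both", "T-vs-P@Q1", ck_t.per_session[0], ck_p.per_session[0])
        add(feature, "both", "T-vs-P@Q5", ck_t.per_session[4], ck_p.per_session[4])

    reject, qvals = bh_fdr([r.p for r in results], alpha=alpha)
    for r, rej, q in zip(results, reject, qvals):
        r.q = float(q)
        r.significant = bool(rej)

    labels = []
    for feature in PER_SPEAKER_FEATURES:
        sig = {
            r.contrast: r.significant
            for r in results
            if r.feature == feature and r.contrast.startswith("T-vs-P")
        }
        if "T-vs-P@Q1" not in sig or "T-vs-P@Q5" not in sig:
            continue
        q1, q5 = sig["T-vs-P@Q1"], sig["T-vs-P@Q5"]
        if q1 and not q5:
            lab = "convergent"
        elif q5 and not q1:
            lab = "divergent"
        elif q1 and q5:
            lab = "parallel-distinct"
        else:
            lab = "indistinct"
        labels.append(AlignmentLabel(feature, lab))
    return results, labels


def plot_quintile_curves(
    curves: Mapping[tuple[str, str], QuintileCurve],
    out_dir,
    role: str = THERAPIST,
):
    """Write one PNG per feature group: min-max-normalized quintile means
    with their natural-cubic-spline smooths.  Returns the written paths."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    from .features import FEATURE_GROUPS

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_group: dict[str, list[QuintileCurve]] = {}
    for (feature, r), curve in curves.items():
        if r == role or (r == "dyad" and role == THERAPIST):
            by_group.setdefault(FEATURE_GROUPS[feature], []).append(curve)
    xs = np.arange(1, 6)
    dense = np.linspace(1, 5, 101)
    paths = []
    for group, group_curves in sorted(by_group.items()):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        for curve in group_curves:
            ys = curve.normalized()
            if not np.all(np.isfinite(ys)):
                continue
            spline = natural_cubic_spline(xs, ys)
            (line,) = ax.plot(dense, spline(dense), label=curve.feature, lw=1.5)
            ax.plot(xs, ys, "o", ms=3, color=line.get_color())
        ax.set_xticks(xs)
        ax.set_xlabel("session quintile")
        ax.set_ylabel("normalized frequency")
        ax.set_title(group)
        ax.legend(fontsize=6)
        fig.tight_layout()
        path = out / f"curves_{group.lower().replace(' ', '_')}.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)
    return paths


def contrasts_table(
    results: list[ContrastResult], labels: list[AlignmentLabel]
) -> pd.DataFrame:
    """Flat CSV-ready table of contrasts with alignment labels joined in."""
    lab_by_feature = {l.feature: l.label for l in labels}
    rows = [
        {
            "feature": r.feature,
            "role": r.role,
            "contrast": r.contrast,
            "U": r.u_stat,
            "p": r.p,
            "q": r.q,
            "significant": r.significant,
            "alignment_label": lab_by_feature.get(r.feature, ""),
        }
        for r in results
    ]
    return pd.DataFrame(rows)
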