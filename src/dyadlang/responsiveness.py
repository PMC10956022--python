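"""Discovery of lagged patient→therapist dependencies in dyadic time series.

The exchange-indexed per-turn feature series of a dyad (16 patient + 16
therapist variables) is first-differenced to remove macro-level trends,
screened (length, zero variance, stationarity after differencing via the
augmented Dickey–Fuller test), and then searched for lagged dependencies
with a two-stage conditional-independence procedure:

1. *condition selection* (PC1): for every variable, iteratively shrink the
   set of lagged candidate parents by removing candidates whose partial
   correlation with the target — given the strongest ``q`` other candidates —
   is non-significant, for growing ``q``;
2. *momentary conditional independence* (MCI): each candidate link
   ``X_i(t−τ) → Y_j(t)`` is tested by the partial correlation of the lagged
   source and the target given the selected parents of **both** variables
   (the source's parents shifted by τ), which controls observed confounding
   and autocorrelation.

Only the patient→therapist direction enters the reported family.  Lag 0 is
admissible in that direction because the patient turn of an exchange
precedes the therapist turn in time.  Per dyad, the 16×16 feature pairs ×
(tau_max+1) lags form the family for Benjamini–Hochberg FDR control; a
feature pair is significant if any of its lags survives, and its reported
coefficient is the partial correlation of the surviving lag with largest
magnitude (ties going to the smaller lag).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.tsa.stattools import adfuller

from .features import N_PER_SPEAKER, PER_SPEAKER_FEATURES, UtteranceSeries
from .timing import bh_fdr

__all__ = [
    "ResponsivenessConfig",
    "ScreenReport",
    "LaggedLink",
    "DyadGraph",
    "first_difference",
    "adf_stationary",
    "screen_session",
    "partial_corr_test",
    "pc1_parents",
    "mci_link_tests",
    "dyad_graph",
    "aggregate_graphs",
    "analyze_responsiveness",
]


@dataclass(frozen=True)
class ResponsivenessConfig:
    tau_max: int = 2
    alpha_pc: float = 0.2
    alpha: float = 0.05
    fdr_scope: str = "per_dyad"  # or "global"
    min_exchanges: int = 10

    def __post_init__(self):
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        if not (0 < self.alpha_pc < 1 and 0 < self.alpha < 1):
            raise ValueError("alpha levels must lie in (0, 1)")
        if self.fdr_scope not in ("per_dyad", "global"):
            raise ValueError(f"unknown fdr_scope {self.fdr_scope!r}")


@dataclass
class ScreenReport:
    session_id: str
    included: bool
    reason: str  # ok | too_short | zero_variance_feature | nonstationary_after_differencing
    offending: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class LaggedLink:
    source: str  # patient feature
    target: str  # therapist feature
    lag: int
    rho: float
    p: float
    q: float
    significant: bool


@dataclass
class DyadGraph:
    session_id: str
    links: list[LaggedLink]
    n_tested: int  # 16 x 16 feature pairs


# ---------------------------------------------------------------------------
# preprocessing


def first_difference(series: Sequence[float] | np.ndarray) -> np.ndarray:
    """Consecutive differences; length shrinks by one."""
    arr = np.asarray(series, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 observations to difference")
    return np.diff(arr, axis=0)


@dataclass(frozen=True)
class AdfResult:
    statistic: float
    p: float
    stationary: bool


def adf_stationary(series: Sequence[float], alpha: float = 0.05) -> AdfResult:
    """Augmented Dickey–Fuller unit-root test (constant, fixed lag order 1).

    ``stationary`` is True when the unit-root null is rejected at ``alpha``
    (MacKinnon approximate p-value).  Zero-variance input cannot be tested
    and raises; callers screen for it separately.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 20:
        raise ValueError("ADF screening needs at least 20 observations")
    if np.ptp(x) == 0:
        raise ValueError("zero-variance series cannot be tested for a unit root")
    stat, p, *_ = adfuller(x, maxlag=1, regression="c", autolag=None)
    return AdfResult(float(stat), float(p), bool(p < alpha))


def _stack_series(series: UtteranceSeries) -> tuple[np.ndarray, list[str]]:
    data = np.hstack([series.patient, series.therapist])
    names = [f"patient:{n}" for n in PER_SPEAKER_FEATURES] + [
        f"therapist:{n}" for n in PER_SPEAKER_FEATURES
    ]
    return data, names


def screen_session(series: UtteranceSeries, cfg: ResponsivenessConfig) -> ScreenReport:
    """Decide whether a dyad's series is analyzable.

    Exclusion reasons, in order of precedence: too few exchanges; a feature
    column with zero variance (before or after differencing, or containing
    non-finite values); a column that remains non-stationary after
    differencing per the ADF test.  Sessions too short for the ADF test
    (< 21 exchanges) skip the stationarity screen.
    """
    sid = series.session_id
    if series.n_exchanges < cfg.min_exchanges:
        return ScreenReport(sid, False, "too_short")
    data, names = _stack_series(series)
    bad = [
        name
        for col, name in zip(data.T, names)
        if not np.all(np.isfinite(col)) or np.ptp(col) == 0
    ]
    if bad:
        return ScreenReport(sid, False, "zero_variance_feature", bad)
    diffed = first_difference(data)
    bad = [name for col, name in zip(diffed.T, names) if np.ptp(col) == 0]
    if bad:
        return ScreenReport(sid, False, "zero_variance_feature", bad)
    if diffed.shape[0] >= 20:
        nonstat = [
            name
            for col, name in zip(diffed.T, names)
            if not adf_stationary(col, cfg.alpha).stationary
        ]
        if nonstat:
            return ScreenReport(sid, False, "nonstationary_after_differencing", nonstat)
    return ScreenReport(sid, True, "ok")


# ---------------------------------------------------------------------------
# partial correlation


def partial_corr_test(
    x: np.ndarray, y: np.ndarray, Z: Iterable[np.ndarray] | np.ndarray | None = None
) -> tuple[float, float]:
    """Partial correlation of x and y given Z, with a two-sided t-test p.

    x and y are residualized on Z (plus an intercept) by least squares; the
    Pearson correlation rho of the residuals is referred to a t distribution
    with n − |Z| − 2 degrees of freedom.  Degenerate residuals (zero
    variance) yield rho = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if Z is None:
        zmat = np.empty((x.size, 0))
    elif isinstance(Z, np.ndarray):
        zmat = Z[:, None] if Z.ndim == 1 else Z
    else:
        zlist = list(Z)
        zmat = np.column_stack(zlist) if zlist else np.empty((x.size, 0))
    n = x.size
    k = zmat.shape[1]
    df = n - k - 2
    if df < 1:
        raise ValueError(f"too few samples (n={n}) for {k} conditioners")
    design = np.column_stack([np.ones(n), zmat])
    coef, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ coef
    rx, ry = resid[:, 0], resid[:, 1]
    sx = float(rx @ rx)
    sy = float(ry @ ry)
    # residual variance indistinguishable from rounding noise -> degenerate
    if sx <= 1e-12 * (float(x @ x) + 1.0) or sy <= 1e-12 * (float(y @ y) + 1.0):
        return 0.0, 1.0
    rho = float(rx @ ry) / math.sqrt(sx * sy)
    rho = max(-1.0, min(1.0, rho))
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt(df / (1.0 - rho * rho))
    p = 2.0 * stats.t.sf(abs(t), df)
    return rho, float(p)


# ---------------------------------------------------------------------------
# PC1 condition selection


def _lagged(data: np.ndarray, i: int, tau: int, start: int) -> np.ndarray:
    """Column i lagged by tau, on the common sample t = start..T-1."""
    T = data.shape[0]
    return data[start - tau : T - tau, i]


def pc1_parents(
    data: np.ndarray,
    tau_max: int,
    alpha_pc: float = 0.2,
    max_conds: int | None = None,
) -> dict[int, list[tuple[int, int]]]:
    """Select lagged parents for every variable (PC1 condition selection).

    For each target, candidates are all (variable, lag) pairs with lag in
    1..tau_max.  Starting from unconditional tests, each surviving candidate
    is re-tested given the ``q`` strongest other candidates, with ``q``
    increasing until it exceeds the number of survivors; a candidate is
    dropped as soon as one test is non-significant at ``alpha_pc``.  A
    candidate's sort strength is the minimum |rho| over its tests.

    Returns {variable index: [(parent index, lag), ...]} sorted by strength.
    The conditioning-set size is capped so the residual degrees of freedom
    stay positive (and at ``max_conds`` if given).
    """
    T, V = data.shape
    n = T - tau_max
    if n < tau_max + 5:
        raise ValueError("series too short for the requested tau_max")
    cap = max(0, n - 4)
    if max_conds is not None:
        cap = min(cap, max_conds)

    cols = {
        (i, tau): _lagged(data, i, tau, tau_max)
        for i in range(V)
        for tau in range(0, tau_max + 1)
    }
    parents: dict[int, list[tuple[int, int]]] = {}
    for j in range(V):
        y = cols[(j, 0)]
        strength: dict[tuple[int, int], float] = {}
        alive: list[tuple[int, int]] = []
        for tau in range(1, tau_max + 1):
            for i in range(V):
                c = (i, tau)
                rho, p = partial_corr_test(cols[c], y)
                if p <= alpha_pc:
                    strength[c] = abs(rho)
                    alive.append(c)
        alive.sort(key=lambda c: -strength[c])
        q = 1
        while q <= len(alive) - 1 and q <= cap:
            removed = False
            for c in list(alive):
                others = [o for o in alive if o != c][:q]
                rho, p = partial_corr_test(
                    cols[c], y, [cols[o] for o in others]
                )
                if p > alpha_pc:
                    alive.remove(c)
                    removed = True
                else:
                    strength[c] = min(strength[c], abs(rho))
            alive.sort(key=lambda c: -strength[c])
            if not removed and q >= len(alive) - 1:
                break
            q += 1
        parents[j] = alive
    return parents


# ---------------------------------------------------------------------------
# MCI tests


def mci_test(
    data: np.ndarray,
    i: int,
    tau: int,
    j: int,
    parents: dict[int, list[tuple[int, int]]],
    tau_max: int,
    max_conds: int | None = None,
) -> tuple[float, float]:
    """Momentary conditional independence test for X_i(t−tau) → X_j(t).

    Conditions on parents(X_j) at their own lags and parents(X_i) shifted by
    tau, excluding the tested pair itself; duplicated conditioners are used
    once.
    """
    cond: list[tuple[int, int]] = []
    for (k, lag) in parents.get(j, []):
        if (k, lag) != (i, tau):
            cond.append((k, lag))
    for (k, lag) in parents.get(i, []):
        shifted = (k, lag + tau)
        if shifted != (i, tau) and shifted != (j, 0) and shifted not in cond:
            cond.append(shifted)
    if max_conds is not None:
        cond = cond[:max_conds]
    start = max([tau_max + tau] + [lag for _, lag in cond])
    x = _lagged(data, i, tau, start)
    y = _lagged(data, j, 0, start)
    Z = [_lagged(data, k, lag, start) for k, lag in cond]
    n = x.size
    while Z and n - len(Z) - 2 < 1:  # cap conditioning for very short series
        Z.pop()
    return partial_corr_test(x, y, Z if Z else None)


def mci_link_tests(
    data: np.ndarray,
    parents: dict[int, list[tuple[int, int]]],
    cfg: ResponsivenessConfig,
    source_idx: Sequence[int] | None = None,
    target_idx: Sequence[int] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MCI (rho, p) for every source×target×lag combination, lags 0..tau_max.

    By default sources are the 16 patient columns and targets the 16
    therapist columns of a stacked dyad matrix — the headline
    patient→therapist family, in which lag 0 is temporally ordered.
    """
    if source_idx is None:
        source_idx = range(N_PER_SPEAKER)
    if target_idx is None:
        target_idx = range(N_PER_SPEAKER, 2 * N_PER_SPEAKER)
    L = cfg.tau_max + 1
    rho = np.empty((len(source_idx), len(target_idx), L))
    pvals = np.empty_like(rho)
    for a, i in enumerate(source_idx):
        for b, j in enumerate(target_idx):
            for tau in range(L):
                r, p = mci_test(data, i, tau, j, parents, cfg.tau_max)
                rho[a, b, tau] = r
                pvals[a, b, tau] = p
    return rho, pvals


# ---------------------------------------------------------------------------
# dyad graphs


def _links_from_matrices(
    session_id: str,
    rho: np.ndarray,
    pvals: np.ndarray,
    qvals: np.ndarray,
    reject: np.ndarray,
) -> DyadGraph:
    n_src, n_tgt, L = rho.shape
    links: list[LaggedLink] = []
    for a in range(n_src):
        for b in range(n_tgt):
            lags = [tau for tau in range(L) if reject[a, b, tau]]
            if not lags:
                continue
            # strongest surviving lag; ties on |rho| broken by smaller lag
            best = max(lags, key=lambda tau: (abs(rho[a, b, tau]), -tau))
            links.append(
                LaggedLink(
                    source=PER_SPEAKER_FEATURES[a],
                    target=PER_SPEAKER_FEATURES[b],
                    lag=best,
                    rho=float(rho[a, b, best]),
                    p=float(pvals[a, b, best]),
                    q=float(qvals[a, b, best]),
                    significant=True,
                )
            )
    return DyadGraph(session_id=session_id, links=links, n_tested=n_src * n_tgt)


def dyad_graph(
    series: UtteranceSeries, cfg: ResponsivenessConfig = ResponsivenessConfig()
) -> DyadGraph:
    """Significant patient→therapist links for one screened dyad.

    Differences the stacked 32-column series, selects parents with PC1,
    runs the MCI tests for all 256 feature pairs at lags 0..tau_max, and
    applies BH-FDR over that per-dyad family at level ``cfg.alpha``.
    """
    data, _ = _stack_series(series)
    diffed = first_difference(data)
    parents = pc1_parents(diffed, cfg.tau_max, cfg.alpha_pc)
    rho, pvals = mci_link_tests(diffed, parents, cfg)
    reject, q = bh_fdr(pvals.ravel(), alpha=cfg.alpha)
    return _links_from_matrices(
        series.session_id, rho, pvals, q.reshape(pvals.shape),
        reject.reshape(pvals.shape),
    )


def analyze_responsiveness(
    all_series: Sequence[UtteranceSeries],
    cfg: ResponsivenessConfig = ResponsivenessConfig(),
) -> tuple[list[ScreenReport], list[DyadGraph]]:
    """Screen every dyad and build its link graph.

    With ``cfg.fdr_scope == "global"`` the BH family is the union of all
    included dyads' (pair, lag) tests instead of one family per dyad.
    """
    reports = [screen_session(s, cfg) for s in all_series]
    included = [
        s for s, rep in zip(all_series, reports) if rep.included
    ]
    if cfg.fdr_scope == "per_dyad":
        graphs = [dyad_graph(s, cfg) for s in included]
        return reports, graphs
    # global scope: pool p-values across dyads before BH
    per_dyad = []
    for s in included:
        data, _ = _stack_series(s)
        diffed = first_difference(data)
        parents = pc1_parents(diffed, cfg.tau_max, cfg.alpha_pc)
        rho, pvals = mci_link_tests(diffed, parents, cfg)
        per_dyad.append((s.session_id, rho, pvals))
    if not per_dyad:
        return reports, []
    pooled = np.concatenate([p.ravel() for _, _, p in per_dyad])
    reject, q = bh_fdr(pooled, alpha=cfg.alpha)
    graphs = []
    ofs = 0
    for sid, rho, pvals in per_dyad:
        k = pvals.size
        graphs.append(
            _links_from_matrices(
                sid,
                rho,
                pvals,
                q[ofs : ofs + k].reshape(pvals.shape),
                reject[ofs : ofs + k].reshape(pvals.shape),
            )
        )
        ofs += k
    return reports, graphs


# ---------------------------------------------------------------------------
# aggregation


def aggregate_graphs(
    graphs: Sequence[DyadGraph], min_count: int = 1
) -> pd.DataFrame:
    """Cross-dyad link frequencies: one row per (source, target) feature pair
    with the number of dyads showing it, the mean partial correlation among
    those dyads, and the positive/negative sign breakdown."""
    if not graphs:
        raise ValueError("need at least one dyad graph")
    acc: dict[tuple[str, str], list[float]] = {}
    for g in graphs:
        for link in g.links:
            acc.setdefault((link.source, link.target), []).append(link.rho)
    rows = [
        {
            "source": src,
            "target": tgt,
            "count": len(rhos),
            "mean_rho": float(np.mean(rhos)),
            "n_positive": sum(1 for r in rhos if r > 0),
            "n_negative": sum(1 for r in rhos if r < 0),
        }
        for (src, tgt), rhos in acc.items()
        if len(rhos) >= min_count
    ]
    df = pd.DataFrame(
        rows, columns=["source", "target", "count", "mean_rho",
                       "n_positive", "n_negative"]
    )
    return df.sort_values(["count", "source", "target"],
                          ascending=[False, True, True]).reset_index(drop=True)


def links_table(graphs: Sequence[DyadGraph]) -> pd.DataFrame:
    rows = [
        {
            "session_id": g.session_id,
            "source": l.source,
            "target": l.target,
            "lag": l.lag,
            "rho": l.rho,
            "p": l.p,
            "q": l.q,
        }
        for g in graphs
        for l in g.links
    ]
    return pd.DataFrame(
        rows, columns=["session_id", "source", "target", "lag", "rho", "p", "q"]
    )
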