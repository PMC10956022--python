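"""Independent reference implementations used only as test oracles.

Each oracle is deliberately coded by a different route than the library
(explicit enumeration, generic optimization, naive loops) so agreement is
evidence of correctness rather than shared bugs.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy import optimize, stats


def phrase_count_bruteforce(tokens: tuple[str, ...], phrases: list[str]) -> int:
    """Greedy non-overlapping phrase count by explicit n-gram enumeration.

    At each position, all phrase n-grams are compared; the longest matching
    one (lexicographically smallest among equals) consumes its span.
    """
    units = sorted((tuple(p.split()) for p in phrases), key=lambda u: (-len(u), u))
    count = 0
    i = 0
    while i < len(tokens):
        matched = None
        for u in units:
            if len(u) <= len(tokens) - i and tuple(tokens[i : i + len(u)]) == u:
                matched = u
                break
        if matched is None:
            i += 1
        else:
            count += 1
            i += len(matched)
    return count


def mann_whitney_enumeration(a, b) -> tuple[float, float]:
    """Exact Mann–Whitney by brute force over all group assignments.

    U for sample ``a`` is counted pairwise (ties contribute 1/2); the
    two-sided p is the share of assignments at least as far from the null
    mean n_a·n_b/2 as the observed U.
    """

    def u_of(sample_a, sample_b):
        u = 0.0
        for x in sample_a:
            for y in sample_b:
                if x > y:
                    u += 1.0
                elif x == y:
                    u += 0.5
        return u

    a = list(a)
    b = list(b)
    pooled = a + b
    n, n_a = len(pooled), len(a)
    mu = n_a * len(b) / 2
    u_obs = u_of(a, b)
    extreme = total = 0
    for combo in itertools.combinations(range(n), n_a):
        ga = [pooled[i] for i in combo]
        gb = [pooled[i] for i in range(n) if i not in combo]
        total += 1
        if abs(u_of(ga, gb) - mu) >= abs(u_obs - mu) - 1e-12:
            extreme += 1
    return u_obs, extreme / total


def bh_reject_enumeration(ps, alpha: float) -> np.ndarray:
    """BH rejections via explicit threshold scan: find the largest k with
    p_(k) <= k·alpha/m and reject everything at or below p_(k)."""
    ps = np.asarray(ps, dtype=float)
    m = ps.size
    order = np.sort(ps)
    k_star = 0
    for k in range(1, m + 1):
        if order[k - 1] <= k * alpha / m:
            k_star = k
    if k_star == 0:
        return np.zeros(m, dtype=bool)
    return ps <= order[k_star - 1]


def partial_corr_residual_oracle(x, y, Z) -> float:
    """Partial correlation via per-variable residual regressions solved with
    explicit normal equations, then np.corrcoef of the residuals."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    design = np.column_stack([np.ones_like(x)] + [np.asarray(z, float) for z in Z])
    gram = design.T @ design
    rx = x - design @ np.linalg.solve(gram, design.T @ x)
    ry = y - design @ np.linalg.solve(gram, design.T @ y)
    return float(np.corrcoef(rx, ry)[0, 1])


def logistic_ridge_oracle(X, y, lam: float) -> tuple[np.ndarray, float]:
    """Penalized logistic fit by generic numerical optimization (BFGS on the
    exact objective), independent of any Newton/IRLS scheme."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n, p = X.shape

    def negll(beta):
        b0, w = beta[0], beta[1:]
        eta = X @ w + b0
        return -(y @ eta - np.logaddexp(0, eta).sum()) + 0.5 * lam * (w @ w)

    res = optimize.minimize(negll, np.zeros(p + 1), method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return res.x[1:], float(res.x[0])


# ---------------------------------------------------------------------------
# reference PC1 + MCI, coded naively


def _pcorr(x, y, Z):
    if Z:
        rho = partial_corr_residual_oracle(x, y, Z)
    else:
        rho = float(np.corrcoef(x, y)[0, 1])
    n = len(x)
    df = n - len(Z) - 2
    rho = max(-0.9999999999, min(0.9999999999, rho))
    t = rho * math.sqrt(df / (1 - rho * rho))
    return rho, 2 * stats.t.sf(abs(t), df)


def _col(data, var, lag, start):
    T = data.shape[0]
    return data[start - lag : T - lag, var]


def pcmci_reference(data: np.ndarray, tau_max: int, alpha_pc: float,
                    alpha: float) -> set[tuple[int, int, int]]:
    """Naive PC1 + MCI: returns the set of links (i, tau, j) with BH-significant
    momentary-conditional-independence tests over all ordered variable pairs
    and lags 1..tau_max (self-links excluded)."""
    T, V = data.shape
    cands = [(i, tau) for tau in range(1, tau_max + 1) for i in range(V)]

    parents: dict[int, list] = {}
    for j in range(V):
        y = _col(data, j, 0, tau_max)
        surv = []
        strength = {}
        for c in cands:
            rho, p = _pcorr(_col(data, c[0], c[1], tau_max), y, [])
            if p <= alpha_pc:
                surv.append(c)
                strength[c] = abs(rho)
        surv.sort(key=lambda c: -strength[c])
        q = 1
        while q <= len(surv) - 1:
            any_removed = False
            for c in list(surv):
                cond = [o for o in surv if o != c][:q]
                rho, p = _pcorr(
                    _col(data, c[0], c[1], tau_max),
                    y,
                    [_col(data, o[0], o[1], tau_max) for o in cond],
                )
                if p > alpha_pc:
                    surv.remove(c)
                    any_removed = True
                else:
                    strength[c] = min(strength[c], abs(rho))
            surv.sort(key=lambda c: -strength[c])
            if not any_removed and q >= len(surv) - 1:
                break
            q += 1
        parents[j] = surv

    pvals = {}
    for j in range(V):
        for i in range(V):
            if i == j:
                continue
            for tau in range(1, tau_max + 1):
                cond = [c for c in parents[j] if c != (i, tau)]
                cond += [
                    (k, l + tau)
                    for k, l in parents[i]
                    if (k, l + tau) != (i, tau) and (k, l + tau) not in cond
                    and (k, l + tau) != (j, 0)
                ]
                start = max([tau_max + tau] + [l for _, l in cond])
                _, p = _pcorr(
                    _col(data, i, tau, start),
                    _col(data, j, 0, start),
                    [_col(data, k, l, start) for k, l in cond],
                )
                pvals[(i, tau, j)] = p
    keys = list(pvals)
    ps = np.array([pvals[k] for k in keys])
    rej = bh_reject_enumeration(ps, alpha)
    return {k for k, r in zip(keys, rej) if r}
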