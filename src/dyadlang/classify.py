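"""Classifying patient clinical labels from therapist signatures.

Two binary tasks: admitting diagnosis (depression vs. eating disorder) and
symptom severity (PHQ-9 < 10 vs. ≥ 10; sessions with a missing PHQ-9 are
dropped from this task only).  An L2-penalized logistic regression on the
16-dimensional therapist signature is evaluated by repeated random 50/50
splits: per split the model accuracy on the evaluation half is compared to
chance, defined as always predicting the majority label *of that evaluation
half*; the empirical p-value is the fraction of splits on which the model
fails to beat chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consistency import SignatureMatrix
from .transcripts import Corpus

__all__ = [
    "LabeledSignatures",
    "SplitEvaluation",
    "labeled_signatures",
    "fit_logistic",
    "predict_proba",
    "majority_baseline",
    "repeated_split_eval",
]

TASKS = ("diagnosis", "severity")
PHQ9_SEVERITY_CUTOFF = 10


@dataclass
class LabeledSignatures:
    X: np.ndarray  # (n, 16)
    y: np.ndarray  # binary 0/1
    task: str
    session_ids: list[str] = field(default_factory=list)
    excluded: list[str] = field(default_factory=list)


def labeled_signatures(
    m: SignatureMatrix, corpus: Corpus, task: str
) -> LabeledSignatures:
    """Attach task labels to a signature matrix (primary sessions only).

    Diagnosis: depression = 1, eating_disorder = 0; unknown-diagnosis
    sessions are excluded.  Severity: PHQ-9 ≥ 10 → 1; missing PHQ-9 →
    excluded.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}")
    md_by_sid = {s.session_id: s.metadata for s in corpus.sessions}
    X_rows, y, sids, excluded = [], [], [], []
    for i, sid in enumerate(m.session_ids):
        if m.samples[i] != "primary":
            continue
        md = md_by_sid[sid]
        if task == "diagnosis":
            if md.diagnosis == "depression":
                label = 1
            elif md.diagnosis == "eating_disorder":
                label = 0
            else:
                excluded.append(sid)
                continue
        else:
            if md.phq9 is None:
                excluded.append(sid)
                continue
            label = 1 if md.phq9 >= PHQ9_SEVERITY_CUTOFF else 0
        X_rows.append(m.values[i])
        y.append(label)
        sids.append(sid)
    return LabeledSignatures(
        X=np.array(X_rows), y=np.array(y, dtype=int), task=task,
        session_ids=sids, excluded=excluded,
    )


# ---------------------------------------------------------------------------
# ridge logistic regression (Newton / IRLS)


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> tuple[np.ndarray, float]:
    """Fit logistic regression maximizing the L2-penalized log-likelihood.

    The ridge penalty ``lam/2 * ||w||^2`` applies to the weights, not the
    intercept; Newton iterations run until the gradient norm falls below
    ``tol``.  Returns (weights, intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in X")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain both classes")
    n, p = X.shape
    A = np.column_stack([np.ones(n), X])  # intercept first
    beta = np.zeros(p + 1)
    pen = np.full(p + 1, lam)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = A @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = A.T @ (y - mu) - pen * beta
        if np.linalg.norm(grad) < tol:
            break
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (A.T * w) @ A + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # halve the step until the penalized log-likelihood does not decrease
        ll0 = _pen_ll(A, y, beta, pen)
        t = 1.0
        while t > 1e-8:
            cand = beta + t * step
            if _pen_ll(A, y, cand, pen) >= ll0 - 1e-12:
                break
            t /= 2
        beta = beta + t * step
    return beta[1:], float(beta[0])


def _pen_ll(A, y, beta, pen) -> float:
    eta = A @ beta
    ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
    return ll - 0.5 * float(pen @ (beta * beta))


def predict_proba(X: np.ndarray, weights: np.ndarray, intercept: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(np.asarray(X, dtype=float) @ weights + intercept)))


def majority_baseline(y_eval: np.ndarray) -> float:
    """Chance accuracy: share of the majority label of the evaluation half
    (a tie counts as 0.5)."""
    y_eval = np.asarray(y_eval)
    if y_eval.size == 0:
        raise ValueError("empty evaluation set")
    share = y_eval.mean()
    return float(max(share, 1.0 - share))


# ---------------------------------------------------------------------------
# repeated random-split evaluation


@dataclass
class SplitEvaluation:
    task: str
    n: int
    n_repeats: int
    model_accuracy: np.ndarray  # per repeat
    chance_accuracy: np.ndarray
    difference: np.ndarray
    seed: int

    @property
    def mean_model_accuracy(self) -> float:
        return float(self.model_accuracy.mean())

    @property
    def mean_chance_accuracy(self) -> float:
        return float(self.chance_accuracy.mean())

    @property
    def mean_difference(self) -> float:
        return float(self.difference.mean())

    def ci_difference(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.difference, [2.5, 97.5])
        return float(lo), float(hi)

    def empirical_p(self, strict: bool = False) -> float:
        """Fraction of repeats on which the model did not beat chance
        (difference ≤ 0; ``strict=True`` uses < 0)."""
        if strict:
            return float(np.mean(self.difference < 0))
        return float(np.mean(self.difference <= 0))

    def summary(self) -> dict:
        lo, hi = self.ci_difference()
        return {
            "task": self.task,
            "n": self.n,
            "n_repeats": self.n_repeats,
            "mean_model_accuracy": self.mean_model_accuracy,
            "mean_chance_accuracy": self.mean_chance_accuracy,
            "mean_difference": self.mean_difference,
            "ci_difference": [lo, hi],
            "empirical_p": self.empirical_p(),
            "seed": self.seed,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "repeat": np.arange(self.n_repeats),
                "model_accuracy": self.model_accuracy,
                "chance_accuracy": self.chance_accuracy,
                "difference": self.difference,
            }
        )


def repeated_split_eval(
    data: LabeledSignatures,
    n_repeats: int = 1000,
    seed: int = 0,
    lam: float = 1.0,
    max_redraws: int = 100,
) -> SplitEvaluation:
    """Repeated random 50/50 split evaluation against the majority baseline.

    Per repeat: shuffle rows, give the training half the extra row when n is
    odd, redraw if the training half is single-class (up to ``max_redraws``
    times), standardize features with training-half statistics, fit the
    ridge logistic model, and record model accuracy minus chance accuracy on
    the evaluation half.  Fully reproducible given ``seed``.
    """
    n = data.X.shape[0]
    if n < 10:
        raise ValueError("need at least 10 labeled sessions")
    if np.unique(data.y).size < 2:
        raise ValueError("need both classes in the dataset")
    rng = np.random.default_rng(seed)
    n_train = n - n // 2  # odd n -> training gets the extra row
    model_acc = np.empty(n_repeats)
    chance_acc = np.empty(n_repeats)
    for r in range(n_repeats):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            train, evl = perm[:n_train], perm[n_train:]
            if np.unique(data.y[train]).size == 2:
                break
        else:
            raise RuntimeError(
                f"could not draw a two-class training half in {max_redraws} tries"
            )
        Xtr, ytr = data.X[train], data.y[train]
        Xev, yev = data.X[evl], data.y[evl]
        mean = Xtr.mean(axis=0)
        sd = Xtr.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        w, b = fit_logistic((Xtr - mean) / sd, ytr, lam=lam)
        pred = (predict_proba((Xev - mean) / sd, w, b) >= 0.5).astype(int)
        model_acc[r] = float(np.mean(pred == yev))
        chance_acc[r] = majority_baseline(yev)
    return SplitEvaluation(
        task=data.task,
        n=n,
        n_repeats=n_repeats,
        model_accuracy=model_acc,
        chance_accuracy=chance_acc,
        difference=model_acc - chance_acc,
        seed=seed,
    )
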