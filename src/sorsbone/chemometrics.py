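"""Partial least squares regression, leave-one-out CV, and WHO classification.

PLS1 is implemented from first principles by NIPALS-style deflation (for a
single response this is equivalent to SIMPLS).  Predictors and response are
mean-centered only; no unit-variance scaling of spectral channels is applied
by default.  Rank selection follows the minimum-RMSE_CV rule over a
leave-one-out sweep, with ties broken toward the smaller (more parsimonious)
rank; a nested per-fold selection variant is available.

WHO bone-health categories follow the standard T-score thresholds:
Normal (T > -1), Osteopenia (-2.5 < T <= -1), Osteoporosis (T <= -2.5).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


class WHOClass(str, enum.Enum):
    NORMAL = "Normal"
    OSTEOPENIA = "Osteopenia"
    OSTEOPOROSIS = "Osteoporosis"

    def __str__(self) -> str:  # clean CSV output
        return self.value


#: WHO T-score thresholds (upper bounds): T <= -2.5 osteoporosis, T <= -1 osteopenia.
T_OSTEOPENIA = -1.0
T_OSTEOPOROSIS = -2.5


def classify_who(tscore: float) -> WHOClass:
    """Map a DXA T-score to its WHO category (boundaries -1 and -2.5 inclusive below)."""
    t = float(tscore)
    if not np.isfinite(t):
        raise ValueError("T-score must be finite")
    if t <= T_OSTEOPOROSIS:
        return WHOClass.OSTEOPOROSIS
    if t <= T_OSTEOPENIA:
        return WHOClass.OSTEOPENIA
    return WHOClass.NORMAL


def classification_accuracy(true_classes, pred_classes) -> float:
    """Fraction of exact class matches."""
    t = list(true_classes)
    p = list(pred_classes)
    if len(t) != len(p) or not t:
        raise ValueError("class vectors must be equal length and non-empty")
    return sum(a == b for a, b in zip(t, p)) / len(t)


@dataclass
class PLSModel:
    """Fitted PLS1 state: ``yhat = y_mean + (x - x_mean) @ coef``."""

    rank: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray    # (p, A)
    loadings: np.ndarray   # (p, A)
    q: np.ndarray          # (A,) response loadings
    scores: np.ndarray     # (n, A)
    coef: np.ndarray       # (p,)


@dataclass
class CVConfig:
    rank_grid: tuple[int, ...] = tuple(range(1, 10))
    rank_selection: str = "global"  # "global" | "per_fold"

    def __post_init__(self) -> None:
        if not self.rank_grid or min(self.rank_grid) < 1:
            raise ValueError("rank grid must be non-empty with ranks >= 1")
        if self.rank_selection not in ("global", "per_fold"):
            raise ValueError("rank_selection must be 'global' or 'per_fold'")


@dataclass
class CVResult:
    rank_grid: tuple[int, ...]
    rmse_cv: np.ndarray          # per rank in rank_grid (global sweep)
    optimal_rank: int
    y_true: np.ndarray
    y_pred: np.ndarray           # LOO predictions at the optimal rank
    r: float
    rmse: float
    classes_true: list = field(default_factory=list)
    classes_pred: list = field(default_factory=list)
    accuracy: float = float("nan")
    per_fold_rank: np.ndarray | None = None


def _nipals(X0: np.ndarray, y0: np.ndarray, rank: int):
    """Deflation loop on centered data; may stop early on rank deficiency."""
    n, p = X0.shape
    W, P, Q, T = [], [], [], []
    Xd, yd = X0.copy(), y0.copy()
    scale = np.linalg.norm(X0) * np.linalg.norm(y0) + 1e-300
    for _ in range(rank):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= 1e-12 * scale:
            warnings.warn("weight vector vanished; stopping at achieved rank")
            break
        w /= nw
        t = Xd @ w
        tt = t @ t
        if tt <= 1e-300:
            warnings.warn("score vector vanished; stopping at achieved rank")
            break
        pa = Xd.T @ t / tt
        qa = yd @ t / tt
        Xd -= np.outer(t, pa)
        yd -= qa * t
        W.append(w)
        P.append(pa)
        Q.append(qa)
        T.append(t)
    A = len(W)
    return (
        np.array(W).T.reshape(p, A),
        np.array(P).T.reshape(p, A),
        np.array(Q),
        np.array(T).T.reshape(n, A),
    )


def fit_pls(X: np.ndarray, y: np.ndarray, rank: int) -> PLSModel:
    """Fit a rank-``rank`` PLS1 model on mean-centered ``X`` (n x p) and ``y``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n or n < 2:
        raise ValueError("X and y sizes incompatible or n < 2")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("X and y must be finite")
    max_rank = min(n - 1, p)
    if not 1 <= rank <= max_rank:
        raise ValueError(f"rank must be in [1, {max_rank}]")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, Q, T = _nipals(X - x_mean, y - y_mean, rank)
    coef = W @ np.linalg.solve(P.T @ W, Q)
    return PLSModel(
        rank=W.shape[1], x_mean=x_mean, y_mean=y_mean,
        weights=W, loadings=P, q=Q, scores=T, coef=coef,
    )


def predict_pls(model: PLSModel, x: np.ndarray) -> np.ndarray | float:
    """Predict T-score(s): ``y_mean + (x - x_mean) @ coef``."""
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 1
    x2 = np.atleast_2d(x)
    if x2.shape[1] != model.x_mean.size:
        raise ValueError("predictor length does not match the fitted model")
    yhat = model.y_mean + (x2 - model.x_mean) @ model.coef
    return float(yhat[0]) if scalar else yhat


def _coef_per_rank(X0: np.ndarray, y0: np.ndarray, max_rank: int) -> np.ndarray:
    """Coefficient vectors for every rank 1..A from one deflation sweep (p x A)."""
    W, P, Q, _ = _nipals(X0, y0, max_rank)
    A = W.shape[1]
    out = np.empty((X0.shape[1], A))
    for a in range(1, A + 1):
        out[:, a - 1] = W[:, :a] @ np.linalg.solve(P[:, :a].T @ W[:, :a], Q[:a])
    return out


def loocv_select_rank(
    X: np.ndarray,
    y: np.ndarray,
    cfg: CVConfig | None = None,
    classes_true=None,
) -> CVResult:
    """Leave-one-out sweep over the rank grid with minimum-RMSE_CV selection.

    Centering is recomputed inside every fold, so no statistic of the held-out
    specimen leaks into its training set.  Ranks exceeding a fold's admissible
    maximum are capped with a warning.
    """
    cfg = cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n < 3:
        raise ValueError("LOOCV needs at least 3 specimens")
    grid = tuple(sorted(set(cfg.rank_grid)))
    fold_max = min(n - 2, p)  # training set has n-1 samples
    if max(grid) > fold_max:
        warnings.warn(f"rank grid capped at {fold_max} for {n}-specimen LOOCV")
    ranks = tuple(a for a in grid if a <= fold_max) or (fold_max,)

    preds = np.empty((len(ranks), n))
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X[keep], y[keep]
        xm, ym = Xtr.mean(axis=0), ytr.mean()
        coefs = _coef_per_rank(Xtr - xm, ytr - ym, max(ranks))
        achieved = coefs.shape[1]
        for j, a in enumerate(ranks):
            preds[j, i] = ym + (X[i] - xm) @ coefs[:, min(a, achieved) - 1]
    rmse_cv = np.sqrt(np.mean((preds - y[None, :]) ** 2, axis=1))

    per_fold_rank = None
    if cfg.rank_selection == "per_fold":
        y_pred = np.empty(n)
        per_fold_rank = np.empty(n, dtype=int)
        for i in range(n):
            keep = np.arange(n) != i
            inner = loocv_select_rank(
                X[keep], y[keep], CVConfig(rank_grid=ranks, rank_selection="global")
            )
            per_fold_rank[i] = inner.optimal_rank
            j = ranks.index(inner.optimal_rank)
            y_pred[i] = preds[j, i]
        optimal = int(np.bincount(per_fold_rank).argmax())
    else:
        j_opt = int(np.argmin(rmse_cv))  # argmin takes the first = smallest rank on ties
        optimal = ranks[j_opt]
        y_pred = preds[j_opt]

    r, rmse = regression_metrics(y, y_pred)
    result = CVResult(
        rank_grid=ranks, rmse_cv=rmse_cv, optimal_rank=optimal,
        y_true=y, y_pred=y_pred, r=r, rmse=rmse, per_fold_rank=per_fold_rank,
    )
    result.classes_pred = [classify_who(t) for t in y_pred]
    result.classes_true = (
        list(classes_true) if classes_true is not None else [classify_who(t) for t in y]
    )
    result.accuracy = classification_accuracy(result.classes_true, result.classes_pred)
    return result


def regression_metrics(y_true, y_pred) -> tuple[float, float]:
    """Pearson r and root-mean-square error of ``y_pred`` against ``y_true``."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("need equal-length vectors with at least 2 entries")
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant input: Pearson r undefined")
        return float("nan"), rmse
    r = float(stats.pearsonr(y_true, y_pred).statistic)
    return r, rmse
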