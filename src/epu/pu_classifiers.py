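"""The three weighted positive-unlabeled base classifiers.

All three consume the integrated propagation score as a per-gene
confidence weight and emit a two-class posterior ``(p_pos, p_neg)`` with
``p_pos + p_neg = 1``:

* **WKNN** — weighted k-nearest-neighbour: the posterior is the share of
  positive integrated-score mass among the query's k nearest training
  genes (magnitude-weighted class vote).
* **WNB** — weighted multinomial naive Bayes with Laplace smoothing and
  equal class priors; fractional feature counts are weighted by each
  pool gene's confidence.
* **MSVM** — multi-level weighted SVM: the remaining unlabeled genes are
  stratified by integrated score into likely-positive (LP),
  likely-negative (LN) and weak-negative (WN) sets; P and LP train as
  +1, RN, LN and WN as -1, each stratum with its own slack cost.
  Posteriors come from a Platt-style sigmoid on decision values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .exceptions import ValidationError

Posterior = tuple[float, float]


# ---------------------------------------------------------------------------
# WKNN


def wknn_posterior(
    x: np.ndarray,
    pool_vectors: np.ndarray,
    pool_scores: np.ndarray,
    k: int = 3,
    pool_ids: Sequence[str] | None = None,
) -> Posterior:
    """Posterior of one query vector from its k nearest pool genes.

    Neighbours with integrated score >= 0 contribute their score to the
    positive mass, the rest their magnitude to the negative mass;
    ``p_pos`` is the positive share of the total.  Zero total mass (all
    neighbour scores zero) yields the uninformative (0.5, 0.5).
    Distance ties are broken by ascending gene identifier when
    ``pool_ids`` is given, else by pool position.
    """
    pool_vectors = np.asarray(pool_vectors, dtype=float)
    pool_scores = np.asarray(pool_scores, dtype=float)
    n = pool_vectors.shape[0]
    if k <= 0 or k > n:
        raise ValidationError(f"k={k} out of range for pool of {n}")
    d = np.linalg.norm(pool_vectors - np.asarray(x, dtype=float), axis=1)
    if pool_ids is not None:
        tie = np.argsort(np.argsort(np.asarray(pool_ids)))
    else:
        tie = np.arange(n)
    top = np.lexsort((tie, d))[:k]
    s = pool_scores[top]
    pos = float(s[s >= 0].sum())
    neg = float(-s[s < 0].sum())
    total = pos + neg
    if total == 0.0:
        return (0.5, 0.5)
    return (pos / total, neg / total)


class WeightedKNN:
    """Convenience wrapper holding the training pool."""

    def __init__(self, k: int = 3):
        self.k = k
        self._ids: list[str] | None = None
        self._V: np.ndarray | None = None
        self._scores: np.ndarray | None = None

    def fit(self, ids: Sequence[str], vectors: np.ndarray, scores: np.ndarray) -> "WeightedKNN":
        if len(ids) < self.k:
            raise ValidationError(f"pool of {len(ids)} smaller than k={self.k}")
        self._ids = list(ids)
        self._V = np.asarray(vectors, dtype=float)
        self._scores = np.asarray(scores, dtype=float)
        return self

    def posterior(self, x: np.ndarray) -> Posterior:
        return wknn_posterior(x, self._V, self._scores, self.k, self._ids)

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        D = cdist(X, self._V)
        tie = np.argsort(np.argsort(np.asarray(self._ids)))
        out = np.empty((X.shape[0], 2))
        for i in range(X.shape[0]):
            top = np.lexsort((tie, D[i]))[: self.k]
            s = self._scores[top]
            pos = float(s[s >= 0].sum())
            neg = float(-s[s < 0].sum())
            total = pos + neg
            out[i] = (0.5, 0.5) if total == 0.0 else (pos / total, neg / total)
        return out


# ---------------------------------------------------------------------------
# WNB


class WeightedNaiveBayes:
    """Weighted multinomial naive Bayes over nonnegative features.

    Per-class feature likelihoods use confidence-weighted fractional
    counts with Laplace smoothing:

        P(f_k | c) = (lambda + sum_g w_g * v_g[k])
                     / (m * lambda + sum_k' sum_g w_g * v_g[k'])

    and the posterior is computed in log space with equal priors, then
    exponentiated and normalised.
    """

    def __init__(self, laplace: float = 1.0, priors: tuple[float, float] = (0.5, 0.5)):
        if laplace <= 0:
            raise ValidationError("laplace smoothing must be positive")
        self.laplace = laplace
        self.priors = priors
        self._log_like: np.ndarray | None = None  # (2, m): pos, neg

    def fit(
        self,
        V_pos: np.ndarray,
        w_pos: np.ndarray,
        V_neg: np.ndarray,
        w_neg: np.ndarray,
    ) -> "WeightedNaiveBayes":
        V_pos = np.atleast_2d(np.asarray(V_pos, dtype=float))
        V_neg = np.atleast_2d(np.asarray(V_neg, dtype=float))
        w_pos = np.asarray(w_pos, dtype=float)
        w_neg = np.asarray(w_neg, dtype=float)
        if V_pos.shape[0] == 0 or w_pos.sum() <= 0:
            raise ValidationError("positive pool is empty")
        if V_neg.shape[0] == 0 or w_neg.sum() <= 0:
            raise ValidationError("negative pool is empty")
        if (V_pos < 0).any() or (V_neg < 0).any():
            raise ValidationError("naive Bayes requires nonnegative features")
        rows = []
        for V, w in ((V_pos, w_pos), (V_neg, w_neg)):
            counts = self.laplace + w @ V
            rows.append(np.log(counts) - np.log(counts.sum()))
        self._log_like = np.vstack(rows)
        return self

    def posterior(self, x: np.ndarray) -> Posterior:
        return tuple(self.posteriors(np.atleast_2d(x))[0])  # type: ignore[return-value]

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        if self._log_like is None:
            raise ValidationError("model not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        log_post = X @ self._log_like.T + np.log(np.asarray(self.priors))
        log_post -= log_post.max(axis=1, keepdims=True)
        post = np.exp(log_post)
        return post / post.sum(axis=1, keepdims=True)


def wnb_pools(
    P: Iterable[str],
    RN: Iterable[str],
    U_rest: Iterable[str],
    int_score: Mapping[str, float],
) -> tuple[list[str], list[float], list[str], list[float]]:
    """Confidence-weighted pools for the naive Bayes model.

    P and RN genes carry weight 1; remaining unlabeled genes join the
    pool matching the sign of their integrated score, weighted by its
    magnitude (zero-score genes join neither).
    """
    pos_ids = sorted(set(P))
    pos_w = [1.0] * len(pos_ids)
    neg_ids = sorted(set(RN))
    neg_w = [1.0] * len(neg_ids)
    for g in sorted(set(U_rest)):
        s = float(int_score.get(g, 0.0))
        if s > 0:
            pos_ids.append(g)
            pos_w.append(s)
        elif s < 0:
            neg_ids.append(g)
            neg_w.append(-s)
    return pos_ids, pos_w, neg_ids, neg_w


# ---------------------------------------------------------------------------
# level partition and MSVM


@dataclass(frozen=True)
class LevelPartition:
    """Stratification of the remaining unlabeled genes by integrated score."""

    LP: frozenset[str]
    LN: frozenset[str]
    WN: frozenset[str]
    mu_pos: float
    mu_neg: float


def partition_levels(U_rest: Iterable[str], int_score: Mapping[str, float]) -> LevelPartition:
    """LP / LN / WN split at the class-conditional score means.

    ``mu_pos`` is the mean integrated score over positively scored genes
    (``mu_neg`` analogously); LP collects scores >= mu_pos, LN scores
    <= mu_neg, WN the rest.  An empty side leaves its stratum empty.
    The split is invariant under positive rescaling of the scores.
    """
    genes = sorted(set(U_rest))
    scores = np.array([float(int_score.get(g, 0.0)) for g in genes])
    pos = scores[scores > 0]
    neg = scores[scores < 0]
    mu_pos = float(pos.mean()) if pos.size else float("inf")
    mu_neg = float(neg.mean()) if neg.size else float("-inf")
    LP = frozenset(g for g, s in zip(genes, scores) if s > 0 and s >= mu_pos)
    LN = frozenset(g for g, s in zip(genes, scores) if s < 0 and s <= mu_neg)
    WN = frozenset(genes) - LP - LN
    return LevelPartition(LP=LP, LN=LN, WN=WN, mu_pos=mu_pos, mu_neg=mu_neg)


class MultiLevelSVM:
    """Soft-margin SVM with per-stratum slack costs.

    The base cost C is chosen by internal stratified cross-validation on
    F-measure over ``cost_grid``; each training point's effective cost is
    C times its stratum multiplier (points with multiplier <= 0 are
    dropped — a zero slack penalty removes a point from the objective).
    Posteriors are produced by a Platt-style sigmoid fitted to the
    decision values of the training points.
    """

    def __init__(
        self,
        cost_grid: Sequence[float] = (0.1, 1.0, 10.0),
        kernel: str = "linear",
        cv_folds: int = 3,
        random_state: int = 0,
    ):
        if kernel not in ("linear", "rbf"):
            raise ValidationError(f"unsupported kernel {kernel!r}")
        self.cost_grid = tuple(cost_grid)
        self.kernel = kernel
        self.cv_folds = cv_folds
        self.random_state = random_state
        self.best_C_: float | None = None
        self._svc: SVC | None = None
        self._platt: LogisticRegression | None = None

    def fit(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> "MultiLevelSVM":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        weights = np.asarray(weights, dtype=float)
        keep = weights > 0
        X, y, weights = X[keep], y[keep], weights[keep]
        classes = np.unique(y)
        if set(classes) != {-1, 1}:
            raise ValidationError(f"need both classes in training data, got {classes}")
        self.best_C_ = self._select_cost(X, y, weights)
        self._svc = SVC(C=self.best_C_, kernel=self.kernel, random_state=self.random_state)
        self._svc.fit(X, y, sample_weight=weights)
        d = self._svc.decision_function(X).reshape(-1, 1)
        self._platt = LogisticRegression()
        self._platt.fit(d, y)
        return self

    def _select_cost(self, X: np.ndarray, y: np.ndarray, weights: np.ndarray) -> float:
        from .evaluation import f_measure

        min_class = int(min(np.sum(y == 1), np.sum(y == -1)))
        n_splits = min(self.cv_folds, min_class)
        if len(self.cost_grid) == 1 or n_splits < 2:
            return float(self.cost_grid[len(self.cost_grid) // 2])
        best_C, best_f = None, -1.0
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.random_state)
        for C in self.cost_grid:
            tp = fp = fn = 0
            for tr, va in skf.split(X, y):
                svc = SVC(C=C, kernel=self.kernel, random_state=self.random_state)
                svc.fit(X[tr], y[tr], sample_weight=weights[tr])
                pred = svc.predict(X[va])
                tp += int(np.sum((pred == 1) & (y[va] == 1)))
                fp += int(np.sum((pred == 1) & (y[va] == -1)))
                fn += int(np.sum((pred == -1) & (y[va] == 1)))
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            f = f_measure(p, r)
            if f > best_f:
                best_C, best_f = float(C), f
        return best_C if best_C is not None else float(self.cost_grid[0])

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        if self._svc is None:
            raise ValidationError("model not fitted")
        return self._svc.decision_function(np.atleast_2d(np.asarray(X, dtype=float)))

    def posterior(self, x: np.ndarray) -> Posterior:
        return tuple(self.posteriors(np.atleast_2d(x))[0])  # type: ignore[return-value]

    def posteriors(self, X: np.ndarray) -> np.ndarray:
        if self._platt is None:
            raise ValidationError("model not fitted")
        d = self.decision_values(X).reshape(-1, 1)
        proba = self._platt.predict_proba(d)
        pos_col = int(np.where(self._platt.classes_ == 1)[0][0])
        p_pos = proba[:, pos_col]
        return np.column_stack([p_pos, 1.0 - p_pos])


def msvm_training_arrays(
    P: Iterable[str],
    RN: Iterable[str],
    levels: LevelPartition,
    rows: Mapping[str, np.ndarray] | None = None,
    features=None,
    level_multipliers: Mapping[str, float] | None = None,
) -> tuple[list[str], np.ndarray, np.ndarray, np.ndarray]:
    """Assemble (ids, X, y, weights) for the multi-level SVM.

    Labels: +1 for P and LP; -1 for RN, LN and WN.  Weights are the
    per-stratum multipliers.  Gene vectors come from ``rows`` (a mapping)
    or from a feature matrix via ``features.row``.
    """
    mult = dict(level_multipliers or {"P": 1.0, "RN": 1.0, "LP": 0.5, "LN": 0.5, "WN": 0.25})
    strata = (
        (sorted(set(P)), 1, mult["P"]),
        (sorted(levels.LP), 1, mult["LP"]),
        (sorted(set(RN)), -1, mult["RN"]),
        (sorted(levels.LN), -1, mult["LN"]),
        (sorted(levels.WN), -1, mult["WN"]),
    )
    ids: list[str] = []
    X: list[np.ndarray] = []
    y: list[int] = []
    w: list[float] = []
    get_row = rows.__getitem__ if rows is not None else features.row
    for genes, label, weight in strata:
        for g in genes:
            ids.append(g)
            X.append(np.asarray(get_row(g), dtype=float))
            y.append(label)
            w.append(weight)
    return ids, np.asarray(X), np.asarray(y), np.asarray(w)
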