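"""Gradient-descent combination of the base classifiers.

Each training gene contributes a row of margins ``m_ij = P_j(+) - P_j(-)``
(one per base classifier) and a label ``y_i`` in {-1, +1}.  The combiner
scores a gene as ``s_i = sum_j a_j * m_ij`` and predicts ``sign(s_i)``
(ties go to the negative class — conservative for prioritization).

The weight vector ``a`` is learned by batch least-mean-squares descent on
the continuous squared error ``E = 1/2 * sum_i (y_i - s_i)^2`` (the hard
+/-1 prediction would make E non-differentiable), with update
``delta_a_j = eta_t * sum_i (y_i - s_i) * m_ij`` and a gradually decaying
learning rate ``eta_t = eta0 / (1 + t / halflife)``.  The initial weights
are drawn uniform on [0, 1) from a mandatory seed, so training is fully
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import ValidationError


@dataclass
class MarginMatrix:
    """|D| x k base-classifier margins with +/-1 labels."""

    genes: list[str]
    M: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.M.ndim != 2 or self.M.shape[0] != len(self.genes):
            raise ValidationError("margin matrix shape mismatch")
        if self.y.shape != (self.M.shape[0],):
            raise ValidationError("label vector length mismatch")
        if np.abs(self.M).max(initial=0.0) > 1.0 + 1e-9:
            raise ValidationError("margins must lie in [-1, 1]")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ValidationError("labels must be -1 or +1")

    @property
    def k(self) -> int:
        return self.M.shape[1]


def ensemble_score(a: Sequence[float], m_row: Sequence[float]) -> float:
    """Weighted margin sum for one gene."""
    a = np.asarray(a, dtype=float)
    m = np.asarray(m_row, dtype=float)
    if a.shape != m.shape:
        raise ValidationError(f"weight/margin length mismatch: {a.shape} vs {m.shape}")
    return float(a @ m)


def ensemble_predict(a: Sequence[float], m_row: Sequence[float]) -> int:
    """+1 if the weighted score is strictly positive, else -1."""
    return 1 if ensemble_score(a, m_row) > 0 else -1


@dataclass
class EnsembleWeights:
    """Learned weight vector plus its training trajectory.

    ``history`` records the continuous squared error E at every
    iteration (before that iteration's update); ``hard_error`` is the
    final count-based error using hard +/-1 predictions.
    """

    a: np.ndarray
    history: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    hard_error: float = 0.0

    def predict(self, M: np.ndarray) -> np.ndarray:
        s = np.asarray(M, dtype=float) @ self.a
        return np.where(s > 0, 1, -1)

    def scores(self, M: np.ndarray) -> np.ndarray:
        return np.asarray(M, dtype=float) @ self.a


def lms_delta(M: np.ndarray, y: np.ndarray, a: np.ndarray, eta: float) -> np.ndarray:
    """One batch LMS weight update: ``eta * sum_i (y_i - s_i) * m_i``."""
    M = np.asarray(M, dtype=float)
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    return eta * (M.T @ (y - M @ a))


def train_weights(
    margins: MarginMatrix,
    eta0: float = 0.001,
    tol: float = 1e-6,
    max_iter: int = 10000,
    seed: int = 0,
    decay_halflife: float = 100.0,
) -> EnsembleWeights:
    """Batch LMS descent on the ensemble squared error.

    Stops when the L1 norm of the weight update falls below ``tol`` or
    after ``max_iter`` iterations.  Emits a warning (but still trains)
    when all labels share one class.
    """
    if eta0 <= 0:
        raise ValidationError("eta0 must be positive")
    M, y = margins.M, margins.y
    if M.shape[0] == 0:
        raise ValidationError("empty margin matrix")
    if np.unique(y).size == 1:
        import warnings

        warnings.warn("all training labels share one class", stacklevel=2)
    rng = np.random.default_rng(seed)
    a = rng.random(margins.k)
    history: list[float] = []
    converged = False
    iterations = 0
    for t in range(max_iter):
        s = M @ a
        resid = y - s
        history.append(0.5 * float(resid @ resid))
        eta = eta0 / (1.0 + t / decay_halflife)
        delta = lms_delta(M, y, a, eta)
        a = a + delta
        iterations = t + 1
        if float(np.abs(delta).sum()) < tol:
            converged = True
            break
    hard = np.where(M @ a > 0, 1, -1)
    hard_error = float(np.mean(hard != y))
    return EnsembleWeights(
        a=a, history=history, iterations=iterations, converged=converged, hard_error=hard_error
    )
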