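"""Random walk with restart from signed seeds.

The walk iterates ``R_t = (1 - alpha) * What @ R_{t-1} + alpha * R0``
starting from ``R_1 = R0``, where ``What`` is the column-oriented
transition matrix of a network and ``alpha`` the restart probability
(default 0.7).  Iteration stops when the L1 change drops below the
tolerance (default 1e-6) or an iteration cap is hit, in which case the
result is flagged non-converged.

Converged per-network scores are combined into one integrated score per
gene — by default the arithmetic mean over the three networks, counting a
gene absent from a network as 0 there.  The sign of the integrated score
encodes disease (positive) versus non-disease (negative) leaning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .network_builder import TransitionMatrix
from .pu_seeding import SeedScores


@dataclass
class PropagationResult:
    """Converged score vector over one network's node set."""

    nodes: list[str]
    scores: np.ndarray
    iterations: int
    final_delta: float
    alpha: float
    converged: bool
    #: L1 change per iteration (diagnostic; non-increasing after step 1
    #: for substochastic transition matrices)
    deltas: list[float] = field(default_factory=list)
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.nodes)}

    def score(self, gene: str) -> float:
        """Score of ``gene``; genes absent from this network score 0."""
        i = self._index.get(gene)
        return 0.0 if i is None else float(self.scores[i])

    def __contains__(self, gene: str) -> bool:
        return gene in self._index


def rwr(
    T: TransitionMatrix,
    seeds: SeedScores | np.ndarray,
    alpha: float = 0.7,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> PropagationResult:
    """Propagate signed seed scores to convergence on one network."""
    if not 0.0 < alpha <= 1.0:
        raise ValidationError(f"alpha must be in (0, 1], got {alpha}")
    if tol <= 0:
        raise ValidationError("tol must be positive")
    r0 = seeds.vector(T.nodes) if isinstance(seeds, SeedScores) else np.asarray(seeds, dtype=float)
    if r0.shape != (len(T.nodes),):
        raise ValidationError("seed vector length does not match network")
    r = r0.copy()  # R_1 = R_0
    delta = np.inf
    deltas: list[float] = []
    iterations = 0
    for iterations in range(1, max_iter + 1):
        r_next = (1.0 - alpha) * (T.What @ r) + alpha * r0
        delta = float(np.abs(r_next - r).sum())
        deltas.append(delta)
        r = r_next
        if delta < tol:
            break
    return PropagationResult(
        nodes=list(T.nodes),
        scores=r,
        iterations=iterations,
        final_delta=delta,
        alpha=alpha,
        converged=delta < tol,
        deltas=deltas,
    )


def integrate_scores(
    *results: PropagationResult, mean_over_present: bool = False
) -> dict[str, float]:
    """Combine per-network scores into one integrated score per gene.

    Defined over the union of node sets.  By default the sum is divided
    by the number of networks regardless of membership (a gene missing
    from a network contributes 0); ``mean_over_present`` divides by the
    number of networks actually containing the gene instead.
    """
    if not results:
        raise ValidationError("at least one propagation result required")
    union: list[str] = []
    seen: set[str] = set()
    for res in results:
        for g in res.nodes:
            if g not in seen:
                seen.add(g)
                union.append(g)
    out: dict[str, float] = {}
    for g in union:
        total = sum(res.score(g) for res in results)
        if mean_over_present:
            n = sum(1 for res in results if g in res)
            out[g] = total / n if n else 0.0
        else:
            out[g] = total / len(results)
    return out
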