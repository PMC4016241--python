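"""Construction of the gene similarity networks.

Three evidence networks back the propagation stage:

* ``PPI`` — binary protein–protein interaction adjacency,
* ``GE``  — Pearson co-expression, sparsified to each gene's top-k partners,
* ``GO``  — functional similarity ``1/(1 + EuclideanDistance)`` on the GO
  feature block, likewise top-k sparsified.

Top-k neighbour lists are per-gene and directed; the stored matrix is
symmetrised by *union* (an edge survives if either endpoint ranks the other
in its top k), so ``W`` is symmetric as its matrix uses require.  Ties are
broken by ascending gene identifier for cross-platform determinism.

The phenotype similarity matrix is filtered through a logistic squashing
function so that only high, informative similarities survive as candidate
links.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Sequence

import numpy as np
import scipy.sparse as sp

from .exceptions import ValidationError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .data_io import EdgeList, ExpressionTable, PhenotypeSimMatrix
    from .gene_features import GeneFeatureMatrix


@dataclass
class GeneNetwork:
    """A named, sparse, symmetric, zero-diagonal gene-gene weight matrix."""

    name: str
    nodes: list[str]
    W: sp.csr_matrix
    #: genes whose expression profile had zero variance (GE networks only)
    zero_variance: frozenset[str] = frozenset()
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.nodes)}
        if len(self._index) != len(self.nodes):
            raise ValidationError(f"duplicate node ids in network {self.name!r}")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def index(self, gene: str) -> int:
        return self._index[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self._index

    def degrees(self, use_abs: bool = True) -> np.ndarray:
        """Weighted degree vector (sum of |w| by default)."""
        W = abs(self.W) if use_abs else self.W
        return np.asarray(W.sum(axis=1)).ravel()


@dataclass
class TransitionMatrix:
    """Column-oriented transition form of a network.

    ``What`` is the transpose of the row-normalized weight matrix
    ``D^-1 W``: each nonzero column sums to one (for nonnegative weights),
    so a matrix-vector product distributes every gene's score over its
    neighbours proportionally to edge weight.  Zero-degree genes have
    all-zero columns.
    """

    nodes: list[str]
    What: sp.csr_matrix


def pearson_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation between two expression profiles.

    Returns 0.0 when either profile has zero variance (the degenerate case
    is flagged at network level via :attr:`GeneNetwork.zero_variance`).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"profile length mismatch: {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValidationError("profiles need at least 2 values")
    xd = x - x.mean()
    yd = y - y.mean()
    nx = np.sqrt(xd @ xd)
    ny = np.sqrt(yd @ yd)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.clip((xd @ yd) / (nx * ny), -1.0, 1.0))


def _pairwise_pearson(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson over matrix rows; constant rows correlate 0.

    Returns ``(sims, zero_variance_mask)``.
    """
    X = np.asarray(values, dtype=float)
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    zero = norms == 0.0
    safe = np.where(zero, 1.0, norms)
    Xn = Xc / safe[:, None]
    sims = np.clip(Xn @ Xn.T, -1.0, 1.0)
    sims[zero, :] = 0.0
    sims[:, zero] = 0.0
    return sims, zero


def top_k_neighbors(
    scores: np.ndarray, self_index: int, id_rank: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the k best-scoring partners of one gene.

    Ordered by descending score, ties broken by ascending gene identifier
    (``id_rank`` maps position -> lexicographic rank of the id).
    """
    order = np.lexsort((id_rank, -scores))
    order = order[order != self_index]
    return order[:k]


def _knn_union_network(
    name: str,
    nodes: list[str],
    scores: np.ndarray,
    k: int,
    weights: np.ndarray | None = None,
    zero_variance: frozenset[str] = frozenset(),
) -> GeneNetwork:
    """Union-symmetrised kNN graph; edge weight taken from ``weights``
    (defaults to ``scores``)."""
    if k <= 0:
        raise ValidationError("k must be positive")
    n = len(nodes)
    k = min(k, n - 1)
    if weights is None:
        weights = scores
    id_rank = np.argsort(np.argsort(np.asarray(nodes)))
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    seen: set[tuple[int, int]] = set()
    for i in range(n):
        for j in top_k_neighbors(scores[i], i, id_rank, k):
            a, b = (i, int(j)) if i < j else (int(j), i)
            if (a, b) in seen:
                continue
            seen.add((a, b))
            rows.extend((a, b))
            cols.extend((b, a))
            w = float(weights[a, b])
            vals.extend((w, w))
    W = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    return GeneNetwork(name=name, nodes=list(nodes), W=W, zero_variance=zero_variance)


def build_expression_network(expr: "ExpressionTable", k: int = 5) -> GeneNetwork:
    """Co-expression network: per-gene top-k partners by Pearson similarity.

    Edge weight is the (symmetric) Pearson correlation, which may be
    negative; propagation takes absolute values when normalizing.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if len(expr.genes) < 2:
        raise ValidationError("need at least 2 genes to build a network")
    sims, zero = _pairwise_pearson(expr.values)
    zero_genes = frozenset(g for g, z in zip(expr.genes, zero) if z)
    return _knn_union_network("GE", list(expr.genes), sims, k, zero_variance=zero_genes)


def build_go_network(features: "GeneFeatureMatrix", k: int = 5) -> GeneNetwork:
    """Functional similarity network from the GO block of the feature matrix.

    Similarity between two genes is ``1/(1 + Dis)`` where ``Dis`` is the
    Euclidean distance between their GO feature sub-vectors — bounded in
    (0, 1], equal to 1 for identical annotation profiles, and monotone
    decreasing in distance.
    """
    block = features.block("MF", "BP", "CC")
    if block.shape[1] == 0:
        raise ValidationError("GO feature block is empty")
    from scipy.spatial.distance import squareform, pdist

    dist = squareform(pdist(block, metric="euclidean"))
    weights = 1.0 / (1.0 + dist)
    np.fill_diagonal(weights, 0.0)
    # rank by ascending distance == descending weight
    return _knn_union_network("GO", list(features.genes), weights, k, weights=weights)


def build_ppi_network(edges: "EdgeList", nodes: list[str] | None = None) -> GeneNetwork:
    """Binary interaction adjacency.  No sparsification: physical
    interaction maps are already sparse."""
    if nodes is None:
        nodes = sorted(edges.nodes())
    index = {g: i for i, g in enumerate(nodes)}
    rows: list[int] = []
    cols: list[int] = []
    for (a, b), _w in edges.edges.items():
        if a not in index or b not in index:
            continue
        ia, ib = index[a], index[b]
        rows.extend((ia, ib))
        cols.extend((ib, ia))
    vals = np.ones(len(rows))
    W = sp.coo_matrix((vals, (rows, cols)), shape=(len(nodes), len(nodes))).tocsr()
    W.data[:] = 1.0  # collapse any accidental double counting
    return GeneNetwork(name="PPI", nodes=list(nodes), W=W)


def logistic_filter_value(s: float, c: float = -15.0, d: float = math.log(9999.0)) -> float:
    """L(s) = 1/(1 + exp(c*s + d)); with the defaults, L crosses 0.5 at
    s = ln(9999)/15 ~ 0.614, so weak phenotype similarities are dropped."""
    return float(1.0 / (1.0 + math.exp(c * s + d)))


def filter_phenotype_network(
    sims: "PhenotypeSimMatrix", c: float = -15.0, d: float = math.log(9999.0)
) -> "PhenotypeSimMatrix":
    """Logistic filtering of phenotype similarities.

    Every off-diagonal similarity ``s`` is replaced by ``L(s)``; entries
    with ``L(s) < 0.5`` are zeroed (deemed uninformative).  The diagonal
    stays at 1.
    """
    from .data_io import PhenotypeSimMatrix

    S = np.asarray(sims.sims, dtype=float)
    L = 1.0 / (1.0 + np.exp(c * S + d))
    out = np.where(L >= 0.5, L, 0.0)
    np.fill_diagonal(out, 1.0)
    return PhenotypeSimMatrix(phenotypes=list(sims.phenotypes), sims=out)


def to_transition(net: GeneNetwork, use_abs: bool = True) -> TransitionMatrix:
    """Row-normalize by weighted degree, then transpose.

    With ``use_abs`` (the default) both the degree and the propagated
    weight use |w|, so networks carrying negative co-expression weights
    still define a proper flow.  Zero-degree genes yield all-zero columns.
    """
    W = abs(net.W.tocsr()) if use_abs else net.W.tocsr()
    deg = np.asarray(abs(W).sum(axis=1)).ravel()
    inv = np.zeros_like(deg)
    nz = deg > 0
    inv[nz] = 1.0 / deg[nz]
    D_inv = sp.diags(inv)
    What = (D_inv @ W).T.tocsr()
    return TransitionMatrix(nodes=list(net.nodes), What=What)
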