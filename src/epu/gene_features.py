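"""Gene feature vectors.

A gene is represented as a concatenation of five blocks:

``(MF | BP | CC | DOMAIN | TOPO)``

* the three GO blocks hold, per selected anchor term, the gene's best Wang
  semantic similarity between any of its annotated terms and the anchor;
* the domain block holds binary protein-domain indicators;
* the topology block holds four interaction-network statistics (degree,
  mean neighbour degree, clustering coefficient, isolation flag), min-max
  scaled to [0, 1] over the gene universe.

Anchor terms are chosen per sub-ontology by how well they separate the
positive class from the unlabeled class: the score of a candidate term is
the absolute difference of its mean feature value over P and over U, and
the top-n terms are kept.

Wang's measure scores two terms by the overlap of their ancestor closures,
where each ancestor's semantic contribution decays by a per-edge factor
(0.8 for ``is_a``, 0.6 for ``part_of``) along the best child-to-parent
path from the query term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .exceptions import ValidationError
from .network_builder import GeneNetwork

NAMESPACES = ("MF", "BP", "CC")
GO_BLOCKS = frozenset(NAMESPACES)
EDGE_TYPE_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class OntologyDAG:
    """One GO sub-ontology as a typed DAG.

    ``graph`` holds child -> parent edges with attributes ``relation``
    (``is_a`` | ``part_of``) and ``weight`` (the semantic contribution
    factor of that edge type).
    """

    namespace: str
    graph: nx.DiGraph
    _svalues: dict[str, dict[str, float]] = field(
        default_factory=dict, init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise ValidationError(
                f"ontology {self.namespace} contains a cycle through {cycle[0][0]!r}"
            )

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def __contains__(self, term: str) -> bool:
        return term in self.graph

    def semantic_contributions(self, term: str) -> dict[str, float]:
        """S-values of ``term`` and all its ancestors.

        S(term) = 1; for an ancestor t, S(t) is the maximum over child
        edges (t' -> t) inside the closure of ``weight(t'->t) * S(t')``.
        Cached per term.
        """
        cached = self._svalues.get(term)
        if cached is not None:
            return cached
        if term not in self.graph:
            raise ValidationError(f"term {term!r} not in {self.namespace} ontology")
        # edges run child -> parent, so the ancestor closure of `term` is
        # its descendant set in graph orientation
        closure = {term} | nx.descendants(self.graph, term)
        sub = self.graph.subgraph(closure)
        s: dict[str, float] = {term: 1.0}
        for node in nx.topological_sort(sub):
            if node == term:
                continue
            best = 0.0
            for child, _, data in sub.in_edges(node, data=True):
                if child in s:
                    best = max(best, data["weight"] * s[child])
            s[node] = best
        self._svalues[term] = s
        return s


def wang_term_similarity(a: str, b: str, dag: OntologyDAG) -> float:
    """Wang similarity of two terms of the same sub-ontology, in [0, 1]."""
    sa = dag.semantic_contributions(a)
    sb = dag.semantic_contributions(b)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    num = sum(sa[t] + sb[t] for t in common)
    return float(num / (sum(sa.values()) + sum(sb.values())))


def term_similarity_matrix(
    terms_a: Sequence[str], terms_b: Sequence[str], dag: OntologyDAG
) -> np.ndarray:
    """Dense |A| x |B| Wang similarity matrix (S-values are cached, so this
    is cheap for repeated calls on the same DAG)."""
    out = np.zeros((len(terms_a), len(terms_b)))
    for i, a in enumerate(terms_a):
        for j, b in enumerate(terms_b):
            out[i, j] = wang_term_similarity(a, b, dag)
    return out


def gene_feature_value(
    gene: str, feature_term: str, annots: "AnnotationLike", dag: OntologyDAG
) -> float:
    """Similarity of a gene to one anchor term: the max Wang similarity
    over the gene's annotated terms in the anchor's namespace; 0 if the
    gene has no annotation there."""
    terms = [t for t in annots.terms_for(gene) if t in dag]
    if not terms:
        return 0.0
    return max(wang_term_similarity(t, feature_term, dag) for t in terms)


def go_feature_block(
    genes: Sequence[str],
    feature_terms: Sequence[str],
    annots: "AnnotationLike",
    dag: OntologyDAG,
) -> np.ndarray:
    """Genes x anchor-terms block of best-match Wang similarities."""
    annotated_terms = sorted(
        {t for g in genes for t in annots.terms_for(g) if t in dag}
    )
    if not annotated_terms or not feature_terms:
        return np.zeros((len(genes), len(feature_terms)))
    sims = term_similarity_matrix(annotated_terms, list(feature_terms), dag)
    term_idx = {t: i for i, t in enumerate(annotated_terms)}
    block = np.zeros((len(genes), len(feature_terms)))
    for gi, g in enumerate(genes):
        idx = [term_idx[t] for t in annots.terms_for(g) if t in dag]
        if idx:
            block[gi] = sims[idx].max(axis=0)
    return block


def select_go_features(
    P: Iterable[str],
    U: Iterable[str],
    candidates: Sequence[str],
    annots: "AnnotationLike",
    dag: OntologyDAG,
    n: int = 1000,
) -> list[str]:
    """Pick the n anchor terms that best separate P from U.

    Score(term) = |mean feature value over P - mean over U|; ties are
    broken by ascending term identifier.  Returns all candidates when
    fewer than n exist.
    """
    P = sorted(set(P))
    U = sorted(set(U))
    if not P or not U:
        raise ValidationError("P and U must both be non-empty")
    if set(P) & set(U):
        raise ValidationError("P and U must be disjoint")
    candidates = list(candidates)
    vp = go_feature_block(P, candidates, annots, dag).mean(axis=0)
    vu = go_feature_block(U, candidates, annots, dag).mean(axis=0)
    return rank_feature_scores(candidates, np.abs(vp - vu), n)


def rank_feature_scores(
    candidates: Sequence[str], scores: np.ndarray, n: int
) -> list[str]:
    """Top-n candidates by descending score, ties by ascending identifier."""
    cand = np.asarray(candidates)
    id_rank = np.argsort(np.argsort(cand))
    order = np.lexsort((id_rank, -np.asarray(scores, dtype=float)))
    return [str(c) for c in cand[order][:n]]


TOPO_STATS = ("degree", "mean_neighbor_degree", "clustering", "isolated")


def topology_features(
    genes: Sequence[str], ppi: GeneNetwork, scale: bool = True
) -> np.ndarray:
    """Four interaction-topology statistics per gene.

    Genes absent from the interaction network count as isolated:
    (0, 0, 0, 1) before scaling.  With ``scale`` the columns are min-max
    mapped to [0, 1] over the supplied gene universe (constant columns
    collapse to 0).
    """
    A = (ppi.W > 0).astype(float)
    deg = np.asarray(A.sum(axis=1)).ravel()
    graph = nx.from_scipy_sparse_array(A)
    clust = nx.clustering(graph)
    out = np.zeros((len(genes), 4))
    for gi, g in enumerate(genes):
        if g not in ppi:
            out[gi] = (0.0, 0.0, 0.0, 1.0)
            continue
        i = ppi.index(g)
        d = deg[i]
        if d == 0:
            out[gi] = (0.0, 0.0, 0.0, 1.0)
            continue
        neigh = A[i].indices
        out[gi] = (d, deg[neigh].mean(), clust[i], 0.0)
    if scale:
        lo = out.min(axis=0)
        span = out.max(axis=0) - lo
        span[span == 0] = 1.0
        out = (out - lo) / span
    return out


def domain_feature_block(
    genes: Sequence[str], annots: "AnnotationLike", domains: Sequence[str] | None = None
) -> tuple[np.ndarray, list[str]]:
    """Binary presence indicators for protein domains."""
    if domains is None:
        domains = sorted({d for g in genes for d in annots.terms_for(g)})
    domains = list(domains)
    idx = {d: i for i, d in enumerate(domains)}
    block = np.zeros((len(genes), len(domains)))
    for gi, g in enumerate(genes):
        for d in annots.terms_for(g):
            if d in idx:
                block[gi, idx[d]] = 1.0
    return block, domains


@dataclass
class GeneFeatureMatrix:
    """Gene x feature matrix with labelled column blocks.

    Column order is fixed: MF, BP, CC, DOMAIN, TOPO.  GO and domain
    entries lie in [0, 1]; topology columns are min-max scaled.
    """

    genes: list[str]
    kinds: list[str]
    names: list[str]
    V: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.V.shape != (len(self.genes), len(self.names)):
            raise ValidationError("feature matrix shape mismatch")
        if len(self.kinds) != len(self.names):
            raise ValidationError("kinds/names length mismatch")
        self._index = {g: i for i, g in enumerate(self.genes)}

    @property
    def m(self) -> int:
        return self.V.shape[1]

    def index(self, gene: str) -> int:
        return self._index[gene]

    def row(self, gene: str) -> np.ndarray:
        return self.V[self._index[gene]]

    def rows(self, genes: Iterable[str]) -> np.ndarray:
        return self.V[[self._index[g] for g in genes]]

    def block(self, *kinds: str) -> np.ndarray:
        mask = np.isin(np.asarray(self.kinds), list(kinds))
        return self.V[:, mask]


def build_feature_matrix(
    genes: Sequence[str],
    dags: Mapping[str, OntologyDAG],
    go_annots: "AnnotationLike",
    selected_terms: Mapping[str, Sequence[str]],
    domain_annots: "AnnotationLike",
    ppi: GeneNetwork,
) -> GeneFeatureMatrix:
    """Assemble the full (MF | BP | CC | DOMAIN | TOPO) matrix."""
    genes = list(genes)
    blocks: list[np.ndarray] = []
    kinds: list[str] = []
    names: list[str] = []
    for ns in NAMESPACES:
        terms = list(selected_terms.get(ns, ()))
        blocks.append(go_feature_block(genes, terms, go_annots, dags[ns]))
        kinds.extend([ns] * len(terms))
        names.extend(terms)
    dom_block, domains = domain_feature_block(genes, domain_annots)
    blocks.append(dom_block)
    kinds.extend(["DOMAIN"] * len(domains))
    names.extend(domains)
    blocks.append(topology_features(genes, ppi))
    kinds.extend(["TOPO"] * len(TOPO_STATS))
    names.extend(TOPO_STATS)
    V = np.hstack(blocks)
    return GeneFeatureMatrix(genes=genes, kinds=kinds, names=names, V=V)


def positive_representative(P: Iterable[str], features: GeneFeatureMatrix) -> np.ndarray:
    """Mean feature vector of the positive genes.

    The mean (rather than a unit-normalised sum) keeps the representative
    on the same scale as individual gene vectors, which matters because
    reliable-negative extraction compares raw Euclidean distances to it.
    """
    P = list(P)
    if not P:
        raise ValidationError("positive set is empty")
    return features.rows(P).mean(axis=0)


class AnnotationLike:
    """Protocol-ish base: anything with ``terms_for(gene) -> set``.

    Implemented by :class:`epu.data_io.AnnotationTable`; tests may pass a
    bare dict wrapped in :class:`MappingAnnotations`.
    """

    def terms_for(self, gene: str) -> frozenset[str]:  # pragma: no cover
        raise NotImplementedError


class MappingAnnotations(AnnotationLike):
    """Adapter exposing a plain mapping as an annotation table."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map = {g: frozenset(ts) for g, ts in mapping.items()}

    def terms_for(self, gene: str) -> frozenset[str]:
        return self._map.get(gene, frozenset())
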