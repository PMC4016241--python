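"""Seeding of the label-propagation stage.

From the positive set P and the unlabeled universe U we derive:

* **CP** — candidate positives: known-disease-universe genes associated
  with phenotypes that survive the logistic similarity filter against the
  query disease's phenotypes (guilt by association).  CP genes only seed
  propagation; they never enter classifier training sets.
* **RN** — reliable negatives: unlabeled genes strictly farther (Euclidean)
  from the positive representative vector than the average unlabeled gene.
* **R0** — signed initial scores: +1 for P, the maximal filtered phenotype
  similarity for CP, and a shared negative value for RN chosen so that the
  total seed mass is zero (positive and negative flow are balanced).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .data_io import PhenotypeAssoc, PhenotypeSimMatrix
from .exceptions import ValidationError
from .gene_features import GeneFeatureMatrix


def extract_candidate_positives(
    query_P: Iterable[str],
    assoc: PhenotypeAssoc,
    sims: PhenotypeSimMatrix,
    exclude: Iterable[str] = (),
) -> tuple[set[str], dict[str, float]]:
    """Candidate positives and their phenotype-similarity scores.

    ``sims`` must already be logistic-filtered: a zero entry means "not
    similar".  A gene outside P (and outside ``exclude``, used by the
    evaluation harness to keep held-out genes out of seeding) joins CP if
    any of its phenotypes has nonzero filtered similarity to any phenotype
    of P; its score is the maximum such similarity, in (0, 1].
    """
    P = set(query_P)
    excluded = P | set(exclude)
    ph_P = sorted({ph for g in P for ph in assoc.phenotypes_of(g) if ph in sims})
    if not ph_P:
        warnings.warn("positive set has no phenotype associations; CP is empty", stacklevel=2)
        return set(), {}
    ph_P_idx = [sims.index(ph) for ph in ph_P]
    cp: set[str] = set()
    scores: dict[str, float] = {}
    for gene in assoc.genes:
        if gene in excluded:
            continue
        idx = [sims.index(ph) for ph in assoc.phenotypes_of(gene) if ph in sims]
        if not idx:
            continue
        best = float(sims.sims[np.ix_(idx, ph_P_idx)].max())
        if best > 0.0:
            cp.add(gene)
            scores[gene] = min(best, 1.0)
    return cp, scores


def extract_reliable_negatives(
    U: Iterable[str], pr: np.ndarray, features: GeneFeatureMatrix
) -> set[str]:
    """Unlabeled genes strictly farther from ``pr`` than the U average."""
    U = list(U)
    if not U:
        raise ValidationError("unlabeled set is empty")
    dists = np.linalg.norm(features.rows(U) - pr, axis=1)
    d_avg = dists.mean()
    return {g for g, d in zip(U, dists) if d > d_avg}


@dataclass
class SeedScores:
    """Per-gene signed initial scores R0 (genes absent from the mapping
    score 0)."""

    scores: dict[str, float]
    balanced: bool = True

    def vector(self, nodes: list[str]) -> np.ndarray:
        return np.array([self.scores.get(g, 0.0) for g in nodes])

    def total(self) -> float:
        return float(sum(self.scores.values()))

    def __getitem__(self, gene: str) -> float:
        return self.scores.get(gene, 0.0)


def init_seed_scores(
    P: Iterable[str],
    CP: Iterable[str],
    cp_scores: Mapping[str, float],
    RN: Iterable[str],
    balance_include_cp: bool = True,
) -> SeedScores:
    """Flow-balanced initial scores.

    Each positive gene seeds +1, each candidate positive its phenotype
    score, and every reliable negative the shared value
    ``-(positive mass)/|RN|`` so that the signed seed mass sums to zero.
    With ``balance_include_cp=False`` the balanced mass is |P| alone.
    """
    P = sorted(set(P))
    CP = sorted(set(CP))
    RN = sorted(set(RN))
    if set(P) & set(CP) or set(P) & set(RN) or set(CP) & set(RN):
        raise ValidationError("P, CP and RN must be pairwise disjoint")
    scores: dict[str, float] = {g: 1.0 for g in P}
    for g in CP:
        s = float(cp_scores[g])
        if not 0.0 < s <= 1.0:
            raise ValidationError(f"CP score for {g!r} outside (0, 1]: {s}")
        scores[g] = s
    pos_mass = float(len(P))
    if balance_include_cp:
        pos_mass += float(sum(scores[g] for g in CP))
    if RN:
        n0 = -pos_mass / len(RN)
        for g in RN:
            scores[g] = n0
        balanced = True
    else:
        warnings.warn("RN is empty; seed scores are not flow-balanced", stacklevel=2)
        balanced = False
    return SeedScores(scores=scores, balanced=balanced)
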