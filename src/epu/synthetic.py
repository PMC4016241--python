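"""Synthetic data bundle with a planted disease module.

The generator emulates the structure the method exploits in real data:

* **Interactions** — a planted-partition graph: module genes interact
  with probability ``p_in``, all other pairs with ``p_out``.
* **Expression** — a shared-factor model over ``n_tissues`` tissues;
  module genes load on a common tissue factor so that their pairwise
  Pearson correlation targets ``expr_corr_in``; background genes are
  independent noise.
* **Ontology** — three random DAG sub-ontologies (MF/BP/CC) of given
  depth and branching; module genes annotate inside one "disease clade"
  per namespace, background genes annotate uniformly.  A small noise
  rate swaps annotations across the boundary.
* **Domains** — a few disease-enriched domains for module genes,
  scattered background domains otherwise.
* **Phenotypes** — grouped phenotypes with high within-group similarity
  (~U(0.7, 1)) and low between-group similarity (~U(0, 0.3)); every
  disease gene links to at least one phenotype of the disease group,
  background genes occasionally link to other groups.

Half of the true module (``hidden_frac``) is withheld from the declared
positive list: these *hidden positives* sit in the unlabeled universe and
are the currency for measuring positive-unlabeled behaviour.  Generation
is a pure function of the config (seeded).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np

from . import data_io
from .data_io import (
    AnnotationTable,
    DataBundle,
    EdgeList,
    ExpressionTable,
    PhenotypeAssoc,
    PhenotypeSimMatrix,
)
from .exceptions import ValidationError
from .gene_features import NAMESPACES, OntologyDAG


@dataclass(frozen=True)
class SyntheticConfig:
    n_genes: int = 600
    n_disease: int = 60
    n_tissues: int = 16
    n_phenotypes: int = 100
    n_pheno_groups: int = 5
    p_in: float = 0.2
    p_out: float = 0.01
    expr_corr_in: float = 0.7
    go_depth: int = 3
    go_branching: int = 3
    n_domains: int = 20
    n_disease_domains: int = 3
    feature_noise: float = 0.1
    hidden_frac: float = 0.5
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValidationError("need 0 <= p_out < p_in <= 1")
        if not 0 < self.hidden_frac < 1:
            raise ValidationError("hidden_frac must be in (0, 1)")
        if self.n_disease >= self.n_genes:
            raise ValidationError("disease module larger than gene universe")
        for name in ("n_genes", "n_disease", "n_tissues", "n_phenotypes", "n_pheno_groups"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")


@dataclass
class SyntheticBundle:
    """Generated inputs plus the ground truth the pipeline never sees."""

    config: SyntheticConfig
    genes: list[str]
    module: list[str]
    declared: list[str]
    hidden: list[str]
    ppi_edges: EdgeList
    expression: ExpressionTable
    dags: dict[str, OntologyDAG]
    go_annots: AnnotationTable
    domain_annots: AnnotationTable
    pheno_assoc: PhenotypeAssoc
    pheno_sims: PhenotypeSimMatrix
    #: gene -> (is_disease, is_hidden)
    truth: dict[str, tuple[bool, bool]]

    def data_bundle(self) -> DataBundle:
        """The truth-free view the pipeline consumes."""
        return DataBundle(
            genes=list(self.genes),
            ppi_edges=self.ppi_edges,
            expression=self.expression,
            dags=self.dags,
            go_annots=self.go_annots,
            domain_annots=self.domain_annots,
            pheno_assoc=self.pheno_assoc,
            pheno_sims=self.pheno_sims,
            positives=list(self.declared),
        )


def _random_dag(ns: str, depth: int, branching: int, rng: np.random.Generator) -> tuple[OntologyDAG, list[str], list[list[str]]]:
    """Random layered DAG; returns (dag, all_terms, levels)."""
    graph = nx.DiGraph()
    counter = 0

    def new_term() -> str:
        nonlocal counter
        counter += 1
        return f"{ns}:{counter:07d}"

    root = new_term()
    graph.add_node(root)
    levels = [[root]]
    for _ in range(depth):
        prev = levels[-1]
        level: list[str] = []
        for parent in prev:
            for _ in range(branching):
                term = new_term()
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                graph.add_edge(term, parent, relation=rel, weight=0.8 if rel == "is_a" else 0.6)
                # occasional second parent elsewhere in the previous level
                if len(prev) > 1 and rng.random() < 0.2:
                    other = prev[int(rng.integers(len(prev)))]
                    if other != parent:
                        rel2 = "is_a" if rng.random() < 0.8 else "part_of"
                        graph.add_edge(
                            term, other, relation=rel2, weight=0.8 if rel2 == "is_a" else 0.6
                        )
                level.append(term)
        levels.append(level)
    return OntologyDAG(namespace=ns, graph=graph), list(graph.nodes), levels


def _clade_terms(dag: OntologyDAG, levels: list[list[str]], rng: np.random.Generator) -> list[str]:
    """One depth-1 subtree: the disease clade of this namespace."""
    anchor = levels[1][int(rng.integers(len(levels[1])))]
    clade = {anchor} | nx.ancestors(dag.graph, anchor)  # graph edges run child->parent
    return sorted(clade)


def generate(config: SyntheticConfig | None = None, **overrides) -> SyntheticBundle:
    """Generate a complete bundle from a (seeded) config."""
    if config is None:
        config = SyntheticConfig(**overrides)
    elif overrides:
        config = replace(config, **overrides)
    rng = np.random.default_rng(config.seed)
    n = config.n_genes
    genes = [f"G{i:05d}" for i in range(1, n + 1)]

    module_idx = np.sort(rng.choice(n, size=config.n_disease, replace=False))
    module = [genes[i] for i in module_idx]
    n_hidden = int(round(config.hidden_frac * config.n_disease))
    hidden_pick = rng.choice(config.n_disease, size=n_hidden, replace=False)
    hidden = sorted(module[i] for i in hidden_pick)
    declared = sorted(set(module) - set(hidden))

    # --- interactions: planted partition -----------------------------------
    in_module = np.zeros(n, dtype=bool)
    in_module[module_idx] = True
    iu, ju = np.triu_indices(n, k=1)
    p = np.where(in_module[iu] & in_module[ju], config.p_in, config.p_out)
    keep = rng.random(p.size) < p
    edges = {
        (genes[a], genes[b]): 1.0
        for a, b in zip(iu[keep], ju[keep])
    }
    ppi = EdgeList(edges=edges)

    # --- expression: shared module factor ----------------------------------
    rho = config.expr_corr_in
    factor = rng.normal(size=config.n_tissues)
    X = rng.normal(size=(n, config.n_tissues))
    X[in_module] = np.sqrt(rho) * factor + np.sqrt(1 - rho) * X[in_module]
    X += 5.0  # shift to expression-like positive scale; Pearson is shift-invariant
    expression = ExpressionTable(genes=list(genes), tissues=[f"tissue_{t+1:02d}" for t in range(config.n_tissues)], values=X)

    # --- ontology and annotations ------------------------------------------
    dags: dict[str, OntologyDAG] = {}
    go_map: dict[str, set[str]] = {g: set() for g in genes}
    for ns in NAMESPACES:
        dag, terms, levels = _random_dag(ns, config.go_depth, config.go_branching, rng)
        dags[ns] = dag
        clade = _clade_terms(dag, levels, rng)
        non_root = [t for t in terms if t != levels[0][0]]
        for gi, g in enumerate(genes):
            k_ann = int(rng.integers(1, 4))
            source = clade if in_module[gi] else non_root
            picked = [source[int(rng.integers(len(source)))] for _ in range(k_ann)]
            # annotation noise across the module boundary
            picked = [
                non_root[int(rng.integers(len(non_root)))]
                if rng.random() < config.feature_noise
                else t
                for t in picked
            ]
            go_map[g].update(picked)
    go_annots = AnnotationTable({g: frozenset(ts) for g, ts in go_map.items()})

    domains = [f"DOM{i:04d}" for i in range(1, config.n_domains + 1)]
    disease_domains = domains[: config.n_disease_domains]
    background_domains = domains[config.n_disease_domains :]
    dom_map: dict[str, set[str]] = {}
    for gi, g in enumerate(genes):
        ds: set[str] = set()
        if in_module[gi]:
            for d in disease_domains:
                if rng.random() < 0.5:
                    ds.add(d)
            if rng.random() < config.feature_noise and background_domains:
                ds.add(background_domains[int(rng.integers(len(background_domains)))])
        else:
            for d in background_domains:
                if rng.random() < 0.08:
                    ds.add(d)
            if rng.random() < config.feature_noise:
                ds.add(disease_domains[int(rng.integers(len(disease_domains)))])
        if ds:
            dom_map[g] = ds
    domain_annots = AnnotationTable({g: frozenset(ds) for g, ds in dom_map.items()})

    # --- phenotypes ---------------------------------------------------------
    n_ph = config.n_phenotypes
    phenos = [f"PH{i:04d}" for i in range(1, n_ph + 1)]
    group_of = np.arange(n_ph) % config.n_pheno_groups
    S = rng.uniform(0.0, 0.3, size=(n_ph, n_ph))
    same = group_of[:, None] == group_of[None, :]
    S[same] = rng.uniform(0.7, 1.0, size=int(same.sum()))
    S = np.triu(S, 1)
    S = S + S.T
    np.fill_diagonal(S, 1.0)
    sims = PhenotypeSimMatrix(phenotypes=phenos, sims=S)

    disease_group_ph = [ph for ph, grp in zip(phenos, group_of) if grp == 0]
    other_ph = [ph for ph, grp in zip(phenos, group_of) if grp != 0]
    pairs: list[tuple[str, str]] = []
    for gi, g in enumerate(genes):
        if in_module[gi]:
            k_ph = int(rng.integers(1, 3))
            for _ in range(k_ph):
                pairs.append((disease_group_ph[int(rng.integers(len(disease_group_ph)))], g))
        elif rng.random() < 0.3 and other_ph:
            k_ph = int(rng.integers(1, 3))
            for _ in range(k_ph):
                pairs.append((other_ph[int(rng.integers(len(other_ph)))], g))
    assoc = PhenotypeAssoc.from_pairs(pairs)

    truth = {
        g: (bool(in_module[gi]), g in set(hidden)) for gi, g in enumerate(genes)
    }
    return SyntheticBundle(
        config=config,
        genes=genes,
        module=module,
        declared=declared,
        hidden=hidden,
        ppi_edges=ppi,
        expression=expression,
        dags=dags,
        go_annots=go_annots,
        domain_annots=domain_annots,
        pheno_assoc=assoc,
        pheno_sims=sims,
        truth=truth,
    )


def write_bundle(bundle: SyntheticBundle, directory) -> None:
    """Write every input in the standard bundle layout, plus truth.tsv
    (which the pipeline's loaders deliberately never read)."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    files = data_io.BUNDLE_FILES
    data_io.write_edge_list(bundle.ppi_edges, d / files["ppi"])
    data_io.write_expression(bundle.expression, d / files["expression"])
    data_io.write_obo(bundle.dags, d / files["ontology"])
    data_io.write_annotations(bundle.go_annots, d / files["go_annotations"])
    data_io.write_annotations(bundle.domain_annots, d / files["domains"])
    data_io.write_phenotype_assoc(bundle.pheno_assoc, d / files["pheno_assoc"])
    data_io.write_phenotype_sim(bundle.pheno_sims, d / files["pheno_sim"])
    data_io.write_gene_list(bundle.declared, d / files["positives"])
    with open(d / files["truth"], "w", encoding="utf-8") as fh:
        fh.write("gene_id\tis_disease\tis_hidden\n")
        for g in bundle.genes:
            dis, hid = bundle.truth[g]
            fh.write(f"{g}\t{int(dis)}\t{int(hid)}\n")


def read_truth(path) -> dict[str, tuple[bool, bool]]:
    """Load truth.tsv — evaluation-only; never part of a DataBundle."""
    truth: dict[str, tuple[bool, bool]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("gene_id"):
            raise ValidationError(f"{path}: unexpected truth header")
        for line in fh:
            g, dis, hid = line.rstrip("\n").split("\t")
            truth[g] = (dis == "1", hid == "1")
    return truth
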