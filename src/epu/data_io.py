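"""Readers and writers for every external format the pipeline touches.

All tabular formats are tab-separated UTF-8 text; lines starting with
``#`` are comments.  Ontologies are OBO 1.2 (parsed with :mod:`obonet`).
Loaders validate eagerly and raise :class:`~epu.exceptions.ParseError`
(naming the line) or :class:`~epu.exceptions.ValidationError`, so the
rest of the system only ever sees checked in-memory domain types.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import obonet
import pandas as pd

from .exceptions import ParseError, ValidationError
from .gene_features import EDGE_TYPE_WEIGHTS, AnnotationLike, OntologyDAG

_NS_LONG = {"BP": "biological_process", "MF": "molecular_function", "CC": "cellular_component"}
_NS_SHORT = {v: k for k, v in _NS_LONG.items()}


def _check_gene_id(token: str, path, lineno: int) -> str:
    token = token.strip()
    if not token or any(ch.isspace() for ch in token):
        raise ParseError(f"{path}:{lineno}: invalid identifier {token!r}")
    return token


def _data_lines(path):
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# edge lists


@dataclass
class EdgeList:
    """Undirected weighted edge set keyed by the sorted gene pair."""

    edges: dict[tuple[str, str], float]
    n_duplicates: int = 0
    n_self_loops: int = 0

    def nodes(self) -> set[str]:
        return {g for pair in self.edges for g in pair}

    def __len__(self) -> int:
        return len(self.edges)


def read_edge_list(path) -> EdgeList:
    """Load a 2- or 3-column TSV edge list.

    Missing weights default to 1.0; duplicate pairs collapse keeping the
    maximum weight; self-loops are dropped and counted.
    """
    edges: dict[tuple[str, str], float] = {}
    n_dup = 0
    n_self = 0
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) not in (2, 3):
            raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns, got {len(parts)}")
        a = _check_gene_id(parts[0], path, lineno)
        b = _check_gene_id(parts[1], path, lineno)
        if len(parts) == 3:
            try:
                w = float(parts[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad weight {parts[2]!r}") from exc
        else:
            w = 1.0
        if w < 0:
            raise ValidationError(f"{path}:{lineno}: negative edge weight {w}")
        if a == b:
            n_self += 1
            continue
        key = (a, b) if a < b else (b, a)
        if key in edges:
            n_dup += 1
            edges[key] = max(edges[key], w)
        else:
            edges[key] = w
    return EdgeList(edges=edges, n_duplicates=n_dup, n_self_loops=n_self)


def write_edge_list(edges: EdgeList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (a, b), w in sorted(edges.edges.items()):
            fh.write(f"{a}\t{b}\t{w:.10g}\n")


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionTable:
    """Gene x tissue expression matrix with no missing entries."""

    genes: list[str]
    tissues: list[str]
    values: np.ndarray
    n_dropped: int = 0
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            dups = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene rows: {dups}")
        if self.values.shape != (len(self.genes), len(self.tissues)):
            raise ValidationError("expression matrix shape mismatch")
        self._index = {g: i for i, g in enumerate(self.genes)}

    def profile(self, gene: str) -> np.ndarray:
        return self.values[self._index[gene]]


def read_expression(path) -> ExpressionTable:
    """Load a TSV expression matrix (header = tissues, first column = gene
    ids).  Rows containing any non-numeric cell are dropped and counted."""
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"{path}: expression file has no tissue columns")
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{path}: duplicate gene rows: {dups}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    keep = ~numeric.isna().any(axis=1)
    n_dropped = int((~keep).sum())
    numeric = numeric[keep]
    return ExpressionTable(
        genes=[str(g) for g in numeric.index],
        tissues=[str(t) for t in df.columns],
        values=numeric.to_numpy(dtype=float),
        n_dropped=n_dropped,
    )


def write_expression(table: ExpressionTable, path) -> None:
    df = pd.DataFrame(table.values, index=table.genes, columns=table.tissues)
    df.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# ontology


def read_ontology(
    path,
    w_is_a: float = EDGE_TYPE_WEIGHTS["is_a"],
    w_part_of: float = EDGE_TYPE_WEIGHTS["part_of"],
) -> dict[str, OntologyDAG]:
    """Parse an OBO 1.2 file into one typed DAG per namespace.

    Only ``is_a`` and ``relationship: part_of`` edges are kept; obsolete
    terms are excluded; cross-namespace edges are ignored.
    """
    graph = obonet.read_obo(path, ignore_obsolete=True)
    default_ns = graph.graph.get("default-namespace", ["biological_process"])
    if isinstance(default_ns, list):
        default_ns = default_ns[0]
    weights = {"is_a": w_is_a, "part_of": w_part_of}

    def ns_of(term: str) -> str:
        long = graph.nodes[term].get("namespace", default_ns)
        return _NS_SHORT.get(long, str(long))

    per_ns: dict[str, nx.DiGraph] = {}
    for term in graph.nodes:
        per_ns.setdefault(ns_of(term), nx.DiGraph()).add_node(term)
    for child, parent, rel in graph.edges(keys=True):
        if rel not in weights:
            continue
        ns = ns_of(child)
        if ns_of(parent) != ns:
            continue
        per_ns[ns].add_edge(child, parent, relation=rel, weight=weights[rel])
    return {ns: OntologyDAG(namespace=ns, graph=g) for ns, g in per_ns.items()}


def write_obo(dags: Mapping[str, OntologyDAG], path) -> None:
    """Serialize DAGs back to a minimal OBO 1.2 document."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: go\n")
        for ns in sorted(dags):
            dag = dags[ns]
            long_ns = _NS_LONG.get(ns, ns)
            for term in sorted(dag.graph.nodes):
                fh.write(f"\n[Term]\nid: {term}\nname: {term}\nnamespace: {long_ns}\n")
                for _, parent, data in sorted(dag.graph.out_edges(term, data=True)):
                    if data["relation"] == "is_a":
                        fh.write(f"is_a: {parent}\n")
                    else:
                        fh.write(f"relationship: part_of {parent}\n")


# ---------------------------------------------------------------------------
# annotations and phenotype data


@dataclass
class AnnotationTable(AnnotationLike):
    """Gene -> set-of-term-ids mapping (GO terms or protein domains)."""

    mapping: dict[str, frozenset[str]]

    @property
    def genes(self) -> set[str]:
        return set(self.mapping)

    @property
    def all_terms(self) -> set[str]:
        return {t for ts in self.mapping.values() for t in ts}

    def terms_for(self, gene: str) -> frozenset[str]:
        return self.mapping.get(gene, frozenset())


def read_annotations(path, ontology: Mapping[str, OntologyDAG] | None = None) -> AnnotationTable:
    """Load a 2-column gene\\tterm TSV.  When an ontology is supplied every
    term must exist in one of its namespaces."""
    known: set[str] | None = None
    if ontology is not None:
        known = set()
        for dag in ontology.values():
            known |= dag.terms
    mapping: dict[str, set[str]] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        gene = _check_gene_id(parts[0], path, lineno)
        term = parts[1].strip()
        if not term:
            raise ParseError(f"{path}:{lineno}: empty term id")
        if known is not None and term not in known:
            raise ValidationError(f"{path}:{lineno}: unknown term {term!r}")
        mapping.setdefault(gene, set()).add(term)
    return AnnotationTable({g: frozenset(ts) for g, ts in mapping.items()})


def write_annotations(table: AnnotationTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(table.mapping):
            for term in sorted(table.mapping[gene]):
                fh.write(f"{gene}\t{term}\n")


@dataclass
class PhenotypeAssoc:
    """Bidirectional phenotype <-> gene association maps (exact inverses)."""

    pheno_to_genes: dict[str, frozenset[str]]
    gene_to_phenos: dict[str, frozenset[str]]

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "PhenotypeAssoc":
        p2g: dict[str, set[str]] = {}
        g2p: dict[str, set[str]] = {}
        for ph, g in pairs:
            p2g.setdefault(ph, set()).add(g)
            g2p.setdefault(g, set()).add(ph)
        return cls(
            {ph: frozenset(gs) for ph, gs in p2g.items()},
            {g: frozenset(phs) for g, phs in g2p.items()},
        )

    @property
    def genes(self) -> set[str]:
        return set(self.gene_to_phenos)

    def genes_of(self, phenotype: str) -> frozenset[str]:
        return self.pheno_to_genes.get(phenotype, frozenset())

    def phenotypes_of(self, gene: str) -> frozenset[str]:
        return self.gene_to_phenos.get(gene, frozenset())


def read_phenotype_assoc(path) -> PhenotypeAssoc:
    """Load a 2-column phenotype\\tgene TSV."""
    pairs: list[tuple[str, str]] = []
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        ph = parts[0].strip()
        gene = _check_gene_id(parts[1], path, lineno)
        if not ph:
            raise ParseError(f"{path}:{lineno}: empty phenotype id")
        pairs.append((ph, gene))
    return PhenotypeAssoc.from_pairs(pairs)


def write_phenotype_assoc(assoc: PhenotypeAssoc, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for ph in sorted(assoc.pheno_to_genes):
            for g in sorted(assoc.pheno_to_genes[ph]):
                fh.write(f"{ph}\t{g}\n")


@dataclass
class PhenotypeSimMatrix:
    """Symmetric phenotype similarity matrix in [0, 1] with unit diagonal."""

    phenotypes: list[str]
    sims: np.ndarray
    n_clipped: int = 0
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.phenotypes)
        if self.sims.shape != (n, n):
            raise ValidationError("similarity matrix shape mismatch")
        if np.abs(self.sims - self.sims.T).max(initial=0.0) > 1e-12:
            raise ValidationError("similarity matrix not symmetric")
        self._index = {p: i for i, p in enumerate(self.phenotypes)}

    def index(self, phenotype: str) -> int:
        return self._index[phenotype]

    def __contains__(self, phenotype: str) -> bool:
        return phenotype in self._index

    def sim(self, a: str, b: str) -> float:
        return float(self.sims[self._index[a], self._index[b]])


def read_phenotype_sim(path) -> PhenotypeSimMatrix:
    """Load a labelled square similarity TSV.

    Asymmetries beyond 1e-6 are a validation error; smaller ones are
    symmetrised away.  Out-of-range values are clipped to [0, 1] and any
    off-unit diagonal reset to 1, both with a warning count.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", header=0, index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"{path}: empty similarity file") from exc
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column labels differ")
    S = df.to_numpy(dtype=float)
    if np.abs(S - S.T).max(initial=0.0) > 1e-6:
        raise ValidationError(f"{path}: asymmetric similarity matrix")
    S = (S + S.T) / 2.0
    n_clipped = int(((S < 0) | (S > 1)).sum())
    S = np.clip(S, 0.0, 1.0)
    diag_bad = int((np.diag(S) != 1.0).sum())
    if diag_bad:
        np.fill_diagonal(S, 1.0)
    total = n_clipped + diag_bad
    if total:
        warnings.warn(f"{path}: clipped {total} similarity entries", stacklevel=2)
    return PhenotypeSimMatrix(
        phenotypes=[str(p) for p in df.index], sims=S, n_clipped=total
    )


def write_phenotype_sim(matrix: PhenotypeSimMatrix, path) -> None:
    df = pd.DataFrame(matrix.sims, index=matrix.phenotypes, columns=matrix.phenotypes)
    df.to_csv(path, sep="\t", index_label="phenotype")


# ---------------------------------------------------------------------------
# gene lists and reports


def read_gene_list(path) -> list[str]:
    """One gene identifier per line, order preserved, duplicates rejected."""
    genes: list[str] = []
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        gene = _check_gene_id(line, path, lineno)
        if gene in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate gene {gene!r}")
        seen.add(gene)
        genes.append(gene)
    return genes


def write_gene_list(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_report(path, report: Mapping) -> None:
    """Serialize a run report as JSON with stable key order."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_report(path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# bundles

BUNDLE_FILES = {
    "ppi": "ppi_edges.tsv",
    "expression": "expression.tsv",
    "ontology": "ontology.obo",
    "go_annotations": "go_annotations.tsv",
    "domains": "domain_annotations.tsv",
    "pheno_assoc": "phenotype_genes.tsv",
    "pheno_sim": "phenotype_similarity.tsv",
    "positives": "positives.txt",
    "truth": "truth.tsv",
}


@dataclass
class DataBundle:
    """Everything the pipeline consumes, already validated.

    ``genes`` is the analysis universe (the expression table's row order,
    extended with any genes seen only in other sources).
    """

    genes: list[str]
    ppi_edges: EdgeList
    expression: ExpressionTable
    dags: dict[str, OntologyDAG]
    go_annots: AnnotationTable
    domain_annots: AnnotationTable
    pheno_assoc: PhenotypeAssoc
    pheno_sims: PhenotypeSimMatrix
    positives: list[str]


def load_bundle(directory) -> DataBundle:
    """Load a bundle directory written by :func:`epu.synthetic.write_bundle`
    (or assembled by hand in the same layout).  Ground-truth labels, if
    present, are deliberately not loaded here."""
    d = Path(directory)
    expression = read_expression(d / BUNDLE_FILES["expression"])
    ppi = read_edge_list(d / BUNDLE_FILES["ppi"])
    dags = read_ontology(d / BUNDLE_FILES["ontology"])
    go_annots = read_annotations(d / BUNDLE_FILES["go_annotations"], ontology=dags)
    domains = read_annotations(d / BUNDLE_FILES["domains"])
    assoc = read_phenotype_assoc(d / BUNDLE_FILES["pheno_assoc"])
    sims = read_phenotype_sim(d / BUNDLE_FILES["pheno_sim"])
    positives = read_gene_list(d / BUNDLE_FILES["positives"])
    genes = list(expression.genes)
    known = set(genes)
    extra = (ppi.nodes() | go_annots.genes | domains.genes | assoc.genes | set(positives)) - known
    genes.extend(sorted(extra))
    missing_ph = {ph for phs in assoc.gene_to_phenos.values() for ph in phs} - set(sims.phenotypes)
    if missing_ph:
        raise ValidationError(f"phenotypes without similarity entries: {sorted(missing_ph)[:5]}")
    return DataBundle(
        genes=genes,
        ppi_edges=ppi,
        expression=expression,
        dags=dags,
        go_annots=go_annots,
        domain_annots=domains,
        pheno_assoc=assoc,
        pheno_sims=sims,
        positives=positives,
    )
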