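"""End-to-end experimental protocol and metrics.

The protocol mirrors the published evaluation design: for a disease with
positive set P, several unlabeled groups U with |U| = |P| are sampled;
each (P + U) sample is split into 3 outer folds; on the two training
folds the full pipeline runs (candidate-positive / reliable-negative
seeding, random-walk propagation on the three networks, integrated
scores, the three weighted base classifiers) and the base classifiers'
soft labels — obtained by leave-one-out (or inner k-fold) refitting on
the training folds — feed the gradient-descent ensemble combiner.  The
held-out fold is then predicted and precision / recall / F-measure
recorded per model.  Macro averages are per-run means of p, r and F.

A leakage audit is built in: an assertion verifies on every fold that no
test gene enters seeding, propagation seeds, any classifier pool or the
ensemble training set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .config import EPUConfig
from .data_io import DataBundle
from .ensemble import EnsembleWeights, MarginMatrix, train_weights
from .exceptions import ValidationError
from .gene_features import (
    NAMESPACES,
    GeneFeatureMatrix,
    positive_representative,
    rank_feature_scores,
)
from .network_builder import (
    GeneNetwork,
    TransitionMatrix,
    build_expression_network,
    build_go_network,
    build_ppi_network,
    filter_phenotype_network,
    to_transition,
)
from .propagation import integrate_scores, rwr
from .pu_classifiers import (
    LevelPartition,
    MultiLevelSVM,
    WeightedKNN,
    WeightedNaiveBayes,
    msvm_training_arrays,
    partition_levels,
    wnb_pools,
)
from .pu_seeding import (
    SeedScores,
    extract_candidate_positives,
    extract_reliable_negatives,
    init_seed_scores,
)

logger = logging.getLogger("epu")

MODELS = ("WKNN", "WNB", "MSVM", "EPU")


def f_measure(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not 0.0 <= p <= 1.0 or not 0.0 <= r <= 1.0:
        raise ValidationError(f"precision/recall out of [0,1]: p={p}, r={r}")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def sample_unlabeled(
    universe: Iterable[str],
    P: Iterable[str],
    n_groups: int,
    seed: int,
    size: int | None = None,
) -> list[list[str]]:
    """n_groups independent uniform samples of unlabeled genes.

    Each group has |P| genes (or ``size``), drawn without replacement from
    ``universe`` minus P, seeded deterministically per group.
    """
    P = set(P)
    avail = sorted(set(universe) - P)
    size = len(P) if size is None else size
    if size > len(avail):
        raise ValidationError(f"cannot draw {size} unlabeled genes from {len(avail)}")
    groups = []
    for g in range(n_groups):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(g,)))
        groups.append(sorted(rng.choice(avail, size=size, replace=False)))
    return groups


@dataclass
class ExperimentPlan:
    """Sampling/fold design of one evaluation run."""

    n_u_groups: int = 10
    n_folds: int = 3
    inner_folds: int = 0  # 0 = leave-one-out soft labels
    seed: int = 0


@dataclass
class FoldArtifacts:
    """Everything the classifiers need for one training fold."""

    P: list[str]
    U: list[str]
    CP: set[str]
    cp_scores: dict[str, float]
    RN: set[str]
    U_rest: list[str]
    seeds: SeedScores
    int_score: dict[str, float]
    levels: LevelPartition
    features: GeneFeatureMatrix
    propagation_converged: bool


class Pipeline:
    """Holds a data bundle plus everything reusable across folds
    (unsupervised networks, annotation-derived feature values)."""

    def __init__(self, data: DataBundle, config: EPUConfig | None = None):
        self.data = data
        self.config = config or EPUConfig()
        cfg = self.config
        self.ppi_net: GeneNetwork = build_ppi_network(data.ppi_edges)
        self.ge_net: GeneNetwork = build_expression_network(
            data.expression, k=cfg.network.k_neighbors
        )
        self.ppi_T: TransitionMatrix = to_transition(self.ppi_net, cfg.network.use_abs_weights)
        self.ge_T: TransitionMatrix = to_transition(self.ge_net, cfg.network.use_abs_weights)
        self.filtered_sims = filter_phenotype_network(
            data.pheno_sims, cfg.network.logistic_c, cfg.network.logistic_d
        )
        # per-namespace candidate anchor terms and gene x term value blocks
        from .gene_features import go_feature_block

        self.candidates: dict[str, list[str]] = {}
        self.go_values: dict[str, np.ndarray] = {}
        for ns in NAMESPACES:
            dag = data.dags.get(ns)
            if dag is None:
                raise ValidationError(f"bundle lacks {ns} ontology")
            terms = sorted(dag.terms)
            self.candidates[ns] = terms
            self.go_values[ns] = go_feature_block(data.genes, terms, data.go_annots, dag)
        logger.info(
            "pipeline ready: %d genes, PPI %d nodes/%d edges, GE %d nodes",
            len(data.genes),
            self.ppi_net.n_nodes,
            self.ppi_net.W.nnz // 2,
            self.ge_net.n_nodes,
        )

    # -- per-fold stages ----------------------------------------------------

    def select_features(self, P: Sequence[str], U: Sequence[str]) -> GeneFeatureMatrix:
        """Class-aware GO feature selection + fixed domain/topology blocks."""
        cfg = self.config
        gidx = {g: i for i, g in enumerate(self.data.genes)}
        selected: dict[str, list[str]] = {}
        go_blocks: dict[str, np.ndarray] = {}
        p_rows = [gidx[g] for g in P]
        u_rows = [gidx[g] for g in U]
        for ns in NAMESPACES:
            vals = self.go_values[ns]
            score = np.abs(vals[p_rows].mean(axis=0) - vals[u_rows].mean(axis=0))
            chosen = rank_feature_scores(self.candidates[ns], score, cfg.features.n_go_features)
            selected[ns] = chosen
            cols = [self.candidates[ns].index(t) for t in chosen]
            go_blocks[ns] = vals[:, cols]
        # assemble without recomputing the Wang values
        from .gene_features import TOPO_STATS, domain_feature_block, topology_features

        dom_block, domains = domain_feature_block(self.data.genes, self.data.domain_annots)
        topo = topology_features(self.data.genes, self.ppi_net)
        kinds: list[str] = []
        names: list[str] = []
        blocks = []
        for ns in NAMESPACES:
            blocks.append(go_blocks[ns])
            kinds.extend([ns] * len(selected[ns]))
            names.extend(selected[ns])
        blocks.append(dom_block)
        kinds.extend(["DOMAIN"] * len(domains))
        names.extend(domains)
        blocks.append(topo)
        kinds.extend(["TOPO"] * len(TOPO_STATS))
        names.extend(TOPO_STATS)
        return GeneFeatureMatrix(
            genes=list(self.data.genes), kinds=kinds, names=names, V=np.hstack(blocks)
        )

    def fold_artifacts(
        self,
        P_train: Sequence[str],
        U_train: Sequence[str],
        exclude_from_seeding: Iterable[str] = (),
    ) -> FoldArtifacts:
        """Seeding, propagation and stratification for one training fold.

        ``exclude_from_seeding`` lists genes (the full evaluation sample,
        including held-out folds) that must not become candidate-positive
        seeds.
        """
        cfg = self.config
        P_train = sorted(P_train)
        U_train = sorted(U_train)
        features = self.select_features(P_train, U_train)
        go_net = build_go_network(features, k=cfg.network.k_neighbors)
        go_T = to_transition(go_net, cfg.network.use_abs_weights)

        pr = positive_representative(P_train, features)
        RN = extract_reliable_negatives(U_train, pr, features)
        CP, cp_scores = extract_candidate_positives(
            P_train,
            self.data.pheno_assoc,
            self.filtered_sims,
            exclude=set(exclude_from_seeding) | set(U_train),
        )
        seeds = init_seed_scores(
            P_train, CP, cp_scores, RN, balance_include_cp=cfg.seed.balance_include_cp
        )
        prop = cfg.propagation
        results = [
            rwr(T, seeds, alpha=prop.alpha, tol=prop.tol, max_iter=prop.max_iter)
            for T in (self.ppi_T, go_T, self.ge_T)
        ]
        int_score = integrate_scores(*results, mean_over_present=prop.mean_over_present)
        U_rest = sorted(set(U_train) - RN)
        levels = partition_levels(U_rest, int_score)
        logger.info(
            "fold artifacts: |P|=%d |U|=%d |CP|=%d |RN|=%d |LP|=%d |LN|=%d |WN|=%d seed_sum=%.2e",
            len(P_train),
            len(U_train),
            len(CP),
            len(RN),
            len(levels.LP),
            len(levels.LN),
            len(levels.WN),
            seeds.total(),
        )
        return FoldArtifacts(
            P=P_train,
            U=U_train,
            CP=CP,
            cp_scores=cp_scores,
            RN=RN,
            U_rest=U_rest,
            seeds=seeds,
            int_score=int_score,
            levels=levels,
            features=features,
            propagation_converged=all(r.converged for r in results),
        )

    def fit_base_models(
        self, art: FoldArtifacts, holdout: Iterable[str] = (), svm_seed: int = 0
    ) -> dict[str, object]:
        """Fit WKNN / WNB / MSVM on the training fold minus ``holdout``."""
        cfg = self.config
        held = set(holdout)
        P = [g for g in art.P if g not in held]
        RN = sorted(g for g in art.RN if g not in held)
        U_rest = [g for g in art.U_rest if g not in held]
        V = art.features
        scores = art.int_score

        # WKNN pool = P u RN u U'; every pool gene carries its converged
        # integrated score (P positive, RN negative by construction)
        pool_ids = sorted(set(P) | set(RN) | set(U_rest))
        pool_scores = np.array([scores.get(g, 0.0) for g in pool_ids])
        wknn = WeightedKNN(k=cfg.knn.k).fit(pool_ids, V.rows(pool_ids), pool_scores)

        pos_ids, pos_w, neg_ids, neg_w = wnb_pools(P, RN, U_rest, scores)
        wnb = WeightedNaiveBayes(laplace=cfg.nb.laplace).fit(
            V.rows(pos_ids), np.asarray(pos_w), V.rows(neg_ids), np.asarray(neg_w)
        )

        lv = art.levels
        lv_held = LevelPartition(
            LP=frozenset(lv.LP - held),
            LN=frozenset(lv.LN - held),
            WN=frozenset(lv.WN - held),
            mu_pos=lv.mu_pos,
            mu_neg=lv.mu_neg,
        )
        _, X, y, w = msvm_training_arrays(
            P, RN, lv_held, features=V, level_multipliers=cfg.svm.level_multipliers
        )
        msvm = MultiLevelSVM(
            cost_grid=cfg.svm.cost_grid,
            kernel=cfg.svm.kernel,
            cv_folds=cfg.svm.cv_folds,
            random_state=svm_seed,
        ).fit(X, y, w)
        return {"WKNN": wknn, "WNB": wnb, "MSVM": msvm}

    def margins(self, models: Mapping[str, object], genes: Sequence[str], V: GeneFeatureMatrix) -> np.ndarray:
        """|genes| x 3 margin rows (p_pos - p_neg per base model)."""
        X = V.rows(genes)
        cols = []
        for name in ("WKNN", "WNB", "MSVM"):
            post = models[name].posteriors(X)  # type: ignore[attr-defined]
            cols.append(post[:, 0] - post[:, 1])
        return np.column_stack(cols)

    def soft_label_matrix(
        self,
        art: FoldArtifacts,
        labels: Mapping[str, int],
        inner_folds: int = 0,
        seed: int = 0,
    ) -> MarginMatrix:
        """Held-out margins for every training gene.

        With ``inner_folds=0`` each gene is left out in turn (LOOCV);
        otherwise the training genes are split into k shuffled inner
        folds and each fold's margins come from models fitted on the
        rest.  Either way no gene's own margin row is produced by a model
        that saw it.
        """
        D = sorted(set(art.P) | set(art.U))
        rng = np.random.default_rng(seed)
        if inner_folds <= 0:
            parts = [[g] for g in D]
        else:
            perm = list(np.asarray(D)[rng.permutation(len(D))])
            parts = [perm[i::inner_folds] for i in range(inner_folds)]
        M = np.zeros((len(D), 3))
        pos_of = {g: i for i, g in enumerate(D)}
        for part in parts:
            if not part:
                continue
            models = self.fit_base_models(art, holdout=part, svm_seed=seed)
            rows = self.margins(models, part, art.features)
            for g, row in zip(part, rows):
                M[pos_of[g]] = row
        y = np.array([labels[g] for g in D], dtype=float)
        return MarginMatrix(genes=D, M=M, y=y)

    # -- full protocol -------------------------------------------------------

    def evaluate_fold(
        self,
        P_train: Sequence[str],
        U_train: Sequence[str],
        test_P: Sequence[str],
        test_U: Sequence[str],
        sample_genes: Iterable[str],
        inner_folds: int,
        seed: int,
    ) -> tuple[dict[str, dict[str, float]], EnsembleWeights]:
        """Train on one fold pair, predict the held-out fold, audit leakage."""
        test = sorted(set(test_P) | set(test_U))
        art = self.fold_artifacts(P_train, U_train, exclude_from_seeding=sample_genes)
        _assert_no_leakage(art, test)
        labels = {g: 1 for g in P_train}
        labels.update({g: -1 for g in U_train})
        margin = self.soft_label_matrix(art, labels, inner_folds=inner_folds, seed=seed)
        assert not (set(margin.genes) & set(test))
        ew = train_weights(
            margin,
            eta0=self.config.ensemble.eta0,
            tol=self.config.ensemble.tol,
            max_iter=self.config.ensemble.max_iter,
            seed=seed,
            decay_halflife=self.config.ensemble.decay_halflife,
        )
        models = self.fit_base_models(art, svm_seed=seed)
        M_test = self.margins(models, test, art.features)
        is_pos = np.array([g in set(test_P) for g in test])
        metrics: dict[str, dict[str, float]] = {}
        for j, name in enumerate(("WKNN", "WNB", "MSVM")):
            pred = M_test[:, j] > 0
            metrics[name] = _prf(pred, is_pos)
        epu_pred = (M_test @ ew.a) > 0
        metrics["EPU"] = _prf(epu_pred, is_pos)
        return metrics, ew


@dataclass
class EvalReport:
    """Per-fold rows and macro-averaged metrics per model."""

    rows: list[dict] = field(default_factory=list)
    macro: dict[str, dict[str, float]] = field(default_factory=dict)
    plan: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)
    leakage_checked: bool = False

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "macro": self.macro,
            "plan": self.plan,
            "config": self.config,
            "counts": self.counts,
            "leakage_checked": self.leakage_checked,
        }


def _prf(pred_pos: np.ndarray, is_pos: np.ndarray) -> dict[str, float]:
    tp = int(np.sum(pred_pos & is_pos))
    fp = int(np.sum(pred_pos & ~is_pos))
    fn = int(np.sum(~pred_pos & is_pos))
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    return {"precision": p, "recall": r, "f": f_measure(p, r)}


def _assert_no_leakage(art: FoldArtifacts, test: Sequence[str]) -> None:
    """Test genes must not appear in any training-stage gene set."""
    test_set = set(test)
    stages = {
        "P": set(art.P),
        "U": set(art.U),
        "CP": set(art.CP),
        "RN": set(art.RN),
        "LP": set(art.levels.LP),
        "LN": set(art.levels.LN),
        "WN": set(art.levels.WN),
        "seeds": {g for g, s in art.seeds.scores.items() if s != 0.0},
    }
    for stage, genes in stages.items():
        leaked = test_set & genes
        assert not leaked, f"leakage: test genes {sorted(leaked)[:3]} found in stage {stage}"


def _stratified_folds(
    P: Sequence[str], U: Sequence[str], n_folds: int, rng: np.random.Generator
) -> list[tuple[list[str], list[str]]]:
    """Split P and U separately into n shuffled folds; fold i pairs the
    i-th part of each."""
    P_perm = list(np.asarray(sorted(P))[rng.permutation(len(P))])
    U_perm = list(np.asarray(sorted(U))[rng.permutation(len(U))])
    return [(P_perm[i::n_folds], U_perm[i::n_folds]) for i in range(n_folds)]


def run_experiment(
    data: DataBundle, plan: ExperimentPlan | None = None, config: EPUConfig | None = None
) -> EvalReport:
    """Full cross-validated protocol over resampled unlabeled groups."""
    plan = plan or ExperimentPlan()
    config = config or EPUConfig()
    pipeline = Pipeline(data, config)
    P = sorted(data.positives)
    if not P:
        raise ValidationError("bundle has no positive genes")
    groups = sample_unlabeled(data.genes, P, plan.n_u_groups, plan.seed)
    report = EvalReport(
        plan={
            "n_u_groups": plan.n_u_groups,
            "n_folds": plan.n_folds,
            "inner_folds": plan.inner_folds,
            "seed": plan.seed,
        },
        config=config.to_dict(),
    )
    leakage_ok = True
    for gi, U in enumerate(groups):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=plan.seed, spawn_key=(1000 + gi,)))
        folds = _stratified_folds(P, U, plan.n_folds, rng)
        sample_genes = set(P) | set(U)
        for fi in range(plan.n_folds):
            test_P, test_U = folds[fi]
            train_P = [g for j in range(plan.n_folds) if j != fi for g in folds[j][0]]
            train_U = [g for j in range(plan.n_folds) if j != fi for g in folds[j][1]]
            fold_seed = int(
                np.random.SeedSequence(entropy=plan.seed, spawn_key=(gi, fi)).generate_state(1)[0]
                % (2**31)
            )
            try:
                metrics, ew = pipeline.evaluate_fold(
                    train_P,
                    train_U,
                    test_P,
                    test_U,
                    sample_genes,
                    inner_folds=plan.inner_folds,
                    seed=fold_seed,
                )
            except AssertionError:
                leakage_ok = False
                raise
            for model, m in metrics.items():
                report.rows.append(
                    {
                        "group": gi,
                        "fold": fi,
                        "model": model,
                        "precision": m["precision"],
                        "recall": m["recall"],
                        "f": m["f"],
                        "ensemble_converged": bool(ew.converged),
                    }
                )
            logger.info(
                "group %d fold %d: %s",
                gi,
                fi,
                {k: round(v["f"], 3) for k, v in metrics.items()},
            )
    for model in MODELS:
        rows = [r for r in report.rows if r["model"] == model]
        report.macro[model] = {
            "precision": float(np.mean([r["precision"] for r in rows])),
            "recall": float(np.mean([r["recall"] for r in rows])),
            "f": float(np.mean([r["f"] for r in rows])),
        }
    report.counts = {"n_positives": len(P), "n_groups": len(groups)}
    report.leakage_checked = leakage_ok
    return report


def rank_unlabeled(
    data: DataBundle,
    config: EPUConfig | None = None,
    seed: int = 0,
    inner_folds: int = 5,
) -> list[tuple[str, float]]:
    """Prioritize every unlabeled gene by ensemble score.

    Trains on the full declared positive list plus one sampled unlabeled
    group, then scores the whole unlabeled universe (universe minus
    declared positives), descending.
    """
    config = config or EPUConfig()
    pipeline = Pipeline(data, config)
    P = sorted(data.positives)
    U = sample_unlabeled(data.genes, P, 1, seed)[0]
    art = pipeline.fold_artifacts(P, U, exclude_from_seeding=set(P) | set(U))
    labels = {g: 1 for g in P}
    labels.update({g: -1 for g in U})
    margin = pipeline.soft_label_matrix(art, labels, inner_folds=inner_folds, seed=seed)
    ew = train_weights(
        margin,
        eta0=config.ensemble.eta0,
        tol=config.ensemble.tol,
        max_iter=config.ensemble.max_iter,
        seed=seed,
        decay_halflife=config.ensemble.decay_halflife,
    )
    models = pipeline.fit_base_models(art, svm_seed=seed)
    unlabeled = [g for g in data.genes if g not in set(P)]
    M = pipeline.margins(models, unlabeled, art.features)
    scores = M @ ew.a
    order = np.lexsort((np.asarray(unlabeled), -scores))
    return [(unlabeled[i], float(scores[i])) for i in order]
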