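"""Wang semantic similarity, feature construction and GO feature selection."""

import numpy as np
import pytest

from epu import gene_features as gf
from epu.data_io import EdgeList
from epu.exceptions import ValidationError
from epu.network_builder import build_ppi_network

from conftest import make_dag, random_dag


def s_values_oracle(dag, term):
    """Independent S-value computation by fixpoint relaxation (no
    topological sort): repeatedly propagate w * S(child) upward taking
    the max until nothing changes."""
    import networkx as nx

    closure = {term} | nx.descendants(dag.graph, term)
    s = {term: 1.0}
    changed = True
    while changed:
        changed = False
        for child, parent, data in dag.graph.edges(data=True):
            if child in s and parent in closure:
                v = data["weight"] * s[child]
                if v > s.get(parent, 0.0) + 1e-15:
                    s[parent] = v
                    changed = True
    for t in closure:
        s.setdefault(t, 0.0)
    return s


def wang_oracle(a, b, dag):
    sa, sb = s_values_oracle(dag, a), s_values_oracle(dag, b)
    common = sa.keys() & sb.keys()
    if not common:
        return 0.0
    return sum(sa[t] + sb[t] for t in common) / (sum(sa.values()) + sum(sb.values()))


class TestWangSimilarity:
    def test_self_similarity_is_one(self):
        dag = make_dag("BP", [("B", "A", "is_a")])
        assert gf.wang_term_similarity("B", "B", dag) == 1.0

    def test_three_term_hand_recursion(self):
        """A and B are both is_a children of root R: each has SV = 1 + 0.8
        and shares only {R}, so sim = (0.8 + 0.8) / (1.8 + 1.8)."""
        dag = make_dag("BP", [("A", "R", "is_a"), ("B", "R", "is_a")])
        assert gf.wang_term_similarity("A", "B", dag) == pytest.approx(1.6 / 3.6)

    def test_disjoint_ancestries_score_zero(self):
        dag = make_dag("BP", [("A", "R1", "is_a"), ("B", "R2", "is_a")])
        assert gf.wang_term_similarity("A", "B", dag) == 0.0

    def test_part_of_edges_use_smaller_factor(self):
        dag = make_dag("BP", [("A", "R", "part_of"), ("B", "R", "part_of")])
        # SV = 1 + 0.6 each, shared contribution 0.6 + 0.6
        assert gf.wang_term_similarity("A", "B", dag) == pytest.approx(1.2 / 3.2)

    def test_unknown_term_rejected(self):
        dag = make_dag("BP", [("B", "A", "is_a")])
        with pytest.raises(ValidationError):
            gf.wang_term_similarity("B", "NOPE", dag)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_relaxation_oracle_on_random_dags(self, seed):
        dag = random_dag(seed)
        terms = sorted(dag.terms)
        rng = np.random.default_rng(seed)
        for _ in range(30):
            a, b = (terms[i] for i in rng.integers(len(terms), size=2))
            assert gf.wang_term_similarity(a, b, dag) == pytest.approx(
                wang_oracle(a, b, dag), abs=1e-12
            )

    @pytest.mark.parametrize("seed", range(3))
    def test_symmetric_unit_diagonal_bounded(self, seed):
        dag = random_dag(seed, n_terms=15)
        terms = sorted(dag.terms)
        M = gf.term_similarity_matrix(terms, terms, dag)
        np.testing.assert_allclose(M, M.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(M), 1.0)
        assert M.min() >= 0.0 and M.max() <= 1.0 + 1e-12


class TestGeneFeatureValue:
    dag = make_dag("BP", [("A", "R", "is_a"), ("B", "R", "is_a"), ("C", "B", "is_a")])

    def test_annotation_with_feature_term_itself(self):
        annots = gf.MappingAnnotations({"g": {"A"}})
        assert gf.gene_feature_value("g", "A", annots, self.dag) == 1.0

    def test_unannotated_gene_scores_zero(self):
        annots = gf.MappingAnnotations({})
        assert gf.gene_feature_value("g", "A", annots, self.dag) == 0.0

    def test_max_over_annotated_terms_matches_brute_force(self):
        annots = gf.MappingAnnotations({"g": {"A", "C"}})
        got = gf.gene_feature_value("g", "B", annots, self.dag)
        expected = max(
            gf.wang_term_similarity(t, "B", self.dag) for t in ("A", "C")
        )
        assert got == pytest.approx(expected)


class TestSelectGoFeatures:
    def test_perfect_separator_ranked_first(self):
        dag = make_dag("BP", [("A", "R", "is_a"), ("B", "R", "is_a")])
        annots = gf.MappingAnnotations({"p1": {"A"}, "p2": {"A"}, "u1": set(), "u2": set()})
        chosen = gf.select_go_features(["p1", "p2"], ["u1", "u2"], ["A", "B", "R"], annots, dag, n=3)
        assert chosen[0] == "A"

    def test_ranking_matches_exhaustive_oracle(self):
        dag = random_dag(7, n_terms=20)
        terms = sorted(dag.terms)
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(12)]
        annots = gf.MappingAnnotations(
            {g: set(np.asarray(terms)[rng.integers(len(terms), size=2)]) for g in genes}
        )
        P, U = genes[:6], genes[6:]
        got = gf.select_go_features(P, U, terms, annots, dag, n=5)
        scores = {
            t: abs(
                np.mean([gf.gene_feature_value(g, t, annots, dag) for g in P])
                - np.mean([gf.gene_feature_value(g, t, annots, dag) for g in U])
            )
            for t in terms
        }
        expected = sorted(terms, key=lambda t: (-scores[t], t))[:5]
        assert got == expected

    def test_invariant_to_set_order(self):
        dag = make_dag("BP", [("A", "R", "is_a"), ("B", "R", "is_a")])
        annots = gf.MappingAnnotations({"p1": {"A"}, "p2": {"B"}, "u1": {"R"}})
        a = gf.select_go_features(["p1", "p2"], ["u1"], ["A", "B"], annots, dag, n=2)
        b = gf.select_go_features(["p2", "p1"], ["u1"], ["B", "A"], annots, dag, n=2)
        assert a == b

    def test_overlapping_classes_rejected(self):
        dag = make_dag("BP", [("A", "R", "is_a")])
        with pytest.raises(ValidationError):
            gf.select_go_features(["g"], ["g"], ["A"], gf.MappingAnnotations({}), dag)


class TestTopologyFeatures:
    def test_isolated_gene_prescale_signature(self):
        ppi = build_ppi_network(EdgeList(edges={("A", "B"): 1.0}), nodes=["A", "B", "C"])
        raw = gf.topology_features(["A", "B", "C"], ppi, scale=False)
        np.testing.assert_allclose(raw[2], [0.0, 0.0, 0.0, 1.0])

    def test_triangle_member_clustering_one(self):
        ppi = build_ppi_network(
            EdgeList(edges={("A", "B"): 1.0, ("B", "C"): 1.0, ("A", "C"): 1.0})
        )
        raw = gf.topology_features(["A", "B", "C"], ppi, scale=False)
        np.testing.assert_allclose(raw[:, 2], 1.0)

    def test_degree_column_equals_row_sums(self):
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(10)]
        edges = {}
        for i in range(10):
            for j in range(i + 1, 10):
                if rng.random() < 0.3:
                    edges[(genes[i], genes[j])] = 1.0
        ppi = build_ppi_network(EdgeList(edges=edges), nodes=genes)
        raw = gf.topology_features(genes, ppi, scale=False)
        np.testing.assert_allclose(raw[:, 0], np.asarray(ppi.W.sum(axis=1)).ravel())

    def test_scaled_columns_in_unit_interval(self):
        ppi = build_ppi_network(EdgeList(edges={("A", "B"): 1.0}), nodes=["A", "B", "C"])
        scaled = gf.topology_features(["A", "B", "C"], ppi)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0


class TestPositiveRepresentative:
    def _fm(self, genes, V):
        V = np.asarray(V, dtype=float)
        return gf.GeneFeatureMatrix(
            genes=list(genes), kinds=["MF"] * V.shape[1],
            names=[f"f{i}" for i in range(V.shape[1])], V=V,
        )

    def test_singleton_returns_gene_vector(self):
        fm = self._fm(["g"], [[0.3, 0.7]])
        np.testing.assert_allclose(gf.positive_representative(["g"], fm), [0.3, 0.7])

    def test_mean_of_two_genes(self):
        fm = self._fm(["a", "b"], [[1, 0], [0, 1]])
        np.testing.assert_allclose(gf.positive_representative(["a", "b"], fm), [0.5, 0.5])

    def test_order_invariant(self):
        fm = self._fm(["a", "b", "c"], [[1, 0], [0, 1], [0.5, 0.5]])
        pr1 = gf.positive_representative(["a", "b", "c"], fm)
        pr2 = gf.positive_representative(["c", "a", "b"], fm)
        np.testing.assert_allclose(pr1, pr2)

    def test_empty_set_rejected(self):
        fm = self._fm(["a"], [[1.0]])
        with pytest.raises(ValidationError):
            gf.positive_representative([], fm)


class TestFeatureMatrixAssembly:
    def test_block_order_and_ranges(self, small_bundle):
        data = small_bundle.data_bundle()
        ppi = build_ppi_network(data.ppi_edges)
        selected = {ns: sorted(data.dags[ns].terms)[:5] for ns in gf.NAMESPACES}
        fm = gf.build_feature_matrix(
            data.genes, data.dags, data.go_annots, selected, data.domain_annots, ppi
        )
        kinds = fm.kinds
        # declared column order MF | BP | CC | DOMAIN | TOPO
        boundaries = [kinds.index(k) for k in ("MF", "BP", "CC", "DOMAIN", "TOPO")]
        assert boundaries == sorted(boundaries)
        assert fm.block("MF", "BP", "CC").min() >= 0.0
        assert fm.block("MF", "BP", "CC").max() <= 1.0
        assert set(np.unique(fm.block("DOMAIN"))) <= {0.0, 1.0}
        assert fm.block("TOPO").shape[1] == 4
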