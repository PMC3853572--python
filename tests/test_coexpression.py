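"""PCC/Mutual-Rank computation, network construction, modules, recruitment."""

import networkx as nx
import numpy as np
import pytest

from floralnet.coexpression import (
    annotate_module,
    build_network,
    edge_class_of,
    extract_modules,
    FunctionModule,
    mutual_rank,
    pcc_matrix,
    recruit_candidates,
)
from floralnet.differential import FilterMode, NormalizedMatrix, filter_detected, normalize
from floralnet.io import CoreGeneList, GoAnnotationTable

from oracles import mutual_rank_bruteforce


def _nm(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return NormalizedMatrix(genes, [f"S{j + 1}" for j in range(values.shape[1])],
                            values)


class TestPcc:
    def test_unit_diagonal_symmetry_and_range(self):
        rng = np.random.default_rng(1)
        _, pcc = pcc_matrix(_nm(rng.normal(size=(15, 8))))
        np.testing.assert_allclose(np.diag(pcc), 1.0)
        np.testing.assert_allclose(pcc, pcc.T)
        assert pcc.min() >= -1.0 and pcc.max() <= 1.0

    def test_negation_and_scaling(self):
        base = np.arange(1.0, 9.0)
        values = np.vstack([base, -base + 3.0, 2.0 * base])
        _, pcc = pcc_matrix(_nm(values))
        assert pcc[0, 1] == pytest.approx(-1.0)
        assert pcc[0, 2] == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        values = np.vstack([np.arange(8.0), np.ones(8)])
        with pytest.raises(ValueError, match="zero-variance"):
            pcc_matrix(_nm(values))


class TestMutualRank:
    def test_reciprocal_top_partners_mr_one(self):
        base = np.arange(8.0)
        rng = np.random.default_rng(0)
        values = np.vstack([base, base + rng.normal(0, 0.01, 8),
                            rng.normal(size=8), rng.normal(size=8)])
        _, pcc = pcc_matrix(_nm(values))
        mr = mutual_rank(pcc)
        assert mr[0, 1] == pytest.approx(1.0)

    def test_rank_arithmetic(self):
        # hand-built 3x3: check sqrt(R_ab * R_ba) directly
        pcc = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.5], [0.2, 0.5, 1.0]])
        mr = mutual_rank(pcc)
        # g0: partners ranked g1 (0.9) then g2 (0.2); g1: g0 then g2
        assert mr[0, 1] == pytest.approx(1.0)
        assert mr[0, 2] == pytest.approx(np.sqrt(2 * 2))
        assert mr[1, 2] == pytest.approx(np.sqrt(2 * 1))

    def test_matches_bruteforce_oracle_exactly(self):
        """Vectorized MR equals an independent double-loop on seeded
        random matrices of 20–50 genes, elementwise exactly."""
        rng = np.random.default_rng(123)
        for trial in range(20):
            n = int(rng.integers(20, 51))
            values = rng.normal(size=(n, 8))
            _, pcc = pcc_matrix(_nm(values))
            mr = mutual_rank(pcc)
            oracle = np.array(mutual_rank_bruteforce(pcc.tolist()))
            np.testing.assert_array_equal(mr, oracle)

    def test_tied_pccs_get_mean_ranks(self):
        # g1 and g2 are identical profiles → tie for rank 1 from g0
        pcc = np.array(
            [[1.0, 0.8, 0.8, 0.1],
             [0.8, 1.0, 1.0, 0.2],
             [0.8, 1.0, 1.0, 0.2],
             [0.1, 0.2, 0.2, 1.0]]
        )
        mr = mutual_rank(pcc)
        oracle = np.array(mutual_rank_bruteforce(pcc.tolist()))
        np.testing.assert_array_equal(mr, oracle)
        # from g0 the tie spans positions 1 and 2 → mean rank 1.5 both ways? no:
        # R(0→1) = 1.5 and R(1→0) = 2 (g1's best partner is its twin g2)
        assert mr[0, 1] == pytest.approx(np.sqrt(1.5 * 2.0))

    def test_symmetry_and_floor(self):
        rng = np.random.default_rng(7)
        _, pcc = pcc_matrix(_nm(rng.normal(size=(30, 8))))
        mr = mutual_rank(pcc)
        np.testing.assert_allclose(mr, mr.T)
        off = mr[~np.eye(30, dtype=bool)]
        assert off.min() >= 1.0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="n ≥ 2"):
            mutual_rank(np.array([[1.0]]))


class TestNetwork:
    def _small(self):
        rng = np.random.default_rng(5)
        base = np.sin(np.linspace(0, 3, 8))
        rows = [base + rng.normal(0, 0.05, 8) for _ in range(4)]
        rows += [rng.normal(size=8) for _ in range(16)]
        genes = [f"g{i}" for i in range(20)]
        nm = _nm(np.vstack(rows), genes)
        order, pcc = pcc_matrix(nm)
        return order, pcc, mutual_rank(pcc)

    @pytest.mark.parametrize(
        "mr, expected",
        [(1.0, "bold"), (5.0, "bold"), (5.1, "normal"), (30.0, "normal"),
         (30.5, "thin"), (50.0, "thin")],
    )
    def test_edge_classes(self, mr, expected):
        assert edge_class_of(mr) == expected

    def test_edges_only_touch_cores_and_cut_applies(self):
        order, pcc, mr = self._small()
        core = CoreGeneList(genes=["g0", "g1"])
        g = build_network(order, mr, pcc, core, mr_cut=50.0)
        core_set = {"g0", "g1"}
        for a, b, d in g.edges(data=True):
            assert a in core_set or b in core_set
            assert d["mr"] <= 50.0
            assert d["edge_class"] == edge_class_of(d["mr"])

    def test_mr_above_cut_excluded(self):
        order, pcc, mr = self._small()
        core = CoreGeneList(genes=["g0"])
        g = build_network(order, mr, pcc, core, mr_cut=5.0)
        assert all(d["mr"] <= 5.0 for _, _, d in g.edges(data=True))

    def test_missing_core_rejected(self):
        order, pcc, mr = self._small()
        with pytest.raises(ValueError, match="no core gene"):
            build_network(order, mr, pcc, CoreGeneList(genes=["nope"]))

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(11)
        values = rng.normal(size=(25, 8))
        genes = [f"g{i}" for i in range(25)]
        nm = _nm(values, genes)
        core = CoreGeneList(genes=["g3", "g7"])

        def edges_of(nm_):
            order, pcc = pcc_matrix(nm_)
            g = build_network(order, mutual_rank(pcc), pcc, core)
            return {
                frozenset((a, b)): (round(d["pcc"], 10), round(d["mr"], 10))
                for a, b, d in g.edges(data=True)
            }

        perm = rng.permutation(25)
        nm_perm = _nm(values[perm], [genes[i] for i in perm])
        assert edges_of(nm) == edges_of(nm_perm)


class TestModules:
    def _graph_from_edges(self, edges):
        g = nx.Graph()
        for a, b, mr in edges:
            g.add_node(a, is_core=a.startswith("core"))
            g.add_node(b, is_core=b.startswith("core"))
            g.add_edge(a, b, mr=mr, pcc=0.9, edge_class=edge_class_of(mr))
        return g

    def test_two_cliques_two_modules(self):
        edges = [("core1", "a", 2.0), ("core1", "b", 3.0), ("a", "b", 2.0),
                 ("core2", "x", 2.0), ("core2", "y", 4.0)]
        modules = extract_modules(self._graph_from_edges(edges))
        assert len(modules) == 2
        assert modules[0].members == {"core1", "a", "b"}  # larger first
        assert modules[1].members == {"core2", "x", "y"}

    def test_thin_only_graph_has_no_modules(self):
        edges = [("core1", "a", 40.0), ("core1", "b", 45.0)]
        assert extract_modules(self._graph_from_edges(edges)) == []

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="unknown module method"):
            extract_modules(self._graph_from_edges([("core1", "a", 2.0)]),
                            method="louvain")

    def test_greedy_modularity_available(self):
        edges = [("core1", "a", 2.0), ("core1", "b", 3.0),
                 ("core2", "x", 2.0)]
        modules = extract_modules(self._graph_from_edges(edges),
                                  method="greedy-modularity")
        assert {frozenset(m.members) for m in modules} == {
            frozenset({"core1", "a", "b"}), frozenset({"core2", "x"})
        }


class TestAnnotateAndRecruit:
    def _ann(self, mapping):
        names = {t: t for ts in mapping.values() for t in ts}
        names.setdefault("GO:flower", "GO:flower")
        return GoAnnotationTable(mapping=mapping, term_names=names,
                                 flower_terms={"GO:flower"})

    def test_percentages_to_two_decimals(self):
        members = {f"g{i}" for i in range(12)}
        mapping = {f"g{i}": {"GO:x"} for i in range(7)}
        mapping.update({f"g{i}": {"GO:y"} for i in range(7, 12)})
        m = FunctionModule(module_id=1, members=members)
        annotate_module(m, self._ann(mapping))
        assert m.go_profile["GO:x"] == 58.33
        assert m.go_profile["GO:y"] == 41.67

    def test_all_and_none_annotated(self):
        members = {"a", "b"}
        m = FunctionModule(module_id=1, members=members)
        annotate_module(m, self._ann({"a": {"GO:x"}, "b": {"GO:x"}}))
        assert m.go_profile == {"GO:x": 100.0}
        assert "GO:absent" not in m.go_profile

    def test_flowering_flag_top3_rule(self):
        members = {"a", "b", "c"}
        mapping = {"a": {"GO:flower"}, "b": {"GO:flower"}, "c": {"GO:z"}}
        m = FunctionModule(module_id=1, members=members)
        annotate_module(m, self._ann(mapping))
        assert m.flowering_flag

    def test_empty_module_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            annotate_module(FunctionModule(module_id=1, members=set()),
                            self._ann({"a": {"GO:x"}}))

    def _recruit_graph(self):
        g = nx.Graph()
        g.add_node("core1", is_core=True)
        for node, pcc, mr in [("hit", 0.85, 25.0), ("low_pcc", 0.79, 25.0),
                              ("high_mr", 0.9, 31.0), ("no_go", 0.9, 10.0)]:
            g.add_node(node, is_core=False)
            g.add_edge("core1", node, pcc=pcc, mr=mr,
                       edge_class=edge_class_of(mr))
        g.add_node("core2", is_core=True)
        g.add_edge("core1", "core2", pcc=0.95, mr=2.0, edge_class="bold")
        return g

    def test_recruitment_rule_boundaries(self):
        g = self._recruit_graph()
        ann = self._ann({n: {"GO:flower"} for n in
                         ["hit", "low_pcc", "high_mr", "core2"]})
        cands = recruit_candidates(g, ann, mr_max=30.0, pcc_min=0.8)
        assert [c.contig_id for c in cands] == ["hit"]
        assert cands[0].partners == [("core1", 0.85, 25.0)]
        assert cands[0].go_basis == {"GO:flower"}

    def test_core_never_recruited(self):
        g = self._recruit_graph()
        ann = self._ann({"core2": {"GO:flower"}})
        assert recruit_candidates(g, ann) == []

    def test_monotone_in_thresholds(self):
        g = self._recruit_graph()
        ann = self._ann({n: {"GO:flower"} for n in
                         ["hit", "low_pcc", "high_mr"]})
        strict = {c.contig_id for c in recruit_candidates(g, ann, 30.0, 0.8)}
        relaxed = {c.contig_id for c in recruit_candidates(g, ann, 35.0, 0.75)}
        assert strict <= relaxed
        assert relaxed == {"hit", "low_pcc", "high_mr"}


class TestPlantedRecovery:
    def test_partner_precision_recall(self, default_fixture):
        """Planted partners of flower-flagged cores are recovered by the
        recruitment rule with precision and recall ≥ 0.9."""
        cfg, matrix, truth, go = default_fixture
        present = filter_detected(matrix, FilterMode.require_one_present)
        nm = normalize(present)
        order, pcc = pcc_matrix(nm)
        mr = mutual_rank(pcc)
        core = CoreGeneList(genes=truth.core_genes)
        g = build_network(order, mr, pcc, core)
        cands = recruit_candidates(g, go)
        recruited = {c.contig_id for c in cands}
        planted = truth.flower_partners()
        tp = len(recruited & planted)
        assert tp / max(len(recruited), 1) >= 0.9
        assert tp / len(planted) >= 0.9
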