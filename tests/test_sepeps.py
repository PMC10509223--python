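"""SEPEP identification, FDR estimation, classification and naming."""
from __future__ import annotations

import numpy as np
import pytest

from sepepkit.datasets import toy_tripartite_graph
from sepepkit.proteome import PeptideIndex, generate_decoys
from sepepkit.sepeps import (
    EvidenceSet,
    PeptideEvidence,
    Sepep,
    TripartiteGraph,
    build_graph,
    build_mapping_table,
    classify_sepep,
    classify_sepeps,
    estimate_fdr,
    filter_fdr,
    identify_sepeps,
    name_sepeps,
    score_sepep,
    score_sepeps,
)


def make_sepep(members, proteins, genes=("G",), decoy=False, score=None):
    return Sepep(
        member_peptides=tuple(sorted(members)),
        protein_set=frozenset(proteins),
        gene_set=frozenset(genes),
        is_decoy=decoy,
        score=score,
    )


def random_graph(rng, n_peptides, n_proteins, n_genes=10):
    graph = TripartiteGraph()
    for j in range(n_proteins):
        graph.add_protein(f"P{j}", f"G{j % n_genes}")
    for i in range(n_peptides):
        k = int(rng.integers(1, min(4, n_proteins) + 1))
        proteins = rng.choice(n_proteins, size=k, replace=False)
        graph.add_peptide(f"pep{i}", [f"P{j}" for j in proteins])
    return graph


class TestBuildGraph:
    def test_minimal_and_multigene_graphs(self, tiny_db):
        db = generate_decoys(tiny_db)
        index = PeptideIndex(db)
        evidence = EvidenceSet(
            [
                PeptideEvidence("CCCDDDK", 0.9),  # unique to A.P1
                PeptideEvidence("GGGHHHK", 0.8),  # A.P1 and B.Q1
            ],
            samples=[],
            platform="ratio",
        )
        graph = build_graph(evidence, db, index)
        assert graph.protein_neighbors("CCCDDDK") == {"A.P1"}
        assert graph.protein_neighbors("GGGHHHK") == {"A.P1", "B.Q1"}
        assert {graph.gene_of(p) for p in graph.protein_neighbors("GGGHHHK")} == {
            "GENEA",
            "GENEB",
        }

    def test_unmappable_peptides_counted_and_all_unmappable_errors(self, tiny_db):
        db = generate_decoys(tiny_db)
        index = PeptideIndex(db)
        evidence = EvidenceSet(
            [PeptideEvidence("CCCDDDK", 0.9), PeptideEvidence("QQQQQQQ", 0.5)],
            samples=[],
            platform="ratio",
        )
        graph = build_graph(evidence, db, index)
        assert graph.n_unmapped == 1
        with pytest.raises(ValueError):
            build_graph(
                EvidenceSet([PeptideEvidence("QQQQQQQ", 0.5)], [], "ratio"), db, index
            )


class TestIdentifySepeps:
    def test_grouping_by_identical_neighborhood(self):
        graph = TripartiteGraph.from_edges(
            {"p1": ["A"], "p2": ["A"], "p3": ["A", "B"]},
            {"A": "G1", "B": "G1"},
        )
        sepeps = identify_sepeps(graph)
        groups = {s.protein_set: set(s.member_peptides) for s in sepeps}
        assert groups == {
            frozenset({"A"}): {"p1", "p2"},
            frozenset({"A", "B"}): {"p3"},
        }

    def test_toy_worked_example_has_eight_sepeps(self):
        sepeps = identify_sepeps(toy_tripartite_graph())
        assert len(sepeps) == 8
        multi_gene = [s for s in sepeps if len(s.gene_set) > 1]
        assert len(multi_gene) == 1

    def test_partition_property(self):
        rng = np.random.default_rng(1)
        graph = random_graph(rng, 150, 30)
        sepeps = identify_sepeps(graph)
        members = [p for s in sepeps for p in s.member_peptides]
        assert sorted(members) == graph.peptides()

    def test_agrees_with_pairwise_brute_force(self):
        """Grouping equals O(n^2) pairwise neighborhood comparison."""
        rng = np.random.default_rng(99)
        for _ in range(30):
            graph = random_graph(
                rng, int(rng.integers(5, 100)), int(rng.integers(2, 30))
            )
            sepeps = identify_sepeps(graph)
            peptide_to_group = {}
            for i, s in enumerate(sepeps):
                for p in s.member_peptides:
                    peptide_to_group[p] = i
            peps = graph.peptides()
            for a in peps:
                for b in peps:
                    same = graph.protein_neighbors(a) == graph.protein_neighbors(b)
                    assert (peptide_to_group[a] == peptide_to_group[b]) == same


class TestScoring:
    def test_max_rollup(self):
        sepep = make_sepep(["a", "b"], ["P1"])
        assert score_sepep(sepep, {"a": 0.9, "b": 0.99}) == 0.99
        assert score_sepep(make_sepep(["a"], ["P1"]), {"a": 0.5}) == 0.5
        assert score_sepep(make_sepep(["a", "b", "c"], ["P1"]), dict.fromkeys("abc", 1.0)) == 1.0

    def test_missing_score_is_error(self):
        with pytest.raises(ValueError, match="missing best_score"):
            score_sepep(make_sepep(["a", "b"], ["P1"]), {"a": 0.9})


class TestEstimateFdr:
    def test_hand_computed_example(self):
        """Labels [T,T,D,T] in score order -> q-values [0, 0, 1/3, 1/3]."""
        sepeps = [
            make_sepep(["p1"], ["P1"], score=0.9),
            make_sepep(["p2"], ["P2"], score=0.8),
            make_sepep(["d1"], ["rev_P1"], decoy=True, score=0.7),
            make_sepep(["p3"], ["P3"], score=0.6),
        ]
        estimate_fdr(sepeps)
        assert [s.q_value for s in sepeps] == pytest.approx([0, 0, 1 / 3, 1 / 3])

    def test_all_targets_and_all_decoys(self):
        targets = [make_sepep([f"p{i}"], [f"P{i}"], score=i) for i in range(3)]
        estimate_fdr(targets)
        assert all(s.q_value == 0 for s in targets)
        decoys = [
            make_sepep([f"d{i}"], [f"rev_P{i}"], decoy=True, score=i) for i in range(3)
        ]
        estimate_fdr(decoys)
        assert all(s.q_value == 1.0 for s in decoys)

    def test_q_monotone_and_order_invariant(self):
        rng = np.random.default_rng(5)
        sepeps = [
            make_sepep(
                [f"x{i}"], [f"P{i}"], decoy=bool(rng.random() < 0.3),
                score=float(rng.random()),
            )
            for i in range(60)
        ]
        estimate_fdr(sepeps)
        ranked = sorted(sepeps, key=lambda s: -s.score)
        qs = [s.q_value for s in ranked]
        assert all(a <= b for a, b in zip(qs, qs[1:]))
        shuffled = list(sepeps)
        rng.shuffle(shuffled)
        by_member = {s.smallest_peptide: s.q_value for s in sepeps}
        for s in shuffled:
            s.q_value = None
        estimate_fdr(shuffled)
        assert {s.smallest_peptide: s.q_value for s in shuffled} == by_member

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            estimate_fdr([])


class TestFilterFdr:
    def test_threshold_behaviour(self):
        sepeps = [
            make_sepep(["p1"], ["P1"], score=1.0),
            make_sepep(["p2"], ["P2"], score=0.9),
        ]
        sepeps[0].q_value = 0.001
        sepeps[1].q_value = 0.02
        kept = filter_fdr(sepeps)
        assert [s.smallest_peptide for s in kept] == ["p1"]
        assert len(filter_fdr(sepeps, threshold=1.0)) == 2

    def test_decoys_always_removed_and_empty_ok(self):
        decoy = make_sepep(["d"], ["rev_P"], decoy=True, score=1.0)
        decoy.q_value = 0.0
        assert filter_fdr([decoy]) == []

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            filter_fdr([], threshold=0.0)


class TestClassifyAndName:
    def test_class_assignment(self, tiny_db):
        assert classify_sepep(make_sepep(["x"], ["A.P1"], ["GENEA"]), tiny_db) == "C2"
        assert (
            classify_sepep(
                make_sepep(["x"], ["A.P1", "A.P2", "A.P3"], ["GENEA"]), tiny_db
            )
            == "C4"
        )
        assert (
            classify_sepep(make_sepep(["x"], ["A.P1", "B.Q1"], ["GENEA", "GENEB"]), tiny_db)
            == "C5"
        )
        assert classify_sepep(make_sepep(["x"], ["B.Q1"], ["GENEB"]), tiny_db) == "C1"
        with pytest.raises(ValueError):
            classify_sepep(make_sepep(["x"], ["rev_A"], decoy=True), tiny_db)

    def test_naming_order_within_gene(self):
        big = make_sepep(["a", "b", "c"], ["P1", "P2"], ["GENE1"])
        big.sepep_class = "C4"
        small = make_sepep(["z"], ["P1"], ["GENE1"])
        small.sepep_class = "C2"
        name_sepeps([small, big])
        assert big.name == "GENE1_SEPEP.1_C4"
        assert small.name == "GENE1_SEPEP.2_C2"

    def test_multi_gene_naming(self):
        c5 = make_sepep(["m"], ["P1", "Q1"], ["GA", "GB"])
        c5.sepep_class = "C5"
        name_sepeps([c5])
        assert c5.name == "Multiple_SEPEP.1_C5"

    def test_name_uniqueness_over_many_sepeps(self):
        rng = np.random.default_rng(2)
        sepeps = []
        for i in range(1000):
            gene = f"G{int(rng.integers(0, 80))}"
            s = make_sepep([f"pep{i}"], [f"{gene}.P{i}"], [gene])
            s.sepep_class = str(rng.choice(["C1", "C2", "C3", "C4"]))
            sepeps.append(s)
        name_sepeps(sepeps)
        names = [s.name for s in sepeps]
        assert len(set(names)) == len(names)


class TestMappingTable:
    def _named(self):
        s1 = make_sepep(["pepA", "pepB"], ["NP_9", "NP_1"], ["G1"])
        s1.sepep_class = "C3"
        s1.q_value = 0.0
        s2 = make_sepep(["pepC"], ["NP_2"], ["G1"])
        s2.sepep_class = "C2"
        s2.q_value = 0.005
        return [s1, s2]

    def test_keys_sorted_and_rows_complete(self):
        sepeps = name_sepeps(self._named())
        table = build_mapping_table(sepeps)
        assert len(table) == 2
        row = table.set_index("name").loc["G1_SEPEP.1_C3"]
        assert row["protein_key"] == "NP_1;NP_9"
        assert row["peptides"] == "pepA;pepB"

    def test_byte_identical_on_shuffled_input(self):
        rng = np.random.default_rng(3)
        sepeps = []
        for i in range(40):
            gene = f"G{int(rng.integers(0, 8))}"
            s = make_sepep(
                [f"pep{i}{chr(97 + j)}" for j in range(int(rng.integers(1, 4)))],
                [f"{gene}.P{i}"],
                [gene],
            )
            s.sepep_class = "C2"
            s.q_value = float(rng.random() * 0.01)
            sepeps.append(s)
        first = build_mapping_table(name_sepeps(list(sepeps))).to_csv(sep="\t")
        shuffled = list(sepeps)
        rng.shuffle(shuffled)
        for s in shuffled:
            s.name = None
        second = build_mapping_table(name_sepeps(shuffled)).to_csv(sep="\t")
        assert first == second
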