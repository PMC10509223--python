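"""Tryptic digestion against a regex-split oracle, and classification."""
from __future__ import annotations

import re
from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sepepkit.digestion import (
    DigestionParams,
    PeptideClass,
    assess_proteome,
    classify_peptide,
    digest,
)
from sepepkit.proteome import ProteinRecord, ProteomeDatabase

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# -- independent oracle ------------------------------------------------------


def oracle_digest(sequence, max_missed=0, min_length=1, max_length=10**9, mode="full_tryptic"):
    """Regex split on K/R-not-before-P, then join consecutive fragments."""
    fragments = re.split(r"(?<=[KR])(?!P)", sequence)
    fragments = [f for f in fragments if f]
    starts = []
    pos = 0
    for frag in fragments:
        starts.append(pos + 1)
        pos += len(frag)
    spans = set()
    for i in range(len(fragments)):
        for mc in range(max_missed + 1):
            if i + mc >= len(fragments):
                break
            pep = "".join(fragments[i : i + mc + 1])
            spans.add((pep, starts[i], mc))
            if mode == "semi_tryptic":
                for cut in range(1, len(pep)):
                    spans.add((pep[:cut], starts[i], None))
                    spans.add((pep[cut:], starts[i] + cut, None))
    # deduplicate by (sequence, start); recompute missed cleavages per span
    sites = {starts[i] + len(fragments[i]) - 1 for i in range(len(fragments) - 1)}
    out = set()
    for pep, start, _ in spans:
        if not min_length <= len(pep) <= max_length:
            continue
        internal = sum(1 for s in sites if start <= s < start + len(pep) - 1)
        out.add((pep, start, internal))
    return out


# -- digestion ---------------------------------------------------------------


class TestDigest:
    def test_cleaves_after_k_and_r_but_not_before_proline(self):
        params = DigestionParams(max_missed_cleavages=0, min_length=1)
        assert {(p.sequence, p.start, p.missed_cleavages) for p in digest("AKRPK", params)} == {
            ("AK", 1, 0),
            ("RPK", 3, 0),
        }

    def test_missed_cleavage_products(self):
        params = DigestionParams(max_missed_cleavages=1, min_length=1)
        got = {(p.sequence, p.missed_cleavages) for p in digest("MKAARPKLK", params)}
        assert got == {
            ("MK", 0), ("AARPK", 0), ("LK", 0),
            ("MKAARPK", 1), ("AARPKLK", 1),
        }

    def test_sequence_without_sites_is_one_product(self):
        params = DigestionParams(max_missed_cleavages=2, min_length=7)
        assert digest("PPPPPPPP", params) == [("PPPPPPPP", 1, 0)]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            digest("", DigestionParams())

    def test_semi_tryptic_includes_prefixes_and_suffixes(self):
        params = DigestionParams(max_missed_cleavages=0, min_length=2, max_length=50, mode="semi_tryptic")
        got = {(p.sequence, p.start) for p in digest("ABCDKFG", params)}
        # full products ABCDK and FG plus internal prefixes/suffixes
        assert ("ABCDK", 1) in got and ("FG", 6) in got
        assert ("ABCD", 1) in got and ("BCDK", 2) in got and ("AB", 1) in got

    @pytest.mark.parametrize("max_missed,mode", list(product([0, 1, 2], ["full_tryptic", "semi_tryptic"])))
    def test_matches_regex_split_oracle(self, max_missed, mode):
        """100 random sequences, all missed-cleavage counts and both modes."""
        rng = np.random.default_rng(7 + max_missed)
        for _ in range(100):
            seq = "".join(
                rng.choice(list(ALPHABET), size=rng.integers(1, 120))
            )
            params = DigestionParams(max_missed, 1, 10**9, mode)
            got = {tuple(p) for p in digest(seq, params)}
            assert got == oracle_digest(seq, max_missed, mode=mode)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet=ALPHABET, min_size=1, max_size=200))
    def test_zero_missed_fragments_reconstruct_sequence(self, seq):
        params = DigestionParams(max_missed_cleavages=0, min_length=1, max_length=10**9)
        zero_mc = [p for p in digest(seq, params) if p.missed_cleavages == 0]
        zero_mc.sort(key=lambda p: p.start)
        assert "".join(p.sequence for p in zero_mc) == seq

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.text(alphabet=ALPHABET, min_size=2, max_size=200))
    def test_no_cut_point_precedes_proline(self, seq):
        params = DigestionParams(max_missed_cleavages=0, min_length=1, max_length=10**9)
        for p in digest(seq, params):
            internal_end = p.start - 1 + len(p.sequence)
            if internal_end < len(seq):  # a cut happened here
                assert seq[internal_end] != "P"
                assert p.sequence[-1] in "KR"


# -- classification ----------------------------------------------------------


class TestClassifyPeptide:
    def test_taxonomy_examples(self, tiny_db):
        assert classify_peptide({"A.P1"}, tiny_db) == PeptideClass.FULLY_DISCRIMINATIVE
        assert (
            classify_peptide({"A.P1", "A.P2", "A.P3"}, tiny_db)
            == PeptideClass.NON_DISCRIMINATIVE
        )
        assert classify_peptide({"A.P1", "B.Q1"}, tiny_db) == PeptideClass.MULTI_GENE
        assert classify_peptide({"B.Q1"}, tiny_db) == PeptideClass.SINGLE_ISOFORM
        assert (
            classify_peptide({"A.P1", "A.P2"}, tiny_db)
            == PeptideClass.PARTIALLY_DISCRIMINATIVE
        )

    def test_errors(self, tiny_db):
        with pytest.raises(ValueError):
            classify_peptide(set(), tiny_db)
        with pytest.raises(KeyError):
            classify_peptide({"NOPE"}, tiny_db)

    def test_exhaustive_truth_table(self):
        """Every (n isoforms <= 4, k mapped, single/multi gene) combination."""
        for n in range(1, 5):
            records = [
                ProteinRecord(f"G.P{i}", "G", "W" * (i + 5) + "K") for i in range(n)
            ]
            records.append(ProteinRecord("H.Q1", "H", "YYYYYK"))
            db = ProteomeDatabase(records)
            isoforms = [f"G.P{i}" for i in range(n)]
            for k in range(1, n + 1):
                for multi_gene in (False, True):
                    chosen = set(isoforms[:k])
                    if multi_gene:
                        chosen.add("H.Q1")
                        expected = PeptideClass.MULTI_GENE
                    elif n == 1:
                        expected = PeptideClass.SINGLE_ISOFORM
                    elif k == 1:
                        expected = PeptideClass.FULLY_DISCRIMINATIVE
                    elif k == n:
                        expected = PeptideClass.NON_DISCRIMINATIVE
                    else:
                        expected = PeptideClass.PARTIALLY_DISCRIMINATIVE
                    assert classify_peptide(chosen, db) == expected, (n, k, multi_gene)


class TestAssessProteome:
    def test_single_isoform_gene(self):
        db = ProteomeDatabase([ProteinRecord("P1", "G1", "AAAK")])
        table = assess_proteome(db, DigestionParams(0, 1, 50)).set_index("class")
        assert table.loc["single_isoform", "proportion"] == 1.0

    def test_shared_and_unique_split(self):
        db = ProteomeDatabase(
            [
                ProteinRecord("P1", "G1", "AAAKCCCK"),
                ProteinRecord("P2", "G1", "AAAK"),
            ]
        )
        table = assess_proteome(db, DigestionParams(0, 1, 50)).set_index("class")
        assert table.loc["non_discriminative", "count"] == 1  # AAAK
        assert table.loc["fully_discriminative", "count"] == 1  # CCCK
        assert table.loc["non_discriminative", "proportion_within_multi_isoform"] == 0.5

    def test_proportions_partition_to_one(self, tiny_db):
        table = assess_proteome(tiny_db, DigestionParams(1, 1, 50))
        assert table["proportion"].sum() == pytest.approx(1.0)
        assert (table["count"] >= 0).all()
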