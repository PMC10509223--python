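"""In silico tryptic digestion and peptide informativeness classification.

Trypsin cuts C-terminal to K or R unless the next residue is P.  Digestion
emits fully tryptic products for every missed-cleavage count up to the
configured maximum; semi-tryptic mode additionally emits every
length-filtered prefix and suffix of each fully tryptic product (one
tryptic terminus).

A peptide's mapping pattern against a gene-annotated database places it in
exactly one of five informativeness classes:

* ``MULTI_GENE`` -- maps to proteins of more than one gene;
* ``SINGLE_ISOFORM`` -- its single host gene has only one isoform;
* ``FULLY_DISCRIMINATIVE`` -- maps to exactly one of several isoforms;
* ``PARTIALLY_DISCRIMINATIVE`` -- maps to a proper subset (>1) of isoforms;
* ``NON_DISCRIMINATIVE`` -- maps to all isoforms of a multi-isoform gene.
"""
from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, NamedTuple

import pandas as pd

from .proteome import PeptideIndex, ProteomeDatabase


class PeptideClass(Enum):
    MULTI_GENE = "multi_gene"
    SINGLE_ISOFORM = "single_isoform"
    FULLY_DISCRIMINATIVE = "fully_discriminative"
    PARTIALLY_DISCRIMINATIVE = "partially_discriminative"
    NON_DISCRIMINATIVE = "non_discriminative"


#: Classes describing peptides of multi-isoform genes.
MULTI_ISOFORM_CLASSES = (
    PeptideClass.FULLY_DISCRIMINATIVE,
    PeptideClass.PARTIALLY_DISCRIMINATIVE,
    PeptideClass.NON_DISCRIMINATIVE,
)


@dataclass(frozen=True)
class DigestionParams:
    """Tryptic digestion settings (length window 7-50, <=2 missed cleavages)."""

    max_missed_cleavages: int = 2
    min_length: int = 7
    max_length: int = 50
    mode: str = "full_tryptic"

    def __post_init__(self) -> None:
        if not 0 <= self.max_missed_cleavages <= 2:
            raise ValueError("max_missed_cleavages must be in {0, 1, 2}")
        if self.min_length < 1 or self.min_length > self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.mode not in ("full_tryptic", "semi_tryptic"):
            raise ValueError(f"unknown digestion mode {self.mode!r}")


class DigestedPeptide(NamedTuple):
    sequence: str
    start: int  # 1-based position in the protein
    missed_cleavages: int


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions *after* which trypsin cuts (K/R not followed by P)."""
    return [
        i + 1
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(sequence: str, params: DigestionParams | None = None) -> list[DigestedPeptide]:
    """Digest one protein sequence.

    Returns length-filtered products as ``(peptide, start, missed_cleavages)``
    tuples with 1-based start positions, ordered by position then length.
    In semi-tryptic mode, products sharing a span are reported once.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    params = params or DigestionParams()
    sites = cleavage_sites(sequence)
    bounds = [0] + sites + [len(sequence)]
    n_frag = len(bounds) - 1

    spans: set[tuple[int, int]] = set()
    for i in range(n_frag):
        for mc in range(params.max_missed_cleavages + 1):
            j = i + mc
            if j >= n_frag:
                break
            spans.add((bounds[i], bounds[j + 1]))
            if params.mode == "semi_tryptic":
                start, end = bounds[i], bounds[j + 1]
                for cut in range(start + 1, end):
                    spans.add((start, cut))  # prefixes
                    spans.add((cut, end))  # suffixes

    out: list[DigestedPeptide] = []
    for start, end in spans:
        length = end - start
        if not params.min_length <= length <= params.max_length:
            continue
        # internal missed cleavages = tryptic sites strictly inside the span
        mc = bisect_left(sites, end) - bisect_right(sites, start)
        out.append(DigestedPeptide(sequence[start:end], start + 1, mc))
    out.sort(key=lambda p: (p.start, len(p.sequence)))
    return out


def classify_peptide(
    protein_set: Iterable[str], db: ProteomeDatabase
) -> PeptideClass:
    """Classify a peptide by the set of target proteins containing it."""
    accessions = set(protein_set)
    if not accessions:
        raise ValueError("protein set is empty")
    for acc in accessions:
        if acc not in db:
            raise KeyError(f"unknown accession {acc!r}")
        if db.is_decoy(acc):
            raise ValueError(f"decoy accession {acc!r} in classification input")
    genes = {db.gene_of(acc) for acc in accessions}
    if len(genes) > 1:
        return PeptideClass.MULTI_GENE
    n = db.n_isoforms(next(iter(genes)))
    k = len(accessions)
    if n == 1:
        return PeptideClass.SINGLE_ISOFORM
    if k == 1:
        return PeptideClass.FULLY_DISCRIMINATIVE
    if k == n:
        return PeptideClass.NON_DISCRIMINATIVE
    return PeptideClass.PARTIALLY_DISCRIMINATIVE


def assess_proteome(
    db: ProteomeDatabase,
    params: DigestionParams | None = None,
    il_equivalent: bool = False,
) -> pd.DataFrame:
    """Digest every target protein and classify the unique peptides.

    Peptide sequences are deduplicated study-wide before classification,
    each mapped exhaustively back to all containing proteins.  Returns a
    table with one row per class: count, proportion of all unique
    peptides, and (for the three multi-isoform classes) the proportion
    within the multi-isoform group.
    """
    if db.has_decoys:
        raise ValueError("assess_proteome expects a target-only database")
    params = params or DigestionParams()
    index = PeptideIndex(db, il_equivalent=il_equivalent)
    unique_peptides: set[str] = set()
    for rec in db.target_records():
        unique_peptides.update(p.sequence for p in digest(rec.sequence, params))

    counts = {cls: 0 for cls in PeptideClass}
    for pep in unique_peptides:
        hits = index.lookup(pep)
        counts[classify_peptide(hits, db)] += 1

    total = sum(counts.values())
    multi_iso_total = sum(counts[c] for c in MULTI_ISOFORM_CLASSES)
    rows = []
    for cls in PeptideClass:
        row = {
            "class": cls.value,
            "count": counts[cls],
            "proportion": counts[cls] / total if total else 0.0,
        }
        if cls in MULTI_ISOFORM_CLASSES:
            row["proportion_within_multi_isoform"] = (
                counts[cls] / multi_iso_total if multi_iso_total else 0.0
            )
        else:
            row["proportion_within_multi_isoform"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
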