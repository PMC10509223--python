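"""Protein database handling.

Loads a protein FASTA plus an accession->gene mapping table, generates
reversed decoy sequences, and answers exhaustive "which proteins contain
this peptide" substring queries.  The database ties every protein to
exactly one gene; decoys live under a shadow gene carrying the decoy
prefix so target and decoy name spaces never collide.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Standard amino-acid alphabet; non-standard residues (U, X, B, Z, *) are
#: tolerated and matched literally, since mapping is sequence-based.
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

DEFAULT_DECOY_PREFIX = "rev_"


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence tied to a single host gene."""

    accession: str
    gene_symbol: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("protein accession must be non-empty")
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")


@dataclass(frozen=True)
class GeneRecord:
    """A gene and its protein isoforms (alphabetically sorted accessions)."""

    symbol: str
    isoform_accessions: tuple[str, ...]

    @property
    def n_isoforms(self) -> int:
        return len(self.isoform_accessions)


class ProteomeDatabase:
    """Indexed protein records with gene annotation and decoy bookkeeping.

    Invariants enforced at construction: unique accessions, non-empty
    sequences, every protein belongs to exactly one gene, decoy status
    matches the decoy prefix, and target/decoy accession sets are disjoint
    (guaranteed by the prefix rule).
    """

    def __init__(
        self,
        proteins: Iterable[ProteinRecord],
        decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    ) -> None:
        self.decoy_prefix = decoy_prefix
        self.proteins: dict[str, ProteinRecord] = {}
        for rec in proteins:
            if rec.accession in self.proteins:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            if rec.is_decoy != rec.accession.startswith(decoy_prefix):
                raise ValueError(
                    f"decoy flag inconsistent with prefix for {rec.accession!r}"
                )
            self.proteins[rec.accession] = rec
        by_gene: dict[str, list[str]] = {}
        for rec in self.proteins.values():
            by_gene.setdefault(rec.gene_symbol, []).append(rec.accession)
        self.genes: dict[str, GeneRecord] = {
            sym: GeneRecord(sym, tuple(sorted(accs)))
            for sym, accs in sorted(by_gene.items())
        }

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.proteins)

    def __contains__(self, accession: str) -> bool:
        return accession in self.proteins

    def gene_of(self, accession: str) -> str:
        return self.proteins[accession].gene_symbol

    def n_isoforms(self, gene_symbol: str) -> int:
        return self.genes[gene_symbol].n_isoforms

    def is_decoy(self, accession: str) -> bool:
        return self.proteins[accession].is_decoy

    def target_accessions(self) -> list[str]:
        return [a for a, r in self.proteins.items() if not r.is_decoy]

    def decoy_accessions(self) -> list[str]:
        return [a for a, r in self.proteins.items() if r.is_decoy]

    @property
    def has_decoys(self) -> bool:
        return any(r.is_decoy for r in self.proteins.values())

    def target_records(self) -> list[ProteinRecord]:
        return [r for r in self.proteins.values() if not r.is_decoy]

    # -- I/O -------------------------------------------------------------

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(rec.sequence), id=rec.accession, description="")
            for rec in self.proteins.values()
        ]
        SeqIO.write(records, str(path), "fasta")

    def write_gene_map(self, path: str | Path) -> None:
        rows = [
            {"accession": rec.accession, "gene_symbol": rec.gene_symbol}
            for rec in self.proteins.values()
            if not rec.is_decoy
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_map(path: str | Path) -> dict[str, str]:
    """Read a two-column headered TSV ``accession<TAB>gene_symbol``."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    if table.shape[1] < 2:
        raise ValueError(f"gene map {path} needs two columns (accession, gene)")
    acc_col, gene_col = table.columns[:2]
    return dict(zip(table[acc_col].astype(str), table[gene_col].astype(str)))


def load_fasta(
    fasta_path: str | Path,
    gene_map_path: str | Path,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> ProteomeDatabase:
    """Load a protein FASTA and its accession->gene table into a database.

    Decoy entries already present in the FASTA are recognised by the
    prefix and assigned a shadow gene ``<prefix><symbol>`` derived from
    the corresponding target accession's gene.  Any target accession
    missing from the gene map is a hard error naming the accession.
    """
    gene_map = read_gene_map(gene_map_path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for seq_rec in SeqIO.parse(str(fasta_path), "fasta"):
        accession = seq_rec.id
        if accession in seen:
            raise ValueError(f"duplicate accession {accession!r} in {fasta_path}")
        seen.add(accession)
        sequence = str(seq_rec.seq).upper()
        if not sequence:
            raise ValueError(f"empty sequence for accession {accession!r}")
        if accession.startswith(decoy_prefix):
            base = accession[len(decoy_prefix):]
            gene = gene_map.get(accession)
            if gene is None:
                if base not in gene_map:
                    raise ValueError(
                        f"decoy accession {accession!r}: no gene mapping for "
                        f"itself or its base accession {base!r}"
                    )
                gene = decoy_prefix + gene_map[base]
            records.append(ProteinRecord(accession, gene, sequence, is_decoy=True))
        else:
            if accession not in gene_map:
                raise ValueError(
                    f"target accession {accession!r} missing from gene map"
                )
            records.append(ProteinRecord(accession, gene_map[accession], sequence))
    if not records:
        raise ValueError(f"no sequences read from {fasta_path}")
    return ProteomeDatabase(records, decoy_prefix=decoy_prefix)


def generate_decoys(db: ProteomeDatabase) -> ProteomeDatabase:
    """Add one whole-sequence-reversed decoy per target protein.

    Decoy accession = ``decoy_prefix + target accession``, decoy gene =
    ``decoy_prefix + gene symbol``.  Target records are unchanged.  A
    database that already contains decoys is refused.
    """
    if db.has_decoys:
        raise ValueError("database already contains decoy proteins")
    records = list(db.proteins.values())
    for rec in db.proteins.values():
        records.append(
            ProteinRecord(
                accession=db.decoy_prefix + rec.accession,
                gene_symbol=db.decoy_prefix + rec.gene_symbol,
                sequence=rec.sequence[::-1],
                is_decoy=True,
            )
        )
    return ProteomeDatabase(records, decoy_prefix=db.decoy_prefix)


class PeptideIndex:
    """Seed-and-verify substring index over all protein sequences.

    Each k-mer seed (default k=4) maps to the set of accessions whose
    sequence contains it; a query is resolved by fetching the candidates
    for its first k-mer and verifying full substring containment, which
    is sublinear in total database size for typical peptide queries.
    Queries shorter than the seed length fall back to a full scan.

    With ``il_equivalent`` the residues I and L are collapsed to a single
    symbol on both the database and the query side.
    """

    def __init__(
        self,
        db: ProteomeDatabase,
        il_equivalent: bool = False,
        seed_length: int = 4,
    ) -> None:
        if seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        self.il_equivalent = il_equivalent
        self.seed_length = seed_length
        self._sequences: dict[str, str] = {
            acc: self._canonical(rec.sequence) for acc, rec in db.proteins.items()
        }
        k = seed_length
        seeds: dict[str, set[str]] = {}
        for acc, seq in self._sequences.items():
            for i in range(len(seq) - k + 1):
                seeds.setdefault(seq[i : i + k], set()).add(acc)
        self._seeds = seeds

    def _canonical(self, sequence: str) -> str:
        return sequence.replace("L", "I") if self.il_equivalent else sequence

    def lookup(self, peptide: str) -> frozenset[str]:
        """All accessions whose sequence contains *peptide* as a substring."""
        if not peptide:
            raise ValueError("empty peptide query")
        query = self._canonical(peptide)
        if len(query) < self.seed_length:
            candidates: Iterable[str] = self._sequences
        else:
            candidates = self._seeds.get(query[: self.seed_length], ())
        return frozenset(
            acc for acc in candidates if query in self._sequences[acc]
        )

    def map_peptides(self, peptides: Iterable[str]) -> dict[str, frozenset[str]]:
        return {p: self.lookup(p) for p in peptides}


def build_peptide_index(
    db: ProteomeDatabase, il_equivalent: bool = False
) -> PeptideIndex:
    """Build the peptide->protein substring index for *db*."""
    return PeptideIndex(db, il_equivalent=il_equivalent)
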