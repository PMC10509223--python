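"""Tripartite graph construction and SEPEP identification.

Identified peptides, the proteins containing them, and the proteins' host
genes form a tripartite graph.  Peptides connected to exactly the same
set of protein vertices are structurally equivalent and are grouped into
one SEPEP (structurally equivalent peptide group), the unit of
identification, FDR control and quantification in this package.

SEPEP classes mirror the peptide informativeness taxonomy:
C1 single-isoform, C2 fully discriminative, C3 partially discriminative,
C4 non-discriminative, C5 multi-gene.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .digestion import PeptideClass, classify_peptide
from .proteome import PeptideIndex, ProteomeDatabase

logger = logging.getLogger(__name__)

#: SEPEP class labels keyed by the peptide-level class they correspond to.
CLASS_LABELS: dict[PeptideClass, str] = {
    PeptideClass.SINGLE_ISOFORM: "C1",
    PeptideClass.FULLY_DISCRIMINATIVE: "C2",
    PeptideClass.PARTIALLY_DISCRIMINATIVE: "C3",
    PeptideClass.NON_DISCRIMINATIVE: "C4",
    PeptideClass.MULTI_GENE: "C5",
}

KEY_DELIMITER = ";"


@dataclass
class PeptideEvidence:
    """One identified stripped peptide with its per-sample quantities.

    ``quantities`` holds log2 ratios (NaN = missing) for isobaric data;
    ``psm_counts`` holds non-negative spectral counts for label-free data.
    Either may be None when the platform does not provide it.
    """

    sequence: str
    best_score: float
    quantities: np.ndarray | None = None
    psm_counts: np.ndarray | None = None
    mapped_proteins: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")


@dataclass
class EvidenceSet:
    """Peptide evidence plus the study's shared sample axis."""

    peptides: list[PeptideEvidence]
    samples: list[str]
    platform: str  # "ratio" | "label_free"

    def __post_init__(self) -> None:
        if self.platform not in ("ratio", "label_free"):
            raise ValueError(f"unknown platform {self.platform!r}")
        n = len(self.samples)
        for ev in self.peptides:
            for arr in (ev.quantities, ev.psm_counts):
                if arr is not None and len(arr) != n:
                    raise ValueError(
                        f"peptide {ev.sequence!r}: quantity vector length "
                        f"{len(arr)} != {n} samples"
                    )

    def by_sequence(self) -> dict[str, PeptideEvidence]:
        return {ev.sequence: ev for ev in self.peptides}

    def __len__(self) -> int:
        return len(self.peptides)


class TripartiteGraph:
    """Peptide-protein-gene graph with layered vertices.

    Only proteins containing at least one identified peptide appear;
    every protein vertex carries exactly one gene edge.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()
        self.n_unmapped = 0  # peptides dropped for lack of any protein hit

    @classmethod
    def from_edges(
        cls,
        peptide_to_proteins: Mapping[str, Iterable[str]],
        protein_to_gene: Mapping[str, str],
        decoy_proteins: Iterable[str] = (),
    ) -> "TripartiteGraph":
        """Build a graph directly from explicit edge mappings."""
        graph = cls()
        decoys = set(decoy_proteins)
        for protein, gene in protein_to_gene.items():
            graph.add_protein(protein, gene, is_decoy=protein in decoys)
        for peptide, proteins in peptide_to_proteins.items():
            proteins = list(proteins)
            if not proteins:
                raise ValueError(f"peptide {peptide!r} has no protein edges")
            for protein in proteins:
                if ("protein", protein) not in graph._g:
                    raise KeyError(f"protein {protein!r} lacks a gene edge")
            graph.add_peptide(peptide, proteins)
        return graph

    def add_protein(self, accession: str, gene: str, is_decoy: bool = False) -> None:
        self._g.add_node(("protein", accession), is_decoy=is_decoy)
        self._g.add_node(("gene", gene))
        self._g.add_edge(("protein", accession), ("gene", gene))

    def add_peptide(self, sequence: str, proteins: Iterable[str]) -> None:
        self._g.add_node(("peptide", sequence))
        for acc in proteins:
            self._g.add_edge(("peptide", sequence), ("protein", acc))

    # -- accessors -------------------------------------------------------

    def peptides(self) -> list[str]:
        return sorted(n[1] for n in self._g.nodes if n[0] == "peptide")

    def proteins(self) -> list[str]:
        return sorted(n[1] for n in self._g.nodes if n[0] == "protein")

    def genes(self) -> list[str]:
        return sorted(n[1] for n in self._g.nodes if n[0] == "gene")

    def protein_neighbors(self, peptide: str) -> frozenset[str]:
        return frozenset(
            n[1] for n in self._g.neighbors(("peptide", peptide)) if n[0] == "protein"
        )

    def gene_of(self, protein: str) -> str:
        genes = [n[1] for n in self._g.neighbors(("protein", protein)) if n[0] == "gene"]
        if len(genes) != 1:
            raise ValueError(f"protein {protein!r} has {len(genes)} gene edges")
        return genes[0]

    def protein_is_decoy(self, protein: str) -> bool:
        return bool(self._g.nodes[("protein", protein)].get("is_decoy", False))


def build_graph(
    evidence: EvidenceSet | Sequence[PeptideEvidence],
    db: ProteomeDatabase,
    index: PeptideIndex | None = None,
    trust_mappings: bool = False,
) -> TripartiteGraph:
    """Connect every evidence peptide to all proteins containing it.

    Peptides are re-mapped exhaustively against the database through the
    substring index (parsimony-based upstream tools may under-report
    mappings); with ``trust_mappings`` the recorded ``mapped_proteins``
    sets are used instead.  Peptides with zero hits are dropped, counted
    in ``graph.n_unmapped`` and logged; a study where nothing maps is an
    error.
    """
    peptides = evidence.peptides if isinstance(evidence, EvidenceSet) else list(evidence)
    if not peptides:
        raise ValueError("no peptide evidence provided")
    if index is None and not trust_mappings:
        index = PeptideIndex(db)
    graph = TripartiteGraph()
    n_mapped = 0
    for ev in peptides:
        hits = (
            frozenset(ev.mapped_proteins) if trust_mappings else index.lookup(ev.sequence)
        )
        if not hits:
            graph.n_unmapped += 1
            logger.warning("peptide %s maps to no protein; dropped", ev.sequence)
            continue
        for acc in hits:
            if ("protein", acc) not in graph._g:
                graph.add_protein(acc, db.gene_of(acc), is_decoy=db.is_decoy(acc))
        graph.add_peptide(ev.sequence, hits)
        ev.mapped_proteins = hits
        n_mapped += 1
    if n_mapped == 0:
        raise ValueError("no peptide could be mapped to any protein")
    return graph


@dataclass
class Sepep:
    """A maximal group of peptides sharing an identical protein neighborhood."""

    member_peptides: tuple[str, ...]  # sorted
    protein_set: frozenset[str]
    gene_set: frozenset[str]
    is_decoy: bool
    score: float | None = None
    q_value: float | None = None
    sepep_class: str | None = None  # "C1".."C5"
    name: str | None = None

    @property
    def n_peptides(self) -> int:
        return len(self.member_peptides)

    @property
    def smallest_peptide(self) -> str:
        return self.member_peptides[0]

    @property
    def protein_key(self) -> str:
        return KEY_DELIMITER.join(sorted(self.protein_set))

    @property
    def gene_key(self) -> str:
        return KEY_DELIMITER.join(sorted(self.gene_set))


def identify_sepeps(graph: TripartiteGraph) -> list[Sepep]:
    """Group peptides with identical protein neighborhoods into SEPEPs.

    The returned SEPEPs partition the peptide vertex set.  A SEPEP is a
    decoy hit iff every protein in its neighborhood is a decoy; mixed
    target/decoy neighborhoods count as targets (and are logged).
    """
    groups: dict[frozenset[str], list[str]] = {}
    for pep in graph.peptides():
        groups.setdefault(graph.protein_neighbors(pep), []).append(pep)
    sepeps = []
    for protein_set, members in groups.items():
        targets = frozenset(p for p in protein_set if not graph.protein_is_decoy(p))
        is_decoy = not targets
        if targets and len(targets) < len(protein_set):
            logger.info(
                "mixed target/decoy protein set treated as target: %s",
                sorted(protein_set),
            )
        # gene_set (and hence class/name) follows the target proteins when
        # any exist; decoy neighbors are competition artifacts
        gene_basis = targets if targets else protein_set
        sepeps.append(
            Sepep(
                member_peptides=tuple(sorted(members)),
                protein_set=protein_set,
                gene_set=frozenset(graph.gene_of(p) for p in gene_basis),
                is_decoy=is_decoy,
            )
        )
    sepeps.sort(key=lambda s: (s.protein_key, s.smallest_peptide))
    return sepeps


def score_sepep(sepep: Sepep, scores_by_sequence: Mapping[str, float]) -> float:
    """Best-evidence rollup: max member best_score (ranking statistic for FDR)."""
    try:
        return max(scores_by_sequence[p] for p in sepep.member_peptides)
    except KeyError as exc:
        raise ValueError(f"missing best_score for member peptide {exc.args[0]!r}")


def score_sepeps(
    sepeps: Sequence[Sepep], evidence: EvidenceSet | Mapping[str, float]
) -> list[Sepep]:
    """Set ``score`` on every SEPEP from the member peptides' best scores."""
    if isinstance(evidence, EvidenceSet):
        scores = {ev.sequence: ev.best_score for ev in evidence.peptides}
    else:
        scores = dict(evidence)
    for sepep in sepeps:
        sepep.score = score_sepep(sepep, scores)
    return list(sepeps)


def estimate_fdr(sepeps: Sequence[Sepep]) -> list[Sepep]:
    """Target-decoy q-values at the SEPEP level.

    SEPEPs are ranked by score descending (ties: decoys before targets,
    then lexicographically smallest member peptide).  At rank r the raw
    FDR is ``#decoys / max(1, #targets)`` among the top r, clamped to 1;
    the q-value is the running minimum of raw FDR from the bottom up, so
    q is monotone non-decreasing along the ranking.  Input order is
    preserved; only ``q_value`` is set.
    """
    if not sepeps:
        raise ValueError("no SEPEPs to estimate FDR on")
    for sepep in sepeps:
        if sepep.score is None:
            raise ValueError(f"unscored SEPEP {sepep.protein_key}")
    ranked = sorted(
        sepeps,
        key=lambda s: (-s.score, 0 if s.is_decoy else 1, s.smallest_peptide),
    )
    n_decoys = n_targets = 0
    raw: list[float] = []
    for sepep in ranked:
        if sepep.is_decoy:
            n_decoys += 1
        else:
            n_targets += 1
        raw.append(min(1.0, n_decoys / max(1, n_targets)))
    running_min = 1.0
    for i in range(len(ranked) - 1, -1, -1):
        running_min = min(running_min, raw[i])
        ranked[i].q_value = running_min
    return list(sepeps)


def filter_fdr(sepeps: Sequence[Sepep], threshold: float = 0.01) -> list[Sepep]:
    """Retain target SEPEPs with q-value <= threshold; drop all decoys.

    Logs the number of rejected target SEPEPs and their mean member
    count (rejected SEPEPs are typically single-peptide identifications).
    """
    if not 0 < threshold <= 1:
        raise ValueError("FDR threshold must be in (0, 1]")
    for sepep in sepeps:
        if sepep.q_value is None:
            raise ValueError("q-values must be estimated before filtering")
    targets = [s for s in sepeps if not s.is_decoy]
    kept = [s for s in targets if s.q_value <= threshold]
    rejected = [s for s in targets if s.q_value > threshold]
    if rejected:
        mean_members = float(np.mean([s.n_peptides for s in rejected]))
        logger.info(
            "FDR filter rejected %d target SEPEPs (mean member peptides %.2f)",
            len(rejected),
            mean_members,
        )
    return kept


def classify_sepep(sepep: Sepep, db: ProteomeDatabase) -> str:
    """Assign the C1..C5 class from the SEPEP's protein neighborhood.

    Mixed target/decoy neighborhoods are classified on the target
    proteins only (the SEPEP is a target hit; decoy members are
    competition artifacts).
    """
    if sepep.is_decoy:
        raise ValueError("decoy SEPEPs are not classified")
    targets = {a for a in sepep.protein_set if a in db and not db.is_decoy(a)}
    return CLASS_LABELS[classify_peptide(targets, db)]


def classify_sepeps(sepeps: Sequence[Sepep], db: ProteomeDatabase) -> list[Sepep]:
    for sepep in sepeps:
        sepep.sepep_class = classify_sepep(sepep, db)
    return list(sepeps)


def name_sepeps(sepeps: Sequence[Sepep]) -> list[Sepep]:
    """Assign deterministic, study-unique names.

    Single-gene SEPEPs (C1-C4) are numbered within their gene as
    ``<GENE>_SEPEP.<k>_C<class>``; multi-gene SEPEPs are numbered
    study-wide as ``Multiple_SEPEP.<k>_C5`` ordered by their sorted
    concatenated gene key.  Ordering is descending member-peptide count
    with ties broken by the lexicographically smallest member peptide,
    so re-running on shuffled input yields identical names.
    """
    for sepep in sepeps:
        if sepep.sepep_class is None:
            raise ValueError("SEPEPs must be classified before naming")
    by_gene: dict[str, list[Sepep]] = {}
    multi: list[Sepep] = []
    for sepep in sepeps:
        if sepep.sepep_class == "C5":
            multi.append(sepep)
        else:
            by_gene.setdefault(next(iter(sepep.gene_set)), []).append(sepep)
    for gene, members in by_gene.items():
        members.sort(key=lambda s: (-s.n_peptides, s.smallest_peptide))
        for k, sepep in enumerate(members, start=1):
            sepep.name = f"{gene}_SEPEP.{k}_{sepep.sepep_class}"
    multi.sort(key=lambda s: (s.gene_key, -s.n_peptides, s.smallest_peptide))
    for k, sepep in enumerate(multi, start=1):
        sepep.name = f"Multiple_SEPEP.{k}_C5"
    return list(sepeps)


def build_mapping_table(sepeps: Sequence[Sepep]) -> pd.DataFrame:
    """One row per named SEPEP with the alphabetically sorted join keys.

    The protein key (sorted accessions joined by ';') is the cross-study
    join key: two studies observing the same protein neighborhood produce
    the same key regardless of internal numbering.
    """
    rows = []
    for sepep in sepeps:
        if sepep.name is None:
            raise ValueError("SEPEPs must be named before building the table")
        rows.append(
            {
                "name": sepep.name,
                "class": sepep.sepep_class,
                "gene_key": sepep.gene_key,
                "protein_key": sepep.protein_key,
                "peptides": KEY_DELIMITER.join(sepep.member_peptides),
                "n_peptides": sepep.n_peptides,
                "q_value": sepep.q_value,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "name", "class", "gene_key", "protein_key",
            "peptides", "n_peptides", "q_value",
        ],
    )
    return table.sort_values("name", kind="mergesort").reset_index(drop=True)
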