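"""End-to-end study analysis: database -> graph -> SEPEPs -> quantification.

:func:`analyze_study` runs the in-memory chain (decoys, indexing,
exhaustive re-mapping, SEPEP identification, target-decoy FDR, class
assignment, naming, rollup, normalization, missingness filter, mapping
table); :func:`run_pipeline` is the file-based wrapper used by the CLI.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .io import read_evidence
from .proteome import PeptideIndex, ProteomeDatabase, load_fasta, generate_decoys
from .quant import (
    Platform,
    QuantMatrix,
    apply_normalization,
    filter_missing,
    median_center,
    rollup_gene,
    rollup_label_free,
    rollup_ratio,
)
from .sepeps import (
    EvidenceSet,
    Sepep,
    build_graph,
    build_mapping_table,
    classify_sepeps,
    estimate_fdr,
    filter_fdr,
    identify_sepeps,
    name_sepeps,
    score_sepeps,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a file-based run (defaults: FDR 0.01,
    missingness 0.5, decoy prefix ``rev_``)."""

    fasta: Path
    gene_map: Path
    evidence: Path
    out_dir: Path
    platform: str = "ratio"
    decoy_prefix: str = "rev_"
    fdr_threshold: float = 0.01
    max_missing_fraction: float = 0.5
    il_equivalent: bool = False
    trust_mappings: bool = False


@dataclass
class StudyResult:
    """In-memory results of one analyzed study."""

    sepeps: list[Sepep]  # FDR-passing, classified, named
    all_sepeps: list[Sepep]  # including decoys and rejected targets
    mapping_table: pd.DataFrame
    sepep_matrix: QuantMatrix  # quantifiable (post-filter), normalized if ratio
    gene_matrix: QuantMatrix
    normalization_factors: pd.Series | None
    sepep_to_gene: dict[str, str]  # single-gene SEPEP name -> host gene
    n_unmapped: int


def analyze_study(
    db: ProteomeDatabase,
    evidence: EvidenceSet,
    fdr_threshold: float = 0.01,
    max_missing_fraction: float = 0.5,
    il_equivalent: bool = False,
    trust_mappings: bool = False,
) -> StudyResult:
    """Run the full SEPEP chain on an in-memory database and evidence set.

    The database may be target-only (decoys are generated) or already
    decoy-augmented.  Ratio studies are normalized by per-sample median
    centering derived from the gene-level matrix; label-free PSM sums
    are left unnormalized.
    """
    if not db.has_decoys:
        db = generate_decoys(db)
    index = PeptideIndex(db, il_equivalent=il_equivalent)
    graph = build_graph(evidence, db, index=index, trust_mappings=trust_mappings)
    sepeps = identify_sepeps(graph)
    score_sepeps(sepeps, evidence)
    estimate_fdr(sepeps)
    passing = filter_fdr(sepeps, threshold=fdr_threshold)
    classify_sepeps(passing, db)
    name_sepeps(passing)
    mapping_table = build_mapping_table(passing)

    if evidence.platform == Platform.LABEL_FREE_PSM.value:
        sepep_matrix = rollup_label_free(passing, evidence)
    else:
        sepep_matrix = rollup_ratio(passing, evidence)
    gene_matrix = rollup_gene(evidence, db)

    factors = None
    if evidence.platform == Platform.LOG_RATIO.value:
        factors = median_center(gene_matrix)
        gene_matrix = apply_normalization(gene_matrix, factors)
        sepep_matrix = apply_normalization(sepep_matrix, factors)

    sepep_matrix = filter_missing(sepep_matrix, max_missing_fraction)
    gene_matrix = filter_missing(gene_matrix, max_missing_fraction)

    sepep_to_gene = {
        s.name: next(iter(s.gene_set))
        for s in passing
        if s.sepep_class != "C5" and s.name in sepep_matrix.data.index
    }
    return StudyResult(
        sepeps=passing,
        all_sepeps=sepeps,
        mapping_table=mapping_table,
        sepep_matrix=sepep_matrix,
        gene_matrix=gene_matrix,
        normalization_factors=factors,
        sepep_to_gene=sepep_to_gene,
        n_unmapped=graph.n_unmapped,
    )


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    digest.update(Path(path).read_bytes())
    return digest.hexdigest()


def fdr_report(sepeps: list[Sepep]) -> pd.DataFrame:
    rows = [
        {
            "protein_key": s.protein_key,
            "gene_key": s.gene_key,
            "n_peptides": s.n_peptides,
            "is_decoy": s.is_decoy,
            "score": s.score,
            "q_value": s.q_value,
        }
        for s in sorted(sepeps, key=lambda s: (s.q_value, -s.score, s.protein_key))
    ]
    return pd.DataFrame(
        rows, columns=["protein_key", "gene_key", "n_peptides", "is_decoy", "score", "q_value"]
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the file-based pipeline and write all study outputs.

    Writes the SEPEP quantification matrix, gene matrix, mapping table,
    FDR report, and a deterministic run log with input hashes and a
    parameter echo.  Any stage failure aborts with the stage named.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    stage = "load_database"
    try:
        db = load_fasta(config.fasta, config.gene_map, decoy_prefix=config.decoy_prefix)
        stage = "read_evidence"
        evidence = read_evidence(config.evidence, platform=config.platform)
        stage = "analyze"
        result = analyze_study(
            db,
            evidence,
            fdr_threshold=config.fdr_threshold,
            max_missing_fraction=config.max_missing_fraction,
            il_equivalent=config.il_equivalent,
            trust_mappings=config.trust_mappings,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    paths = {
        "sepep_matrix": out_dir / "sepep_matrix.tsv",
        "gene_matrix": out_dir / "gene_matrix.tsv",
        "mapping_table": out_dir / "mapping_table.tsv",
        "fdr_report": out_dir / "fdr_report.tsv",
        "run_log": out_dir / "run_log.txt",
    }
    result.sepep_matrix.to_tsv(paths["sepep_matrix"])
    result.gene_matrix.to_tsv(paths["gene_matrix"])
    result.mapping_table.to_csv(paths["mapping_table"], sep="\t", index=False, na_rep="NA")
    fdr_report(result.all_sepeps).to_csv(paths["fdr_report"], sep="\t", index=False)

    n_rejected = (
        len([s for s in result.all_sepeps if not s.is_decoy]) - len(result.sepeps)
    )
    log_lines = [
        "sepepkit run log",
        f"fasta\t{config.fasta}\t{_sha256(Path(config.fasta))}",
        f"gene_map\t{config.gene_map}\t{_sha256(Path(config.gene_map))}",
        f"evidence\t{config.evidence}\t{_sha256(Path(config.evidence))}",
        f"platform\t{config.platform}",
        f"decoy_prefix\t{config.decoy_prefix}",
        f"fdr_threshold\t{config.fdr_threshold}",
        f"max_missing_fraction\t{config.max_missing_fraction}",
        f"il_equivalent\t{config.il_equivalent}",
        f"trust_mappings\t{config.trust_mappings}",
        f"n_peptides\t{len(evidence)}",
        f"n_unmapped_peptides\t{result.n_unmapped}",
        f"n_sepeps_total\t{len(result.all_sepeps)}",
        f"n_sepeps_passing\t{len(result.sepeps)}",
        f"n_sepeps_rejected\t{n_rejected}",
        f"n_quantifiable_sepeps\t{len(result.sepep_matrix.features)}",
    ]
    paths["run_log"].write_text("\n".join(log_lines) + "\n")
    return paths
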