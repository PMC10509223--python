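"""Synthetic study generator with recorded ground truth.

Builds a self-contained proteomics study: a proteome in which most genes
carry several highly similar isoforms (derived from a base sequence by
exon-skip-like internal deletions or alternative N-termini, so shared
and isoform-specific tryptic peptides both exist), peptide evidence with
detection noise and decoy contamination, and planted isoform-specific
abundance effects whose identities are recorded for recovery scoring.

Peptide quantities mix additively across source isoforms on the linear
scale and are then logged: a peptide shared by isoforms with log2
abundances a and b has expected log2 value ``log2(2**a + 2**b)``.  This
is the physical model that makes parsimony-style rollup distort isoform
quantification, and the reason a shared-peptide group and an
isoform-specific group can move differently.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .digestion import DigestionParams, digest
from .proteome import PeptideIndex, ProteomeDatabase, ProteinRecord, generate_decoys
from .sepeps import EvidenceSet, PeptideEvidence

# residues for random segments; K/R reserved for termini, P excluded from
# segment starts so every segment boundary is a true cleavage site
_INTERIOR = "ACDEFGHILMNQSTVWY"
_INTERIOR_WITH_P = _INTERIOR + "P"


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    Defaults describe a TMT-like two-group study of 200 genes and 20
    samples with 20 planted isoform-specific effects of 1.0 log2 units,
    measurement noise sd 0.3, 5% decoy-origin contamination among
    reported peptides, 90% peptide detection, a 10% per-sample missing
    rate, minor isoforms at 10% of the dominant isoform's linear
    abundance, and gene-level biological sample variation of sd 0.2.
    """

    n_genes: int = 200
    isoform_count_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.25, 2: 0.35, 3: 0.25, 4: 0.15}
    )
    n_samples: int = 20
    design: str = "two_group"  # or "time_course"
    n_regulated_genes: int = 20
    effect_size: float = 1.0  # log2 units
    peptide_detection_probability: float = 0.9
    false_id_rate: float = 0.05
    noise_sd: float = 0.3
    per_sample_missing_rate: float = 0.1
    minor_isoform_fraction: float = 0.1
    biological_sd: float = 0.2
    paralog_fraction: float = 0.1  # genes sharing a segment run with a sibling
    psm_scale: float = 8.0
    n_segments: tuple[int, int] = (8, 14)
    segment_length: tuple[int, int] = (8, 18)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.peptide_detection_probability <= 1:
            raise ValueError("peptide_detection_probability must be in (0, 1]")
        if not 0 <= self.false_id_rate < 1:
            raise ValueError("false_id_rate must be in [0, 1)")
        if not 0 <= self.per_sample_missing_rate < 1:
            raise ValueError("per_sample_missing_rate must be in [0, 1)")
        if self.n_regulated_genes > self.n_genes:
            raise ValueError("n_regulated_genes cannot exceed n_genes")
        if self.design not in ("two_group", "time_course"):
            raise ValueError(f"unknown design {self.design!r}")
        total = sum(self.isoform_count_probs.values())
        if not np.isclose(total, 1.0):
            raise ValueError("isoform_count_probs must sum to 1")

    @property
    def digestion_params(self) -> DigestionParams:
        # identified peptides are dominated by zero-missed-cleavage products
        return DigestionParams(max_missed_cleavages=0, min_length=7, max_length=50)


@dataclass
class GroundTruth:
    """Everything needed to score recovery of the planted effects."""

    isoforms_by_gene: dict[str, list[str]]
    isoform_log2: pd.DataFrame  # accessions x samples, true log2 abundance
    regulated: list[tuple[str, str, int]]  # (gene, accession, direction)
    false_peptides: set[str]
    group_labels: np.ndarray | None = None
    covariate: np.ndarray | None = None

    @property
    def regulated_genes(self) -> set[str]:
        return {gene for gene, _, _ in self.regulated}


# ---------------------------------------------------------------------------
# proteome simulation


def _random_segment(rng: np.random.Generator, length: int) -> str:
    first = rng.choice(list(_INTERIOR))
    interior = rng.choice(list(_INTERIOR_WITH_P), size=max(0, length - 2))
    terminal = rng.choice(["K", "R"])
    return first + "".join(interior) + terminal


def _base_segments(
    rng: np.random.Generator,
    config: SimulationConfig,
    shared_from: list[str] | None = None,
) -> list[str]:
    """Random tryptic segments; paralogs inherit a run of segments from a
    sibling gene, creating multi-gene shared peptides."""
    n_seg = int(rng.integers(config.n_segments[0], config.n_segments[1] + 1))
    lo, hi = config.segment_length
    segments = [
        _random_segment(rng, int(rng.integers(lo, hi + 1))) for _ in range(n_seg)
    ]
    if shared_from:
        run = max(2, len(shared_from) // 3)
        start = int(rng.integers(0, len(shared_from) - run + 1))
        insert_at = int(rng.integers(0, len(segments)))
        segments[insert_at : insert_at + run] = shared_from[start : start + run]
    return segments


def _internal_deletion(rng: np.random.Generator, seq: str) -> str:
    """Delete a mid-sequence span starting and ending off cleavage boundaries,
    creating a junction peptide unique to the short variant."""
    n = len(seq)
    for _ in range(20):
        start = int(rng.integers(n // 6, n // 2))
        end = int(rng.integers(start + n // 6, min(n - 10, start + n // 2)))
        variant = seq[:start] + seq[end:]
        if len(variant) >= 20 and variant != seq:
            return variant
    raise ValueError("infeasible deletion parameters for this sequence")


def _exon_exchange(
    rng: np.random.Generator, seq: str, config: SimulationConfig
) -> str:
    """Replace a mid-sequence span with a novel segment, emulating mutually
    exclusive exon splicing: the variant gains junction and novel-exon
    peptides while keeping both flanks shared."""
    n = len(seq)
    lo, hi = config.segment_length
    for _ in range(20):
        start = int(rng.integers(n // 6, n // 2))
        end = int(rng.integers(start + n // 6, min(n - 10, start + n // 2)))
        novel = _random_segment(rng, int(rng.integers(lo, hi + 1)))
        variant = seq[:start] + novel + seq[end:]
        if variant != seq:
            return variant
    raise ValueError("infeasible exon-exchange parameters for this sequence")


def _alternative_n_terminus(
    rng: np.random.Generator, seq: str, config: SimulationConfig
) -> str:
    """Replace the N-terminal region up to a cleavage boundary with a novel
    segment, emulating an alternative first exon: the variant gains
    isoform-specific tryptic peptides instead of being a pure substring."""
    from .digestion import cleavage_sites

    sites = cleavage_sites(seq)
    if not sites:
        raise ValueError("sequence has no cleavage site for an alternative start")
    candidates = [s for s in sites if len(seq) // 8 <= s <= len(seq) // 2]
    if not candidates:
        candidates = sites[:1]
    cut = int(rng.choice(candidates))
    lo, hi = config.segment_length
    novel = _random_segment(rng, int(rng.integers(lo, hi + 1)))
    return novel + seq[cut:]


def _has_specific_peptide(
    variant: str, references: list[str], params: DigestionParams
) -> bool:
    """True if the variant yields >=1 length-filtered tryptic peptide that is
    not a substring of any reference isoform sequence."""
    for pep in digest(variant, params):
        if not any(pep.sequence in ref for ref in references):
            return True
    return False


def simulate_proteome(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    out_dir: str | Path | None = None,
) -> ProteomeDatabase:
    """Generate a target-only proteome with isoform structure.

    Each gene's first isoform is the full base sequence (the dominant
    form); further isoforms derive from it by an exon-skip-like internal
    deletion (40%), a mutually-exclusive-exon-like span exchange (30%)
    or an alternative N-terminal exon (30%), so flanking tryptic
    peptides are shared while junction / variant-specific peptides
    discriminate.  Every isoform is validated to carry at least one
    isoform-specific length-filtered tryptic peptide under substring
    mapping.
    Deterministic given the config seed; optionally writes the FASTA and
    gene-map TSV into *out_dir*.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    iso_counts = sorted(config.isoform_count_probs)
    iso_probs = [config.isoform_count_probs[k] for k in iso_counts]
    records: list[ProteinRecord] = []
    previous_segments: list[str] | None = None
    for g in range(config.n_genes):
        gene = f"GENE{g + 1:04d}"
        n_iso = int(rng.choice(iso_counts, p=iso_probs))
        shared = None
        if previous_segments is not None and rng.random() < config.paralog_fraction:
            shared = previous_segments
        segments = _base_segments(rng, config, shared_from=shared)
        previous_segments = segments
        base = "".join(segments)
        sequences = [base]
        params = config.digestion_params
        attempts = 0
        while len(sequences) < n_iso:
            attempts += 1
            if attempts > 50:
                raise ValueError(f"could not generate distinct isoforms for {gene}")
            draw = rng.random()
            if draw < 0.4:
                variant = _internal_deletion(rng, base)
            elif draw < 0.7:
                variant = _exon_exchange(rng, base, config)
            else:
                variant = _alternative_n_terminus(rng, base, config)
            # every isoform must carry both shared and isoform-specific
            # tryptic peptides under substring mapping
            if variant in sequences:
                continue
            if not _has_specific_peptide(variant, sequences, params):
                continue
            if not all(
                _has_specific_peptide(prev, sequences[:i] + sequences[i + 1:] + [variant], params)
                for i, prev in enumerate(sequences)
            ):
                continue
            sequences.append(variant)
        for i, seq in enumerate(sequences, start=1):
            records.append(ProteinRecord(f"{gene}.P{i}", gene, seq))
    db = ProteomeDatabase(records)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        db.write_fasta(out_dir / "proteome.fasta")
        db.write_gene_map(out_dir / "gene_map.tsv")
    return db


# ---------------------------------------------------------------------------
# evidence simulation


def _sample_axis(config: SimulationConfig) -> tuple[list[str], np.ndarray | None, np.ndarray | None]:
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    if config.design == "two_group":
        half = config.n_samples // 2
        labels = np.array(["A"] * half + ["B"] * (config.n_samples - half))
        return samples, labels, None
    covariate = np.linspace(0.0, 14.0, config.n_samples)
    return samples, None, covariate


def _isoform_abundances(
    db: ProteomeDatabase,
    config: SimulationConfig,
    rng: np.random.Generator,
    group_labels: np.ndarray | None,
    covariate: np.ndarray | None,
) -> tuple[pd.DataFrame, list[tuple[str, str, int]]]:
    """True per-sample log2 abundance for every isoform, with planted effects
    applied to one minor isoform of each regulated multi-isoform gene."""
    n = config.n_samples
    target_genes = sorted(
        g
        for g, rec in db.genes.items()
        if not any(db.is_decoy(a) for a in rec.isoform_accessions)
    )
    multi_iso_genes = [g for g in target_genes if db.genes[g].n_isoforms >= 2]
    n_reg = min(config.n_regulated_genes, len(multi_iso_genes))
    if config.effect_size == 0:
        regulated_genes: list[str] = []
    else:
        regulated_genes = sorted(
            rng.choice(multi_iso_genes, size=n_reg, replace=False)
        )
    regulated: list[tuple[str, str, int]] = []

    abundances: dict[str, np.ndarray] = {}
    for gene in target_genes:
        rec = db.genes[gene]
        gene_bio = rng.normal(0.0, config.biological_sd, size=n)
        reg_acc, direction = None, 0
        if gene in regulated_genes:
            minor = list(rec.isoform_accessions[1:])
            reg_acc = str(rng.choice(minor))
            direction = int(rng.choice([-1, 1]))
            regulated.append((gene, reg_acc, direction))
        for i, acc in enumerate(rec.isoform_accessions):
            weight = 1.0 if i == 0 else config.minor_isoform_fraction
            a = np.log2(weight) + gene_bio
            if acc == reg_acc:
                if group_labels is not None:
                    a = a + direction * config.effect_size * (group_labels == "B")
                else:
                    trend = (covariate - covariate.mean()) / (
                        covariate.max() - covariate.min()
                    )
                    a = a + direction * config.effect_size * trend
            abundances[acc] = a
    table = pd.DataFrame.from_dict(abundances, orient="index")
    return table, regulated


def simulate_evidence(
    db: ProteomeDatabase,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[EvidenceSet, GroundTruth]:
    """Draw peptide evidence from a decoy-augmented database.

    Each unique fully tryptic target peptide is detected with the
    configured probability; its log2 ratio per sample is the log of the
    summed linear abundances of its source isoforms plus Gaussian noise,
    with per-sample dropout; PSM counts are Poisson draws proportional
    to the linear abundance.  A ``false_id_rate`` fraction of reported
    peptides is drawn from decoy-only sequences with low scores.
    """
    if not db.has_decoys:
        raise ValueError("simulate_evidence needs a database with decoys")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    samples, group_labels, covariate = _sample_axis(config)
    n = config.n_samples

    iso_log2, regulated = _isoform_abundances(db, config, rng, group_labels, covariate)
    iso_log2.columns = samples
    iso_linear = np.power(2.0, iso_log2.to_numpy())
    iso_row = {acc: i for i, acc in enumerate(iso_log2.index)}

    params = config.digestion_params
    target_peptides: set[str] = set()
    for rec in db.target_records():
        target_peptides.update(p.sequence for p in digest(rec.sequence, params))

    index = PeptideIndex(db)
    evidence: list[PeptideEvidence] = []
    for pep in sorted(target_peptides):
        if rng.random() > config.peptide_detection_probability:
            continue
        hits = index.lookup(pep)
        target_hits = [a for a in hits if not db.is_decoy(a)]
        if not target_hits:
            continue
        linear = np.sum([iso_linear[iso_row[a]] for a in target_hits], axis=0)
        expected = np.log2(linear)
        ratios = expected + rng.normal(0.0, config.noise_sd, size=n)
        dropout = rng.random(n) < config.per_sample_missing_rate
        ratios[dropout] = np.nan
        psm = rng.poisson(config.psm_scale * linear).astype(float)
        evidence.append(
            PeptideEvidence(
                sequence=pep,
                best_score=float(rng.beta(8.0, 2.0)),
                quantities=ratios,
                psm_counts=psm,
                mapped_proteins=frozenset(hits),
            )
        )
    if not evidence:
        raise ValueError("no detectable target peptides under this configuration")

    # decoy-origin contamination: peptides digestible only from decoys
    false_peptides: set[str] = set()
    if config.false_id_rate > 0:
        decoy_peptides: set[str] = set()
        for acc in db.decoy_accessions():
            decoy_peptides.update(
                p.sequence for p in digest(db.proteins[acc].sequence, params)
            )
        decoy_only = sorted(
            pep
            for pep in decoy_peptides - target_peptides
            if not any(not db.is_decoy(a) for a in index.lookup(pep))
        )
        n_false = int(round(
            len(evidence) * config.false_id_rate / (1 - config.false_id_rate)
        ))
        n_false = min(n_false, len(decoy_only))
        chosen = rng.choice(decoy_only, size=n_false, replace=False)
        for pep in sorted(chosen):
            ratios = rng.normal(0.0, config.noise_sd, size=n)
            ratios[rng.random(n) < config.per_sample_missing_rate] = np.nan
            evidence.append(
                PeptideEvidence(
                    sequence=pep,
                    best_score=float(rng.beta(2.0, 8.0)),
                    quantities=ratios,
                    psm_counts=rng.poisson(1.0, size=n).astype(float),
                    mapped_proteins=index.lookup(pep),
                )
            )
            false_peptides.add(pep)

    evidence.sort(key=lambda ev: ev.sequence)
    truth = GroundTruth(
        isoforms_by_gene={
            g: list(rec.isoform_accessions)
            for g, rec in sorted(db.genes.items())
            if not any(db.is_decoy(a) for a in rec.isoform_accessions)
        },
        isoform_log2=iso_log2,
        regulated=regulated,
        false_peptides=false_peptides,
        group_labels=group_labels,
        covariate=covariate,
    )
    return EvidenceSet(evidence, samples, platform="ratio"), truth


def simulate_study(
    config: SimulationConfig, out_dir: str | Path | None = None
) -> tuple[ProteomeDatabase, EvidenceSet, GroundTruth]:
    """One-call study generation behind a single seeded generator.

    Returns the decoy-augmented database, the evidence set and the
    ground truth; optionally writes FASTA, gene map, evidence TSV,
    ground-truth TSV and a config echo into *out_dir*.
    """
    rng = np.random.default_rng(config.seed)
    targets = simulate_proteome(config, rng=rng, out_dir=out_dir)
    db = generate_decoys(targets)
    evidence, truth = simulate_evidence(db, config, rng=rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_evidence(evidence, out_dir / "evidence.tsv")
        write_ground_truth(truth, out_dir / "ground_truth.tsv")
        write_sample_metadata(truth, evidence.samples, out_dir / "samples.tsv")
        _echo_config(config, out_dir / "config.tsv")
    return db, evidence, truth


# ---------------------------------------------------------------------------
# output writers


def write_evidence(evidence: EvidenceSet, path: str | Path) -> None:
    """Write evidence as TSV: peptide, best_score, one column per sample.

    Ratio studies write log2 ratios (NA = missing); label-free studies
    write PSM counts.
    """
    rows = []
    for ev in evidence.peptides:
        row: dict = {"peptide": ev.sequence, "best_score": ev.best_score}
        values = ev.quantities if evidence.platform == "ratio" else ev.psm_counts
        for sample, value in zip(evidence.samples, values):
            row[sample] = value
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = [
        {"gene": gene, "accession": acc, "direction": direction}
        for gene, acc, direction in truth.regulated
    ]
    pd.DataFrame(rows, columns=["gene", "accession", "direction"]).to_csv(
        path, sep="\t", index=False
    )


def write_sample_metadata(
    truth: GroundTruth, samples: list[str], path: str | Path
) -> None:
    table = pd.DataFrame({"sample": samples})
    if truth.group_labels is not None:
        table["group"] = truth.group_labels
    if truth.covariate is not None:
        table["day"] = truth.covariate
    table.to_csv(path, sep="\t", index=False)


def _echo_config(config: SimulationConfig, path: str | Path) -> None:
    rows = []
    for key, value in vars(config).items():
        rows.append({"parameter": key, "value": repr(value)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery scoring


def recovery_metrics(
    discordance: pd.DataFrame, truth: GroundTruth
) -> dict[str, float]:
    """Sensitivity and false-discovery proportion for planted gene recovery.

    A planted gene counts as recovered when any of its SEPEPs falls in
    the ``sepep_only`` or ``opposite_sign`` category; reported genes not
    planted count toward the false-discovery proportion.
    """
    flagged = discordance[discordance["category"].isin(["sepep_only", "opposite_sign"])]
    reported = set(flagged["gene"])
    planted = truth.regulated_genes
    sensitivity = len(reported & planted) / len(planted) if planted else float("nan")
    fdp = len(reported - planted) / max(1, len(reported))
    return {
        "sensitivity": sensitivity,
        "fdp": fdp,
        "n_reported": float(len(reported)),
        "n_planted": float(len(planted)),
    }
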