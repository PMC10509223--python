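"""SEPEP- and gene-level quantification rollup, normalization and filtering.

Label-free data roll up as the sum of member-peptide PSM counts (a zero
total means nothing was observed and is recorded as missing); isobaric
ratio data roll up as the median of the member peptides' non-missing
log2 ratios.  Gene-level rollup applies the same rules to all peptides
whose host-gene set is exactly one gene; multi-gene peptides contribute
to no gene row.  Ratio matrices are median-centered per sample using
factors derived from the gene-level matrix, and features with more than
50% missing values are dropped as non-quantifiable.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .proteome import ProteomeDatabase
from .sepeps import EvidenceSet, Sepep

MISSING_TOKEN = "NA"


def _nanmedian(stacked: np.ndarray) -> np.ndarray:
    """Column-wise median over observed values; NaN where none observed."""
    out = np.full(stacked.shape[1], np.nan)
    observed = ~np.isnan(stacked)
    cols = observed.any(axis=0)
    if cols.any():
        out[cols] = np.nanmedian(stacked[:, cols], axis=0)
    return out


class Platform(str, Enum):
    LABEL_FREE_PSM = "label_free"
    LOG_RATIO = "ratio"


@dataclass
class QuantMatrix:
    """Features x samples table with NaN as the missing marker."""

    data: pd.DataFrame
    platform: Platform

    def __post_init__(self) -> None:
        self.platform = Platform(self.platform)
        if self.platform is Platform.LABEL_FREE_PSM:
            values = self.data.to_numpy(dtype=float)
            if np.nanmin(values, initial=0.0) < 0:
                raise ValueError("label-free PSM matrix must be non-negative")

    @property
    def features(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    def missing_fraction(self) -> pd.Series:
        return self.data.isna().mean(axis=1)

    def to_tsv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "feature"
        out.to_csv(path, sep="\t", na_rep=MISSING_TOKEN)

    @classmethod
    def from_tsv(cls, path: str | Path, platform: Platform | str) -> "QuantMatrix":
        data = pd.read_csv(path, sep="\t", index_col="feature", na_values=[MISSING_TOKEN])
        return cls(data, Platform(platform))


#: Per-sample log2 offsets, indexed by sample name.
NormalizationFactors = pd.Series


def _feature_id(sepep: Sepep) -> str:
    return sepep.name if sepep.name is not None else sepep.protein_key


def rollup_label_free(sepeps: Sequence[Sepep], evidence: EvidenceSet) -> QuantMatrix:
    """Sum member-peptide PSM counts per sample; zero totals become missing."""
    lookup = evidence.by_sequence()
    rows = {}
    for sepep in sepeps:
        total = np.zeros(len(evidence.samples), dtype=float)
        for pep in sepep.member_peptides:
            ev = lookup.get(pep)
            if ev is None:
                continue
            if ev.psm_counts is None:
                raise ValueError(f"peptide {pep!r} lacks PSM counts")
            total += np.asarray(ev.psm_counts, dtype=float)
        rows[_feature_id(sepep)] = np.where(total > 0, total, np.nan)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=evidence.samples)
    return QuantMatrix(data, Platform.LABEL_FREE_PSM)


def rollup_ratio(sepeps: Sequence[Sepep], evidence: EvidenceSet) -> QuantMatrix:
    """Median of member peptides' non-missing log2 ratios per sample."""
    lookup = evidence.by_sequence()
    rows = {}
    for sepep in sepeps:
        member_values = [
            np.asarray(lookup[pep].quantities, dtype=float)
            for pep in sepep.member_peptides
            if pep in lookup and lookup[pep].quantities is not None
        ]
        if not member_values:
            rows[_feature_id(sepep)] = np.full(len(evidence.samples), np.nan)
            continue
        stacked = np.vstack(member_values)
        rows[_feature_id(sepep)] = _nanmedian(stacked)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=evidence.samples)
    return QuantMatrix(data, Platform.LOG_RATIO)


def rollup_gene(evidence: EvidenceSet, db: ProteomeDatabase) -> QuantMatrix:
    """Gene-level rollup over single-gene peptides, mirroring the SEPEP rules.

    A peptide contributes to a gene only when its mapped target proteins
    all belong to that one gene; multi-gene peptides are excluded.
    """
    by_gene: dict[str, list] = {}
    for ev in evidence.peptides:
        target_accs = [a for a in ev.mapped_proteins if a in db and not db.is_decoy(a)]
        if not target_accs:
            continue
        genes = {db.gene_of(a) for a in target_accs}
        if len(genes) != 1:
            continue
        by_gene.setdefault(next(iter(genes)), []).append(ev)

    rows = {}
    n = len(evidence.samples)
    for gene in sorted(by_gene):
        members = by_gene[gene]
        if evidence.platform == Platform.LABEL_FREE_PSM.value:
            total = np.zeros(n, dtype=float)
            for ev in members:
                total += np.asarray(ev.psm_counts, dtype=float)
            rows[gene] = np.where(total > 0, total, np.nan)
        else:
            stacked = np.vstack(
                [np.asarray(ev.quantities, dtype=float) for ev in members]
            )
            rows[gene] = _nanmedian(stacked)
    data = pd.DataFrame.from_dict(rows, orient="index", columns=evidence.samples)
    platform = Platform(evidence.platform)
    return QuantMatrix(data, platform)


def median_center(gene_matrix: QuantMatrix) -> NormalizationFactors:
    """Per-sample normalization factors: the median observed gene-level value."""
    if gene_matrix.platform is not Platform.LOG_RATIO:
        raise ValueError("median centering applies to log-ratio matrices")
    factors = gene_matrix.data.median(axis=0, skipna=True)
    if factors.isna().any():
        bad = list(factors.index[factors.isna()])
        raise ValueError(f"samples with no observed gene values: {bad}")
    return factors


def apply_normalization(
    matrix: QuantMatrix, factors: NormalizationFactors
) -> QuantMatrix:
    """Subtract the per-sample factor from every cell; missing stays missing."""
    if matrix.platform is not Platform.LOG_RATIO:
        raise ValueError("normalization applies to log-ratio matrices")
    missing = set(matrix.samples) - set(factors.index)
    if missing:
        raise ValueError(f"no normalization factor for samples: {sorted(missing)}")
    data = matrix.data.sub(factors[matrix.samples], axis=1)
    return QuantMatrix(data, matrix.platform)


def filter_missing(
    matrix: QuantMatrix, max_missing_fraction: float = 0.5
) -> QuantMatrix:
    """Drop features with missing fraction strictly above the threshold.

    A feature missing in exactly half the samples is retained ("more
    than 50% missing" read strictly).  Idempotent.
    """
    if not 0 <= max_missing_fraction <= 1:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    keep = matrix.missing_fraction() <= max_missing_fraction
    return QuantMatrix(matrix.data.loc[keep], matrix.platform)
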