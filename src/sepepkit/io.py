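"""Evidence readers and small IO helpers.

The evidence contract is one generic headered TSV: a ``peptide`` column
(modification annotations such as bracketed masses or lowercase flags
are stripped to the bare uppercase sequence), a ``best_score`` column,
and one numeric quantity column per sample (PSM counts for label-free
studies, log2 ratios for isobaric studies; ``NA`` marks missing).
Search-engine peptide reports convert by column renaming only.
"""
from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .sepeps import EvidenceSet, PeptideEvidence

_BRACKETED = re.compile(r"\[[^\]]*\]|\([^)]*\)|\{[^}]*\}")

RESERVED_COLUMNS = ("peptide", "best_score", "mapped_proteins")


def strip_modifications(peptide: str) -> str:
    """Reduce a modified peptide string to its bare uppercase sequence."""
    bare = _BRACKETED.sub("", peptide)
    return "".join(c for c in bare if c.isalpha() and c.isupper())


def read_evidence(
    path: str | Path,
    platform: str,
    sample_columns: list[str] | None = None,
) -> EvidenceSet:
    """Read an evidence TSV into an :class:`EvidenceSet`.

    Rows collapsing to the same stripped sequence are combined: PSM
    counts summed, ratios averaged over observed values, best_score the
    maximum.  An optional semicolon-separated ``mapped_proteins`` column
    is carried along (used only with ``trust_mappings``).  Non-numeric
    quantity cells are an error naming the row.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    if "peptide" not in table.columns:
        raise ValueError(f"{path}: missing required 'peptide' column")
    if sample_columns is None:
        sample_columns = [c for c in table.columns if c not in RESERVED_COLUMNS]
    if not sample_columns:
        raise ValueError(f"{path}: no sample quantity columns resolved")

    values = np.empty((len(table), len(sample_columns)), dtype=float)
    for j, col in enumerate(sample_columns):
        if col not in table.columns:
            raise ValueError(f"{path}: sample column {col!r} not found")
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() & table[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based plus header line
            raise ValueError(
                f"{path}: non-numeric quantity {table[col][bad.idxmax()]!r} "
                f"in column {col!r}, line {row}"
            )
        values[:, j] = numeric.to_numpy()

    if "best_score" in table.columns:
        scores = pd.to_numeric(table["best_score"], errors="coerce").fillna(0.0)
    else:
        scores = pd.Series(1.0, index=table.index)
    stripped = table["peptide"].map(strip_modifications)
    if (stripped == "").any():
        raise ValueError(f"{path}: row with empty peptide sequence after stripping")

    mapped = None
    if "mapped_proteins" in table.columns:
        mapped = table["mapped_proteins"].fillna("")

    peptides: list[PeptideEvidence] = []
    for seq, idx in stripped.groupby(stripped).groups.items():
        rows = values[np.asarray(idx)]
        best = float(scores.iloc[np.asarray(idx)].max())
        proteins: frozenset[str] = frozenset()
        if mapped is not None:
            proteins = frozenset(
                acc
                for cell in mapped.iloc[np.asarray(idx)]
                for acc in str(cell).split(";")
                if acc
            )
        if platform == "label_free":
            counts = np.nansum(np.nan_to_num(rows, nan=0.0), axis=0)
            peptides.append(
                PeptideEvidence(seq, best, psm_counts=counts, mapped_proteins=proteins)
            )
        else:
            observed = ~np.isnan(rows)
            ratios = np.full(rows.shape[1], np.nan)
            cols = observed.any(axis=0)
            if cols.any():
                ratios[cols] = np.nanmean(rows[:, cols], axis=0)
            peptides.append(
                PeptideEvidence(seq, best, quantities=ratios, mapped_proteins=proteins)
            )
    peptides.sort(key=lambda ev: ev.sequence)
    return EvidenceSet(peptides, list(sample_columns), platform=platform)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV with a ``sample`` column."""
    table = pd.read_csv(path, sep="\t")
    if "sample" not in table.columns:
        raise ValueError(f"{path}: missing required 'sample' column")
    return table
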