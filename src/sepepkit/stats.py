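"""Downstream statistics for isoform-level regulation.

Two-group differential tests (two-sided t, Welch by default), covariate
Pearson correlation tests, Benjamini-Hochberg adjustment across tested
features, SEPEP-host-gene concordance correlations, and the discordance
report that flags SEPEPs significant without matching significance at
the host-gene level (the signature of isoform-specific regulation).
"""
from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .quant import QuantMatrix

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["statistic", "p_value", "adjusted_p", "direction", "n_used", "tested"]

CATEGORIES = ("concordant", "sepep_only", "opposite_sign")


def _frame(matrix: QuantMatrix | pd.DataFrame) -> pd.DataFrame:
    return matrix.data if isinstance(matrix, QuantMatrix) else matrix


def _adjust(results: pd.DataFrame) -> pd.DataFrame:
    tested = results["tested"]
    if tested.any():
        adjusted = multipletests(
            results.loc[tested, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
        results.loc[tested, "adjusted_p"] = adjusted
    return results


def differential_test(
    matrix: QuantMatrix | pd.DataFrame,
    group_labels: Sequence,
    paired: bool = False,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Two-sided t test per feature between the two levels of *group_labels*.

    Unpaired tests use Welch's t by default; ``paired=True`` runs the
    classic paired t over complete pairs.  Each feature uses its own
    non-missing observations and needs at least two per group (two
    complete pairs if paired); features failing that are reported with
    ``tested=False`` rather than dropped.  The statistic is group2 minus
    group1 in sorted label order; ``direction`` is its sign.  Adjusted
    p-values are Benjamini-Hochberg across all tested features.
    """
    data = _frame(matrix)
    labels = np.asarray(group_labels)
    if len(labels) != data.shape[1]:
        raise ValueError("group_labels length must match the sample count")
    levels = sorted(pd.unique(labels))
    if len(levels) != 2:
        raise ValueError(f"need exactly two group levels, got {levels}")
    mask_a = labels == levels[0]
    mask_b = labels == levels[1]
    if paired and mask_a.sum() != mask_b.sum():
        raise ValueError("paired test requires equally sized groups")

    rows = []
    for feature, values in data.iterrows():
        x = values.to_numpy(dtype=float)
        a, b = x[mask_a], x[mask_b]
        if paired:
            ok = ~np.isnan(a) & ~np.isnan(b)
            a, b = a[ok], b[ok]
            enough = ok.sum() >= 2 and not np.allclose(b - a, (b - a)[0])
        else:
            a, b = a[~np.isnan(a)], b[~np.isnan(b)]
            enough = len(a) >= 2 and len(b) >= 2
        if not enough:
            logger.info("feature %s skipped: insufficient observations", feature)
            rows.append((feature, np.nan, np.nan, np.nan, 0, 0, False))
            continue
        if paired:
            t, p = sps.ttest_rel(b, a)
        else:
            t, p = sps.ttest_ind(b, a, equal_var=equal_var)
        effect = float(np.mean(b) - np.mean(a))
        rows.append((feature, float(t), float(p), np.nan, np.sign(effect), len(a) + len(b), True))

    results = pd.DataFrame(
        rows,
        columns=["feature", "statistic", "p_value", "adjusted_p", "direction", "n_used", "tested"],
    ).set_index("feature")
    return _adjust(results)


def covariate_correlation(
    matrix: QuantMatrix | pd.DataFrame, covariate: Sequence[float]
) -> pd.DataFrame:
    """Pearson r and two-sided p per feature against a numeric covariate.

    Pairwise-complete observations per feature; at least three complete
    pairs and non-zero variance required, otherwise the feature is
    reported untested.  BH adjustment across tested features.
    """
    data = _frame(matrix)
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != data.shape[1]:
        raise ValueError("covariate length must match the sample count")
    if np.allclose(cov, cov[0]):
        raise ValueError("constant covariate")

    rows = []
    for feature, values in data.iterrows():
        x = values.to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(cov)
        if ok.sum() < 3 or np.allclose(x[ok], x[ok][0]) or np.allclose(cov[ok], cov[ok][0]):
            rows.append((feature, np.nan, np.nan, np.nan, 0, 0, False))
            continue
        r, p = sps.pearsonr(x[ok], cov[ok])
        rows.append((feature, float(r), float(p), np.nan, np.sign(r), int(ok.sum()), True))

    results = pd.DataFrame(
        rows,
        columns=["feature", "statistic", "p_value", "adjusted_p", "direction", "n_used", "tested"],
    ).set_index("feature")
    return _adjust(results)


def sepep_gene_correlation(
    sepep_matrix: QuantMatrix | pd.DataFrame,
    gene_matrix: QuantMatrix | pd.DataFrame,
    mapping: Mapping[str, str],
) -> pd.Series:
    """Pearson correlation of each single-gene SEPEP with its host gene.

    Computed over samples where both profiles are observed; NaN when
    fewer than three complete pairs remain or either profile has zero
    variance.  SEPEPs whose host gene has no row are skipped with a
    warning.
    """
    sepep_data = _frame(sepep_matrix)
    gene_data = _frame(gene_matrix)
    out = {}
    for sepep_name, gene in mapping.items():
        if sepep_name not in sepep_data.index:
            continue
        if gene not in gene_data.index:
            logger.warning("SEPEP %s: host gene %s not quantified; skipped", sepep_name, gene)
            continue
        x = sepep_data.loc[sepep_name].to_numpy(dtype=float)
        y = gene_data.loc[gene].to_numpy(dtype=float)
        ok = ~np.isnan(x) & ~np.isnan(y)
        if ok.sum() < 3 or np.allclose(x[ok], x[ok][0]) or np.allclose(y[ok], y[ok][0]):
            out[sepep_name] = np.nan
            continue
        out[sepep_name] = float(sps.pearsonr(x[ok], y[ok])[0])
    return pd.Series(out, name="r", dtype=float)


def discordance_report(
    sepep_results: pd.DataFrame,
    gene_results: pd.DataFrame,
    mapping: Mapping[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Categorise each single-gene SEPEP against its host-gene test result.

    ``sepep_only``: SEPEP significant (BH-adjusted p < alpha) while the
    gene is not.  ``opposite_sign``: both significant with opposite
    effect directions.  ``concordant``: everything else.  Both result
    frames must already carry BH-adjusted p-values (as produced by
    :func:`differential_test` / :func:`covariate_correlation`).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    rows = []
    for sepep_name, gene in mapping.items():
        if sepep_name not in sepep_results.index or gene not in gene_results.index:
            continue
        s = sepep_results.loc[sepep_name]
        g = gene_results.loc[gene]
        if not (s.get("tested", True) and g.get("tested", True)):
            continue
        s_sig = s["adjusted_p"] < alpha
        g_sig = g["adjusted_p"] < alpha
        if s_sig and not g_sig:
            category = "sepep_only"
        elif s_sig and g_sig and s["direction"] * g["direction"] < 0:
            category = "opposite_sign"
        else:
            category = "concordant"
        rows.append(
            {
                "sepep": sepep_name,
                "gene": gene,
                "sepep_direction": s["direction"],
                "gene_direction": g["direction"],
                "sepep_adjusted_p": s["adjusted_p"],
                "gene_adjusted_p": g["adjusted_p"],
                "category": category,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sepep", "gene", "sepep_direction", "gene_direction",
            "sepep_adjusted_p", "gene_adjusted_p", "category",
        ],
    )


def discordance_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Counts of unique SEPEPs and unique host genes per category."""
    rows = []
    for category in CATEGORIES:
        sub = report[report["category"] == category]
        rows.append(
            {
                "category": category,
                "n_sepeps": sub["sepep"].nunique(),
                "n_genes": sub["gene"].nunique(),
            }
        )
    return pd.DataFrame(rows)
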