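"""Count normalization, expression filtering and differential expression.

The network stage needs a normalized expression matrix restricted to genes
that are reliably detected and differentially expressed between tumor and
reference samples.  Normalization is log2(CPM + 1); the two-group test is a
Wilcoxon rank-sum with Benjamini-Hochberg FDR control.  The stage is
deliberately pluggable: an externally computed differential-expression table
in the same schema can be substituted for :func:`differential_expression`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, REFERENCE, TUMOR

DE_COLUMNS = ["symbol", "biotype", "log2fc", "pvalue", "fdr", "is_de"]


def normalize_counts(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Return log2(CPM + 1) expression.

    Each sample's counts are scaled to sum to one million before the log
    transform.  A sample with zero library size has no defined CPM and is a
    hard error.
    """
    arr = counts.values.to_numpy(dtype=float)
    libsize = arr.sum(axis=0)
    if (libsize == 0).any():
        bad = [s for s, tot in zip(counts.sample_ids, libsize) if tot == 0]
        raise ValueError(f"zero library size for sample(s): {bad}")
    cpm = arr / libsize * 1e6
    values = pd.DataFrame(
        np.log2(cpm + 1.0), index=counts.values.index, columns=counts.values.columns
    )
    return counts.with_values(values)


def filter_low_expression(
    m: ExpressionMatrix, max_zero_fraction: float = 0.10
) -> ExpressionMatrix:
    """Drop genes with zero expression in more than ``max_zero_fraction`` of samples.

    The comparison is strict: a gene at exactly the threshold is kept.
    Gene order is otherwise preserved.
    """
    if m.values.empty:
        raise ValueError("empty expression matrix")
    zero_frac = (m.values.to_numpy() == 0).mean(axis=1)
    keep = [g for g, f in zip(m.gene_ids, zero_frac) if f <= max_zero_fraction]
    if not keep:
        raise ValueError(
            "no genes survive the zero-expression filter; "
            "consider relaxing max_zero_fraction"
        )
    return m.subset_genes(keep)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, dtype=float), method="fdr_bh")[1]


def differential_expression(
    m: ExpressionMatrix,
    fdr_threshold: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Two-group differential expression on a normalized matrix.

    Per gene: ``log2fc`` is the tumor-minus-reference mean on the log2
    scale, the p-value comes from a two-sided Wilcoxon rank-sum test, and
    ``fdr`` from Benjamini-Hochberg over all tested genes.  A gene is
    flagged ``is_de`` when fdr < ``fdr_threshold`` and \\|log2fc\\| >
    ``lfc_threshold`` (both strict).
    """
    ref = m.values[m.ref_sample_ids].to_numpy()
    tum = m.values[m.tumor_sample_ids].to_numpy()
    if ref.shape[1] < 2 or tum.shape[1] < 2:
        raise ValueError("each sample group needs at least 2 samples")
    log2fc = tum.mean(axis=1) - ref.mean(axis=1)
    res = stats.ranksums(tum, ref, axis=1)
    pvalue = np.asarray(res.pvalue, dtype=float)
    fdr = benjamini_hochberg(pvalue)
    table = pd.DataFrame(
        {
            "symbol": m.gene_info["symbol"],
            "biotype": m.gene_info["biotype"],
            "log2fc": log2fc,
            "pvalue": pvalue,
            "fdr": fdr,
        },
        index=m.values.index,
    )
    table["is_de"] = de_flags(table, fdr_threshold, lfc_threshold)
    return table


def de_flags(
    table: pd.DataFrame, fdr_threshold: float = 0.05, lfc_threshold: float = 1.0
) -> pd.Series:
    """Apply the strict differential-expression thresholds to a DE table."""
    return (table["fdr"] < fdr_threshold) & (table["log2fc"].abs() > lfc_threshold)


def remove_duplicate_symbols(
    lnc_symbols: pd.Series, mrna_symbols: pd.Series
) -> tuple[list[str], list[str]]:
    """Resolve symbol collisions between the lncRNA and mRNA gene sets.

    Any symbol present in both sets is removed from both; within a set,
    duplicate symbols keep the first occurrence (in the given gene order)
    and drop the rest.  Inputs map gene id -> symbol; outputs are the
    retained gene ids, order preserved.
    """
    shared = set(lnc_symbols) & set(mrna_symbols)

    def dedupe(symbols: pd.Series) -> list[str]:
        seen: set[str] = set()
        keep = []
        for gene_id, symbol in symbols.items():
            if symbol in shared or symbol in seen:
                continue
            seen.add(symbol)
            keep.append(gene_id)
        return keep

    return dedupe(lnc_symbols), dedupe(mrna_symbols)
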