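"""Coexpressed protein-coding genes of the biomarker lncRNAs.

For each biomarker lncRNA, every protein-coding gene is tested for Pearson
correlation across tumor samples; genes with r > 0.45 and p < 0.01 (both
strict) are retained as significantly coexpressed.  The union over the
biomarkers ("correlated with at least one") is the gene list handed to
external enrichment services.  The threshold is on the signed correlation
by default; set ``absolute=True`` to threshold |r| instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CoexpressionResult:
    """Per-lncRNA retained genes with their correlation and p-value."""

    per_lnc: dict[str, pd.DataFrame]
    union: list[str]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (lnc_id, gene_id, r, p) over all lncRNAs."""
        frames = []
        for lnc, df in self.per_lnc.items():
            out = df.copy()
            out.insert(0, "lnc_id", lnc)
            frames.append(out)
        if not frames:
            return pd.DataFrame(columns=["lnc_id", "gene_id", "r", "p"])
        return pd.concat(frames, ignore_index=True)


def _correlation_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p-value of a Pearson correlation via the t transform (n-2 df)."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 1e-300))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def coexpressed_genes(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    r_threshold: float = 0.45,
    p_threshold: float = 0.01,
    absolute: bool = False,
) -> CoexpressionResult:
    """Select protein-coding genes coexpressed with each biomarker lncRNA.

    Both inputs are genes x samples over the same (tumor) samples, with at
    least 3 samples.  Constant genes are skipped with a warning.
    """
    if not lnc_expr.columns.equals(mrna_expr.columns):
        raise ValueError("lncRNA and mRNA matrices must share the same samples")
    n = lnc_expr.shape[1]
    if n < 3:
        raise ValueError("need at least 3 samples")

    X = lnc_expr.to_numpy(dtype=float)
    Y = mrna_expr.to_numpy(dtype=float)
    const_lnc = X.std(axis=1) == 0
    const_mrna = Y.std(axis=1) == 0
    if const_lnc.any():
        warnings.warn(
            f"skipping constant lncRNA(s): {list(lnc_expr.index[const_lnc])}",
            stacklevel=2,
        )
    if const_mrna.any():
        warnings.warn(
            f"skipping {int(const_mrna.sum())} constant protein-coding gene(s)",
            stacklevel=2,
        )

    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    nx = np.sqrt((Xc * Xc).sum(axis=1))
    ny = np.sqrt((Yc * Yc).sum(axis=1))
    denom = np.outer(nx, ny)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (Xc @ Yc.T) / np.where(denom > 0, denom, 1.0), np.nan)
    p = _correlation_pvalues(r, n)

    per_lnc: dict[str, pd.DataFrame] = {}
    union: set[str] = set()
    genes = mrna_expr.index.to_numpy()
    for i, lnc in enumerate(lnc_expr.index):
        if const_lnc[i]:
            per_lnc[lnc] = pd.DataFrame(columns=["gene_id", "r", "p"])
            continue
        ri, pi = r[i], p[i]
        stat = np.abs(ri) if absolute else ri
        keep = ~const_mrna & ~np.isnan(ri) & (stat > r_threshold) & (pi < p_threshold)
        df = pd.DataFrame(
            {"gene_id": genes[keep], "r": ri[keep], "p": pi[keep]}
        ).sort_values("r", ascending=False, kind="stable", ignore_index=True)
        per_lnc[lnc] = df
        union |= set(df["gene_id"])
    return CoexpressionResult(per_lnc=per_lnc, union=sorted(union))
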