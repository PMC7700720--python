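"""Core data containers and plain-text I/O.

The pipeline's substrate is a genes x samples expression matrix annotated
with per-gene biotypes (lncRNA vs protein-coding mRNA) and per-sample group
labels (reference vs tumor), plus a clinical table carrying overall-survival
follow-up and covariates.  Both are stored as tab-separated text so every
artifact in a run is diffable and portable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

LNCRNA = "lncRNA"
MRNA = "mRNA"
REFERENCE = "reference"
TUMOR = "tumor"

#: Columns required of a clinical table, in canonical order.
CLINICAL_COLUMNS = [
    "os_days",
    "event",
    "age",
    "sex",
    "weight",
    "grade",
    "stage",
    "group",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with gene and sample annotation.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with sample ids as columns.  Entries
        may be raw counts or normalized expression; all stages state which
        scale they expect.
    gene_info
        DataFrame indexed by gene id with columns ``symbol`` and
        ``biotype`` (``"lncRNA"`` or ``"mRNA"``), aligned to ``values``.
    sample_group
        Series indexed by sample id mapping to ``"reference"`` or
        ``"tumor"``, aligned to the columns of ``values``.
    """

    values: pd.DataFrame
    gene_info: pd.DataFrame
    sample_group: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {sorted(set(dupes))[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()]
            raise ValueError(f"duplicate sample ids: {sorted(set(dupes))[:5]}")
        if not self.gene_info.index.equals(self.values.index):
            raise ValueError("gene_info index must match values index")
        if not self.sample_group.index.equals(self.values.columns):
            raise ValueError("sample_group index must match values columns")
        missing = {"symbol", "biotype"} - set(self.gene_info.columns)
        if missing:
            raise ValueError(f"gene_info missing columns: {sorted(missing)}")
        bad = set(self.gene_info["biotype"]) - {LNCRNA, MRNA}
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        bad = set(self.sample_group) - {REFERENCE, TUMOR}
        if bad:
            raise ValueError(f"unknown sample groups: {sorted(bad)}")
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if (arr < 0).any():
            raise ValueError("expression values must be non-negative")

    # -- convenience views -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def lnc_ids(self) -> list[str]:
        mask = self.gene_info["biotype"] == LNCRNA
        return list(self.gene_info.index[mask])

    @property
    def mrna_ids(self) -> list[str]:
        mask = self.gene_info["biotype"] == MRNA
        return list(self.gene_info.index[mask])

    @property
    def ref_sample_ids(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == REFERENCE])

    @property
    def tumor_sample_ids(self) -> list[str]:
        return list(self.sample_group.index[self.sample_group == TUMOR])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        return ExpressionMatrix(
            values=self.values.loc[gene_ids],
            gene_info=self.gene_info.loc[gene_ids],
            sample_group=self.sample_group.copy(),
        )

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        sample_ids = list(sample_ids)
        return ExpressionMatrix(
            values=self.values[sample_ids],
            gene_info=self.gene_info.copy(),
            sample_group=self.sample_group.loc[sample_ids],
        )

    def with_values(self, values: pd.DataFrame) -> "ExpressionMatrix":
        """Return a copy carrying ``values`` (same genes and samples)."""
        return ExpressionMatrix(
            values=values,
            gene_info=self.gene_info.copy(),
            sample_group=self.sample_group.copy(),
        )


# -- clinical table --------------------------------------------------------


def validate_clinical(clinical: pd.DataFrame) -> pd.DataFrame:
    """Validate a clinical table (indexed by sample id) and return it.

    Requires unique sample ids, non-negative ``os_days`` and a 0/1
    ``event`` indicator.
    """
    if clinical.index.duplicated().any():
        raise ValueError("duplicate sample ids in clinical table")
    missing = set(CLINICAL_COLUMNS) - set(clinical.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    if (clinical["os_days"] < 0).any():
        raise ValueError("os_days must be non-negative")
    if not clinical["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return clinical


# -- TSV round-trips -------------------------------------------------------


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    """Write genes as rows: gene_id, symbol, biotype, then one column per sample."""
    out = pd.concat([expr.gene_info[["symbol", "biotype"]], expr.values], axis=1)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_expression_tsv(path, sample_group: pd.Series | None = None,
                        clinical: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read an expression TSV written by :func:`write_expression_tsv`.

    Sample group labels are not stored in the matrix file; pass either an
    explicit ``sample_group`` series or a ``clinical`` table, in which case
    samples present in the clinical table are labelled tumor and the rest
    reference.
    """
    df = pd.read_csv(path, sep="\t", index_col="gene_id")
    gene_info = df[["symbol", "biotype"]]
    values = df.drop(columns=["symbol", "biotype"])
    if sample_group is None:
        if clinical is None:
            raise ValueError("provide sample_group or clinical to label samples")
        labels = [TUMOR if s in clinical.index else REFERENCE for s in values.columns]
        sample_group = pd.Series(labels, index=values.columns)
    else:
        sample_group = sample_group.loc[values.columns]
    return ExpressionMatrix(values=values, gene_info=gene_info, sample_group=sample_group)


def write_clinical_tsv(clinical: pd.DataFrame, path) -> None:
    out = clinical[CLINICAL_COLUMNS].copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_clinical_tsv(path) -> pd.DataFrame:
    clinical = pd.read_csv(path, sep="\t", index_col="sample_id")
    return validate_clinical(clinical)
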