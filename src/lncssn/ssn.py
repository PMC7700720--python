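"""Single-sample perturbation networks.

A reference correlation network N_r holds the Pearson correlation of every
lncRNA against every partner gene (all lncRNAs and all mRNAs) across the
reference samples.  For each tumor sample s, adding s to the reference group
and recomputing gives the perturbed network N_p; the sample's single-sample
network is the elementwise absolute difference |N_r - N_p| (the dPCC
matrix).  Summing each lncRNA's row of dPCC over all incident edges yields
its perturbation score SD, and stacking the SD vectors of all tumor samples
column-wise yields the perturbation matrix M on which candidate ranking
operates.

Edges are the complete set of lncRNA-lncRNA and lncRNA-mRNA pairs; no
significance pruning is applied.  Self pairs are fixed at correlation 1 in
the networks and contribute exactly 0 to every dPCC row sum.  A gene with
constant expression has no defined correlation; its entries are set to 0 by
convention so it contributes no perturbation signal.

An optional z-score mode divides each dPCC entry by the large-sample
standard error of a correlation difference, (1 - r_ref^2) / (n_ref - 1),
for comparability with perturbation tests that normalize edge shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

DELTA = "delta"
ZSCORE = "zscore"


@dataclass
class ReferenceNetwork:
    """Correlation of each lncRNA (rows) against each partner gene (columns).

    ``partner_ids`` is the concatenation of the lncRNA ids and the mRNA
    ids, so the matrix covers lncRNA-lncRNA and lncRNA-mRNA edges.
    """

    lnc_ids: list[str]
    partner_ids: list[str]
    pcc: np.ndarray  # L x P, in [-1, 1]
    n_ref: int

    def __post_init__(self) -> None:
        self.pcc = np.asarray(self.pcc, dtype=float)
        if self.pcc.shape != (len(self.lnc_ids), len(self.partner_ids)):
            raise ValueError("pcc shape does not match id lists")


@dataclass
class DeltaMatrix:
    """|dPCC| of every edge for one test sample; self pairs are 0."""

    sample_id: str
    lnc_ids: list[str]
    partner_ids: list[str]
    delta: np.ndarray  # L x P, in [0, 2]


def _pairwise_pcc(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row Pearson correlation between A (L x n) and B (P x n).

    Rows with zero variance correlate 0 against everything by convention.
    """
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    na = np.sqrt((A * A).sum(axis=1))
    nb = np.sqrt((B * B).sum(axis=1))
    denom = np.outer(na, nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        pcc = np.where(denom > 0, (A @ B.T) / np.where(denom > 0, denom, 1.0), 0.0)
    # numerical safety: correlations live in [-1, 1]
    return np.clip(pcc, -1.0, 1.0)


def _self_pair_indices(
    lnc_ids: list[str], partner_ids: list[str]
) -> tuple[np.ndarray, np.ndarray]:
    pos = {g: j for j, g in enumerate(partner_ids)}
    rows = np.array([i for i, g in enumerate(lnc_ids) if g in pos], dtype=int)
    cols = np.array([pos[g] for g in lnc_ids if g in pos], dtype=int)
    return rows, cols


def _network_from_values(
    values: np.ndarray, lnc_idx: np.ndarray, lnc_ids, partner_ids, n_ref: int
) -> ReferenceNetwork:
    pcc = _pairwise_pcc(values[lnc_idx], values)
    rows, cols = _self_pair_indices(list(lnc_ids), list(partner_ids))
    pcc[rows, cols] = 1.0
    return ReferenceNetwork(
        lnc_ids=list(lnc_ids), partner_ids=list(partner_ids), pcc=pcc, n_ref=n_ref
    )


def reference_network(
    ref_expr: ExpressionMatrix, lnc_ids, mrna_ids
) -> ReferenceNetwork:
    """Correlation network over the reference samples.

    ``ref_expr`` may contain non-reference samples; only columns labelled
    reference are used.  At least 3 reference samples are required.
    """
    lnc_ids, mrna_ids = list(lnc_ids), list(mrna_ids)
    ref_samples = ref_expr.ref_sample_ids
    if len(ref_samples) < 3:
        raise ValueError(
            f"need at least 3 reference samples, got {len(ref_samples)}"
        )
    partner_ids = lnc_ids + mrna_ids
    sub = ref_expr.values.loc[partner_ids, ref_samples].to_numpy(dtype=float)
    lnc_idx = np.arange(len(lnc_ids))
    return _network_from_values(sub, lnc_idx, lnc_ids, partner_ids, len(ref_samples))


def perturbed_network(
    ref_expr: ExpressionMatrix,
    test_sample: pd.Series,
    net: ReferenceNetwork,
) -> ReferenceNetwork:
    """Correlation network over the reference samples plus one test sample."""
    missing = [g for g in net.partner_ids if g not in test_sample.index]
    if missing:
        raise ValueError(f"test sample missing genes: {missing[:5]}")
    ref_samples = ref_expr.ref_sample_ids
    base = ref_expr.values.loc[net.partner_ids, ref_samples].to_numpy(dtype=float)
    extra = test_sample.loc[net.partner_ids].to_numpy(dtype=float)[:, None]
    aug = np.concatenate([base, extra], axis=1)
    lnc_idx = np.arange(len(net.lnc_ids))
    return _network_from_values(
        aug, lnc_idx, net.lnc_ids, net.partner_ids, net.n_ref + 1
    )


def delta_matrix(
    n_r: ReferenceNetwork,
    n_p: ReferenceNetwork,
    sample_id: str,
    mode: str = DELTA,
) -> DeltaMatrix:
    """Elementwise |N_r - N_p| for one sample, with self pairs forced to 0."""
    if n_r.pcc.shape != n_p.pcc.shape:
        raise ValueError("reference and perturbed networks differ in shape")
    if n_r.lnc_ids != n_p.lnc_ids or n_r.partner_ids != n_p.partner_ids:
        raise ValueError("reference and perturbed networks differ in gene order")
    delta = np.abs(n_r.pcc - n_p.pcc)
    if mode == ZSCORE:
        se = (1.0 - n_r.pcc**2) / max(n_r.n_ref - 1, 1)
        with np.errstate(divide="ignore", invalid="ignore"):
            delta = np.where(se > 0, delta / np.where(se > 0, se, 1.0), 0.0)
    elif mode != DELTA:
        raise ValueError(f"unknown mode {mode!r}")
    rows, cols = _self_pair_indices(n_r.lnc_ids, n_r.partner_ids)
    delta[rows, cols] = 0.0
    return DeltaMatrix(
        sample_id=sample_id,
        lnc_ids=n_r.lnc_ids,
        partner_ids=n_r.partner_ids,
        delta=delta,
    )


def sd_vector(d: DeltaMatrix) -> pd.Series:
    """Per-lncRNA sum of |dPCC| over all incident edges (row sums)."""
    return pd.Series(d.delta.sum(axis=1), index=d.lnc_ids, name=d.sample_id)


def perturbation_matrix(
    ref_expr: ExpressionMatrix,
    tumor_expr: ExpressionMatrix,
    lnc_ids,
    mrna_ids,
    mode: str = DELTA,
) -> pd.DataFrame:
    """lncRNAs x tumor-samples matrix of perturbation scores.

    The reference network is computed once; each tumor sample is then added
    to the reference group in turn, and that sample's SD vector becomes one
    column of the output.
    """
    lnc_ids, mrna_ids = list(lnc_ids), list(mrna_ids)
    tumor_samples = tumor_expr.tumor_sample_ids
    if not tumor_samples:
        raise ValueError("no tumor samples")
    n_r = reference_network(ref_expr, lnc_ids, mrna_ids)

    ref_vals = ref_expr.values.loc[n_r.partner_ids, ref_expr.ref_sample_ids].to_numpy(
        dtype=float
    )
    tum_vals = tumor_expr.values.loc[n_r.partner_ids, tumor_samples].to_numpy(
        dtype=float
    )
    lnc_idx = np.arange(len(lnc_ids))
    columns = {}
    for j, sample in enumerate(tumor_samples):
        aug = np.concatenate([ref_vals, tum_vals[:, j : j + 1]], axis=1)
        n_p = _network_from_values(
            aug, lnc_idx, n_r.lnc_ids, n_r.partner_ids, n_r.n_ref + 1
        )
        d = delta_matrix(n_r, n_p, sample, mode=mode)
        columns[sample] = sd_vector(d)
    return pd.DataFrame(columns, index=pd.Index(lnc_ids, name="lnc_id"))
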