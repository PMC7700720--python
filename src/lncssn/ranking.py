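"""Top-K frequency ranking of perturbation scores.

Each column of the perturbation matrix is sorted by SD (descending: the
most perturbed lncRNA first), giving a per-sample ordering of lncRNA
identities.  For a window size K, a lncRNA's frequency is the number of
tumor samples in which it appears within the top K positions.  The top 5%
of lncRNAs by frequency are retained for each K, and the intersection
across K in {5, 10, 20, 30} forms the final candidate set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

DEFAULT_KS = (5, 10, 20, 30)
DEFAULT_FRACTION = 0.05


@dataclass
class CandidateSet:
    """Per-K retained sets, their frequency tables, and the intersection."""

    per_k_sets: dict[int, list[str]]
    frequencies: dict[int, pd.Series]
    final: list[str]


def rank_columns(m: pd.DataFrame) -> pd.DataFrame:
    """Order every column's lncRNA ids by descending SD.

    Ties are broken by lexicographic lncRNA id so the ordering is
    deterministic.  The output has the same shape as ``m``; entry (r, j) is
    the id of the lncRNA ranked r-th in tumor sample j.
    """
    if m.empty:
        raise ValueError("empty perturbation matrix")
    ids = m.index.to_numpy(dtype=object)
    id_sortable = m.index.to_numpy(dtype=str)
    out = {}
    for sample in m.columns:
        sd = m[sample].to_numpy(dtype=float)
        # lexsort: last key is primary (descending SD), then ascending id
        order = np.lexsort((id_sortable, -sd))
        out[sample] = ids[order]
    return pd.DataFrame(out, index=pd.RangeIndex(len(ids), name="rank"))


def topk_frequency(ml: pd.DataFrame, k: int) -> pd.Series:
    """Number of samples in which each lncRNA ranks within the top k."""
    n_lnc = len(ml.index)
    if not 1 <= k <= n_lnc:
        raise ValueError(f"k must be in [1, {n_lnc}], got {k}")
    all_ids = pd.Index(sorted(ml.iloc[:, 0].astype(str)))
    top = ml.iloc[:k].to_numpy(dtype=object).ravel()
    counts = pd.Series(top).value_counts()
    freq = counts.reindex(all_ids, fill_value=0).astype(int)
    freq.index.name = "lnc_id"
    return freq


def top_fraction(freq: pd.Series, fraction: float = DEFAULT_FRACTION) -> list[str]:
    """Retain the highest-frequency round(fraction * L) lncRNAs.

    Rounding is to the nearest integer (5% of 956 lncRNAs keeps 48).
    Frequency ties at
    the retention boundary are broken by lexicographic id.
    """
    if freq.empty:
        raise ValueError("empty frequency table")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = int(np.rint(fraction * len(freq)))
    if n_keep == 0:
        raise ValueError(
            f"fraction {fraction} of {len(freq)} lncRNAs rounds to zero; "
            "use a larger fraction"
        )
    ordered = freq.sort_index().sort_values(ascending=False, kind="stable")
    return list(ordered.index[:n_keep])


def candidate_intersection(
    m: pd.DataFrame,
    ks=DEFAULT_KS,
    fraction: float = DEFAULT_FRACTION,
) -> CandidateSet:
    """Final candidates: intersection of the per-K top-fraction sets."""
    ks = sorted(set(int(k) for k in ks))
    ml = rank_columns(m)
    per_k_sets: dict[int, list[str]] = {}
    frequencies: dict[int, pd.Series] = {}
    for k in ks:
        freq = topk_frequency(ml, k)
        frequencies[k] = freq
        per_k_sets[k] = top_fraction(freq, fraction)
    final_set = set(per_k_sets[ks[0]])
    for k in ks[1:]:
        final_set &= set(per_k_sets[k])
    if not final_set:
        warnings.warn("candidate intersection is empty", stacklevel=2)
    return CandidateSet(
        per_k_sets=per_k_sets,
        frequencies=frequencies,
        final=sorted(final_set),
    )
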