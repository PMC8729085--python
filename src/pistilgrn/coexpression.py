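"""Pearson-correlation and mutual-rank co-expression edge calling.

For each ordered gene pair (A, B), ``rank_AB`` is the position of B when
A's partners are sorted by decreasing Pearson correlation (self excluded,
rank 1 = best partner, ties get average ranks). The raw mutual rank is the
geometric mean ``sqrt(rank_AB * rank_BA)``; it is mapped onto the 0-1 scale
used for thresholding by the linear rescale

    MR_score = 1 - (MR_raw - 1) / (N - 2)

(clipped to [0, 1]; ``N`` genes), so mutual best partners score exactly 1.
A reciprocal variant ``1 / MR_raw`` is available. An edge is kept when
|PCC| >= 0.95 and MR_score >= 0.95 (both inclusive, both configurable).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["pcc_matrix", "mutual_rank", "call_edges"]


def pcc_matrix(profile: pd.DataFrame, gene_subset=None) -> pd.DataFrame:
    """Symmetric Pearson correlation of per-gene profiles (rows).

    Genes with a constant profile have undefined correlation and are
    excluded with a warning.
    """
    x = profile
    if gene_subset is not None:
        gene_subset = [g for g in gene_subset if g in x.index]
        if not gene_subset:
            raise ValueError("empty gene subset")
        x = x.loc[gene_subset]
    if x.shape[1] < 3:
        raise ValueError("need at least 3 observations per gene")
    arr = x.to_numpy(dtype=float)
    constant = arr.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"excluding {int(constant.sum())} constant gene(s) from the PCC matrix"
        )
        x = x.loc[~constant]
        arr = arr[~constant]
    corr = np.atleast_2d(np.corrcoef(arr))
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=x.index, columns=x.index)


def mutual_rank(pcc: pd.DataFrame, normalization: str = "linear") -> pd.DataFrame:
    """Edge table with PCC, directed ranks, raw MR and the MR score.

    One row per unordered pair (A, B) with A before B in the input order.
    """
    n = pcc.shape[0]
    if n < 3:
        raise ValueError("mutual rank needs at least 3 genes")
    if pcc.shape[0] != pcc.shape[1] or not np.allclose(
        pcc.to_numpy(), pcc.to_numpy().T, atol=1e-12
    ):
        raise ValueError("PCC matrix must be square and symmetric")
    if normalization not in ("linear", "reciprocal"):
        raise ValueError(f"unknown MR normalization {normalization!r}")
    c = pcc.to_numpy(dtype=float)
    ranks = np.zeros_like(c)
    idx = np.arange(n)
    for i in range(n):
        row = np.delete(c[i], i)
        r = rankdata(-row, method="average")
        ranks[i, idx != i] = r
    mr_raw = np.sqrt(ranks * ranks.T)
    if normalization == "linear":
        score = np.clip(1.0 - (mr_raw - 1.0) / (n - 2), 0.0, 1.0)
    else:
        score = 1.0 / mr_raw
    iu, ju = np.triu_indices(n, k=1)
    genes = pcc.index.to_numpy()
    return pd.DataFrame(
        {
            "gene_a": genes[iu],
            "gene_b": genes[ju],
            "pcc": c[iu, ju],
            "rank_ab": ranks[iu, ju],
            "rank_ba": ranks[ju, iu],
            "mr_raw": mr_raw[iu, ju],
            "mr_score": score[iu, ju],
        }
    )


def call_edges(
    edges: pd.DataFrame, pcc_threshold: float = 0.95, mr_threshold: float = 0.95
) -> pd.DataFrame:
    """Keep edges with |PCC| and MR score at or above their thresholds."""
    keep = (edges["pcc"].abs() >= pcc_threshold) & (edges["mr_score"] >= mr_threshold)
    return edges.loc[keep].reset_index(drop=True)
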