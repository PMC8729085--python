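"""Flat over-representation analysis against a gene -> term annotation.

Given a gene set drawn from a stated universe, each annotated term with at
least one universe gene is tested with the upper-tail hypergeometric
probability of the observed overlap; the headline criterion is the raw
p <= 0.05 rule, with BH-adjusted values reported alongside. The annotation
is a flat table (term hierarchy propagation is out of scope).
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom

from .diffexp import bh_adjust

__all__ = ["read_annotation", "ora"]


def read_annotation(path) -> pd.DataFrame:
    """Read a gene -> term TSV with columns gene_id, term_id, term_name, namespace."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    required = {"gene_id", "term_id"}
    if not required <= set(ann.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    for optional in ("term_name", "namespace"):
        if optional not in ann.columns:
            ann[optional] = ""
    return ann


def ora(
    gene_set,
    annotation: pd.DataFrame,
    universe,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``gene_set`` per annotated term."""
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        raise ValueError(f"gene set is not contained in the universe: {sorted(stray)[:5]}")
    ann = annotation[annotation["gene_id"].isin(universe)]
    n_universe = len(universe)
    n_set = len(gene_set)
    rows = []
    for term_id, sub in ann.groupby("term_id", sort=True):
        term_genes = set(sub["gene_id"])
        big_k = len(term_genes)
        k = len(term_genes & gene_set)
        p = float(hypergeom.sf(k - 1, n_universe, big_k, n_set))
        rows.append(
            {
                "term_id": term_id,
                "term_name": sub["term_name"].iloc[0],
                "namespace": sub["namespace"].iloc[0],
                "overlap": k,
                "set_size": n_set,
                "term_size": big_k,
                "universe_size": n_universe,
                "p_value": p,
            }
        )
    result = pd.DataFrame(
        rows,
        columns=[
            "term_id",
            "term_name",
            "namespace",
            "overlap",
            "set_size",
            "term_size",
            "universe_size",
            "p_value",
        ],
    )
    result["padj_bh"] = bh_adjust(result["p_value"].to_numpy())
    result["enriched"] = result["p_value"] <= p_threshold
    return result.sort_values(["p_value", "term_id"]).reset_index(drop=True)
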