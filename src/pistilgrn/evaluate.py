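"""Recovery metrics: planted truth versus pipeline output.

Used by the test suite and the reproduction script to quantify how well a
run on synthetic data recovers the planted stage-preferential genes,
sex-differential genes, TF -> target regulatory edges, and motif
enrichments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .motifs import enrich_motifs
from .pipeline import STAGE_CONTRASTS, STAGE_MERGE, load_networks
from .simulate import SyntheticDataset, SyntheticTruth

__all__ = [
    "planted_genes",
    "ss_recovery",
    "de_recovery",
    "edge_recovery",
    "motif_recovery",
    "hub_recovery",
]


def planted_genes(truth: SyntheticTruth) -> set[str]:
    """Every gene carrying planted structure of any kind."""
    out = set(truth.stage_specific)
    for d in truth.de_genes.values():
        out |= set(d)
    for tf, targets in truth.modules.items():
        out |= {tf} | set(targets)
    return out


def ss_recovery(truth: SyntheticTruth, ss_table, all_genes) -> dict:
    """Sensitivity on planted stage-preferential genes; false-call rate on
    genes with no planted structure at all."""
    pref = ss_table.preferential
    hits = sum(
        1
        for gene, group in truth.stage_specific.items()
        if group in pref.columns and bool(pref.at[gene, group])
    )
    n_planted = len(truth.stage_specific)
    background = sorted(set(all_genes) - planted_genes(truth))
    false = int(pref.loc[background].any(axis=1).sum()) if background else 0
    return {
        "sensitivity": hits / n_planted if n_planted else float("nan"),
        "false_call_rate": false / len(background) if background else 0.0,
        "n_planted": n_planted,
        "n_background": len(background),
    }


def de_recovery(truth: SyntheticTruth, shared_per_contrast: dict) -> dict:
    """Sensitivity and empirical FDR of the shared-DEG calls, pooled over
    contrasts (per-contrast counting)."""
    tp = fn = fp = 0
    for contrast, genes in shared_per_contrast.items():
        called = set(genes)
        true = set(truth.de_genes.get(contrast, {}))
        tp += len(called & true)
        fn += len(true - called)
        fp += len(called - true)
    total_true = tp + fn
    total_called = tp + fp
    return {
        "sensitivity": tp / total_true if total_true else float("nan"),
        "fdr": fp / total_called if total_called else 0.0,
        "n_true": total_true,
        "n_called": total_called,
    }


def _network_stage(stage: str) -> str:
    return STAGE_MERGE.get(stage, stage)


def edge_recovery(truth: SyntheticTruth, networks: dict) -> dict:
    """Fraction of planted TF -> target pairs present in the assembled
    network of the module's (sex, stage)."""
    total = found = 0
    for tf, targets in truth.modules.items():
        sex, stage = truth.module_info[tf]
        net = networks.get(f"{sex}{_network_stage(stage)}")
        for target in targets:
            total += 1
            if net is not None and net.has_edge(tf, target):
                found += 1
    return {
        "recovery": found / total if total else float("nan"),
        "n_planted_edges": total,
        "n_recovered": found,
    }


def motif_recovery(truth: SyntheticTruth, hits: pd.DataFrame, adj_p: float = 0.001) -> dict:
    """Enrichment of each planted motif in its true target set against all
    other genes, at the Bonferroni-adjusted cutoff."""
    enriched = {}
    universe = set(hits.index)
    for tf, targets in truth.modules.items():
        motif_id = truth.tf_motif[tf]
        fg = set(targets) & universe
        if not fg:
            enriched[motif_id] = False
            continue
        res = enrich_motifs(fg, universe - fg, hits, adj_p_threshold=adj_p)
        row = res[res["motif_id"] == motif_id].iloc[0]
        enriched[motif_id] = bool(row["enriched"])
    n = len(enriched)
    return {
        "fraction_enriched": sum(enriched.values()) / n if n else float("nan"),
        "all_enriched": all(enriched.values()) if n else False,
        "per_motif": enriched,
    }


def hub_recovery(truth: SyntheticTruth, hub_table: pd.DataFrame, networks: dict) -> dict:
    """Planted TFs present in the hub list of their own stage network,
    among those whose module made it into that network at all."""
    eligible = recovered = 0
    for tf, (sex, stage) in truth.module_info.items():
        name = f"{sex}{_network_stage(stage)}"
        net = networks.get(name)
        if net is None or tf not in net.nodes:
            continue
        eligible += 1
        in_hubs = (
            (hub_table["network"] == name) & (hub_table["gene_id"] == tf)
        ).any()
        if in_hubs:
            recovered += 1
    return {
        "recovery": recovered / eligible if eligible else float("nan"),
        "n_eligible": eligible,
    }


def evaluate_run(dataset: SyntheticDataset, outdir, ss_threshold: float = 0.3) -> dict:
    """All recovery metrics for one completed pipeline run directory."""
    outdir = Path(outdir)
    truth = dataset.truth
    scores = pd.read_csv(outdir / "ss_scores.tsv", sep="\t", index_col=0)
    ss_table = type("_SS", (), {})()
    ss_table.preferential = scores > ss_threshold
    shared = pd.read_csv(outdir / "shared_degs.tsv", sep="\t")
    shared_map = {
        c: list(sub["gene_id"]) for c, sub in shared.groupby("contrast", sort=False)
    }
    for contrast in truth.de_genes:
        shared_map.setdefault(contrast, [])
    hits = pd.read_csv(outdir / "motif_hits.tsv", sep="\t", index_col=0)
    networks = load_networks(outdir)
    hubs = pd.read_csv(outdir / "hubs.tsv", sep="\t")
    return {
        "ss": ss_recovery(truth, ss_table, dataset.matrix.gene_ids),
        "de": de_recovery(truth, shared_map),
        "edges": edge_recovery(truth, networks),
        "motifs": motif_recovery(truth, hits),
        "hubs": hub_recovery(truth, hubs, networks),
    }
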