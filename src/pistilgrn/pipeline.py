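"""Stage orchestration: artifacts on disk, one directory per run.

Every stage reads its inputs from the run directory (no hidden state), so
each subcommand is individually re-runnable from prior artifacts; a missing
prerequisite raises :class:`PipelineError` naming the file and the stage
that produces it. All artifacts are plain TSV / FASTA / GFF3 / GraphML /
JSON; ``manifest.json`` records what each stage wrote and the thresholds it
applied.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coexpression, diffexp, motifs as motifs_mod, network as network_mod
from .ora import ora as run_ora, read_annotation
from .expression import (
    ExpressionMatrix,
    GroupProfile,
    counts_to_fpkm,
    expressed_fraction,
    expression_bins,
    group_means,
    pca_embedding,
    read_expression,
    replicate_correlation,
    ss_scores,
)
from .simulate import SimulationConfig, simulate_dataset, write_dataset

log = logging.getLogger("pistilgrn")

STAGE_MERGE = {"S2": "S2-3", "S3": "S2-3"}
NETWORK_STAGES = ("S1", "S2-3", "S4")
#: which contrasts feed each network stage's DEG set
STAGE_CONTRASTS = {
    "S1": ("FS1_vs_MS1",),
    "S2-3": ("FS2_vs_MS2", "FS3_vs_MS3"),
    "S4": ("FS4_vs_MS4",),
}


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Thresholds, paths and the seed for one pipeline run."""

    seed: int = 0
    ss_threshold: float = 0.3
    fdr: float = 0.05
    lfc: float = 1.0
    pcc_threshold: float = 0.95
    mr_threshold: float = 0.95
    mr_normalization: str = "linear"
    coexpress_log: bool = True  # correlate log2(FPKM + 1) group profiles
    motif_adj_p: float = 0.001
    expressed_fpkm: float = 1.0
    hub_fraction: float = 0.10
    scan_p: float = 1e-4
    stage_merge: dict = field(default_factory=lambda: dict(STAGE_MERGE))
    paths: dict = field(default_factory=dict)  # overrides for input artifacts
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides
    annotation: str = ""  # optional gene -> term TSV for ORA

    def __post_init__(self) -> None:
        for name in ("fdr", "motif_adj_p", "scan_p", "hub_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in ("pcc_threshold", "mr_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        kwargs = dict(self.simulation)
        kwargs.setdefault("seed", self.seed)
        return SimulationConfig(**kwargs)


def _artifact(cfg: PipelineConfig, outdir: Path, name: str, producer: str) -> Path:
    path = Path(cfg.paths[name]) if name in cfg.paths else outdir / _DEFAULT_FILES[name]
    if not path.exists():
        raise PipelineError(
            f"missing artifact {path} ({name}); run the '{producer}' stage first"
        )
    return path


_DEFAULT_FILES = {
    "counts": "counts.tsv",
    "samples": "samples.tsv",
    "gene_lengths": "gene_lengths.tsv",
    "genome": "genome.fasta",
    "gff3": "genes.gff3",
    "tf_annotation": "tf_annotation.tsv",
    "motifs": "motifs.jaspar",
    "fpkm": "fpkm.tsv",
    "group_means": "group_means.tsv",
    "group_means_merged": "group_means_merged.tsv",
    "ss_calls": "ss_calls.tsv",
    "de_results": "de_results.tsv",
    "shared_degs": "shared_degs.tsv",
    "edges": "edges.tsv",
    "motif_hits": "motif_hits.tsv",
    "enrichment": "enrichment.tsv",
    "topology": "topology.tsv",
    "hubs": "hubs.tsv",
    "sex_specific": "sex_specific_calls.tsv",
    "subnetwork": "subnetwork.graphml",
}


def _update_manifest(outdir: Path, stage: str, files: dict, params: dict) -> None:
    manifest_path = outdir / "manifest.json"
    manifest = {}
    if manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
    manifest[stage] = {"files": {k: str(v) for k, v in files.items()}, "params": params}
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _load_matrix(cfg: PipelineConfig, outdir: Path) -> ExpressionMatrix:
    counts = _artifact(cfg, outdir, "counts", "simulate")
    samples = _artifact(cfg, outdir, "samples", "simulate")
    lengths_path = _artifact(cfg, outdir, "gene_lengths", "simulate")
    lengths = pd.read_csv(lengths_path, sep="\t", index_col=0)["length"]
    return read_expression(counts, samples, unit="counts", gene_lengths=lengths)


# ---------------------------------------------------------------------------
# stages


def stage_simulate(cfg: PipelineConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    sim_cfg = cfg.simulation_config()
    dataset = simulate_dataset(sim_cfg)
    files = write_dataset(dataset, outdir)
    log.info("simulated %d genes x %d samples (seed %d)",
             sim_cfg.n_genes, dataset.matrix.values.shape[1], sim_cfg.seed)
    _update_manifest(outdir, "simulate", files, {"seed": sim_cfg.seed, **asdict(sim_cfg)})
    return files


def stage_expression(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = _load_matrix(cfg, outdir)
    fpkm = counts_to_fpkm(matrix)
    fpkm.values.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="gene_id")
    profile = group_means(fpkm)
    profile.values.to_csv(outdir / "group_means.tsv", sep="\t", index_label="gene_id")
    merged = group_means(fpkm, stage_merge=cfg.stage_merge)
    merged.values.to_csv(outdir / "group_means_merged.tsv", sep="\t", index_label="gene_id")
    replicate_correlation(fpkm).to_csv(outdir / "replicate_correlation.tsv", sep="\t", index=False)
    coords, ratio = pca_embedding(fpkm)
    coords.to_csv(outdir / "pca.tsv", sep="\t", index_label="sample")
    bins = expression_bins(fpkm.values)
    bins["fractions"].to_csv(outdir / "expression_bins.tsv", sep="\t", index_label="bin")
    summary = {
        "expressed_fraction_any_sample": expressed_fraction(
            fpkm.values, threshold=cfg.expressed_fpkm
        ),
        "pca_explained_variance_ratio": [float(v) for v in ratio],
    }
    (outdir / "expression_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    files = {k: outdir / f"{k}.tsv" for k in
             ("fpkm", "group_means", "group_means_merged", "replicate_correlation",
              "pca", "expression_bins")}
    _update_manifest(outdir, "expression", files, {"expressed_fpkm": cfg.expressed_fpkm})
    return summary


def stage_ss(cfg: PipelineConfig, outdir: Path) -> dict:
    path = _artifact(cfg, outdir, "group_means", "expression")
    profile = GroupProfile(values=pd.read_csv(path, sep="\t", index_col=0))
    table = ss_scores(profile, threshold=cfg.ss_threshold)
    table.scores.to_csv(outdir / "ss_scores.tsv", sep="\t", index_label="gene_id")
    long = table.preferential.stack().rename("preferential").reset_index()
    long.columns = ["gene_id", "group", "preferential"]
    long["score"] = table.scores.stack().to_numpy()
    long[long["preferential"]].to_csv(outdir / "ss_calls.tsv", sep="\t", index=False)
    counts = table.preferential.sum(axis=0).to_dict()
    _update_manifest(outdir, "ss", {"ss_scores": outdir / "ss_scores.tsv",
                                    "ss_calls": outdir / "ss_calls.tsv"},
                     {"ss_threshold": cfg.ss_threshold})
    return {"preferential_per_group": {k: int(v) for k, v in counts.items()}}


def stage_de(cfg: PipelineConfig, outdir: Path) -> dict:
    matrix = _load_matrix(cfg, outdir)
    contrasts = diffexp.make_stage_contrasts(matrix)
    results_a, results_b, frames = {}, {}, []
    for contrast in contrasts:
        ra = diffexp.de_test_A(matrix, contrast, fdr=cfg.fdr, lfc_threshold=cfg.lfc)
        rb = diffexp.de_test_B(matrix, contrast, fdr=cfg.fdr, lfc_threshold=cfg.lfc)
        results_a[contrast.name], results_b[contrast.name] = ra, rb
        frames += [ra, rb]
    pd.concat(frames, ignore_index=True).to_csv(outdir / "de_results.tsv", sep="\t", index=False)
    shared = diffexp.shared_degs(results_a, results_b)
    pd.DataFrame(
        [(c, g) for c, genes in shared["per_contrast"].items() for g in genes],
        columns=["contrast", "gene_id"],
    ).to_csv(outdir / "shared_degs.tsv", sep="\t", index=False)
    summary = {
        "per_method_counts": {
            "A": sum(int(r["significant"].sum()) for r in results_a.values()),
            "B": sum(int(r["significant"].sum()) for r in results_b.values()),
        },
        "shared_per_contrast": shared["counts"],
        "shared_total": shared["total"],
    }
    (outdir / "de_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _update_manifest(outdir, "de", {"de_results": outdir / "de_results.tsv",
                                    "shared_degs": outdir / "shared_degs.tsv"},
                     {"fdr": cfg.fdr, "lfc": cfg.lfc})
    return summary


def _shared_deg_table(cfg: PipelineConfig, outdir: Path) -> pd.DataFrame:
    path = _artifact(cfg, outdir, "shared_degs", "de")
    return pd.read_csv(path, sep="\t")


def stage_coexpress(cfg: PipelineConfig, outdir: Path) -> dict:
    """PCC / mutual rank over the union of shared DEGs.

    Correlation uses the full 10-group log2 mean-FPKM profile (both sexes
    plus leaves): correlations are computed for all DEGs over all sample
    groups; the per-sex stage networks are differentiated later through
    the expression rule, not through sex-restricted profiles.
    """
    path = _artifact(cfg, outdir, "group_means", "expression")
    profile = pd.read_csv(path, sep="\t", index_col=0)
    if cfg.coexpress_log:
        profile = np.log2(profile + 1.0)
    shared = _shared_deg_table(cfg, outdir)
    universe = sorted(set(shared["gene_id"]))
    meta = {"n_genes": len(universe), "mr_normalization": cfg.mr_normalization}
    if len(universe) < 3:
        called = pd.DataFrame(
            columns=["gene_a", "gene_b", "pcc", "rank_ab", "rank_ba", "mr_raw", "mr_score"]
        )
    else:
        pcc = coexpression.pcc_matrix(profile, gene_subset=universe)
        edges = coexpression.mutual_rank(pcc, normalization=cfg.mr_normalization)
        called = coexpression.call_edges(
            edges, pcc_threshold=cfg.pcc_threshold, mr_threshold=cfg.mr_threshold
        )
    called.to_csv(outdir / "edges.tsv", sep="\t", index=False)
    meta["edges"] = len(called)
    (outdir / "coexpress_meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    _update_manifest(outdir, "coexpress", {"edges": outdir / "edges.tsv"},
                     {"pcc_threshold": cfg.pcc_threshold, "mr_threshold": cfg.mr_threshold,
                      "mr_normalization": cfg.mr_normalization})
    return meta


def stage_motifs(cfg: PipelineConfig, outdir: Path) -> dict:
    genome = _artifact(cfg, outdir, "genome", "simulate")
    gff3 = _artifact(cfg, outdir, "gff3", "simulate")
    motif_path = _artifact(cfg, outdir, "motifs", "simulate")
    tf_path = _artifact(cfg, outdir, "tf_annotation", "simulate")
    shared = _shared_deg_table(cfg, outdir)
    promoters = motifs_mod.extract_promoters(genome, gff3)
    promoters.write_fasta(outdir / "promoters_extracted.fasta")
    background = motifs_mod.background_frequencies(promoters)
    motifset = motifs_mod.read_motifs(motif_path, fmt="jaspar", background=background)
    hits = motifs_mod.scan_promoters(promoters, motifset, p_threshold=cfg.scan_p)
    hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index_label="gene_id")
    tf_annotation = pd.read_csv(tf_path, sep="\t").fillna({"motif_id": ""})
    universe = sorted(set(shared["gene_id"]))
    edges = pd.read_csv(_artifact(cfg, outdir, "edges", "coexpress"), sep="\t")
    rows = []
    for _, tf_row in tf_annotation.iterrows():
        tf, motif_id = tf_row["gene_id"], tf_row["motif_id"]
        if not motif_id:
            continue
        partners = set(edges.loc[edges["gene_a"] == tf, "gene_b"]) | set(
            edges.loc[edges["gene_b"] == tf, "gene_a"]
        )
        partners.discard(tf)
        if not partners:
            continue
        res = motifs_mod.enrich_motifs(
            partners, set(universe) - partners, hits, adj_p_threshold=cfg.motif_adj_p
        )
        row = res[res["motif_id"] == motif_id].iloc[0].to_dict()
        row.update({"tf": tf, "n_foreground": len(partners)})
        rows.append(row)
    result = pd.DataFrame(
        rows,
        columns=["tf", "motif_id", "fg_hits", "fg_misses", "bg_hits",
                 "bg_misses", "p_value", "adj_p", "enriched", "n_foreground"],
    )
    result.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    summary = {"enriched": int(result["enriched"].sum()) if len(result) else 0}
    _update_manifest(outdir, "motifs",
                     {"motif_hits": outdir / "motif_hits.tsv",
                      "enrichment": outdir / "enrichment.tsv"},
                     {"scan_p": cfg.scan_p, "motif_adj_p": cfg.motif_adj_p})
    return summary


def _network_name(sex: str, stage: str) -> str:
    return f"{sex}{stage}"


def stage_network(cfg: PipelineConfig, outdir: Path) -> dict:
    import networkx as nx

    tf_annotation = pd.read_csv(
        _artifact(cfg, outdir, "tf_annotation", "simulate"), sep="\t"
    ).fillna({"motif_id": ""})
    hits = pd.read_csv(_artifact(cfg, outdir, "motif_hits", "motifs"), sep="\t", index_col=0)
    shared = _shared_deg_table(cfg, outdir)
    merged = pd.read_csv(
        _artifact(cfg, outdir, "group_means_merged", "expression"), sep="\t", index_col=0
    )
    topo_rows, hub_rows = [], []
    networks = {}
    edges = pd.read_csv(_artifact(cfg, outdir, "edges", "coexpress"), sep="\t")
    enrichment = pd.read_csv(_artifact(cfg, outdir, "enrichment", "motifs"), sep="\t")
    for sex in ("F", "M"):
        for stage in NETWORK_STAGES:
            degs = set(
                shared.loc[shared["contrast"].isin(STAGE_CONTRASTS[stage]), "gene_id"]
            )
            # a node joins the sex's stage network only if expressed there
            expressed = set(
                merged.index[merged[f"{sex}:{stage}"] >= cfg.expressed_fpkm]
            )
            net = network_mod.assemble_network(
                edges, tf_annotation, enrichment, hits,
                motif_adj_p=cfg.motif_adj_p, sex=sex, stage=stage,
                gene_subset=degs & expressed,
            )
            name = _network_name(sex, stage)
            networks[name] = net
            network_mod.export_network(net, outdir / f"network_{name}.graphml", "graphml")
            stats = network_mod.topology(net)
            topo_rows.append({"network": name, **stats.as_dict()})
            hubs = network_mod.select_hubs(net, fraction=cfg.hub_fraction)
            for g in hubs.genes:
                hub_rows.append({"network": name, "gene_id": g, "degree": hubs.degrees[g]})
    pd.DataFrame(topo_rows).to_csv(outdir / "topology.tsv", sep="\t", index=False)
    hub_df = pd.DataFrame(hub_rows, columns=["network", "gene_id", "degree"])
    hub_df.to_csv(outdir / "hubs.tsv", sep="\t", index=False)

    # sex-specific expression of hub TFs under the FPKM >= 1 rule
    tf_ids = set(tf_annotation["gene_id"])
    hub_tfs = sorted(set(hub_df["gene_id"]) & tf_ids)
    profile = GroupProfile(values=merged)
    calls = network_mod.sex_specific_calls(
        profile, hub_tfs, NETWORK_STAGES, expressed_threshold=cfg.expressed_fpkm
    )
    call_df = pd.DataFrame(
        [
            {"gene_id": c.gene_id, "verdict": c.verdict, "stages": "/".join(c.stages)}
            for c in calls
        ],
        columns=["gene_id", "verdict", "stages"],
    )
    call_df.to_csv(outdir / "sex_specific_calls.tsv", sep="\t", index=False)
    summary = {
        "hub_counts": {n: int((hub_df["network"] == n).sum()) for n in networks},
        "hub_total": int(len(hub_df)),
        "female_specific_tfs": sorted(call_df.loc[call_df["verdict"] == "female-specific", "gene_id"]),
        "male_specific_tfs": sorted(call_df.loc[call_df["verdict"] == "male-specific", "gene_id"]),
    }
    (outdir / "network_summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    _update_manifest(outdir, "network",
                     {"topology": outdir / "topology.tsv", "hubs": outdir / "hubs.tsv",
                      "sex_specific": outdir / "sex_specific_calls.tsv"},
                     {"hub_fraction": cfg.hub_fraction, "motif_adj_p": cfg.motif_adj_p})
    return summary


def load_networks(outdir: Path) -> dict:
    import networkx as nx

    nets = {}
    for sex in ("F", "M"):
        for stage in NETWORK_STAGES:
            name = _network_name(sex, stage)
            path = outdir / f"network_{name}.graphml"
            if path.exists():
                g = nx.read_graphml(path)
                g = nx.DiGraph(g)
                g.graph.setdefault("sex", sex)
                g.graph.setdefault("stage", stage)
                nets[name] = g
    return nets


def stage_subnet(cfg: PipelineConfig, outdir: Path, seeds=None) -> dict:
    if not (outdir / "sex_specific_calls.tsv").exists():
        raise PipelineError(
            f"missing artifact {outdir / 'sex_specific_calls.tsv'} (sex_specific); "
            "run the 'network' stage first"
        )
    if seeds is None:
        calls = pd.read_csv(outdir / "sex_specific_calls.tsv", sep="\t")
        seeds = sorted(
            calls.loc[calls["verdict"].isin(["female-specific", "male-specific"]), "gene_id"]
        )
        if not seeds:
            # no hub TF is fully sex-specific: fall back to all hub TFs
            seeds = sorted(calls["gene_id"])
    nets = load_networks(outdir)
    sub = network_mod.extract_subnetwork(list(nets.values()), seeds)
    network_mod.export_network(sub, outdir / "subnetwork.graphml", "graphml")
    network_mod.export_network(sub, outdir / "subnetwork.sif", "sif")
    summary = {"seeds": list(seeds), "nodes": sub.number_of_nodes(), "edges": sub.number_of_edges()}
    _update_manifest(outdir, "subnet",
                     {"subnetwork": outdir / "subnetwork.graphml"}, {"n_seeds": len(seeds)})
    return summary


def stage_ora(cfg: PipelineConfig, outdir: Path) -> dict:
    if not cfg.annotation:
        return {"skipped": "no annotation table configured"}
    ann_path = Path(cfg.annotation)
    if not ann_path.exists():
        raise PipelineError(f"missing artifact {ann_path} (annotation); provide annotation path")
    fpkm = pd.read_csv(_artifact(cfg, outdir, "fpkm", "expression"), sep="\t", index_col=0)
    universe = set(fpkm.index[(fpkm >= cfg.expressed_fpkm).any(axis=1)])
    annotation = read_annotation(ann_path)
    nets = load_networks(outdir)
    summary = {}
    for name, net in nets.items():
        gene_set = set(net.nodes) & universe
        if not gene_set:
            continue
        res = run_ora(gene_set, annotation, universe)
        res.to_csv(outdir / f"ora_{name}.tsv", sep="\t", index=False)
        summary[name] = int(res["enriched"].sum())
    _update_manifest(outdir, "ora", {}, {"universe": "expressed genes"})
    return {"enriched_terms": summary}


def stage_report(cfg: PipelineConfig, outdir: Path) -> dict:
    report = {"seed": cfg.seed}
    for name, producer in [
        ("expression_summary.json", "expression"),
        ("de_summary.json", "de"),
        ("coexpress_meta.json", "coexpress"),
        ("network_summary.json", "network"),
    ]:
        path = outdir / name
        if not path.exists():
            raise PipelineError(f"missing artifact {path}; run the '{producer}' stage first")
        report[name.replace(".json", "")] = json.loads(path.read_text())
    de = report["de_summary"]
    report["consistency"] = {
        "shared_sum_equals_total": sum(de["shared_per_contrast"].values()) == de["shared_total"],
        "hub_sum_equals_total": sum(report["network_summary"]["hub_counts"].values())
        == report["network_summary"]["hub_total"],
    }
    text = json.dumps(report, indent=2, sort_keys=True)
    (outdir / "report.json").write_text(text)
    return report


STAGES = {
    "simulate": stage_simulate,
    "expression": stage_expression,
    "ss": stage_ss,
    "de": stage_de,
    "coexpress": stage_coexpress,
    "motifs": stage_motifs,
    "network": stage_network,
    "subnet": stage_subnet,
    "ora": stage_ora,
    "report": stage_report,
}
STAGE_ORDER = ("simulate", "expression", "ss", "de", "coexpress",
               "motifs", "network", "subnet", "ora", "report")


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run every stage in order; returns the final report dict."""
    outdir = Path(outdir)
    result = {}
    for stage in STAGE_ORDER:
        log.info("stage %s", stage)
        result = STAGES[stage](cfg, outdir)
    return result
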