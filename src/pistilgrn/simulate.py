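"""Seeded synthetic datasets with planted ground truth.

The generator emulates the study design the pipeline targets: two sexes x
four pistil developmental stages x three replicates of negative-binomial
RNA-seq counts, plus one leaf group per sex with two replicates. Into a
lognormal baseline it plants

* stage-preferential genes (mean multiplied by ``specificity_fold`` in one
  (sex, stage) group),
* sex-differential genes per stage contrast (one sex's arm multiplied by
  ``2**de_log2fc``, signs alternating),
* TF-led regulatory modules whose members share a latent, strongly
  stage-modulated group profile (lognormal across groups) perturbed by
  per-gene lognormal noise, so within-module Pearson correlation is high,
  and which are sex-differential at their most-expressed stage,
* promoter sequences (i.i.d. background at a stated GC) carrying one planted
  consensus instance of the module TF's motif per true target.

Everything is drawn from a single seeded generator in a fixed order, so a
fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, GroupProfile
from .motifs import MotifSet, PWM, PromoterRecord, PromoterSet, reverse_complement, write_jaspar

PISTIL_STAGES = ("S1", "S2", "S3", "S4")
DEFAULT_GROUPS = tuple(
    [(sex, stage, 3) for sex in ("F", "M") for stage in PISTIL_STAGES]
    + [("F", "leaf", 2), ("M", "leaf", 2)]
)
TF_FAMILIES = ("MADS", "bHLH", "MYB", "C2H2", "ERF", "HD-ZIP", "bZIP", "NAC", "GATA", "WRKY")


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the target design."""

    n_genes: int = 2000
    n_tfs: int = 10
    groups: tuple = DEFAULT_GROUPS
    baseline_mean: float = 100.0  # geometric mean of the lognormal baseline
    baseline_log_sd: float = 1.0
    dispersion: float = 0.1  # NB alpha, var = mu + alpha mu^2
    n_stage_specific: int = 20  # per pistil (sex, stage) group
    specificity_fold: float = 5.0
    n_de: int = 50  # standalone DE genes per stage contrast
    de_log2fc: float = 3.0
    n_modules: int = 10
    module_size: int = 12  # regulator TF + (module_size - 1) targets
    module_noise_sd: float = 0.05  # lognormal per-gene x group noise
    module_profile_log_sd: float = 2.0  # spread of the shared latent profile
    module_min_profile_sd: float = 1.2  # enforced realized spread across stages
    module_baseline_mean: float = 200.0
    gene_length: int = 1000
    promoter_length: int = 2000
    motif_length: int = 10
    motif_planting_rate: float = 1.0
    background_gc: float = 0.35
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_genes,
            self.n_tfs,
            self.n_stage_specific,
            self.n_de,
            self.n_modules,
            self.module_size,
        )
        if any(c < 0 for c in counts):
            raise ConfigurationError("counts must be non-negative")
        if not 0.0 <= self.motif_planting_rate <= 1.0:
            raise ConfigurationError("motif_planting_rate must be in [0, 1]")
        if not 0.0 < self.background_gc < 1.0:
            raise ConfigurationError("background_gc must be in (0, 1)")
        if self.promoter_length <= self.motif_length:
            raise ConfigurationError("promoter_length must exceed the motif length")
        if self.specificity_fold < 1.0:
            raise ConfigurationError("specificity_fold must be >= 1")
        n_pistil_groups = sum(1 for _, st, _ in self.groups if st != "leaf")
        planted = (
            self.n_modules * self.module_size
            + self.n_stage_specific * n_pistil_groups
            + self.n_de * len(PISTIL_STAGES)
        )
        if self.n_modules * self.module_size > self.n_genes:
            raise ConfigurationError("module genes exceed n_genes")
        if planted > self.n_genes:
            raise ConfigurationError(
                f"planted genes ({planted}) exceed n_genes ({self.n_genes})"
            )
        if self.n_tfs < self.n_modules:
            raise ConfigurationError("need at least one TF per module")


@dataclass
class SyntheticTruth:
    """Planted structure: what a perfect analysis should recover."""

    stage_specific: dict[str, str] = field(default_factory=dict)  # gene -> "sex:stage"
    de_genes: dict[str, dict[str, float]] = field(default_factory=dict)  # contrast -> gene -> lfc
    modules: dict[str, set[str]] = field(default_factory=dict)  # TF -> target set
    module_info: dict[str, tuple[str, str]] = field(default_factory=dict)  # TF -> (sex, stage)
    motif_placements: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)
    tf_motif: dict[str, str] = field(default_factory=dict)  # TF gene -> motif id


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    matrix: ExpressionMatrix  # raw counts
    true_means: GroupProfile  # noiseless per-group count means
    promoters: PromoterSet
    tf_annotation: pd.DataFrame  # gene_id, family, motif_id
    motif_counts: dict[str, np.ndarray]  # JASPAR-style integer PFMs
    motifs: MotifSet
    truth: SyntheticTruth
    genome: dict[str, str]  # contig -> sequence (promoter + gene body)
    gene_strand: dict[str, str]


def _contrast_name(stage: str) -> str:
    return f"F{stage}_vs_M{stage}"


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one seeded dataset with its ground truth."""
    rng = np.random.default_rng(config.seed)
    cfg = config
    genes = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    group_keys = [f"{sex}:{stage}" for sex, stage, _ in cfg.groups]
    stages_by_sex = {sex: [st for s, st, _ in cfg.groups if s == sex] for sex in ("F", "M")}

    # --- gene role allocation (fixed order for determinism) ---------------
    cursor = 0
    module_genes: list[list[str]] = []
    for _ in range(cfg.n_modules):
        module_genes.append(genes[cursor : cursor + cfg.module_size])
        cursor += cfg.module_size
    pistil_groups = [(s, st) for s, st, _ in cfg.groups if st != "leaf"]
    ss_genes: dict[str, str] = {}
    for sex, stage in pistil_groups:
        for g in genes[cursor : cursor + cfg.n_stage_specific]:
            ss_genes[g] = f"{sex}:{stage}"
        cursor += cfg.n_stage_specific
    de_standalone: dict[str, dict[str, float]] = {_contrast_name(s): {} for s in PISTIL_STAGES}
    for stage in PISTIL_STAGES:
        block = genes[cursor : cursor + cfg.n_de]
        cursor += cfg.n_de
        for i, g in enumerate(block):
            sign = 1.0 if i % 2 == 0 else -1.0
            de_standalone[_contrast_name(stage)][g] = sign * cfg.de_log2fc
    extra_tfs = genes[cursor : cursor + max(0, cfg.n_tfs - cfg.n_modules)]
    background_start = cursor + len(extra_tfs)

    # --- group means -------------------------------------------------------
    baseline = np.exp(rng.normal(np.log(cfg.baseline_mean), cfg.baseline_log_sd, cfg.n_genes))
    mu = np.tile(baseline[:, None], (1, len(group_keys)))
    mu_df = pd.DataFrame(mu, index=genes, columns=group_keys)

    for g, grp in ss_genes.items():
        mu_df.loc[g, grp] *= cfg.specificity_fold
    for stage in PISTIL_STAGES:
        for g, lfc in de_standalone[_contrast_name(stage)].items():
            if lfc > 0:
                mu_df.loc[g, f"F:{stage}"] *= 2.0 ** abs(lfc)
            else:
                mu_df.loc[g, f"M:{stage}"] *= 2.0 ** abs(lfc)

    truth = SyntheticTruth(stage_specific=dict(ss_genes), de_genes=de_standalone)
    # a stage-preferential gene is also sex-differential at its own stage
    if np.log2(cfg.specificity_fold) > 1.0:
        for g, grp in ss_genes.items():
            sex, stage = grp.split(":")
            if stage == "leaf":
                continue
            sign = 1.0 if sex == "F" else -1.0
            truth.de_genes[_contrast_name(stage)][g] = sign * np.log2(cfg.specificity_fold)
    fold = 2.0**cfg.de_log2fc
    for m, members in enumerate(module_genes):
        mod_sex = "F" if m % 2 == 0 else "M"
        other_sex = "M" if mod_sex == "F" else "F"
        tf = members[0]
        targets = set(members[1:])
        # one shared latent level per stage (and leaf), strongly modulated;
        # redraw until the realized spread across pistil stages is large
        # enough that within-module correlation is genuinely high (the
        # planted property must hold for every module, not on average)
        for _ in range(1000):
            draws = {
                st: rng.normal(0.0, cfg.module_profile_log_sd)
                for st in stages_by_sex[mod_sex]
            }
            if np.std([draws[st] for st in PISTIL_STAGES]) >= cfg.module_min_profile_sd:
                break
        latent = {
            st: cfg.module_baseline_mean * np.exp(v) for st, v in draws.items()
        }
        dominant = max(PISTIL_STAGES, key=lambda st: latent[st])
        noise = np.exp(
            rng.normal(0.0, cfg.module_noise_sd, (len(members), len(stages_by_sex[mod_sex])))
        )
        for k, st in enumerate(stages_by_sex[mod_sex]):
            vals = latent[st] * noise[:, k]
            mu_df.loc[members, f"{mod_sex}:{st}"] = vals
            if st == "leaf":
                mu_df.loc[members, f"{other_sex}:{st}"] = vals
            elif st == dominant:
                mu_df.loc[members, f"{other_sex}:{st}"] = vals / fold
            else:
                mu_df.loc[members, f"{other_sex}:{st}"] = vals
        sign = cfg.de_log2fc if mod_sex == "F" else -cfg.de_log2fc
        contrast = _contrast_name(dominant)
        for g in members:
            truth.de_genes[contrast][g] = sign
        truth.modules[tf] = targets
        truth.module_info[tf] = (mod_sex, dominant)

    # --- counts ------------------------------------------------------------
    sample_rows = []
    count_cols = {}
    for sex, stage, n_rep in cfg.groups:
        means = mu_df[f"{sex}:{stage}"].to_numpy()
        r = 1.0 / cfg.dispersion
        p = r / (r + means)
        for rep in range(1, n_rep + 1):
            sample_id = f"{sex}{'L' if stage == 'leaf' else stage}_{rep}"
            count_cols[sample_id] = rng.negative_binomial(r, p)
            sample_rows.append((sample_id, sex, stage, rep))
    values = pd.DataFrame(count_cols, index=pd.Index(genes, name="gene_id"))
    samples = pd.DataFrame(
        sample_rows, columns=["sample", "sex", "stage", "replicate"]
    ).set_index("sample")
    lengths = pd.Series(cfg.gene_length, index=values.index, name="length")
    matrix = ExpressionMatrix(
        values=values, samples=samples, unit="counts", gene_lengths=lengths
    )

    # --- TF annotation and motifs -----------------------------------------
    tf_rows = []
    motif_counts: dict[str, np.ndarray] = {}
    pwms = []
    for m, members in enumerate(module_genes):
        tf = members[0]
        motif_id = f"MOTIF{m + 1:02d}"
        family = TF_FAMILIES[m % len(TF_FAMILIES)]
        consensus_idx = rng.integers(0, 4, cfg.motif_length)
        counts = np.full((4, cfg.motif_length), 5, dtype=int)
        counts[consensus_idx, np.arange(cfg.motif_length)] = 85
        motif_counts[motif_id] = counts
        pwms.append(PWM.from_counts(motif_id, counts))
        tf_rows.append((tf, family, motif_id))
        truth.tf_motif[tf] = motif_id
    for i, tf in enumerate(extra_tfs):
        tf_rows.append((tf, TF_FAMILIES[(cfg.n_modules + i) % len(TF_FAMILIES)], ""))
    tf_annotation = pd.DataFrame(tf_rows, columns=["gene_id", "family", "motif_id"])
    motifset = MotifSet(motifs=pwms)

    # --- promoters, genome and motif planting ------------------------------
    gc = cfg.background_gc
    base_probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    byte_lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    target_motif = {}
    for tf, targets in truth.modules.items():
        for g in targets:
            target_motif[g] = truth.tf_motif[tf]
    prom_codes = rng.choice(4, size=(cfg.n_genes, cfg.promoter_length), p=base_probs)
    body_codes = rng.choice(4, size=(cfg.n_genes, cfg.gene_length), p=base_probs)
    promoters: dict[str, PromoterRecord] = {}
    genome: dict[str, str] = {}
    gene_strand: dict[str, str] = {}
    for i, g in enumerate(genes):
        seq = byte_lookup[prom_codes[i]].tobytes().decode()
        if g in target_motif and rng.random() < cfg.motif_planting_rate:
            motif_id = target_motif[g]
            consensus = "".join(
                "ACGT"[j] for j in motif_counts[motif_id].argmax(axis=0)
            )
            off = int(rng.integers(0, cfg.promoter_length - cfg.motif_length + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inst = consensus if strand == "+" else reverse_complement(consensus)
            seq = seq[:off] + inst + seq[off + cfg.motif_length :]
            truth.motif_placements.setdefault(g, []).append((motif_id, off, strand))
        body = byte_lookup[body_codes[i]].tobytes().decode()
        g_strand = "+" if i % 2 == 0 else "-"
        gene_strand[g] = g_strand
        contig = f"contig_{g}"
        if g_strand == "+":
            genome[contig] = seq + body
            start, end = 0, cfg.promoter_length
        else:
            genome[contig] = body + reverse_complement(seq)
            start, end = cfg.gene_length, cfg.gene_length + cfg.promoter_length
        promoters[g] = PromoterRecord(
            gene_id=g, sequence=seq, contig=contig, start=start, end=end, strand=g_strand
        )

    true_means = GroupProfile(values=mu_df, unit="counts")
    return SyntheticDataset(
        config=cfg,
        matrix=matrix,
        true_means=true_means,
        promoters=PromoterSet(records=promoters),
        tf_annotation=tf_annotation,
        motif_counts=motif_counts,
        motifs=motifset,
        truth=truth,
        genome=genome,
        gene_strand=gene_strand,
    )


# ---------------------------------------------------------------------------
# writers / readers


def write_gff3(dataset: SyntheticDataset, path) -> None:
    cfg = dataset.config
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g, strand in dataset.gene_strand.items():
            contig = f"contig_{g}"
            if strand == "+":
                start = cfg.promoter_length + 1
                end = cfg.promoter_length + cfg.gene_length
            else:
                start = 1
                end = cfg.gene_length
            fh.write(
                f"{contig}\tpistilgrn\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={g}\n"
            )


def write_genome_fasta(dataset: SyntheticDataset, path) -> None:
    with open(path, "w") as fh:
        for contig, seq in dataset.genome.items():
            fh.write(f">{contig}\n{seq}\n")


def write_truth(truth: SyntheticTruth, outdir) -> None:
    """Serialize the planted truth as TSV files (lossless round-trip)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(g, grp) for g, grp in truth.stage_specific.items()],
        columns=["gene_id", "group"],
    ).to_csv(outdir / "truth_stage_specific.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (contrast, g, lfc)
            for contrast, d in truth.de_genes.items()
            for g, lfc in d.items()
        ],
        columns=["contrast", "gene_id", "log2fc"],
    ).to_csv(outdir / "truth_de_genes.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (tf, g, truth.module_info[tf][0], truth.module_info[tf][1], truth.tf_motif[tf])
            for tf, targets in truth.modules.items()
            for g in sorted(targets)
        ],
        columns=["tf", "target", "sex", "stage", "motif_id"],
    ).to_csv(outdir / "truth_modules.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (g, motif, off, strand)
            for g, placements in truth.motif_placements.items()
            for motif, off, strand in placements
        ],
        columns=["gene_id", "motif_id", "offset", "strand"],
    ).to_csv(outdir / "truth_motif_placements.tsv", sep="\t", index=False)


def read_truth(outdir) -> SyntheticTruth:
    outdir = Path(outdir)
    truth = SyntheticTruth()
    ss = pd.read_csv(outdir / "truth_stage_specific.tsv", sep="\t")
    truth.stage_specific = dict(zip(ss["gene_id"], ss["group"]))
    de = pd.read_csv(outdir / "truth_de_genes.tsv", sep="\t")
    for contrast, sub in de.groupby("contrast", sort=False):
        truth.de_genes[contrast] = dict(zip(sub["gene_id"], sub["log2fc"]))
    for stage in PISTIL_STAGES:  # preserve empty contrasts
        truth.de_genes.setdefault(_contrast_name(stage), {})
    mods = pd.read_csv(outdir / "truth_modules.tsv", sep="\t")
    for tf, sub in mods.groupby("tf", sort=False):
        truth.modules[tf] = set(sub["target"])
        truth.module_info[tf] = (sub["sex"].iloc[0], sub["stage"].iloc[0])
        truth.tf_motif[tf] = sub["motif_id"].iloc[0]
    pl = pd.read_csv(outdir / "truth_motif_placements.tsv", sep="\t")
    for _, row in pl.iterrows():
        truth.motif_placements.setdefault(row["gene_id"], []).append(
            (row["motif_id"], int(row["offset"]), row["strand"])
        )
    return truth


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every artifact of a synthetic dataset; returns a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "promoters": outdir / "promoters.fasta",
        "genome": outdir / "genome.fasta",
        "gff3": outdir / "genes.gff3",
        "tf_annotation": outdir / "tf_annotation.tsv",
        "motifs": outdir / "motifs.jaspar",
    }
    dataset.matrix.to_tsv(paths["counts"], paths["samples"])
    dataset.matrix.gene_lengths.rename("length").to_csv(
        paths["gene_lengths"], sep="\t", index_label="gene_id"
    )
    dataset.promoters.write_fasta(paths["promoters"])
    write_genome_fasta(dataset, paths["genome"])
    write_gff3(dataset, paths["gff3"])
    dataset.tf_annotation.to_csv(paths["tf_annotation"], sep="\t", index=False)
    write_jaspar(dataset.motif_counts, paths["motifs"])
    write_truth(dataset.truth, outdir)
    return {k: str(v) for k, v in paths.items()}
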