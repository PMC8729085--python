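"""Expression-matrix containers and stage-level expression statistics.

This module holds the abundance-side computations of the pipeline: reading a
gene x sample table with its metadata, converting raw counts to FPKM, binning
expression levels, expressed-gene fractions, within-group replicate
correlation (Spearman), PCA of samples, per-gene Z-scores of group means, the
stage-specificity (SS) score used to call preferentially expressed genes, and
the 2^-ddCt relative quantification used for qPCR cross-checks.

The SS score of gene *i* in group *j* over a set of group-mean FPKM values
``E`` is ``SS(i,j) = 1 - max_{s != j} E_s / E_j``; a gene is called
preferentially expressed in *j* when SS exceeds a threshold (default 0.3,
strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

SEXES = ("F", "M")
STAGES = ("S1", "S2", "S3", "S4", "leaf")

__all__ = [
    "ExpressionMatrix",
    "GroupProfile",
    "ZScoreMatrix",
    "SSScoreTable",
    "DdctResult",
    "read_expression",
    "counts_to_fpkm",
    "group_means",
    "expression_bins",
    "expressed_fraction",
    "replicate_correlation",
    "pca_embedding",
    "zscore",
    "ss_scores",
    "ddct",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Non-negative abundances, index = gene ids, columns = sample ids.
    samples : DataFrame
        One row per sample (index = sample id) with columns ``sex``
        (``F``/``M``), ``stage`` (``S1``..``S4`` or ``leaf``) and
        ``replicate`` (integer).
    unit : str
        ``"counts"`` or ``"fpkm"``.
    gene_lengths : Series, optional
        Transcript length in bases per gene; required for counts -> FPKM.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    unit: str = "counts"
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()]
            raise ValueError(f"duplicate gene ids: {list(dupes[:5])}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = self.values.columns.difference(self.samples.index)
        if len(missing):
            raise ValueError(f"samples missing from metadata: {list(missing)}")
        self.samples = self.samples.loc[self.values.columns]
        if self.unit not in ("counts", "fpkm"):
            raise ValueError(f"unknown unit {self.unit!r}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    def group_labels(self) -> pd.Series:
        """Per-sample ``sex:stage`` group label."""
        return self.samples["sex"].str.cat(self.samples["stage"], sep=":")

    def to_tsv(self, matrix_path, metadata_path) -> None:
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
        self.samples.to_csv(metadata_path, sep="\t", index_label="sample")


@dataclass
class GroupProfile:
    """Mean abundance per (sex, stage) group; columns labelled ``sex:stage``."""

    values: pd.DataFrame
    unit: str = "fpkm"

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def groups(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ZScoreMatrix:
    values: pd.DataFrame
    valid_mask: pd.Series  # False where the gene had SD = 0 across groups


@dataclass
class SSScoreTable:
    """Per-gene, per-group SS scores and preferential-expression calls."""

    scores: pd.DataFrame
    preferential: pd.DataFrame
    threshold: float = 0.3

    def preferential_genes(self, group: str) -> pd.Index:
        return self.preferential.index[self.preferential[group]]


@dataclass
class DdctResult:
    target_ct: float
    reference_ct: float
    calibrator_dct: float
    ddct: float
    relative_quantity: float


def read_expression(
    tsv_path, metadata_path, unit: str = "counts", gene_lengths: pd.Series | None = None
) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a sample metadata TSV."""
    values = pd.read_csv(tsv_path, sep="\t", index_col=0)
    bad = values.columns[~values.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(bad):
        raise ValueError(f"non-numeric expression columns: {list(bad)}")
    meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
    meta.index = meta.index.astype(str)
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values=values, samples=meta, unit=unit, gene_lengths=gene_lengths)


def counts_to_fpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """FPKM_ij = count_ij * 1e9 / (length_i * library_size_j)."""
    if matrix.unit != "counts":
        raise ValueError("counts_to_fpkm requires a counts matrix")
    if matrix.gene_lengths is None:
        raise ValueError("gene lengths are required for FPKM conversion")
    lengths = matrix.gene_lengths.reindex(matrix.gene_ids)
    if lengths.isna().any():
        raise ValueError("missing gene lengths")
    libsize = matrix.values.sum(axis=0)
    if (libsize == 0).any():
        empty = libsize.index[libsize == 0]
        raise ValueError(f"zero library size in samples: {list(empty)}")
    fpkm = matrix.values.mul(1e9).div(lengths, axis=0).div(libsize, axis=1)
    return ExpressionMatrix(
        values=fpkm, samples=matrix.samples, unit="fpkm", gene_lengths=matrix.gene_lengths
    )


def group_means(
    matrix: ExpressionMatrix, stage_merge: dict[str, str] | None = None
) -> GroupProfile:
    """Arithmetic mean per (sex, stage) group.

    ``stage_merge`` maps original stage names onto merged labels, e.g.
    ``{"S2": "S2-3", "S3": "S2-3"}`` pools all six replicates of the two
    meiosis stages into one group.
    """
    stage = matrix.samples["stage"]
    if stage_merge:
        stage = stage.replace(stage_merge)
    labels = matrix.samples["sex"].str.cat(stage, sep=":")
    means = matrix.values.T.groupby(labels).mean().T
    # keep metadata order of first appearance rather than alphabetical
    order = list(dict.fromkeys(labels))
    return GroupProfile(values=means[order], unit=matrix.unit)


#: expression-level bins on the FPKM scale, highest first
EXPRESSION_BINS = (
    ("extremely_high", 100.0, np.inf),
    ("high", 50.0, 100.0),
    ("medium", 10.0, 50.0),
    ("low", 1.0, 10.0),
    ("not_expressed", -np.inf, 1.0),
)


def expression_bins(values: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-sample (or per-group) gene counts and fractions by FPKM level.

    Bins: >=100 extremely high, [50,100) high, [10,50) medium, [1,10) low,
    <1 not expressed. Fractions sum to 1 in every column.
    """
    counts = {}
    for name, lo, hi in EXPRESSION_BINS:
        counts[name] = ((values >= lo) & (values < hi)).sum(axis=0)
    count_df = pd.DataFrame(counts).T
    frac_df = count_df / count_df.sum(axis=0)
    return {"counts": count_df, "fractions": frac_df}


def expressed_fraction(
    values: pd.DataFrame, threshold: float = 1.0, scope: str = "any-sample"
):
    """Fraction of genes expressed (FPKM >= threshold).

    ``scope="any-sample"`` returns a scalar (expressed in at least one
    column); ``scope="per-column"`` returns a per-column Series.
    """
    expressed = values >= threshold
    if scope == "any-sample":
        return float(expressed.any(axis=1).mean())
    if scope == "per-column":
        return expressed.mean(axis=0)
    raise ValueError(f"unknown scope {scope!r}")


def replicate_correlation(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Spearman correlation for every within-group replicate pair.

    Returns a table with columns group, sample_a, sample_b, spearman_rho.
    Constant profiles yield NaN (correlation undefined).
    """
    rows = []
    labels = matrix.group_labels()
    for group in dict.fromkeys(labels):
        cols = labels.index[labels == group]
        for i in range(len(cols)):
            for j in range(i + 1, len(cols)):
                a = matrix.values[cols[i]].to_numpy()
                b = matrix.values[cols[j]].to_numpy()
                if np.ptp(a) == 0 or np.ptp(b) == 0:
                    rho = np.nan
                else:
                    rho = stats.spearmanr(a, b).statistic
                rows.append((group, cols[i], cols[j], rho))
    return pd.DataFrame(rows, columns=["group", "sample_a", "sample_b", "spearman_rho"])


def pca_embedding(matrix: ExpressionMatrix, n_components: int = 3):
    """Sample PCA on log2(FPKM + 1), gene-centered, via SVD.

    Returns (coordinates DataFrame samples x PCs, explained variance ratio).
    Components are ordered by decreasing variance; if ``n_components``
    exceeds the rank, the embedding is truncated.
    """
    x = np.log2(matrix.values.to_numpy(dtype=float) + 1.0)
    x = x - x.mean(axis=1, keepdims=True)  # center each gene
    # samples are observations: operate on x.T (samples x genes)
    u, s, _ = np.linalg.svd(x.T, full_matrices=False)
    n_samples = x.shape[1]
    var = s**2 / max(n_samples - 1, 1)
    total = var.sum()
    rank = int((s > s[0] * 1e-12).sum()) if len(s) else 0
    k = min(n_components, rank)
    if k < n_components:
        import warnings

        warnings.warn(
            f"requested {n_components} components but the centered matrix has "
            f"rank {rank}; returning {k}"
        )
    coords = u[:, :k] * s[:k]
    cols = [f"PC{i + 1}" for i in range(k)]
    coords = pd.DataFrame(coords, index=matrix.values.columns, columns=cols)
    ratio = var[:k] / total if total > 0 else np.zeros(k)
    return coords, ratio


def zscore(profile: GroupProfile) -> ZScoreMatrix:
    """Per-gene standardization of group means: z = (x - mean) / SD (n-1)."""
    x = profile.values
    mu = x.mean(axis=1)
    sd = x.std(axis=1, ddof=1)
    valid = sd > 0
    z = x.sub(mu, axis=0).div(sd.where(valid), axis=0)
    z[~valid] = np.nan
    return ZScoreMatrix(values=z, valid_mask=valid)


def ss_scores(profile: GroupProfile, threshold: float = 0.3) -> SSScoreTable:
    """Stage-specificity score per gene and group.

    ``SS(i,j) = 1 - max_{s != j} E_s / E_j`` on the group-mean FPKM profile.
    ``E_j = 0`` yields a -inf sentinel (never preferential); a gene expressed
    only in ``j`` scores exactly 1. Preferential calls use a strict
    ``SS > threshold``.
    """
    e = profile.values.to_numpy(dtype=float)
    n_genes, n_groups = e.shape
    if n_groups < 2:
        raise ValueError("SS scores require at least two groups")
    scores = np.full((n_genes, n_groups), -np.inf)
    pref = np.zeros((n_genes, n_groups), dtype=bool)
    for j in range(n_groups):
        others = np.delete(e, j, axis=1)
        max_other = others.max(axis=1)
        focal = e[:, j]
        pos = focal > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            scores[pos, j] = 1.0 - max_other[pos] / focal[pos]
        # SS > t  <=>  max_other < (1 - t) * E_j; the ratio form avoids the
        # 1 - x/y rounding that would misclassify exact-boundary profiles
        pref[:, j] = pos & (max_other < (1.0 - threshold) * focal)
    score_df = pd.DataFrame(scores, index=profile.gene_ids, columns=profile.groups)
    pref_df = pd.DataFrame(pref, index=profile.gene_ids, columns=profile.groups)
    return SSScoreTable(scores=score_df, preferential=pref_df, threshold=threshold)


def ddct(
    target_ct: float,
    ref_ct: float,
    calibrator_target_ct: float,
    calibrator_ref_ct: float,
) -> DdctResult:
    """Relative quantification 2^-ddCt against a reference gene and calibrator."""
    for v in (target_ct, ref_ct, calibrator_target_ct, calibrator_ref_ct):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dct = target_ct - ref_ct
    cal_dct = calibrator_target_ct - calibrator_ref_ct
    dd = dct - cal_dct
    return DdctResult(
        target_ct=target_ct,
        reference_ct=ref_ct,
        calibrator_dct=cal_dct,
        ddct=dd,
        relative_quantity=float(2.0 ** (-dd)),
    )
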