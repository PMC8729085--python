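"""Negative-binomial differential expression, two ways, and shared DEGs.

Each female-vs-male stage contrast is tested with two methodologically
distinct negative-binomial procedures and the per-contrast intersection of
their significant genes ("shared DEGs") feeds the network stages:

* method A — a Wald test: per-gene method-of-moments dispersion shrunk
  toward a binned mean-dispersion trend, normalized group means, and a
  normal test of log2FC / SE;
* method B — a conditional exact test: library sizes equalized through size
  factors, then the split of the two group sums is compared against its
  exact conditional NB distribution (doubled smaller tail, capped at 1).

Significance in either method is BH-adjusted p < 0.05 together with
|log2FC| > 1 (both strict). BH adjustment is the classic step-up procedure,
implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

from .expression import ExpressionMatrix

DISPERSION_FLOOR = 1e-8
PSEUDOCOUNT = 0.5

__all__ = [
    "Contrast",
    "make_stage_contrasts",
    "normalize_size_factors",
    "bh_adjust",
    "estimate_dispersions",
    "de_test_A",
    "de_test_B",
    "shared_degs",
]


@dataclass
class Contrast:
    """Named two-group comparison; A over B in fold changes."""

    name: str
    group_a: list[str]
    group_b: list[str]

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError(f"contrast {self.name}: both sample groups must be non-empty")
        if set(self.group_a) & set(self.group_b):
            raise ValueError(f"contrast {self.name}: sample groups overlap")


def make_stage_contrasts(
    matrix: ExpressionMatrix, stages=("S1", "S2", "S3", "S4")
) -> list[Contrast]:
    """One F-vs-M contrast per pistil stage (FS1_vs_MS1, ...)."""
    out = []
    meta = matrix.samples
    for stage in stages:
        fa = list(meta.index[(meta["sex"] == "F") & (meta["stage"] == stage)])
        mb = list(meta.index[(meta["sex"] == "M") & (meta["stage"] == stage)])
        out.append(Contrast(name=f"F{stage}_vs_M{stage}", group_a=fa, group_b=mb))
    return out


# ---------------------------------------------------------------------------
# normalization


def normalize_size_factors(counts: pd.DataFrame, method: str = "median-of-ratios") -> pd.Series:
    """Per-sample sequencing-depth factors.

    ``median-of-ratios``: per-sample median of count ratios against the
    per-gene geometric-mean reference (genes with a zero anywhere drop out
    of the reference). ``tmm``: library size scaled by a trimmed (30% log
    ratio / 5% abundance) mean of log ratios against a reference sample.
    """
    x = counts.to_numpy(dtype=float)
    if (x.sum(axis=0) == 0).any():
        bad = counts.columns[x.sum(axis=0) == 0]
        raise ValueError(f"all-zero samples: {list(bad)}")
    if method == "median-of-ratios":
        with np.errstate(divide="ignore"):
            logx = np.log(x)
        ref = logx.mean(axis=1)  # -inf for genes with any zero
        usable = np.isfinite(ref)
        if not usable.any():
            raise ValueError("no gene is positive in every sample")
        ratios = logx[usable] - ref[usable, None]
        return pd.Series(np.exp(np.median(ratios, axis=0)), index=counts.columns)
    if method == "tmm":
        lib = x.sum(axis=0)
        # reference sample: library size closest to the mean
        ref_j = int(np.argmin(np.abs(lib - lib.mean())))
        factors = np.ones(x.shape[1])
        for j in range(x.shape[1]):
            if j == ref_j:
                continue
            ok = (x[:, j] > 0) & (x[:, ref_j] > 0)
            m = np.log2((x[ok, j] / lib[j]) / (x[ok, ref_j] / lib[ref_j]))
            a = 0.5 * np.log2((x[ok, j] / lib[j]) * (x[ok, ref_j] / lib[ref_j]))
            keep = (
                (m >= np.quantile(m, 0.30))
                & (m <= np.quantile(m, 0.70))
                & (a >= np.quantile(a, 0.05))
                & (a <= np.quantile(a, 0.95))
            )
            factors[j] = 2.0 ** np.mean(m[keep]) if keep.any() else 1.0
        sf = factors * lib
        sf = sf / np.exp(np.mean(np.log(sf)))
        return pd.Series(sf, index=counts.columns)
    raise ValueError(f"unknown normalization method {method!r}")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


# ---------------------------------------------------------------------------
# dispersion


def estimate_dispersions(
    counts: pd.DataFrame,
    groups: list[list[str]],
    size_factors: pd.Series,
    n_bins: int = 20,
    shrink_weight: float = 0.15,
) -> pd.Series:
    """Per-gene NB dispersion: method-of-moments shrunk toward a mean trend.

    The raw estimate solves var(y) = mu * mean(1/s) + alpha * mu^2 on
    normalized counts, pooled within groups. The trend is the *mean* raw
    estimate in equal-count bins of log mean, interpolated: with few
    replicates the raw estimator is strongly right-skewed, so binned
    medians sit well below the true dispersion while binned means (negative
    estimates included) stay close to unbiased. The final value is a
    log-scale blend with ``shrink_weight`` on the per-gene estimate; the
    weight is kept small because each raw estimate carries only a few
    degrees of freedom.
    """
    y = counts.div(size_factors, axis=1).to_numpy(dtype=float)
    inv_s = float((1.0 / size_factors).mean())
    resid_ss = np.zeros(counts.shape[0])
    dof = 0
    mu = np.zeros(counts.shape[0])
    n_total = 0
    for g in groups:
        idx = [counts.columns.get_loc(c) for c in g]
        sub = y[:, idx]
        m = sub.mean(axis=1)
        resid_ss += ((sub - m[:, None]) ** 2).sum(axis=1)
        dof += len(idx) - 1
        mu += m * len(idx)
        n_total += len(idx)
    mu /= n_total
    var = resid_ss / max(dof, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (var - mu * inv_s) / mu**2
    raw[~np.isfinite(raw)] = 0.0
    # trend: binned mean raw estimate over log mean
    pos = mu > 0
    if pos.sum() >= n_bins:
        logmu = np.log(mu[pos])
        order = np.argsort(logmu, kind="stable")
        edges = np.array_split(order, n_bins)
        centers = np.array([logmu[e].mean() for e in edges])
        levels = np.array([max(np.mean(raw[pos][e]), DISPERSION_FLOOR) for e in edges])
        trend = np.interp(np.log(np.maximum(mu, 1e-12)), centers, levels)
    else:
        fallback = np.mean(raw[pos]) if pos.any() else DISPERSION_FLOOR
        trend = np.full_like(mu, max(fallback, DISPERSION_FLOOR))
    trend = np.maximum(trend, DISPERSION_FLOOR)
    raw_f = np.maximum(raw, DISPERSION_FLOOR)
    alpha = np.exp(
        shrink_weight * np.log(raw_f) + (1.0 - shrink_weight) * np.log(trend)
    )
    alpha[raw <= 0] = trend[raw <= 0]  # uninformative raw estimate: take the trend
    return pd.Series(np.maximum(alpha, DISPERSION_FLOOR), index=counts.index)


# ---------------------------------------------------------------------------
# tests


def _normalized_group_means(counts, contrast, size_factors):
    ya = counts[contrast.group_a].div(size_factors[contrast.group_a], axis=1)
    yb = counts[contrast.group_b].div(size_factors[contrast.group_b], axis=1)
    return ya.mean(axis=1), yb.mean(axis=1)


def _log2fc(mean_a: pd.Series, mean_b: pd.Series) -> pd.Series:
    return np.log2((mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT))


def _finish(result: pd.DataFrame, fdr: float, lfc_threshold: float) -> pd.DataFrame:
    result["padj"] = bh_adjust(result["pvalue"].to_numpy())
    result["significant"] = (result["padj"] < fdr) & (
        result["log2fc"].abs() > lfc_threshold
    )
    return result


def de_test_A(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    fdr: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """NB Wald test with trend-shrunk moment dispersions."""
    if matrix.unit != "counts":
        raise ValueError("DE tests run on raw counts")
    if len(contrast.group_a) < 2 or len(contrast.group_b) < 2:
        raise ValueError(f"contrast {contrast.name}: need >= 2 replicates per side")
    cols = contrast.group_a + contrast.group_b
    counts = matrix.values[cols]
    sf = normalize_size_factors(counts)
    alpha = estimate_dispersions(counts, [contrast.group_a, contrast.group_b], sf)
    mean_a, mean_b = _normalized_group_means(counts, contrast, sf)
    lfc = _log2fc(mean_a, mean_b)

    def group_var(group, mean):
        s = sf[group].to_numpy()
        mu = mean.to_numpy()
        per_sample = mu[:, None] / s[None, :] + alpha.to_numpy()[:, None] * mu[:, None] ** 2
        return per_sample.sum(axis=1) / len(group) ** 2

    va = group_var(contrast.group_a, mean_a) / (mean_a.to_numpy() + PSEUDOCOUNT) ** 2
    vb = group_var(contrast.group_b, mean_b) / (mean_b.to_numpy() + PSEUDOCOUNT) ** 2
    se_log2 = np.sqrt(va + vb) / np.log(2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_log2 > 0, lfc.to_numpy() / se_log2, 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    result = pd.DataFrame(
        {
            "gene_id": counts.index,
            "contrast": contrast.name,
            "method": "A",
            "log2fc": lfc.to_numpy(),
            "pvalue": np.clip(p, 0.0, 1.0),
        }
    )
    return _finish(result, fdr, lfc_threshold)


def _exact_nb_pvalue(sum_a: int, sum_b: int, n_a: int, n_b: int, alpha: float) -> float:
    """Conditional exact NB test of a group-sum split given the total.

    The sum of ``n`` i.i.d. NB(mu, alpha) counts is NB(n mu, alpha / n).
    Conditional on the total, the probability of each split is the product
    of the two sum pmfs renormalized; the p-value doubles the smaller tail.
    """
    total = sum_a + sum_b
    if total == 0:
        return 1.0
    mu = total / (n_a + n_b)
    x = np.arange(total + 1)
    r_a, r_b = n_a / alpha, n_b / alpha
    pa = r_a / (r_a + n_a * mu)
    pb = r_b / (r_b + n_b * mu)
    log_joint = stats.nbinom.logpmf(x, r_a, pa) + stats.nbinom.logpmf(total - x, r_b, pb)
    log_joint -= logsumexp(log_joint)
    probs = np.exp(log_joint)
    p_low = probs[: sum_a + 1].sum()
    p_high = probs[sum_a:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def de_test_B(
    matrix: ExpressionMatrix,
    contrast: Contrast,
    fdr: float = 0.05,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Conditional exact NB test on library-equalized group sums."""
    if matrix.unit != "counts":
        raise ValueError("DE tests run on raw counts")
    if len(contrast.group_a) < 2 or len(contrast.group_b) < 2:
        raise ValueError(f"contrast {contrast.name}: need >= 2 replicates per side")
    cols = contrast.group_a + contrast.group_b
    counts = matrix.values[cols]
    sf = normalize_size_factors(counts)
    sf = sf / np.exp(np.mean(np.log(sf)))  # common scale for pseudo-counts
    alpha = estimate_dispersions(counts, [contrast.group_a, contrast.group_b], sf)
    pseudo = counts.div(sf, axis=1)
    sums_a = np.rint(pseudo[contrast.group_a].sum(axis=1)).astype(np.int64)
    sums_b = np.rint(pseudo[contrast.group_b].sum(axis=1)).astype(np.int64)
    n_a, n_b = len(contrast.group_a), len(contrast.group_b)
    pvals = np.array(
        [
            _exact_nb_pvalue(int(sa), int(sb), n_a, n_b, max(a, DISPERSION_FLOOR))
            for sa, sb, a in zip(sums_a, sums_b, alpha.to_numpy())
        ]
    )
    mean_a, mean_b = _normalized_group_means(counts, contrast, sf)
    result = pd.DataFrame(
        {
            "gene_id": counts.index,
            "contrast": contrast.name,
            "method": "B",
            "log2fc": _log2fc(mean_a, mean_b).to_numpy(),
            "pvalue": pvals,
        }
    )
    return _finish(result, fdr, lfc_threshold)


def shared_degs(
    results_a: dict[str, pd.DataFrame], results_b: dict[str, pd.DataFrame]
) -> dict:
    """Intersection of the two methods' significant genes, per contrast.

    The printed total is the sum of per-contrast counts (a gene significant
    in several contrasts counts once per contrast).
    """
    if set(results_a) != set(results_b):
        raise ValueError("the two methods were run on different contrasts")
    shared: dict[str, list[str]] = {}
    for contrast in results_a:
        a = results_a[contrast]
        sig_a = set(a.loc[a["significant"], "gene_id"])
        b = results_b[contrast]
        sig_b = set(b.loc[b["significant"], "gene_id"])
        shared[contrast] = sorted(sig_a & sig_b)
    counts = {c: len(g) for c, g in shared.items()}
    return {"per_contrast": shared, "counts": counts, "total": sum(counts.values())}
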