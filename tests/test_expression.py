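"""Expression-side computations: FPKM, bins, correlation, PCA, Z, SS, ddCt."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pistilgrn.expression import (
    GroupProfile,
    counts_to_fpkm,
    ddct,
    expressed_fraction,
    expression_bins,
    group_means,
    pca_embedding,
    read_expression,
    replicate_correlation,
    ss_scores,
    zscore,
)

from conftest import toy_matrix


# ---------------------------------------------------------------------- I/O


def test_read_expression_round_trip(tmp_path, small_dataset):
    m, s = tmp_path / "m.tsv", tmp_path / "s.tsv"
    small_dataset.matrix.to_tsv(m, s)
    back = read_expression(m, s, unit="counts",
                           gene_lengths=small_dataset.matrix.gene_lengths)
    pd.testing.assert_frame_equal(back.values, small_dataset.matrix.values)
    pd.testing.assert_frame_equal(back.samples, small_dataset.matrix.samples)


def test_read_expression_toy_and_errors(tmp_path):
    (tmp_path / "m.tsv").write_text("gene_id\ts1\ts2\ng1\t1\t2\ng2\t3\t4\n")
    (tmp_path / "meta.tsv").write_text("sample\tsex\tstage\treplicate\ns1\tF\tS1\t1\ns2\tF\tS1\t2\n")
    mat = read_expression(tmp_path / "m.tsv", tmp_path / "meta.tsv")
    assert mat.values.shape == (2, 2)
    # a sample absent from the metadata is an error
    (tmp_path / "meta2.tsv").write_text("sample\tsex\tstage\treplicate\ns1\tF\tS1\t1\n")
    with pytest.raises(ValueError, match="missing from metadata"):
        read_expression(tmp_path / "m.tsv", tmp_path / "meta2.tsv")
    # duplicate gene ids are an error
    (tmp_path / "dup.tsv").write_text("gene_id\ts1\ts2\ng1\t1\t2\ng1\t3\t4\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_expression(tmp_path / "dup.tsv", tmp_path / "meta.tsv")


# --------------------------------------------------------------------- FPKM


def test_fpkm_hand_value_and_zero_gene():
    # 10 fragments on a 1 kb gene in a 1M-read library -> FPKM 10
    groups = {"s1": ("F", "S1", 1)}
    mat = toy_matrix({"s1": [10, 1_000_000 - 10, 0]}, groups, unit="counts",
                     lengths=[1000, 1000, 500])
    fpkm = counts_to_fpkm(mat)
    assert fpkm.values.at["g1", "s1"] == pytest.approx(10.0)
    assert fpkm.values.at["g3", "s1"] == 0.0
    assert fpkm.unit == "fpkm"


def test_fpkm_invariant_to_uniform_depth_scaling():
    groups = {"s1": ("F", "S1", 1), "s2": ("F", "S1", 2)}
    mat = toy_matrix({"s1": [10, 30, 60], "s2": [20, 60, 120]}, groups,
                     unit="counts", lengths=[500, 1000, 2000])
    fpkm = counts_to_fpkm(mat)
    np.testing.assert_allclose(fpkm.values["s1"], fpkm.values["s2"])


def test_fpkm_requires_counts_and_lengths():
    groups = {"s1": ("F", "S1", 1)}
    with pytest.raises(ValueError, match="lengths"):
        counts_to_fpkm(toy_matrix({"s1": [1]}, groups, unit="counts"))


# -------------------------------------------------------------- group means


def test_group_means_with_and_without_merge():
    groups = {
        "a1": ("F", "S2", 1), "a2": ("F", "S2", 2), "a3": ("F", "S2", 3),
        "b1": ("F", "S3", 1), "b2": ("F", "S3", 2), "b3": ("F", "S3", 3),
        "c1": ("F", "S4", 1),
    }
    mat = toy_matrix({"a1": [1], "a2": [3], "a3": [2], "b1": [10], "b2": [20],
                      "b3": [30], "c1": [7]}, groups)
    plain = group_means(mat)
    assert plain.values.at["g1", "F:S2"] == pytest.approx(2.0)
    assert plain.values.at["g1", "F:S4"] == 7.0  # single replicate = value
    merged = group_means(mat, stage_merge={"S2": "S2-3", "S3": "S2-3"})
    assert merged.values.at["g1", "F:S2-3"] == pytest.approx((1 + 3 + 2 + 10 + 20 + 30) / 6)


# --------------------------------------------------------------------- bins


def test_expression_bins_boundaries_and_normalization(rng):
    df = pd.DataFrame({"s": [100.0, 99.9, 50.0, 10.0, 1.0, 0.5, 0.0]})
    bins = expression_bins(df)
    c = bins["counts"]["s"]
    assert c["extremely_high"] == 1  # FPKM 100 is extremely high
    assert c["high"] == 2
    assert c["medium"] == 1
    assert c["low"] == 1
    assert c["not_expressed"] == 2  # 0 < FPKM < 1 means not expressed
    random = pd.DataFrame(rng.gamma(1, 40, (500, 4)))
    np.testing.assert_allclose(expression_bins(random)["fractions"].sum(axis=0), 1.0)


def test_uniform_fpkm_is_all_medium():
    df = pd.DataFrame({"s": [10.0] * 8})
    assert expression_bins(df)["fractions"].at["medium", "s"] == 1.0


def test_expressed_fraction_matches_brute_force(small_dataset):
    fpkm = counts_to_fpkm(small_dataset.matrix).values
    frac = expressed_fraction(fpkm)
    brute = sum(1 for g in fpkm.index if (fpkm.loc[g] >= 1.0).any()) / len(fpkm)
    assert frac == pytest.approx(brute)
    assert expressed_fraction(pd.DataFrame({"s": [2.0, 0.0], "t": [3.0, 0.5]})) == 0.5


# -------------------------------------------------------------- correlation


def test_replicate_correlation_known_cases():
    groups = {"r1": ("F", "S1", 1), "r2": ("F", "S1", 2), "r3": ("F", "S1", 3)}
    vals = {"r1": [1, 2, 3, 4, 5], "r2": [1, 2, 3, 4, 5], "r3": [5, 4, 3, 2, 1]}
    table = replicate_correlation(toy_matrix(vals, groups))
    by_pair = table.set_index(["sample_a", "sample_b"])["spearman_rho"]
    assert by_pair[("r1", "r2")] == pytest.approx(1.0)
    assert by_pair[("r1", "r3")] == pytest.approx(-1.0)


def test_replicate_correlation_equals_rank_pearson(rng):
    groups = {"r1": ("M", "S2", 1), "r2": ("M", "S2", 2)}
    a, b = rng.gamma(2, 30, 5), rng.gamma(2, 30, 5)
    table = replicate_correlation(toy_matrix({"r1": a, "r2": b}, groups))
    ranks_a = pd.Series(a).rank().to_numpy()
    ranks_b = pd.Series(b).rank().to_numpy()
    assert table["spearman_rho"].iloc[0] == pytest.approx(np.corrcoef(ranks_a, ranks_b)[0, 1])


def test_replicate_correlation_constant_profile_is_missing():
    groups = {"r1": ("F", "S1", 1), "r2": ("F", "S1", 2)}
    table = replicate_correlation(toy_matrix({"r1": [1, 1, 1], "r2": [1, 2, 3]}, groups))
    assert np.isnan(table["spearman_rho"].iloc[0])


# ---------------------------------------------------------------------- PCA


def test_pca_identical_samples_collocate_and_rank1_line(rng):
    groups = {f"s{i}": ("F", "S1", i) for i in range(1, 4)}
    vals = rng.gamma(2, 30, 50)
    mat = toy_matrix({"s1": vals, "s2": vals, "s3": rng.gamma(2, 30, 50)}, groups)
    coords, _ = pca_embedding(mat, n_components=2)
    np.testing.assert_allclose(coords.loc["s1"], coords.loc["s2"], atol=1e-9)
    # samples on a line in log space: PC1 carries all the variance
    base = rng.gamma(2, 2, 40)
    line = toy_matrix(
        {"s1": 2.0**base, "s2": 2.0 ** (base + 1), "s3": 2.0 ** (base + 2)},
        groups,
    )
    # subtract 1 so that log2(x+1) is exactly affine in the latent coordinate
    line.values.iloc[:] = np.maximum(line.values.to_numpy() - 1.0, 0.0)
    _, ratio = pca_embedding(line, n_components=3)
    assert ratio[0] == pytest.approx(1.0, abs=1e-9)


def test_pca_variance_conservation(rng):
    groups = {f"s{i}": ("M", "S3", i) for i in range(1, 6)}
    mat = toy_matrix({f"s{i}": rng.gamma(2, 30, 80) for i in range(1, 6)}, groups)
    x = np.log2(mat.values.to_numpy() + 1)
    x = x - x.mean(axis=1, keepdims=True)
    total = np.var(x.T, axis=0, ddof=1).sum()
    coords, ratio = pca_embedding(mat, n_components=4)
    recovered = np.var(coords.to_numpy(), axis=0, ddof=1)
    np.testing.assert_allclose(recovered / total, ratio, rtol=1e-9)
    assert ratio.sum() <= 1.0 + 1e-12


# ------------------------------------------------------------------ Z-score


def test_zscore_hand_case_and_masking():
    profile = GroupProfile(values=pd.DataFrame(
        {"F:S1": [1.0, 5.0], "F:S2": [2.0, 5.0], "F:S3": [3.0, 5.0]},
        index=["g1", "g2"]))
    z = zscore(profile)
    np.testing.assert_allclose(z.values.loc["g1"], [-1.0, 0.0, 1.0])
    assert not z.valid_mask["g2"]
    assert z.values.loc["g2"].isna().all()


@given(st.lists(st.floats(min_value=0.1, max_value=1e4), min_size=3, max_size=10,
                unique=True),
       st.floats(min_value=0.1, max_value=50),
       st.floats(min_value=-100, max_value=100))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_zscore_affine_invariance(row, scale, shift):
    cols = [f"F:S{i}" for i in range(len(row))]
    base = GroupProfile(values=pd.DataFrame([row], columns=cols, index=["g"]))
    moved = GroupProfile(values=pd.DataFrame([[scale * v + shift for v in row]],
                                             columns=cols, index=["g"]))
    z1, z2 = zscore(base), zscore(moved)
    np.testing.assert_allclose(z1.values.to_numpy(), z2.values.to_numpy(),
                               rtol=1e-8, atol=1e-8)
    assert z1.values.loc["g"].mean() == pytest.approx(0.0, abs=1e-9)
    assert z1.values.loc["g"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------- SS score


def _ss_brute_force(e):
    """Independent double-loop evaluation of the SS definition."""
    n_genes, n_groups = e.shape
    out = np.full_like(e, -np.inf, dtype=float)
    for i in range(n_genes):
        for j in range(n_groups):
            if e[i, j] > 0:
                max_other = max(e[i, s] for s in range(n_groups) if s != j)
                out[i, j] = 1.0 - max_other / e[i, j]
    return out


def test_ss_hand_cases_and_threshold_strictness():
    cols = [f"F:S{i}" for i in range(1, 5)]
    e = pd.DataFrame(
        [
            [4.0, 1.0, 1.0, 1.0],  # SS = 1 - 1/4 = 0.75 in group 1
            [2.0, 2.0, 1.0, 1.0],  # focal equals max elsewhere: SS = 0
            [10.0, 7.0, 1.0, 1.0],  # SS = 0.3 exactly in group 1
            [0.0, 0.0, 0.0, 0.0],  # all-zero gene: sentinel everywhere
            [3.0, 0.0, 0.0, 0.0],  # expressed only in group 1: SS = 1
        ],
        columns=cols, index=list("abcde"))
    table = ss_scores(GroupProfile(values=e))
    assert table.scores.at["a", "F:S1"] == pytest.approx(0.75)
    assert table.preferential.at["a", "F:S1"]
    assert table.scores.at["b", "F:S1"] == 0.0
    assert not table.preferential.at["b", "F:S1"]
    assert table.scores.at["c", "F:S1"] == pytest.approx(0.3)
    assert not table.preferential.at["c", "F:S1"]  # strict > 0.3
    assert np.isneginf(table.scores.loc["d"]).all()
    assert not table.preferential.loc["d"].any()
    assert table.scores.at["e", "F:S1"] == 1.0


@given(st.integers(min_value=0, max_value=2**31 - 1))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_ss_matches_brute_force_on_random_profiles(seed):
    r = np.random.default_rng(seed)
    e = r.gamma(1.0, 50.0, (12, 10))
    e[r.random((12, 10)) < 0.15] = 0.0  # exercise the zero branches
    cols = [f"G{j}" for j in range(10)]
    table = ss_scores(GroupProfile(values=pd.DataFrame(e, columns=cols)))
    np.testing.assert_allclose(table.scores.to_numpy(), _ss_brute_force(e),
                               atol=1e-12, rtol=0)


# -------------------------------------------------------------------- ddCt


@pytest.mark.parametrize(
    "target,ref,cal_t,cal_r,expected",
    [
        (20.0, 18.0, 22.0, 20.0, 1.0),   # ddCt = 0
        (21.0, 18.0, 22.0, 20.0, 0.5),   # ddCt = 1
        (18.0, 18.0, 22.0, 20.0, 4.0),   # ddCt = -2
    ],
)
def test_ddct_relative_quantities(target, ref, cal_t, cal_r, expected):
    assert ddct(target, ref, cal_t, cal_r).relative_quantity == pytest.approx(expected)


def test_ddct_rejects_non_finite():
    with pytest.raises(ValueError):
        ddct(np.nan, 18.0, 22.0, 20.0)
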