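"""Promoters, PWM parsing, exact-null scanning, Fisher enrichment."""

import math

import numpy as np
import pandas as pd
import pytest

from pistilgrn.motifs import (
    MotifSet,
    PWM,
    PromoterSet,
    background_frequencies,
    enrich_motifs,
    extract_promoters,
    read_motifs,
    reverse_complement,
    scan_promoters,
    scan_sequence,
    score_distribution,
    score_threshold,
    write_jaspar,
    write_meme,
)


# ---------------------------------------------------------------- promoters


def _write_toy_genome(tmp_path, contig_len=10_000, seed=0):
    rng = np.random.default_rng(seed)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, contig_len))
    (tmp_path / "genome.fa").write_text(f">chr1\n{seq}\n")
    return seq


def test_plus_strand_promoter_coordinates(tmp_path):
    seq = _write_toy_genome(tmp_path)
    (tmp_path / "genes.gff3").write_text(
        "##gff-version 3\nchr1\tsrc\tgene\t3001\t4000\t.\t+\t.\tID=geneA\n")
    proms = extract_promoters(tmp_path / "genome.fa", tmp_path / "genes.gff3")
    rec = proms.records["geneA"]
    assert rec.sequence == seq[1000:3000]
    assert (rec.start, rec.end, rec.strand, rec.truncated) == (1000, 3000, "+", False)


def test_minus_strand_promoter_is_reverse_complement(tmp_path):
    seq = _write_toy_genome(tmp_path, seed=1)
    (tmp_path / "genes.gff3").write_text(
        "##gff-version 3\nchr1\tsrc\tgene\t2001\t5000\t.\t-\t.\tID=geneB\n")
    proms = extract_promoters(tmp_path / "genome.fa", tmp_path / "genes.gff3")
    assert proms.sequence("geneB") == reverse_complement(seq[5000:7000])


def test_promoter_truncated_at_contig_edge(tmp_path):
    _write_toy_genome(tmp_path, contig_len=1500, seed=2)
    (tmp_path / "genes.gff3").write_text(
        "##gff-version 3\nchr1\tsrc\tgene\t501\t900\t.\t+\t.\tID=geneC\n")
    rec = extract_promoters(tmp_path / "genome.fa", tmp_path / "genes.gff3").records["geneC"]
    assert len(rec.sequence) == 500 and rec.truncated


def test_extraction_errors(tmp_path):
    _write_toy_genome(tmp_path)
    (tmp_path / "bad_contig.gff3").write_text(
        "##gff-version 3\nchrX\tsrc\tgene\t3001\t4000\t.\t+\t.\tID=g\n")
    with pytest.raises(ValueError, match="absent from genome"):
        extract_promoters(tmp_path / "genome.fa", tmp_path / "bad_contig.gff3")
    (tmp_path / "no_strand.gff3").write_text(
        "##gff-version 3\nchr1\tsrc\tgene\t3001\t4000\t.\t.\t.\tID=g\n")
    with pytest.raises(ValueError, match="strand"):
        extract_promoters(tmp_path / "genome.fa", tmp_path / "no_strand.gff3")


def test_extracted_promoters_equal_generated_ones(tmp_path, small_dataset):
    from pistilgrn.simulate import write_dataset

    files = write_dataset(small_dataset, tmp_path)
    ext = extract_promoters(files["genome"], files["gff3"])
    for g in small_dataset.promoters.gene_ids():
        assert ext.sequence(g) == small_dataset.promoters.sequence(g)


def test_promoter_fasta_round_trip(tmp_path, small_dataset):
    path = tmp_path / "p.fa"
    small_dataset.promoters.write_fasta(path)
    back = PromoterSet.read_fasta(path)
    for g, rec in small_dataset.promoters.records.items():
        assert back.records[g] == rec


# ------------------------------------------------------------------ parsing


def test_jaspar_parsing_columns_sum_to_one(tmp_path):
    counts = np.array([[85, 5, 5, 5], [5, 85, 5, 5], [5, 5, 85, 5], [5, 5, 5, 85]])
    write_jaspar({"M1": counts}, tmp_path / "m.jaspar")
    ms = read_motifs(tmp_path / "m.jaspar", fmt="jaspar")
    assert ms.ids() == ["M1"]
    np.testing.assert_allclose(ms.motifs[0].probs.sum(axis=0), 1.0, atol=1e-9)


def test_meme_minimal_round_trip(tmp_path, small_dataset):
    write_jaspar(small_dataset.motif_counts, tmp_path / "m.jaspar")
    ms = read_motifs(tmp_path / "m.jaspar", fmt="jaspar")
    write_meme(ms, tmp_path / "m.meme")
    ms2 = read_motifs(tmp_path / "m.meme", fmt="meme")
    assert ms.ids() == ms2.ids()
    for a, b in zip(ms, ms2):
        np.testing.assert_allclose(a.probs, b.probs, atol=1e-3)


def test_uniform_counts_give_zero_log_odds():
    pwm = PWM.from_counts("flat", np.full((4, 6), 25))
    np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)


def test_degenerate_matrices_rejected():
    with pytest.raises(ValueError, match="4 x L"):
        PWM.from_counts("short", np.full((4, 2), 10))


# ----------------------------------------------------------------- scanning


def test_score_distribution_normalizes():
    rng = np.random.default_rng(0)
    counts = rng.integers(1, 60, (4, 8))
    pwm = PWM.from_counts("m", counts, background=np.array([0.3, 0.2, 0.2, 0.3]))
    _, dist = score_distribution(pwm)
    assert dist.sum() == pytest.approx(1.0, abs=1e-9)


def test_threshold_tail_probability_is_exact():
    rng = np.random.default_rng(1)
    pwm = PWM.from_counts("m", rng.integers(1, 60, (4, 9)))
    for p in (1e-2, 1e-3, 1e-4):
        theta = score_threshold(pwm, p)
        offset, dist = score_distribution(pwm)
        grid = (offset + np.arange(len(dist))) * 1e-3
        assert dist[grid >= theta - 5e-4].sum() <= p
        # theta is the *smallest* such score: one grid step lower exceeds p
        assert dist[grid >= theta - 1e-3 - 5e-4].sum() > p


def test_unreachable_p_threshold_disables_hits():
    """A motif whose best score is likelier than the requested p never hits."""
    pwm = PWM.from_counts("m", np.full((4, 4), 25) + np.eye(4, 4, dtype=int))
    assert score_threshold(pwm, 1e-6) == np.inf


def test_uniform_pwm_never_hits():
    pwm = PWM.from_counts("flat", np.full((4, 6), 25))
    res = scan_sequence("ACGTACGTACGTACGT", pwm, p_threshold=0.5)
    assert res.best_score == 0.0 and not res.hit


def test_planted_consensus_is_found_at_recorded_position(small_dataset):
    ms = MotifSet(motifs=[PWM.from_counts(mid, c)
                          for mid, c in small_dataset.motif_counts.items()])
    for gene, placements in small_dataset.truth.motif_placements.items():
        seq = small_dataset.promoters.sequence(gene)
        for motif_id, offset, strand in placements:
            res = scan_sequence(seq, ms.get(motif_id))
            assert res.hit
            assert (res.offset, res.strand) == (offset, strand)


def test_scan_is_strand_symmetric(small_dataset):
    ms = MotifSet(motifs=[PWM.from_counts(mid, c)
                          for mid, c in small_dataset.motif_counts.items()])
    genes = small_dataset.promoters.gene_ids()[:25]
    fwd = PromoterSet(records={g: small_dataset.promoters.records[g] for g in genes})
    hits = scan_promoters(fwd, ms)
    rc_records = {}
    for g in genes:
        rec = small_dataset.promoters.records[g]
        rc_records[g] = type(rec)(gene_id=g, sequence=reverse_complement(rec.sequence))
    rc_hits = scan_promoters(PromoterSet(records=rc_records), ms)
    pd.testing.assert_frame_equal(hits, rc_hits)


def test_scan_rejects_short_sequence():
    pwm = PWM.from_counts("m", np.full((4, 6), 10))
    with pytest.raises(ValueError, match="shorter"):
        scan_sequence("ACG", pwm)


def test_n_bases_score_as_background():
    counts = np.zeros((4, 4), int)
    counts[0] = 50  # AAAA consensus
    pwm = PWM.from_counts("polyA", counts)
    res = scan_sequence("N" * 10, pwm, p_threshold=0.5)
    assert res.best_score == 0.0


def test_background_frequencies_match_composition():
    from pistilgrn.motifs import PromoterRecord

    ps = PromoterSet(records={"g": PromoterRecord(gene_id="g", sequence="AACG")})
    np.testing.assert_allclose(background_frequencies(ps), [0.5, 0.25, 0.25, 0.0])


# --------------------------------------------------------------- enrichment


def _fisher_brute_force(a, b, c, d):
    """Exhaustive hypergeometric upper tail with exact rational arithmetic."""
    from fractions import Fraction

    n_total, k_total, n_fg = a + b + c + d, a + c, a + b
    denom = math.comb(n_total, n_fg)
    p = Fraction(0)
    for x in range(a, min(n_fg, k_total) + 1):
        if n_fg - x <= n_total - k_total:
            p += Fraction(math.comb(k_total, x) * math.comb(n_total - k_total, n_fg - x),
                          denom)
    return float(p)


def test_enrichment_hand_example():
    hits = pd.DataFrame({"m": [True] * 3 + [False] * 1 + [True] * 1 + [False] * 3},
                        index=[f"g{i}" for i in range(8)])
    fg = {f"g{i}" for i in range(4)}
    bg = {f"g{i}" for i in range(4, 8)}
    res = enrich_motifs(fg, bg, hits)
    assert res["p_value"].iloc[0] == pytest.approx(17 / 70, abs=1e-12)


def test_fisher_matches_exhaustive_enumeration(rng):
    for _ in range(40):
        n_fg, n_bg = rng.integers(2, 21), rng.integers(2, 21)
        fg_hits = rng.integers(0, n_fg + 1)
        bg_hits = rng.integers(0, n_bg + 1)
        hits = pd.DataFrame(
            {"m": [True] * fg_hits + [False] * (n_fg - fg_hits)
                  + [True] * bg_hits + [False] * (n_bg - bg_hits)},
            index=[f"g{i}" for i in range(n_fg + n_bg)])
        fg = {f"g{i}" for i in range(n_fg)}
        bg = {f"g{i}" for i in range(n_fg, n_fg + n_bg)}
        res = enrich_motifs(fg, bg, hits)
        expected = _fisher_brute_force(fg_hits, n_fg - fg_hits, bg_hits, n_bg - bg_hits)
        assert res["p_value"].iloc[0] == pytest.approx(expected, abs=1e-12)


def test_no_foreground_hits_is_not_enriched():
    hits = pd.DataFrame({"m": [False] * 5 + [True] * 5},
                        index=[f"g{i}" for i in range(10)])
    res = enrich_motifs({f"g{i}" for i in range(5)},
                        {f"g{i}" for i in range(5, 10)}, hits)
    assert res["p_value"].iloc[0] == 1.0 and not res["enriched"].iloc[0]


def test_empty_foreground_is_an_error():
    hits = pd.DataFrame({"m": [True]}, index=["g0"])
    with pytest.raises(ValueError, match="foreground"):
        enrich_motifs(set(), {"g0"}, hits)


def test_fully_planted_motif_is_enriched_after_bonferroni(rng):
    n = 20
    hits = pd.DataFrame({
        "planted": [True] * n + [False] * n,
        "other": list(rng.random(2 * n) < 0.3),
    }, index=[f"g{i}" for i in range(2 * n)])
    fg = {f"g{i}" for i in range(n)}
    bg = {f"g{i}" for i in range(n, 2 * n)}
    res = enrich_motifs(fg, bg, hits).set_index("motif_id")
    assert res.at["planted", "enriched"]
    assert res.at["planted", "adj_p"] == pytest.approx(
        min(1.0, res.at["planted", "p_value"] * 2))


def test_planted_motifs_enriched_in_true_targets(small_dataset, small_run):
    _, outdir, _ = small_run
    hits = pd.read_csv(outdir / "motif_hits.tsv", sep="\t", index_col=0)
    from pistilgrn.evaluate import motif_recovery

    rec = motif_recovery(small_dataset.truth, hits)
    assert rec["all_enriched"]
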