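"""Promoter extraction, PWM scanning and motif enrichment.

Promoters are the 2 kb upstream of the annotated TSS (strand-aware,
truncated at contig edges). Binding sites are predicted by scoring every
window of a promoter on both strands with a log-odds position weight matrix;
a window is a hit when its score reaches the threshold whose exact tail
probability under the background base composition — computed by dynamic
programming over the discretized per-position score distribution — drops to
the requested per-window p-value. Enrichment of a motif in a foreground gene
set against a background set is a one-tailed Fisher exact test
(hypergeometric upper tail) with Bonferroni correction across motifs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy.stats import hypergeom

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

__all__ = [
    "PromoterRecord",
    "PromoterSet",
    "PWM",
    "MotifSet",
    "ScanResult",
    "extract_promoters",
    "read_motifs",
    "write_jaspar",
    "write_meme",
    "scan_sequence",
    "scan_promoters",
    "enrich_motifs",
    "reverse_complement",
]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class PromoterRecord:
    gene_id: str
    sequence: str
    contig: str = ""
    start: int = 0  # half-open 0-based genomic window [start, end)
    end: int = 0
    strand: str = "+"
    truncated: bool = False


@dataclass
class PromoterSet:
    """Gene id -> upstream promoter sequence with genomic provenance."""

    records: dict[str, PromoterRecord] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.records

    def sequence(self, gene_id: str) -> str:
        return self.records[gene_id].sequence

    def gene_ids(self) -> list[str]:
        return list(self.records)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for rec in self.records.values():
                trunc = " truncated" if rec.truncated else ""
                fh.write(
                    f">{rec.gene_id} {rec.contig}:{rec.start}-{rec.end}"
                    f"({rec.strand}){trunc}\n{rec.sequence}\n"
                )

    @classmethod
    def read_fasta(cls, path) -> "PromoterSet":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            fields = rec.description.split()
            contig, start, end, strand, truncated = "", 0, 0, "+", False
            if len(fields) > 1 and ":" in fields[1]:
                loc = fields[1]
                contig, span = loc.rsplit(":", 1)
                coords, strand = span[:-3].rsplit("(", 1)[0], span[span.index("(") + 1]
                start, end = (int(x) for x in coords.split("-"))
                truncated = "truncated" in fields[2:]
            records[rec.id] = PromoterRecord(
                gene_id=rec.id,
                sequence=str(rec.seq).upper(),
                contig=contig,
                start=start,
                end=end,
                strand=strand,
                truncated=truncated,
            )
        return cls(records=records)


def extract_promoters(genome_fasta, gff3_path, length: int = 2000) -> PromoterSet:
    """Strand-aware promoter windows upstream of each gene's TSS.

    Plus strand: ``[TSS - length, TSS)``; minus strand: ``(TSS, TSS + length]``
    reverse-complemented, where the TSS is the annotated gene start (5' end).
    Windows are truncated at contig boundaries and flagged.
    """
    import gffutils

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")}
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", force=True, keep_order=True, merge_strategy="error"
    )
    records: dict[str, PromoterRecord] = {}
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes.get("ID", [gene.id])[0]
        if gene.seqid not in contigs:
            raise ValueError(f"gene {gene_id}: contig {gene.seqid!r} absent from genome")
        if gene.strand not in ("+", "-"):
            raise ValueError(f"gene {gene_id}: strand is not annotated")
        contig = contigs[gene.seqid]
        if gene.strand == "+":
            tss = gene.start - 1  # 0-based
            start = max(0, tss - length)
            end = tss
            seq = contig[start:end]
        else:
            tss = gene.end  # 0-based position just past the 5'-most base
            start = tss
            end = min(len(contig), tss + length)
            seq = reverse_complement(contig[start:end])
        records[gene_id] = PromoterRecord(
            gene_id=gene_id,
            sequence=seq,
            contig=gene.seqid,
            start=start,
            end=end,
            strand=gene.strand,
            truncated=len(seq) < length,
        )
    return PromoterSet(records=records)


@dataclass
class PWM:
    """Position weight matrix with pseudocounted probabilities and log-odds.

    ``probs`` and ``log_odds`` are 4 x L arrays with rows in A, C, G, T
    order; log-odds are log2(p / background).
    """

    motif_id: str
    probs: np.ndarray
    background: np.ndarray
    source_format: str = "jaspar"

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.shape[0] != 4 or self.probs.shape[1] < 4:
            raise ValueError(f"motif {self.motif_id}: need a 4 x L matrix with L >= 4")
        colsums = self.probs.sum(axis=0)
        if not np.allclose(colsums, 1.0, atol=1e-6):
            raise ValueError(f"motif {self.motif_id}: probability columns must sum to 1")

    @classmethod
    def from_counts(
        cls,
        motif_id: str,
        counts: np.ndarray,
        pseudocount: float = 0.01,
        background: np.ndarray | None = None,
        source_format: str = "jaspar",
    ) -> "PWM":
        counts = np.asarray(counts, dtype=float)
        if background is None:
            background = np.full(4, 0.25)
        probs = (counts + pseudocount) / (counts.sum(axis=0) + 4.0 * pseudocount)
        return cls(
            motif_id=motif_id,
            probs=probs,
            background=np.asarray(background, dtype=float),
            source_format=source_format,
        )

    @property
    def length(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))


@dataclass
class MotifSet:
    motifs: list[PWM] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    def ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]

    def get(self, motif_id: str) -> PWM:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m
        raise KeyError(motif_id)


def read_motifs(
    path,
    fmt: str = "jaspar",
    pseudocount: float = 0.01,
    background: np.ndarray | None = None,
) -> MotifSet:
    """Parse a JASPAR PFM or minimal MEME motif file into a :class:`MotifSet`."""
    bio_fmt = {"jaspar": "jaspar", "meme": "minimal"}.get(fmt)
    if bio_fmt is None:
        raise ValueError(f"unknown motif format {fmt!r}")
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, bio_fmt)
    pwms = []
    for m in parsed:
        counts = np.array([list(m.counts[b]) for b in BASES], dtype=float)
        if counts.shape[1] == 0:
            raise ValueError("zero-length motif")
        name = m.matrix_id if getattr(m, "matrix_id", None) else m.name
        pwms.append(
            PWM.from_counts(
                name, counts, pseudocount=pseudocount, background=background, source_format=fmt
            )
        )
    return MotifSet(motifs=pwms)


def write_jaspar(motif_counts: dict[str, np.ndarray], path) -> None:
    """Write integer count matrices in JASPAR PFM format."""
    with open(path, "w") as fh:
        for motif_id, counts in motif_counts.items():
            fh.write(f">{motif_id} {motif_id}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{int(v):6d}" for v in counts[i])
                fh.write(f"{base}  [ {row} ]\n")


def write_meme(motifset: MotifSet, path, nsites: int = 20) -> None:
    """Write motifs in minimal MEME format (letter-probability matrices)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = motifset.motifs[0].background if motifset.motifs else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.5f}" for b, f in zip(BASES, bg)) + "\n\n")
        for m in motifset:
            fh.write(f"MOTIF {m.motif_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.length} "
                f"nsites= {nsites} E= 0\n"
            )
            for col in m.probs.T:
                fh.write(" " + " ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def background_frequencies(promoters: PromoterSet) -> np.ndarray:
    """A/C/G/T frequencies pooled over a promoter set (N bases ignored)."""
    counts = np.zeros(4)
    for rec in promoters.records.values():
        seq = rec.sequence.upper()
        for i, base in enumerate(BASES):
            counts[i] += seq.count(base)
    total = counts.sum()
    if total == 0:
        return np.full(4, 0.25)
    return counts / total


# ---------------------------------------------------------------------------
# scanning

_SCORE_STEP = 1e-3  # discretization of log-odds scores in the DP null


def _encode(seq: str) -> np.ndarray:
    """Map A/C/G/T to 0..3 and anything else (N) to 4."""
    out = np.full(len(seq), 4, dtype=np.int8)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def _lo_with_n(pwm: PWM) -> np.ndarray:
    """Log-odds matrix extended with a zero row for N bases (5 x L)."""
    lo = pwm.log_odds
    return np.vstack([lo, np.zeros((1, lo.shape[1]))])


def _revcomp_lo(lo5: np.ndarray) -> np.ndarray:
    """Score matrix equivalent to scanning the reverse complement."""
    rc = lo5[[3, 2, 1, 0, 4], ::-1]
    return rc


def score_distribution(pwm: PWM, step: float = _SCORE_STEP):
    """Exact distribution of the window log-odds score under the background.

    Scores are discretized to multiples of ``step``; returns (offset of the
    minimal score in grid units, probability vector over the score grid).
    """
    lo_int = np.rint(pwm.log_odds / step).astype(np.int64)
    bg = pwm.background
    dist = np.zeros(1)
    dist[0] = 1.0
    cur_min = 0
    size = 1
    for j in range(pwm.length):
        col = lo_int[:, j]
        cmin, cmax = int(col.min()), int(col.max())
        new_size = size + (cmax - cmin)
        new = np.zeros(new_size)
        for b in range(4):
            shift = int(col[b]) - cmin
            new[shift : shift + size] += bg[b] * dist[:size]
        dist = new
        size = new_size
        cur_min += cmin
    return cur_min, dist[:size]


def score_threshold(pwm: PWM, p_threshold: float = 1e-4, step: float = _SCORE_STEP) -> float:
    """Smallest score whose upper-tail background probability is <= p_threshold."""
    offset, dist = score_distribution(pwm, step)
    tail = np.cumsum(dist[::-1])[::-1]
    idx = np.searchsorted(-tail, -p_threshold)  # first index with tail <= p
    if idx >= len(dist):
        # even the best achievable score is more probable than p: no window
        # can ever be called a hit (e.g. an uninformative matrix)
        return np.inf
    return (offset + idx) * step


@dataclass
class ScanResult:
    gene_id: str
    motif_id: str
    hit: bool
    best_score: float
    offset: int
    strand: str
    threshold: float


def _window_scores(codes: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    """Scores of every window of one or more encoded sequences (2-D input)."""
    L = lo5.shape[1]
    n_win = codes.shape[-1] - L + 1
    scores = np.zeros(codes.shape[:-1] + (n_win,))
    for k in range(L):
        scores += lo5[codes[..., k : k + n_win], k]
    return scores


def scan_sequence(
    seq: str, pwm: PWM, p_threshold: float = 1e-4, gene_id: str = ""
) -> ScanResult:
    """Best log-odds window over both strands, with an exact-null hit call."""
    if len(seq) < pwm.length:
        raise ValueError("sequence shorter than the motif")
    codes = _encode(seq.upper())[None, :]
    lo5 = _lo_with_n(pwm)
    fwd = _window_scores(codes, lo5)[0]
    rev = _window_scores(codes, _revcomp_lo(lo5))[0]
    theta = score_threshold(pwm, p_threshold)
    if fwd.max() >= rev.max():
        best, strand = fwd, "+"
    else:
        best, strand = rev, "-"
    off = int(best.argmax())
    best_score = float(best[off])
    # compare on the discretized grid so the call matches the DP threshold
    hit = np.rint(best_score / _SCORE_STEP) >= np.rint(theta / _SCORE_STEP)
    return ScanResult(
        gene_id=gene_id,
        motif_id=pwm.motif_id,
        hit=bool(hit),
        best_score=best_score,
        offset=off,
        strand=strand,
        threshold=theta,
    )


def scan_promoters(
    promoters: PromoterSet,
    motifset: MotifSet,
    p_threshold: float = 1e-4,
    max_n_fraction: float = 0.5,
) -> pd.DataFrame:
    """Hit matrix (genes x motifs, boolean) over a promoter set.

    Promoters with more than ``max_n_fraction`` ambiguous bases are excluded.
    Thresholds are computed once per motif from the exact score DP.
    """
    genes, seqs = [], []
    for rec in promoters.records.values():
        seq = rec.sequence.upper()
        if len(seq) == 0:
            continue
        if seq.count("N") / len(seq) > max_n_fraction:
            continue
        genes.append(rec.gene_id)
        seqs.append(seq)
    if not genes:
        return pd.DataFrame(columns=motifset.ids(), dtype=bool)
    max_len = max(len(s) for s in seqs)
    codes = np.full((len(seqs), max_len), 4, dtype=np.int8)
    pad = np.zeros(len(seqs), dtype=int)
    for i, s in enumerate(seqs):
        codes[i, : len(s)] = _encode(s)
        pad[i] = max_len - len(s)
    hits = {}
    for pwm in motifset:
        lo5 = _lo_with_n(pwm)
        theta_int = np.rint(score_threshold(pwm, p_threshold) / _SCORE_STEP)
        best = np.maximum(
            _window_scores(codes, lo5).max(axis=1),
            _window_scores(codes, _revcomp_lo(lo5)).max(axis=1),
        )
        # trailing pad windows score 0 (N rows); only a concern for theta <= 0
        hits[pwm.motif_id] = np.rint(best / _SCORE_STEP) >= theta_int
    return pd.DataFrame(hits, index=pd.Index(genes, name="gene_id"))


# ---------------------------------------------------------------------------
# enrichment


def enrich_motifs(
    foreground: set[str],
    background: set[str],
    hits: pd.DataFrame,
    adj_p_threshold: float = 0.001,
) -> pd.DataFrame:
    """AME-style one-tailed Fisher enrichment with Bonferroni correction.

    ``hits`` is the boolean gene x motif matrix from :func:`scan_promoters`.
    The background is taken net of the foreground; genes absent from the hit
    matrix (excluded promoters) are dropped from both sets.
    """
    if not foreground:
        raise ValueError("empty foreground gene set")
    fg = sorted(set(foreground) & set(hits.index))
    bg = sorted((set(background) - set(foreground)) & set(hits.index))
    n_motifs = hits.shape[1]
    rows = []
    for motif_id in hits.columns:
        col = hits[motif_id]
        a = int(col.loc[fg].sum())
        b = len(fg) - a
        c = int(col.loc[bg].sum())
        d = len(bg) - c
        # one-tailed (enrichment) Fisher = hypergeometric upper tail
        p = float(hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
        adj = min(1.0, p * n_motifs)
        rows.append((motif_id, a, b, c, d, p, adj, adj < adj_p_threshold))
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id",
            "fg_hits",
            "fg_misses",
            "bg_hits",
            "bg_misses",
            "p_value",
            "adj_p",
            "enriched",
        ],
    )
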