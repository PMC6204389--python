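"""Promoter extraction and PWM scanning with exact background p-values.

Promoters are the 1.5 kb of sense-strand sequence immediately upstream of a
gene's start codon (reverse-complemented for minus-strand genes, truncated at
contig ends).  A position weight matrix is built from aligned site sequences
or a nucleotide count matrix with a background-proportional pseudocount; the
null distribution of its log-odds score under the 0-order background is
computed exactly (full 4^w enumeration for short motifs, a discretised
positionwise convolution otherwise), giving each scanned window an exact
p-value.  Both strands are scanned and hits are reported in promoter
coordinates: offset -1 is the base immediately upstream of the ATG and a
hit's offset is the 5'-most base of the matched window on the gene's sense
orientation (for either strand of the match).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Promoter",
    "PromoterSet",
    "PWMModel",
    "ScoreDistribution",
    "MotifHit",
    "extract_promoters",
    "gene_models_from_gff",
    "build_pwm",
    "score_distribution",
    "scan",
    "genes_with_xbs",
]

_NUC = "ACGT"
_NUC_INDEX = {b: i for i, b in enumerate(_NUC)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SCORE_BIN = 1e-3  # bits; discretisation of the convolution grid


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Promoter:
    """Sense-strand upstream sequence of one gene."""

    gene: str
    sequence: str  # uppercase ACGTN, 5'->3' on the gene's sense orientation
    contig: str
    strand: str
    atg_position: int  # 1-based genomic coordinate of the A of ATG
    truncated: bool

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PromoterSet:
    promoters: dict[str, Promoter]
    length: int  # requested upstream length

    def __iter__(self):
        return iter(self.promoters.values())

    def __getitem__(self, gene: str) -> Promoter:
        return self.promoters[gene]

    def __len__(self) -> int:
        return len(self.promoters)

    def total_bp(self) -> int:
        return sum(len(p) for p in self)

    def write_fasta(self, path: str | Path) -> None:
        lines = []
        for p in self.promoters.values():
            lines.append(f">{p.gene}|{-len(p)}..-1")
            lines.append(p.sequence)
        Path(path).write_text("\n".join(lines) + "\n")


def gene_models_from_gff(gff_path: str | Path) -> pd.DataFrame:
    """Gene model table (gene, contig, strand, cds_start, cds_end) from GFF3.

    CDS features are unioned per gene; coordinates are 1-based inclusive.
    """
    import gffutils

    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", force=True
    )
    rows = []
    for gene in db.features_of_type("gene"):
        cds = list(db.children(gene, featuretype="CDS"))
        feats = cds if cds else [gene]
        rows.append({
            "gene": gene.id,
            "contig": gene.seqid,
            "strand": gene.strand,
            "cds_start": min(f.start for f in feats),
            "cds_end": max(f.end for f in feats),
        })
    return pd.DataFrame(rows, columns=["gene", "contig", "strand", "cds_start", "cds_end"])


def extract_promoters(
    genome: Mapping[str, str],
    models: pd.DataFrame,
    length: int = 1500,
) -> PromoterSet:
    """Upstream windows of each gene's ATG, strand-aware and truncation-flagged.

    Plus strand, ATG at 1-based position s: genomic window [max(1, s-length),
    s-1] as-is.  Minus strand, ATG at position e (= CDS end): window
    [e+1, min(contig_end, e+length)] reverse-complemented.
    """
    out: dict[str, Promoter] = {}
    for _, row in models.iterrows():
        gene, contig, strand = row["gene"], row["contig"], row["strand"]
        if contig not in genome:
            raise KeyError(f"gene {gene} references missing contig {contig!r}")
        seq = genome[contig]
        if strand == "+":
            s = int(row["cds_start"])
            lo = max(1, s - length)
            window = seq[lo - 1:s - 1].upper()
            truncated = lo > s - length
            atg = s
        else:
            e = int(row["cds_end"])
            hi = min(len(seq), e + length)
            window = _revcomp(seq[e:hi].upper())
            truncated = hi < e + length
            atg = e
        out[gene] = Promoter(
            gene=gene, sequence=window, contig=contig, strand=strand,
            atg_position=atg, truncated=truncated,
        )
    return PromoterSet(promoters=out, length=length)


# ---------------------------------------------------------------------------
# PWM construction and exact score distribution
# ---------------------------------------------------------------------------

@dataclass
class ScoreDistribution:
    """Exact null distribution of a PWM score under a 0-order background.

    ``resolution`` is the largest absolute error between a true window score
    and its representation on the distribution's score grid (0 up to float
    error for full enumeration, ``width * bin_width / 2`` for the
    discretised convolution); lookups tolerate it so a window score computed
    with the exact log-odds maps onto the correct probability mass.
    """

    scores: np.ndarray  # ascending distinct (possibly discretised) scores
    tail_p: np.ndarray  # P(score >= scores[i])
    resolution: float = 1e-9

    def pvalue(self, score: float) -> float:
        """P(random background word scores >= ``score``)."""
        idx = np.searchsorted(self.scores, score - self.resolution - 1e-9,
                              side="left")
        if idx >= self.scores.size:
            return 0.0
        return float(self.tail_p[idx])

    def score_at(self, p_threshold: float) -> float:
        """Smallest grid score whose tail probability is <= ``p_threshold``."""
        ok = self.tail_p <= p_threshold
        if not ok.any():
            return math.inf
        return float(self.scores[np.argmax(ok)])


@dataclass
class PWMModel:
    """Count / frequency / log-odds matrices with the background model.

    Rows are A, C, G, T; columns are motif positions.  Log-odds are in bits.
    """

    counts: np.ndarray
    freq: np.ndarray
    log_odds: np.ndarray
    background: np.ndarray
    pseudocount: float
    distribution: ScoreDistribution | None = None

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(_NUC[i] for i in self.freq.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def information_content(self) -> float:
        """Total information content in bits relative to the background."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ic = self.freq * np.log2(self.freq / self.background[:, None])
        return float(np.nansum(ic))

    def reverse_complement(self) -> "PWMModel":
        rc = lambda m: m[::-1, ::-1]
        return PWMModel(
            counts=rc(self.counts), freq=rc(self.freq),
            log_odds=rc(self.log_odds),
            background=self.background[::-1].copy(),
            pseudocount=self.pseudocount,
        )

    def score_word(self, word: str) -> float:
        idx = [_NUC_INDEX[b] for b in word]
        return float(self.log_odds[idx, range(self.width)].sum())


def build_pwm(
    sites: Sequence[str] | np.ndarray | pd.DataFrame,
    pseudocount: float = 1.0,
    background: Sequence[float] | None = None,
) -> PWMModel:
    """PWM from aligned equal-length site sequences or a 4 x width count matrix.

    The pseudocount is distributed by background composition: cell (b, j)
    receives ``pseudocount * 4 * background[b]`` additional observations (one
    per cell under the uniform background).  A zero pseudocount is rejected
    when any count is zero.  Widths outside the 6-10 bp range used for motif
    discovery get a warning, widths below 4 an error.
    """
    import warnings

    if background is None:
        background = (0.25, 0.25, 0.25, 0.25)
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("background must be 4 probabilities summing to 1")
    if isinstance(sites, pd.DataFrame):
        counts = sites.to_numpy(dtype=float)
    elif isinstance(sites, np.ndarray):
        counts = sites.astype(float)
    else:
        sites = list(sites)
        if not sites:
            raise ValueError("no sites given")
        width = len(sites[0])
        if any(len(s) != width for s in sites):
            raise ValueError("site sequences must have equal length")
        counts = np.zeros((4, width))
        for s in sites:
            for j, b in enumerate(s.upper()):
                if b not in _NUC_INDEX:
                    raise ValueError(f"non-ACGT character {b!r} in site {s!r}")
                counts[_NUC_INDEX[b], j] += 1
    if counts.shape[0] != 4 or np.any(counts < 0):
        raise ValueError("counts must be a nonnegative 4 x width matrix")
    width = counts.shape[1]
    if width < 4:
        raise ValueError("motif width must be >= 4")
    if not 6 <= width <= 10:
        warnings.warn(
            f"motif width {width} outside the 6-10 bp discovery range",
            RuntimeWarning,
            stacklevel=2,
        )
    if pseudocount == 0 and np.any(counts == 0):
        raise ValueError("pseudocount 0 with zero counts gives -inf log-odds; "
                         "use a positive pseudocount")
    pseudo = pseudocount * 4.0 * bg
    freq = (counts + pseudo[:, None]) / (counts.sum(axis=0) + 4.0 * pseudocount)
    log_odds = np.log2(freq / bg[:, None])
    return PWMModel(
        counts=counts, freq=freq, log_odds=log_odds, background=bg.copy(),
        pseudocount=pseudocount,
    )


def score_distribution(
    pwm: PWMModel,
    method: str = "auto",
    enumerate_max_width: int = 8,
    bin_width: float = _SCORE_BIN,
) -> ScoreDistribution:
    """Exact distribution of the log-odds score of a random background word.

    ``method='enumerate'`` sums over all 4^w words (exact); ``method='dp'``
    convolves positionwise on a score grid discretised to ``bin_width`` bits.
    ``'auto'`` enumerates up to ``enumerate_max_width`` and otherwise uses
    the convolution.
    """
    if method == "auto":
        method = "enumerate" if pwm.width <= enumerate_max_width else "dp"
    if method == "enumerate":
        resolution = 1e-9
        scores = np.zeros(1)
        probs = np.ones(1)
        for j in range(pwm.width):
            scores = (scores[:, None] + pwm.log_odds[:, j][None, :]).ravel()
            probs = (probs[:, None] * pwm.background[None, :]).ravel()
    elif method == "dp":
        resolution = pwm.width * bin_width / 2.0
        lo_bins = np.round(pwm.log_odds / bin_width).astype(np.int64)
        offset = lo_bins.min(axis=0).sum()
        cur = np.array([1.0])
        for j in range(pwm.width):
            col = lo_bins[:, j] - lo_bins[:, j].min()
            width_j = col.max() + 1
            nxt = np.zeros(cur.size + width_j - 1)
            for b in range(4):
                nxt[col[b]:col[b] + cur.size] += pwm.background[b] * cur
            cur = nxt
        scores = (offset + np.arange(cur.size)) * bin_width
        probs = cur
    else:
        raise ValueError("method must be 'auto', 'enumerate' or 'dp'")
    realised = probs > 0
    scores, probs = scores[realised], probs[realised]
    order = np.argsort(scores)
    scores = scores[order]
    probs = probs[order]
    # aggregate duplicates, then cumulative tail from the top
    uniq, inverse = np.unique(np.round(scores / 1e-9).astype(np.int64),
                              return_inverse=True)
    agg = np.zeros(uniq.size)
    np.add.at(agg, inverse, probs)
    uscores = uniq * 1e-9
    tail = np.cumsum(agg[::-1])[::-1]
    tail = np.minimum(tail, 1.0)
    return ScoreDistribution(scores=uscores, tail_p=tail, resolution=resolution)


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

@dataclass
class MotifHit:
    gene: str
    offset: int  # 5'-most base of the match on the sense orientation; -1 = adjacent to ATG
    strand: str  # relative to the gene
    score: float  # bits
    p_value: float


def _window_scores(seq_idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Score of every window of ``seq_idx`` (N coded as -1 -> NaN score)."""
    w = log_odds.shape[1]
    n_win = seq_idx.size - w + 1
    if n_win <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(seq_idx, w)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(n_win, np.nan)
    if valid.any():
        vw = windows[valid]
        scores[valid] = log_odds[vw, np.arange(w)[None, :]].sum(axis=1)
    return scores


def scan(
    pwm: PWMModel,
    promoters: PromoterSet,
    p_threshold: float = 1e-4,
    both_strands: bool = True,
) -> list[MotifHit]:
    """Scan every promoter window on both strands, keeping hits with p <= threshold.

    Windows containing N are skipped.  A minus-strand hit at a window is a
    match of the motif's reverse complement on the sense sequence; its offset
    is still the window's 5'-most sense base.
    """
    dist_fwd = score_distribution(pwm)
    rc = pwm.reverse_complement()
    dist_rev = score_distribution(rc) if both_strands else None
    hits: list[MotifHit] = []
    for promoter in promoters:
        seq = promoter.sequence.upper()
        if len(seq) < pwm.width:
            continue
        idx = np.array([_NUC_INDEX.get(b, -1) for b in seq], dtype=np.int64)
        length = len(seq)
        strands = [("+", pwm.log_odds, dist_fwd)]
        if both_strands:
            strands.append(("-", rc.log_odds, dist_rev))
        for strand, lo, dist in strands:
            scores = _window_scores(idx, lo)
            cutoff = dist.score_at(p_threshold) - dist.resolution - 1e-9
            for i in np.flatnonzero(~np.isnan(scores)):
                if scores[i] >= cutoff:
                    hits.append(MotifHit(
                        gene=promoter.gene,
                        offset=int(i) - length,
                        strand=strand,
                        score=float(scores[i]),
                        p_value=dist.pvalue(float(scores[i])),
                    ))
    hits.sort(key=lambda h: (h.gene, h.offset, h.strand))
    return hits


def hits_table(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"gene": h.gene, "offset": h.offset, "strand": h.strand,
          "score": h.score, "p_value": h.p_value} for h in hits],
        columns=["gene", "offset", "strand", "score", "p_value"],
    )


def genes_with_xbs(hits: Sequence[MotifHit] | pd.DataFrame) -> dict[str, bool]:
    """True for every gene with at least one predicted binding site."""
    if isinstance(hits, pd.DataFrame):
        genes = set(hits["gene"])
    else:
        genes = {h.gene for h in hits}
    return {g: True for g in sorted(genes)}
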