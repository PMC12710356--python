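"""PWM scanning of promoter windows with exact p-values and tiered filtering.

The scanner mirrors the classic exact-p-value approach: log-odds scores are
quantised to an integer grid, the null distribution of window scores under
the background model (independent positions) is built by column-by-column
convolution, and each hit's p-value is the exact tail mass P(S >= score).

Hits pass three tiers: (1) the raw p-value threshold (default 1e-4);
(2) for extremely short motifs (width < 6) only words attaining the
maximum achievable score are kept — maximal stringency, operationalising a
"p-value threshold of zero"; (3) a motif-level symmetry QC flag
(palindromicity of the consensus) annotates motifs whose shape lacks the
dyad symmetry typical of homodimeric regulator sites; tier 3 flags rather
than deletes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import DNA, GeneRecord, MotifModel

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASE_INDEX = {b: i for i, b in enumerate(DNA + "N")}

DEFAULT_P_THRESHOLD = 1e-4
DEFAULT_WINDOW = 400


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class LogOddsMatrix:
    """Integer-quantised log2-odds scoring matrix for one motif."""

    motif_id: str
    scores: np.ndarray           # 4 x width, log2(p_hat / background)
    int_scores: np.ndarray       # round(scores / granularity)
    granularity: float

    @property
    def width(self) -> int:
        return self.scores.shape[1]

    @property
    def max_int_score(self) -> int:
        return int(self.int_scores.max(axis=0).sum())

    @property
    def min_int_score(self) -> int:
        return int(self.int_scores.min(axis=0).sum())


@dataclass
class ScoreDistribution:
    """Exact pmf of the integer window score under the background model."""

    pmf: np.ndarray              # probabilities over min_score .. max_score
    min_score: int
    granularity: float
    survival: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if not np.isclose(self.pmf.sum(), 1.0, atol=1e-9):
            raise ValueError(f"pmf sums to {self.pmf.sum()}, not 1")
        self.survival = np.cumsum(self.pmf[::-1])[::-1]

    @property
    def max_score(self) -> int:
        return self.min_score + len(self.pmf) - 1

    def pvalue_int(self, int_score: int) -> float:
        """Tail mass P(S >= int_score); clamps below support to 1 and above
        to the exact mass at the maximum (p-values stay in (0, 1])."""
        if int_score <= self.min_score:
            return 1.0
        if int_score > self.max_score:
            int_score = self.max_score
        return float(self.survival[int_score - self.min_score])


@dataclass(frozen=True)
class MotifHit:
    """One PWM match inside an upstream window."""

    window_id: str
    motif_id: str
    offset: int                  # 0-based within the window
    strand: str                  # orientation of the match within the window
    score: float                 # quantised log2-odds (int score * granularity)
    pvalue: float
    int_score: int = 0


@dataclass(frozen=True)
class UpstreamWindow:
    """Strand-corrected promoter region immediately 5' of a gene start."""

    gene_id: str
    genome_id: str
    contig_id: str
    sequence: str
    interval: tuple[int, int]    # genomic [start, end) of the window
    strand: str                  # strand of the gene the window belongs to
    truncated: bool = False

    @property
    def window_id(self) -> str:
        return f"{self.genome_id}:{self.gene_id}"


def make_log_odds(
    motif: MotifModel,
    pseudocount: float = 0.1,
    granularity: float | None = None,
) -> LogOddsMatrix:
    """Build the integer-scaled log-odds matrix for a motif.

    Probabilities are regularised as
    ``p_hat = (p + pseudocount * background) / (1 + pseudocount)`` and
    scored as ``log2(p_hat / background)``. When ``granularity`` is not
    given it is set so the widest-spanning column covers at most 1000
    integer bins.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    bg = motif.background
    if np.any(bg <= 0):
        raise ValueError("background entries must be positive")
    p_hat = (motif.prob_matrix + pseudocount * bg[:, None]) / (1.0 + pseudocount)
    scores = np.log2(p_hat / bg[:, None])
    if granularity is None:
        span = float((scores.max(axis=0) - scores.min(axis=0)).max())
        granularity = max(span / 1000.0, 1e-9)
    elif granularity <= 0:
        raise ValueError("granularity must be positive")
    int_scores = np.round(scores / granularity).astype(np.int64)
    # collision check: distinct real scores within a column collapsing to one bin
    for j in range(scores.shape[1]):
        col, icol = scores[:, j], int_scores[:, j]
        for a in range(4):
            for b in range(a + 1, 4):
                if icol[a] == icol[b] and abs(col[a] - col[b]) > granularity:
                    warnings.warn(
                        f"motif {motif.motif_id}: granularity {granularity} merges "
                        f"distinct scores in column {j}",
                        RuntimeWarning,
                        stacklevel=2,
                    )
    return LogOddsMatrix(
        motif_id=motif.motif_id,
        scores=scores,
        int_scores=int_scores,
        granularity=float(granularity),
    )


def score_distribution(lom: LogOddsMatrix, background: np.ndarray | None = None) -> ScoreDistribution:
    """Exact null distribution of the integer window score.

    Column-by-column convolution: each column contributes its four integer
    scores weighted by the background probability of the emitting base.
    """
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    mins = lom.int_scores.min(axis=0)
    maxs = lom.int_scores.max(axis=0)
    total_min, total_max = int(mins.sum()), int(maxs.sum())
    pmf = np.zeros(total_max - total_min + 1)
    pmf[0] = 1.0
    cur_min = 0  # pmf[i] is probability of (score - running_min = i)
    run_min = 0
    for j in range(lom.width):
        col = lom.int_scores[:, j]
        cmin = int(mins[j])
        new = np.zeros(len(pmf))
        for b in range(4):
            shift = int(col[b]) - cmin
            if background[b] == 0:
                continue
            if shift == 0:
                new[: len(pmf)] += background[b] * pmf
            else:
                new[shift:] += background[b] * pmf[: len(pmf) - shift]
        pmf = new
        run_min += cmin
    return ScoreDistribution(pmf=pmf, min_score=total_min, granularity=lom.granularity)


def pvalue(dist: ScoreDistribution, score: float) -> float:
    """Exact tail probability P(S >= score) for a real-valued score."""
    return dist.pvalue_int(int(round(score / dist.granularity)))


def extract_upstream(
    gene: GeneRecord, contig_sequence: str, window: int = DEFAULT_WINDOW
) -> UpstreamWindow:
    """Strand-corrected window immediately 5' of the gene start.

    Plus strand: bases [max(0, start - window), start) as-is; minus strand:
    bases [end, min(L, end + window)) reverse-complemented. Windows
    truncated by a contig edge are flagged; an empty window is legal.
    """
    length = len(contig_sequence)
    if gene.end > length:
        raise ValueError(
            f"gene {gene.gene_id} [{gene.start}, {gene.end}) outside contig of length {length}"
        )
    if gene.strand == "+":
        lo, hi = max(0, gene.start - window), gene.start
        seq = contig_sequence[lo:hi].upper()
    else:
        lo, hi = gene.end, min(length, gene.end + window)
        seq = reverse_complement(contig_sequence[lo:hi].upper())
    return UpstreamWindow(
        gene_id=gene.gene_id,
        genome_id=gene.genome_id,
        contig_id=gene.contig_id,
        sequence=seq,
        interval=(lo, hi),
        strand=gene.strand,
        truncated=(hi - lo) < window,
    )


def _window_int_scores(sequence: str, lom: LogOddsMatrix) -> np.ndarray:
    """Integer score at every offset of one strand (empty when too short)."""
    w = lom.width
    length = len(sequence)
    if length < w:
        return np.zeros(0, dtype=np.int64)
    try:
        idx = np.array([_BASE_INDEX[ch] for ch in sequence], dtype=np.int64)
    except KeyError as exc:
        raise ValueError(f"invalid nucleotide {exc.args[0]!r} in window") from exc
    # row 4 (N): worst (minimum) score of the column
    ext = np.vstack([lom.int_scores, lom.int_scores.min(axis=0)])
    windows = np.lib.stride_tricks.sliding_window_view(idx, w)
    return ext[windows, np.arange(w)].sum(axis=1)


def scan_window(
    window: UpstreamWindow,
    lom: LogOddsMatrix,
    dist: ScoreDistribution,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[MotifHit]:
    """Score every offset on both strands; return hits with p <= threshold.

    Hits are sorted by (p-value, offset, strand); ambiguous bases (N) take
    the worst score of their column. Offsets are 0-based within the window
    on its given orientation; a minus-strand hit at offset o means the
    reverse complement of window[o:o+w] matches the motif.
    """
    seq = window.sequence.upper()
    w = lom.width
    hits: list[MotifHit] = []
    fwd = _window_int_scores(seq, lom)
    rev = _window_int_scores(reverse_complement(seq), lom)
    n_off = len(fwd)
    for strand, totals in (("+", fwd), ("-", rev)):
        for pos, total in enumerate(totals):
            p = dist.pvalue_int(int(total))
            if p <= p_threshold:
                offset = pos if strand == "+" else n_off - 1 - pos
                hits.append(
                    MotifHit(
                        window_id=window.window_id,
                        motif_id=lom.motif_id,
                        offset=offset,
                        strand=strand,
                        score=float(total * lom.granularity),
                        pvalue=p,
                        int_score=int(total),
                    )
                )
    hits.sort(key=lambda h: (h.pvalue, h.offset, h.strand))
    return hits


@dataclass(frozen=True)
class TierRules:
    """Filtering thresholds for the three-tier strategy."""

    p_threshold: float = DEFAULT_P_THRESHOLD
    short_motif_width: int = 6       # motifs below this width get tier 2
    symmetry_threshold: float = 0.6  # tier-3 QC flag cutoff


def palindromicity(motif: MotifModel) -> float:
    """Fraction of consensus positions complementary to their mirror position.

    1.0 means the consensus is its own reverse complement (perfect dyad);
    0.0 means no position pairs complementarily.
    """
    if motif.width < 2:
        raise ValueError("palindromicity needs width >= 2")
    consensus = motif.consensus
    rc = reverse_complement(consensus)
    return sum(a == b for a, b in zip(consensus, rc)) / motif.width


def tier_filter(
    hits: Sequence[MotifHit],
    motif: MotifModel,
    lom: LogOddsMatrix,
    rules: TierRules = TierRules(),
) -> tuple[list[MotifHit], dict]:
    """Apply tiers 2 and 3 to tier-1 hits; returns (kept hits, motif QC).

    Tier 2: motifs narrower than ``short_motif_width`` keep only hits at
    the maximum achievable score. Tier 3: motifs whose consensus
    palindromicity falls below ``symmetry_threshold`` are flagged in the
    QC record (hits are retained).
    """
    kept = list(hits)
    tier2_applied = motif.width < rules.short_motif_width
    if tier2_applied:
        top = lom.max_int_score
        kept = [h for h in kept if h.int_score >= top]
    symmetry = palindromicity(motif)
    qc = dict(
        motif_id=motif.motif_id,
        width=motif.width,
        tier2_applied=tier2_applied,
        palindromicity=symmetry,
        symmetry_flag=symmetry < rules.symmetry_threshold,
    )
    return kept, qc


def scan_genes(
    contigs: Mapping[str, str],
    genes: Sequence[GeneRecord],
    motif_list: Sequence[MotifModel],
    window: int = DEFAULT_WINDOW,
    pseudocount: float = 0.1,
    rules: TierRules = TierRules(),
) -> tuple[list[tuple[MotifHit, GeneRecord, str]], list[dict]]:
    """Scan every gene's upstream window with every motif, tiers applied.

    Returns (hit records, motif QC rows); each hit record is
    (hit, gene, gr_type of the motif).
    """
    prepared = []
    for motif in motif_list:
        lom = make_log_odds(motif, pseudocount=pseudocount)
        dist = score_distribution(lom, motif.background)
        prepared.append((motif, lom, dist))
    windows = {}
    for gene in genes:
        if gene.contig_id not in contigs:
            raise ValueError(f"gene {gene.gene_id}: unknown contig {gene.contig_id}")
        windows[gene.gene_id] = extract_upstream(gene, contigs[gene.contig_id], window)
    out: list[tuple[MotifHit, GeneRecord, str]] = []
    qc_rows: list[dict] = []
    for motif, lom, dist in prepared:
        all_kept: list[MotifHit] = []
        qc = None
        for gene in genes:
            raw = scan_window(windows[gene.gene_id], lom, dist, rules.p_threshold)
            kept, qc = tier_filter(raw, motif, lom, rules)
            for hit in kept:
                out.append((hit, gene, motif.gr_type))
            all_kept += kept
        if qc is not None:
            qc_rows.append(qc)
    return out, qc_rows
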