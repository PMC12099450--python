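"""Novel-sequence (mobile-element) insertion characterization.

Insertions are read from alignment insertion operations — amplicon and
genome reads anchor on both sides of the event, so a spliced or contiguous
aligner represents the novel segment as an internal CIGAR ``I`` op; soft-clip
rescue is out of scope.  The stages are:

1. cluster qualifying insertion operations by reference anchor into events;
2. build a per-position majority consensus of the inserted sequences,
   anchored at the insertion start with the median observed length;
3. identify the consensus against an element library by local
   (Smith-Waterman, affine-gap) alignment in both orientations;
4. for genome-level reads, decompose the full inserted allele into ordered
   segments — element fragment(s) with orientation, terminal homopolymer
   runs, and residual literals — mirroring an HGVS ``ins[...]`` description;
5. scan the consensus with a canonical splice-donor position weight matrix
   to rank candidate novel donor sites (a coarse motif score, not a
   substitute for dedicated splice predictors).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from Bio import Align

from .errors import DataError
from .models_io import ElementLibrary
from .splice import ReadAlignment

log = logging.getLogger(__name__)

DEFAULT_MIN_INSERTION_LEN = 50
DEFAULT_CLUSTER_WINDOW = 20
DEFAULT_MIN_SUPPORT = 10
HOMOPOLYMER_MIN_RUN = 10
MIN_HIT_SCORE = 20.0

MATCH_SCORE = 2.0
MISMATCH_SCORE = -3.0
GAP_OPEN = -5.0
GAP_EXTEND = -2.0

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = MATCH_SCORE
    a.mismatch_score = MISMATCH_SCORE
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


def local_alignment_score(a: str, b: str) -> float:
    """Best local-alignment score between two sequences (affine gaps: the
    first gap base costs ``GAP_OPEN``, each further base ``GAP_EXTEND``)."""
    if not a or not b:
        return 0.0
    return float(_aligner().score(a, b))


def local_alignment(target: str, query: str):
    """Best local alignment (first co-optimal) of query against target."""
    return _aligner().align(target, query)[0]


# ---------------------------------------------------------------------------
# event collection and consensus


@dataclass
class InsertionEvent:
    anchor: int  # representative (median) reference anchor, 0-based
    sequences: list  # supporting inserted sequences
    anchors: list  # per-read anchors

    @property
    def supporting_reads(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> np.ndarray:
        return np.array([len(s) for s in self.sequences])

    @property
    def median_length(self) -> float:
        return float(np.median(self.lengths))

    def length_summary(self) -> dict:
        ln = self.lengths
        return {
            "n": int(ln.size),
            "median": float(np.median(ln)),
            "q1": float(np.percentile(ln, 25)),
            "q3": float(np.percentile(ln, 75)),
            "min": int(ln.min()),
            "max": int(ln.max()),
        }

    def consensus(self) -> str:
        return consensus_sequence(self.sequences)


def collect_insertion_reads(
    reads: Iterable[ReadAlignment],
    min_insertion_len: int = DEFAULT_MIN_INSERTION_LEN,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> list[InsertionEvent]:
    """Cluster insertion operations >= ``min_insertion_len`` by reference
    anchor; clusters with at least ``min_support`` reads become events."""
    ops: list[tuple[int, str]] = []
    for read in reads:
        for anchor, seq in read.insertions:
            if len(seq) >= min_insertion_len:
                ops.append((anchor, seq))
    ops.sort(key=lambda t: t[0])
    events: list[InsertionEvent] = []
    cluster: list[tuple[int, str]] = []

    def _flush():
        if len(cluster) >= min_support:
            anchors = [a for a, _ in cluster]
            events.append(
                InsertionEvent(
                    anchor=int(np.median(anchors)),
                    sequences=[s for _, s in cluster],
                    anchors=anchors,
                )
            )

    for anchor, seq in ops:
        if cluster and anchor - cluster[0][0] > cluster_window:
            _flush()
            cluster = []
        cluster.append((anchor, seq))
    if cluster:
        _flush()
    return events


def consensus_sequence(sequences: Sequence[str]) -> str:
    """Per-position majority consensus over a length-anchored layout.

    Sequences are anchored at the insertion start; the consensus length is
    the median observed length.  Ties break to the alphabetically first base;
    the number of ambiguous columns is logged.
    """
    if not sequences:
        raise DataError("consensus requires at least one sequence")
    length = int(np.median([len(s) for s in sequences]))
    arr = np.full((len(sequences), length), ord("N"), dtype=np.uint8)
    for i, s in enumerate(sequences):
        b = np.frombuffer(s[:length].encode(), dtype=np.uint8)
        arr[i, : b.size] = b
    out = bytearray(length)
    ambiguous = 0
    base_codes = np.frombuffer(b"ACGT", dtype=np.uint8)
    counts = np.zeros((4, length), dtype=np.int64)
    for bi, code in enumerate(base_codes):
        counts[bi] = (arr == code).sum(axis=0)
    best = counts.argmax(axis=0)  # argmax takes the first max: A<C<G<T order
    ambiguous = int(
        ((counts == counts.max(axis=0)).sum(axis=0) > 1).sum()
    )
    for j in range(length):
        out[j] = base_codes[best[j]]
    if ambiguous:
        log.info("consensus: %d ambiguous (tied) columns", ambiguous)
    return out.decode()


# ---------------------------------------------------------------------------
# element identification


@dataclass(frozen=True)
class ElementHit:
    element: str
    percent_identity: float
    element_span: tuple[int, int]  # on the element, 0-based half-open
    consensus_span: tuple[int, int]
    orientation: str  # "forward" | "reverse"
    score: float


def identify_element(
    consensus: str,
    library: ElementLibrary,
    min_score: float = MIN_HIT_SCORE,
) -> ElementHit | None:
    """Best local-alignment hit of the consensus against the element library,
    testing both orientations; ``None`` when nothing scores above
    ``min_score`` (an explicit no-hit result)."""
    if not consensus:
        raise DataError("empty consensus sequence")
    if len(library) == 0:
        raise DataError("empty element library")
    aligner = _aligner()
    best = None  # (score, entry, orientation, target_seq)
    for entry in library:
        for orientation, target in (
            ("forward", entry.sequence),
            ("reverse", reverse_complement(entry.sequence)),
        ):
            score = float(aligner.score(target, consensus))
            if best is None or score > best[0]:
                best = (score, entry, orientation, target)
    score, entry, orientation, target = best
    if score < min_score:
        log.info("no element hit above score %.1f (best %.1f)", min_score, score)
        return None
    aln = aligner.align(target, consensus)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    pct = 100.0 * counts.identities / columns if columns else 0.0
    t_blocks, q_blocks = aln.aligned
    t_span = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    q_span = (int(q_blocks[0][0]), int(q_blocks[-1][1]))
    if orientation == "reverse":
        n = len(entry.sequence)
        t_span = (n - t_span[1], n - t_span[0])
    return ElementHit(
        element=entry.name,
        percent_identity=pct,
        element_span=t_span,
        consensus_span=q_span,
        orientation=orientation,
        score=score,
    )


# ---------------------------------------------------------------------------
# genomic-level decomposition


@dataclass(frozen=True)
class Segment:
    kind: str  # "literal" | "element_fragment" | "homopolymer"
    sequence: str
    orientation: str | None = None  # element fragments only
    element: str | None = None
    element_span: tuple[int, int] | None = None

    def brackets(self) -> str:
        if self.kind == "homopolymer":
            return f"{self.sequence[0]}{len(self.sequence)}"
        if self.kind == "element_fragment":
            span = (
                f"{self.element}:{self.element_span[0] + 1}-{self.element_span[1]}"
                if self.element_span
                else self.element
            )
            inv = "inv" if self.orientation == "reverse" else ""
            return f"{span}{inv}"
        return self.sequence


@dataclass
class GenomicInsertionAllele:
    insertion_site: tuple[int, int]  # flanking reference positions, 1-based
    segments: tuple[Segment, ...]
    supporting_reads: int

    @property
    def total_length(self) -> int:
        return sum(len(s.sequence) for s in self.segments)

    @property
    def sequence(self) -> str:
        return "".join(s.sequence for s in self.segments)

    def description(self) -> str:
        inner = "; ".join(s.brackets() for s in self.segments)
        return (
            f"g.{self.insertion_site[0]}_{self.insertion_site[1]}ins[{inner}]"
        )


def _peel_homopolymers(residual: str) -> list[Segment]:
    """Split a residual string into terminal homopolymer runs (>= threshold)
    and a middle literal."""
    if not residual:
        return []
    segs: list[Segment] = []
    start, end = 0, len(residual)
    lead = 1
    while lead < end - start and residual[start + lead] == residual[start]:
        lead += 1
    if lead >= HOMOPOLYMER_MIN_RUN:
        segs.append(Segment(kind="homopolymer", sequence=residual[start : start + lead]))
        start += lead
    trail = 0
    if end > start:
        trail = 1
        while trail < end - start and residual[end - trail - 1] == residual[end - 1]:
            trail += 1
        if trail < HOMOPOLYMER_MIN_RUN:
            trail = 0
    middle = residual[start : end - trail]
    if middle:
        segs.append(Segment(kind="literal", sequence=middle))
    if trail:
        segs.append(Segment(kind="homopolymer", sequence=residual[end - trail :]))
    return segs


def decompose_insertion(
    consensus: str, library: ElementLibrary
) -> tuple[Segment, ...]:
    """Greedy decomposition of an inserted sequence: the best element hit
    claims its consensus span; the flanking residuals are split into terminal
    homopolymer runs and literals.  Segment sequences concatenate back to the
    consensus byte-exactly."""
    hit = identify_element(consensus, library)
    if hit is None:
        return tuple(_peel_homopolymers(consensus))
    qs, qe = hit.consensus_span
    segs: list[Segment] = []
    segs.extend(_peel_homopolymers(consensus[:qs]))
    segs.append(
        Segment(
            kind="element_fragment",
            sequence=consensus[qs:qe],
            orientation=hit.orientation,
            element=hit.element,
            element_span=hit.element_span,
        )
    )
    segs.extend(_peel_homopolymers(consensus[qe:]))
    return tuple(segs)


def resolve_genomic_insertion(
    reads: Iterable[ReadAlignment],
    library: ElementLibrary,
    locus: tuple[int, int] | None = None,
    min_insertion_len: int = DEFAULT_MIN_INSERTION_LEN,
    cluster_window: int = DEFAULT_CLUSTER_WINDOW,
    min_support: int = DEFAULT_MIN_SUPPORT,
) -> GenomicInsertionAllele:
    """Reconstruct the inserted allele from genome reads spanning the site.

    Reads must anchor on both sides of the insertion; the largest qualifying
    event within ``locus`` (if given) is consensus-called and decomposed
    against the element library.
    """
    reads = list(reads)
    spanning = [
        r
        for r in reads
        if r.insertions
        and (
            locus is None
            or any(locus[0] <= a < locus[1] for a, _ in r.insertions)
        )
    ]
    events = collect_insertion_reads(
        spanning,
        min_insertion_len=min_insertion_len,
        cluster_window=cluster_window,
        min_support=min_support,
    )
    if not events:
        n = len(spanning)
        raise DataError(
            f"insertion unresolved: only {n} spanning reads with qualifying "
            f"insertion operations (min_support={min_support})"
        )
    event = max(events, key=lambda e: e.supporting_reads)
    consensus = event.consensus()
    segments = decompose_insertion(consensus, library)
    return GenomicInsertionAllele(
        insertion_site=(event.anchor, event.anchor + 1),
        segments=segments,
        supporting_reads=event.supporting_reads,
    )


# ---------------------------------------------------------------------------
# donor-site motif scan


# canonical human splice-donor base frequencies over positions -3..+6
# (exon|GT intron); a coarse consensus PWM, not a trained splice predictor
DONOR_PWM_FREQS = {
    "A": (0.33, 0.60, 0.08, 0.001, 0.001, 0.49, 0.71, 0.06, 0.17),
    "C": (0.37, 0.13, 0.04, 0.001, 0.001, 0.03, 0.08, 0.05, 0.19),
    "G": (0.18, 0.14, 0.81, 0.997, 0.001, 0.45, 0.12, 0.82, 0.19),
    "T": (0.12, 0.13, 0.07, 0.001, 0.997, 0.03, 0.09, 0.07, 0.45),
}
DONOR_PWM_WIDTH = 9
DONOR_EXONIC_BASES = 3  # window offset of the first intron base


@dataclass(frozen=True)
class DonorSiteScore:
    position: int  # 0-based index of the first intron base (the G of GT)
    pwm_score: float  # log2-odds vs uniform background
    passes_gt_rule: bool


def _pwm_matrix(freqs: dict) -> np.ndarray:
    mat = np.full((4, DONOR_PWM_WIDTH), -10.0)
    for bi, base in enumerate("ACGT"):
        for j, f in enumerate(freqs[base]):
            mat[bi, j] = math.log2(max(f, 1e-4) / 0.25)
    return mat


def score_donor_sites(
    consensus: str,
    pwm_freqs: dict | None = None,
    top_k: int = 5,
    gt_filter: bool = True,
) -> list[DonorSiteScore]:
    """Rank candidate donor positions in an inserted sequence by PWM
    log-odds.  With ``gt_filter`` (default) only positions whose +1/+2 bases
    are GT are reported.  Deterministic; ties keep the leftmost position
    first."""
    if len(consensus) < DONOR_PWM_WIDTH:
        raise DataError(
            f"consensus shorter than the PWM width ({DONOR_PWM_WIDTH})"
        )
    mat = _pwm_matrix(pwm_freqs or DONOR_PWM_FREQS)
    codes = np.frombuffer(consensus.encode(), dtype=np.uint8)
    idx = np.full(codes.size, -1, dtype=np.int64)
    for bi, base in enumerate(b"ACGT"):
        idx[codes == base] = bi
    scores = []
    for w in range(0, len(consensus) - DONOR_PWM_WIDTH + 1):
        window = idx[w : w + DONOR_PWM_WIDTH]
        if (window < 0).any():
            continue
        pos = w + DONOR_EXONIC_BASES
        gt = consensus[pos : pos + 2] == "GT"
        if gt_filter and not gt:
            continue
        s = float(mat[window, np.arange(DONOR_PWM_WIDTH)].sum())
        scores.append(DonorSiteScore(position=pos, pwm_score=s, passes_gt_rule=gt))
    scores.sort(key=lambda d: (-d.pwm_score, d.position))
    return scores[:top_k]
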