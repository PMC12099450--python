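"""Core splice engine: quality filtering, junction-chain extraction, per-read
isoform classification against a transcript model, and event quantification.

A read's *junction chain* — the ordered (intron_start, intron_end) gaps its
alignment skips — is its splicing fingerprint.  Classification decomposes any
departure from the canonical chain into a set of splicing deviations:

* ``ExonSkip``      — one or more amplicon exons with no aligned block;
                      adjacent skipped exons merge into a single co-skip.
* ``Pseudoexon``    — an aligned block strictly inside an intron, bounded by
                      junctions on both sides (a cryptic-exon inclusion).
* ``Truncation``    — a junction sharing one canonical boundary while the
                      other is displaced *into* the exon by more than ``tol``.
* ``Elongation``    — the same, displaced into the intron.
* ``InsertionDev``  — an alignment insertion operation of at least
                      ``min_insertion_len`` bases (novel sequence, e.g. a
                      retrotransposon fragment spliced into the mRNA).

Aberrant-splicing levels use the junction-percentage formula
``100 * junction_reads / total_reads`` where the denominator is every read
that passed the quality filter, overlaps the amplicon and was classified.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence, Union

import pysam

from .errors import DataError
from .models_io import Amplicon, TranscriptModel, VariantMarker

log = logging.getLogger(__name__)

DEFAULT_RQ_THRESHOLD = 0.99
DEFAULT_TOL = 5
DEFAULT_MIN_INSERTION_LEN = 50
RQ_TAG = "rq"

MISSING_BASE = "."


# ---------------------------------------------------------------------------
# splicing deviations


@dataclass(frozen=True, order=True)
class ExonSkip:
    """Absence of a run of adjacent exons (transcript numbering)."""

    exons: tuple[int, ...]

    def key(self) -> str:
        return "skip[" + ",".join(str(e) for e in self.exons) + "]"


@dataclass(frozen=True, order=True)
class Pseudoexon:
    """Intron-internal block included in the mRNA (0-based half-open)."""

    start: int
    end: int

    def key(self) -> str:
        return f"pe[{self.start + 1}-{self.end}]"


@dataclass(frozen=True, order=True)
class Truncation:
    """Exon boundary displaced into the exon; ``side`` is the genomic side."""

    exon: int
    side: str  # "start" | "end"
    delta_bp: int

    def __post_init__(self):
        if self.delta_bp <= 0:
            raise ValueError("truncation delta must be positive")

    def key(self) -> str:
        return f"trunc[{self.exon}{'L' if self.side == 'start' else 'R'}-{self.delta_bp}]"


@dataclass(frozen=True, order=True)
class Elongation:
    """Exon boundary displaced into the intron (cryptic splice-site use)."""

    exon: int
    side: str
    delta_bp: int

    def __post_init__(self):
        if self.delta_bp <= 0:
            raise ValueError("elongation delta must be positive")

    def key(self) -> str:
        return f"elong[{self.exon}{'L' if self.side == 'start' else 'R'}+{self.delta_bp}]"


@dataclass(frozen=True, order=True)
class InsertionDev:
    """Novel inserted sequence at a reference anchor (insertion CIGAR op)."""

    anchor: int
    length: int

    def key(self) -> str:
        return f"ins[{self.anchor + 1}:{self.length}]"


Deviation = Union[ExonSkip, Pseudoexon, Truncation, Elongation, InsertionDev]


def isoform_key(deviations: Iterable[Deviation]) -> str:
    """Canonical text serialization of a deviation set."""
    keys = sorted(d.key() for d in deviations)
    return "+".join(keys) if keys else "canonical"


def describe_deviation(dev: Deviation, model: TranscriptModel) -> str:
    if isinstance(dev, ExonSkip):
        if len(dev.exons) == 1:
            return f"exon {dev.exons[0]} skipping"
        return "exon " + " and ".join(str(e) for e in dev.exons) + " co-skipping"
    if isinstance(dev, Pseudoexon):
        return (
            f"{dev.end - dev.start}-nt pseudoexon inclusion "
            f"({model.chrom}:{dev.start + 1}-{dev.end})"
        )
    if isinstance(dev, (Truncation, Elongation)):
        kind = "truncation" if isinstance(dev, Truncation) else "elongation"
        # translate the genomic side into transcript-relative 5'/3'
        if model.strand == "+":
            prime = "5'" if dev.side == "start" else "3'"
        else:
            prime = "3'" if dev.side == "start" else "5'"
        return f"exon {dev.exon} {prime} {kind} ({dev.delta_bp} bp)"
    if isinstance(dev, InsertionDev):
        return f"{dev.length}-nt insertion at {model.chrom}:{dev.anchor + 1}"
    return str(dev)


def describe_isoform(deviations: Iterable[Deviation], model: TranscriptModel) -> str:
    devs = sorted(deviations, key=lambda d: d.key())
    if not devs:
        return "normal splicing"
    return " + ".join(describe_deviation(d, model) for d in devs)


# ---------------------------------------------------------------------------
# read alignments


@dataclass
class ReadAlignment:
    """One long read's aligned structure, stripped to what analysis needs.

    ``blocks`` are gapless aligned intervals (0-based half-open, sorted);
    consecutive blocks are separated by splice junctions (CIGAR N).
    ``insertions`` carry the inserted query sequence at its reference anchor.
    ``marker_bases`` maps each supplied marker to the observed base, or
    ``"."`` when the read does not cover the marker position.
    """

    read_id: str
    blocks: tuple[tuple[int, int], ...]
    insertions: tuple[tuple[int, str], ...] = ()
    marker_bases: dict = field(default_factory=dict)
    rq: float | None = None

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.blocks[i][1], self.blocks[i + 1][0])
            for i in range(len(self.blocks) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]


_QUERY_CONSUMING = {0, 1, 4, 7, 8}  # M I S = X
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M D N = X


def read_alignment_from_segment(
    seg: pysam.AlignedSegment,
    markers: Sequence[VariantMarker] = (),
    rq_tag: str = RQ_TAG,
) -> ReadAlignment:
    """Convert a pysam record: walk the CIGAR once, collecting gapless blocks
    (deletions stay inside a block; N closes it), insertion sequences, marker
    bases and the read-quality tag."""
    blocks: list[list[int]] = []
    insertions: list[tuple[int, str]] = []
    marker_want = {m.pos: m for m in markers}
    marker_bases: dict[VariantMarker, str] = {m: MISSING_BASE for m in markers}
    seq = seg.query_sequence or ""
    rpos = seg.reference_start
    qpos = 0
    cur: list[int] | None = None
    for op, length in seg.cigartuples or ():
        if op in (0, 7, 8):  # M/=/X
            if cur is None:
                cur = [rpos, rpos + length]
            else:
                cur[1] = rpos + length
            if marker_want:
                for mpos, m in marker_want.items():
                    if rpos <= mpos < rpos + length:
                        marker_bases[m] = seq[qpos + (mpos - rpos)]
            rpos += length
            qpos += length
        elif op == 2:  # D — keep block contiguous
            if cur is not None:
                cur[1] = rpos + length
            rpos += length
        elif op == 3:  # N — splice junction
            if cur is not None:
                blocks.append(cur)
                cur = None
            rpos += length
        elif op == 1:  # I
            insertions.append((rpos, seq[qpos : qpos + length]))
            qpos += length
        elif op == 4:  # S
            qpos += length
        # H/P consume nothing we track
    if cur is not None:
        blocks.append(cur)
    rq = None
    if seg.has_tag(rq_tag):
        rq = float(seg.get_tag(rq_tag))
    return ReadAlignment(
        read_id=seg.query_name,
        blocks=tuple((s, e) for s, e in blocks),
        insertions=tuple(insertions),
        marker_bases=marker_bases,
        rq=rq,
    )


def load_reads(
    bam_path: str | Path,
    markers: Sequence[VariantMarker] = (),
    rq_tag: str = RQ_TAG,
) -> list[ReadAlignment]:
    """Read all primary alignments from a BAM/SAM file."""
    reads = []
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for seg in bam.fetch(until_eof=True):
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                continue
            reads.append(read_alignment_from_segment(seg, markers, rq_tag))
    return reads


# ---------------------------------------------------------------------------
# quality filter


@dataclass
class RQFilterResult:
    kept: list[ReadAlignment]
    n_input: int
    n_below: int
    n_missing_rq: int

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def filter_by_rq(
    reads: Iterable[ReadAlignment], threshold: float = DEFAULT_RQ_THRESHOLD
) -> RQFilterResult:
    """Retain reads with predicted accuracy RQ >= threshold (HiFi criterion).

    Reads lacking an RQ tag are retained with a warning and counted
    separately, so an untagged input never silently empties the run.
    """
    if not 0.0 <= threshold <= 1.0:
        raise DataError(f"RQ threshold must be in [0,1], got {threshold}")
    kept: list[ReadAlignment] = []
    n_input = n_below = n_missing = 0
    for read in reads:
        n_input += 1
        if read.rq is None:
            n_missing += 1
            kept.append(read)
        elif read.rq >= threshold:
            kept.append(read)
        else:
            n_below += 1
    if n_missing:
        log.warning("%d reads lacked an RQ tag and were retained", n_missing)
    return RQFilterResult(
        kept=kept, n_input=n_input, n_below=n_below, n_missing_rq=n_missing
    )


# ---------------------------------------------------------------------------
# classification


def extract_junction_chain(read: ReadAlignment) -> tuple[tuple[int, int], ...]:
    """The read's splice gaps as genomically sorted (intron_start, intron_end)
    pairs; a single-block read yields an empty chain."""
    if not read.blocks:
        raise DataError(f"read {read.read_id}: no aligned blocks")
    return read.junctions


@dataclass(frozen=True)
class IsoformCall:
    read_id: str
    deviations: frozenset
    canonical: bool

    @property
    def key(self) -> str:
        return isoform_key(self.deviations)


def classify_read(
    read: ReadAlignment,
    model: TranscriptModel,
    amplicon: Amplicon | None = None,
    tol: int = DEFAULT_TOL,
    min_insertion_len: int = DEFAULT_MIN_INSERTION_LEN,
) -> IsoformCall:
    """Decompose one read's alignment into a set of splicing deviations.

    Pure function of (read, model, amplicon, tol, min_insertion_len).  Reads
    not overlapping the amplicon raise :class:`DataError` so callers can count
    the rejection reason.
    """
    if amplicon is None:
        amplicon = Amplicon(model=model, first_exon=1, last_exon=model.n_exons)
    exons = amplicon.exons_genomic()  # (number, start, end) genomic order
    span = amplicon.genomic_span
    if not read.blocks or read.span[1] <= span[0] or read.span[0] >= span[1]:
        raise DataError(f"read {read.read_id} does not overlap the amplicon")

    deviations: set[Deviation] = set()

    # pseudoexon blocks: fully intronic, junction-bounded on both sides
    n_blocks = len(read.blocks)
    is_pseudo = [False] * n_blocks
    for i, (bs, be) in enumerate(read.blocks):
        if 0 < i < n_blocks - 1 and not any(
            bs < e and s < be for _, s, e in exons
        ):
            is_pseudo[i] = True
            deviations.add(Pseudoexon(start=bs, end=be))

    # skipped exons: no overlapping exonic block; merge adjacent runs
    present: set[int] = set()
    for i, (bs, be) in enumerate(read.blocks):
        if is_pseudo[i]:
            continue
        for num, s, e in exons:
            if bs < e and s < be:
                present.add(num)
    missing = sorted(n for n in amplicon.exon_numbers if n not in present)
    run: list[int] = []
    for n in missing:
        if run and n == run[-1] + 1:
            run.append(n)
        else:
            if run:
                deviations.add(ExonSkip(exons=tuple(run)))
            run = [n]
    if run:
        deviations.add(ExonSkip(exons=tuple(run)))

    # junction-end displacement: truncation / elongation
    def _exon_for(block_idx: int, boundary: int, side: str):
        """Model exon whose canonical boundary this junction end belongs to."""
        bs, be = read.blocks[block_idx]
        best, best_ov = None, -1
        for num, s, e in exons:
            ov = min(be, e) - max(bs, s)
            if ov > best_ov:
                best, best_ov = (num, s, e), ov
        return best if best_ov > 0 else None

    for i in range(n_blocks - 1):
        left, right = read.blocks[i], read.blocks[i + 1]
        jl, jr = left[1], right[0]
        if not is_pseudo[i]:
            hit = _exon_for(i, jl, "end")
            if hit is not None:
                num, s, e = hit
                d = jl - e
                if d > tol:
                    deviations.add(Elongation(exon=num, side="end", delta_bp=d))
                elif d < -tol:
                    deviations.add(Truncation(exon=num, side="end", delta_bp=-d))
        if not is_pseudo[i + 1]:
            hit = _exon_for(i + 1, jr, "start")
            if hit is not None:
                num, s, e = hit
                d = s - jr
                if d > tol:
                    deviations.add(Elongation(exon=num, side="start", delta_bp=d))
                elif d < -tol:
                    deviations.add(Truncation(exon=num, side="start", delta_bp=-d))

    # novel-sequence insertions
    for anchor, seq in read.insertions:
        if len(seq) >= min_insertion_len:
            deviations.add(InsertionDev(anchor=anchor, length=len(seq)))

    fs = frozenset(deviations)
    return IsoformCall(read_id=read.read_id, deviations=fs, canonical=not fs)


@dataclass
class ClassificationResult:
    calls: list[IsoformCall]
    rejected: Counter

    @property
    def n_classified(self) -> int:
        return len(self.calls)


def classify_reads(
    reads: Iterable[ReadAlignment],
    model: TranscriptModel,
    amplicon: Amplicon | None = None,
    tol: int = DEFAULT_TOL,
    min_insertion_len: int = DEFAULT_MIN_INSERTION_LEN,
) -> ClassificationResult:
    calls = []
    rejected: Counter = Counter()
    for read in reads:
        try:
            calls.append(
                classify_read(read, model, amplicon, tol, min_insertion_len)
            )
        except DataError:
            rejected["no_amplicon_overlap"] += 1
    return ClassificationResult(calls=calls, rejected=rejected)


# ---------------------------------------------------------------------------
# quantification


def junction_percentage(junction_reads: int, total_reads: int) -> float:
    """Aberrant-splicing level: 100 * junction_reads / total_reads."""
    if total_reads == 0:
        raise DataError("junction percentage undefined: total_reads is 0")
    if junction_reads < 0 or junction_reads > total_reads:
        raise DataError(
            f"junction_reads {junction_reads} outside 0..{total_reads}"
        )
    return 100.0 * junction_reads / total_reads


@dataclass
class JunctionTable:
    """Per-junction spanning-read counts and per-isoform counts/percentages.

    ``hidden`` flags junctions below the display threshold (they stay in the
    table; the threshold only affects sashimi-style rendering, mirroring a
    junction-coverage *min* display parameter)."""

    junction_counts: dict  # (start, end) -> count
    isoform_counts: dict  # isoform_key -> count
    isoform_deviations: dict  # isoform_key -> frozenset of deviations
    total_reads: int
    display_min_coverage: int = 0

    @property
    def hidden(self) -> set:
        return {
            j
            for j, c in self.junction_counts.items()
            if c < self.display_min_coverage
        }

    def isoform_percentage(self, key: str) -> float:
        return junction_percentage(
            self.isoform_counts.get(key, 0), self.total_reads
        )

    def percentage(self, junction: tuple[int, int]) -> float:
        return junction_percentage(
            self.junction_counts.get(junction, 0), self.total_reads
        )


def build_junction_table(
    calls: Sequence[IsoformCall],
    reads: Sequence[ReadAlignment],
    display_min_coverage: int = 0,
) -> JunctionTable:
    """Tabulate junction spanning counts and isoform counts.

    ``calls`` and ``reads`` must be keyed by the same read ids; the junction
    counts come from the raw chains of the *classified* reads only, so the two
    views share one denominator."""
    call_ids = {c.read_id for c in calls}
    reads_by_id = {r.read_id: r for r in reads}
    missing = call_ids - set(reads_by_id)
    if missing:
        raise DataError(
            f"{len(missing)} classified reads have no alignment record"
        )
    junction_counts: Counter = Counter()
    for c in calls:
        junction_counts.update(reads_by_id[c.read_id].junctions)
    isoform_counts: Counter = Counter()
    isoform_devs: dict[str, frozenset] = {}
    for c in calls:
        isoform_counts[c.key] += 1
        isoform_devs.setdefault(c.key, c.deviations)
    return JunctionTable(
        junction_counts=dict(junction_counts),
        isoform_counts=dict(isoform_counts),
        isoform_deviations=isoform_devs,
        total_reads=len(calls),
        display_min_coverage=display_min_coverage,
    )


# ---------------------------------------------------------------------------
# pseudoexon variant check


@dataclass
class PseudoexonCheck:
    n_pseudoexon_reads: int
    n_alt: int
    n_ref: int
    n_other: int

    @property
    def alt_fraction(self) -> float:
        if self.n_pseudoexon_reads == 0:
            raise DataError("no pseudoexon-containing reads")
        return self.n_alt / self.n_pseudoexon_reads


def variant_in_pseudoexon_check(
    reads: Iterable[ReadAlignment],
    pseudoexon: tuple[int, int],
    variant: VariantMarker,
    tol: int = DEFAULT_TOL,
) -> PseudoexonCheck:
    """Fraction of pseudoexon-containing reads carrying the ALT base at the
    underlying (deep-intronic) variant position.

    The variant must lie inside the pseudoexon interval; reads must have been
    loaded with this variant in their marker list so the observed base is
    available."""
    ps, pe = pseudoexon
    if not ps <= variant.pos < pe:
        raise DataError("variant position not inside the pseudoexon interval")
    n = n_alt = n_ref = n_other = 0
    for read in reads:
        covers = any(
            bs <= ps + tol and be >= pe - tol for bs, be in read.blocks
        )
        if not covers:
            continue
        n += 1
        base = read.marker_bases.get(variant, MISSING_BASE)
        if base == variant.alt_base:
            n_alt += 1
        elif base == variant.ref_base:
            n_ref += 1
        else:
            n_other += 1
    return PseudoexonCheck(
        n_pseudoexon_reads=n, n_alt=n_alt, n_ref=n_ref, n_other=n_other
    )
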