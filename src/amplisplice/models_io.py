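"""Reference inputs: transcript exon models, amplicon definitions, phasing
markers and mobile-element libraries.

All genomic coordinates are stored 0-based half-open internally; user-facing
reports translate to 1-based inclusive.  Exons are numbered in transcript
(biological) order: for a minus-strand transcript, exon 1 is the genomically
rightmost interval, but all arithmetic stays in genomic coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import ConfigError, ParseError

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's exon structure on the genome.

    ``exons`` is sorted by genomic coordinate and non-overlapping; exon
    *numbers* (1..n) follow transcript orientation, so for ``strand == '-'``
    exon 1 is the last tuple entry.
    """

    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"strand must be '+' or '-', got {self.strand!r}")
        if len(self.exons) < 2:
            raise ConfigError(
                f"{self.transcript_id}: a spliced model needs >= 2 exons"
            )
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise ConfigError(
                    f"{self.transcript_id}: empty or inverted exon {start}-{end}"
                )
            if prev_end is not None and start <= prev_end:
                raise ConfigError(
                    f"{self.transcript_id}: exons overlap or are unsorted "
                    f"(intron length < 1 before genomic position {start})"
                )
            prev_end = end

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon(self, number: int) -> tuple[int, int]:
        """Genomic interval of exon ``number`` (1-based, transcript order)."""
        if not 1 <= number <= self.n_exons:
            raise ConfigError(f"exon number {number} out of 1..{self.n_exons}")
        idx = number - 1 if self.strand == "+" else self.n_exons - number
        return self.exons[idx]

    def exon_number(self, genomic_index: int) -> int:
        """Transcript exon number of the exon at genomic sort position."""
        if self.strand == "+":
            return genomic_index + 1
        return self.n_exons - genomic_index

    def canonical_junctions(self) -> tuple[tuple[int, int], ...]:
        """All (intron_start, intron_end) splice gaps in genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(self.n_exons - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class Amplicon:
    """RT-PCR product covering exons ``first_exon``..``last_exon`` of a model.

    Primer offsets inside the terminal exons are not modelled: reads are only
    required to begin and end within those exons, which is all the junction
    logic depends on.
    """

    model: TranscriptModel
    first_exon: int
    last_exon: int
    expected_wt_length: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.first_exon < self.last_exon <= self.model.n_exons:
            raise ConfigError(
                f"amplicon exon range {self.first_exon}..{self.last_exon} "
                f"invalid for a {self.model.n_exons}-exon model"
            )
        if self.expected_wt_length is not None:
            total = sum(
                e - s for s, e in (self.model.exon(n) for n in self.exon_numbers)
            )
            if self.expected_wt_length != total:
                raise ConfigError(
                    f"expected_wt_length {self.expected_wt_length} != sum of "
                    f"included exon lengths {total}"
                )

    @property
    def exon_numbers(self) -> range:
        return range(self.first_exon, self.last_exon + 1)

    @property
    def genomic_span(self) -> tuple[int, int]:
        intervals = [self.model.exon(n) for n in self.exon_numbers]
        return min(s for s, _ in intervals), max(e for _, e in intervals)

    def exons_genomic(self) -> list[tuple[int, int, int]]:
        """Included exons as (exon_number, start, end), genomically sorted."""
        out = [(n, *self.model.exon(n)) for n in self.exon_numbers]
        out.sort(key=lambda t: t[1])
        return out


@dataclass(frozen=True)
class VariantMarker:
    """A heterozygous SNV inside the amplicon used to phase reads to alleles."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    alt_base: str
    allele_label_ref: str = "allele2"
    allele_label_alt: str = "allele1"
    hgvs_label: str = ""

    def __post_init__(self) -> None:
        if self.ref_base == self.alt_base:
            raise ConfigError("marker REF and ALT must differ")
        for b in (self.ref_base, self.alt_base):
            if len(b) != 1 or b not in "ACGT":
                raise ConfigError(f"marker bases must be single ACGT, got {b!r}")

    def base_for_allele(self, allele: str) -> str:
        if allele == self.allele_label_ref:
            return self.ref_base
        if allele == self.allele_label_alt:
            return self.alt_base
        raise ConfigError(f"marker carries no base for allele {allele!r}")


@dataclass(frozen=True)
class ElementEntry:
    name: str
    sequence: str
    source_locus: str | None = None


@dataclass(frozen=True)
class ElementLibrary:
    """Named reference sequences of candidate mobile elements."""

    entries: tuple[ElementEntry, ...]

    def __post_init__(self) -> None:
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise ParseError("duplicate element names in library")
        for e in self.entries:
            if not e.sequence:
                raise ParseError(f"element {e.name}: empty sequence")
            bad = set(e.sequence) - VALID_BASES
            if bad:
                raise ParseError(
                    f"element {e.name}: invalid characters {sorted(bad)}"
                )

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def get(self, name: str) -> ElementEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


# ---------------------------------------------------------------------------
# loaders


def load_transcript_model(
    path: str | Path, format: str, transcript_id: str | None = None
) -> TranscriptModel:
    """Load one transcript model from a BED12 or GFF3 file.

    For BED12 the record whose name column equals ``transcript_id`` is
    selected (or the single record if the file has exactly one and no id is
    given).  For GFF3, exon features are grouped by their ``Parent``
    attribute.
    """
    path = Path(path)
    fmt = format.upper()
    if fmt == "BED12":
        return _load_bed12(path, transcript_id)
    if fmt == "GFF3":
        return _load_gff3(path, transcript_id)
    raise ConfigError(f"unknown model format {format!r} (use BED12 or GFF3)")


def _load_bed12(path: Path, transcript_id: str | None) -> TranscriptModel:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ParseError(
                    f"{path}:{lineno}: BED12 requires 12 columns, got {len(fields)}"
                )
            records.append((lineno, fields))
    if not records:
        raise ParseError(f"{path}: no BED12 records")
    if transcript_id is not None:
        records = [
            (ln, f)
            for ln, f in records
            if f[3] == transcript_id or f[3].split("|")[-1] == transcript_id
        ]
        if not records:
            raise ParseError(f"{path}: transcript {transcript_id!r} not found")
    if len(records) != 1:
        raise ParseError(
            f"{path}: {len(records)} records match; pass transcript_id to select one"
        )
    lineno, f = records[0]
    try:
        chrom, chrom_start = f[0], int(f[1])
        name, strand = f[3], f[5]
        thick_start, thick_end = int(f[6]), int(f[7])
        block_count = int(f[9])
        sizes = [int(x) for x in f[10].rstrip(",").split(",")]
        starts = [int(x) for x in f[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"{path}:{lineno}: malformed BED12 field: {exc}") from exc
    if len(sizes) != block_count or len(starts) != block_count:
        raise ParseError(
            f"{path}:{lineno}: blockCount={block_count} but "
            f"{len(sizes)} sizes / {len(starts)} starts"
        )
    if starts != sorted(starts):
        raise ParseError(f"{path}:{lineno}: blockStarts not sorted")
    exons = tuple(
        (chrom_start + s, chrom_start + s + sz) for s, sz in zip(starts, sizes)
    )
    cds_start = thick_start if thick_start < thick_end else None
    cds_end = thick_end if thick_start < thick_end else None
    gene = name.split("|")[0] if "|" in name else name
    tid = name.split("|")[1] if "|" in name else name
    try:
        return TranscriptModel(
            gene_symbol=gene,
            transcript_id=tid,
            chrom=chrom,
            strand=strand,
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        )
    except ConfigError as exc:
        raise ParseError(f"{path}:{lineno}: {exc}") from exc


def _load_gff3(path: Path, transcript_id: str | None) -> TranscriptModel:
    if transcript_id is None:
        raise ConfigError("GFF3 loading requires a transcript_id")
    import gffutils

    try:
        db = gffutils.create_db(
            str(path), ":memory:", merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:
        raise ParseError(f"{path}: malformed GFF3: {exc}") from exc
    exons: list[tuple[int, int]] = []
    chrom = strand = None
    gene = transcript_id
    for feat in db.all_features(featuretype="exon"):
        if transcript_id in feat.attributes.get("Parent", []):
            exons.append((feat.start - 1, feat.end))
            chrom, strand = feat.seqid, feat.strand
    try:
        parent = db[transcript_id]
        gene = (
            parent.attributes.get("gene", [])
            or parent.attributes.get("gene_name", [gene])
        )[0]
    except gffutils.FeatureNotFoundError:
        pass
    if not exons:
        raise ParseError(f"{path}: no exons with Parent={transcript_id!r}")
    exons.sort()
    try:
        return TranscriptModel(
            gene_symbol=gene,
            transcript_id=transcript_id,
            chrom=chrom,
            strand=strand,
            exons=tuple(exons),
        )
    except ConfigError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_bed12(model: TranscriptModel, path: str | Path) -> None:
    """Serialize a model to a single BED12 line (round-trips with the loader)."""
    start, end = model.span
    sizes = ",".join(str(e - s) for s, e in model.exons)
    starts = ",".join(str(s - start) for s, _ in model.exons)
    thick_start = model.cds_start if model.cds_start is not None else start
    thick_end = model.cds_end if model.cds_end is not None else start
    name = (
        model.transcript_id
        if model.gene_symbol == model.transcript_id
        else f"{model.gene_symbol}|{model.transcript_id}"
    )
    line = "\t".join(
        str(x)
        for x in (
            model.chrom, start, end, name, 0, model.strand,
            thick_start, thick_end, 0, model.n_exons, sizes, starts,
        )
    )
    Path(path).write_text(line + "\n")


def load_markers(path: str | Path, amplicon: Amplicon) -> list[VariantMarker]:
    """Load SNV phasing markers from a VCF-like tab file.

    Expected columns: CHROM POS(1-based) ID REF ALT INFO where INFO may carry
    ``ALLELES=<ref_label>|<alt_label>``.  Markers outside the amplicon's
    genomic span are dropped with a warning; indels and multi-allelic records
    are rejected because phasing supports SNV markers only.
    """
    path = Path(path)
    span = amplicon.genomic_span
    markers: list[VariantMarker] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ParseError(f"{path}:{lineno}: need >= 5 columns")
            chrom, pos1, vid, ref, alt = f[0], f[1], f[2], f[3], f[4]
            info = f[5] if len(f) > 5 else ""
            if "," in alt:
                raise ParseError(
                    f"{path}:{lineno}: multi-allelic record; SNV markers only"
                )
            if len(ref) != 1 or len(alt) != 1:
                raise ParseError(f"{path}:{lineno}: indel ALT; SNV markers only")
            try:
                pos = int(pos1) - 1
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad POS {pos1!r}") from exc
            labels = ("allele2", "allele1")
            for kv in info.split(";"):
                if kv.startswith("ALLELES="):
                    parts = kv[len("ALLELES="):].split("|")
                    if len(parts) == 2:
                        labels = (parts[0], parts[1])
            if chrom != amplicon.model.chrom or not span[0] <= pos < span[1]:
                log.warning(
                    "marker %s at %s:%d outside amplicon span; dropped",
                    vid, chrom, pos + 1,
                )
                continue
            markers.append(
                VariantMarker(
                    chrom=chrom, pos=pos, ref_base=ref, alt_base=alt,
                    allele_label_ref=labels[0], allele_label_alt=labels[1],
                    hgvs_label=vid,
                )
            )
    return markers


def write_markers(markers: Sequence[VariantMarker], path: str | Path) -> None:
    lines = ["#CHROM\tPOS\tID\tREF\tALT\tINFO"]
    for m in markers:
        lines.append(
            "\t".join(
                (
                    m.chrom, str(m.pos + 1), m.hgvs_label or ".",
                    m.ref_base, m.alt_base,
                    f"ALLELES={m.allele_label_ref}|{m.allele_label_alt}",
                )
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def load_element_library(path: str | Path) -> ElementLibrary:
    """Load a mobile-element FASTA; sequences are upper-cased."""
    entries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        entries.append(
            ElementEntry(
                name=rec.id,
                sequence=str(rec.seq).upper(),
                source_locus=rec.description.split(maxsplit=1)[1]
                if " " in rec.description
                else None,
            )
        )
    if not entries:
        raise ParseError(f"{path}: empty element FASTA")
    return ElementLibrary(entries=tuple(entries))


def write_fasta(entries: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in entries:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
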