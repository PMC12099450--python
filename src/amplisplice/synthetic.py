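"""Synthetic aligned long-read generator for amplicon splice analysis.

Emits coordinate-sorted, indexed alignments over a bundled mini-genome in
which each read's aligned blocks are constructed exactly from its isoform's
exon structure: introns become CIGAR skip (N) operations, novel payloads
become insertion (I) operations at their declared breakpoint.  Alongside the
alignments a truth table records, per read, the isoform drawn, the allele,
the read quality (RQ) and the marker bases actually emitted — so every
analysis stage can be validated against known ground truth.

What the generator emulates, and what it does not: reads are full length
over the amplicon (no 5'/3' truncation model, so denominators are
unambiguous); substitution errors are uniform per base and never touch the
two bases flanking a splice junction (junction extraction stays exact and
classification tests isolate classification logic); there is no chimera/PCR
artifact model and no homopolymer-specific error model.  Marker positions
carry the allele's base, replaced with probability ``marker_artifact_rate``
by one of the two non-REF non-ALT bases — mimicking the sequencing artifacts
that produce "undefined" reads at a G/A phasing site.

Presets transcribe per-subject read populations (isoform mixtures at the
published percentages) onto synthetic mini-genomes with the same exon-count
topology as the genes studied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pysam

from .errors import ConfigError
from .models_io import (
    Amplicon,
    ElementEntry,
    ElementLibrary,
    TranscriptModel,
    VariantMarker,
    write_bed12,
    write_fasta,
    write_markers,
)
from .splice import (
    RQ_TAG,
    Deviation,
    Elongation,
    ExonSkip,
    InsertionDev,
    Pseudoexon,
    Truncation,
    isoform_key,
)

log = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# free parameter: the study never reports a per-base error profile
DEFAULT_SUBSTITUTION_RATE = 0.002
JUNCTION_FLANK_PROTECT = 2


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RQMixture:
    """Read-quality mixture: a high-accuracy mode straddling the HiFi
    threshold and a low tail, so the RQ filter is exercised without
    dominating the run."""

    p_high: float = 0.97
    high: tuple[float, float] = (0.99, 1.0)
    low: tuple[float, float] = (0.95, 0.99)

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        is_high = rng.random(n) < self.p_high
        rq = np.where(
            is_high,
            rng.uniform(self.high[0], self.high[1], n),
            rng.uniform(self.low[0], self.low[1], n),
        )
        return rq


@dataclass(frozen=True)
class IsoformSpec:
    name: str
    deviations: frozenset
    allele: str
    proportion: float

    @property
    def key(self) -> str:
        return isoform_key(self.deviations)


@dataclass
class ScenarioConfig:
    model: TranscriptModel
    amplicon: Amplicon
    isoforms: list[IsoformSpec]
    reference: str
    markers: list[VariantMarker] = field(default_factory=list)
    n_reads: int = 50_000
    substitution_error_rate: float = DEFAULT_SUBSTITUTION_RATE
    marker_artifact_rate: float = 0.0
    rq_mixture: RQMixture = field(default_factory=RQMixture)
    insertion_payloads: dict = field(default_factory=dict)
    elements: ElementLibrary | None = None
    seed: int = 1
    rq_tag: str = RQ_TAG
    name: str = "scenario"

    def validate(self) -> None:
        if self.n_reads < 1:
            raise ConfigError("n_reads must be >= 1")
        for rate in (self.substitution_error_rate, self.marker_artifact_rate):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0,1]")
        total = sum(i.proportion for i in self.isoforms)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"isoform proportions sum to {total}, not 1")
        span = self.amplicon.genomic_span
        for iso in self.isoforms:
            for dev in iso.deviations:
                if isinstance(dev, Pseudoexon) and not (
                    span[0] <= dev.start and dev.end <= span[1]
                ):
                    raise ConfigError(
                        f"{iso.name}: pseudoexon outside the amplicon"
                    )
                if isinstance(dev, InsertionDev):
                    if dev not in self.insertion_payloads:
                        raise ConfigError(
                            f"{iso.name}: no payload for insertion {dev.key()}"
                        )
                    payload = self.insertion_payloads[dev]
                    if len(payload) != dev.length:
                        raise ConfigError(
                            f"{iso.name}: payload length {len(payload)} != "
                            f"declared {dev.length}"
                        )


@dataclass
class SimResult:
    bam: Path
    truth: Path
    reference_fasta: Path
    model_bed: Path
    markers_tsv: Path | None = None
    elements_fasta: Path | None = None
    fastq: Path | None = None


# ---------------------------------------------------------------------------
# isoform template construction


@dataclass
class _Template:
    cigar: tuple[tuple[int, int], ...]
    ref_start: int
    seq: bytes
    allowed_error_pos: np.ndarray  # query indices where substitutions may land
    marker_qpos: dict  # VariantMarker -> query index (covered markers only)


def _apply_deviations(
    amplicon: Amplicon, deviations: frozenset
) -> tuple[list[list[int]], list[tuple[int, str]]]:
    """Turn the amplicon exon structure plus a deviation set into aligned
    blocks; returns (blocks, insertion (anchor, placeholder) list)."""
    exons = {num: [s, e] for num, s, e in amplicon.exons_genomic()}
    insertions: list[InsertionDev] = []
    extra_blocks: list[list[int]] = []
    for dev in deviations:
        if isinstance(dev, ExonSkip):
            for n in dev.exons:
                if n not in exons:
                    raise ConfigError(f"skip of exon {n} outside amplicon")
                del exons[n]
        elif isinstance(dev, Pseudoexon):
            extra_blocks.append([dev.start, dev.end])
        elif isinstance(dev, (Truncation, Elongation)):
            if dev.exon not in exons:
                raise ConfigError(
                    f"boundary deviation on skipped/absent exon {dev.exon}"
                )
            iv = exons[dev.exon]
            sign = 1 if isinstance(dev, Elongation) else -1
            if dev.side == "end":
                iv[1] += sign * dev.delta_bp
            else:
                iv[0] -= sign * dev.delta_bp
            if iv[1] - iv[0] < 1:
                raise ConfigError(f"exon {dev.exon} truncated to nothing")
        elif isinstance(dev, InsertionDev):
            insertions.append(dev)
        else:
            raise ConfigError(f"unknown deviation {dev!r}")
    blocks = sorted(list(exons.values()) + extra_blocks)
    prev_end = None
    for s, e in blocks:
        if prev_end is not None and s <= prev_end:
            raise ConfigError("deviations produce overlapping blocks")
        prev_end = e
    return blocks, insertions


def _build_template(config: ScenarioConfig, iso: IsoformSpec) -> _Template:
    blocks, ins_devs = _apply_deviations(config.amplicon, iso.deviations)
    ins_by_anchor: dict[int, str] = {}
    for dev in sorted(ins_devs, key=lambda d: d.anchor):
        if dev.anchor in ins_by_anchor:
            raise ConfigError("two insertions at the same anchor")
        ins_by_anchor[dev.anchor] = config.insertion_payloads[dev]

    ref = config.reference
    cigar: list[tuple[int, int]] = []
    seq_parts: list[str] = []
    protected: list[tuple[int, int]] = []  # query intervals to keep error-free
    marker_qpos: dict[VariantMarker, int] = {}
    qlen = 0
    prev_end: int | None = None
    def _emit_insertion(anchor: int) -> None:
        nonlocal qlen
        payload = ins_by_anchor.pop(anchor)
        cigar.append((1, len(payload)))
        seq_parts.append(payload)
        qlen += len(payload)

    for bs, be in blocks:
        if prev_end is not None:
            cigar.append((3, bs - prev_end))  # N
        # split the M block at any internal insertion anchors
        bounds = [bs] + sorted(a for a in ins_by_anchor if bs < a < be) + [be]
        for ss, se in zip(bounds, bounds[1:]):
            m_len = se - ss
            cigar.append((0, m_len))
            for m in config.markers:
                if ss <= m.pos < se:
                    marker_qpos[m] = qlen + (m.pos - ss)
            seq_parts.append(ref[ss:se])
            protected.append((qlen, qlen + JUNCTION_FLANK_PROTECT))
            protected.append((qlen + m_len - JUNCTION_FLANK_PROTECT, qlen + m_len))
            qlen += m_len
            if se != be and se in ins_by_anchor:
                _emit_insertion(se)
        if be in ins_by_anchor:  # payload at the spliced block end
            _emit_insertion(be)
        prev_end = be
    if ins_by_anchor:
        raise ConfigError(
            f"insertion anchors {sorted(ins_by_anchor)} fall outside blocks"
        )
    seq = "".join(seq_parts)
    mask = np.ones(qlen, dtype=bool)
    for a, b in protected:
        mask[max(a, 0) : min(b, qlen)] = False
    for qp in marker_qpos.values():
        mask[qp] = False
    allowed = np.flatnonzero(mask)
    return _Template(
        cigar=tuple(cigar),
        ref_start=blocks[0][0],
        seq=seq.encode(),
        allowed_error_pos=allowed,
        marker_qpos=marker_qpos,
    )


# ---------------------------------------------------------------------------
# simulation


def simulate_scenario(
    config: ScenarioConfig,
    outdir: str | Path,
    prefix: str | None = None,
    write_fastq: bool = False,
) -> SimResult:
    """Simulate a scenario into ``outdir``: sorted+indexed BAM, truth table
    TSV, mini-reference FASTA, model BED12 and (when present) marker/element
    files.  Deterministic for a fixed config seed."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prefix = prefix or config.name
    rng = np.random.default_rng(config.seed)

    templates = [_build_template(config, iso) for iso in config.isoforms]
    props = np.array([iso.proportion for iso in config.isoforms])
    props = props / props.sum()
    n = config.n_reads
    iso_idx = rng.choice(len(templates), size=n, p=props)
    # quantize to float32 so the BAM tag and the truth table carry the exact
    # same value (the tag is stored as a 32-bit float)
    rqs = config.rq_mixture.draw(rng, n).astype(np.float32)

    chrom = config.model.chrom
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": chrom, "LN": len(config.reference)}],
        }
    )
    unsorted_bam = outdir / f"{prefix}.unsorted.bam"
    bam_path = outdir / f"{prefix}.bam"
    truth_path = outdir / f"{prefix}.truth.tsv"
    fastq_path = outdir / f"{prefix}.fastq" if write_fastq else None

    err_rate = config.substitution_error_rate
    art_rate = config.marker_artifact_rate
    other_bases = {
        m: np.frombuffer(
            "".join(
                b for b in "ACGT" if b not in (m.ref_base, m.alt_base)
            ).encode(),
            dtype=np.uint8,
        )
        for m in config.markers
    }

    fq = open(fastq_path, "w") if fastq_path else None
    with open(truth_path, "w") as truth, pysam.AlignmentFile(
        str(unsorted_bam), "wb", header=header
    ) as bam:
        truth.write("read_id\tisoform\tallele\trq\tmarker_bases\n")
        for i in range(n):
            iso = config.isoforms[iso_idx[i]]
            tpl = templates[iso_idx[i]]
            seq = bytearray(tpl.seq)
            if err_rate > 0 and len(tpl.allowed_error_pos):
                k = rng.binomial(len(tpl.allowed_error_pos), err_rate)
                if k:
                    pos = rng.choice(tpl.allowed_error_pos, size=k, replace=False)
                    for p in pos:
                        cur = seq[p]
                        new = cur
                        while new == cur:
                            new = _BASES[rng.integers(4)]
                        seq[p] = new
            mb_rec = []
            for m in config.markers:
                qp = tpl.marker_qpos.get(m)
                if qp is None:
                    mb_rec.append(f"{m.pos + 1}:.")
                    continue
                base = m.base_for_allele(iso.allele)
                if art_rate > 0 and rng.random() < art_rate:
                    base = chr(other_bases[m][rng.integers(len(other_bases[m]))])
                seq[qp] = ord(base)
                mb_rec.append(f"{m.pos + 1}:{base}")
            read_id = f"r{i:07d}"
            a = pysam.AlignedSegment(header)
            a.query_name = read_id
            a.flag = 0
            a.reference_id = 0
            a.reference_start = tpl.ref_start
            a.mapping_quality = 60
            a.cigartuples = tpl.cigar
            a.query_sequence = seq.decode()
            a.query_qualities = pysam.qualitystring_to_array("~" * len(seq))
            a.set_tag(config.rq_tag, float(rqs[i]), value_type="f")
            bam.write(a)
            truth.write(
                f"{read_id}\t{iso.name}\t{iso.allele}\t{float(rqs[i])!r}\t"
                + (";".join(mb_rec) if mb_rec else ".")
                + "\n"
            )
            if fq:
                fq.write(f"@{read_id}\n{seq.decode()}\n+\n{'~' * len(seq)}\n")
    if fq:
        fq.close()

    pysam.sort("-o", str(bam_path), str(unsorted_bam))
    unsorted_bam.unlink()
    pysam.index(str(bam_path))

    ref_path = outdir / f"{prefix}.reference.fa"
    write_fasta([(chrom, config.reference)], ref_path)
    model_path = outdir / f"{prefix}.model.bed"
    write_bed12(config.model, model_path)
    markers_path = None
    if config.markers:
        markers_path = outdir / f"{prefix}.markers.tsv"
        write_markers(config.markers, markers_path)
    elements_path = None
    if config.elements is not None:
        elements_path = outdir / f"{prefix}.elements.fa"
        write_fasta([(e.name, e.sequence) for e in config.elements], elements_path)
    return SimResult(
        bam=bam_path,
        truth=truth_path,
        reference_fasta=ref_path,
        model_bed=model_path,
        markers_tsv=markers_path,
        elements_fasta=elements_path,
        fastq=fastq_path,
    )


def load_truth(path: str | Path):
    """Truth table as a pandas DataFrame."""
    import pandas as pd

    return pd.read_csv(path, sep="\t", dtype={"marker_bases": str})


# ---------------------------------------------------------------------------
# bundled synthetic mobile element

_ELEMENT_SEED = 777
_ELEMENT_LEN = 2514  # matches the span of the source-locus annotation used
_DONOR_MOTIF = "CAGGTAAGT"
# offset of the planted donor 9-mer within the transcribed (inserted) form;
# the GT dinucleotide sits at payload positions 860-861 (0-based)
DONOR_MOTIF_OFFSET = 857
CDNA_PAYLOAD_LEN = 875
GENOMIC_HOMOPOLYMER = "A" * 38
GENOMIC_TAIL_LITERAL = "GACTAGAGAACC"


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def sva_inserted_form() -> str:
    """The transcribed orientation of the bundled SVA_F-like element, with a
    canonical donor 9-mer planted at a fixed offset (synthetic sequence)."""
    rng = np.random.default_rng(_ELEMENT_SEED)
    seq = list(_random_seq(rng, _ELEMENT_LEN))
    seq[DONOR_MOTIF_OFFSET : DONOR_MOTIF_OFFSET + len(_DONOR_MOTIF)] = _DONOR_MOTIF
    return "".join(seq)


def sva_element_library() -> ElementLibrary:
    """Single-entry library holding the element in its source-locus
    orientation (the transcribed form is its reverse complement, so hits on
    cDNA payloads report orientation 'reverse', i.e. an inverted element)."""
    return ElementLibrary(
        entries=(
            ElementEntry(
                name="SVA_F_synthetic",
                sequence=reverse_complement(sva_inserted_form()),
                source_locus="synthetic mobile-element stand-in",
            ),
        )
    )


def cdna_insertion_payload() -> str:
    """The partial element carried by the aberrant cDNA isoform: the first
    875 nt of the transcribed element form, ending shortly after the planted
    donor site."""
    return sva_inserted_form()[:CDNA_PAYLOAD_LEN]


def genomic_insertion_payload() -> str:
    """The full inserted allele at the genomic level:
    [literal G; inverted element (full length); A-homopolymer; literal]."""
    return "G" + sva_inserted_form() + GENOMIC_HOMOPOLYMER + GENOMIC_TAIL_LITERAL


# ---------------------------------------------------------------------------
# mini-genome scaffolding for presets


def _make_scene(
    internal_seed: int,
    gene: str,
    transcript_id: str,
    n_exons: int,
    strand: str = "+",
    exon_len: tuple[int, int] = (80, 120),
    intron_len: tuple[int, int] = (200, 400),
    flank: int = 300,
) -> tuple[TranscriptModel, str]:
    """Deterministic mini-genome + exon model; the internal seed is fixed per
    preset so the reference is identical across run seeds."""
    rng = np.random.default_rng(internal_seed)
    exons = []
    pos = flank
    for i in range(n_exons):
        el = int(rng.integers(exon_len[0], exon_len[1] + 1))
        exons.append((pos, pos + el))
        pos += el
        if i < n_exons - 1:
            pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
    genome_len = pos + flank
    genome = _random_seq(rng, genome_len)
    model = TranscriptModel(
        gene_symbol=gene,
        transcript_id=transcript_id,
        chrom=f"chr_{gene}",
        strand=strand,
        exons=tuple(exons),
    )
    return model, genome


def _set_base(genome: str, pos: int, base: str) -> str:
    return genome[:pos] + base + genome[pos + 1 :]


def _iso(name, deviations, allele, proportion) -> IsoformSpec:
    return IsoformSpec(
        name=name,
        deviations=frozenset(deviations),
        allele=allele,
        proportion=proportion,
    )


def _marker_in_exon(
    model: TranscriptModel, genome: str, exon_number: int, offset: int,
    ref_base: str, alt_base: str, label_ref: str, label_alt: str, hgvs: str,
) -> tuple[VariantMarker, str]:
    s, _ = model.exon(exon_number)
    pos = s + offset
    genome = _set_base(genome, pos, ref_base)
    m = VariantMarker(
        chrom=model.chrom, pos=pos, ref_base=ref_base, alt_base=alt_base,
        allele_label_ref=label_ref, allele_label_alt=label_alt, hgvs_label=hgvs,
    )
    return m, genome


def _preset_p1() -> ScenarioConfig:
    model, genome = _make_scene(101, "HGSNAT", "TX_HGSNAT.1", n_exons=18)
    amplicon = Amplicon(model=model, first_exon=2, last_exon=18)
    isoforms = [
        _iso("wt", (), "allele1", 0.851),
        _iso("skip_ex4", (ExonSkip(exons=(4,)),), "allele1", 0.149),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        name="P1_HGSNAT",
    )


def _preset_p2() -> ScenarioConfig:
    model, genome = _make_scene(102, "CEP290", "TX_CEP290.1", n_exons=19)
    amplicon = Amplicon(model=model, first_exon=1, last_exon=19)
    # 97-nt pseudoexon inside the intron downstream of exon 12, with the
    # activating deep-intronic variant inside it on allele 2
    e12_end = model.exon(12)[1]
    pe = Pseudoexon(start=e12_end + 150, end=e12_end + 150 + 97)
    marker = VariantMarker(
        chrom=model.chrom, pos=pe.start + 40, ref_base="A", alt_base="G",
        allele_label_ref="allele1", allele_label_alt="allele2",
        hgvs_label="deep_intronic_A>G",
    )
    genome = _set_base(genome, marker.pos, "A")
    isoforms = [
        _iso("wt_allele1", (), "allele1", 0.50),
        _iso("pseudoexon_allele2", (pe,), "allele2", 0.35),
        _iso("wt_allele2", (), "allele2", 0.15),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        markers=[marker], marker_artifact_rate=0.002, name="P2_CEP290",
    )


def _impg2_scene():
    return _make_scene(104, "IMPG2", "TX_IMPG2.1", n_exons=19)


def _preset_p4_ctrl() -> ScenarioConfig:
    model, genome = _impg2_scene()
    amplicon = Amplicon(model=model, first_exon=13, last_exon=19)
    isoforms = [
        _iso("wt", (), "allele1", 0.314),
        _iso("skip_ex16", (ExonSkip(exons=(16,)),), "allele1", 0.182),
        _iso("skip_ex16_17", (ExonSkip(exons=(16, 17)),), "allele1", 0.195),
        _iso("skip_ex17", (ExonSkip(exons=(17,)),), "allele1", 0.309),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        name="P4_IMPG2_ctrl",
    )


def _preset_p4_mut() -> ScenarioConfig:
    model, genome = _impg2_scene()
    amplicon = Amplicon(model=model, first_exon=13, last_exon=19)
    trunc15 = Truncation(exon=15, side="end", delta_bp=21)
    isoforms = [
        _iso("wt", (), "allele1", 0.399),
        _iso("skip_ex16", (ExonSkip(exons=(16,)),), "allele1", 0.133),
        _iso("skip_ex16_17", (ExonSkip(exons=(16, 17)),), "allele1", 0.163),
        _iso("trunc_ex15", (trunc15,), "allele2", 0.155),
        _iso(
            "trunc_ex15_skip_ex16",
            (trunc15, ExonSkip(exons=(16,))),
            "allele2",
            0.150,
        ),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        name="P4_IMPG2_mut",
    )


def _chm_scene():
    return _make_scene(105, "CHM", "TX_CHM.1", n_exons=15)


def _preset_p5() -> ScenarioConfig:
    model, genome = _chm_scene()
    amplicon = Amplicon(model=model, first_exon=1, last_exon=15)
    isoforms = [
        _iso("wt", (), "allele1", 0.102),
        _iso("skip_ex12", (ExonSkip(exons=(12,)),), "allele1", 0.800),
        _iso("skip_ex11_12", (ExonSkip(exons=(11, 12)),), "allele1", 0.098),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        name="P5_CHM",
    )


def _preset_carrier() -> ScenarioConfig:
    model, genome = _chm_scene()
    amplicon = Amplicon(model=model, first_exon=1, last_exon=15)
    isoforms = [
        _iso("wt", (), "allele1", 0.600),
        _iso("skip_ex12", (ExonSkip(exons=(12,)),), "allele2", 0.387),
        _iso("skip_ex11_12", (ExonSkip(exons=(11, 12)),), "allele2", 0.013),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        name="CARRIER_CHM",
    )


def _nmnat1_scene():
    # wider introns so the elongated exon 2 plus breakpoint fits comfortably
    return _make_scene(
        106, "NMNAT1", "TX_NMNAT1.1", n_exons=5, intron_len=(300, 500)
    )


def _nmnat1_marker(model, genome, hgvs="c.769G>A"):
    return _marker_in_exon(
        model, genome, exon_number=5, offset=40, ref_base="G", alt_base="A",
        label_ref="allele2", label_alt="allele1", hgvs=hgvs,
    )


def _preset_p6() -> ScenarioConfig:
    model, genome = _nmnat1_scene()
    marker, genome = _nmnat1_marker(model, genome)
    amplicon = Amplicon(model=model, first_exon=1, last_exon=5)
    isoforms = [_iso("wt_allele1", (), "allele1", 1.0)]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        markers=[marker], marker_artifact_rate=0.002, name="P6_NMNAT1",
    )


def _preset_p7() -> ScenarioConfig:
    model, genome = _nmnat1_scene()
    marker, genome = _nmnat1_marker(model, genome)
    amplicon = Amplicon(model=model, first_exon=1, last_exon=5)
    isoforms = [
        _iso("wt_allele1", (), "allele1", 0.9985),
        _iso("wt_allele2", (), "allele2", 0.0015),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        markers=[marker], marker_artifact_rate=0.002, name="P7_NMNAT1",
        n_reads=100_000,
    )


SVA_ELONGATION_BP = 39  # exon-2 read-through into intron 2 before the payload


def _preset_monoallelic(name: str, hgvs: str) -> ScenarioConfig:
    model, genome = _nmnat1_scene()
    marker, genome = _nmnat1_marker(model, genome, hgvs=hgvs)
    amplicon = Amplicon(model=model, first_exon=1, last_exon=5)
    e2_end = model.exon(2)[1]
    payload = cdna_insertion_payload()
    elong = Elongation(exon=2, side="end", delta_bp=SVA_ELONGATION_BP)
    ins = InsertionDev(anchor=e2_end + SVA_ELONGATION_BP, length=len(payload))
    isoforms = [
        _iso("wt_allele1", (), "allele1", 0.910),
        _iso("wt_allele2", (), "allele2", 0.045),
        _iso("sva_allele2", (elong, ins), "allele2", 0.045),
    ]
    return ScenarioConfig(
        model=model, amplicon=amplicon, isoforms=isoforms, reference=genome,
        markers=[marker], marker_artifact_rate=0.005,
        insertion_payloads={ins: payload}, elements=sva_element_library(),
        name=name,
    )


_PRESET_BUILDERS = {
    "P1_HGSNAT": _preset_p1,
    "P2_CEP290": _preset_p2,
    "P4_IMPG2_ctrl": _preset_p4_ctrl,
    "P4_IMPG2_mut": _preset_p4_mut,
    "P5_CHM": _preset_p5,
    "CARRIER_CHM": _preset_carrier,
    "P6_NMNAT1": _preset_p6,
    "P7_NMNAT1": _preset_p7,
    "P8_NMNAT1": lambda: _preset_monoallelic("P8_NMNAT1", "c.769G>A"),
    "P9_NMNAT1": lambda: _preset_monoallelic("P9_NMNAT1", "c.769G>A"),
    "P10_NMNAT1": lambda: _preset_monoallelic("P10_NMNAT1", "c.634G>A"),
}

PRESET_NAMES = tuple(_PRESET_BUILDERS)


def preset(
    name: str, n_reads: int | None = None, seed: int | None = None
) -> ScenarioConfig:
    """A fully populated scenario on a synthetic mini-genome.  Isoform
    proportions are the published per-subject percentages; ``n_reads`` and
    ``seed`` override the defaults."""
    if name not in _PRESET_BUILDERS:
        raise ConfigError(
            f"unknown preset {name!r}; choose from {', '.join(PRESET_NAMES)}"
        )
    cfg = _PRESET_BUILDERS[name]()
    if n_reads is not None:
        cfg.n_reads = n_reads
    if seed is not None:
        cfg.seed = seed
    return cfg


# ---------------------------------------------------------------------------
# genomic-level scenario (DNA reads spanning the element insertion site)


@dataclass
class GenomicSimResult:
    bam: Path
    reference_fasta: Path
    elements_fasta: Path
    insertion_site: int
    payload: str


def simulate_genomic_insertion(
    outdir: str | Path,
    n_reads: int = 14,
    seed: int = 1,
    substitution_error_rate: float = 0.0,
    payload: str | None = None,
) -> GenomicSimResult:
    """Genome-sequencing counterpart of the monoallelic presets: contiguous
    DNA reads spanning the intron-2 insertion site, each carrying the full
    inserted allele as one insertion operation.  Default error rate 0 so the
    inserted allele is reconstructable byte-exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, genome = _nmnat1_scene()
    site = model.exon(2)[1] + SVA_ELONGATION_BP  # payload begins here
    if payload is None:
        payload = genomic_insertion_payload()
    rng = np.random.default_rng(seed)
    chrom = model.chrom
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": chrom, "LN": len(genome)}],
        }
    )
    bam_path = outdir / "genomic.bam"
    flank = 400
    with pysam.AlignmentFile(str(bam_path), "wb", header=header) as bam:
        starts = sorted(
            int(rng.integers(max(0, site - flank - 200), site - flank))
            for _ in range(n_reads)
        )
        for i, start in enumerate(starts):
            end = min(len(genome), site + flank + int(rng.integers(0, 200)))
            left = genome[start:site]
            right = genome[site:end]
            pl = payload
            if substitution_error_rate > 0:
                pl = _mutate(pl, substitution_error_rate, rng)
                left = _mutate(left, substitution_error_rate, rng)
                right = _mutate(right, substitution_error_rate, rng)
            a = pysam.AlignedSegment(header)
            a.query_name = f"g{i:04d}"
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigartuples = [
                (0, site - start),
                (1, len(pl)),
                (0, end - site),
            ]
            a.query_sequence = left + pl + right
            a.query_qualities = pysam.qualitystring_to_array(
                "~" * (len(left) + len(pl) + len(right))
            )
            a.set_tag(RQ_TAG, 0.999, value_type="f")
            bam.write(a)
    pysam.index(str(bam_path))
    ref_path = outdir / "genomic.reference.fa"
    write_fasta([(chrom, genome)], ref_path)
    elements_path = outdir / "genomic.elements.fa"
    write_fasta(
        [(e.name, e.sequence) for e in sva_element_library()], elements_path
    )
    return GenomicSimResult(
        bam=bam_path,
        reference_fasta=ref_path,
        elements_fasta=elements_path,
        insertion_site=site,
        payload=payload,
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = bytearray(seq.encode())
    k = rng.binomial(len(out), rate)
    if k:
        for p in rng.choice(len(out), size=k, replace=False):
            cur = out[p]
            new = cur
            while new == cur:
                new = _BASES[rng.integers(4)]
            out[p] = new
    return out.decode()
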