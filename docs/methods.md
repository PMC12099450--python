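# Methods

## Scope and model

`amplisplice` analyses targeted long-read cDNA amplicon sequencing of a
single transcript: an RT-PCR product spanning a chosen exon range is
sequenced with high-fidelity long reads, each read covering the amplicon
end to end. Because every read is a full-length observation of one mRNA
molecule, splice defects can be read out per molecule and, when a
heterozygous variant lies inside the amplicon, per allele.

The pipeline starts from quality-tagged spliced alignments (BAM/SAM).
Demultiplexing, consensus generation and alignment itself are upstream
tools' jobs; the synthetic generator emits alignments by construction, so
no aligner is run anywhere in the package.

## Read classification

A read's splicing fingerprint is its **junction chain**: the ordered
`(intron_start, intron_end)` gaps (CIGAR `N` operations) of its alignment.
Classification decomposes the difference between a read's chain and the
transcript model's canonical chain into deviations, applied jointly:

- **exon skip** — an amplicon exon with no overlapping aligned block;
  adjacent skipped exons merge into one co-skip deviation, so
  `skip[16,17]` is a different isoform from `skip[16]` + `skip[17]`,
  mirroring how multi-exon skipping events are named in the field;
- **pseudoexon** — an aligned block strictly inside an intron, bounded by
  junctions on both sides (cryptic-exon inclusion);
- **truncation / elongation** — a junction sharing one canonical boundary
  while the other end is displaced by more than `tol` into the exon or the
  intron (cryptic splice-site use); the displacement in bp is part of the
  deviation identity;
- **insertion** — an alignment insertion operation of at least
  `min_insertion_len` bases (novel sequence, e.g. a retrotransposon
  fragment spliced into the mRNA). Shorter insertions are treated as
  sequencing indel noise.

Deviation sets compose freely (a read can be elongation + insertion). The
serialized, sorted deviation set is the isoform key; an empty set is
canonical.

Key parameters:

| parameter | default | meaning |
|---|---|---|
| `rq_threshold` | 0.99 | minimum per-read predicted accuracy (HiFi criterion); reads without an RQ tag are kept but counted separately |
| `tol` | 5 bp | junction-end matching tolerance, each end independently; absorbs aligner jitter without merging distinct events. Raising `tol` can only reclassify deviant reads as canonical, never the reverse |
| `min_insertion_len` | 50 bp | separates novel-sequence insertions from HiFi indel noise (the events of interest are hundreds of nt) |
| `display_min_coverage` | 0 | sashimi-style rendering threshold; junctions below it are hidden in plots but always retained in tables |

Event levels use the junction-percentage formula
`100 × junction_reads / total_reads`. The denominator is every read that
passed the RQ filter, overlaps the amplicon and was classified; rejected
reads are counted and reported separately. A zero denominator is an
explicit error, never 0%.

## Allele phasing

Each covered marker SNV votes for the allele whose base the read shows. A
base matching neither REF nor ALT is an artifact vote. Unanimous
non-artifact votes assign the allele; conflicting votes or artifact-only
observations make the read **undefined**; reads covering no marker are
**unphaseable**. Undefined and unphaseable reads are excluded from every
allele denominator, so allele percentages are invariant to the number of
artifact reads — the exclusion rule the analysis depends on. Unanimity
across multiple markers is deliberately conservative; typical runs have a
single marker.

Allelic depletion is flagged per allele from an exact two-sided binomial
test against the expected heterozygous balance (default 0.5), plus a
qualitative flag: `absent` (0 reads), `near_absent` (< 1%, a configurable
convention of this package), `skewed` (test rejects at `alpha`),
`balanced`. Strong depletion of one allele is the signature of transcript
degradation (e.g. NMD or promoter-variant instability); the test is a
reporting aid, not a clinical classifier.

## Insertion characterization

Insertions are consumed from alignment insertion operations (amplicon and
genome reads anchor on both sides of the event, so aligners emit internal
`I` operations; soft-clip rescue is a non-goal). Operations ≥
`min_insertion_len` are clustered by reference anchor within
`cluster_window` (20 bp); clusters with ≥ `min_support` (10) reads become
events.

The consensus is a per-position majority over sequences anchored at the
insertion start, with length equal to the median observed length; ties
break to the alphabetically first base and the number of ambiguous columns
is logged. At HiFi-like substitution rates the majority vote recovers the
true payload exactly with overwhelming probability (per-site error
≪ 1/length for the supports involved).

Element identification is local Smith–Waterman alignment (match +2,
mismatch −3, gap open −5, gap extend −2; a gap of length L costs
−5 −2(L−1)) of the consensus against every library entry in both
orientations; percent identity = identities / alignment columns × 100.
Identification is orientation-symmetric: reverse-complementing the
consensus flips the reported orientation and preserves score and identity.

Genome-level resolution extracts the inserted segment from spanning reads,
consensus-calls it, and decomposes it greedily: the best element hit claims
its span; flanking residuals are split into terminal homopolymer runs
(≥ 10 nt, chosen to capture poly-A tracts typical of retrotransposon
integration; not a literature constant) and literals. Segment sequences
concatenate back to the consensus byte-exactly, and the reported insertion
site is the 1-based flanking reference position pair, mirroring HGVS
`ins[...]` syntax.

Candidate novel donor sites in an inserted sequence are ranked by a 9-mer
splice-donor position weight matrix (consensus (C/A)AG|GTAAGT, log2-odds
against a uniform background) over positions whose +1/+2 bases are GT.
This is a coarse motif scan for flagging plausible donors — explicitly not
a reimplementation of dedicated splice-site predictors, whose scores it
does not approximate.

## Synthetic data

The generator emits coordinate-sorted, indexed BAM alignments over
deterministic mini-genomes, plus a per-read truth table (isoform, allele,
RQ, emitted marker bases). Reads are built exactly from their isoform's
exon structure; the only stochastic elements are the isoform draw, the RQ
draw, substitution errors and marker artifacts, all driven by one seeded
generator, so runs are byte-reproducible.

Design choices that matter for interpretation:

- Reads are full-length over the amplicon. Real libraries contain some
  truncated molecules; passing tests therefore demonstrate correctness of
  classification and accounting, not robustness to degraded RNA.
- Substitution errors (default rate 0.002/base, a free parameter — no
  per-base error profile is published for this assay) never touch the two
  bases flanking a junction, so junction extraction is exact and tests
  isolate classification logic from alignment-error modelling.
- Marker artifacts replace the allele base with one of the two
  non-REF/non-ALT bases at `marker_artifact_rate`, reproducing the
  undefined-read phenomenon at a G/A site (C or T observed).
- RQ is drawn from a mixture with 97% of reads at ≥ 0.99, exercising the
  HiFi filter without dominating it, and is quantized to float32 so the
  BAM tag and the truth table agree bitwise.
- Insertions are encoded as alignment insertion operations, matching how a
  spliced aligner represents an internal novel segment in both-side
  anchored reads.
- No chimera/PCR model, no homopolymer-specific errors, no real-genome
  coordinates: presets are synthetic mini-genomes with the same exon-count
  topology as the genes they emulate.

Preset mixtures are the published per-subject percentages. Where printed
percentages do not sum to 100%, the remainder goes to isoforms of the
types reported for that subject (e.g. an exon-17 skip in the control
condition; exon-15 truncation combinations in the mutant condition), and
where only an event's percentage is printed, the known primary effect
takes the bulk of the remainder. These fillers are package defaults chosen
once; the tested quantities never depend on them beyond occupying the
complement of the mixture. The three monoallelic presets all use the
published mean enrichment (0.91) since per-subject values are not printed.

The bundled mobile element is a synthetic 2,514-nt sequence (stored in its
source-locus orientation; the transcribed form is its reverse complement)
with a canonical donor 9-mer planted at offset 857 of the transcribed
form. The cDNA payload is the first 875 nt of the transcribed form; the
genomic payload is `[G; full element inverted; A×38; GACTAGAGAACC]`. The
exon-2 elongation is 39 bp so elongation + payload = 914 bp of novel
sequence past the canonical donor.

## Problem sizes

Validation runs use 50,000 reads per amplicon preset (100,000 for the
severe-depletion scenario, where the minor allele is 0.15%), matching the
order of magnitude of real runs while keeping each preset execution in
seconds. Oracle-equivalence checks run at a few hundred reads where
brute-force re-derivation is cheap; the genome-level preset uses 14
spanning reads, as few as a real whole-genome experiment provides.

## Known limitations

- One transcript model per run; no isoform-database support.
- No statistical phasing from read co-occurrence; markers must be given.
- Intron retention is not a modelled deviation class (a retained intron
  would surface as an elongation pair or unclassified configuration).
- No full/partial splice-defect verdict is ever issued automatically; when
  phasing is impossible the output simply lacks allele columns.
- The donor PWM is a motif scan, not a splice-strength predictor.
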