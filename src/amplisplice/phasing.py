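"""Allele phasing of amplicon reads via in-amplicon heterozygous SNV markers.

Each covered marker votes for the allele whose base the read shows; a base
matching neither REF nor ALT is a sequencing artifact vote.  Reads with
unanimous non-artifact votes get that allele; conflicting votes, or
artifact-only observations, are *undefined* and excluded from every allele
denominator (the study's exclusion rule for artifact bases at the phasing
site).  Reads covering no marker at all are *unphaseable* — a separate class,
because an amplicon without informative variants is a different situation
from an artifact base at a covered site.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy.stats import binomtest

from .errors import DataError
from .models_io import VariantMarker
from .splice import MISSING_BASE, IsoformCall, ReadAlignment

log = logging.getLogger(__name__)

UNDEFINED = "undefined"
UNPHASEABLE = "unphaseable"


@dataclass(frozen=True)
class AlleleAssignment:
    read_id: str
    label: str  # an allele label, "undefined" or "unphaseable"
    observations: tuple  # (marker, base, vote) per marker

    @property
    def defined(self) -> bool:
        return self.label not in (UNDEFINED, UNPHASEABLE)


def assign_allele(
    read: ReadAlignment, markers: Sequence[VariantMarker]
) -> AlleleAssignment:
    """Assign one read to an allele by marker-base voting (unanimity rule)."""
    if not markers:
        raise DataError("assign_allele requires at least one marker")
    votes: list[str] = []
    artifacts = 0
    observations = []
    for m in markers:
        base = read.marker_bases.get(m, MISSING_BASE)
        if base == MISSING_BASE:
            observations.append((m, base, "missing"))
            continue
        if base == m.ref_base:
            votes.append(m.allele_label_ref)
            observations.append((m, base, m.allele_label_ref))
        elif base == m.alt_base:
            votes.append(m.allele_label_alt)
            observations.append((m, base, m.allele_label_alt))
        else:
            artifacts += 1
            observations.append((m, base, "artifact"))
    if votes and len(set(votes)) == 1:
        label = votes[0]
    elif votes:  # conflicting markers
        label = UNDEFINED
    elif artifacts:
        label = UNDEFINED
    else:
        label = UNPHASEABLE
    return AlleleAssignment(
        read_id=read.read_id, label=label, observations=tuple(observations)
    )


def assign_alleles(
    reads: Iterable[ReadAlignment], markers: Sequence[VariantMarker]
) -> list[AlleleAssignment]:
    return [assign_allele(r, markers) for r in reads]


@dataclass
class AlleleSummary:
    """Read counts and percentages per allele, with per-allele isoform
    splits.  Percentages are computed over *defined* reads only; undefined
    and unphaseable counts are reported but excluded from denominators."""

    allele_counts: dict  # allele label -> count
    n_undefined: int
    n_unphaseable: int
    isoform_by_allele: dict  # allele -> {isoform_key: count}

    @property
    def n_defined(self) -> int:
        return sum(self.allele_counts.values())

    def percentage(self, allele: str) -> float:
        if self.n_defined == 0:
            raise DataError("no defined reads; allele percentages undefined")
        return 100.0 * self.allele_counts.get(allele, 0) / self.n_defined

    def within_allele_percentages(self, allele: str) -> dict:
        counts = self.isoform_by_allele.get(allele, {})
        total = sum(counts.values())
        if total == 0:
            return {}
        return {k: 100.0 * c / total for k, c in counts.items()}

    def wt_aberrant_split(self, allele: str) -> tuple[float, float]:
        """Within one allele, percentage of reads with normal vs aberrant
        splicing."""
        counts = self.isoform_by_allele.get(allele, {})
        total = sum(counts.values())
        if total == 0:
            raise DataError(f"no reads assigned to allele {allele!r}")
        wt = counts.get("canonical", 0)
        return 100.0 * wt / total, 100.0 * (total - wt) / total


def allele_summary(
    assignments: Sequence[AlleleAssignment],
    calls: Sequence[IsoformCall] = (),
) -> AlleleSummary:
    """Summarize allele subpopulations, optionally joined with isoform calls
    (by read id) for the per-allele WT/aberrant split."""
    allele_counts: Counter = Counter()
    n_undef = n_unphase = 0
    for a in assignments:
        if a.label == UNDEFINED:
            n_undef += 1
        elif a.label == UNPHASEABLE:
            n_unphase += 1
        else:
            allele_counts[a.label] += 1
    if not allele_counts:
        raise DataError("zero defined reads: no allele could be assigned")
    iso_by_allele: dict[str, Counter] = defaultdict(Counter)
    if calls:
        call_by_id = {c.read_id: c for c in calls}
        for a in assignments:
            if not a.defined:
                continue
            c = call_by_id.get(a.read_id)
            if c is not None:
                iso_by_allele[a.label][c.key] += 1
    return AlleleSummary(
        allele_counts=dict(allele_counts),
        n_undefined=n_undef,
        n_unphaseable=n_unphase,
        isoform_by_allele={k: dict(v) for k, v in iso_by_allele.items()},
    )


NEAR_ABSENT_FRACTION = 0.01  # qualitative flag threshold (not a study value)


@dataclass
class AlleleDepletion:
    allele: str
    count: int
    fraction: float
    p_value: float
    flag: str  # balanced | skewed | near_absent | absent


def detect_allelic_depletion(
    summary: AlleleSummary,
    expected: float = 0.5,
    alpha: float = 0.01,
    near_absent_fraction: float = NEAR_ABSENT_FRACTION,
) -> list[AlleleDepletion]:
    """Exact two-sided binomial test of each allele's fraction against the
    expected heterozygous balance, plus a qualitative flag.  A strongly
    depleted allele is the signature of transcript degradation (e.g. NMD) of
    that allele."""
    n = summary.n_defined
    if n < 1:
        raise DataError("depletion test requires at least one defined read")
    alleles = sorted(summary.allele_counts)
    if len(alleles) == 1:
        # the unseen partner allele is reported as absent
        seen = alleles[0]
        other = "allele2" if seen != "allele2" else "allele1"
        alleles.append(other)
    out = []
    for allele in alleles:
        k = summary.allele_counts.get(allele, 0)
        frac = k / n
        p = binomtest(k, n, expected, alternative="two-sided").pvalue
        if k == 0:
            flag = "absent"
        elif frac < near_absent_fraction:
            flag = "near_absent"
        elif p <= alpha:
            flag = "skewed"
        else:
            flag = "balanced"
        out.append(
            AlleleDepletion(
                allele=allele, count=k, fraction=frac, p_value=float(p), flag=flag
            )
        )
    return out
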