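"""End-to-end orchestration: filter -> classify -> quantify -> phase ->
insertion analysis, with tabular reports whose every percentage is
recomputable from counts carried alongside it.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .errors import ConfigError, DataError
from .insertion import (
    DEFAULT_MIN_SUPPORT,
    collect_insertion_reads,
    identify_element,
    score_donor_sites,
)
from .models_io import (
    Amplicon,
    load_element_library,
    load_markers,
    load_transcript_model,
)
from .phasing import allele_summary, assign_alleles, detect_allelic_depletion
from .splice import (
    DEFAULT_MIN_INSERTION_LEN,
    DEFAULT_RQ_THRESHOLD,
    DEFAULT_TOL,
    JunctionTable,
    build_junction_table,
    classify_reads,
    describe_isoform,
    filter_by_rq,
    load_reads,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    bam: str
    model: str
    model_format: str = "BED12"
    transcript_id: str | None = None
    first_exon: int = 1
    last_exon: int | None = None
    markers: str | None = None
    elements: str | None = None
    outdir: str | None = None
    rq_threshold: float = DEFAULT_RQ_THRESHOLD
    tol: int = DEFAULT_TOL
    min_insertion_len: int = DEFAULT_MIN_INSERTION_LEN
    min_support: int = DEFAULT_MIN_SUPPORT
    display_min_coverage: int = 0
    alpha: float = 0.01
    run_insertion: bool = True

    def validate(self) -> None:
        for p in (self.bam, self.model, self.markers, self.elements):
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input path does not exist: {p}")
        if not 0 <= self.rq_threshold <= 1:
            raise ConfigError("rq_threshold must be in [0,1]")
        if self.tol < 0 or self.min_insertion_len < 1:
            raise ConfigError("tol must be >= 0 and min_insertion_len >= 1")


@dataclass
class RunReport:
    """Machine-readable aggregate of the whole run; percentages always sit
    next to the counts they derive from."""

    counts: dict
    junctions: list
    isoforms: list
    alleles: dict | None
    insertions: list
    provenance: dict
    errors: list = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def _config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(asdict(config), sort_keys=True).encode()
    ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    """Run every stage on one sample; stage failures are recorded in the
    report's ``errors`` and a partial report is still returned/written."""
    config.validate()
    t0 = time.time()
    model = load_transcript_model(
        config.model, config.model_format, config.transcript_id
    )
    last = config.last_exon or model.n_exons
    amplicon = Amplicon(model=model, first_exon=config.first_exon, last_exon=last)
    markers = (
        load_markers(config.markers, amplicon) if config.markers else []
    )
    reads = load_reads(config.bam, markers)
    counts = {"input": len(reads)}
    errors: list[str] = []
    junction_rows: list = []
    isoform_rows: list = []
    allele_block = None
    insertion_rows: list = []

    flt = filter_by_rq(reads, config.rq_threshold)
    counts.update(
        rq_pass=flt.n_kept,
        rq_below=flt.n_below,
        rq_missing=flt.n_missing_rq,
    )
    if not flt.kept:
        errors.append("no reads after filtering")
    else:
        result = classify_reads(
            flt.kept, model, amplicon, config.tol, config.min_insertion_len
        )
        counts["classified"] = result.n_classified
        counts["rejected"] = dict(result.rejected)
        if result.calls:
            table = build_junction_table(
                result.calls, flt.kept, config.display_min_coverage
            )
            junction_rows = _junction_rows(table)
            isoform_rows = _isoform_rows(table, model)
            if markers:
                try:
                    assignments = assign_alleles(flt.kept, markers)
                    summary = allele_summary(assignments, result.calls)
                    depletion = detect_allelic_depletion(
                        summary, alpha=config.alpha
                    )
                    counts["phased_defined"] = summary.n_defined
                    counts["undefined"] = summary.n_undefined
                    counts["unphaseable"] = summary.n_unphaseable
                    allele_block = _allele_block(summary, depletion)
                except DataError as exc:
                    errors.append(f"phase: {exc}")
            if config.run_insertion:
                try:
                    insertion_rows = _insertion_rows(config, flt.kept)
                except DataError as exc:
                    errors.append(f"insertion: {exc}")
        else:
            errors.append("classify: no reads overlap the amplicon")

    report = RunReport(
        counts=counts,
        junctions=junction_rows,
        isoforms=isoform_rows,
        alleles=allele_block,
        insertions=insertion_rows,
        provenance={
            "package": "amplisplice",
            "version": __version__,
            "config_hash": _config_hash(config),
            "config": asdict(config),
            "elapsed_s": round(time.time() - t0, 3),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
        errors=errors,
    )
    if config.outdir:
        write_report_files(report, config.outdir)
    return report


def _junction_rows(table: JunctionTable) -> list:
    hidden = table.hidden
    rows = []
    for (s, e), count in sorted(table.junction_counts.items()):
        rows.append(
            {
                "junction_start": s + 1,  # 1-based inclusive intron bounds
                "junction_end": e,
                "count": count,
                "total_reads": table.total_reads,
                "percentage": round(table.percentage((s, e)), 4),
                "hidden_in_plots": (s, e) in hidden,
            }
        )
    return rows


def _isoform_rows(table: JunctionTable, model) -> list:
    rows = []
    for key, count in sorted(
        table.isoform_counts.items(), key=lambda kv: -kv[1]
    ):
        rows.append(
            {
                "isoform_key": key,
                "description": describe_isoform(
                    table.isoform_deviations[key], model
                ),
                "count": count,
                "total_reads": table.total_reads,
                "percentage": round(table.isoform_percentage(key), 4),
            }
        )
    return rows


def _allele_block(summary, depletion) -> dict:
    return {
        "defined": summary.n_defined,
        "undefined": summary.n_undefined,
        "unphaseable": summary.n_unphaseable,
        "alleles": {
            allele: {
                "count": count,
                "percentage": round(summary.percentage(allele), 4),
                "isoforms": summary.isoform_by_allele.get(allele, {}),
            }
            for allele, count in sorted(summary.allele_counts.items())
        },
        "depletion": [asdict(d) for d in depletion],
    }


def _insertion_rows(config: RunConfig, reads) -> list:
    events = collect_insertion_reads(
        reads,
        min_insertion_len=config.min_insertion_len,
        min_support=config.min_support,
    )
    library = (
        load_element_library(config.elements) if config.elements else None
    )
    rows = []
    for ev in events:
        consensus = ev.consensus()
        row = {
            "anchor": ev.anchor + 1,
            "supporting_reads": ev.supporting_reads,
            "length": ev.length_summary(),
            "consensus_length": len(consensus),
        }
        if library is not None:
            hit = identify_element(consensus, library)
            if hit is not None:
                row["best_hit"] = {
                    "element": hit.element,
                    "percent_identity": round(hit.percent_identity, 2),
                    "orientation": hit.orientation,
                    "element_span": [
                        hit.element_span[0] + 1,
                        hit.element_span[1],
                    ],
                    "score": hit.score,
                }
        donors = score_donor_sites(consensus, top_k=3)
        row["donor_candidates"] = [
            {"position": d.position + 1, "pwm_score": round(d.pwm_score, 2)}
            for d in donors
        ]
        rows.append(row)
    return rows


# ---------------------------------------------------------------------------
# report files and sashimi-style rendering


def write_report_files(report: RunReport, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report.to_json(outdir / "report.json")
    _write_tsv(
        outdir / "junctions.tsv",
        report.junctions,
        (
            "junction_start", "junction_end", "count", "total_reads",
            "percentage", "hidden_in_plots",
        ),
    )
    _write_tsv(
        outdir / "isoforms.tsv",
        report.isoforms,
        ("isoform_key", "description", "count", "total_reads", "percentage"),
    )
    if report.alleles:
        rows = [
            {
                "allele": allele,
                "count": blk["count"],
                "percentage": blk["percentage"],
            }
            for allele, blk in report.alleles["alleles"].items()
        ]
        _write_tsv(outdir / "alleles.tsv", rows, ("allele", "count", "percentage"))


def _write_tsv(path: Path, rows: list, columns: tuple) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")


def render_sashimi_counts(
    table: JunctionTable, min_coverage: int = 0, path: str | Path | None = None
) -> str:
    """Text rendering of junction arcs with their spanning-read counts;
    junctions below ``min_coverage`` are suppressed from the rendering but
    remain in the table.  With ``path`` ending in .svg/.png an arc plot is
    also written (requires matplotlib)."""
    if not table.junction_counts:
        raise DataError("empty junction table")
    lines = [f"# sashimi junction counts (total reads {table.total_reads})"]
    shown = []
    for (s, e), count in sorted(table.junction_counts.items()):
        if count < min_coverage:
            continue
        shown.append(((s, e), count))
        pct = table.percentage((s, e))
        lines.append(f"{s + 1}..{e}\tn={count}\t{pct:.2f}%")
    text = "\n".join(lines) + "\n"
    if path is not None:
        path = Path(path)
        if path.suffix in (".svg", ".png"):
            _plot_sashimi(shown, table.total_reads, path)
        else:
            path.write_text(text)
    return text


def _plot_sashimi(shown, total, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    fig, ax = plt.subplots(figsize=(10, 3))
    for (s, e), count in shown:
        x = np.linspace(s, e, 50)
        mid = (s + e) / 2
        h = 0.2 + 0.8 * count / max(c for _, c in shown)
        y = h * (1 - ((x - mid) / ((e - s) / 2)) ** 2)
        ax.plot(x, y, lw=1 + 2 * count / total * 10)
        ax.text(mid, h, str(count), ha="center", va="bottom", fontsize=7)
    ax.set_ylim(0, 1.4)
    ax.set_yticks([])
    ax.set_xlabel("genomic position")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
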