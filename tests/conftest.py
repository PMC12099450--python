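"""Shared fixtures: memoized preset runs and an independent local-alignment
dynamic-programming oracle."""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from amplisplice.phasing import allele_summary, assign_alleles
from amplisplice.splice import (
    build_junction_table,
    classify_reads,
    filter_by_rq,
    load_reads,
)
from amplisplice.synthetic import load_truth, preset, simulate_scenario


@dataclass
class PresetRun:
    cfg: object
    sim: object
    truth: object
    reads: list
    kept: list
    calls: list
    table: object

    def isoform_pct(self, key: str) -> float:
        return self.table.isoform_percentage(key)

    def allele_summary(self):
        asn = assign_alleles(self.kept, self.cfg.markers)
        return allele_summary(asn, self.calls)


@pytest.fixture(scope="session")
def run_preset(tmp_path_factory):
    """Memoized end-to-end preset execution (simulate -> filter -> classify
    -> tabulate); heavy runs are shared across tests."""
    cache: dict = {}

    def _run(name: str, n_reads: int, seed: int) -> PresetRun:
        key = (name, n_reads, seed)
        if key in cache:
            return cache[key]
        outdir = tmp_path_factory.mktemp(f"{name}_{n_reads}_{seed}")
        cfg = preset(name, n_reads=n_reads, seed=seed)
        sim = simulate_scenario(cfg, outdir)
        reads = load_reads(sim.bam, cfg.markers)
        kept = filter_by_rq(reads).kept
        result = classify_reads(kept, cfg.model, cfg.amplicon)
        table = build_junction_table(result.calls, kept)
        run = PresetRun(
            cfg=cfg,
            sim=sim,
            truth=load_truth(sim.truth),
            reads=reads,
            kept=kept,
            calls=result.calls,
            table=table,
        )
        cache[key] = run
        return run

    return _run


def gotoh_local_score(a: str, b: str, match=2.0, mismatch=-3.0,
                      gap_open=-5.0, gap_extend=-2.0) -> float:
    """Exhaustive affine-gap local alignment (Gotoh) in plain Python: the
    first base of a gap costs gap_open, each further base gap_extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    best = 0.0
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best
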