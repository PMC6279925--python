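#!/usr/bin/env python
"""Generate the two synthetic interference screens used by the downstream
analyses: screen A (3 replicates per condition) and screen B (2 replicates,
half the depth), sharing one vector library and one ground-truth effect
table, plus the screen's sample sheets. A small read-level dataset
(screen A at reduced depth, with sequencing errors) and the barcode->shRNA
assignment amplicons are emitted as FASTQ for the read-processing analysis.

Writes: results/library.tsv, results/effects.tsv, results/counts_{A,B}.tsv,
results/sheet_{A,B}.tsv, results/reads_demo.fastq, results/assignment.fastq
"""

import os

from pathscreen import (
    SimConfig,
    build_library,
    emit_assignment_reads,
    emit_screen_reads,
    make_sample_sheet,
    simulate_counts,
)
from pathscreen.simdata import effects_to_tsv

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 2018

def main() -> None:
    os.makedirs(OUT, exist_ok=True)

    # screen A: reference conditions (200 genes, 3 vs 3, 2e6 baseline reads)
    cfg_a = SimConfig(seed=SEED)
    lib, eff = build_library(cfg_a)
    counts_a = simulate_counts(lib, eff, cfg_a)
    # screen B: an independent biological repeat at half depth, 2 replicates
    cfg_b = SimConfig(depth=1_000_000, n_replicates=2, seed=SEED + 1)
    counts_b = simulate_counts(lib, eff, cfg_b)

    lib.to_tsv(f"{OUT}/library.tsv")
    effects_to_tsv(eff, f"{OUT}/effects.tsv")
    counts_a.to_tsv(f"{OUT}/counts_A.tsv")
    counts_b.to_tsv(f"{OUT}/counts_B.tsv")
    sheet_a = make_sample_sheet(counts_a.design, SEED)
    sheet_b = make_sample_sheet(counts_b.design, SEED + 1)
    sheet_a.to_csv(f"{OUT}/sheet_A.tsv", sep="\t", index=False)
    sheet_b.to_csv(f"{OUT}/sheet_B.tsv", sep="\t", index=False)

    # read-level demo at reduced depth so the FASTQ stays light
    cfg_demo = SimConfig(depth=20_000, n_replicates=2, error_rate=0.005, seed=SEED)
    counts_demo = simulate_counts(lib, eff, cfg_demo)
    counts_demo.to_tsv(f"{OUT}/counts_demo.tsv")
    sheet_demo = make_sample_sheet(counts_demo.design, SEED)
    sheet_demo.to_csv(f"{OUT}/sheet_demo.tsv", sep="\t", index=False)
    n = emit_screen_reads(counts_demo, lib, sheet_demo, cfg_demo, f"{OUT}/reads_demo.fastq")
    na = emit_assignment_reads(lib, 10, cfg_demo, f"{OUT}/assignment.fastq")

    n_pos = (eff.groupby("gene")["class"].first() == "positive_regulator").sum()
    n_neg = (eff.groupby("gene")["class"].first() == "negative_regulator").sum()
    print(f"library: {len(lib.vectors)} vectors / {len(lib.genes)} genes "
          f"({n_pos} positive, {n_neg} negative regulators planted)")
    print(f"screen A: {counts_a.counts.shape[1]} samples, column sums "
          f"{counts_a.counts.sum().min()}-{counts_a.counts.sum().max()}")
    print(f"screen B: {counts_b.counts.shape[1]} samples at half depth")
    print(f"read demo: {n} screen reads, {na} assignment reads (0.5% error rate)")

if __name__ == "__main__":
    main()
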