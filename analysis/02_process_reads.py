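#!/usr/bin/env python
"""Read-level processing of the demo screen from 01: demultiplex by sample
code, build the barcode->shRNA assignment dictionary from the amplicon run,
match barcodes and count. Reports read conservation at every stage and how
closely the recovered matrix tracks the simulated truth despite the 0.5%
per-base error rate.

Reads:  results/reads_demo.fastq, results/assignment.fastq,
        results/library.tsv, results/sheet_demo.tsv, results/counts_demo.tsv
Writes: results/assignment_table.tsv, results/counts_recovered.tsv,
        results/readproc_tally.json
"""

import json
import os

import numpy as np

from pathscreen.containers import read_matrix_tsv
from pathscreen.fastq import read_sequences
from pathscreen.readproc import SampleSheet, build_assignment, count_features, demultiplex
from pathscreen.simdata import LibraryDef

OUT = os.path.join(os.path.dirname(__file__), "..", "results")

def main() -> None:
    lib = LibraryDef.from_tsv(f"{OUT}/library.tsv")
    sheet = SampleSheet.from_tsv(f"{OUT}/sheet_demo.tsv")

    assignment, report = build_assignment(read_sequences(f"{OUT}/assignment.fastq"), lib)
    assignment.to_csv(f"{OUT}/assignment_table.tsv", sep="\t", index=False)
    print(f"assignment: {report['barcodes_assigned']}/{report['barcodes_observed']} barcodes assigned, "
          f"gene recovery {report['gene_recovery']:.1%}")

    per_sample, _, demux_tally = demultiplex(read_sequences(f"{OUT}/reads_demo.fastq"), sheet)
    assert demux_tally["assigned"] + demux_tally["unassigned"] == demux_tally["total"]
    print(f"demux: {demux_tally['assigned']}/{demux_tally['total']} reads assigned "
          f"({demux_tally['unassigned']} ambiguous/unmatched codes)")

    counts, tallies = count_features(per_sample, lib, sheet, level="shrna", assignment=assignment)
    counts.to_tsv(f"{OUT}/counts_recovered.tsv")
    counted = sum(t.get("counted", 0) for t in tallies.values())
    lost = {k: sum(t.get(k, 0) for t in tallies.values()) for k in ("unmatched", "ambiguous", "no_anchor")}
    print(f"count: {counted} reads counted at shRNA level; lost to {lost}")
    with open(f"{OUT}/readproc_tally.json", "w") as fh:
        json.dump({"demux": demux_tally, "count": tallies}, fh, indent=2, sort_keys=True)

    truth, _ = read_matrix_tsv(f"{OUT}/counts_demo.tsv")
    truth_shrna = truth.groupby(lib.vectors.set_index("vector_id")["shrna_id"]).sum()
    rec = counts.counts.reindex(index=truth_shrna.index, columns=truth_shrna.columns, fill_value=0)
    rel = np.abs(rec - truth_shrna).to_numpy().sum() / truth_shrna.to_numpy().sum()
    print(f"recovered counts deviate from truth by {rel:.2%} of total reads "
          f"(reads dropped by error tolerance, never misassigned)")

if __name__ == "__main__":
    main()
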