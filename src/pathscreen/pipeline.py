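"""End-to-end orchestration: reads -> counts -> rankings -> hits -> QC.

`analyze_screen` holds the statistical stage sequence so it can run
directly on a count matrix (simulated or loaded); `run_screen` and
`run_profiler` wrap it with read processing and write a reproducible
output bundle plus a JSON manifest. Outputs contain no timestamps, so a
rerun with the same inputs and seed is byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .containers import COND_BIC, COND_TTX, CountMatrix, write_matrix_tsv
from .cisprofiler import classify_kinetics, profile_timecourse, rank_dynamic_range
from .fastq import read_sequences
from .hitsenrich import call_hits, hypergeom_overlap
from .qc import correlation_matrix, hcluster, rank_concordance
from .quant import aggregate, collapse_replicates, log2fc_conditions, normalize_total
from .rankstats import NBWaldResult, collapse_to_gene, make_ranking, nb_wald
from .readproc import SampleSheet, build_assignment, count_features, demultiplex
from .simdata import LibraryDef


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class ScreenResult:
    counts_shrna: CountMatrix
    ranking: pd.DataFrame       # per-shRNA log2fc, enh_z, gene
    gene_table: pd.DataFrame    # strongest-effect gene scores
    diff: NBWaldResult          # NB-Wald table at shRNA level
    hits_z: tuple[list, list]
    hits_fdr: tuple[list, list]
    correlation: pd.DataFrame
    dendrogram: dict
    method_overlap: dict        # top-100 positive regulators, Z vs Wald


def analyze_screen(
    counts: CountMatrix,
    z_cut: float = 3.0,
    fdr_cut: float = 0.05,
    pseudocount: float = 0.5,
    mean_filter: float = 5.0,
    dispersion_mode: str = "pooled",
    top_k: int = 100,
) -> ScreenResult:
    """The statistical stage chain on barcode- or shRNA-level counts."""
    if counts.level == "barcode":
        counts_shrna = aggregate(counts, counts.features["shrna_id"].rename("shrna"), mode="sum", axis="rows")
    else:
        counts_shrna = counts

    norm = normalize_total(counts_shrna)
    corr = correlation_matrix(norm)
    dendro = hcluster(corr)

    collapsed = collapse_replicates(norm)
    bic_col = next((c for c in collapsed.values.columns if c.startswith(COND_BIC)), None)
    if bic_col is None:
        raise StageError("log2fc", "no stimulated (BIC) samples in design")
    lfc = log2fc_conditions(collapsed, bic_col, COND_TTX, pseudocount)
    ranking = make_ranking(lfc, counts_shrna.features["gene"])
    gene_table = collapse_to_gene(ranking)

    diff = nb_wald(counts_shrna, COND_TTX, COND_BIC, dispersion_mode, mean_filter)

    hits_z = call_hits(gene_table, mode="z", z_cut=z_cut)
    hits_fdr = call_hits(diff.table, mode="fdr", fdr_cut=fdr_cut)

    # cross-method concordance: gene-level Wald score by the same
    # strongest-effect rule, then top-k positive-regulator overlap
    wald_gene = diff.table["wald_stat"].groupby(counts_shrna.features["gene"]).min()
    conc = rank_concordance(gene_table["pos_score"], wald_gene, top_k=(top_k,))
    k = conc["top_overlap"][top_k]
    universe = int(counts_shrna.features["gene"].nunique())
    _, p = hypergeom_overlap(
        list(gene_table["pos_score"].nsmallest(top_k).index),
        list(wald_gene.nsmallest(top_k).index),
        universe,
    )
    overlap = {"rho": conc["rho"], "top_k": top_k, "overlap": k, "universe": universe, "p": p}

    return ScreenResult(counts_shrna, ranking, gene_table, diff, hits_z, hits_fdr, corr, dendro, overlap)


def run_screen(
    reads_fastq: str,
    sheet: SampleSheet,
    library: LibraryDef,
    out_dir: str,
    assignment_fastq: str | None = None,
    seed: int = 0,
    max_code_mm: int = 1,
    max_edit: int = 2,
    min_reads: int = 3,
    min_purity: float = 0.8,
    **analysis_kw,
) -> ScreenResult:
    """Full screen run from FASTQ to hit lists; writes the output bundle."""
    os.makedirs(out_dir, exist_ok=True)

    reads = read_sequences(reads_fastq)
    per_sample, _unassigned, demux_tally = demultiplex(reads, sheet, max_code_mm)
    if demux_tally["total"] == 0:
        raise StageError("demux", f"no reads in {reads_fastq}")

    assignment = None
    assign_report: dict = {}
    if assignment_fastq is not None:
        assignment, assign_report = build_assignment(
            read_sequences(assignment_fastq), library, min_reads, min_purity
        )
        assignment.to_csv(os.path.join(out_dir, "assignment.tsv"), sep="\t", index=False)

    counts, count_tallies = count_features(per_sample, library, sheet, level="barcode", max_edit=max_edit)
    counts.to_tsv(os.path.join(out_dir, "counts_barcode.tsv"))

    res = analyze_screen(counts, **analysis_kw)

    res.counts_shrna.to_tsv(os.path.join(out_dir, "counts_shrna.tsv"))
    res.ranking.to_csv(os.path.join(out_dir, "ranking.tsv"), sep="\t")
    res.gene_table.to_csv(os.path.join(out_dir, "gene_table.tsv"), sep="\t")
    diff = res.diff.table.copy()
    diff.insert(0, "gene", res.counts_shrna.features["gene"])
    diff.to_csv(os.path.join(out_dir, "diff.tsv"), sep="\t", index_label="shrna_id")
    res.correlation.to_csv(os.path.join(out_dir, "correlation.tsv"), sep="\t")
    for name, lists in (("z", res.hits_z), ("fdr", res.hits_fdr)):
        pd.Series(lists[0], name="gene" if name == "z" else "shrna_id").to_csv(
            os.path.join(out_dir, f"hits_{name}_positive.tsv"), sep="\t", index=False)
        pd.Series(lists[1], name="gene" if name == "z" else "shrna_id").to_csv(
            os.path.join(out_dir, f"hits_{name}_negative.tsv"), sep="\t", index=False)

    manifest = {
        "tool": "pathscreen",
        "version": __version__,
        "mode": "screen",
        "seed": seed,
        "parameters": {
            "max_code_mm": max_code_mm, "max_edit": max_edit,
            "min_reads": min_reads, "min_purity": min_purity, **analysis_kw,
        },
        "tallies": {"demux": demux_tally, "count": count_tallies, "assignment": assign_report},
        "qc": {"dendrogram": res.dendrogram, "method_overlap": res.method_overlap},
        "outputs": sorted(f for f in os.listdir(out_dir) if f != "manifest.json"),
    }
    _write_manifest(os.path.join(out_dir, "manifest.json"), manifest)
    return res


def run_profiler(
    reads_fastq: str,
    sheet: SampleSheet,
    library: LibraryDef,
    out_dir: str,
    seed: int = 0,
    max_code_mm: int = 1,
    max_edit: int = 2,
    pseudocount: float = 0.5,
    induced_threshold: float = 1.0,
    decay_fraction: float = 0.5,
) -> pd.DataFrame:
    """Full profiling run from FASTQ to the ranked sensor table."""
    os.makedirs(out_dir, exist_ok=True)
    reads = read_sequences(reads_fastq)
    per_sample, _un, demux_tally = demultiplex(reads, sheet, max_code_mm)
    if demux_tally["total"] == 0:
        raise StageError("demux", f"no reads in {reads_fastq}")
    counts, count_tallies = count_features(per_sample, library, sheet, level="barcode", max_edit=max_edit)
    counts.to_tsv(os.path.join(out_dir, "counts_barcode.tsv"))

    profile, mw_stats = profile_timecourse(counts, pseudocount)
    ranked = rank_dynamic_range(profile)
    ranked["kinetics"] = classify_kinetics(profile, induced_threshold, decay_fraction)
    ranked.to_csv(os.path.join(out_dir, "profile.tsv"), sep="\t")
    mw_stats.to_csv(os.path.join(out_dir, "profile_stats.tsv"), sep="\t", index=False)

    manifest = {
        "tool": "pathscreen",
        "version": __version__,
        "mode": "profiler",
        "seed": seed,
        "parameters": {
            "max_code_mm": max_code_mm, "max_edit": max_edit, "pseudocount": pseudocount,
            "induced_threshold": induced_threshold, "decay_fraction": decay_fraction,
        },
        "tallies": {"demux": demux_tally, "count": count_tallies},
        "outputs": sorted(f for f in os.listdir(out_dir) if f != "manifest.json"),
    }
    _write_manifest(os.path.join(out_dir, "manifest.json"), manifest)
    return ranked


def _write_manifest(path: str, manifest: dict) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
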