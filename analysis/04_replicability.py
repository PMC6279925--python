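#!/usr/bin/env python
"""Replicability and concordance: within-screen replicate correlations with
hierarchical clustering, cross-screen gene-rank correlation, top-100 hit
overlaps with hypergeometric tests (within the simulated universe and,
analytically, at the published list sizes against the 4,400-gene library
universe), and gene-set over-representation of the top positive regulators
on ground-truth-derived gene sets.

Reads:  results/counts_{A,B}.tsv, results/genes_{A,B}.tsv, results/effects.tsv
Writes: results/correlation_{A,B}.tsv, results/concordance.json,
        results/ora.tsv
"""

import json
import math
import os

import pandas as pd

from pathscreen.containers import CountMatrix, read_matrix_tsv
from pathscreen.hitsenrich import hypergeom_logsf_ge, hypergeom_overlap, ora
from pathscreen.qc import correlation_matrix, first_merges_within_condition, hcluster, rank_concordance
from pathscreen.quant import normalize_total
from pathscreen.readproc import SampleSheet
from pathscreen.simdata import LibraryDef, effects_from_tsv

OUT = os.path.join(os.path.dirname(__file__), "..", "results")

def main() -> None:
    lib = LibraryDef.from_tsv(f"{OUT}/library.tsv")
    eff = effects_from_tsv(f"{OUT}/effects.tsv")
    out = {}

    for tag in ("A", "B"):
        df, _ = read_matrix_tsv(f"{OUT}/counts_{tag}.tsv")
        design = SampleSheet.from_tsv(f"{OUT}/sheet_{tag}.tsv").design()
        cm = CountMatrix(df.astype(int), design, lib.feature_table().loc[df.index])
        corr = correlation_matrix(normalize_total(cm))
        corr.to_csv(f"{OUT}/correlation_{tag}.tsv", sep="\t")
        within = min(
            corr.loc[reps, reps].to_numpy()[0, 1]
            for reps in (cm.samples_for("TTX"), cm.samples_for("BIC"))
        )
        clustered = first_merges_within_condition(hcluster(corr), design)
        out[f"screen_{tag}_min_within_condition_pearson"] = round(float(within), 4)
        out[f"screen_{tag}_replicates_cluster_by_condition"] = bool(clustered)
        print(f"screen {tag}: within-condition Pearson >= {within:.3f}; "
              f"replicates cluster by condition: {clustered}")

    genes_a = pd.read_csv(f"{OUT}/genes_A.tsv", sep="\t", index_col="gene")
    genes_b = pd.read_csv(f"{OUT}/genes_B.tsv", sep="\t", index_col="gene")
    conc = rank_concordance(genes_a["pos_score"], genes_b["pos_score"])
    k = conc["top_overlap"][100]
    universe = conc["n_shared"]
    _, p = hypergeom_overlap(
        list(genes_a["pos_score"].nsmallest(100).index),
        list(genes_b["pos_score"].nsmallest(100).index),
        universe,
    )
    out["crossscreen_rho"] = round(conc["rho"], 4)
    out["crossscreen_top100_overlap"] = k
    out["crossscreen_top100_p"] = p
    print(f"cross-screen gene-rank rho {conc['rho']:.3f}; top-100 overlap {k}/100 "
          f"(p = {p:.2e}, hypergeometric, universe {universe})")

    # analytic: the published overlaps at the library's 4,400-gene universe
    for name, kk, bound in [("crossmethod_54", 54, 1e-10), ("crossscreen_z_45", 45, 1e-10),
                            ("crossscreen_wald_55", 55, 1e-10), ("negative_15", 15, 1e-8)]:
        pp = math.exp(hypergeom_logsf_ge(kk, 4400, 100, 100))
        out[f"published_overlap_p_{name}"] = pp
        print(f"published top-100 overlap {kk}/100 at universe 4400: p = {pp:.2e} (< {bound:g})")

    # over-representation of the top-50 positive regulators against sets
    # derived from the planted truth (signal set + decoys)
    gene_class = eff.groupby("gene")["class"].first()
    sets = {
        "planted_positive_regulators": list(gene_class.index[gene_class == "positive_regulator"]),
        "planted_negative_regulators": list(gene_class.index[gene_class == "negative_regulator"]),
        "random_nulls": list(gene_class.index[gene_class == "null"][:30]),
    }
    hits = list(genes_a["pos_score"].nsmallest(50).index)
    res = ora(hits, sets, list(gene_class.index))
    res.to_csv(f"{OUT}/ora.tsv", sep="\t")
    print("ORA of top-50 positive regulators:")
    print(res.to_string())

    with open(f"{OUT}/concordance.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)

if __name__ == "__main__":
    main()
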