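#!/usr/bin/env python
"""Sensor profiling: simulate the ~70-reporter panel (three barcode
replicates per sensor, promoter-only calibrators, duplicates of untreated
reference, TTX silencing, and BIC stimulation at 2/4/8 h), apply the fixed
normalization chain, rank sensors by dynamic range, classify response
kinetics, and demonstrate knockdown-profile normalization to a
non-targeting control.

Writes: results/profile.tsv, results/profile_stats.tsv,
        results/knockdown_profiles.tsv
"""

import os

import numpy as np
import pandas as pd

from pathscreen import SimConfig, default_panel, simulate_cisprofiler
from pathscreen.cisprofiler import (
    classify_kinetics,
    normalize_to_control,
    profile_timecourse,
    rank_dynamic_range,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results")
SEED = 2018

def main() -> None:
    os.makedirs(OUT, exist_ok=True)
    cfg = SimConfig(depth=1_000_000, seed=SEED)
    panel = default_panel(70, n_calibrators=3, seed=SEED)
    _lib, counts = simulate_cisprofiler(cfg, panel)

    profile, stats = profile_timecourse(counts)
    ranked = rank_dynamic_range(profile)
    ranked["kinetics"] = classify_kinetics(profile)
    ranked.to_csv(f"{OUT}/profile.tsv", sep="\t")
    stats.to_csv(f"{OUT}/profile_stats.tsv", sep="\t", index=False)

    top = ranked.index[0]
    print(f"top sensor by dynamic range (BIC 4h - TTX): {top} "
          f"({ranked['dynamic_range'].iloc[0]:.2f} log2 = "
          f"{2 ** ranked['dynamic_range'].iloc[0]:.0f}-fold)")
    print(ranked.head(8).round(2).to_string())
    print("kinetic classes:", ranked["kinetics"].value_counts().to_dict())
    n_sig = (stats.loc[stats["condition"] == "BIC4h", "padj"] < 0.05).sum()
    print(f"sensors with BIC-4h response at FDR<0.05: {n_sig}/{len(ranked)}")

    # knockdown profiling demo: three perturbations scale the activity
    # sensors' responses (graded suppression), profiles shown relative to
    # the non-targeting control
    rng = np.random.default_rng(SEED)
    responsive = profile["BIC4h"].clip(lower=0.0)
    profiles = pd.DataFrame({
        "shNTC": profile["BIC4h"],
        "shStrong": profile["BIC4h"] - 0.8 * responsive + rng.normal(0, 0.05, len(profile)),
        "shMid": profile["BIC4h"] - 0.4 * responsive + rng.normal(0, 0.05, len(profile)),
        "shWeak": profile["BIC4h"] - 0.15 * responsive + rng.normal(0, 0.05, len(profile)),
    })
    rel = normalize_to_control(profiles, "shNTC")
    rel.to_csv(f"{OUT}/knockdown_profiles.tsv", sep="\t")
    means = rel.loc[responsive > 1.0].mean().round(2)
    print("mean suppression of responsive sensors vs control (log2):",
          means.drop("shNTC").to_dict())

if __name__ == "__main__":
    main()
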