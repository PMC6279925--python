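"""Multiplexed sensor profiling.

Turns a panel count matrix (sensors x {untreated reference, TTX, BIC
2/4/8 h} in replicates, three barcode replicates per sensor, promoter-only
calibrators) into per-sensor log2 fold-change time courses, ranks sensors
by dynamic range, classifies response kinetics, and normalizes knockdown
profiles to a non-targeting control.

The fixed profiling chain is: total-read normalization -> calibrator
normalization -> mean over barcode replicates -> mean over sample
replicates -> log2 versus the untreated reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import COND_BIC, COND_REF, COND_TTX, CountMatrix, NormMatrix
from .quant import aggregate, collapse_replicates, log2fc, normalize_calibrator, normalize_total
from .rankstats import mannwhitney_fdr

BIC_COLS = ["BIC2h", "BIC4h", "BIC8h"]


def profile_timecourse(
    counts: CountMatrix,
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the profiling chain; returns (profile, stats).

    profile: sensor x condition log2 fold changes relative to the untreated
    reference. stats: per sensor and BIC timepoint, the Mann-Whitney p
    (TTX vs BIC observations, one observation per barcode replicate and
    sample) with BH adjustment across sensors per timepoint.
    """
    ref_samples = counts.samples_for(COND_REF)
    if not ref_samples:
        raise ValueError("profiling requires untreated reference samples")

    tn = normalize_total(counts)
    cal_rows = counts.features.index[counts.features["is_calibrator"]]
    cal_mean = tn.values.loc[cal_rows].mean(axis=0)
    norm = normalize_calibrator(tn)

    # `pseudocount` is in reads; translate it onto the calibrator-normalized
    # scale (median over samples of what one read maps to) so it protects
    # zeros without compressing fold changes.
    totals = counts.counts.sum(axis=0)
    one_read = (1e6 / totals) / cal_mean
    p_scaled = float(pseudocount * np.median(one_read))
    sensor_of = counts.features["gene"]
    by_sensor = aggregate(norm, sensor_of.rename("sensor"), mode="mean", axis="rows")
    collapsed = collapse_replicates(by_sensor)

    conds = [c for c in [COND_TTX] + BIC_COLS if c in collapsed.values.columns]
    profile = pd.DataFrame(
        {c: log2fc(collapsed.values[c], collapsed.values[COND_REF], p_scaled) for c in conds}
    )
    profile.index.name = "sensor"

    # per-sensor TTX vs BIC test at each timepoint; one observation per
    # barcode replicate and sample, as that barcode's log2 fold change over
    # its own reference mean (removes the per-barcode abundance component)
    ref_mean = norm.values[ref_samples].mean(axis=1)
    per_bc = np.log2(norm.values.add(p_scaled)).sub(np.log2(ref_mean + p_scaled), axis=0)
    sensors = list(profile.index)
    stats_rows = []
    ttx_samples = counts.samples_for(COND_TTX)
    for tp, col in zip((2.0, 4.0, 8.0), BIC_COLS):
        bic_samples = counts.samples_for(COND_BIC, tp)
        if not bic_samples or not ttx_samples:
            continue
        ga, gb = [], []
        for s in sensors:
            rows = sensor_of.index[sensor_of == s]
            ga.append(per_bc.loc[rows, ttx_samples].to_numpy().ravel())
            gb.append(per_bc.loc[rows, bic_samples].to_numpy().ravel())
        p, padj = mannwhitney_fdr(ga, gb)
        for s, pv, pa in zip(sensors, p, padj):
            stats_rows.append((s, col, pv, pa))
    stats = pd.DataFrame(stats_rows, columns=["sensor", "condition", "p", "padj"])
    return profile, stats


def rank_dynamic_range(profile: pd.DataFrame) -> pd.DataFrame:
    """Sensors ordered by dynamic range = FC(BIC 4h) - FC(TTX), descending;
    ties broken by sensor id."""
    for col in ("BIC4h", COND_TTX):
        if col not in profile.columns:
            raise ValueError(f"profile lacks column {col!r}")
    out = profile.copy()
    out["dynamic_range"] = out["BIC4h"] - out[COND_TTX]
    out = out.sort_index()  # tie-break: sensor id (stable sort below keeps it)
    return out.sort_values("dynamic_range", ascending=False, kind="mergesort")


def classify_kinetics(
    profile: pd.DataFrame,
    induced_threshold: float = 1.0,
    decay_fraction: float = 0.5,
    tolerance: float = 0.1,
) -> pd.Series:
    """Kinetic class per sensor from its BIC 2/4/8 h fold changes.

    nonresponsive: peak FC below the induction threshold (log2 units);
    amplified: still rising at 8 h (FC8 > FC4 >= FC2 - tolerance);
    transient: decayed below decay_fraction * peak by 8 h;
    sustained: everything else. Classes are exhaustive and exclusive.
    """
    for col in BIC_COLS:
        if col not in profile.columns:
            raise ValueError(f"profile lacks column {col!r}")
    out = {}
    for sensor, row in profile.iterrows():
        fc2, fc4, fc8 = (float(row[c]) for c in BIC_COLS)
        peak = max(fc2, fc4, fc8)
        if peak < induced_threshold:
            out[sensor] = "nonresponsive"
        elif fc8 > fc4 >= fc2 - tolerance:
            out[sensor] = "amplified"
        elif fc8 < decay_fraction * peak:
            out[sensor] = "transient"
        else:
            out[sensor] = "sustained"
    return pd.Series(out, name="kinetics").rename_axis("sensor")


def normalize_to_control(profiles: pd.DataFrame, control_id: str = "shNTC") -> pd.DataFrame:
    """Subtract the non-targeting control column from every perturbation
    column (log2 scale); the control column becomes zero."""
    if control_id not in profiles.columns:
        raise ValueError(f"control perturbation {control_id!r} missing")
    return profiles.sub(profiles[control_id], axis=0)
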