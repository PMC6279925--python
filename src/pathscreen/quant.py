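"""Normalization and aggregation chains.

Two fixed chains are supported, mirroring how barcode counts are turned
into activities:

* screen chain: counts -> sum barcodes per shRNA -> total-read
  normalization (counts per million) -> mean over replicates ->
  log2(BIC/TTX),
* profiling chain: total-read normalization -> calibrator normalization
  (divide by the mean of the promoter-only control rows) -> mean over
  barcode replicates -> mean over sample replicates -> log2 vs the
  untreated reference.

Each operation records itself in the matrix provenance; operations that
only make sense at a specific point in a chain check the provenance of
their input.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import CountMatrix, NormMatrix

TAG_TOTAL = "total_norm"
TAG_CALIB = "calibrator_norm"


def normalize_total(counts: CountMatrix | NormMatrix, scale: float = 1e6) -> NormMatrix:
    """Scale each column to sum to `scale` (reads per million by default)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts.values
    sums = df.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"zero column sum for sample(s): {list(zero.index)}")
    values = df / sums * scale
    prov = ("counts",) if isinstance(counts, CountMatrix) else counts.provenance
    return NormMatrix(values, counts.design, counts.features, counts.level, prov + (TAG_TOTAL,))


def normalize_calibrator(norm: NormMatrix, calibrator_ids: list[str] | None = None) -> NormMatrix:
    """Divide each column by the mean over its calibrator rows.

    Input must already be total-read normalized. After this step the mean
    over calibrator rows is 1 in every column.
    """
    if TAG_TOTAL not in norm.provenance:
        raise ValueError("calibrator normalization requires total-read-normalized input")
    if calibrator_ids is None:
        calibrator_ids = list(norm.features.index[norm.features["is_calibrator"]])
    if not calibrator_ids:
        raise ValueError("no calibrator rows")
    cal = norm.values.loc[calibrator_ids].mean(axis=0)
    bad = cal[cal <= 0]
    if len(bad):
        raise ValueError(f"calibrator mean is zero for sample(s): {list(bad.index)}")
    return norm.with_values(norm.values / cal, TAG_CALIB)


def aggregate(
    matrix: CountMatrix | NormMatrix,
    grouping: pd.Series | dict,
    mode: str = "sum",
    axis: str = "rows",
) -> CountMatrix | NormMatrix:
    """Reduce groups of rows (features) or columns (samples) by sum or mean.

    `grouping` maps every row (or column) id to its group key; a feature
    mapped to two groups is impossible by construction of a mapping, but a
    missing key is an error. Output ordering is deterministic (sorted by
    group key).
    """
    if mode not in ("sum", "mean"):
        raise ValueError("mode must be 'sum' or 'mean'")
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    grouping = pd.Series(grouping)
    df = matrix.counts if isinstance(matrix, CountMatrix) else matrix.values
    ids = df.index if axis == "rows" else df.columns
    missing = [i for i in ids if i not in grouping.index]
    if missing:
        raise ValueError(f"grouping does not cover: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    keys = grouping.loc[ids]

    if axis == "rows":
        out = df.groupby(keys.to_numpy()).agg(mode)
        out = out.sort_index()
        out.index.name = "feature"
    else:
        out = df.T.groupby(keys.to_numpy()).agg(mode).T
        out = out[sorted(out.columns)]

    tag = f"{mode}:{axis}"
    if isinstance(matrix, CountMatrix):
        if mode == "mean":
            raise ValueError("mean aggregation of raw counts is not part of any chain; normalize first")
        if axis == "columns":
            raise ValueError("column aggregation of raw counts is not part of any chain")
        feats = _regroup_features(matrix.features, keys)
        return CountMatrix(out.astype(np.int64), matrix.design, feats, level="shrna")

    if axis == "rows":
        feats = _regroup_features(matrix.features, keys)
        new_level = str(keys.name) if keys.name else matrix.level
        return NormMatrix(out, matrix.design, feats, new_level, matrix.provenance + (tag,))
    # column aggregation: design collapses to one row per group
    design = matrix.design.loc[list(df.columns)].copy()
    design["__group"] = keys.to_numpy()
    new_design = design.groupby("__group").first()
    new_design.index.name = "sample_id"
    return NormMatrix(out, new_design, matrix.features, matrix.level, matrix.provenance + (tag,))


def _regroup_features(features: pd.DataFrame, keys: pd.Series) -> pd.DataFrame:
    f = features.loc[keys.index].copy()
    f["__group"] = keys.to_numpy()
    out = f.groupby("__group").first()
    out.index.name = "feature"
    return out


def collapse_replicates(norm: NormMatrix) -> NormMatrix:
    """Mean of normalized counts over replicate samples of the same
    (condition, timepoint) group."""
    d = norm.design.loc[norm.values.columns]
    labels = [
        c if pd.isna(t) else f"{c}{int(t) if float(t).is_integer() else t}h"
        for c, t in zip(d["condition"], d["timepoint"])
    ]
    return aggregate(norm, pd.Series(labels, index=norm.values.columns), mode="mean", axis="columns")


def log2fc(stimulated: pd.Series | np.ndarray, reference: pd.Series | np.ndarray, pseudocount: float = 0.5) -> pd.Series | np.ndarray:
    """log2((s + p) / (r + p)) per feature; finite for all inputs >= 0."""
    s = np.asarray(stimulated, dtype=float)
    r = np.asarray(reference, dtype=float)
    if (s < 0).any() or (r < 0).any():
        raise ValueError("log2fc inputs must be non-negative")
    out = np.log2(s + pseudocount) - np.log2(r + pseudocount)
    if isinstance(stimulated, pd.Series):
        return pd.Series(out, index=stimulated.index, name="log2fc")
    return out


def log2fc_conditions(
    collapsed: NormMatrix,
    stimulated: str,
    reference: str,
    pseudocount: float = 0.5,
) -> pd.Series:
    """Per-feature log2 ratio between two collapsed condition columns.

    Requires replicate-collapsed input (enforced via provenance)."""
    if "mean:columns" not in collapsed.provenance:
        raise ValueError("log2fc requires replicate-collapsed input (mean over samples)")
    for c in (stimulated, reference):
        if c not in collapsed.values.columns:
            raise ValueError(f"condition column {c!r} not present")
    return log2fc(collapsed.values[stimulated], collapsed.values[reference], pseudocount)
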