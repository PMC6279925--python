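"""Replicate-quality and cross-screen concordance diagnostics."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .containers import NormMatrix


def correlation_matrix(
    norm: NormMatrix | pd.DataFrame,
    method: str = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Pairwise sample-sample correlation (Pearson on log2(x+1) by default,
    or Spearman). Symmetric with unit diagonal."""
    df = norm.values if isinstance(norm, NormMatrix) else norm
    if df.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    x = df.to_numpy(dtype=float)
    if method == "pearson" and log_transform:
        x = np.log2(x + 1.0)
    flat = x.std(axis=0) == 0
    if flat.any():
        raise ValueError(f"zero-variance sample(s): {list(df.columns[flat])}")
    if method == "pearson":
        corr = np.corrcoef(x, rowvar=False)
    elif method == "spearman":
        rho = stats.spearmanr(x, axis=0).statistic
        if np.ndim(rho) == 0:  # scipy collapses the 2-sample case to a scalar
            corr = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        else:
            corr = np.asarray(rho)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=df.columns, columns=df.columns)


def hcluster(corr: pd.DataFrame) -> dict:
    """Average-linkage agglomerative clustering on distance 1 - rho.

    Samples are pre-sorted by id so tie-breaking never depends on input
    order. Returns a JSON-friendly dendrogram: leaf names plus a merge list
    of (node_i, node_j, distance, size) rows, scipy linkage convention.
    """
    order = sorted(corr.index)
    c = corr.loc[order, order].to_numpy(dtype=float)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)  # symmetrize against float noise
    z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    return {
        "leaves": order,
        "merges": [[int(a), int(b), float(d), int(n)] for a, b, d, n in z],
    }


def first_merges_within_condition(dendrogram: dict, design: pd.DataFrame) -> bool:
    """True if every merge of two leaves joins samples of one condition."""
    leaves = dendrogram["leaves"]
    n = len(leaves)
    for a, b, _d, _n in dendrogram["merges"]:
        if a < n and b < n:
            if design.loc[leaves[a], "condition"] != design.loc[leaves[b], "condition"]:
                return False
    return True


def auroc(scores: np.ndarray | pd.Series, labels: np.ndarray | pd.Series) -> float:
    """Area under the ROC curve: P(score of a positive > score of a
    negative), ties counted half. Rank-based (Mann-Whitney) computation."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need both positive and negative labels")
    r = stats.rankdata(s)
    return float((r[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def rank_concordance(
    ranking_a: pd.Series,
    ranking_b: pd.Series,
    top_k: tuple[int, ...] = (100,),
) -> dict:
    """Spearman rho between two score vectors over their shared universe,
    plus top-k overlap counts (top = most negative score, the
    positive-regulator direction)."""
    shared = ranking_a.index.intersection(ranking_b.index)
    if len(shared) == 0:
        raise ValueError("no shared features between rankings")
    a = ranking_a.loc[shared]
    b = ranking_b.loc[shared]
    rho = float(stats.spearmanr(a, b).statistic) if len(shared) > 1 else 1.0
    overlaps = {}
    for k in top_k:
        ta = set(a.nsmallest(k).index)
        tb = set(b.nsmallest(k).index)
        overlaps[int(k)] = len(ta & tb)
    return {"rho": rho, "n_shared": int(len(shared)), "top_overlap": overlaps}
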