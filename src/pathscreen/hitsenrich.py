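"""Hit calling, replicability overlap tests, and gene-set
over-representation.

Hit direction convention: negative enhanced Z / negative log2FC means
knockdown lowered stimulated activity, i.e. the gene is a candidate
positive regulator of the pathway.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp


def call_hits(
    table: pd.DataFrame,
    mode: str | None = None,
    z_cut: float = 3.0,
    fdr_cut: float = 0.05,
) -> tuple[list, list]:
    """Split a score table into (positive-regulator, negative-regulator)
    hit lists.

    Z-mode (gene table with pos_score/neg_score): pos hits have
    pos_score <= -z_cut, neg hits neg_score >= +z_cut, boundary inclusive.
    FDR-mode (differential table with p-adj/log2FC): p-adj < fdr_cut split
    by log2FC sign; NA adjusted p is never a hit.
    """
    has_z = {"pos_score", "neg_score"} <= set(table.columns)
    has_fdr = {"p-adj", "log2FC"} <= set(table.columns)
    if mode is None:
        if has_z == has_fdr:
            raise ValueError("ambiguous table: pass mode='z' or mode='fdr'")
        mode = "z" if has_z else "fdr"
    if mode == "z":
        if not has_z:
            raise ValueError("Z-mode needs pos_score/neg_score columns")
        pos = table.index[table["pos_score"] <= -z_cut]
        neg = table.index[table["neg_score"] >= z_cut]
        pos = table.loc[pos].sort_values("pos_score").index
        neg = table.loc[neg].sort_values("neg_score", ascending=False).index
        return list(pos), list(neg)
    if mode == "fdr":
        if not has_fdr:
            raise ValueError("FDR-mode needs p-adj/log2FC columns")
        sig = table["p-adj"].notna() & (table["p-adj"] < fdr_cut)
        pos = table.index[sig & (table["log2FC"] < 0)]
        neg = table.index[sig & (table["log2FC"] > 0)]
        pos = table.loc[pos].sort_values("p-adj").index
        neg = table.loc[neg].sort_values("p-adj").index
        return list(pos), list(neg)
    raise ValueError("mode must be 'z' or 'fdr'")


def hypergeom_logsf_ge(k: int, N: int, K: int, n: int) -> float:
    """log P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    if k <= 0:
        return 0.0
    kmax = min(K, n)
    if k > kmax:
        return -np.inf
    ks = np.arange(k, kmax + 1)
    return float(logsumexp(stats.hypergeom.logpmf(ks, N, K, n)))


def hypergeom_overlap(list_a, list_b, universe_size: int) -> tuple[int, float]:
    """Overlap count k and the exact upper-tail probability P(X >= k) that
    two lists of the observed sizes drawn from a universe of
    `universe_size` share at least k members."""
    a, b = set(list_a), set(list_b)
    k = len(a & b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("list larger than universe")
    if universe_size < len(a) + len(b) - k:
        raise ValueError("universe smaller than the union of the lists")
    logp = hypergeom_logsf_ge(k, universe_size, len(a), len(b))
    return k, float(min(np.exp(logp), 1.0))


def read_gmt(path: str) -> dict[str, list[str]]:
    """GMT gene sets: one set per line, 'name <tab> description <tab> genes...'."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path: str, sets: dict[str, list[str]]) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, ""] + list(genes)) + "\n")


def ora(
    hits,
    gene_sets: dict[str, list[str]],
    universe,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each gene set in the hit list.

    Symbols are harmonized case-insensitively; each set is restricted to
    the universe before testing; sets disjoint from the universe are
    reported with NA statistics. BH adjustment across the tested sets.
    """
    uni = {str(g).upper() for g in universe}
    hit = {str(g).upper() for g in hits} & uni
    rows = []
    for name, genes in gene_sets.items():
        members = {str(g).upper() for g in genes} & uni
        if not members:
            rows.append((name, 0, 0, np.nan))
            continue
        k = len(members & hit)
        logp = hypergeom_logsf_ge(k, len(uni), len(members), len(hit))
        rows.append((name, len(members), k, float(min(np.exp(logp), 1.0))))
    from .rankstats import bh_adjust

    out = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"]).set_index("set")
    tested = out["p"].notna().to_numpy()
    out["padj"] = bh_adjust(out["p"].fillna(0.0).to_numpy(), filter_mask=tested)
    return out.sort_values("p")
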