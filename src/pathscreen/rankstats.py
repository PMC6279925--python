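"""Hit-ranking statistics.

Two independent rankings of the same screen:

* enhanced Z-score: the per-shRNA log2(BIC/TTX) ratio robustly
  standardized against the library, z_i = (r_i - median(r)) /
  (1.4826 * MAD(r)). Negative z = knockdown lowered stimulated sensor
  activity = candidate positive regulator.
* negative-binomial Wald test: per feature a NB model with variance
  mu + alpha*mu^2, median-of-ratios size factors, method-of-moments
  dispersion, group means fit by maximum likelihood, and a Wald test on
  the log fold change with Benjamini-Hochberg adjustment (features below
  a mean-count filter get padj = NA). This is a deliberately simplified
  relative of DESeq2: no dispersion shrinkage toward a trend, no outlier
  handling, and a plain mean-count filter instead of independent-filtering
  optimization.

Gene-level scores use the strongest-effect rule: a gene is represented by
its most extreme shRNA in the relevant direction (min z for positive
regulators, max z for negative regulators).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import COND_BIC, COND_TTX, CountMatrix


def enhanced_zscore(log2fc: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Robust Z-score: (r - median) / (1.4826 * MAD).

    Falls back to the standard deviation when MAD is zero; all-zero output
    when both scales are degenerate. Requires >= 3 finite values.
    """
    r = np.asarray(log2fc, dtype=float)
    finite = np.isfinite(r)
    if finite.sum() < 3:
        raise ValueError("enhanced Z-score needs at least 3 finite values")
    med = np.median(r[finite])
    mad = np.median(np.abs(r[finite] - med))
    scale = 1.4826 * mad
    if scale == 0:
        scale = r[finite].std(ddof=0)
    z = np.zeros_like(r) if scale == 0 else (r - med) / scale
    if isinstance(log2fc, pd.Series):
        return pd.Series(z, index=log2fc.index, name="enh_z")
    return z


def make_ranking(log2fc: pd.Series, genes: pd.Series) -> pd.DataFrame:
    """Per-shRNA ranking table: log2fc, enhanced Z, gene."""
    tab = pd.DataFrame({"log2fc": log2fc, "enh_z": enhanced_zscore(log2fc), "gene": genes.loc[log2fc.index]})
    tab.index.name = "shrna_id"
    return tab


def collapse_to_gene(ranking: pd.DataFrame) -> pd.DataFrame:
    """Strongest-effect gene collapse.

    pos_score = min enhanced Z over the gene's shRNAs (most negative =
    strongest candidate positive regulator), neg_score = max. Sorted by
    pos_score ascending. Every shRNA must carry a gene annotation.
    """
    missing = ranking.index[ranking["gene"].isna() | (ranking["gene"] == "")]
    if len(missing):
        raise ValueError(f"shRNAs without gene annotation: {list(missing[:5])}")
    grp = ranking.groupby("gene")["enh_z"]
    out = pd.DataFrame({
        "pos_score": grp.min(),
        "neg_score": grp.max(),
        "pos_shrna": grp.idxmin(),
        "neg_shrna": grp.idxmax(),
    })
    out.index.name = "gene"
    return out.sort_values("pos_score")


def size_factors(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample scaling factors.

    factor_j = median over features (restricted to rows with a positive
    geometric mean, i.e. no zero entry) of count_ij / geomean_i.
    """
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    x = df.to_numpy(dtype=float)
    pos = (x > 0).all(axis=1)
    if not pos.any():
        raise ValueError("size factors need at least one feature with all-positive counts")
    logx = np.log(x[pos])
    log_geomean = logx.mean(axis=1)
    ratios = logx - log_geomean[:, None]
    return pd.Series(np.exp(np.median(ratios, axis=0)), index=df.columns, name="size_factor")


@dataclass
class NBWaldResult:
    """Per-feature NB-Wald differential test output."""

    table: pd.DataFrame  # base_mean, log2FC, wald_stat, p-value, p-adj
    size_factors: pd.Series
    dispersion: pd.Series  # alpha-hat per feature


def _fit_group_means(K: np.ndarray, s: np.ndarray, alpha: np.ndarray, floor: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Newton ML fit of the NB group mean (on log scale) at fixed
    dispersion. Returns (eta = ln q, Fisher information at the MLE).

    For equal size factors the MLE is the plain mean of normalized counts;
    Newton handles unequal factors. All-zero groups are floored at half a
    normalized read so the log stays finite.
    """
    q0 = np.maximum((K / s).mean(axis=1), floor / s.mean())
    eta = np.log(q0)
    for _ in range(40):
        mu = s * np.exp(eta)[:, None]
        denom = 1.0 + alpha[:, None] * mu
        U = ((K - mu) / denom).sum(axis=1)
        info = (mu / denom).sum(axis=1)
        step = np.clip(U / info, -1.0, 1.0)
        eta = eta + step
        if np.max(np.abs(step)) < 1e-12:
            break
    eta = np.maximum(eta, np.log(floor / s.mean()))
    mu = s * np.exp(eta)[:, None]
    info = (mu / (1.0 + alpha[:, None] * mu)).sum(axis=1)
    return eta, info


def estimate_dispersion(
    K: np.ndarray,
    s: np.ndarray,
    groups: list[np.ndarray],
    mode: str = "pooled",
    floor: float = 1e-8,
) -> np.ndarray:
    """Method-of-moments NB dispersion from size-factor-normalized counts.

    Per feature, the within-group variances are pooled and solved for alpha
    in Var(y) = q * mean(1/s) + alpha * q^2. mode='pooled' (default)
    averages the per-feature moment estimates across all features into one
    common alpha — exact when dispersion is shared, and the stabilisation
    that replaces dispersion shrinkage here; mode='per-feature' keeps the
    raw per-feature estimates (noisy at 2-3 replicates per group).
    """
    y = K / s
    n_tot = K.shape[1]
    n_groups = len(groups)
    v = sum(y[:, g].var(axis=1, ddof=1) * (len(g) - 1) for g in groups) / (n_tot - n_groups)
    m = y.mean(axis=1)
    xi = float(np.mean(1.0 / s))
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = (v - m * xi) / m**2
    raw = np.where(np.isfinite(raw), raw, 0.0)
    if mode == "pooled":
        return np.full(K.shape[0], max(float(raw.mean()), floor))
    if mode == "per-feature":
        return np.maximum(raw, floor)
    raise ValueError("mode must be 'pooled' or 'per-feature'")


def nb_wald(
    counts: CountMatrix,
    condition_a: str = COND_TTX,
    condition_b: str = COND_BIC,
    dispersion_mode: str = "pooled",
    mean_filter: float = 5.0,
) -> NBWaldResult:
    """Two-group NB-Wald differential test (condition_b vs condition_a).

    Per feature: size factors by median-of-ratios, method-of-moments
    dispersion (see estimate_dispersion), group means by ML at fixed
    dispersion, log2FC = log2(q_b / q_a), Wald statistic from the observed
    Fisher information, two-sided normal p, and BH adjustment over features
    whose mean normalized count reaches `mean_filter` (others get NA).
    """
    sa = counts.samples_for(condition_a)
    sb = counts.samples_for(condition_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("need >= 2 samples per group")
    cols = sa + sb
    K = counts.counts[cols].to_numpy(dtype=float)
    sf = size_factors(counts.counts[cols])
    s = sf.to_numpy()
    ia = np.arange(len(sa))
    ib = np.arange(len(sa), len(cols))

    alpha = estimate_dispersion(K, s, [ia, ib], mode=dispersion_mode)
    eta_a, info_a = _fit_group_means(K[:, ia], s[ia], alpha)
    eta_b, info_b = _fit_group_means(K[:, ib], s[ib], alpha)

    lfc_ln = eta_b - eta_a
    se = np.sqrt(1.0 / info_a + 1.0 / info_b)
    wald = lfc_ln / se
    p = 2.0 * stats.norm.sf(np.abs(wald))
    base_mean = (K / s).mean(axis=1)
    padj = bh_adjust(p, filter_mask=base_mean >= mean_filter)

    table = pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2FC": lfc_ln / np.log(2.0),
            "wald_stat": wald,
            "p-value": p,
            "p-adj": padj,
        },
        index=counts.counts.index,
    )
    return NBWaldResult(table, sf, pd.Series(alpha, index=counts.counts.index, name="dispersion"))


def bh_adjust(p: np.ndarray | pd.Series, filter_mask: np.ndarray | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up over unfiltered entries; filtered -> NaN.

    filter_mask is True for entries that take part in the adjustment.
    """
    parr = np.asarray(p, dtype=float)
    if ((parr < 0) | (parr > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    out = np.full(parr.shape, np.nan)
    keep = np.ones(len(parr), dtype=bool) if filter_mask is None else np.asarray(filter_mask, dtype=bool)
    pk = parr[keep]
    m = len(pk)
    if m == 0:
        return out
    order = np.argsort(pk, kind="mergesort")
    ranked = pk[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    vals = np.empty(m)
    vals[order] = np.minimum(adj, 1.0)
    out[keep] = vals
    return out


def mannwhitney_fdr(
    groups_a: list[np.ndarray],
    groups_b: list[np.ndarray],
    exact_limit: int = 8,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Mann-Whitney U per feature plus BH across features.

    groups_a[i] and groups_b[i] are the two observation vectors of feature
    i. The exact U distribution is used when both group sizes are <=
    exact_limit and there are no ties; otherwise the normal approximation
    with tie correction.
    """
    if len(groups_a) != len(groups_b):
        raise ValueError("groups_a and groups_b must align")
    ps = []
    for a, b in zip(groups_a, groups_b):
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if len(a) < 2 or len(b) < 2:
            raise ValueError("need >= 2 observations per group")
        if np.array_equal(np.sort(a), np.sort(b)):
            ps.append(1.0)
            continue
        exact = len(a) <= exact_limit and len(b) <= exact_limit and len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact" if exact else "asymptotic", use_continuity=False)
        ps.append(float(min(res.pvalue, 1.0)))
    p = np.array(ps)
    return p, bh_adjust(p)
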