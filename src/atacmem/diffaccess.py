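"""Top-N-median normalization and negative-binomial differential testing.

Normalization: each sample is scaled by a correction factor derived from
the median count of its top-N features (default N = 30,000), referenced to
the geometric mean of those medians across samples.  Dividing counts by
the factors equalizes the top-N medians exactly.  A median-of-ratios mode
(the scheme used by standard RNA-seq count testing) is also exposed.

Testing: a two-group negative-binomial Wald test with per-feature
method-of-moments dispersion shrunk toward the across-feature mean.  The
NB is parameterized variance = mu + alpha * mu^2.  Group means are fitted
by maximum likelihood with sample size factors as offsets; the Wald
statistic is the log2 fold change over its standard error from the
observed Fisher information, with a two-sided normal reference.
Benjamini-Hochberg adjustment controls FDR across features.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .peakcall import CountMatrix

__all__ = [
    "size_factors_topN",
    "size_factors_median_of_ratios",
    "normalize",
    "estimate_dispersion",
    "nb_wald_test",
    "bh_adjust",
]

_LN2 = np.log(2.0)


def size_factors_topN(counts: CountMatrix | pd.DataFrame, n_top: int = 30_000) -> pd.Series:
    """Per-sample correction factors from the median of each sample's top-N counts.

    ``factor_j = m_j / geomean_k(m_k)`` where ``m_j`` is the median of the
    ``n_top`` highest counts in sample j (all features when fewer).  Dividing
    sample j by ``factor_j`` equalizes top-N medians across samples.
    """
    if n_top < 1:
        raise ValueError("n_top must be >= 1")
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    medians = {}
    for sample in df.columns:
        col = df[sample].to_numpy()
        if (col == 0).all():
            raise ValueError(f"sample {sample!r} has no nonzero feature")
        k = min(n_top, len(col))
        top = np.sort(col)[-k:]
        medians[sample] = float(np.median(top))
    m = pd.Series(medians)
    geo = float(np.exp(np.mean(np.log(m))))
    return m / geo


def size_factors_median_of_ratios(counts: CountMatrix | pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (geometric-mean reference per feature)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    arr = df.to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        log_arr = np.log(arr)
    usable = np.isfinite(log_arr).all(axis=1)
    if not usable.any():
        raise ValueError("no feature with nonzero counts in every sample")
    ref = log_arr[usable].mean(axis=1, keepdims=True)
    factors = np.exp(np.median(log_arr[usable] - ref, axis=0))
    return pd.Series(factors, index=df.columns)


def normalize(counts: CountMatrix | pd.DataFrame, factors: pd.Series) -> pd.DataFrame:
    """Divide each sample's counts by its factor (zeros stay zero)."""
    df = counts.counts if isinstance(counts, CountMatrix) else counts
    factors = factors.reindex(df.columns)
    if factors.isna().any():
        raise ValueError("factors missing for some samples")
    if (factors <= 0).any():
        raise ValueError("factors must be > 0")
    return df / factors


def estimate_dispersion(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: tuple[Sequence[str], Sequence[str]],
    shrink_weight: float = 0.5,
    clamp: tuple[float, float] = (1e-8, 10.0),
) -> pd.Series:
    """Per-feature NB dispersion alpha by pooled within-group method of moments.

    Within each group, ``alpha = max(0, (s^2 - mean) / mean^2)`` on
    size-factor-normalized counts; group estimates are pooled weighted by
    degrees of freedom, then shrunk toward the across-feature mean with
    weight ``shrink_weight`` and clamped to ``clamp``.  Estimates that fall
    below the across-feature mean are raised to it: with a handful of
    replicates, a low moment estimate is far more often noise than signal,
    and keeping it would understate the standard error of those features
    (the same asymmetry standard count-testing frameworks apply).
    """
    norm = normalize(counts, factors)
    pooled = np.zeros(len(norm))
    total_df = 0
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 samples")
        sub = norm[list(g)].to_numpy()
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (s2 - mu) / np.maximum(mu, 1e-12) ** 2, 0.0)
        a = np.maximum(a, 0.0)
        dof = len(g) - 1
        pooled += a * dof
        total_df += dof
    raw = pooled / total_df
    trend = float(raw.mean())
    shrunk = np.maximum((1 - shrink_weight) * raw + shrink_weight * trend, trend)
    return pd.Series(np.clip(shrunk, *clamp), index=counts.index)


def _fit_group_mean(y: np.ndarray, s: np.ndarray, alpha: np.ndarray, n_iter: int = 60) -> np.ndarray:
    """MLE of the per-feature NB mean m with size-factor offsets (mu_ij = s_j * m_i).

    Solves the score equation sum_j (y_ij - s_j m_i) / (1 + alpha_i s_j m_i) = 0
    by fixed-point iteration m = sum_j y/(1+a s m) / sum_j s/(1+a s m); the
    iteration starts at the size-factor-corrected sample mean.
    """
    m = (y / s).mean(axis=1)
    for _ in range(n_iter):
        denom = 1.0 + alpha[:, None] * s[None, :] * m[:, None]
        num = (y / denom).sum(axis=1)
        den = (s[None, :] / denom).sum(axis=1)
        m_new = np.where(den > 0, num / den, 0.0)
        if np.allclose(m_new, m, rtol=1e-12, atol=1e-12):
            m = m_new
            break
        m = m_new
    return np.maximum(m, 0.0)


def nb_wald_test(
    counts: pd.DataFrame,
    factors: pd.Series,
    groups: tuple[Sequence[str], Sequence[str]],
    alpha: pd.Series | None = None,
    pseudo_mean: float = 0.5,
) -> pd.DataFrame:
    """Two-group NB Wald test per feature.

    Returns a DataFrame indexed like ``counts`` with columns ``base_mean_a``,
    ``base_mean_b``, ``log2fc`` (group b over group a), ``alpha``, ``se``,
    ``stat``, ``pvalue``, ``padj``.  When either fitted group mean is zero,
    ``pseudo_mean`` is added to both means so the fold change stays finite;
    degenerate standard errors yield p = 1.
    """
    ga, gb = [list(g) for g in groups]
    if len(ga) < 2 or len(gb) < 2:
        raise ValueError("each group needs >= 2 samples")
    factors = factors.reindex(counts.columns)
    if alpha is None:
        alpha = estimate_dispersion(counts, factors, (ga, gb))
    a = alpha.reindex(counts.index).to_numpy(dtype=float)

    ya = counts[ga].to_numpy(dtype=float)
    yb = counts[gb].to_numpy(dtype=float)
    sa = factors[ga].to_numpy(dtype=float)
    sb = factors[gb].to_numpy(dtype=float)

    ma = _fit_group_mean(ya, sa, a)
    mb = _fit_group_mean(yb, sb, a)

    zero = (ma <= 0) | (mb <= 0)
    ma_eff = np.where(zero, ma + pseudo_mean, ma)
    mb_eff = np.where(zero, mb + pseudo_mean, mb)
    log2fc = np.log2(mb_eff) - np.log2(ma_eff)

    # observed/expected Fisher information for log-mean: I = sum_j mu_j/(1+alpha mu_j)
    mu_a = sa[None, :] * ma_eff[:, None]
    mu_b = sb[None, :] * mb_eff[:, None]
    info_a = (mu_a / (1.0 + a[:, None] * mu_a)).sum(axis=1)
    info_b = (mu_b / (1.0 + a[:, None] * mu_b)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_log = 1.0 / info_a + 1.0 / info_b
    se = np.sqrt(var_log) / _LN2

    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / se, 0.0)
    pvalue = 2.0 * stats.norm.sf(np.abs(stat))
    degenerate = ~np.isfinite(se) | (se == 0) | (log2fc == 0)
    pvalue = np.where(degenerate & (log2fc == 0), 1.0, pvalue)
    both_zero = (ma <= 0) & (mb <= 0)
    pvalue = np.where(both_zero, 1.0, pvalue)
    log2fc = np.where(both_zero, 0.0, log2fc)
    pvalue = np.clip(pvalue, 0.0, 1.0)

    res = pd.DataFrame(
        {
            "base_mean_a": ma,
            "base_mean_b": mb,
            "log2fc": log2fc,
            "alpha": a,
            "se": se,
            "stat": stat,
            "pvalue": pvalue,
        },
        index=counts.index,
    )
    res["padj"] = bh_adjust(res["pvalue"].to_numpy())
    return res


def bh_adjust(pvalues: np.ndarray | Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
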