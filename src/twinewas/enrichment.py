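"""GWAS-proximity enrichment of within-pair EWAS signal.

Tests whether CpGs lying within a fixed window (default 1 Mb) of
genome-wide-significant SNPs (default p < 5e-8) from a smoking GWAS show a
stronger within-pair EWAS signal than other CpGs, by regressing the absolute
paired-test t-statistic on the binary proximity indicator:

    |t| = intercept + beta_gwaslocus * GWASlocus

With a binary predictor the OLS slope equals the difference of class means.
Uncertainty comes from a nonparametric bootstrap over CpGs (case resampling):
the SE is the SD of the bootstrap slopes, the CI is percentile-based, and the
two-sided p uses a normal approximation on beta/SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "normalize_chrom",
    "flag_proximal_cpgs",
    "enrichment_regression",
    "bootstrap_se",
    "EnrichmentResult",
]


@dataclass
class EnrichmentResult:
    """Point estimate and bootstrap uncertainty of the proximity slope."""

    beta_gwaslocus: float
    intercept: float
    n_flagged: int
    n_total: int
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p: float | None = None
    n_boot: int | None = None
    n_redrawn: int | None = None
    seed: int | None = None


def normalize_chrom(values) -> pd.Series:
    """Strip a 'chr' prefix and uppercase chromosome names."""
    s = pd.Series(values).astype(str).str.strip()
    s = s.str.replace(r"(?i)^chr", "", regex=True).str.upper()
    return s


def flag_proximal_cpgs(
    annotation: pd.DataFrame,
    hits: pd.DataFrame,
    window: int = 1_000_000,
    sig: float = 5e-8,
) -> pd.Series:
    """Indicator: CpG within ``window`` bp (inclusive) of a significant SNP.

    ``annotation`` needs ``chrom``/``pos`` columns (1-based, same build as
    the hits); ``hits`` needs ``chrom``/``pos``/``pvalue``.  SNPs enter only
    with p strictly below ``sig``.
    """
    for col in ("chrom", "pos"):
        if col not in annotation.columns:
            raise ValueError(f"annotation lacks column {col!r}")
        if col not in hits.columns:
            raise ValueError(f"GWAS hits lack column {col!r}")
    if "pvalue" not in hits.columns:
        raise ValueError("GWAS hits lack column 'pvalue'")
    if window < 0:
        raise ValueError("window must be non-negative")

    cpg_chrom = normalize_chrom(annotation["chrom"]).to_numpy()
    hit_chrom = normalize_chrom(hits["chrom"]).to_numpy()
    sig_hits = hits.loc[hits["pvalue"].to_numpy() < sig]
    hit_chrom = hit_chrom[hits["pvalue"].to_numpy() < sig]

    flag = np.zeros(len(annotation), dtype=int)
    cpg_pos = annotation["pos"].to_numpy(dtype=np.int64)
    for chrom in np.unique(hit_chrom):
        snp_pos = np.sort(sig_hits["pos"].to_numpy(dtype=np.int64)[hit_chrom == chrom])
        on_chrom = cpg_chrom == chrom
        if not on_chrom.any():
            continue
        pos = cpg_pos[on_chrom]
        idx = np.searchsorted(snp_pos, pos)
        left = np.where(idx > 0, pos - snp_pos[np.maximum(idx - 1, 0)], np.iinfo(np.int64).max)
        right = np.where(
            idx < snp_pos.size, snp_pos[np.minimum(idx, snp_pos.size - 1)] - pos,
            np.iinfo(np.int64).max,
        )
        flag[on_chrom] = np.where(np.minimum(left, right) <= window, 1, flag[on_chrom])
    return pd.Series(flag, index=annotation.index, name="gwas_locus")


def enrichment_regression(abs_t, indicator) -> EnrichmentResult:
    """OLS of |t| on intercept + proximity indicator (point estimates)."""
    y = np.asarray(abs_t, dtype=float)
    g = np.asarray(indicator, dtype=float)
    ok = ~np.isnan(y)
    y, g = y[ok], g[ok]
    classes = np.unique(g)
    if classes.size < 2:
        raise ValueError("proximity indicator has a single class")
    X = sm.add_constant(g)
    fit = sm.OLS(y, X).fit()
    return EnrichmentResult(
        beta_gwaslocus=float(fit.params[1]),
        intercept=float(fit.params[0]),
        n_flagged=int((g == 1).sum()),
        n_total=int(g.size),
    )


def bootstrap_se(
    abs_t, indicator, n_boot: int = 2000, seed: int = 0
) -> EnrichmentResult:
    """Case-resampling bootstrap of the proximity regression.

    CpGs (rows) are resampled with replacement ``n_boot`` times; single-class
    resamples are redrawn (count reported) so the number of replicates stays
    fixed.  SE = SD of bootstrap slopes; 95% percentile CI; two-sided p from
    a normal approximation.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    y = np.asarray(abs_t, dtype=float)
    g = np.asarray(indicator, dtype=float)
    ok = ~np.isnan(y)
    y, g = y[ok], g[ok]
    n = y.size
    if min((g == 1).sum(), (g == 0).sum()) < 2:
        raise ValueError("each indicator class needs at least 2 members")
    point = enrichment_regression(y, g)

    rng = np.random.default_rng(seed)
    betas = np.empty(n_boot)
    n_redrawn = 0
    filled = 0
    chunk = max(1, min(n_boot, int(2e7 // max(n, 1)) or 1))
    while filled < n_boot:
        k = min(chunk, n_boot - filled)
        idx = rng.integers(0, n, size=(k, n))
        gs = g[idx]
        ys = y[idx]
        n1 = gs.sum(axis=1)
        valid = (n1 > 0) & (n1 < n)
        n_redrawn += int((~valid).sum())
        if not valid.any():
            continue
        gs, ys, n1 = gs[valid], ys[valid], n1[valid]
        mean1 = (ys * gs).sum(axis=1) / n1
        mean0 = (ys * (1 - gs)).sum(axis=1) / (n - n1)
        take = min(mean1.size, n_boot - filled)
        betas[filled : filled + take] = (mean1 - mean0)[:take]
        filled += take

    se = float(betas.std(ddof=1))
    lo, hi = np.percentile(betas, [2.5, 97.5])
    b = point.beta_gwaslocus
    p = float(2.0 * stats.norm.sf(abs(b) / se)) if se > 0 else (0.0 if b != 0 else 1.0)
    return EnrichmentResult(
        beta_gwaslocus=b,
        intercept=point.intercept,
        n_flagged=point.n_flagged,
        n_total=point.n_total,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        p=p,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        seed=seed,
    )
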