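"""Within-pair EWAS: per-CpG paired t-tests on covariate residuals.

For each CpG the within-pair difference is taken as the *less-exposed minus
the more-exposed* twin's residual, so a positive mean difference means lower
methylation in the exposed twin.  A one-sample t-test of the differences
against zero gives the two-sided p-value (t distribution, n-1 df) and the
95% confidence interval.  Family-wise significance uses Bonferroni
correction over the CpGs tested.  Calibration of the test statistics is
summarized by the classical genomic inflation factor lambda (ratio of the
median chi-square implied by the p-values to its null expectation) together
with the mean/SD of probability-integral-transformed z-scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import GROUPS, PairTable, ResidualMatrix

__all__ = [
    "EWAS_COLUMNS",
    "InflationReport",
    "within_pair_differences",
    "paired_ewas",
    "bonferroni_threshold",
    "inflation_lambda",
    "paired_descriptives",
    "rank_by_p",
]

#: Columns of an EWAS result table (one row per CpG).
EWAS_COLUMNS = (
    "n_pairs",
    "mean_diff",
    "sd_diff",
    "t",
    "p",
    "ci_low",
    "ci_high",
    "significant",
    "degenerate",
)

#: Median of the chi-square distribution with 1 df.
CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


@dataclass
class InflationReport:
    """Genomic inflation factor and z-score moments of an EWAS."""

    lam: float
    z_mean: float
    z_sd: float
    n: int


def within_pair_differences(
    residuals: ResidualMatrix, pairs: PairTable, group: str
) -> pd.DataFrame:
    """Per-CpG, per-pair residual differences for one group.

    Discordant groups: less-exposed minus more-exposed member.  Concordant
    groups: twin a minus twin b under the deterministic sample-identifier
    ordering.  Returns a CpG x pair DataFrame (columns are pair ids).
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label: {group!r}")
    sub = pairs.pairs_in_group(group)
    if len(sub) < 2:
        raise ValueError(f"group {group!r} has fewer than 2 pairs")
    missing = set(sub["sample_id_a"]) | set(sub["sample_id_b"])
    missing -= set(residuals.sample_ids)
    if missing:
        raise ValueError(f"pair members absent from residual matrix: {sorted(missing)[:5]}")

    exposed = sub["exposed_member"]
    if group.startswith("discordant"):
        more = exposed.to_numpy()
        less = np.where(
            sub["sample_id_a"].to_numpy() == more,
            sub["sample_id_b"].to_numpy(),
            sub["sample_id_a"].to_numpy(),
        )
    else:
        less = sub["sample_id_a"].to_numpy()  # twin 1
        more = sub["sample_id_b"].to_numpy()  # twin 2
    vals = residuals.values
    diffs = vals.loc[:, less].to_numpy() - vals.loc[:, more].to_numpy()
    return pd.DataFrame(diffs, index=vals.index, columns=sub["pair_id"].to_numpy())


def paired_ewas(diffs: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """One-sample t-test of the within-pair differences per CpG.

    Complete pairs only are used at each CpG; CpGs with fewer than two
    complete pairs or zero-variance differences get a ``degenerate`` flag and
    missing test results instead of infinities.  ``significant`` is the
    Bonferroni flag at ``alpha`` over the CpGs actually tested.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    d = diffs.to_numpy(dtype=float)
    ok = ~np.isnan(d)
    n = ok.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(ok, d, np.nan), axis=1)
        sd = np.nanstd(np.where(ok, d, np.nan), axis=1, ddof=1)

    testable = (n >= 2) & (sd > 0)
    t = np.full(d.shape[0], np.nan)
    p = np.full(d.shape[0], np.nan)
    lo = np.full(d.shape[0], np.nan)
    hi = np.full(d.shape[0], np.nan)

    se = sd[testable] / np.sqrt(n[testable])
    df = n[testable] - 1
    t[testable] = mean[testable] / se
    p[testable] = 2.0 * stats.t.sf(np.abs(t[testable]), df)
    tc = stats.t.ppf(0.975, df)
    lo[testable] = mean[testable] - tc * se
    hi[testable] = mean[testable] + tc * se

    m_tested = int(testable.sum())
    thr = bonferroni_threshold(alpha, m_tested) if m_tested else np.nan
    out = pd.DataFrame(
        {
            "n_pairs": n,
            "mean_diff": mean,
            "sd_diff": sd,
            "t": t,
            "p": p,
            "ci_low": lo,
            "ci_high": hi,
            "significant": np.where(testable, p < thr, False).astype(bool),
            "degenerate": ~testable,
        },
        index=diffs.index,
    )
    out.attrs["alpha"] = alpha
    out.attrs["m_tested"] = m_tested
    out.attrs["bonferroni_threshold"] = thr
    return out


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha / m for family-wise error control."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def rank_by_p(result: pd.DataFrame) -> pd.DataFrame:
    """Sort an EWAS table by ascending p, ties broken by |t| desc, then id."""
    key = result.assign(_abs_t=-result["t"].abs(), _id=result.index)
    key = key.sort_values(["p", "_abs_t", "_id"], na_position="last")
    return result.loc[key.index]


def inflation_lambda(t_stats, df) -> InflationReport:
    """Genomic inflation factor from a vector of t statistics.

    Each t is converted to a two-sided p and the corresponding chi-square
    quantile with 1 df; lambda is the median of those over the null median
    0.4549.  The z-scores are the probability-integral transform of the t
    statistics (sign-preserving); under a calibrated null they are standard
    normal, so their mean/SD are reported alongside.
    """
    t_arr = np.asarray(t_stats, dtype=float)
    t_arr = t_arr[~np.isnan(t_arr)]
    if t_arr.size == 0:
        raise ValueError("no test statistics supplied")
    if t_arr.size < 2:
        raise ValueError("at least two statistics are required")
    if t_arr.size < 100:
        warnings.warn(
            f"inflation factor from only {t_arr.size} statistics is unstable",
            stacklevel=2,
        )
    p_two = 2.0 * stats.t.sf(np.abs(t_arr), df)
    chi2 = stats.chi2.isf(np.clip(p_two, 1e-300, 1.0), 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    # sign-preserving z: z = Phi^{-1}(F_t(t))
    z = stats.norm.ppf(np.clip(stats.t.cdf(t_arr, df), 1e-300, 1 - 1e-16))
    return InflationReport(
        lam=lam, z_mean=float(z.mean()), z_sd=float(z.std(ddof=1)), n=int(t_arr.size)
    )


def paired_descriptives(
    sheet: pd.DataFrame,
    pairs: PairTable,
    variable: str,
    scale: str = "continuous",
    group: str | None = None,
) -> dict:
    """Within-pair test of a phenotype: paired t (continuous) or Wilcoxon
    signed-rank (ordinal).

    Differences are twin a minus twin b (for discordant groups: less-exposed
    minus more-exposed).  Zero differences are dropped for the signed-rank
    test, which uses the exact null for n <= 25 (no ties) and the normal
    approximation with continuity correction above.
    """
    if variable not in sheet.columns:
        raise ValueError(f"unknown variable: {variable!r}")
    if scale not in ("continuous", "ordinal"):
        raise ValueError("scale must be 'continuous' or 'ordinal'")
    table = pairs.table if group is None else pairs.pairs_in_group(group)
    values = sheet.set_index("sample_id")[variable]

    a_ids = table["sample_id_a"].to_numpy()
    b_ids = table["sample_id_b"].to_numpy()
    exposed = table["exposed_member"]
    disc = table["group"].str.startswith("discordant").to_numpy()
    more = np.where(disc, exposed.to_numpy(), b_ids)
    less = np.where(disc & (a_ids == more), b_ids, a_ids)
    d = values.reindex(less).to_numpy(dtype=float) - values.reindex(more).to_numpy(
        dtype=float
    )
    d = d[~np.isnan(d)]
    if d.size < 2:
        raise ValueError("fewer than 2 complete pairs")

    if scale == "continuous":
        sd = d.std(ddof=1)
        if sd == 0:
            return {"statistic": np.nan, "p": np.nan, "n": int(d.size), "degenerate": True}
        t = d.mean() / (sd / np.sqrt(d.size))
        p = 2.0 * stats.t.sf(abs(t), d.size - 1)
        return {"statistic": float(t), "p": float(p), "n": int(d.size), "degenerate": False}

    nz = d[d != 0]
    if nz.size == 0:
        return {"statistic": np.nan, "p": np.nan, "n": int(d.size), "degenerate": True}
    has_ties = np.unique(np.abs(nz)).size < nz.size
    method = "exact" if (nz.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "n": int(nz.size),
        "degenerate": False,
    }
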