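"""Dose-response: within-pair methylation differences versus exposure.

In concordant current-smoking pairs, within-pair differences in methylation
at smoking-reactive CpGs are correlated (Pearson) with within-pair
differences in cigarettes/day, packyears, and plasma cotinine.  In
former/never discordant pairs, the within-pair difference is correlated with
the former smoker's time since quitting, optionally restricted to recent
quitters.  Phenotype deltas use the same member ordering as the methylation
differences (less-exposed minus more-exposed; concordant: twin a minus b).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .preprocess import PairTable

__all__ = [
    "within_pair_delta",
    "pearson_with_p",
    "dose_response_correlations",
    "time_since_quit_correlation",
    "twin_correlation",
]


def _member_order(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(less-exposed, more-exposed) sample ids per pair row."""
    a = table["sample_id_a"].to_numpy()
    b = table["sample_id_b"].to_numpy()
    disc = table["group"].str.startswith("discordant").to_numpy()
    exposed = table["exposed_member"].to_numpy()
    more = np.where(disc, exposed, b)
    less = np.where(disc & (a == more), b, a)
    return less, more


def within_pair_delta(
    sheet: pd.DataFrame, pairs: PairTable, variable: str, group: str | None = None
) -> pd.Series:
    """Per-pair phenotype delta under the fixed member ordering.

    Pairs with a missing value in either member yield a missing delta.
    """
    if variable not in sheet.columns:
        raise ValueError(f"unknown variable: {variable!r}")
    table = pairs.table if group is None else pairs.pairs_in_group(group)
    values = sheet.set_index("sample_id")[variable].astype(float)
    less, more = _member_order(table)
    delta = values.reindex(less).to_numpy() - values.reindex(more).to_numpy()
    return pd.Series(delta, index=table["pair_id"].to_numpy(), name=f"delta_{variable}")


def pearson_with_p(x, y) -> tuple[float, float, int]:
    """Pearson r with two-sided p via the t transform on n-2 df.

    Complete-case; returns (nan, nan, n) with n < 3 or zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = int(x.size)
    if n < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, np.nan, n
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(min(r, 1.0), -1.0)
    if abs(r) == 1.0:
        return r, 0.0, n
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p), n


def dose_response_correlations(
    diff_m: pd.DataFrame, deltas: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Correlate per-pair methylation differences with phenotype deltas.

    ``diff_m`` is CpG x pair; ``deltas`` is a per-pair Series (one phenotype)
    or DataFrame (pairs x phenotypes).  Complete-case per CpG x phenotype.
    Summary mean |r| and the signed range per phenotype are stored in
    ``DataFrame.attrs['summary']``.
    """
    if isinstance(deltas, pd.Series):
        deltas = deltas.to_frame()
    deltas = deltas.reindex(diff_m.columns)
    rows = []
    for cpg, dm in diff_m.iterrows():
        rec = {"cpg_id": cpg}
        for pheno in deltas.columns:
            r, p, n = pearson_with_p(dm.to_numpy(), deltas[pheno].to_numpy())
            rec[f"r_{pheno}"] = r
            rec[f"p_{pheno}"] = p
            rec[f"n_{pheno}"] = n
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("cpg_id")
    summary = {}
    for pheno in deltas.columns:
        r = out[f"r_{pheno}"].dropna()
        summary[pheno] = {
            "mean_abs_r": float(r.abs().mean()) if len(r) else np.nan,
            "r_min": float(r.min()) if len(r) else np.nan,
            "r_max": float(r.max()) if len(r) else np.nan,
        }
    out.attrs["summary"] = summary
    return out


def time_since_quit_correlation(
    diff_m: pd.DataFrame, years_quit: pd.Series, max_years: float | None = None
) -> pd.DataFrame:
    """Correlate within-pair differences with time since quitting.

    ``years_quit`` is indexed by pair id (the former smoker's years since
    quitting in former/never pairs).  With ``max_years`` set, pairs with
    years_quit strictly below the cutoff are kept (e.g. quitters of less
    than 5 years).
    """
    if (years_quit.dropna() < 0).any():
        raise ValueError("years_quit must be non-negative")
    yq = years_quit.reindex(diff_m.columns)
    if max_years is not None:
        keep = yq < max_years
        if keep.sum() < 3:
            warnings.warn(
                f"fewer than 3 pairs quit less than {max_years} years ago; "
                "no correlation computed",
                stacklevel=2,
            )
            return pd.DataFrame(
                index=diff_m.index, columns=["r_years_quit", "p_years_quit", "n_years_quit"]
            )
        diff_m = diff_m.loc[:, keep.to_numpy()]
        yq = yq[keep]
    out = dose_response_correlations(diff_m, yq.rename("years_quit"))
    return out


def twin_correlation(
    sheet: pd.DataFrame, pairs: PairTable, variable: str, group: str
) -> dict:
    """Pearson correlation between co-twins' phenotype values in a group."""
    table = pairs.pairs_in_group(group)
    if len(table) < 3:
        raise ValueError(f"group {group!r} has fewer than 3 pairs")
    values = sheet.set_index("sample_id")[variable].astype(float)
    less, more = _member_order(table)
    r, p, n = pearson_with_p(values.reindex(less), values.reindex(more))
    return {"r": r, "p": p, "n": n, "degenerate": bool(np.isnan(r) and n >= 3)}
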