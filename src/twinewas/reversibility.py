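"""Reversibility of smoking-associated methylation after cessation.

If within-pair methylation differences are reactive to smoking and reversible
upon quitting, the absolute within-pair difference |dM| at smoking-reactive
CpGs should shrink from current/never discordant pairs to former/never pairs,
with current/former pairs intermediate and concordant-never pairs smallest.
Attenuation is quantified as the percent reduction of |dM| relative to the
current/never reference, computed on absolute mean differences (signs are
preserved in reporting but not in the ratio); summary means are taken on
unrounded per-CpG reductions and rounded last (half-up).
"""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

__all__ = [
    "percent_reduction",
    "group_difference_profile",
    "ordering_check",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the given decimal place."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent_reduction(
    ref: pd.DataFrame, comp: pd.DataFrame, cpgs=None
) -> dict:
    """Percent reduction of |mean within-pair difference| at a CpG set.

    ``ref`` and ``comp`` are EWAS result tables (need a ``mean_diff`` column).
    Per CpG: 100 * (1 - |dM_comp| / |dM_ref|); negative if the comparison
    exceeds the reference.  CpGs absent from either table (or with zero
    reference difference) are listed and excluded from the summary.

    Returns a dict with ``table`` (per-CpG reductions), ``mean``/``min``/
    ``max`` on the unrounded values, rounded integer counterparts, and
    ``excluded``.
    """
    cpgs = pd.Index(ref.index if cpgs is None else cpgs)
    present = cpgs[cpgs.isin(ref.index) & cpgs.isin(comp.index)]
    excluded = cpgs.difference(present).tolist()

    ref_dm = ref.loc[present, "mean_diff"].astype(float)
    comp_dm = comp.loc[present, "mean_diff"].astype(float)
    nonzero = ref_dm.abs() > 0
    excluded += present[~nonzero].tolist()
    ref_dm, comp_dm = ref_dm[nonzero], comp_dm[nonzero]

    reduction = 100.0 * (1.0 - comp_dm.abs() / ref_dm.abs())
    table = pd.DataFrame(
        {
            "ref_mean_diff": ref_dm,
            "comp_mean_diff": comp_dm,
            "reduction_pct": reduction,
            "reduction_pct_rounded": [round_half_up(v) for v in reduction],
        }
    )
    if len(reduction) == 0:
        raise ValueError("no CpGs with a non-zero reference difference")
    return {
        "table": table,
        "mean": float(reduction.mean()),
        "min": float(reduction.min()),
        "max": float(reduction.max()),
        "mean_rounded": round_half_up(reduction.mean()),
        "min_rounded": round_half_up(reduction.min()),
        "max_rounded": round_half_up(reduction.max()),
        "excluded": excluded,
    }


def group_difference_profile(
    diffs_by_group: dict[str, pd.DataFrame],
    ranking: pd.DataFrame,
    top_k: int = 1000,
) -> pd.DataFrame:
    """Distribution of mean absolute within-pair differences per group.

    Selects the ``top_k`` CpGs with the lowest p-value from ``ranking`` (ties
    broken by |t| descending then CpG id), computes each group's per-CpG mean
    absolute within-pair difference, and summarizes the distribution.
    Groups with fewer than 2 pairs are omitted with a warning.
    """
    from .ewas import rank_by_p

    if top_k > len(ranking):
        raise ValueError(f"top_k={top_k} exceeds the {len(ranking)} CpGs tested")
    top = rank_by_p(ranking).index[:top_k]

    rows = {}
    for group, diffs in diffs_by_group.items():
        if diffs.shape[1] < 2:
            import warnings

            warnings.warn(f"group {group!r} has < 2 pairs; omitted", stacklevel=2)
            continue
        per_cpg = diffs.loc[top].abs().mean(axis=1)
        rows[group] = {
            "n_pairs": diffs.shape[1],
            "mean": per_cpg.mean(),
            "median": per_cpg.median(),
            "q25": per_cpg.quantile(0.25),
            "q75": per_cpg.quantile(0.75),
        }
    out = pd.DataFrame(rows).T
    out.index.name = "group"
    out.attrs["top_k"] = top_k
    out.attrs["cpgs"] = list(top)
    return out


def ordering_check(profile: pd.DataFrame | dict) -> dict:
    """Evaluate the reversibility ordering hypotheses on group mean |dM|.

    Checks (on the mean absolute within-pair difference over the selected
    CpG set): current/never > current/former, former/never > concordant
    never, and the full ordering current/never > current/former >
    former/never > concordant never.  A missing group makes the flags that
    need it indeterminate (None).
    """
    if isinstance(profile, pd.DataFrame):
        means = profile["mean"].to_dict()
    else:
        means = dict(profile)

    def get(g):
        return means.get(g)

    cn = get("discordant_current_never")
    cf = get("discordant_current_former")
    fn = get("discordant_former_never")
    nn = get("concordant_never")

    def gt(a, b):
        return None if a is None or b is None else bool(a > b)

    flags = {
        "current_never_gt_current_former": gt(cn, cf),
        "former_never_gt_concordant_never": gt(fn, nn),
    }
    parts = [gt(cn, cf), gt(cf, fn), gt(fn, nn)]
    flags["full_ordering"] = None if any(p is None for p in parts) else all(parts)
    return flags
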