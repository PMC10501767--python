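"""Probe/sample filtering, phenotype derivations, pair classification and
covariate residualization.

The analysis substrate is a CpG x sample matrix of methylation beta-values
(methylated fraction, in [0, 1]).  Before any within-pair testing, beta-values
are residualized on technical and cell-composition covariates by ordinary
least squares, one CpG at a time, across the *entire* sample set; the
residuals are what the paired tests consume.  Monozygotic co-twins share sex
and age, so those are not adjusted for by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "MethylationMatrix",
    "PairTable",
    "ResidualMatrix",
    "FilterReport",
    "SAMPLE_SHEET_COLUMNS",
    "DEFAULT_COVARIATES",
    "validate_sample_sheet",
    "filter_probes",
    "compute_packyears",
    "classify_pairs",
    "flag_cotinine_inconsistency",
    "build_design",
    "residualize",
]

#: The six discordance/concordance groups of monozygotic twin pairs.
GROUPS = (
    "discordant_current_never",
    "discordant_former_never",
    "discordant_current_former",
    "concordant_current",
    "concordant_former",
    "concordant_never",
)

#: Map from the unordered pair of smoking statuses to the group label.
_STATUS_PAIR_TO_GROUP = {
    frozenset({"current", "never"}): "discordant_current_never",
    frozenset({"former", "never"}): "discordant_former_never",
    frozenset({"current", "former"}): "discordant_current_former",
    frozenset({"current"}): "concordant_current",
    frozenset({"former"}): "concordant_former",
    frozenset({"never"}): "concordant_never",
}

SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "pair_id",
    "smoking_status",
    "cigarettes_per_day",
    "years_smoked",
    "years_since_quit",
    "packyears",
    "cotinine",
    "neutrophil_pct",
    "lymphocyte_pct",
    "monocyte_pct",
    "eosinophil_pct",
    "basophil_pct",
    "plate",
    "array_row",
    "age",
    "sex",
    "bmi",
)

#: Covariates regressed out of beta-values before within-pair testing.
#: Lymphocyte percentage is excluded (collinear with neutrophils, r ~ -0.93)
#: and basophil percentage is excluded (near-zero in most subjects); plate and
#: array row are dummy-coded.
DEFAULT_COVARIATES = (
    "plate",
    "array_row",
    "neutrophil_pct",
    "monocyte_pct",
    "eosinophil_pct",
)

_CATEGORICAL_COVARIATES = frozenset({"plate", "array_row", "sex"})


@dataclass
class MethylationMatrix:
    """CpG x sample beta-value matrix with annotation and QC companions.

    Parameters
    ----------
    beta
        DataFrame indexed by CpG id with sample ids as columns; values in
        [0, 1] or missing.
    annotation
        Per-CpG table with columns ``chrom``, ``pos`` (1-based), ``gene``
        (empty string for intergenic), indexed by CpG id.
    detection_p, beads, intensity
        Optional companion matrices aligned with ``beta``, used by
        :func:`filter_probes`.
    """

    beta: pd.DataFrame
    annotation: pd.DataFrame | None = None
    detection_p: pd.DataFrame | None = None
    beads: pd.DataFrame | None = None
    intensity: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.index.duplicated().any():
            dups = self.beta.index[self.beta.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicated cpg_ids: {dups[:5]}")
        if self.beta.columns.duplicated().any():
            dups = self.beta.columns[self.beta.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicated sample_ids: {dups[:5]}")
        vals = self.beta.to_numpy(dtype=float)
        bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            r, c = np.argwhere(bad & ~np.isnan(vals))[0]
            raise ValueError(
                "beta-value outside [0, 1] at "
                f"cpg={self.beta.index[r]!r}, sample={self.beta.columns[c]!r}: "
                f"{vals[r, c]}"
            )
        for name in ("detection_p", "beads", "intensity"):
            comp = getattr(self, name)
            if comp is not None and (
                not comp.index.equals(self.beta.index)
                or not comp.columns.equals(self.beta.columns)
            ):
                raise ValueError(f"companion matrix {name!r} not aligned with beta")

    @property
    def cpg_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    def subset(self, cpgs=None, samples=None) -> "MethylationMatrix":
        """Return a new matrix restricted to the given CpGs/samples."""
        cpgs = self.beta.index if cpgs is None else pd.Index(cpgs)
        samples = self.beta.columns if samples is None else pd.Index(samples)

        def _cut(df):
            return None if df is None else df.loc[cpgs, samples]

        ann = None
        if self.annotation is not None:
            ann = self.annotation.loc[self.annotation.index.intersection(cpgs)]
        return MethylationMatrix(
            beta=self.beta.loc[cpgs, samples],
            annotation=ann,
            detection_p=_cut(self.detection_p),
            beads=_cut(self.beads),
            intensity=_cut(self.intensity),
        )


@dataclass
class PairTable:
    """One row per monozygotic pair: members, group, and exposed member.

    ``sample_id_a``/``sample_id_b`` are in sample-identifier order; for
    discordant groups ``exposed_member`` names the more-exposed twin (the
    current smoker in current/never and current/former pairs, the former
    smoker in former/never pairs) and is missing for concordant groups.
    """

    table: pd.DataFrame
    exclusions: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["pair_id", "reason"])
    )

    def __post_init__(self) -> None:
        required = {"pair_id", "sample_id_a", "sample_id_b", "group", "exposed_member"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"PairTable missing columns: {sorted(missing)}")
        members = pd.concat([self.table["sample_id_a"], self.table["sample_id_b"]])
        if members.duplicated().any():
            raise ValueError("a sample appears in more than one pair")
        unknown = set(self.table["group"]) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")

    def pairs_in_group(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise ValueError(f"unknown group label: {group!r}")
        return self.table[self.table["group"] == group]

    def group_counts(self) -> pd.Series:
        return self.table["group"].value_counts().reindex(GROUPS, fill_value=0)


@dataclass
class ResidualMatrix:
    """Residuals of beta on the covariate design; same shape/ids as the input."""

    values: pd.DataFrame
    covariates: tuple[str, ...]
    design_columns: tuple[str, ...]
    n_complete: pd.Series | None = None

    @property
    def cpg_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class FilterReport:
    """Counts removed at each filtering step, in application order."""

    n_detection_failed: int = 0
    n_bead_failed: int = 0
    n_zero_intensity: int = 0
    n_probes_dropped: int = 0
    n_samples_dropped: int = 0
    probes_dropped: list = field(default_factory=list)
    samples_dropped: list = field(default_factory=list)


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and basic invariants of a sample sheet."""
    missing = {"sample_id", "pair_id", "smoking_status"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicated sample_id in sample sheet")
    bad = ~sheet["smoking_status"].isin(["never", "former", "current"]) & sheet[
        "smoking_status"
    ].notna()
    if bad.any():
        raise ValueError(
            f"invalid smoking_status values: {sheet.loc[bad, 'smoking_status'].unique()}"
        )
    for col in (
        "neutrophil_pct",
        "lymphocyte_pct",
        "monocyte_pct",
        "eosinophil_pct",
        "basophil_pct",
    ):
        if col in sheet.columns and (sheet[col].dropna() < 0).any():
            raise ValueError(f"negative cell percentage in column {col!r}")
    return sheet


# ---------------------------------------------------------------------------
# Probe/sample filtering
# ---------------------------------------------------------------------------

def filter_probes(
    matrix: MethylationMatrix,
    detection_p_max: float = 0.01,
    bead_min: int = 3,
    success_min: float = 0.95,
    drop_zero_intensity: bool = True,
) -> tuple[MethylationMatrix, FilterReport]:
    """Apply per-measurement QC rules, then success-rate filtering.

    Individual measurements with detection p-value > ``detection_p_max``,
    bead number < ``bead_min``, or zero raw intensity are set missing; then
    probes and finally samples with a success rate (fraction non-missing)
    below ``success_min`` are dropped.

    A companion matrix missing for a requested rule is a configuration error;
    pass ``detection_p_max=None`` (etc.) to disable a rule explicitly.
    """
    if not (detection_p_max is None or 0 < detection_p_max < 1):
        raise ValueError("detection_p_max must be in (0, 1) or None")
    if not (bead_min is None or bead_min > 0):
        raise ValueError("bead_min must be a positive integer or None")
    if not 0 < success_min <= 1:
        raise ValueError("success_min must be in (0, 1]")

    beta_arr = matrix.beta.to_numpy(dtype=float, copy=True)
    report = FilterReport()

    def _apply_rule(companion, name, mask_fn, attr):
        if companion is None:
            raise ValueError(
                f"companion matrix for the {name} rule is absent; "
                f"disable the rule explicitly to skip it"
            )
        fail = mask_fn(companion.to_numpy(dtype=float)) & ~np.isnan(beta_arr)
        setattr(report, attr, int(fail.sum()))
        beta_arr[fail] = np.nan

    if detection_p_max is not None:
        _apply_rule(
            matrix.detection_p,
            "detection p-value",
            lambda a: a > detection_p_max,
            "n_detection_failed",
        )
    if bead_min is not None:
        _apply_rule(
            matrix.beads, "bead number", lambda a: a < bead_min, "n_bead_failed"
        )
    if drop_zero_intensity:
        _apply_rule(
            matrix.intensity, "zero intensity", lambda a: a == 0, "n_zero_intensity"
        )

    beta = pd.DataFrame(
        beta_arr, index=matrix.beta.index, columns=matrix.beta.columns
    )

    # probe success rate, then sample success rate (in this order)
    probe_ok = beta.notna().mean(axis=1) >= success_min
    report.probes_dropped = beta.index[~probe_ok].tolist()
    report.n_probes_dropped = int((~probe_ok).sum())
    beta = beta.loc[probe_ok]

    sample_ok = beta.notna().mean(axis=0) >= success_min
    report.samples_dropped = beta.columns[~sample_ok].tolist()
    report.n_samples_dropped = int((~sample_ok).sum())
    beta = beta.loc[:, sample_ok]

    filtered = matrix.subset(cpgs=beta.index, samples=beta.columns)
    filtered.beta = beta
    return filtered, report


# ---------------------------------------------------------------------------
# Phenotype derivations and pair classification
# ---------------------------------------------------------------------------

def compute_packyears(cpd, years_smoked):
    """Packyears = (cigarettes per day / 20) x years smoked.

    Accepts scalars or array-likes; missing inputs propagate to missing
    outputs, negative inputs raise.
    """
    cpd_arr = np.asarray(cpd, dtype=float)
    yrs_arr = np.asarray(years_smoked, dtype=float)
    if np.any(cpd_arr[~np.isnan(cpd_arr)] < 0):
        raise ValueError("cigarettes per day must be non-negative")
    if np.any(yrs_arr[~np.isnan(yrs_arr)] < 0):
        raise ValueError("years smoked must be non-negative")
    out = cpd_arr / 20.0 * yrs_arr
    if np.isscalar(cpd) and np.isscalar(years_smoked):
        return float(out)
    return out


def classify_pairs(sheet: pd.DataFrame) -> PairTable:
    """Assign each monozygotic pair to one of the six smoking groups.

    Pairs with anything other than exactly two members with known smoking
    status are listed in the exclusion report rather than silently dropped.
    """
    validate_sample_sheet(sheet)
    rows, excl = [], []
    for pair_id, members in sheet.groupby("pair_id", sort=True):
        if len(members) != 2:
            excl.append({"pair_id": pair_id, "reason": f"{len(members)} samples"})
            continue
        members = members.sort_values("sample_id")
        statuses = members["smoking_status"]
        if statuses.isna().any():
            excl.append({"pair_id": pair_id, "reason": "missing smoking status"})
            continue
        group = _STATUS_PAIR_TO_GROUP[frozenset(statuses)]
        exposed = None
        if group in (
            "discordant_current_never",
            "discordant_current_former",
        ):
            exposed = members.loc[statuses == "current", "sample_id"].iloc[0]
        elif group == "discordant_former_never":
            exposed = members.loc[statuses == "former", "sample_id"].iloc[0]
        rows.append(
            {
                "pair_id": pair_id,
                "sample_id_a": members["sample_id"].iloc[0],
                "sample_id_b": members["sample_id"].iloc[1],
                "group": group,
                "exposed_member": exposed,
            }
        )
    table = pd.DataFrame(
        rows, columns=["pair_id", "sample_id_a", "sample_id_b", "group", "exposed_member"]
    )
    return PairTable(table=table, exclusions=pd.DataFrame(excl, columns=["pair_id", "reason"]))


def flag_cotinine_inconsistency(
    sheet: pd.DataFrame, threshold: float = 15.0
) -> pd.Series:
    """Flag self-reported never smokers whose plasma cotinine indicates smoking.

    Cotinine >= ``threshold`` ng/ml in a never smoker is biochemical evidence
    of misclassified smoking status.  Missing cotinine gives a missing flag.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    never = sheet["smoking_status"] == "never"
    flag = never & (sheet["cotinine"] >= threshold)
    out = flag.astype("boolean")
    out[sheet["cotinine"].isna()] = pd.NA
    out.index = sheet["sample_id"]
    out.name = "cotinine_inconsistent"
    return out


# ---------------------------------------------------------------------------
# Covariate residualization
# ---------------------------------------------------------------------------

def build_design(
    sheet: pd.DataFrame, covariates=DEFAULT_COVARIATES
) -> pd.DataFrame:
    """Design matrix (intercept + dummy-coded categoricals + numeric columns).

    Dummy coding drops the first level by sorted label; any full-rank coding
    gives identical residuals, this one is fixed for reproducibility.
    """
    parts = [pd.Series(1.0, index=sheet.index, name="intercept")]
    for cov in covariates:
        if cov not in sheet.columns:
            raise ValueError(f"covariate column {cov!r} not in sample sheet")
        col = sheet[cov]
        if cov in _CATEGORICAL_COVARIATES or col.dtype == object:
            levels = sorted(col.astype(str).unique())
            if len(levels) < 2:
                raise ValueError(f"covariate {cov!r} is constant")
            dummies = pd.get_dummies(
                pd.Categorical(col.astype(str), categories=levels),
                prefix=cov,
                drop_first=True,
                dtype=float,
            )
            dummies.index = sheet.index
            parts.append(dummies)
        else:
            if col.nunique(dropna=True) < 2:
                raise ValueError(f"covariate {cov!r} is constant")
            parts.append(col.astype(float))
    design = pd.concat(parts, axis=1)
    design.index = sheet["sample_id"].to_numpy()
    return design


def _check_full_rank(X: np.ndarray, names) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR
        _, r, piv = __import__("scipy.linalg", fromlist=["qr"]).qr(
            X, mode="economic", pivoting=True
        )
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        collinear = [names[j] for j in piv[diag < tol]] if np.any(diag < tol) else list(
            names[rank:]
        )
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")


def residualize(
    matrix: MethylationMatrix,
    sheet: pd.DataFrame,
    covariates=DEFAULT_COVARIATES,
) -> ResidualMatrix:
    """OLS residuals of each CpG's beta-values on the covariate design.

    The fit is global (all samples at once).  CpGs with missing values are
    fitted on complete cases, with the complete-case count recorded.
    """
    sheet = sheet.set_index("sample_id", drop=False).loc[list(matrix.sample_ids)]
    design = build_design(sheet, covariates)
    X = design.to_numpy(dtype=float)
    _check_full_rank(X, list(design.columns))

    B = matrix.beta.to_numpy(dtype=float)
    resid = np.full_like(B, np.nan)
    n_complete = np.full(B.shape[0], X.shape[0], dtype=int)

    complete_rows = ~np.isnan(B).any(axis=1)
    if complete_rows.any():
        Y = B[complete_rows].T  # samples x cpgs
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid[complete_rows] = (Y - X @ coef).T
    for i in np.flatnonzero(~complete_rows):
        ok = ~np.isnan(B[i])
        n_complete[i] = int(ok.sum())
        if n_complete[i] <= X.shape[1]:
            continue  # not enough complete cases: residuals stay missing
        coef, *_ = np.linalg.lstsq(X[ok], B[i, ok], rcond=None)
        resid[i, ok] = B[i, ok] - X[ok] @ coef

    values = pd.DataFrame(resid, index=matrix.beta.index, columns=matrix.beta.columns)
    return ResidualMatrix(
        values=values,
        covariates=tuple(covariates),
        design_columns=tuple(design.columns),
        n_complete=pd.Series(n_complete, index=matrix.beta.index, name="n_complete"),
    )
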