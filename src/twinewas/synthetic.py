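"""Synthetic monozygotic twin-cohort generator.

Emulates the statistical structure the within-pair smoking EWAS assumes:
MZ pairs sharing a pair-level methylation baseline, six smoking
discordance/concordance groups, smoking effects at designated reactive CpGs
with a linear dose-response in cigarettes/day and exponential reversal after
quitting, white-blood-cell composition and plate/row batch effects entering
on the logit scale, and twin-correlated smoking quantity in concordant
current-smoking pairs.

Methylation is simulated on the logit scale, mapped through the inverse
logit, the smoking effect is then added on the beta scale (so the configured
effect size *is* the expected within-pair beta difference at the reference
dose), and values are clipped to [0, 1] (clip count reported).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .preprocess import (
    GROUPS,
    MethylationMatrix,
    PairTable,
    SAMPLE_SHEET_COLUMNS,
    compute_packyears,
)

__all__ = ["CohortConfig", "SyntheticTruth", "smoking_effect", "generate_cohort"]


#: Default pairs per group: the study's own counts.
DEFAULT_PAIRS_PER_GROUP = {
    "discordant_current_never": 53,
    "discordant_former_never": 72,
    "discordant_current_former": 66,
    "concordant_current": 83,
    "concordant_former": 88,
    "concordant_never": 406,
}

_GROUP_STATUS = {
    "discordant_current_never": ("current", "never"),
    "discordant_former_never": ("former", "never"),
    "discordant_current_former": ("current", "former"),
    "concordant_current": ("current", "current"),
    "concordant_former": ("former", "former"),
    "concordant_never": ("never", "never"),
}

_GROUP_AGE = {  # mean, sd of age at blood sampling per group
    "discordant_current_never": (33.0, 8.0),
    "discordant_former_never": (41.0, 13.0),
    "discordant_current_former": (42.0, 12.5),
    "concordant_current": (34.0, 10.4),
    "concordant_former": (45.0, 13.4),
    "concordant_never": (33.0, 11.2),
}

_GROUP_QUIT = {  # mean, sd of years since quitting for former smokers
    "discordant_former_never": (13.5, 11.4),
    "discordant_current_former": (9.0, 10.2),
    "concordant_former": (12.7, 10.5),
}


@dataclass
class BatchConfig:
    """Plate and array-row technical effects (additive, logit scale)."""

    n_plates: int = 8
    n_rows: int = 6
    plate_sd_logit: float = 0.05
    row_sd_logit: float = 0.03


@dataclass
class CellConfig:
    """White-blood-cell composition: percentage means/SDs and smoking shift.

    ``smoking_shift`` is added to the neutrophil percentage (and subtracted
    from lymphocytes) of current smokers; ``effect_sd_logit`` is the SD of
    the per-CpG logit-scale coefficient per percentage point for the three
    cell types later used as covariates (neutrophils, monocytes,
    eosinophils), so residualization is exercised non-trivially.
    """

    neutrophil: tuple[float, float] = (53.0, 9.0)
    lymphocyte_resid_sd: float = 3.0  # lymph ~ 90 - neut + noise (r ~ -0.95)
    monocyte: tuple[float, float] = (8.4, 2.1)
    eosinophil: tuple[float, float] = (3.1, 2.0)
    basophil: tuple[float, float] = (0.5, 0.6)
    smoking_shift: float = 1.3
    effect_sd_logit: float = 0.02


@dataclass
class CohortConfig:
    """Parameters of the synthetic twin cohort.

    ``delta_max`` is the beta-scale within-pair effect a current smoker at
    the reference dose (``dose_ref`` cigarettes/day) carries at each reactive
    CpG; ``tau`` is the exponential time constant (years) of reversal after
    quitting; ``twin_r_cpd`` is the target within-pair correlation of
    cigarettes/day in concordant current-smoking pairs.
    """

    n_pairs_per_group: dict = field(
        default_factory=lambda: dict(DEFAULT_PAIRS_PER_GROUP)
    )
    n_cpgs: int = 2000
    n_reactive_cpgs: int = 13
    delta_max: float = 0.13
    dose_ref: float = 10.0
    tau: float = 4.2
    twin_r_cpd: float = 0.50
    noise_sd_logit: float = 0.14
    pair_sd_logit: float = 0.5
    p_hypomethylated: float = 0.6  # fraction of reactive CpGs lower in smokers
    batch: BatchConfig = field(default_factory=BatchConfig)
    cells: CellConfig = field(default_factory=CellConfig)
    detection_fail_rate: float = 0.001
    bead_fail_rate: float = 0.0005
    zero_intensity_rate: float = 0.0001
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.batch, dict):
            self.batch = BatchConfig(**self.batch)
        if isinstance(self.cells, dict):
            self.cells = CellConfig(**self.cells)
        unknown = set(self.n_pairs_per_group) - set(GROUPS)
        if unknown:
            raise ValueError(f"unknown group labels: {sorted(unknown)}")
        if any(v < 0 for v in self.n_pairs_per_group.values()):
            raise ValueError("pair counts must be non-negative")
        if not 0 <= self.delta_max <= 1:
            raise ValueError("delta_max must be in [0, 1]")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if not 0 <= self.twin_r_cpd <= 1:
            raise ValueError("twin_r_cpd must be in [0, 1]")
        if self.n_reactive_cpgs > self.n_cpgs:
            raise ValueError("n_reactive_cpgs exceeds n_cpgs")

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, for parameter-recovery tests.

    ``cpg`` has one row per CpG (``is_reactive``, ``delta``, ``direction``:
    +1 if smoking raises methylation, -1 if it lowers it); ``sample`` has one
    row per sample with the realized exposure effect magnitude (beta scale).
    The effect applied to sample *s* at reactive CpG *j* is
    ``direction[j] * effect[s]``.
    """

    cpg: pd.DataFrame
    sample: pd.DataFrame
    n_clipped: int = 0


def smoking_effect(status, cpd, years_quit, delta, dose_ref, tau):
    """Beta-scale smoking effect magnitude for a sample.

    Never smokers carry no effect; current smokers carry
    ``delta * min(cpd / dose_ref, 2)`` (linear dose-response capped at twice
    the reference dose); former smokers carry the current-smoker effect
    decayed by ``exp(-years_quit / tau)``.  The sign is applied downstream
    per CpG.  Vectorized over status/cpd/years_quit.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if dose_ref <= 0 or tau <= 0:
        raise ValueError("dose_ref and tau must be positive")
    status_arr = np.atleast_1d(np.asarray(status, dtype=object))
    cpd_arr = np.broadcast_to(
        np.atleast_1d(np.asarray(cpd, dtype=float)), status_arr.shape
    )
    yq_arr = np.broadcast_to(
        np.atleast_1d(np.asarray(years_quit, dtype=float)), status_arr.shape
    )
    unknown = ~np.isin(status_arr, ("never", "former", "current"))
    if unknown.any():
        raise ValueError(f"unknown smoking status: {status_arr[unknown][:3]}")
    smoker = status_arr != "never"
    if np.any(cpd_arr[smoker] < 0):
        raise ValueError("cigarettes per day must be non-negative")
    former = status_arr == "former"
    if np.any(np.isnan(yq_arr[former])) or np.any(yq_arr[former] < 0):
        raise ValueError("former smokers require years_quit >= 0")

    effect = np.zeros(status_arr.shape, dtype=float)
    dose = delta * np.minimum(cpd_arr / dose_ref, 2.0)
    effect[status_arr == "current"] = dose[status_arr == "current"]
    effect[former] = dose[former] * np.exp(-yq_arr[former] / tau)
    if np.isscalar(status) or (isinstance(status, str)):
        return float(effect[0])
    return effect


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and SD."""
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def _correlated_pair(rng, n, mean, sd, r):
    """Co-twin draws from a bivariate lognormal with Pearson correlation r.

    The latent Gaussian correlation rho is chosen so the *observed* Pearson
    correlation of the lognormal values equals r:
    r = (exp(rho * s2) - 1) / (exp(s2) - 1), inverted in closed form.
    """
    mu, sigma = _lognormal_params(mean, sd)
    s2 = sigma**2
    rho = np.log1p(r * np.expm1(s2)) / s2
    z = rng.multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n)
    return np.exp(mu + sigma * z)


def _gamma_from_mean_sd(rng, n, mean, sd, lo, hi):
    k = (mean / sd) ** 2
    theta = mean / k
    return np.clip(rng.gamma(k, theta, size=n), lo, hi)


def generate_cohort(
    config: CohortConfig,
) -> tuple[MethylationMatrix, pd.DataFrame, PairTable, SyntheticTruth]:
    """Generate a full synthetic cohort.

    Returns the methylation matrix (with QC companion matrices and CpG
    annotation), the sample sheet, the pair table, and the ground truth.
    Identical seeds give bit-identical output.
    """
    n_total_pairs = sum(config.n_pairs_per_group.get(g, 0) for g in GROUPS)
    if n_total_pairs == 0:
        raise ValueError("empty cohort: zero pairs in every group")
    rng = np.random.default_rng(config.seed)

    # ----- samples and phenotypes ---------------------------------------
    records = []
    pair_idx = 0
    for group in GROUPS:
        n_pairs = config.n_pairs_per_group.get(group, 0)
        status_a, status_b = _GROUP_STATUS[group]
        age_mu, age_sd = _GROUP_AGE[group]
        for _ in range(n_pairs):
            pair_id = f"P{pair_idx:05d}"
            pair_idx += 1
            age = float(np.clip(rng.normal(age_mu, age_sd), 18, 78))
            sex = "F" if rng.random() < 0.7 else "M"
            statuses = [status_a, status_b]
            if status_a != status_b and rng.random() < 0.5:
                statuses = [status_b, status_a]  # which twin label is exposed

            # correlated cigarettes/day for concordant current pairs
            cc_cpd = None
            if group == "concordant_current":
                cc_cpd = _correlated_pair(
                    rng, 1, 11.0, 7.0, config.twin_r_cpd
                )[0]

            for member, status in enumerate(statuses):
                rec = {
                    "sample_id": f"{pair_id}_{member + 1}",
                    "pair_id": pair_id,
                    "smoking_status": status,
                    "age": round(age, 1),
                    "sex": sex,
                    "bmi": round(float(rng.normal(24.0, 3.6)), 1),
                }
                cpd = years_smoked = years_quit = np.nan
                if status == "current":
                    cpd = (
                        cc_cpd[member]
                        if cc_cpd is not None
                        else float(rng.lognormal(*_lognormal_params(8.9, 6.4)))
                    )
                    years_smoked = float(
                        np.clip(rng.normal(age - 18.0, 4.0), 1.0, age - 14.0)
                    )
                elif status == "former":
                    quit_mu, quit_sd = _GROUP_QUIT.get(group, (12.0, 10.0))
                    years_quit = float(
                        _gamma_from_mean_sd(rng, 1, quit_mu, quit_sd, 0.02, 50.0)[0]
                    )
                    cpd = float(rng.lognormal(*_lognormal_params(10.0, 7.0)))
                    years_smoked = float(
                        np.clip(
                            rng.normal(age - 18.0 - years_quit, 4.0),
                            1.0,
                            max(age - 14.0 - years_quit, 1.0),
                        )
                    )
                rec["cigarettes_per_day"] = cpd
                rec["years_smoked"] = years_smoked
                rec["years_since_quit"] = years_quit
                rec["packyears"] = (
                    compute_packyears(cpd, years_smoked)
                    if not np.isnan(cpd)
                    else np.nan
                )
                # plasma cotinine: ~25 ng/ml per cigarette/day in current
                # smokers with lognormal noise; near zero otherwise
                if status == "current":
                    rec["cotinine"] = float(
                        25.0 * cpd * np.exp(rng.normal(-0.125, 0.5))
                    )
                else:
                    rec["cotinine"] = float(abs(rng.normal(1.0, 1.2)))
                records.append(rec)

    sheet = pd.DataFrame(records)
    n_samples = len(sheet)

    # cell composition (percentages); smokers shifted toward neutrophils
    cells = config.cells
    neut = rng.normal(*cells.neutrophil, size=n_samples)
    shift = np.where(
        sheet["smoking_status"].to_numpy() == "current", cells.smoking_shift, 0.0
    )
    neut = neut + shift
    lymph = 90.0 - neut + rng.normal(0.0, cells.lymphocyte_resid_sd, size=n_samples)
    mono = np.clip(rng.normal(*cells.monocyte, size=n_samples), 0.5, None)
    eos = np.clip(rng.normal(*cells.eosinophil, size=n_samples), 0.0, None)
    baso = np.abs(rng.normal(*cells.basophil, size=n_samples))
    sheet["neutrophil_pct"] = np.round(np.clip(neut, 20, 85), 1)
    sheet["lymphocyte_pct"] = np.round(np.clip(lymph, 5, 70), 1)
    sheet["monocyte_pct"] = np.round(mono, 1)
    sheet["eosinophil_pct"] = np.round(eos, 1)
    sheet["basophil_pct"] = np.round(baso, 1)

    batch = config.batch
    sheet["plate"] = [
        f"plate{p + 1:02d}" for p in rng.integers(0, batch.n_plates, size=n_samples)
    ]
    sheet["array_row"] = [
        f"R{r + 1:02d}" for r in rng.integers(0, batch.n_rows, size=n_samples)
    ]
    sheet = sheet[list(SAMPLE_SHEET_COLUMNS)]

    # ----- CpGs ----------------------------------------------------------
    m = config.n_cpgs
    cpg_ids = np.array([f"cg{j:08d}" for j in range(m)])
    reactive = np.zeros(m, dtype=bool)
    reactive[rng.choice(m, size=config.n_reactive_cpgs, replace=False)] = True
    direction = np.where(
        rng.random(m) < config.p_hypomethylated, -1.0, 1.0
    )  # applied at reactive CpGs only
    delta = np.where(reactive, config.delta_max, 0.0)

    # bimodal baseline on the logit scale; reactive CpGs intermediate so the
    # beta-scale effect has headroom
    comp = rng.choice(3, size=m, p=[0.45, 0.45, 0.10])
    base = np.where(
        comp == 0,
        rng.normal(-2.5, 0.7, size=m),
        np.where(comp == 1, rng.normal(2.5, 0.7, size=m), rng.normal(0.0, 1.0, size=m)),
    )
    base[reactive] = rng.normal(0.0, 0.4, size=config.n_reactive_cpgs)

    chrom = rng.integers(1, 23, size=m).astype(str)
    pos = rng.integers(1, 2_400_000_00, size=m)
    gene = np.where(rng.random(m) < 0.6, [f"GENE{j % 997:04d}" for j in range(m)], "")
    annotation = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "gene": gene}, index=pd.Index(cpg_ids, name="cpg_id")
    )

    # ----- latent methylation --------------------------------------------
    pair_codes = pd.Categorical(sheet["pair_id"]).codes
    plate_codes = pd.Categorical(sheet["plate"]).codes
    row_codes = pd.Categorical(sheet["array_row"]).codes
    n_pairs = pair_codes.max() + 1

    pair_base = rng.normal(0.0, config.pair_sd_logit, size=(m, n_pairs))
    plate_eff = rng.normal(0.0, batch.plate_sd_logit, size=(m, plate_codes.max() + 1))
    row_eff = rng.normal(0.0, batch.row_sd_logit, size=(m, row_codes.max() + 1))
    cell_coef = rng.normal(0.0, cells.effect_sd_logit, size=(m, 3))
    cell_mat = sheet[["neutrophil_pct", "monocyte_pct", "eosinophil_pct"]].to_numpy().T
    cell_term = cell_coef @ (cell_mat - cell_mat.mean(axis=1, keepdims=True))
    noise = rng.normal(0.0, config.noise_sd_logit, size=(m, n_samples))

    mu = (
        base[:, None]
        + pair_base[:, pair_codes]
        + plate_eff[:, plate_codes]
        + row_eff[:, row_codes]
        + cell_term
        + noise
    )
    beta0 = expit(mu)

    effect = smoking_effect(
        sheet["smoking_status"].to_numpy(),
        sheet["cigarettes_per_day"].to_numpy(),
        sheet["years_since_quit"].to_numpy(),
        config.delta_max,
        config.dose_ref,
        config.tau,
    )
    applied = (direction * reactive)[:, None] * effect[None, :]
    raw = beta0 + applied
    n_clipped = int(((raw < 0) | (raw > 1)).sum())
    beta = np.clip(raw, 0.0, 1.0)

    sample_ids = sheet["sample_id"].to_numpy()
    beta_df = pd.DataFrame(beta, index=annotation.index, columns=sample_ids)

    # QC companion matrices with rare injected failures
    det = np.full((m, n_samples), 0.001)
    det[rng.random((m, n_samples)) < config.detection_fail_rate] = 0.02
    beads = np.full((m, n_samples), 10.0)
    beads[rng.random((m, n_samples)) < config.bead_fail_rate] = 2.0
    inten = np.full((m, n_samples), 1000.0)
    inten[rng.random((m, n_samples)) < config.zero_intensity_rate] = 0.0

    matrix = MethylationMatrix(
        beta=beta_df,
        annotation=annotation,
        detection_p=pd.DataFrame(det, index=annotation.index, columns=sample_ids),
        beads=pd.DataFrame(beads, index=annotation.index, columns=sample_ids),
        intensity=pd.DataFrame(inten, index=annotation.index, columns=sample_ids),
    )

    from .preprocess import classify_pairs  # deterministic pair classification

    pair_table = classify_pairs(sheet)
    truth = SyntheticTruth(
        cpg=pd.DataFrame(
            {
                "is_reactive": reactive,
                "delta": delta,
                "direction": np.where(reactive, direction, 0.0),
            },
            index=annotation.index,
        ),
        sample=pd.DataFrame(
            {"sample_id": sample_ids, "exposure_effect": effect}
        ).set_index("sample_id"),
        n_clipped=n_clipped,
    )
    return matrix, sheet, pair_table, truth
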