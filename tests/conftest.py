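import numpy as np
import pandas as pd
import pytest

from twinewas import CohortConfig, generate_cohort, residualize, within_pair_differences
from twinewas.preprocess import MethylationMatrix, PairTable, ResidualMatrix


def identity_residuals(matrix: MethylationMatrix) -> ResidualMatrix:
    """Wrap raw beta-values as a residual matrix (no covariate adjustment)."""
    return ResidualMatrix(values=matrix.beta, covariates=(), design_columns=())


@pytest.fixture(scope="session")
def default_cohort():
    """One full six-group synthetic cohort with residuals and group diffs."""
    cfg = CohortConfig(n_cpgs=200, seed=42)
    matrix, sheet, pairs, truth = generate_cohort(cfg)
    resid = residualize(matrix, sheet)
    groups = (
        "discordant_current_never",
        "discordant_former_never",
        "discordant_current_former",
        "concordant_current",
        "concordant_never",
    )
    diffs = {g: within_pair_differences(resid, pairs, g) for g in groups}
    return {
        "config": cfg,
        "matrix": matrix,
        "sheet": sheet,
        "pairs": pairs,
        "truth": truth,
        "resid": resid,
        "diffs": diffs,
    }


def toy_matrix(beta, det=None, beads=None, inten=None, cpgs=None, samples=None):
    """Build a MethylationMatrix from arrays, with good-by-default companions."""
    beta = np.asarray(beta, dtype=float)
    m, n = beta.shape
    cpgs = cpgs or [f"cg{i:03d}" for i in range(m)]
    samples = samples or [f"s{j}" for j in range(n)]

    def _df(a, fill):
        arr = np.full((m, n), fill, dtype=float) if a is None else np.asarray(a, float)
        return pd.DataFrame(arr, index=cpgs, columns=samples)

    return MethylationMatrix(
        beta=pd.DataFrame(beta, index=cpgs, columns=samples),
        detection_p=_df(det, 0.001),
        beads=_df(beads, 10.0),
        intensity=_df(inten, 1000.0),
    )


def toy_pairs(rows):
    """PairTable from (pair_id, a, b, group, exposed) tuples."""
    return PairTable(
        table=pd.DataFrame(
            rows,
            columns=["pair_id", "sample_id_a", "sample_id_b", "group", "exposed_member"],
        )
    )
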