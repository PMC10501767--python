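"""Filtering rules, phenotype derivations, pair classification, residualization."""

import numpy as np
import pandas as pd
import pytest

from twinewas import (
    classify_pairs,
    compute_packyears,
    filter_probes,
    flag_cotinine_inconsistency,
    residualize,
)
from twinewas.preprocess import MethylationMatrix, build_design, validate_sample_sheet

from conftest import toy_matrix


class TestFilterProbes:
    def test_probe_failing_detection_everywhere_is_dropped(self):
        det = np.full((5, 4), 0.001)
        det[2, :] = 0.02  # probe fails detection in every sample
        m = toy_matrix(np.full((5, 4), 0.5), det=det)
        out, report = filter_probes(m)
        assert out.beta.shape == (4, 4)
        assert report.n_detection_failed == 4
        assert report.probes_dropped == ["cg002"]
        assert report.n_samples_dropped == 0

    def test_clean_input_passes_unchanged(self):
        m = toy_matrix(np.random.default_rng(0).uniform(size=(5, 4)))
        out, report = filter_probes(m)
        assert np.array_equal(out.beta.to_numpy(), m.beta.to_numpy())
        assert report.n_probes_dropped == report.n_samples_dropped == 0

    def test_bad_sample_dropped_at_success_rate_step(self):
        # 25 CpGs x 21 samples; one sample fails detection at 96% of probes
        det = np.full((25, 21), 0.001)
        det[:24, 0] = 0.02
        m = toy_matrix(np.full((25, 21), 0.5), det=det)
        out, report = filter_probes(m)
        # probes keep success 20/21 > 95%, the sample drops at 1/25 < 95%
        assert report.n_probes_dropped == 0
        assert report.samples_dropped == ["s0"]
        assert out.beta.shape == (25, 20)

    def test_zero_intensity_and_bead_rules(self):
        # 40 CpGs so one failing measurement leaves sample success above 95%
        inten = np.full((40, 20), 1000.0)
        inten[0, 0] = 0.0
        beads = np.full((40, 20), 10.0)
        beads[1, 1] = 2.0
        m = toy_matrix(np.full((40, 20), 0.5), inten=inten, beads=beads)
        out, report = filter_probes(m)
        assert report.n_zero_intensity == 1
        assert report.n_bead_failed == 1
        assert report.n_samples_dropped == 0
        assert np.isnan(out.beta.iloc[0, 0]) and np.isnan(out.beta.iloc[1, 1])

    def test_idempotent(self):
        det = np.full((25, 21), 0.001)
        det[:24, 0] = 0.02
        m = toy_matrix(np.random.default_rng(1).uniform(size=(25, 21)), det=det)
        once, _ = filter_probes(m)
        twice, rep2 = filter_probes(once)
        assert np.array_equal(
            once.beta.to_numpy(), twice.beta.to_numpy(), equal_nan=True
        )
        assert rep2.n_probes_dropped == rep2.n_samples_dropped == 0

    def test_missing_companion_is_configuration_error(self):
        m = MethylationMatrix(beta=pd.DataFrame([[0.5]], index=["cg0"], columns=["s0"]))
        with pytest.raises(ValueError, match="companion"):
            filter_probes(m)
        # explicit disabling skips the rules
        out, _ = filter_probes(m, detection_p_max=None, bead_min=None,
                               drop_zero_intensity=False)
        assert out.beta.shape == (1, 1)


class TestPackyears:
    @pytest.mark.parametrize(
        "cpd,years,expected", [(20, 10, 10.0), (0, 30, 0.0), (15, 20, 15.0)]
    )
    def test_formula(self, cpd, years, expected):
        assert compute_packyears(cpd, years) == pytest.approx(expected)

    def test_missing_propagates(self):
        assert np.isnan(compute_packyears(np.nan, 10))

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            compute_packyears(-5, 10)
        with pytest.raises(ValueError):
            compute_packyears(5, -10)


def _sheet(rows):
    df = pd.DataFrame(rows, columns=["sample_id", "pair_id", "smoking_status", "cotinine"])
    return df


class TestClassifyPairs:
    def test_six_group_assignment_and_exposed_member(self):
        sheet = _sheet([
            ("a1", "p1", "never", 1), ("a2", "p1", "never", 2),
            ("b1", "p2", "current", 200), ("b2", "p2", "never", 1),
            ("c1", "p3", "current", 250), ("c2", "p3", "former", 5),
            ("d1", "p4", "former", 2), ("d2", "p4", "never", 0),
            ("e1", "p5", "current", 180), ("e2", "p5", "current", 300),
            ("f1", "p6", "former", 1), ("f2", "p6", "former", 2),
        ])
        pt = classify_pairs(sheet)
        got = pt.table.set_index("pair_id")
        assert got.loc["p1", "group"] == "concordant_never"
        assert got.loc["p2", "group"] == "discordant_current_never"
        assert got.loc["p2", "exposed_member"] == "b1"
        assert got.loc["p3", "group"] == "discordant_current_former"
        assert got.loc["p3", "exposed_member"] == "c1"
        assert got.loc["p4", "group"] == "discordant_former_never"
        assert got.loc["p4", "exposed_member"] == "d1"
        assert got.loc["p5", "group"] == "concordant_current"
        assert pd.isna(got.loc["p5", "exposed_member"])
        assert got.loc["p6", "group"] == "concordant_former"
        # partition: every valid pair lands in exactly one group
        assert pt.group_counts().sum() == 6

    def test_malformed_pairs_reported_not_dropped_silently(self):
        sheet = _sheet([
            ("a1", "p1", "never", 1),
            ("b1", "p2", "current", 100), ("b2", "p2", None, 1),
            ("c1", "p3", "never", 1), ("c2", "p3", "never", 1),
        ])
        pt = classify_pairs(sheet)
        assert len(pt.table) == 1
        assert set(pt.exclusions["pair_id"]) == {"p1", "p2"}


class TestCotinineFlag:
    def test_threshold_rule(self):
        sheet = _sheet([
            ("a", "p1", "never", 16.0),
            ("b", "p1", "never", 15.0),
            ("c", "p2", "never", 14.9),
            ("d", "p2", "current", 300.0),
            ("e", "p3", "never", np.nan),
            ("f", "p3", "former", 20.0),
        ])
        flags = flag_cotinine_inconsistency(sheet)
        assert flags["a"] == True  # noqa: E712 - nullable boolean
        assert flags["b"] == True  # noqa: E712 - inclusive boundary
        assert flags["c"] == False  # noqa: E712
        assert flags["d"] == False  # noqa: E712
        assert pd.isna(flags["e"])

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            flag_cotinine_inconsistency(_sheet([("a", "p", "never", 1)]), threshold=0)


def _matrix_and_sheet(beta, covs):
    n = beta.shape[1]
    samples = [f"s{j}" for j in range(n)]
    m = MethylationMatrix(
        beta=pd.DataFrame(beta, index=[f"cg{i}" for i in range(beta.shape[0])],
                          columns=samples)
    )
    sheet = pd.DataFrame({"sample_id": samples, **covs})
    return m, sheet


class TestResidualize:
    def test_perfect_linear_fit_gives_zero_residuals(self):
        beta = np.array([[0.1, 0.2, 0.3, 0.4]])
        m, sheet = _matrix_and_sheet(beta, {"x": [0.0, 1.0, 2.0, 3.0]})
        res = residualize(m, sheet, ("x",))
        assert np.allclose(res.values.to_numpy(), 0.0, atol=1e-12)

    def test_residual_mean_zero_and_orthogonality(self):
        rng = np.random.default_rng(4)
        beta = rng.uniform(0.2, 0.8, size=(12, 30))
        covs = {
            "x": rng.normal(size=30),
            "plate": rng.choice(["A", "B", "C"], size=30),
        }
        m, sheet = _matrix_and_sheet(beta, covs)
        res = residualize(m, sheet, ("plate", "x"))
        r = res.values.to_numpy()
        assert np.max(np.abs(r.mean(axis=1))) < 1e-10
        design = build_design(sheet.set_index("sample_id", drop=False), ("plate", "x"))
        dots = np.abs(r @ design.to_numpy()) / r.shape[1]
        assert dots.max() < 1e-8

    def test_matches_normal_equations_oracle(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            beta = rng.uniform(size=(10, 8))
            covs = {"x1": rng.normal(size=8), "x2": rng.normal(size=8)}
            m, sheet = _matrix_and_sheet(beta, covs)
            res = residualize(m, sheet, ("x1", "x2"))
            X = np.column_stack([np.ones(8), covs["x1"], covs["x2"]])
            coef = np.linalg.solve(X.T @ X, X.T @ beta.T)
            expected = beta - (X @ coef).T
            assert np.max(np.abs(res.values.to_numpy() - expected)) < 1e-8

    def test_rank_deficient_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        m, sheet = _matrix_and_sheet(rng.uniform(size=(3, 10)),
                                     {"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="collinear"):
            residualize(m, sheet, ("x1", "x2"))

    def test_constant_covariate_rejected(self):
        m, sheet = _matrix_and_sheet(np.random.default_rng(1).uniform(size=(2, 6)),
                                     {"x": [1.0] * 6})
        with pytest.raises(ValueError, match="constant"):
            residualize(m, sheet, ("x",))

    def test_missing_values_fit_on_complete_cases(self):
        rng = np.random.default_rng(2)
        beta = rng.uniform(size=(4, 12))
        beta[1, 3] = np.nan
        m, sheet = _matrix_and_sheet(beta, {"x": rng.normal(size=12)})
        res = residualize(m, sheet, ("x",))
        assert res.n_complete["cg1"] == 11
        assert res.n_complete["cg0"] == 12
        row = res.values.loc["cg1"].to_numpy()
        assert np.isnan(row[3])
        assert abs(np.nanmean(row)) < 1e-10


def test_sample_sheet_validation():
    with pytest.raises(ValueError, match="missing columns"):
        validate_sample_sheet(pd.DataFrame({"sample_id": ["a"]}))
    bad = pd.DataFrame(
        {"sample_id": ["a"], "pair_id": ["p"], "smoking_status": ["sometimes"]}
    )
    with pytest.raises(ValueError, match="smoking_status"):
        validate_sample_sheet(bad)
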