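import numpy as np
import pandas as pd
import pytest

from ctaging import (
    ClockPanel,
    age_acceleration,
    calibrate_clock,
    raw_clock_score,
    run_clock,
)
from ctaging import test_group_acceleration as group_acceleration_test  # avoid pytest collection
from ctaging.io import PseudobulkAssay, filter_pseudobulk_genes, preset_params


class TestRawScore:
    def test_two_term_sum(self):
        expr = pd.DataFrame({"d1": [3.0, 4.0]}, index=["gA", "gB"])
        panel = ClockPanel(pd.Series({"gA": 2.0, "gB": -1.0}))
        score, coverage = raw_clock_score(expr, panel)
        assert score["d1"] == 2.0
        assert coverage == (2, 2)

    def test_missing_panel_gene_dropped(self):
        expr = pd.DataFrame({"d1": [3.0]}, index=["gA"])
        panel = ClockPanel(pd.Series({"gA": 2.0, "gMissing": 5.0}))
        score, coverage = raw_clock_score(expr, panel)
        assert score["d1"] == 6.0
        assert coverage == (1, 2)

    def test_no_match_is_error(self):
        expr = pd.DataFrame({"d1": [3.0]}, index=["gA"])
        with pytest.raises(ValueError, match="no panel gene"):
            raw_clock_score(expr, ClockPanel(pd.Series({"gX": 1.0})))

    def test_matches_matrix_vector_oracle(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            rng.normal(0, 1, (100, 20)),
            index=[f"g{i}" for i in range(100)],
            columns=[f"d{i}" for i in range(20)],
        )
        w = pd.Series(rng.normal(0, 1, 100), index=expr.index)
        score, _ = raw_clock_score(expr, ClockPanel(w))
        oracle = expr.to_numpy().T @ w.to_numpy()
        assert np.allclose(score.to_numpy(), oracle, atol=1e-12)


class TestCalibration:
    def test_identity(self):
        ages = np.array([30.0, 40, 50, 60])
        raw = pd.Series(ages, index=list("abcd"))
        slope, intercept, cal = calibrate_clock(raw, ages)
        assert np.isclose(slope, 1) and np.isclose(intercept, 0, atol=1e-10)
        assert np.allclose(cal.to_numpy(), ages)

    def test_affine_recovery(self):
        ages = np.array([30.0, 40, 50, 60, 70])
        raw = pd.Series(2 * ages + 10, index=list("abcde"))
        _, _, cal = calibrate_clock(raw, ages)
        assert np.allclose(cal.to_numpy(), ages, atol=1e-10)

    def test_affine_invariance(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(26, 84, 30)
        raw = pd.Series(0.3 * ages + rng.normal(0, 2, 30), index=[f"d{i}" for i in range(30)])
        _, _, cal1 = calibrate_clock(raw, ages)
        _, _, cal2 = calibrate_clock(5 * raw - 7, ages)
        assert np.allclose(cal1.to_numpy(), cal2.to_numpy(), atol=1e-8)

    def test_noisy_simulation_correlates(self):
        rng = np.random.default_rng(2)
        ages = rng.uniform(26, 84, 60)
        raw = pd.Series(0.5 * ages + rng.normal(0, 3, 60), index=[f"d{i}" for i in range(60)])
        _, _, cal = calibrate_clock(raw, ages)
        assert np.corrcoef(cal.to_numpy(), ages)[0, 1] > 0.9

    def test_constant_scores_are_error(self):
        with pytest.raises(ValueError, match="constant"):
            calibrate_clock(pd.Series([1.0, 1.0, 1.0]), np.array([30.0, 40, 50]))


class TestAcceleration:
    def test_perfect_clock_gives_zero_residuals(self):
        ages = np.array([30.0, 40, 50, 60])
        cal = pd.Series(ages, index=list("abcd"))
        resid = age_acceleration(cal, ages, pd.Series(["B1"] * 4, index=list("abcd")))
        assert np.allclose(resid.to_numpy(), 0, atol=1e-10)

    def test_batch_offset_absorbed(self):
        rng = np.random.default_rng(3)
        ages = rng.uniform(26, 84, 40)
        batch = np.where(np.arange(40) % 2 == 0, "B1", "B2")
        cal = ages + np.where(batch == "B2", 5.0, 0.0)
        resid = age_acceleration(
            pd.Series(cal, index=[f"d{i}" for i in range(40)]), ages, pd.Series(batch)
        )
        assert np.abs(resid.to_numpy()).max() < 1e-8

    def test_disease_offset_survives_batch_adjustment(self):
        rng = np.random.default_rng(4)
        n = 60
        ages = rng.uniform(26, 84, n)
        disease = rng.integers(0, 2, n)
        batch = rng.choice(["B1", "B2"], n)
        cal = ages + 5.0 * disease + rng.normal(0, 0.5, n)
        resid = age_acceleration(pd.Series(cal, index=[f"d{i}" for i in range(n)]), ages, pd.Series(batch))
        diff = resid.to_numpy()[disease == 1].mean() - resid.to_numpy()[disease == 0].mean()
        assert abs(diff - 5.0) < 1.0

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(5)
        ages = rng.uniform(26, 84, 30)
        cal = pd.Series(ages + rng.normal(0, 3, 30), index=[f"d{i}" for i in range(30)])
        batch = pd.Series(rng.choice(["B1", "B2"], 30))
        resid = age_acceleration(cal, ages, batch)
        r = resid.to_numpy()
        assert abs(r @ (ages - ages.mean())) < 1e-6
        assert abs(r[(batch == "B1").to_numpy()].sum()) < 1e-6


def _donor_table(n, rng, with_pc1=True):
    t = pd.DataFrame(
        {
            "donor_id": [f"d{i}" for i in range(n)],
            "age": rng.uniform(26, 84, n),
            "disease_status": rng.integers(0, 2, n),
            "sex": rng.choice(["F", "M"], n),
            "pH": rng.normal(6.5, 0.2, n),
            "RIN": rng.normal(7.5, 1, n),
            "PMI": rng.normal(30, 8, n),
            "lib_batch": rng.choice(["B1", "B2"], n),
        }
    )
    if with_pc1:
        t["PC1"] = rng.normal(0, 1, n)
    return t


class TestGroupTest:
    def test_planted_offset_estimated(self):
        rng = np.random.default_rng(6)
        donors = _donor_table(60, rng)
        resid = pd.Series(
            5.0 * donors["disease_status"].to_numpy() + rng.normal(0, 3, 60),
            index=donors["donor_id"],
        )
        resid = resid - resid.mean()
        out = group_acceleration_test(resid, donors)
        row = out.set_index("term").loc["disease_status"]
        assert 3.0 < row["estimate"] < 7.0
        assert row["p_value"] < 0.01

    def test_constant_disease_is_error(self):
        rng = np.random.default_rng(7)
        donors = _donor_table(20, rng)
        donors["disease_status"] = 1
        with pytest.raises(ValueError, match="constant"):
            group_acceleration_test(pd.Series(np.zeros(20), index=donors["donor_id"]), donors)


class TestEndToEnd:
    def test_planted_acceleration_recovered_from_counts(self, planted_cohort):
        """Full pipeline: simulated counts -> clock -> disease acceleration."""
        from ctaging import aggregate_pseudobulk

        cfg, m, donors, gt = planted_cohort
        full = aggregate_pseudobulk(m, donors, by_cell_type=False)[0]
        viz = filter_pseudobulk_genes(full, **preset_params("viz"))
        panel = ClockPanel(
            pd.Series(gt.clock_panel["weight"].to_numpy(), index=gt.clock_panel["gene_id"])
        )
        res = run_clock(viz, panel)
        assert res.age_correlation_r > 0.8
        row = res.group_test.set_index("term").loc["disease_status"]
        assert 2.0 < row["estimate"] < 8.0  # planted +5 years
        assert row["p_value"] < 0.05
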