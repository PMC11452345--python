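import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats

from ctaging import (
    DesignSpec,
    NucleusCountMatrix,
    aggregate_pseudobulk,
    bh_adjust,
    covariate_corrected_expression,
    design_matrix,
    fit_gene_lm,
    filter_pseudobulk_genes,
    log_cpm,
    preset_params,
    run_de,
    tmm_norm_factors,
    voom_weights,
)


def _donors(n, rng=None, seed=0):
    rng = rng or np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "donor_id": [f"d{i}" for i in range(n)],
            "age": rng.uniform(26, 84, n).round(1),
            "disease_status": rng.integers(0, 2, n),
            "sex": rng.choice(["F", "M"], n),
            "pH": rng.normal(6.5, 0.2, n).round(2),
            "RIN": rng.normal(7.5, 1, n).round(1),
            "PMI": rng.normal(30, 8, n).round(1),
            "lib_batch": rng.choice(["B1", "B2"], n),
        }
    )


class TestTMM:
    def test_identical_donors_give_unit_factors(self):
        counts = np.tile(np.arange(1, 41)[:, None], (1, 4))
        assert np.allclose(tmm_norm_factors(counts), 1.0)

    def test_pure_depth_scaling_gives_unit_factors(self):
        one = np.arange(1, 41)
        counts = np.column_stack([one, 2 * one])
        assert np.allclose(tmm_norm_factors(counts), 1.0)

    def test_composition_bias_detected(self):
        """A donor-specific highly expressed gene shifts factors oppositely."""
        rng = np.random.default_rng(3)
        base = rng.integers(50, 200, 200)
        d1 = base.copy()
        d2 = base.copy()
        d2[0] = 40_000  # dominant donor-specific transcript
        f = tmm_norm_factors(np.column_stack([d1, d2]))
        # shared genes look under-expressed in d2 after depth scaling, so
        # d2's factor falls below 1 and d1's rises above (product 1)
        assert f[1] < 1 < f[0]
        assert np.isclose(f[0] * f[1], 1.0)

    def test_hand_computed_constant_m_case(self):
        """All shared genes proportional: trimmed mean M is exactly log ratio."""
        d1 = np.array([100, 200, 300, 400, 500, 600, 700, 800, 900, 1000, 0], float)
        d2 = np.r_[2.0 * d1[:10], 5000.0]  # plus one d2-only gene
        f = tmm_norm_factors(np.column_stack([d1, d2]))
        # shared-gene proportions: p2/p1 = 2*N1/N2 with N1=5500, N2=16000
        expected_m = np.log2(2 * 5500 / 16000)
        expected_f2 = 2.0**expected_m
        ratio = f[1] / f[0]
        assert np.isclose(np.log2(ratio), expected_m, atol=1e-10)
        assert np.isclose(f[0] * f[1], 1.0)
        assert np.isclose(ratio, expected_f2)

    def test_zero_library_is_error(self):
        with pytest.raises(ValueError, match="zero library"):
            tmm_norm_factors(np.column_stack([np.zeros(5), np.ones(5)]))


class TestLogCPM:
    def test_direct_arithmetic(self):
        counts = np.array([[100.0]])
        # single donor: library is the lone count
        val = log_cpm(counts, factors=np.array([1.0]), prior=0.5)
        assert np.isclose(val[0, 0], np.log2(100.5 / 101 * 1e6))

    def test_reference_value_at_unit_factor(self):
        counts = np.zeros((2, 1))
        counts[0, 0] = 100
        counts[1, 0] = 1e6 - 100
        val = log_cpm(counts)
        assert np.isclose(val[0, 0], 6.6511, atol=1e-3)

    def test_zero_count_is_finite(self):
        assert np.isfinite(log_cpm(np.array([[0.0], [100.0]]))).all()

    def test_depth_doubling_near_invariance_at_high_counts(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(100_000, 300_000, size=(20, 3)).astype(float)
        shift = log_cpm(2 * counts) - log_cpm(counts)
        assert np.abs(shift).max() < 1e-5


class TestVoomWeights:
    def test_homoscedastic_weights_nearly_flat(self):
        rng = np.random.default_rng(1)
        means = rng.uniform(3, 12, 300)
        Y = means[:, None] + rng.normal(0, 0.3, (300, 30))
        counts = np.maximum(2.0 ** Y, 0.1)
        W = voom_weights(Y, counts)
        assert W.max() / W.min() < 2.0

    def test_variance_decreasing_with_mean_gives_increasing_weights(self):
        rng = np.random.default_rng(2)
        means = np.linspace(2, 12, 300)
        sds = np.linspace(0.8, 0.1, 300)  # noisier at low expression
        Y = means[:, None] + rng.normal(0, 1, (300, 30)) * sds[:, None]
        counts = np.maximum(2.0 ** Y, 0.1)
        W = voom_weights(Y, counts)
        per_gene = W.mean(axis=1)
        assert per_gene[200:].mean() > 2 * per_gene[:100].mean()

    def test_degenerate_designs_fall_back_to_unit_weights(self):
        Y = np.outer(np.arange(12), np.ones(3))
        with pytest.warns(UserWarning, match="unit weights"):
            W = voom_weights(Y, 2.0**Y, design=np.eye(3))
        assert np.all(W == 1.0)
        with pytest.warns(UserWarning, match="fewer than 10 genes"):
            W = voom_weights(Y[:3], 2.0 ** Y[:3])
        assert np.all(W == 1.0)


class TestGeneFit:
    def test_noiseless_recovery(self):
        donors = _donors(20)
        X, _ = design_matrix(donors, ["age"])
        y = 0.05 * donors["age"].to_numpy()
        res = fit_gene_lm(y, X, contrast="age")
        assert np.isclose(res["estimate"], 0.05, atol=1e-12)
        assert res["p_value"] < 1e-12

    def test_matches_closed_form_wls_oracle(self):
        rng = np.random.default_rng(4)
        donors = _donors(30, rng)
        X, _ = design_matrix(donors, ["age", "disease_status", "pH"])
        Xv = X.to_numpy(float)
        y = rng.normal(0, 1, 30)
        w = rng.uniform(0.5, 2, 30)
        res = fit_gene_lm(y, X, weights=w, contrast="age")
        Wd = np.diag(w)
        beta = np.linalg.solve(Xv.T @ Wd @ Xv, Xv.T @ Wd @ y)
        resid = y - Xv @ beta
        s2 = (w * resid**2).sum() / (30 - Xv.shape[1])
        se = np.sqrt(s2 * np.linalg.inv(Xv.T @ Wd @ Xv)[1, 1])
        assert np.isclose(res["estimate"], beta[1], atol=1e-10)
        assert np.isclose(res["std_error"], se, atol=1e-10)

    def test_unit_weights_equal_ols(self):
        rng = np.random.default_rng(5)
        donors = _donors(25, rng)
        X, _ = design_matrix(donors, ["age", "sex"])
        y = rng.normal(0, 1, 25)
        res_w = fit_gene_lm(y, X, weights=np.ones(25), contrast="age")
        beta = np.linalg.lstsq(X.to_numpy(float), y, rcond=None)[0]
        assert np.isclose(res_w["estimate"], beta[1], atol=1e-10)

    def test_age_shift_only_moves_intercept(self):
        rng = np.random.default_rng(6)
        donors = _donors(25, rng)
        y = rng.normal(0, 1, 25)
        X1, _ = design_matrix(donors, ["age"])
        shifted = donors.copy()
        shifted["age"] = shifted["age"] + 100
        X2, _ = design_matrix(shifted, ["age"])
        r1 = fit_gene_lm(y, X1, contrast="age")
        r2 = fit_gene_lm(y, X2, contrast="age")
        assert np.isclose(r1["estimate"], r2["estimate"], atol=1e-10)
        assert np.isclose(r1["p_value"], r2["p_value"], atol=1e-10)

    def test_rank_deficient_design_names_columns(self):
        donors = _donors(15)
        donors["age_copy"] = donors["age"]
        X, _ = design_matrix(donors, ["age"])
        X["age_copy"] = X["age"]
        with pytest.raises(ValueError, match="age_copy"):
            fit_gene_lm(np.zeros(15), X, contrast="age")

    def test_null_pvalues_are_uniform(self):
        rng = np.random.default_rng(7)
        donors = _donors(40, rng)
        X, _ = design_matrix(donors, ["age", "disease_status"])
        ps = [fit_gene_lm(rng.normal(0, 1, 40), X, contrast="age")["p_value"] for _ in range(400)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestBH:
    def test_hand_example(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(bh_adjust(p), 0.04)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(0, 1, 200)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_nan_untested(self):
        q = bh_adjust(np.array([0.01, np.nan, 0.5]))
        assert np.isnan(q[1]) and not np.isnan(q[0])


def _sim_assay(donors, betas, seed=0, n_genes=None, base=8.0):
    """Counts whose log2 expression is linear in age with the given slopes."""
    rng = np.random.default_rng(seed)
    age = donors["age"].to_numpy() - donors["age"].mean()
    n_genes = n_genes or len(betas)
    mu = 2.0 ** (base + np.outer(betas, age) + rng.normal(0, 0.1, (n_genes, len(donors))))
    counts = rng.poisson(mu)
    genes = [f"g{i}" for i in range(n_genes)]
    return pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=donors["donor_id"])


def _make_assay(counts_df, donors, cell_type="A"):
    from ctaging.io import PseudobulkAssay

    return PseudobulkAssay(
        cell_type=cell_type,
        counts=counts_df,
        donors=donors.reset_index(drop=True),
        nuclei_contributed=pd.Series(100, index=counts_df.columns),
    )


class TestRunDE:
    def test_fdr_scope_by_contrast(self):
        rng = np.random.default_rng(9)
        donors = _donors(24, rng)
        betas = np.r_[np.full(5, 0.04), np.zeros(45)]
        assays = [
            _make_assay(_sim_assay(donors, betas, seed=i), donors, cell_type=f"CT{i}") for i in range(2)
        ]
        de_age = run_de(assays, DesignSpec(contrast="age", terms=["age", "disease_status", "sex"]))
        # global pool: BH over all rows at once reproduces the fdr column
        assert np.allclose(
            de_age["fdr"].to_numpy(), bh_adjust(de_age["p_value"].to_numpy()), equal_nan=True
        )
        de_dis = run_de(assays, DesignSpec(contrast="disease_status", terms=["age", "disease_status", "sex"]))
        for _, sub in de_dis.groupby("cell_type"):
            assert np.allclose(
                sub["fdr"].to_numpy(), bh_adjust(sub["p_value"].to_numpy()), equal_nan=True
            )

    def test_planted_slopes_recovered(self):
        rng = np.random.default_rng(10)
        donors = _donors(30, rng)
        betas = np.r_[np.full(10, 0.03), np.full(10, -0.03), np.zeros(80)]
        assay = _make_assay(_sim_assay(donors, betas, seed=1), donors)
        de = run_de([assay], DesignSpec(contrast="age", terms=["age", "sex"]))
        top = de.set_index("gene_id").loc[[f"g{i}" for i in range(20)]]
        assert (np.sign(top["estimate"].to_numpy()) == np.sign(betas[:20])).mean() >= 0.95
        assert top["is_de"].mean() > 0.8

    def test_interaction_contrast_runs(self):
        rng = np.random.default_rng(11)
        donors = _donors(30, rng)
        assay = _make_assay(_sim_assay(donors, np.zeros(30)), donors)
        spec = DesignSpec(contrast="age:disease_status", terms=["age", "disease_status"])
        de = run_de([assay], spec)
        assert len(de) == 30 and de["p_value"].notna().all()


class TestCorrectedExpression:
    def test_nuisance_linear_expression_becomes_constant(self):
        donors = _donors(20)
        genes = pd.Index(["g0"], name="gene_id")
        from ctaging.io import PseudobulkAssay

        # expression exactly linear in pH; after removing pH the per-gene
        # profile must be flat across donors
        counts = pd.DataFrame(
            np.round(2.0 ** (10 + 2 * (donors["pH"].to_numpy() - 6.5))[None, :] * 100),
            index=genes,
            columns=donors["donor_id"],
        )
        filler = pd.DataFrame(
            np.full((30, 20), 1000.0), index=[f"f{i}" for i in range(30)], columns=donors["donor_id"]
        )
        assay = PseudobulkAssay("A", pd.concat([counts, filler]), donors, pd.Series(10, index=donors["donor_id"]))
        corrected = covariate_corrected_expression(assay, keep_term="age", terms=["age", "pH"])
        assert corrected.loc["g0"].std() < 0.02

    def test_refit_of_nuisance_terms_is_null(self):
        rng = np.random.default_rng(12)
        donors = _donors(25, rng)
        assay = _make_assay(_sim_assay(donors, rng.normal(0, 0.01, 40)), donors)
        corrected = covariate_corrected_expression(assay, keep_term="age", terms=["age", "pH", "sex"])
        X, _ = design_matrix(donors, ["age", "pH", "sex"])
        Xv = X.to_numpy(float)
        beta = np.linalg.lstsq(Xv, corrected.to_numpy().T, rcond=None)[0]
        # nuisance coefficients (pH, sex) vanish after correction
        assert np.abs(beta[2:]).max() < 1e-8

    def test_unknown_keep_term_is_error(self):
        donors = _donors(10)
        assay = _make_assay(_sim_assay(donors, np.zeros(12)), donors)
        with pytest.raises(ValueError, match="keep_term"):
            covariate_corrected_expression(assay, keep_term="bogus", terms=["age"])
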