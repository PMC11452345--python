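import numpy as np
import pandas as pd
import pytest

from ctaging import (
    compare_signatures,
    effect_concordance,
    fisher_overlap,
    overlap_index,
    replication_eligibility,
)


class TestOverlapIndex:
    def test_direct_formula(self):
        A = set(range(4))
        B = set(range(2, 10))
        assert overlap_index(A, B) == (2 / 4 + 2 / 8) / 2 == 0.375

    def test_identity_and_disjoint(self):
        assert overlap_index({1, 2}, {1, 2}) == 1.0
        assert overlap_index({1, 2}, {3, 4}) == 0.0

    def test_empty_set_convention(self):
        assert overlap_index(set(), {1}) == 0.0

    def test_symmetric(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            A = set(rng.integers(0, 30, 10).tolist())
            B = set(rng.integers(0, 30, 12).tolist())
            assert overlap_index(A, B) == overlap_index(B, A)


class TestFisherOverlap:
    def test_hand_enumerated_tail(self):
        # N=20, |A|=5, |B|=4, overlap 3:
        # p = [C(5,3)C(15,1) + C(5,4)C(15,0)] / C(20,4) = 155/4845
        bg = [f"g{i}" for i in range(20)]
        A = set(bg[:5])
        B = set(bg[:3]) | {bg[10]}
        res = fisher_overlap(A, B, bg)
        assert res.n_overlap == 3
        assert np.isclose(res.fisher_p, 155 / 4845, atol=1e-12)

    def test_zero_overlap_gives_p_one(self):
        bg = [f"g{i}" for i in range(10)]
        res = fisher_overlap(set(bg[:3]), set(bg[5:8]), bg)
        assert res.fisher_p == 1.0

    def test_monotone_in_overlap(self):
        bg = [f"g{i}" for i in range(40)]
        ps = []
        for k in range(6):
            A = set(bg[:10])
            B = set(bg[:k]) | set(bg[20 : 20 + (8 - k)])
            ps.append(fisher_overlap(A, B, bg).fisher_p)
        assert (np.diff(ps) <= 1e-12).all()

    def test_odds_ratio_conventions(self):
        bg = [f"g{i}" for i in range(10)]
        res = fisher_overlap(set(bg[:4]), set(bg[:4]), bg)  # b = c = 0
        assert np.isinf(res.odds_ratio)
        res2 = fisher_overlap(set(bg[:4]), set(bg[4:8]), bg)  # a = 0, d > 0... a*d = 0
        assert res2.n_overlap == 0

    def test_stray_genes_dropped_with_warning(self):
        bg = [f"g{i}" for i in range(10)]
        with pytest.warns(UserWarning, match="outside the background"):
            res = fisher_overlap(set(bg[:3]) | {"alien"}, set(bg[:2]), bg)
        assert res.set_a_size == 3

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError, match="background"):
            fisher_overlap({1}, {1}, set())


class TestEffectConcordance:
    def test_monotone_map_gives_rho_one(self):
        rho, _, conc = effect_concordance(
            pd.Series([1.0, 2, 3], index=list("abc")), pd.Series([2.0, 4, 6], index=list("abc"))
        )
        assert np.isclose(rho, 1.0)
        assert conc == 100.0

    def test_sign_counting(self):
        a = pd.Series([1.0, -1, 1, -1], index=list("abcd"))
        b = pd.Series([1.0, -1, -1, -1], index=list("abcd"))
        _, _, conc = effect_concordance(a, b)
        assert conc == 75.0

    def test_zero_counts_as_discordant(self):
        a = pd.Series([1.0, 1.0], index=list("ab"))
        b = pd.Series([0.0, 1.0], index=list("ab"))
        _, _, conc = effect_concordance(a, b)
        assert conc == 50.0

    def test_small_n_exact_permutation(self):
        rng = np.random.default_rng(1)
        idx = list("abcde")
        x = pd.Series(rng.normal(0, 1, 5), index=idx)
        y = pd.Series(rng.normal(0, 1, 5), index=idx)
        rho, p, _ = effect_concordance(x, y)
        # brute-force: distribution of |rho| over all 120 orderings of y
        import itertools
        from scipy import stats as st

        obs = abs(st.spearmanr(x.to_numpy(), y.to_numpy())[0])
        hits = total = 0
        for perm in itertools.permutations(range(5)):
            total += 1
            hits += abs(st.spearmanr(x.to_numpy(), y.to_numpy()[list(perm)])[0]) >= obs - 1e-12
        assert np.isclose(rho, st.spearmanr(x.to_numpy(), y.to_numpy())[0])
        assert np.isclose(p, hits / total)

    def test_fewer_than_three_shared_genes(self):
        rho, p, conc = effect_concordance(
            pd.Series([1.0, 2.0], index=list("ab")), pd.Series([1.0, -2.0], index=list("ab"))
        )
        assert rho is None and p is None
        assert conc == 50.0


class TestReplicationEligibility:
    def test_flat_half_is_ineligible(self):
        assert not replication_eligibility(np.full(100, 0.5))

    def test_boundary_is_strict(self):
        assert replication_eligibility(np.full(50, 0.099))
        assert not replication_eligibility(np.full(50, 0.1))

    def test_signal_mixture_is_eligible(self):
        rng = np.random.default_rng(2)
        p = np.r_[rng.uniform(0, 0.001, 20), rng.uniform(0, 1, 80)]
        # 20% of mass near zero pushes the 15th percentile below 0.1
        assert np.percentile(p, 15) < 0.1
        assert replication_eligibility(p)

    def test_empty_vector_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            replication_eligibility([])


def _signature(genes, de_genes, signs, cell_type="A", seed=0):
    rng = np.random.default_rng(seed)
    est = rng.normal(0, 0.005, len(genes))
    fdr = np.ones(len(genes))
    gpos = {g: i for i, g in enumerate(genes)}
    for g, s in zip(de_genes, signs):
        est[gpos[g]] = s * rng.uniform(0.01, 0.05)
        fdr[gpos[g]] = rng.uniform(0, 0.04)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "cell_type": cell_type,
            "estimate": est,
            "p_value": fdr / 2,
            "fdr": fdr,
            "direction": np.sign(est).astype(int),
        }
    )


class TestCompareSignatures:
    def test_self_comparison(self):
        genes = [f"g{i}" for i in range(300)]
        rng = np.random.default_rng(3)
        de_genes = list(rng.choice(genes, 40, replace=False))
        signs = rng.choice([-1, 1], 40)
        sig = _signature(genes, de_genes, signs)
        out = compare_signatures(sig, sig, direction="both")
        assert (out["overlap_index"] == 1.0).all()
        assert (out["concordance_pct"] == 100.0).all()
        assert np.isinf(out["odds_ratio"]).all()
        assert (out["fdr"] < 0.05).all()

    def test_planted_shared_signature_detected(self):
        genes = [f"g{i}" for i in range(1000)]
        rng = np.random.default_rng(4)
        de_a = list(rng.choice(genes, 100, replace=False))
        signs_a = rng.choice([-1, 1], 100)
        # half of A's DE genes injected into B with the same signs
        keep = rng.choice(100, 50, replace=False)
        own = list(rng.choice([g for g in genes if g not in de_a], 30, replace=False))
        de_b = [de_a[i] for i in keep] + own
        signs_b = np.r_[signs_a[keep], rng.choice([-1, 1], 30)]
        a = _signature(genes, de_a, signs_a, seed=5)
        b = _signature(genes, de_b, signs_b, seed=6)
        out = compare_signatures(a, b, direction="both")
        assert (out["fdr"] < 0.05).any()
        shared = out.loc[out["n_overlap"] > 0]
        assert (shared["concordance_pct"] > 90).all()

    def test_unmatched_cell_type_skipped(self):
        genes = [f"g{i}" for i in range(50)]
        a = _signature(genes, genes[:5], [1] * 5, cell_type="A")
        b = _signature(genes, genes[:5], [1] * 5, cell_type="B")
        with pytest.warns(UserWarning, match="skipped"):
            out = compare_signatures(a, b, cell_type_map={"A": "missing"})
        assert len(out) == 0
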