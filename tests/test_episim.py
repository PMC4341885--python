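"""Penetrance models and the case-control simulator."""

import numpy as np
import pytest
from scipy import stats

from force_epistasis import (MISSING, RITCHIE_MODELS, SimConfig,
                             sample_individual, simulate_dataset)
from force_epistasis.episim import RejectionBudgetError, _corrupt


def to_a_counts(gm):
    """Undo the minor-allele recoding: copies of the 'a' (frequency-q) allele."""
    g = gm.genotypes.astype(np.int16)
    flip = (gm.snp_meta["allele1"] != "a").to_numpy()
    out = g.copy()
    cols = np.flatnonzero(flip)
    block = out[:, cols]
    block[block != MISSING] = 2 - block[block != MISSING]
    out[:, cols] = block
    return out


class TestPenetranceModels:
    def test_model1_cells(self):
        m = RITCHIE_MODELS[1]
        assert m.penetrance[0, 0] == 0.0          # (AA, BB)
        assert m.penetrance[1, 0] == 0.10         # (Aa, BB)
        assert m.p == 0.5

    def test_model1_prevalence(self):
        assert RITCHIE_MODELS[1].prevalence() == pytest.approx(0.05)

    @pytest.mark.parametrize("mid", range(1, 7))
    def test_marginal_penetrances_near_equal(self, mid):
        """Pure epistasis: each genotype's marginal penetrance is (near) equal.

        Models 1-2 satisfy the property exactly; the search-derived models
        3-6 only minimize the marginals, leaving spreads of a few percent.
        """
        m = RITCHIE_MODELS[mid]
        for snp in (1, 2):
            marg = m.marginal_penetrance(snp)
            rel = np.abs(marg - marg.mean()) / marg.mean()
            assert rel.max() <= (1e-12 if mid <= 2 else 0.05)

    def test_model3_marginal_close_to_prevalence(self):
        m = RITCHIE_MODELS[3]
        marg = m.marginal_penetrance(1)
        assert marg == pytest.approx([m.prevalence()] * 3, rel=0.06)

    def test_sample_individual_matches_penetrance(self):
        rng = np.random.default_rng(5)
        m = RITCHIE_MODELS[1]
        draws = [sample_individual(m, rng) for _ in range(4000)]
        sub = [aff for g1, g2, aff in draws if (g1, g2) == (1, 0)]  # (Aa, BB)
        assert len(sub) > 100
        assert np.mean(sub) == pytest.approx(0.10, abs=3 * 0.3 / np.sqrt(len(sub)))
        assert not any(aff for g1, g2, aff in draws if (g1, g2) == (0, 0))


class TestSimulateDataset:
    def test_deterministic_under_seed(self):
        cfg = SimConfig(model_id=1, noise=frozenset({"GE", "MS"}), seed=123)
        gm1, t1 = simulate_dataset(cfg)
        gm2, t2 = simulate_dataset(cfg)
        np.testing.assert_array_equal(gm1.genotypes, gm2.genotypes)
        assert t1 == t2

    def test_shapes_and_labels(self):
        gm, truth = simulate_dataset(SimConfig(model_id=4, seed=1))
        assert gm.genotypes.shape == (400, 10)
        assert gm.n_cases == 200 and gm.n_controls == 200
        assert truth["planted_pairs"] == [["snp1", "snp2"]]

    def test_null_snps_in_hwe(self):
        cfg = SimConfig(model_id=1, n_cases=5000, n_controls=5000, seed=9,
                        null_maf_range=(0.3, 0.3))
        gm, _ = simulate_dataset(cfg)
        n = gm.n_samples
        expected = np.array([0.49, 0.42, 0.09])
        for j in range(2, gm.n_snps):
            counts = np.bincount(gm.genotypes[:, j], minlength=3)[:3]
            for k in range(3):
                se = np.sqrt(n * expected[k] * (1 - expected[k]))
                assert abs(counts[k] - n * expected[k]) <= 3 * se + 1

    def test_case_genotypes_follow_posterior_model1(self):
        # P(g1, g2 | case) = f(g1, g2) P(g1) P(g2) / prevalence
        cfg = SimConfig(model_id=1, n_cases=10_000, n_controls=200, n_snps=2, seed=3)
        gm, _ = simulate_dataset(cfg)
        g = to_a_counts(gm)[gm.is_case]
        m = RITCHIE_MODELS[1]
        w = m.genotype_probs()
        post = m.penetrance * np.outer(w, w) / m.prevalence()
        obs = np.zeros((3, 3))
        for g1, g2 in g:
            obs[g1, g2] += 1
        obs /= len(g)
        for i in range(3):
            for j in range(3):
                se = np.sqrt(post[i, j] * (1 - post[i, j]) / len(g))
                assert abs(obs[i, j] - post[i, j]) <= 3 * se + 1e-4

    def test_no_main_effect_at_planted_snps_models_1_2(self):
        """Single-SNP case/control distributions are indistinguishable."""
        for mid in (1, 2):
            cfg = SimConfig(model_id=mid, n_cases=5000, n_controls=5000,
                            n_snps=2, seed=17)
            gm, _ = simulate_dataset(cfg)
            g = to_a_counts(gm)
            for j in range(2):
                table = np.array([np.bincount(g[gm.is_case, j], minlength=3),
                                  np.bincount(g[~gm.is_case, j], minlength=3)])
                _, p, _, _ = stats.chi2_contingency(table)
                assert p > 0.01

    def test_planted_marginals_close_models_3_6(self):
        for mid in (3, 6):
            cfg = SimConfig(model_id=mid, n_cases=5000, n_controls=5000,
                            n_snps=2, seed=23)
            gm, _ = simulate_dataset(cfg)
            g = to_a_counts(gm)
            for j in range(2):
                fc = np.bincount(g[gm.is_case, j], minlength=3) / gm.n_cases
                fu = np.bincount(g[~gm.is_case, j], minlength=3) / gm.n_controls
                assert np.abs(fc - fu).max() <= 0.03

    def test_ms_rate_recovered(self):
        cfg = SimConfig(model_id=1, noise=frozenset({"MS"}), seed=6,
                        n_cases=2000, n_controls=2000)
        gm, _ = simulate_dataset(cfg)
        rate = (gm.genotypes == MISSING).mean()
        n = gm.genotypes.size
        assert abs(rate - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / n)

    def test_ge_corruption_rate_recovered(self):
        rng = np.random.default_rng(8)
        g = rng.integers(0, 3, size=(200, 500)).astype(np.int8)
        g2 = _corrupt(g, rng, 0.05)
        changed = (g2 != g).mean()
        assert abs(changed - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / g.size)
        assert set(np.unique(g2)) <= {0, 1, 2}

    def test_readout_ge_differs_from_causal(self):
        base = dict(model_id=2, noise=frozenset({"GE"}), seed=4)
        gm_causal, _ = simulate_dataset(SimConfig(**base))
        gm_readout, _ = simulate_dataset(SimConfig(**base, ge_mode="readout"))
        assert not np.array_equal(gm_causal.genotypes, gm_readout.genotypes)

    def test_gh_has_two_planted_pairs(self):
        gm, truth = simulate_dataset(SimConfig(model_id=2, noise={"GH"}, seed=5))
        assert truth["planted_pairs"] == [["snp1", "snp2"], ["snp3", "snp4"]]
        assert gm.n_snps == 10

    def test_gh_needs_four_snps(self):
        with pytest.raises(ValueError, match="at least 4"):
            SimConfig(model_id=1, noise={"GH"}, n_snps=3)

    def test_rejection_budget_error(self):
        cfg = SimConfig(model_id=6, n_cases=500, n_controls=10, seed=1,
                        rejection_budget=1000)
        with pytest.raises(RejectionBudgetError):
            simulate_dataset(cfg)

    def test_unknown_noise_rejected(self):
        with pytest.raises(ValueError, match="unknown noise"):
            SimConfig(model_id=1, noise={"XX"})


def test_write_dataset_round_trip(tmp_path):
    from force_epistasis import read_plink, write_dataset
    gm, truth = simulate_dataset(SimConfig(model_id=3, noise={"MS"}, seed=2))
    write_dataset(gm, truth, tmp_path / "sim", dialect="ped_map")
    back = read_plink(tmp_path / "sim")
    np.testing.assert_array_equal(back.genotypes, gm.genotypes)
    assert (tmp_path / "sim.truth.json").exists()
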