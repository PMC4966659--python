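"""Interaction information, MDR, logistic ROR_i and allelic extreme ORs."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

import oracles
from snpconverge.epistasis import (
    allelic_extreme_or,
    allelic_or_grid,
    evaluate_pair,
    explicit_epistasis_test,
    interaction_information,
    mdr_test,
    ror_i,
)


def xor_data(n=2000, rng=None, maf=0.5):
    rng = rng or np.random.default_rng(0)
    g1 = rng.binomial(2, maf, n)
    g2 = rng.binomial(2, maf, n)
    y = ((g1 > 0).astype(int) ^ (g2 > 0).astype(int))
    return g1, g2, y


class TestInteractionInformation:
    def test_balanced_xor_is_one_bit(self):
        """Noise-free XOR of two balanced binary loci carries exactly 1 bit."""
        g1 = np.repeat([0, 0, 1, 1], 250)
        g2 = np.tile([0, 1, 0, 1], 250)
        y = g1 ^ g2
        assert interaction_information(g1, g2, y) == pytest.approx(1.0, abs=1e-12)

    def test_independent_phenotype_near_zero(self, rng):
        g1 = rng.binomial(2, 0.3, 10_000)
        g2 = rng.binomial(2, 0.3, 10_000)
        y = rng.integers(0, 2, 10_000)
        assert abs(interaction_information(g1, g2, y)) < 0.01

    def test_constant_genotype_no_error(self, rng):
        g1 = np.zeros(100, dtype=int)
        g2 = rng.binomial(2, 0.5, 100)
        y = rng.integers(0, 2, 100)
        assert np.isfinite(interaction_information(g1, g2, y))

    def test_symmetric_in_genotypes(self, rng):
        g1 = rng.binomial(2, 0.4, 500)
        g2 = rng.binomial(2, 0.2, 500)
        y = rng.integers(0, 2, 500)
        assert interaction_information(g1, g2, y) == pytest.approx(
            interaction_information(g2, g1, y), abs=1e-12
        )

    def test_matches_direct_entropy_arithmetic(self, rng):
        """IG from genotype vectors equals the hand-summed 3x3x2 table value."""
        for _ in range(20):
            table = rng.integers(1, 30, size=(3, 3, 2))
            g1, g2, y = [], [], []
            for i in range(3):
                for j in range(3):
                    for k in range(2):
                        n = int(table[i, j, k])
                        g1 += [i] * n
                        g2 += [j] * n
                        y += [k] * n
            got = interaction_information(np.array(g1), np.array(g2), np.array(y))
            assert got == pytest.approx(
                oracles.naive_interaction_information(table), abs=1e-12
            )

    def test_missing_dropped_listwise(self):
        g1 = np.array([0, 1, -1, 1])
        g2 = np.array([0, 1, 1, -1])
        y = np.array([0, 1, 1, 0])
        assert interaction_information(g1, g2, y) == pytest.approx(
            interaction_information(g1[:2], g2[:2], y[:2]), abs=1e-12
        )


class TestMdr:
    def test_xor_perfectly_separable(self):
        g1, g2, y = xor_data(n=2000)
        acc, p = mdr_test(g1, g2, y, k_folds=10, n_perm=99, seed=1)
        assert acc == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100)

    def test_high_risk_ratio_rule(self):
        """A cell at 8 cases / 2 controls against an overall 1:1 ratio is
        high-risk, so held-in prediction is perfect for that cell."""
        g1 = np.array([0] * 10 + [2] * 10)
        g2 = np.array([0] * 10 + [2] * 10)
        y = np.array([1] * 8 + [0] * 2 + [0] * 8 + [1] * 2)
        acc, _ = mdr_test(g1, g2, y, k_folds=2, n_perm=10, seed=0)
        assert acc > 0.5

    def test_null_accuracy_near_half_and_p_uniform(self, rng):
        """Random phenotypes: chance-level accuracy, uniform permutation p."""
        ps, accs = [], []
        for _ in range(120):
            g1 = rng.binomial(2, 0.4, 300)
            g2 = rng.binomial(2, 0.4, 300)
            y = rng.integers(0, 2, 300)
            acc, p = mdr_test(g1, g2, y, k_folds=5, n_perm=60, seed=rng)
            ps.append(p)
            accs.append(acc)
        assert abs(np.mean(accs) - 0.5) < 0.03
        assert kstest(ps, "uniform").pvalue > 0.01


class TestRorI:
    def test_null_interaction_recovers_one(self, rng):
        vals, ps = [], []
        for _ in range(60):
            g1 = rng.binomial(2, 0.3, 4000)
            g2 = rng.binomial(2, 0.3, 4000)
            eta = -0.5 + 0.2 * g1 + 0.2 * g2
            y = (rng.random(4000) < 1 / (1 + np.exp(-eta))).astype(int)
            r, p, conv = ror_i(g1, g2, y)
            assert conv
            vals.append(r)
            ps.append(p)
        assert np.median(vals) == pytest.approx(1.0, abs=0.05)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_recovers_planted_interaction(self, rng):
        g1 = rng.binomial(2, 0.3, 50_000)
        g2 = rng.binomial(2, 0.3, 50_000)
        eta = -1.0 + 0.1 * g1 + 0.1 * g2 + math.log(1.2) * g1 * g2
        y = (rng.random(50_000) < 1 / (1 + np.exp(-eta))).astype(int)
        r, _, conv = ror_i(g1, g2, y)
        assert conv
        assert 1.1 <= r <= 1.3

    def test_binary_saturated_equals_cross_ratio(self, rng):
        """With binary exposures, exp(b3) is the cross-ratio of the four
        exposure-stratified odds from the 2x2x2 table."""
        table = rng.integers(20, 80, size=(2, 2, 2)).astype(float)
        g1, g2, y = [], [], []
        for i in range(2):
            for j in range(2):
                for k in range(2):
                    n = int(table[i, j, k])
                    g1 += [i] * n
                    g2 += [j] * n
                    y += [k] * n
        r, _, conv = ror_i(np.array(g1), np.array(g2), np.array(y))
        odds = table[:, :, 1] / table[:, :, 0]
        expected = (odds[1, 1] * odds[0, 0]) / (odds[1, 0] * odds[0, 1])
        assert conv
        assert r == pytest.approx(expected, rel=1e-5)

    def test_covariate_adjustment_accepted(self, rng):
        g1 = rng.binomial(2, 0.3, 3000)
        g2 = rng.binomial(2, 0.3, 3000)
        age = rng.normal(50, 10, 3000)
        y = (rng.random(3000) < 1 / (1 + np.exp(-(-2 + 0.02 * age)))).astype(int)
        r, p, conv = ror_i(g1, g2, y, covariates=age)
        assert conv and r > 0


class TestAllelicExtremes:
    def test_cross_product_sixteen(self):
        g1, g2, y = [], [], []
        for combo, (cases, ctrls) in ((2, (40, 10)), (0, (10, 40))):
            g1 += [combo] * (cases + ctrls)
            g2 += [combo] * (cases + ctrls)
            y += [1] * cases + [0] * ctrls
        res = allelic_extreme_or(np.array(g1), np.array(g2), np.array(y))
        assert res.sample_odds_ratio == pytest.approx(16.0)

    def test_equal_ratios_or_one(self):
        g1 = np.array([0] * 20 + [2] * 20)
        g2 = np.array([0] * 20 + [2] * 20)
        y = np.array(([1] * 10 + [0] * 10) * 2)
        res = allelic_extreme_or(g1, g2, y)
        assert res.sample_odds_ratio == pytest.approx(1.0)

    def test_grid_matches_direct_cross_products(self, rng):
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 3, 2))
            g1, g2, y = [], [], []
            for i in range(3):
                for j in range(3):
                    g1 += [i] * int(table[i, j].sum())
                    g2 += [j] * int(table[i, j].sum())
                    y += [1] * int(table[i, j, 1]) + [0] * int(table[i, j, 0])
            grid = allelic_or_grid(np.array(g1), np.array(g2), np.array(y))
            odds = table[:, :, 1] / table[:, :, 0]
            expected = odds / odds[0, 0]
            assert np.allclose(grid, expected)

    def test_empty_extreme_cell_flagged(self):
        g1 = np.array([0, 0, 1, 1])
        g2 = np.array([0, 0, 1, 1])
        y = np.array([0, 1, 0, 1])
        res = allelic_extreme_or(g1, g2, y)  # nobody is (2,2)
        assert res.degenerate


class TestExplicitTest:
    def test_xor_detected(self):
        g1, g2, y = xor_data(n=1500)
        ig, p = explicit_epistasis_test(g1, g2, y, n_perm=99, seed=2)
        assert ig > 0.5
        assert p == pytest.approx(1 / 100)

    def test_evaluate_pair_joint_summary(self):
        g1, g2, y = xor_data(n=1000)
        res = evaluate_pair(g1, g2, y, n_perm=50, seed=4)
        assert res.ig_bits > 0.5
        assert res.mdr_balanced_accuracy == pytest.approx(1.0)
        assert res.n_used == 1000
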