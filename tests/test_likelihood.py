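"""Binomial / piecewise beta-binomial likelihood computations."""

import math

import numpy as np
import pytest
from scipy import stats

from cloneburst import (BulkComposition, BurstingKinetics, CellAssignment,
                        ClonalTree, ErrorPrior, ReadCountSet,
                        joint_log_density, log_pmf_bulk, log_pmf_cell)


class TestBulkPmf:
    def test_empty_support_is_certain(self):
        assert log_pmf_bulk(0, 0, 0.4) == 0.0
        assert log_pmf_bulk(0, 0, 0.4, include_constant=True) == 0.0

    def test_all_alternative_reads_at_full_carrier_fraction(self):
        # q=1 means success probability 1/2
        assert np.isclose(log_pmf_bulk(10, 10, 1.0, include_constant=True),
                          10 * math.log(0.5))

    def test_against_log_factorial_oracle(self):
        # direct evaluation of log C(100,25) + 25 log .25 + 75 log .75
        r, x, p = 25, 100, 0.25
        direct = (math.lgamma(x + 1) - math.lgamma(r + 1) - math.lgamma(x - r + 1)
                  + r * math.log(p) + (x - r) * math.log(1 - p))
        assert np.isclose(log_pmf_bulk(r, x, 0.5, include_constant=True),
                          direct, rtol=1e-12)

    def test_impossible_outcome_is_minus_infinity(self):
        assert log_pmf_bulk(3, 10, 0.0) == -np.inf

    def test_alt_exceeding_total_rejected(self):
        with pytest.raises(ValueError):
            log_pmf_bulk(11, 10, 0.5)

    @pytest.mark.parametrize("x", [0, 1, 5, 17, 30])
    def test_normalizes_to_one(self, x):
        for q in (0.001, 0.2, 0.77, 1.0):
            r = np.arange(x + 1)
            total = np.exp(log_pmf_bulk(r, np.full(x + 1, x), q,
                                        include_constant=True)).sum()
            assert np.isclose(total, 1.0, atol=1e-9)


class TestCellPmf:
    def test_uniform_beta_binomial(self):
        # alpha = beta = 1 makes the carrier beta-binomial uniform on {0..x}
        val = log_pmf_cell(1, 2, 1, (1.0, 1.0), (1.0, 999.0),
                           include_constant=True)
        assert np.isclose(val, math.log(1.0 / 3.0))

    def test_empty_support(self):
        assert log_pmf_cell(0, 0, 1, (0.5, 0.5), (1.0, 999.0)) == 0.0
        assert log_pmf_cell(0, 0, 0, (0.5, 0.5), (1.0, 999.0)) == 0.0

    def test_error_branch_closed_form(self):
        # B(1, 1099)/B(1, 999) = 999/1099 for r=0, x=100, kappa=1, tau=999
        val = log_pmf_cell(0, 100, 0, (0.5, 0.5), (1.0, 999.0),
                           include_constant=True)
        assert np.isclose(val, math.log(999.0 / 1099.0), rtol=1e-12)

    def test_non_positive_shapes_rejected(self):
        with pytest.raises(ValueError):
            log_pmf_cell(1, 2, 1, (0.0, 1.0), (1.0, 999.0))

    @pytest.mark.parametrize("carrier", [0, 1])
    @pytest.mark.parametrize("x", [0, 3, 12, 30])
    def test_normalizes_to_one(self, x, carrier, rng):
        for _ in range(4):
            ab = tuple(rng.uniform(0.1, 3.0, size=2))
            kt = (1.0, float(rng.uniform(100, 2000)))
            r = np.arange(x + 1)
            total = np.exp(log_pmf_cell(r, np.full(x + 1, x), carrier, ab, kt,
                                        include_constant=True)).sum()
            assert np.isclose(total, 1.0, atol=1e-9)

    def test_monte_carlo_marginalization(self, rng):
        # averaging Binom(x, gamma) over gamma ~ Beta(alpha, beta) recovers
        # the beta-binomial mass within 3 Monte-Carlo standard errors
        n_draws = 100_000
        for alpha, beta in ((0.5, 0.5), (1.0, 0.1), (2.0, 5.0)):
            gammas = rng.beta(alpha, beta, size=n_draws)
            for r, x in ((0, 7), (3, 7), (7, 7)):
                pmfs = stats.binom.pmf(r, x, gammas)
                mc, se = pmfs.mean(), pmfs.std(ddof=1) / math.sqrt(n_draws)
                exact = math.exp(log_pmf_cell(r, x, 1, (alpha, beta),
                                              (1.0, 999.0),
                                              include_constant=True))
                assert abs(mc - exact) < 3 * se + 1e-12

    def test_monotone_in_activation_ratio_for_full_alt_reads(self):
        # r = x > 0 in a carrier cell: larger alpha/(alpha+beta) means the
        # gene is active more often, making all-alternative reads likelier
        vals = [log_pmf_cell(5, 5, 1, (a, 2.0 - a), (1.0, 999.0))
                for a in (0.2, 0.5, 1.0, 1.5, 1.8)]
        assert all(v2 > v1 for v1, v2 in zip(vals, vals[1:]))


def _lchoose(x, r):
    return math.lgamma(x + 1) - math.lgamma(r + 1) - math.lgamma(x - r + 1)


def _naive_joint(data, tree, cells, bulk, kin, prior):
    """Independent reference: scipy binom/betabinom log-pmfs with the
    binomial coefficients subtracted, summed in explicit double loops."""
    Z, Ps, Pb = tree.Z, cells.P_s, bulk.P_b
    total = 0.0
    for m in range(data.M):
        for t in range(data.T):
            q = sum(Z[m, k] * Pb[k, t] for k in range(tree.K))
            r, x = data.R_b[m, t], data.X_b[m, t]
            total += stats.binom.logpmf(r, x, q / 2) - _lchoose(x, r)
        for n in range(data.N):
            carrier = sum(Z[m, k] * Ps[k, n] for k in range(tree.K))
            a, b = (kin.alpha[m], kin.beta[m]) if carrier \
                else (prior.kappa, prior.tau)
            r, x = data.R_s[m, n], data.X_s[m, n]
            total += stats.betabinom.logpmf(r, x, a, b) - _lchoose(x, r)
    return total


class TestJointLogDensity:
    def test_single_term_hand_computation(self):
        data = ReadCountSet(R_b=[[3]], X_b=[[10]], R_s=[[2]], X_s=[[4]])
        tree = ClonalTree(2, [-1, 0, 0], [2])
        cells = CellAssignment([1], 2)
        bulk = BulkComposition(np.array([[0.4], [0.6]]))
        kin = BurstingKinetics.constant(1, 0.8, 0.4)
        prior = ErrorPrior()
        parts = joint_log_density(data, tree, cells, bulk, kin, prior)
        expect_bulk = log_pmf_bulk(3, 10, 0.6)
        expect_cell = log_pmf_cell(2, 4, 1, (0.8, 0.4), (1.0, 999.0))
        assert np.isclose(parts.bulk_term, expect_bulk, rtol=1e-12)
        assert np.isclose(parts.cell_term, expect_cell, rtol=1e-12)
        assert np.isclose(parts.total, expect_bulk + expect_cell, rtol=1e-12)

    def test_no_mutations_gives_zero(self):
        data = ReadCountSet(R_b=np.empty((0, 1), int), X_b=np.empty((0, 1), int),
                            R_s=np.empty((0, 2), int), X_s=np.empty((0, 2), int))
        tree = ClonalTree(2, [-1, 0, 0], np.empty(0, int))
        parts = joint_log_density(data, tree, CellAssignment([0, 1], 2),
                                  BulkComposition(np.array([[0.5], [0.5]])),
                                  BurstingKinetics(np.empty(0), np.empty(0)),
                                  ErrorPrior())
        assert parts.total == 0.0

    def test_additive_over_mutations(self, rng):
        from tests.test_tree import random_valid_tree
        tree = random_valid_tree(3, 2, rng)
        kin = BurstingKinetics(rng.uniform(0.2, 2, 2), rng.uniform(0.2, 2, 2))
        cells = CellAssignment(rng.integers(3, size=4), 3)
        bulk = BulkComposition.floored(rng.dirichlet(np.ones(3), size=2).T)
        X_b = rng.integers(5, 30, (2, 2))
        X_s = rng.integers(0, 20, (2, 4))
        data = ReadCountSet(R_b=rng.binomial(X_b, 0.3), X_b=X_b,
                            R_s=rng.binomial(X_s, 0.4), X_s=X_s)
        whole = joint_log_density(data, tree, cells, bulk, kin, prior := ErrorPrior())
        total = 0.0
        for m in range(2):
            sub = ReadCountSet(R_b=data.R_b[[m]], X_b=data.X_b[[m]],
                               R_s=data.R_s[[m]], X_s=data.X_s[[m]])
            subtree = ClonalTree(3, tree.parent, tree.branch_of_mutation[[m]])
            subkin = BurstingKinetics(kin.alpha[[m]], kin.beta[[m]])
            total += joint_log_density(sub, subtree, cells, bulk, subkin,
                                       prior).total
        assert np.isclose(whole.total, total, rtol=1e-12)

    def test_matches_naive_reference_on_random_instances(self):
        from tests.test_tree import random_valid_tree
        for seed in range(8):
            rng = np.random.default_rng(1000 + seed)
            K = int(rng.integers(2, 6))
            M = K + int(rng.integers(0, 3))
            N = int(rng.integers(0, 6))
            T = int(rng.integers(1, 5))
            tree = random_valid_tree(K, M, rng)
            kin = BurstingKinetics(rng.uniform(0.1, 3, M), rng.uniform(0.1, 3, M))
            cells = CellAssignment(rng.integers(K, size=N), K)
            bulk = BulkComposition.floored(rng.dirichlet(np.ones(K), size=T).T)
            X_b = rng.integers(5, 40, (M, T))
            X_s = rng.integers(0, 25, (M, N))
            data = ReadCountSet(R_b=rng.binomial(X_b, 0.3), X_b=X_b,
                                R_s=rng.binomial(X_s, 0.4), X_s=X_s)
            prior = ErrorPrior(1.0, float(rng.uniform(200, 2000)))
            parts = joint_log_density(data, tree, cells, bulk, kin, prior)
            ref = _naive_joint(data, tree, cells, bulk, kin, prior)
            assert np.isclose(parts.total, ref, rtol=1e-10)

    def test_total_is_sum_of_parts(self, sim_default):
        sim = sim_default
        parts = joint_log_density(sim.data, sim.tree, sim.cells, sim.bulk,
                                  sim.config.kinetics(),
                                  sim.config.error_prior())
        assert np.isclose(parts.total, parts.bulk_term + parts.cell_term,
                          rtol=1e-10)
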