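"""Metropolis-within-Gibbs sampler over clonal configurations."""

import numpy as np
import pytest

from cloneburst import (BulkComposition, BurstingKinetics, CellAssignment,
                        ErrorPrior, ReadCountSet, SamplerConfig,
                        initialize_state, joint_log_density, run_mcmc,
                        validate_tree)
from cloneburst.likelihood import LikelihoodCache
from cloneburst.sampler import _propose_topology
from cloneburst.tree import ClonalTree


def bulk_only_data(r, x):
    return ReadCountSet(R_b=[[r]], X_b=[[x]],
                        R_s=np.empty((1, 0), int), X_s=np.empty((1, 0), int))


class TestInitializeState:
    def test_unique_configuration_for_two_clones(self, rng):
        data = bulk_only_data(10, 40)
        kin = BurstingKinetics.constant(1, 0.5, 0.5)
        tree, cells, bulk = initialize_state(data, 2, kin, ErrorPrior(), rng)
        assert tree.K == 2 and tree.branch_of_mutation.tolist() == [2]
        assert validate_tree(tree) == []

    def test_impossible_identifiability_raises(self, rng):
        # one mutation cannot distinguish three tumor clones
        data = bulk_only_data(10, 40)
        kin = BurstingKinetics.constant(1, 0.5, 0.5)
        with pytest.raises(ValueError, match="reduce K"):
            initialize_state(data, 4, kin, ErrorPrior(), rng)

    def test_fixed_seed_reproducible(self, sim_default):
        sim = sim_default
        kin = sim.config.kinetics()
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            tree, cells, bulk = initialize_state(sim.data, 4, kin,
                                                 ErrorPrior(), rng)
            out.append((tree.parent.tolist(),
                        tree.branch_of_mutation.tolist(),
                        cells.clone_index.tolist(), bulk.P_b.tolist()))
        assert out[0] == out[1]

    def test_cells_start_at_likelihood_argmax(self, sim_tiny):
        sim = sim_tiny
        kin = sim.config.kinetics()
        cache = LikelihoodCache(sim.data, kin, ErrorPrior())
        rng = np.random.default_rng(3)
        tree, cells, _ = initialize_state(sim.data, 4, kin, ErrorPrior(), rng,
                                          cache=cache)
        scores = cache.clone_scores(tree.Z)
        np.testing.assert_array_equal(cells.clone_index,
                                      np.argmax(scores, axis=0))


class TestTopologyProposal:
    def test_no_move_for_two_clones(self, rng):
        tree = ClonalTree(2, [-1, 0, 0], [2])
        assert _propose_topology(tree, rng) is None

    def test_three_clones_degenerates_to_leaf_swap(self, rng):
        tree = ClonalTree(3, [-1, 0, 4, 4, 0], [4, 2, 3])
        cand = _propose_topology(tree, rng)
        # same physical shape; pendant mutations exchanged between clones
        assert cand.parent.tolist() == tree.parent.tolist()
        assert cand.branch_of_mutation.tolist() == [4, 3, 2]

    def test_proposals_never_identical_Z_and_stay_bifurcating(self, rng):
        from tests.test_tree import random_valid_tree
        tree = random_valid_tree(5, 7, rng)
        for _ in range(50):
            cand = _propose_topology(tree, rng)
            ch = cand.children()
            assert all(len(ch[v]) == 2 for v in range(cand.K + 1, cand.n_nodes))
            assert not np.array_equal(cand.Z, tree.Z)

    def test_empirical_proposal_symmetry(self):
        """q(T -> T') equals q(T' -> T): sample many proposals from a state
        and from one of its neighbors and compare both directions."""
        rng = np.random.default_rng(77)
        from tests.test_tree import random_valid_tree
        tree = random_valid_tree(4, 6, rng)
        neighbor = None
        while neighbor is None:
            neighbor = _propose_topology(tree, rng)

        def key(t):
            return (t.parent.tobytes(), t.branch_of_mutation.tobytes())

        n = 30_000
        fwd = sum(key(_propose_topology(tree, rng)) == key(neighbor)
                  for _ in range(n)) / n
        rev = sum(key(_propose_topology(neighbor, rng)) == key(tree)
                  for _ in range(n)) / n
        se = np.sqrt(fwd * (1 - fwd) / n + rev * (1 - rev) / n)
        assert abs(fwd - rev) < 4 * se + 1e-9


class TestRunMcmc:
    def test_fixed_seed_gives_identical_traces(self, sim_tiny):
        sim = sim_tiny
        cfg = SamplerConfig(n_iter=100, n_chains=2, seed=5)
        kin = sim.config.kinetics()
        a = run_mcmc(sim.data, 4, kin, ErrorPrior(), cfg)
        b = run_mcmc(sim.data, 4, kin, ErrorPrior(), cfg)
        for ca, cb in zip(a.chains, b.chains):
            np.testing.assert_array_equal(ca.log_densities, cb.log_densities)

    def test_retained_count_and_validity(self, sim_tiny):
        sim = sim_tiny
        cfg = SamplerConfig(n_iter=200, n_chains=1, burnin_frac=0.2, thin=2,
                            seed=9)
        chains = run_mcmc(sim.data, 4, sim.config.kinetics(), ErrorPrior(), cfg)
        c = chains.chains[0]
        assert len(c) == (200 - 40) // 2
        for t in c.trees[::20]:
            assert validate_tree(t) == []
        for cells in c.cells[::20]:
            assert ((cells.clone_index >= 0)
                    & (cells.clone_index < 4)).all()
        for bulk in c.bulks[::20]:
            assert np.allclose(bulk.P_b.sum(axis=0), 1.0)

    def test_no_retained_samples_warns(self, sim_tiny):
        sim = sim_tiny
        cfg = SamplerConfig(n_iter=10, n_chains=1, burnin_frac=0.9, thin=5,
                            seed=1)
        with pytest.warns(UserWarning, match="burn-in"):
            run_mcmc(sim.data, 4, sim.config.kinetics(), ErrorPrior(), cfg)

    def test_logged_density_matches_joint_log_density(self, sim_tiny):
        sim = sim_tiny
        cfg = SamplerConfig(n_iter=60, n_chains=1, seed=11)
        kin = sim.config.kinetics()
        prior = ErrorPrior()
        chains = run_mcmc(sim.data, 4, kin, prior, cfg)
        c = chains.chains[0]
        for i in (0, len(c) - 1):
            parts = joint_log_density(sim.data, c.trees[i], c.cells[i],
                                      c.bulks[i], kin, prior)
            assert np.isclose(parts.total, c.log_densities[i], rtol=1e-9)

    def test_bulk_acceptance_in_working_range(self, sim_default):
        sim = sim_default
        cfg = SamplerConfig(n_iter=400, n_chains=2, seed=21)
        chains = run_mcmc(sim.data, 4, sim.config.kinetics(), ErrorPrior(), cfg)
        for c in chains.chains:
            assert 0.05 < c.acceptance["update_bulk"] < 0.95


def test_label_permutation_invariance(sim_default):
    """Relabeling the tumor clones consistently in Z, P^s, and P^b leaves the
    joint log density unchanged."""
    sim = sim_default
    kin = sim.config.kinetics()
    prior = ErrorPrior()
    base = joint_log_density(sim.data, sim.tree, sim.cells, sim.bulk, kin,
                             prior)
    # swap clones 2 and 3 by swapping the two leaf nodes and pendant edges
    tree = sim.tree.copy()
    tree.parent[2], tree.parent[3] = tree.parent[3], tree.parent[2]
    bom = tree.branch_of_mutation
    i2, i3 = bom == 2, bom == 3
    bom[i2], bom[i3] = 3, 2
    perm = np.array([0, 2, 1, 3])
    inv = np.argsort(perm)
    cells = CellAssignment(inv[sim.cells.clone_index], 4)
    bulk = BulkComposition(sim.bulk.P_b[perm])
    permuted = joint_log_density(sim.data, tree, cells, bulk, kin, prior)
    assert np.isclose(base.total, permuted.total, rtol=1e-10)


def test_conjugate_posterior_mean_on_bulk_only_toy():
    """One truncal mutation, two clones, bulk data only: the tumor-fraction
    samples should center on the conjugate Beta posterior mean."""
    x, r = 400, 100
    data = bulk_only_data(r, x)
    kin = BurstingKinetics.constant(1, 0.5, 0.5)
    cfg = SamplerConfig(n_iter=4000, n_chains=1, seed=13)
    chains = run_mcmc(data, 2, kin, ErrorPrior(), cfg)
    v = np.array([b.P_b[1, 0] for b in chains.chains[0].bulks]) / 2.0
    post_mean = (r + 1) / (x + 2)
    assert abs(v.mean() - post_mean) < 0.01
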