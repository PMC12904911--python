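"""Generative simulator for ground-truth clonal configurations and data.

The simulator draws a uniform random clonal tree, uniform cell-to-clone
assignments, and Dirichlet bulk compositions, then generates read counts under
the same hierarchical model the sampler targets:

* bulk: total depth integer-uniform in a shallow range (30-50x by default),
  alternative reads Binomial(depth, q/2) with q the clonal carrier fraction;
* single cell: a per-(mutation, cell) bursting draw gamma ~ Beta(alpha, beta)
  drives both coverage, x ~ Poisson(s * gamma), and the carrier success rate,
  r ~ Binomial(x, gamma); non-carrier cells see only sequencing error,
  r ~ Binomial(x, eps) with eps drawn once per dataset from Beta(kappa, tau).

Coverage and mutational observability thus share the bursting mechanism: a
silenced gene produces neither reads nor evidence of its mutation, which is
exactly the stochastic-zero phenomenon the model separates from technical and
non-cancerous zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .bursting import ExpressionMatrix
from .metrics import reconstruction_error
from .sampler import SamplerConfig, run_mcmc
from .tree import (BulkComposition, BurstingKinetics, CellAssignment,
                   ClonalTree, ErrorPrior, ReadCountSet)

#: Bursting regimes: (activation, deactivation) rates for high / bursty / low
#: expression.
REGIMES = {"high": (1.0, 0.1), "bursty": (0.5, 0.5), "low": (0.1, 1.0)}


@dataclass
class SimulationConfig:
    """Study conditions for a simulated dataset.

    Defaults mirror a shallow multi-sample design: K=4 subclones, M=K+2
    mutations, N=50 cells, T=4 bulk samples at 30-50x, sequencing error with
    prior mean 0.001, and beta-Poisson expression scale s=300.
    """

    K: int = 4
    M: int | None = None  # defaults to K + 2
    N: int = 50
    T: int = 4
    bulk_depth_range: tuple = (30, 50)
    kappa: float = 1.0
    tau: float = 999.0
    epsilon: float | None = None  # fixed error-rate override; None => draw
    scale_s: float = 300.0
    regime: object = "high"  # name in REGIMES or explicit (alpha, beta) arrays
    seed: int = 0

    def __post_init__(self):
        if self.M is None:
            self.M = self.K + 2
        lo, hi = self.bulk_depth_range
        if not (0 < lo <= hi):
            raise ValueError("bulk depth range must satisfy 0 < low <= high")
        if min(self.K, self.M, self.N + 1, self.T + 1) < 1:
            raise ValueError("counts must be positive")

    def kinetics(self) -> BurstingKinetics:
        if isinstance(self.regime, str):
            a, b = REGIMES[self.regime]
            return BurstingKinetics.constant(self.M, a, b)
        a, b = self.regime
        a = np.broadcast_to(np.asarray(a, dtype=float), (self.M,))
        b = np.broadcast_to(np.asarray(b, dtype=float), (self.M,))
        return BurstingKinetics(a.copy(), b.copy())

    def error_prior(self) -> ErrorPrior:
        return ErrorPrior(self.kappa, self.tau)


@dataclass
class SimTruth:
    """Ground truth plus the observed data generated from it."""

    tree: ClonalTree
    cells: CellAssignment
    bulk: BulkComposition
    data: ReadCountSet
    expression: ExpressionMatrix
    config: SimulationConfig = field(repr=False)


def _identifiable(tree: ClonalTree) -> bool:
    from .sampler import _tree_is_identifiable
    return _tree_is_identifiable(tree)


def simulate_truth(config: SimulationConfig, rng: np.random.Generator,
                   max_tries: int = 10_000):
    """Draw a ground-truth (tree, cell assignment, bulk composition)."""
    K, M = config.K, config.M
    tree = None
    for _ in range(max_tries):
        parent = ClonalTree.random_topology(K, rng)
        placement = rng.choice(np.arange(2, 2 * K - 1), size=M)
        cand = ClonalTree(K, parent, placement)
        if _identifiable(cand):
            tree = cand
            break
    if tree is None:
        raise ValueError(f"no identifiable tree found for K={K}, M={M}; "
                         "reduce K or increase M")
    cells = CellAssignment(rng.integers(K, size=config.N), K)
    P = rng.dirichlet(np.ones(K), size=config.T).T if config.T \
        else np.empty((K, 0))
    bulk = BulkComposition.floored(P) if config.T \
        else BulkComposition(np.empty((K, 0)))
    return tree, cells, bulk


def simulate_counts(tree: ClonalTree, cells: CellAssignment,
                    bulk: BulkComposition, config: SimulationConfig,
                    rng: np.random.Generator) -> ReadCountSet:
    """Generate bulk and single-cell read counts from a ground truth."""
    M, N, T = config.M, config.N, config.T
    kin = config.kinetics()
    lo, hi = config.bulk_depth_range
    Qb = tree.Z.astype(float) @ bulk.P_b
    X_b = rng.integers(lo, hi + 1, size=(M, T))
    R_b = rng.binomial(X_b, Qb / 2.0)
    gamma = rng.beta(kin.alpha[:, None], kin.beta[:, None], size=(M, N))
    X_s = rng.poisson(config.scale_s * gamma)
    eps = config.epsilon if config.epsilon is not None \
        else float(rng.beta(config.kappa, config.tau))
    Qs = tree.Z[:, cells.clone_index].astype(bool)
    rate = np.where(Qs, gamma, eps)
    R_s = rng.binomial(X_s, rate)
    return ReadCountSet(R_b=R_b, X_b=X_b, R_s=R_s, X_s=X_s)


def simulate_expression(config: SimulationConfig,
                        rng: np.random.Generator) -> ExpressionMatrix:
    """Expression counts for the host gene of each mutation (one gene per
    mutation), beta-Poisson with the configured kinetics and shared scale."""
    kin = config.kinetics()
    gamma = rng.beta(kin.alpha[:, None], kin.beta[:, None],
                     size=(config.M, config.N))
    counts = rng.poisson(config.scale_s * gamma)
    return ExpressionMatrix(counts=counts,
                            gene_ids=[f"gene{m + 1}" for m in range(config.M)])


def simulate_dataset(config: SimulationConfig,
                     rng: np.random.Generator | None = None) -> SimTruth:
    """Full simulated study: ground truth, read counts, and expression."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    tree, cells, bulk = simulate_truth(config, rng)
    data = simulate_counts(tree, cells, bulk, config, rng)
    expression = simulate_expression(config, rng)
    return SimTruth(tree, cells, bulk, data, expression, config)


def run_benchmark_grid(grid: dict, base_config: SimulationConfig,
                       sampler_config: SamplerConfig, n_replicates: int = 100,
                       seed: int = 0) -> pd.DataFrame:
    """Factorial benchmark: simulate, fit, and score each grid cell.

    ``grid`` maps SimulationConfig field names to lists of levels; every
    combination is replicated ``n_replicates`` times with seeds derived from
    ``seed``. Each row of the returned tidy table records the factor levels,
    the replicate index, the three reconstruction errors of the MAP state,
    and whether the clonal configuration Z was recovered exactly. Failed
    replicates are recorded with NaN errors rather than aborting the grid.
    """
    from itertools import product

    keys = sorted(grid)
    rows = []
    for combo_i, levels in enumerate(product(*(grid[k] for k in keys))):
        overrides = dict(zip(keys, levels))
        for rep in range(n_replicates):
            cfg = replace(base_config, **overrides)
            # re-derive M when K varies and M was left at its default
            if "K" in overrides and "M" not in overrides \
                    and base_config.M == base_config.K + 2:
                cfg = replace(cfg, M=cfg.K + 2)
            run_seed = [seed, combo_i, rep]
            row = {k: (str(v) if k == "regime" else v)
                   for k, v in overrides.items()}
            row["replicate"] = rep
            try:
                sim = simulate_dataset(cfg, np.random.default_rng(run_seed))
                derived = (seed * 1_000_003 + combo_i * 8191 + rep) % (2 ** 31)
                scfg = replace(sampler_config, seed=derived)
                chains = run_mcmc(sim.data, cfg.K, cfg.kinetics(),
                                  cfg.error_prior(), scfg)
                tree, cells, bulk, _ = chains.best_state()
                err = reconstruction_error(
                    (tree.Z, cells.P_s, bulk.P_b),
                    (sim.tree.Z, sim.cells.P_s, sim.bulk.P_b))
                row.update(error_Z=err.error_Z, error_Ps=err.error_Ps,
                           error_Pb=err.error_Pb,
                           correct_Z=bool(err.error_Z == 0), failed=False)
            except Exception as exc:  # record, do not abort the grid
                row.update(error_Z=np.nan, error_Ps=np.nan, error_Pb=np.nan,
                           correct_Z=False, failed=True, message=str(exc))
            rows.append(row)
    return pd.DataFrame(rows)
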