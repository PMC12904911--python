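"""Metropolis-within-Gibbs sampler over clonal trees, cell assignments, and
bulk compositions.

The target is the posterior proportional to the coefficient-free joint log
density under flat priors on tree space, on cell-to-clone assignments, and on
the bulk composition simplices. One sweep applies, in order:

* ``M`` tree-move attempts, each a symmetric Metropolis proposal chosen
  between per-mutation edge relocation and a topology rearrangement
  (rooted nearest-neighbor interchange on the tumor subtree, degenerating to a
  tumor-leaf label swap when no NNI exists) according to ``move_weights``.
  Tree moves are judged against the partially collapsed posterior in which
  the cell assignments are summed out exactly (each cell contributes an
  enumerable K-way mixture), so a tree rearrangement is not vetoed by the
  assignments drawn under the previous tree;
* one exact Gibbs pass over all cell assignments — cells are conditionally
  independent given the tree, so the full conditional of each cell is an
  enumerable K-way categorical sampled jointly. Redrawing the assignments
  immediately after the collapsed tree moves keeps the sampler a valid
  partially collapsed Gibbs scheme;
* one Metropolis-Hastings pass over bulk composition columns with a
  Dirichlet random-walk proposal centered at the current column.

Proposals that break tree identifiability (an unoccupied internal tumor edge,
or duplicate clone columns in Z) are rejected outright, so every retained
state is a valid clonal configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .likelihood import LikelihoodCache
from .tree import (DELTA, BulkComposition, BurstingKinetics, CellAssignment,
                   ClonalTree, ErrorPrior, ReadCountSet, floor_simplex)

DEFAULT_MOVE_WEIGHTS = {"relocate_mutation": 0.7, "topology_swap": 0.3}


@dataclass
class SamplerConfig:
    """MCMC run configuration.

    Defaults follow common practice for this model class: 10,000 iterations
    with 20% burn-in and 20 chains; 50,000 iterations are recommended for more
    than six subclones. ``proposal_conc`` is the concentration of the Dirichlet
    random walk for bulk composition columns (larger = smaller steps).
    """

    n_iter: int = 10_000
    n_chains: int = 20
    burnin_frac: float = 0.20
    thin: int = 1
    seed: int = 0
    proposal_conc: float = 100.0
    move_weights: dict = field(default_factory=lambda: dict(DEFAULT_MOVE_WEIGHTS))

    def __post_init__(self):
        if not (0 <= self.burnin_frac < 1):
            raise ValueError("burnin_frac must lie in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        w = sum(self.move_weights.values())
        if w <= 0:
            raise ValueError("move_weights must have positive total mass")
        self.move_weights = {k: v / w for k, v in self.move_weights.items()}

    @property
    def burnin(self) -> int:
        return int(self.burnin_frac * self.n_iter)


@dataclass
class ChainResult:
    """Retained samples and bookkeeping for one MCMC chain."""

    trees: list
    cells: list
    bulks: list
    log_densities: np.ndarray
    acceptance: dict
    seed_key: tuple

    def __len__(self) -> int:
        return len(self.trees)


@dataclass
class PosteriorChains:
    """Retained posterior samples across independent chains."""

    chains: list
    config: SamplerConfig
    K: int

    @property
    def n_chains(self) -> int:
        return len(self.chains)

    def log_density_list(self) -> list[np.ndarray]:
        return [c.log_densities for c in self.chains]

    def best_state(self):
        """Highest-log-density retained state across all chains (MAP draw)."""
        best = None
        for c in self.chains:
            if len(c) == 0:
                continue
            i = int(np.argmax(c.log_densities))
            if best is None or c.log_densities[i] > best[3]:
                best = (c.trees[i], c.cells[i], c.bulks[i], float(c.log_densities[i]))
        if best is None:
            raise ValueError("no retained samples")
        return best


def _cell_marginal(cache: LikelihoodCache, Z: np.ndarray):
    """Exact log marginal likelihood of the single-cell data with the cell
    assignments summed out under their flat prior (constant -N log K dropped),
    plus the per-clone score matrix used for the subsequent Gibbs draw."""
    scores = cache.clone_scores(Z)  # (K, N)
    if scores.shape[1] == 0:
        return cache.lc0_sum, scores
    m = scores.max(axis=0)
    marg = cache.lc0_sum + float(np.sum(m + np.log(
        np.sum(np.exp(scores - m), axis=0))))
    return marg, scores


class _State:
    """Mutable chain state with cached log-density terms.

    Tree moves are judged against the partially collapsed posterior (cell
    assignments marginalized out); ``cell_term`` tracks the uncollapsed cell
    contribution of the currently drawn assignments for reporting.
    """

    __slots__ = ("tree", "cells", "bulk", "bulk_term", "cell_term",
                 "cell_marg", "scores")

    def __init__(self, cache: LikelihoodCache, tree, cells, bulk):
        self.tree = tree
        self.cells = cells
        self.bulk = bulk
        self.bulk_term = cache.bulk_term(tree.Z, bulk.P_b)
        self.cell_term = cache.cell_term(tree.Z, cells.clone_index)
        self.cell_marg, self.scores = _cell_marginal(cache, tree.Z)

    @property
    def logdens(self) -> float:
        return self.bulk_term + self.cell_term


def _tree_is_identifiable(tree: ClonalTree) -> bool:
    counts = np.bincount(tree.branch_of_mutation, minlength=tree.n_nodes)
    if (counts[tree.internal_tumor_edges] == 0).any():
        return False
    Z = tree.Z
    cols = {Z[:, k].tobytes() for k in range(tree.K)}
    return len(cols) == tree.K


def initialize_state(data: ReadCountSet, K: int, kinetics: BurstingKinetics,
                     error_prior: ErrorPrior, rng: np.random.Generator,
                     cache: LikelihoodCache | None = None,
                     max_tries: int = 1000):
    """Random valid initial state.

    Topology is a uniform random bifurcation; mutations are placed uniformly
    on eligible edges and resampled until the identifiability constraints hold
    (every internal tumor edge occupied, distinct clone columns). Cells start
    at their likelihood-maximizing clone given the initial tree; bulk columns
    are symmetric-Dirichlet draws floored at the positivity bound.
    """
    if K < 2:
        raise ValueError("K must be at least 2")
    if cache is None:
        cache = LikelihoodCache(data, kinetics, error_prior)
    M = data.M
    n_internal = max(K - 2, 0)  # internal tumor edges incl. the truncal edge
    tree = None
    for _ in range(max_tries):
        parent = ClonalTree.random_topology(K, rng)
        placement = rng.choice(np.arange(2, 2 * K - 1), size=M)
        cand = ClonalTree(K, parent, placement)
        if _tree_is_identifiable(cand):
            tree = cand
            break
    if tree is None:
        raise ValueError(
            f"could not draw an identifiable tree with M={M} mutations and "
            f"K={K} clones ({n_internal} internal tumor edges); "
            "reduce K or provide more mutations")
    if data.N:
        scores = cache.clone_scores(tree.Z)
        cells = CellAssignment(np.argmax(scores, axis=0), K)
    else:
        cells = CellAssignment(np.empty(0, dtype=int), K)
    P = rng.dirichlet(np.ones(K), size=data.T).T if data.T else np.empty((K, 0))
    bulk = BulkComposition.floored(P) if data.T else BulkComposition(np.empty((K, 0)))
    return tree, cells, bulk


# -- individual moves ------------------------------------------------------

def update_mutation_placement(state: _State, cache: LikelihoodCache,
                              rng: np.random.Generator) -> bool:
    """Exact Gibbs relocation of one mutation over all eligible edges.

    The full conditional of a mutation's branch given everything else (with
    cell assignments collapsed) is an enumerable categorical over the
    eligible edges; candidates that would break identifiability get zero
    mass. Because the current edge is always a valid candidate the support is
    never empty. Returns True when the mutation actually moved.
    """
    tree = state.tree
    if tree.M == 0 or tree.eligible_edges.size < 2:
        return False
    m = int(rng.integers(tree.M))
    current = int(tree.branch_of_mutation[m])
    edges = tree.eligible_edges
    mask = tree.leaf_masks()
    Z = tree.Z
    rows = mask[edges].astype(np.int8)                   # (E, K) candidate rows
    # identifiability screen. Internal-edge occupancy: removing m can empty at
    # most the one internal edge it sat on, in which case only that edge is a
    # valid destination for it.
    occ_ok = np.ones(edges.size, dtype=bool)
    if current > tree.K and \
            np.count_nonzero(tree.branch_of_mutation == current) == 1:
        occ_ok = edges == current
    # distinct clone columns: a candidate row breaks identifiability iff some
    # clone pair with identical columns elsewhere gets identical entries in
    # row m too
    Zo = np.delete(Z, m, axis=0)
    eq_pairs = [(k1, k2) for k1 in range(tree.K) for k2 in range(k1 + 1, tree.K)
                if (Zo[:, k1] == Zo[:, k2]).all()]
    if eq_pairs:
        col_ok = np.array([all(r[k1] != r[k2] for k1, k2 in eq_pairs)
                           for r in rows])
        valid = occ_ok & col_ok
    else:
        valid = occ_ok
    # bulk row term per candidate
    half_q = (rows @ state.bulk.P_b) * 0.5               # (E, T)
    with np.errstate(divide="ignore"):
        bulk_rows = (cache._Rb[m] * np.log(half_q)
                     + cache._XmRb[m] * np.log1p(-half_q)).sum(axis=1)
    bulk_rows = np.where(np.isnan(bulk_rows), -np.inf, bulk_rows)
    # collapsed cell term per candidate: only row m's contribution changes
    if state.cells.N:
        S0 = state.scores - Z[m].astype(float)[:, None] * cache.delta[m][None, :]
        S = S0[None, :, :] + rows.astype(float)[:, :, None] \
            * cache.delta[m][None, None, :]              # (E, K, N)
        mx = S.max(axis=1)
        cell_rows = np.sum(mx + np.log(np.sum(np.exp(S - mx[:, None, :]),
                                              axis=1)), axis=1)
    else:
        cell_rows = np.zeros(edges.size)
    logw = np.where(valid, bulk_rows + cell_rows, -np.inf)
    logw = logw - logw.max()
    w = np.exp(logw)
    choice = int(rng.choice(edges.size, p=w / w.sum()))
    new_edge = int(edges[choice])
    if new_edge == current:
        return False
    cand = tree.copy()
    cand.branch_of_mutation[m] = new_edge
    cand._leaf_mask = mask
    cand._Z = Z.copy()
    cand._Z[m] = rows[choice]
    state.tree = cand
    state.bulk_term = cache.bulk_term(cand._Z, state.bulk.P_b)
    state.cell_marg, state.scores = _cell_marginal(cache, cand._Z)
    return True


def _propose_topology(tree: ClonalTree, rng: np.random.Generator):
    """Symmetric topology proposal: rooted NNI when an internal non-root tumor
    node exists (K >= 4), mixed 50/50 with a tumor-leaf label swap; pure label
    swap for K = 3; no move for K = 2."""
    K = tree.K
    if K == 2:
        return None
    can_nni = K >= 4
    if can_nni and rng.random() < 0.5:
        # NNI: swap the sibling of internal node v with one of v's children.
        # Eligible v: internal tumor nodes other than the tumor-subtree root
        # (the node whose parent is the root); there are always K-3 of them,
        # so the uniform choice has state-independent support size.
        internal = [u for u in range(K + 1, 2 * K - 1) if tree.parent[u] != 0]
        v = internal[int(rng.integers(len(internal)))]
        cand = tree.copy()
        u = cand.parent[v]
        sib = next(c for c in range(2, cand.n_nodes)
                   if cand.parent[c] == u and c != v)
        ch = [c for c in range(2, cand.n_nodes) if cand.parent[c] == v]
        child = ch[int(rng.integers(2))]
        cand.parent[sib] = v
        cand.parent[child] = u
        cand._Z = None
        cand._leaf_mask = None
        return cand
    # tumor-leaf label swap: exchange positions of two clone leaves, with
    # pendant-edge mutations staying on their physical branches
    k1, k2 = rng.choice(np.arange(2, K + 1), size=2, replace=False)
    cand = tree.copy()
    cand.parent[k1], cand.parent[k2] = cand.parent[k2], cand.parent[k1]
    bom = cand.branch_of_mutation
    i1, i2 = bom == k1, bom == k2
    bom[i1], bom[i2] = k2, k1
    cand._Z = None
    cand._leaf_mask = None
    return cand


def _composition_estimate(cache: LikelihoodCache, Z: np.ndarray) -> np.ndarray:
    """Deterministic (K, T) composition estimate under a given Z: non-negative
    least squares of the doubled bulk VAFs on the tumor clone indicators, with
    the normal clone absorbing the remaining mass. Used only as the center of
    an independence proposal; correctness requires determinism, not accuracy.
    Memoized on Z (the estimate depends only on Z and the fixed data)."""
    from scipy.optimize import nnls
    memo = cache.__dict__.setdefault("_comp_memo", {})
    key = Z.tobytes()
    if key in memo:
        return memo[key]
    R, X = cache.data.R_b, cache.data.X_b
    K = Z.shape[1]
    T = R.shape[1]
    A = Z[:, 1:].astype(float)
    P = np.empty((K, T))
    with np.errstate(invalid="ignore"):
        vaf = np.where(X > 0, R / np.maximum(X, 1), 0.0)
    for t in range(T):
        q = np.clip(2.0 * vaf[:, t], 0.0, 1.0)
        p_tum, _ = nnls(A, q)
        total = p_tum.sum()
        if total > 1.0:
            p_tum = p_tum / total
            total = 1.0
        P[0, t] = 1.0 - total
        P[1:, t] = p_tum
    P = np.maximum(P, DELTA)
    P = P / P.sum(axis=0, keepdims=True)
    memo[key] = P
    return P


def update_topology(state: _State, cache: LikelihoodCache,
                    rng: np.random.Generator, conc: float = 100.0) -> bool:
    """MH topology rearrangement, optionally jointly with a bulk redraw.

    Half of the attempts hold the bulk composition fixed (plain symmetric
    Metropolis). The other half redraw every bulk column from a Dirichlet
    independence proposal centered at a deterministic least-squares
    composition estimate under the proposed tree, with the matching Hastings
    correction — without this, a composition adapted to the current tree
    vetoes otherwise favorable rearrangements.
    """
    cand = _propose_topology(state.tree, rng)
    if cand is None:
        return False
    joint = state.bulk.T > 0 and rng.random() < 0.5
    if not _tree_is_identifiable(cand):
        return False
    new_marg, new_scores = _cell_marginal(cache, cand.Z)
    if not joint:
        new_bulk = cache.bulk_term(cand.Z, state.bulk.P_b)
        d = (new_bulk - state.bulk_term) + (new_marg - state.cell_marg)
        if np.log(rng.random()) < d:
            state.tree = cand
            state.bulk_term = new_bulk
            state.cell_marg = new_marg
            state.scores = new_scores
            return True
        return False
    center_fwd = _composition_estimate(cache, cand.Z)
    center_rev = _composition_estimate(cache, state.tree.Z)
    P_prop = np.empty_like(state.bulk.P_b)
    log_q_fwd = 0.0
    log_q_rev = 0.0
    for t in range(state.bulk.T):
        raw = rng.dirichlet(conc * center_fwd[:, t])
        P_prop[:, t] = floor_simplex(raw)
        log_q_fwd += _dirichlet_logpdf(raw, conc * center_fwd[:, t])
        log_q_rev += _dirichlet_logpdf(state.bulk.P_b[:, t],
                                       conc * center_rev[:, t])
    new_bulk = cache.bulk_term(cand.Z, P_prop)
    d = (new_bulk - state.bulk_term) + (new_marg - state.cell_marg) \
        + (log_q_rev - log_q_fwd)
    if np.log(rng.random()) < d:
        state.tree = cand
        state.bulk = BulkComposition(P_prop)
        state.bulk_term = new_bulk
        state.cell_marg = new_marg
        state.scores = new_scores
        return True
    return False


def update_cell_assignments(state: _State, cache: LikelihoodCache,
                            rng: np.random.Generator) -> None:
    """Exact Gibbs update of all cell assignments (conditionally independent
    given the tree, so one joint categorical draw per cell is a full pass)."""
    N = state.cells.N
    if N == 0:
        return
    scores = state.scores  # (K, N), cached for the current tree
    gumbel = rng.gumbel(size=scores.shape)
    idx = np.argmax(scores + gumbel, axis=0)
    state.cells = CellAssignment(idx, state.cells.K)
    state.cell_term = cache.lc0_sum + float(scores[idx, np.arange(N)].sum())


def _dirichlet_logpdf(x: np.ndarray, a: np.ndarray) -> float:
    if (x <= 0).any():
        return -np.inf
    return float(np.sum((a - 1) * np.log(x)) - np.sum(gammaln(a))
                 + gammaln(np.sum(a)))


def update_bulk_composition(state: _State, cache: LikelihoodCache,
                            rng: np.random.Generator,
                            conc: float) -> tuple[int, int]:
    """Dirichlet random-walk MH update of each bulk composition column."""
    T = state.bulk.T
    if T == 0:
        return 0, 0
    Z = state.tree.Z
    accepted = 0
    P = state.bulk.P_b.copy()
    for t in range(T):
        p = P[:, t]
        raw = rng.dirichlet(conc * p)
        if (raw <= 0).any():  # degenerate draw under tiny concentrations
            continue
        prop = floor_simplex(raw)
        d_ll = cache.bulk_term_column(Z, prop, t) - cache.bulk_term_column(Z, p, t)
        lq_fwd = _dirichlet_logpdf(raw, conc * p)
        lq_rev = _dirichlet_logpdf(p, conc * prop)
        if np.log(rng.random()) < d_ll + lq_rev - lq_fwd:
            P[:, t] = prop
            accepted += 1
            state.bulk_term += d_ll
    state.bulk = BulkComposition(P)
    return accepted, T


# -- main driver -----------------------------------------------------------

def run_chain(data: ReadCountSet, K: int, kinetics: BurstingKinetics,
              error_prior: ErrorPrior, config: SamplerConfig,
              seed_key: tuple, cache: LikelihoodCache | None = None) -> ChainResult:
    rng = np.random.default_rng(list(seed_key))
    if cache is None:
        cache = LikelihoodCache(data, kinetics, error_prior)
    tree, cells, bulk = initialize_state(data, K, kinetics, error_prior, rng,
                                         cache=cache)
    state = _State(cache, tree, cells, bulk)

    w_rel = config.move_weights.get("relocate_mutation", 0.0)
    w_top = config.move_weights.get("topology_swap", 0.0)
    p_rel = w_rel / (w_rel + w_top) if (w_rel + w_top) > 0 else 1.0

    burnin = config.burnin
    trees, cells_out, bulks, lds = [], [], [], []
    att = {"relocate_mutation": 0, "topology_swap": 0, "update_bulk": 0}
    acc = dict(att)
    n_tree_moves = max(data.M, 1)
    for it in range(config.n_iter):
        for _ in range(n_tree_moves):
            if rng.random() < p_rel:
                att["relocate_mutation"] += 1
                acc["relocate_mutation"] += update_mutation_placement(state, cache, rng)
            else:
                att["topology_swap"] += 1
                acc["topology_swap"] += update_topology(
                    state, cache, rng, conc=config.proposal_conc)
        update_cell_assignments(state, cache, rng)
        a, n = update_bulk_composition(state, cache, rng, config.proposal_conc)
        acc["update_bulk"] += a
        att["update_bulk"] += n
        j = it - burnin
        if j >= 0 and (j + 1) % config.thin == 0:
            trees.append(state.tree)  # states are immutable once replaced
            cells_out.append(state.cells)
            bulks.append(state.bulk)
            lds.append(state.logdens)
    if not trees:
        warnings.warn("no retained samples: n_iter does not exceed burn-in",
                      stacklevel=2)
    rates = {k: (acc[k] / att[k] if att[k] else np.nan) for k in att}
    return ChainResult(trees, cells_out, bulks, np.asarray(lds, dtype=float),
                       rates, seed_key)


def run_mcmc(data: ReadCountSet, K: int, kinetics: BurstingKinetics,
             error_prior: ErrorPrior, config: SamplerConfig) -> PosteriorChains:
    """Run ``config.n_chains`` independent chains.

    Chain ``j`` is seeded with the key ``(config.seed, j)`` fed to numpy's
    seed-sequence mechanism, so runs are reproducible across platforms and
    chains are order-insensitive.
    """
    cache = LikelihoodCache(data, kinetics, error_prior)
    chains = [run_chain(data, K, kinetics, error_prior, config,
                        (config.seed, j), cache=cache)
              for j in range(config.n_chains)]
    return PosteriorChains(chains, config, K)
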