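"""Choosing the number of subclones and judging chain convergence.

Under flat priors the posterior is proportional to the likelihood, so the
maximum a posteriori value can stand in for the maximized likelihood in an
information criterion. Per chain, the maximized log posterior is estimated as
the mode of a Gaussian kernel density fitted to the retained log joint
densities; the third quartile of these per-chain values across chains enters

    BIC_MAP = -2 * Q3(log posterior at MAP) + K * log(n),

with effective sample size n = 2(M*N) + 2(M*T), the aggregate dimension of the
four observed count matrices. Smaller is better; ties break toward fewer
subclones (parsimony). Because log is monotone, taking Q3 on the log scale is
identical to logging the Q3 of the raw posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gaussian_kde, norm

from .sampler import PosteriorChains, SamplerConfig, run_mcmc
from .tree import BurstingKinetics, ErrorPrior, ReadCountSet


@dataclass
class BicResult:
    K: int
    per_chain_map: np.ndarray
    q3_map: float
    n_effective: int
    bic: float


def map_estimate_per_chain(log_densities, use_max: bool = False) -> float:
    """Per-chain maximized log posterior via the mode of a KDE.

    Fits a Gaussian kernel density with Silverman bandwidth to the retained
    log joint densities, evaluates it on a 512-point grid spanning the sample
    range extended by three bandwidths, and returns the grid point of maximal
    density. Degenerate samples (constant, or a single draw) return the
    constant value. With ``use_max`` the raw maximum retained log density is
    returned instead.
    """
    x = np.asarray(log_densities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty log-density vector")
    if use_max:
        return float(np.max(x))
    sd = float(np.std(x))
    if x.size == 1 or sd <= 1e-12 * max(1.0, abs(float(np.mean(x)))):
        return float(np.mean(x))  # numerically constant sample
    kde = gaussian_kde(x, bw_method="silverman")
    h = float(kde.factor) * sd
    grid = np.linspace(x.min() - 3 * h, x.max() + 3 * h, 512)
    dens = kde(grid)
    return float(grid[int(np.argmax(dens))])


def bic_map(chains: PosteriorChains, K: int, M: int, N: int, T: int,
            use_max: bool = False) -> BicResult:
    """Modified BIC from the third quartile of per-chain MAP estimates."""
    maps = [map_estimate_per_chain(c.log_densities, use_max=use_max)
            for c in chains.chains if len(c)]
    if not maps:
        raise ValueError("no chains with retained samples")
    maps = np.asarray(maps)
    q3 = float(np.quantile(maps, 0.75))  # type-7 linear interpolation
    n_eff = 2 * (M * N) + 2 * (M * T)
    return BicResult(K=K, per_chain_map=maps, q3_map=q3, n_effective=n_eff,
                     bic=-2.0 * q3 + K * np.log(n_eff))


def select_K(data: ReadCountSet, kinetics: BurstingKinetics,
             error_prior: ErrorPrior, K_range, config: SamplerConfig,
             return_chains: bool = False):
    """Run the sampler for each candidate K and pick the BIC minimizer.

    Ties break toward smaller K. Returns ``(best_K, [BicResult, ...])``, plus
    a ``{K: PosteriorChains}`` dict when ``return_chains`` is set.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range or min(K_range) < 2:
        raise ValueError("K_range must be non-empty with every K >= 2")
    table, kept = [], {}
    for K in K_range:
        chains = run_mcmc(data, K, kinetics, error_prior, config)
        table.append(bic_map(chains, K, data.M, data.N, data.T))
        if return_chains:
            kept[K] = chains
    best = min(table, key=lambda r: (r.bic, r.K))
    if return_chains:
        return best.K, table, kept
    return best.K, table


# -- convergence diagnostics ----------------------------------------------

def autocorrelation(x, max_lag: int = 50) -> np.ndarray:
    """Sample lag-ACF up to ``max_lag``; NaN when the series is constant."""
    x = np.asarray(x, dtype=float).ravel()
    n = x.size
    lags = min(max_lag, n - 1)
    out = np.full(max_lag + 1, np.nan)
    v = np.var(x)
    if n < 2 or v == 0:
        return out
    xc = x - x.mean()
    out[0] = 1.0
    for lag in range(1, lags + 1):
        out[lag] = float(np.dot(xc[:-lag], xc[lag:]) / (n * v))
    return out


def rank_normalized_rhat(chains_ld: list[np.ndarray]) -> float:
    """Split rank-normalized potential scale reduction on the log densities.

    Each chain is split in half, pooled values are rank-transformed to normal
    scores, and the classical between/within variance ratio is computed on the
    transformed halves. Values near 1 indicate the chains agree.
    """
    halves = []
    for ld in chains_ld:
        ld = np.asarray(ld, dtype=float)
        h = ld.size // 2
        if h >= 2:
            halves.extend([ld[:h], ld[h:2 * h]])
    if len(halves) < 2:
        return np.nan
    pooled = np.concatenate(halves)
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    z = norm.ppf((ranks - 0.375) / (pooled.size + 0.25))
    z_halves = np.split(z, np.cumsum([h.size for h in halves])[:-1])
    m = len(z_halves)
    n = min(h.size for h in z_halves)
    z_halves = [h[:n] for h in z_halves]
    means = np.array([h.mean() for h in z_halves])
    B = n * np.var(means, ddof=1)
    W = float(np.mean([np.var(h, ddof=1) for h in z_halves]))
    if W == 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


def diagnostics(chains: PosteriorChains, max_lag: int = 50) -> dict:
    """Machine-readable convergence report.

    Per chain: the retained log-density trace, its lag-ACF, and the KDE-mode
    MAP estimate. Cross-chain: split rank-normalized R-hat of the traces.
    """
    per_chain = []
    for j, c in enumerate(chains.chains):
        ld = c.log_densities
        entry = {
            "chain": j,
            "n_retained": int(ld.size),
            "trace": ld,
            "acf": autocorrelation(ld, max_lag=max_lag) if ld.size else None,
            "map": map_estimate_per_chain(ld) if ld.size else np.nan,
            "acceptance": c.acceptance,
        }
        per_chain.append(entry)
    return {
        "per_chain": per_chain,
        "rhat": rank_normalized_rhat([c.log_densities for c in chains.chains]),
    }
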