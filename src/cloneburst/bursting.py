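"""Transcriptional bursting kinetics from single-cell expression counts.

Bursty transcription is summarized by the two-state (telegraph) model: a gene
switches on at rate ``alpha`` and off at rate ``beta``, and the realized
activity of cell ``n`` is a draw ``gamma ~ Beta(alpha, beta)``. Observed
expression counts are then beta-Poisson,

    y_n ~ Poisson(s * sf_n * gamma_n),

with ``s`` a scale (exposure) parameter and ``sf_n`` the cell's library-size
factor. Kinetics are estimated per gene, independently of any mutation carrier
status, which decouples the expression stochasticity from the phylogeny.

Two estimators are provided: closed-form factorial-moment matching (fast, but
can return negative estimates on noisy data) and direct maximum likelihood
with fixed-order Gauss-Jacobi quadrature over the latent activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import betaln, gammaln, logsumexp, roots_jacobi

from .tree import BurstingKinetics, DimensionError

#: Fallback kinetics when neither estimator yields a valid fit: the "bursty"
#: regime alpha = beta = 0.5, a neutral default.
FALLBACK_KINETICS = (0.5, 0.5)


@dataclass
class ExpressionMatrix:
    """Genes-by-cells expression count matrix with library-size factors."""

    counts: np.ndarray
    gene_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    size_factors: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise DimensionError("counts must be a genes x cells matrix")
        if (self.counts < 0).any():
            raise ValueError("expression counts must be non-negative")
        if not self.gene_ids:
            self.gene_ids = [f"gene{i + 1}" for i in range(self.counts.shape[0])]
        if self.size_factors is None:
            self.size_factors = compute_size_factors(self.counts)
        else:
            self.size_factors = np.asarray(self.size_factors, dtype=float)
            if (self.size_factors <= 0).any():
                raise ValueError("size factors must be positive")

    @property
    def G(self) -> int:
        return self.counts.shape[0]

    @property
    def N(self) -> int:
        return self.counts.shape[1]


@dataclass
class BetaPoissonFit:
    """A fitted beta-Poisson model for one gene."""

    alpha: float
    beta: float
    scale: float
    method: str  # moments | mle | fallback
    valid: bool
    loglik: float = np.nan


def compute_size_factors(counts: np.ndarray) -> np.ndarray:
    """Library-size factors: cell total over the median total of nonzero cells.

    Cells with zero totals get factor 1 (with a warning) so downstream
    normalization is a no-op for them.
    """
    counts = np.asarray(counts)
    totals = counts.sum(axis=0).astype(float)
    nonzero = totals > 0
    if not nonzero.any():
        raise ValueError("all cells have zero total counts")
    med = float(np.median(totals[nonzero]))
    factors = totals / med
    if (~nonzero).any():
        warnings.warn(f"{int((~nonzero).sum())} cell(s) with zero total counts "
                      "assigned size factor 1", stacklevel=2)
        factors[~nonzero] = 1.0
    return factors


def _factorial_moments(y: np.ndarray) -> tuple[float, float, float]:
    y = y.astype(float)
    m1 = float(np.mean(y))
    m2 = float(np.mean(y * (y - 1)))
    m3 = float(np.mean(y * (y - 1) * (y - 2)))
    return m1, m2, m3


def solve_moment_system(m1: float, m2: float, m3: float):
    """Solve the three beta-Poisson factorial-moment equations for (alpha, beta, s).

    With A = alpha + beta, the k-th factorial moment is
    ``s^k * prod_{i<k} (alpha+i)/(A+i)``, so the ratios r1 = m1, r2 = m2/m1,
    r3 = m3/m2 satisfy three linear relations in (s*alpha, s, A) that eliminate
    to a closed form. Returns None when the system is degenerate.
    """
    if m1 <= 0 or m2 <= 0 or m3 <= 0:
        return None
    r1, r2, r3 = m1, m2 / m1, m3 / m2
    denom = 2 * r2 - r1 - r3
    if denom == 0:
        return None
    A = 2 * (r3 - r2) / denom
    s = (r2 - r1) * A + r2
    if s == 0:
        return None
    alpha = r1 * A / s
    beta = A - alpha
    return alpha, beta, s


def fit_beta_poisson_moments(y, size_factors=None) -> BetaPoissonFit:
    """Method-of-moments beta-Poisson fit on library-size-normalized counts.

    Counts are divided by their size factors and rounded to the nearest
    integer before computing factorial moments. The closed-form solution can
    land outside the parameter space on noisy or degenerate data; such fits
    are returned with ``valid=False`` rather than raising.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if size_factors is not None:
        y = y / np.asarray(size_factors, dtype=float)
    y = np.round(y)
    sol = solve_moment_system(*_factorial_moments(y))
    if sol is None:
        return BetaPoissonFit(np.nan, np.nan, np.nan, "moments", False)
    alpha, beta, s = sol
    ok = all(np.isfinite(v) and v > 0 for v in (alpha, beta, s))
    return BetaPoissonFit(float(alpha), float(beta), float(s), "moments", ok)


def beta_poisson_loglik(y, size_factors, alpha: float, beta: float, s: float,
                        n_quad: int = 50) -> float:
    """Beta-Poisson log likelihood via fixed-order Gauss-Jacobi quadrature.

    The mixture integral over gamma in (0, 1) carries the Beta(alpha, beta)
    kernel as the Jacobi weight function, so endpoint singularities for
    alpha < 1 or beta < 1 are handled exactly by the quadrature rule.
    """
    y = np.asarray(y, dtype=float).ravel()
    sf = np.ones_like(y) if size_factors is None \
        else np.broadcast_to(np.asarray(size_factors, dtype=float), y.shape)
    # collapse identical (count, size factor) pairs
    pairs, counts = np.unique(np.column_stack([y, sf]), axis=0, return_counts=True)
    yu, sfu = pairs[:, 0], pairs[:, 1]
    nodes, weights = roots_jacobi(n_quad, beta - 1.0, alpha - 1.0)
    gam = (1.0 + nodes) / 2.0
    lam = s * sfu[:, None] * gam[None, :]          # (n_unique, n_quad)
    log_pois = yu[:, None] * np.log(lam) - lam - gammaln(yu + 1)[:, None]
    log_norm = -(alpha + beta - 1) * np.log(2.0) - betaln(alpha, beta)
    ll = logsumexp(log_pois + np.log(weights)[None, :], axis=1) + log_norm
    return float(np.dot(counts, ll))


def fit_beta_poisson_mle(y, size_factors=None, init: BetaPoissonFit | None = None,
                         n_quad: int = 50) -> BetaPoissonFit:
    """Maximum-likelihood beta-Poisson fit by direct optimization.

    Optimizes (log alpha, log beta, log s) with Nelder-Mead, starting from the
    moment solution when one is supplied and valid, otherwise from
    alpha = beta = 1 with s matched to twice the normalized mean.
    """
    y = np.asarray(y, dtype=float).ravel()
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    sf = None if size_factors is None else np.asarray(size_factors, dtype=float)
    ybar = np.mean(y if sf is None else y / sf)
    if ybar == 0 or np.ptp(y) == 0:
        return BetaPoissonFit(np.nan, np.nan, np.nan, "mle", False)
    if init is not None and init.valid:
        x0 = np.log([init.alpha, init.beta, init.scale])
    else:
        x0 = np.log([1.0, 1.0, max(2.0 * ybar, 1e-3)])

    def nll(x):
        a, b, s = np.exp(np.clip(x, -12, 12))
        try:
            return -beta_poisson_loglik(y, sf, a, b, s, n_quad=n_quad)
        except (ValueError, FloatingPointError):
            return np.inf

    res = minimize(nll, x0, method="Nelder-Mead",
                   options={"maxiter": 600, "xatol": 1e-5, "fatol": 1e-7})
    a, b, s = np.exp(np.clip(res.x, -12, 12))
    ok = bool(res.success) and np.isfinite(res.fun) \
        and all(v > 0 and np.isfinite(v) for v in (a, b, s))
    return BetaPoissonFit(float(a), float(b), float(s), "mle", ok,
                          loglik=-float(res.fun))


def kinetics_for_mutations(expr: ExpressionMatrix, mutation_to_gene: dict,
                           mutation_ids=None):
    """Per-mutation bursting kinetics from the expression of the host genes.

    For each mutation the gene's counts are fit by moments, falling back to
    MLE when the moment solution is invalid, and finally to the neutral bursty
    default (0.5, 0.5) with a warning. Returns the kinetics plus a record of
    the method used per mutation.
    """
    if mutation_ids is None:
        mutation_ids = list(mutation_to_gene.keys())
    gene_index = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [m for m in mutation_ids if mutation_to_gene.get(m) not in gene_index]
    if missing:
        raise KeyError("mutations mapped to genes absent from the expression "
                       f"matrix: {missing}")
    alphas, betas, methods = [], [], []
    for m in mutation_ids:
        counts = expr.counts[gene_index[mutation_to_gene[m]]]
        fit = fit_beta_poisson_moments(counts, expr.size_factors)
        if not fit.valid:
            fit = fit_beta_poisson_mle(counts, expr.size_factors, init=None)
        if not fit.valid:
            warnings.warn(f"no valid beta-Poisson fit for mutation {m}; "
                          f"using bursty fallback {FALLBACK_KINETICS}", stacklevel=2)
            fit = BetaPoissonFit(*FALLBACK_KINETICS, np.nan, "fallback", True)
        alphas.append(fit.alpha)
        betas.append(fit.beta)
        methods.append(fit.method)
    return BurstingKinetics(np.array(alphas), np.array(betas)), methods
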