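"""Exact log-probability computations for the hierarchical read-count model.

Bulk alternative read counts are binomial with success probability q/2, where
q is the fraction of cells in the sample carrying the mutation (heterozygous,
copy-number-neutral assumption). Single-cell alternative read counts follow a
piecewise beta-binomial: in carrier cells the success rate is the latent
transcriptional activity gamma ~ Beta(alpha_m, beta_m); in non-carrier cells it
is the sequencing error epsilon ~ Beta(kappa, tau). Marginalizing the latent
rates gives beta-binomial mass functions, evaluated here entirely in log space
through log-gamma differences.

The joint log density used by the sampler and by model selection drops the
binomial coefficients (they are constant in the parameters and cancel in
Metropolis-Hastings ratios); the full normalized pmfs are available behind the
``include_constant`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln, gammaln

from .tree import (BulkComposition, BurstingKinetics, CellAssignment,
                   ClonalTree, DimensionError, ErrorPrior, ReadCountSet,
                   carrier_fraction_bulk)


@dataclass(frozen=True)
class JointLogDensityParts:
    """Joint log density split into its bulk and single-cell contributions."""

    bulk_term: float
    cell_term: float

    @property
    def total(self) -> float:
        return self.bulk_term + self.cell_term


def _check_counts(r, x):
    r = np.asarray(r)
    x = np.asarray(x)
    if (r < 0).any() or (x < 0).any():
        raise ValueError("read counts must be non-negative")
    if (r > x).any():
        raise ValueError("alternative reads exceed total reads")
    return r, x


def log_binom_coeff(x, r):
    """log C(x, r), vectorized, via log-gamma."""
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    return gammaln(x + 1) - gammaln(r + 1) - gammaln(x - r + 1)


def log_pmf_bulk(r, x, q, include_constant: bool = False):
    """Log pmf of the bulk binomial model: r ~ Binom(x, q/2).

    ``q`` is the carrier fraction in [0, 1]. Returns 0 for the empty support
    (x = r = 0) and -inf where the pmf vanishes (e.g. q = 0 with r > 0).
    Without ``include_constant`` the binomial coefficient is dropped, matching
    the proportional joint density.
    """
    r, x = _check_counts(r, x)
    q = np.asarray(q, dtype=float)
    if (q < 0).any() or (q > 1).any():
        raise ValueError("q must lie in [0, 1]")
    half_q = q / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(r > 0, r * np.log(half_q), 0.0)
        t2 = np.where(x - r > 0, (x - r) * np.log1p(-half_q), 0.0)
    out = t1 + t2
    # 0*log(0) -> 0 already handled; r>0 at q=0 gives -inf, x-r>0 at q=2 cannot
    out = np.where(np.isnan(out), -np.inf, out)
    if include_constant:
        out = out + log_binom_coeff(x, r)
    return out if out.ndim else float(out)


def log_pmf_cell(r, x, carrier, kinetics, error_prior, include_constant: bool = False):
    """Log pmf of the piecewise beta-binomial single-cell model.

    For carrier cells (carrier=1) the success rate is marginalized over
    Beta(alpha, beta); for non-carriers over Beta(kappa, tau):

        P(r | x) = C(x, r) * B(r + a, x - r + b) / B(a, b)

    with (a, b) = (alpha, beta) or (kappa, tau). Shapes broadcast; ``kinetics``
    is an (alpha, beta) pair and ``error_prior`` a (kappa, tau) pair.
    """
    r, x = _check_counts(r, x)
    alpha, beta = kinetics if not isinstance(kinetics, BurstingKinetics) \
        else (kinetics.alpha, kinetics.beta)
    kappa, tau = (error_prior.kappa, error_prior.tau) \
        if isinstance(error_prior, ErrorPrior) else error_prior
    for name, v in (("alpha", alpha), ("beta", beta), ("kappa", kappa), ("tau", tau)):
        if (np.asarray(v) <= 0).any():
            raise ValueError(f"{name} must be strictly positive")
    carrier = np.asarray(carrier)
    lb1 = betaln(r + alpha, x - r + beta) - betaln(alpha, beta)
    lb0 = betaln(r + kappa, x - r + tau) - betaln(kappa, tau)
    out = np.where(carrier == 1, lb1, lb0)
    if include_constant:
        out = out + log_binom_coeff(x, r)
    return out if out.ndim else float(out)


class LikelihoodCache:
    """Precomputed single-cell log-pmf terms for fast joint-density evaluation.

    The two beta-binomial branches of every (mutation, cell) entry depend only
    on the observed counts and the fixed hyperparameters, never on the tree
    state, so they are tabulated once: ``lc0`` (non-carrier branch), and
    ``delta = lc1 - lc0``. The cell contribution of any configuration is then
    ``lc0.sum() + sum of delta over carrier entries``.
    """

    def __init__(self, data: ReadCountSet, kinetics: BurstingKinetics,
                 error_prior: ErrorPrior):
        if kinetics.M != data.M:
            raise DimensionError("kinetics length must equal number of mutations")
        r, x = data.R_s, data.X_s
        a = kinetics.alpha[:, None]
        b = kinetics.beta[:, None]
        lc1 = betaln(r + a, x - r + b) - betaln(a, b)
        lc0 = betaln(r + error_prior.kappa, x - r + error_prior.tau) \
            - betaln(error_prior.kappa, error_prior.tau)
        self.lc0 = lc0
        self.delta = lc1 - lc0
        self.lc0_sum = float(lc0.sum())
        self.data = data
        self._Rb = data.R_b.astype(float)
        self._XmRb = (data.X_b - data.R_b).astype(float)

    def cell_term(self, Z: np.ndarray, clone_index: np.ndarray) -> float:
        """Cell contribution for carrier matrix Q^s = Z[:, clone_index]."""
        Qs = Z[:, clone_index].astype(bool)
        return self.lc0_sum + float(self.delta[Qs].sum())

    def clone_scores(self, Z: np.ndarray) -> np.ndarray:
        """(K, N) matrix of per-cell log densities under each clone assignment.

        Entry (k, n) is cell n's total single-cell log density if assigned to
        clone k, up to the shared lc0 column sums (which cancel when the
        columns are normalized).
        """
        return Z.T.astype(float) @ self.delta

    def bulk_term(self, Z: np.ndarray, P_b: np.ndarray) -> float:
        """Fast bulk term. Precondition (guaranteed for identifiable trees
        with floored compositions): every carrier fraction is in (0, 1)."""
        half_q = (Z.astype(float) @ P_b) * 0.5
        return float(np.sum(self._Rb * np.log(half_q)
                            + self._XmRb * np.log1p(-half_q)))

    def bulk_term_column(self, Z: np.ndarray, p_col: np.ndarray, t: int) -> float:
        half_q = (Z.astype(float) @ p_col) * 0.5
        return float(self._Rb[:, t] @ np.log(half_q)
                     + self._XmRb[:, t] @ np.log1p(-half_q))


def bulk_loglik(R_b, X_b, Q_b) -> float:
    """Coefficient-free bulk binomial log likelihood, summed over entries."""
    half_q = np.asarray(Q_b, dtype=float) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(R_b > 0, R_b * np.log(half_q), 0.0)
        t2 = np.where(X_b - R_b > 0, (X_b - R_b) * np.log1p(-half_q), 0.0)
    s = t1 + t2
    s = np.where(np.isnan(s), -np.inf, s)
    return float(s.sum())


def joint_log_density(data: ReadCountSet, tree: ClonalTree, cells: CellAssignment,
                      bulk: BulkComposition, kinetics: BurstingKinetics,
                      error_prior: ErrorPrior) -> JointLogDensityParts:
    """Coefficient-free joint log density of bulk and single-cell read counts.

    The bulk term sums ``r log(q/2) + (x - r) log(1 - q/2)`` over mutations and
    samples with q the bulk carrier fraction; the cell term sums the piecewise
    beta-binomial log masses (without binomial coefficients) over mutations and
    cells. Entries with x = r = 0 contribute their exact (generally nonzero,
    for the cell term) value.
    """
    if tree.M != data.M or kinetics.M != data.M:
        raise DimensionError("mutation dimensions do not conform")
    if cells.N != data.N or cells.K != tree.K or bulk.K != tree.K or bulk.T != data.T:
        raise DimensionError("cell/bulk dimensions do not conform")
    if np.isnan(bulk.P_b).any():
        raise ValueError("NaN in bulk composition")
    Qb = carrier_fraction_bulk(tree, bulk)
    bulk_term = bulk_loglik(data.R_b, data.X_b, Qb)
    Qs = tree.Z[:, cells.clone_index]
    cell = log_pmf_cell(data.R_s, data.X_s, Qs,
                        (kinetics.alpha[:, None], kinetics.beta[:, None]),
                        error_prior)
    return JointLogDensityParts(bulk_term=bulk_term, cell_term=float(np.sum(cell)))
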