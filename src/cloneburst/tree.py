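"""Domain types for clonal tree inference.

A tumor is modeled as ``K`` clones: clone 1 is the normal (mutation-free)
population and clones ``2..K`` are tumor subclones arranged as the leaves of a
rooted bifurcating tree. Somatic mutations are placed on edges of the tumor
subtree; a clone carries every mutation on its root-to-leaf path. The binary
mutation-to-clone matrix ``Z`` (M x K) is derived from the tree, which
guarantees the perfect-phylogeny (laminar carrier set) property by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Positivity floor for bulk clonal proportions. A clone proportion of exactly
#: zero makes any observed alternative read at a mutation carried only by that
#: clone impossible (zero likelihood), so the continuous state space excludes it.
DELTA = 1e-4


class DimensionError(ValueError):
    """Raised when matrix dimensions do not conform."""


def floor_simplex(v: np.ndarray, delta: float = DELTA) -> np.ndarray:
    """Project a non-negative vector onto the simplex with entries >= delta.

    Entries are floored at delta and the excess mass is removed
    proportionally from the remaining entries; a final adjustment of the
    largest entry (always far above delta) makes the sum exactly one.
    """
    v = np.maximum(np.asarray(v, dtype=float), delta)
    for _ in range(3):
        excess = v.sum() - 1.0
        if excess == 0:
            break
        over = v > delta
        v[over] -= excess * v[over] / v[over].sum()
        v = np.maximum(v, delta)
    v[np.argmax(v)] += 1.0 - v.sum()
    return v


def _as_int_matrix(x, name: str) -> np.ndarray:
    a = np.asarray(x)
    if a.ndim != 2:
        raise DimensionError(f"{name} must be 2-dimensional, got shape {a.shape}")
    if not np.issubdtype(a.dtype, np.integer):
        if not np.allclose(a, np.round(a)):
            raise ValueError(f"{name} must contain integer counts")
        a = np.round(a).astype(np.int64)
    return a.astype(np.int64, copy=False)


@dataclass
class ReadCountSet:
    """Paired alternative/total read-count matrices for bulk and single cells.

    Attributes
    ----------
    R_b, X_b : (M, T) integer arrays
        Bulk alternative and total read counts.
    R_s, X_s : (M, N) integer arrays
        Single-cell alternative and total read counts.
    mutation_ids, cell_ids, sample_ids : lists of labels
    """

    R_b: np.ndarray
    X_b: np.ndarray
    R_s: np.ndarray
    X_s: np.ndarray
    mutation_ids: list = field(default_factory=list)
    cell_ids: list = field(default_factory=list)
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.R_b = _as_int_matrix(self.R_b, "R_b")
        self.X_b = _as_int_matrix(self.X_b, "X_b")
        self.R_s = _as_int_matrix(self.R_s, "R_s")
        self.X_s = _as_int_matrix(self.X_s, "X_s")
        M = self.R_b.shape[0]
        if not (self.X_b.shape[0] == self.R_s.shape[0] == self.X_s.shape[0] == M):
            raise DimensionError("mutation dimension M differs across count matrices")
        if self.R_b.shape != self.X_b.shape:
            raise DimensionError("R_b and X_b shapes differ")
        if self.R_s.shape != self.X_s.shape:
            raise DimensionError("R_s and X_s shapes differ")
        for name, a in (("R_b", self.R_b), ("X_b", self.X_b),
                        ("R_s", self.R_s), ("X_s", self.X_s)):
            if (a < 0).any():
                raise ValueError(f"{name} contains negative counts")
        if (self.R_b > self.X_b).any():
            m, t = np.argwhere(self.R_b > self.X_b)[0]
            raise ValueError(f"bulk alternative reads exceed total reads at "
                             f"(mutation {m}, sample {t})")
        if (self.R_s > self.X_s).any():
            m, n = np.argwhere(self.R_s > self.X_s)[0]
            raise ValueError(f"single-cell alternative reads exceed total reads at "
                             f"(mutation {m}, cell {n})")
        if not self.mutation_ids:
            self.mutation_ids = [f"mut{i + 1}" for i in range(M)]
        if not self.cell_ids:
            self.cell_ids = [f"cell{i + 1}" for i in range(self.R_s.shape[1])]
        if not self.sample_ids:
            self.sample_ids = [f"sample{i + 1}" for i in range(self.R_b.shape[1])]

    @property
    def M(self) -> int:
        return self.R_b.shape[0]

    @property
    def T(self) -> int:
        return self.R_b.shape[1]

    @property
    def N(self) -> int:
        return self.R_s.shape[1]


@dataclass(frozen=True)
class ErrorPrior:
    """Beta(kappa, tau) prior on the sequencing error rate epsilon.

    The defaults (1, 999) give a prior mean of kappa/(kappa+tau) = 0.001,
    the commonly reported per-nucleotide error rate of short-read sequencing.
    """

    kappa: float = 1.0
    tau: float = 999.0

    def __post_init__(self):
        if not (self.kappa > 0 and self.tau > 0):
            raise ValueError("kappa and tau must be positive")

    @property
    def mean(self) -> float:
        return self.kappa / (self.kappa + self.tau)


@dataclass
class BurstingKinetics:
    """Per-mutation transcriptional bursting rates.

    ``alpha[m]`` is the activation rate and ``beta[m]`` the deactivation rate of
    the gene harboring mutation ``m``; the latent per-cell expression activity
    is Beta(alpha, beta) distributed.
    """

    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.alpha.shape != self.beta.shape or self.alpha.ndim != 1:
            raise DimensionError("alpha and beta must be 1-d vectors of equal length")
        if (self.alpha <= 0).any() or (self.beta <= 0).any():
            raise ValueError("bursting rates must be strictly positive")

    @property
    def M(self) -> int:
        return self.alpha.shape[0]

    @classmethod
    def constant(cls, M: int, alpha: float, beta: float) -> "BurstingKinetics":
        return cls(np.full(M, alpha), np.full(M, beta))


class CellAssignment:
    """One-hot cell-to-clone assignment (K x N matrix P^s).

    Stored internally as a clone-index vector; ``P_s`` materializes the one-hot
    matrix. Clone indices are 0-based internally (0 = normal clone 1).
    """

    def __init__(self, clone_index: Sequence[int], K: int):
        idx = np.asarray(clone_index, dtype=np.int64)
        if idx.ndim != 1:
            raise DimensionError("clone_index must be a vector")
        if idx.size and (idx.min() < 0 or idx.max() >= K):
            raise ValueError("clone indices out of range")
        self.clone_index = idx
        self.K = int(K)

    @property
    def N(self) -> int:
        return self.clone_index.shape[0]

    @property
    def P_s(self) -> np.ndarray:
        P = np.zeros((self.K, self.N), dtype=np.int8)
        P[self.clone_index, np.arange(self.N)] = 1
        return P

    @classmethod
    def from_matrix(cls, P_s: np.ndarray) -> "CellAssignment":
        P = np.asarray(P_s)
        if P.ndim != 2:
            raise DimensionError("P_s must be a K x N matrix")
        col_sums = P.sum(axis=0)
        if not np.all(col_sums == 1) or not np.isin(P, (0, 1)).all():
            raise ValueError("each P_s column must be one-hot")
        return cls(np.argmax(P, axis=0), P.shape[0])

    def copy(self) -> "CellAssignment":
        return CellAssignment(self.clone_index.copy(), self.K)


class BulkComposition:
    """Fractional clonal composition of each bulk sample (K x T matrix P^b).

    Columns lie on the simplex with every entry at least ``DELTA``.
    """

    def __init__(self, P_b: np.ndarray, delta: float = DELTA):
        P = np.asarray(P_b, dtype=float)
        if P.ndim != 2:
            raise DimensionError("P_b must be a K x T matrix")
        if not np.allclose(P.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("P_b columns must sum to 1")
        if (P < delta - 1e-12).any():
            raise ValueError(f"P_b entries must be >= {delta}")
        self.P_b = P
        self.delta = delta

    @property
    def K(self) -> int:
        return self.P_b.shape[0]

    @property
    def T(self) -> int:
        return self.P_b.shape[1]

    def copy(self) -> "BulkComposition":
        return BulkComposition(self.P_b.copy(), self.delta)

    @staticmethod
    def floored(P: np.ndarray, delta: float = DELTA) -> "BulkComposition":
        """Floor entries at delta and project each column back to the simplex."""
        P = np.asarray(P, dtype=float).copy()
        for t in range(P.shape[1]):
            P[:, t] = floor_simplex(P[:, t], delta)
        return BulkComposition(P, delta)


class ClonalTree:
    """Rooted bifurcating clonal tree with mutations placed on tumor edges.

    Node numbering: node 0 is the root, nodes ``1..K`` are the clone leaves
    (node k = clone k, clone 1 normal), nodes ``K+1 .. 2K-2`` are internal
    nodes of the tumor subtree. Each non-root node identifies the edge from its
    parent; mutations live on edges of the tumor subtree (every edge except
    root->normal). ``branch_of_mutation[m]`` is the child-node id of the edge
    carrying mutation ``m``.
    """

    def __init__(self, K: int, parent: np.ndarray, branch_of_mutation: np.ndarray):
        if K < 2:
            raise ValueError("need at least 2 clones (normal + one tumor clone)")
        self.K = int(K)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.branch_of_mutation = np.asarray(branch_of_mutation, dtype=np.int64)
        n_nodes = 2 * K - 1
        if self.parent.shape != (n_nodes,):
            raise DimensionError(f"parent array must have length {n_nodes}")
        if self.parent[0] != -1 or self.parent[1] != 0:
            raise ValueError("node 0 must be the root and node 1 the normal leaf")
        eligible = self.eligible_edges
        if self.branch_of_mutation.size and not np.isin(
                self.branch_of_mutation, eligible).all():
            raise ValueError("mutations must be placed on tumor-subtree edges")
        self._leaf_mask = None
        self._Z = None

    # -- structure ---------------------------------------------------------

    @property
    def M(self) -> int:
        return self.branch_of_mutation.shape[0]

    @property
    def n_nodes(self) -> int:
        return 2 * self.K - 1

    @property
    def eligible_edges(self) -> np.ndarray:
        """Child-node ids of edges that may carry mutations (all but root->normal)."""
        return np.arange(2, self.n_nodes)

    @property
    def internal_tumor_edges(self) -> np.ndarray:
        """Edges whose child is an internal node of the tumor subtree."""
        return np.arange(self.K + 1, self.n_nodes)

    def children(self) -> list[list[int]]:
        ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for v in range(1, self.n_nodes):
            ch[self.parent[v]].append(v)
        return ch

    def leaf_masks(self) -> np.ndarray:
        """(n_nodes, K) boolean: mask[v, k-1] True iff leaf k descends from v."""
        if self._leaf_mask is None:
            mask = np.zeros((self.n_nodes, self.K), dtype=bool)
            for k in range(1, self.K + 1):
                mask[k, k - 1] = True
            ch = self.children()
            order = self._postorder(ch)
            for v in order:
                for c in ch[v]:
                    mask[v] |= mask[c]
            self._leaf_mask = mask
        return self._leaf_mask

    def _postorder(self, ch: list[list[int]]) -> list[int]:
        out, stack = [], [0]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(ch[v])
        return out[::-1]

    @property
    def Z(self) -> np.ndarray:
        """Binary (M, K) mutation-to-clone matrix derived from the topology."""
        if self._Z is None:
            mask = self.leaf_masks()
            self._Z = mask[self.branch_of_mutation].astype(np.int8)
        return self._Z

    def copy(self) -> "ClonalTree":
        # hot path in the sampler: bypass __init__ revalidation
        new = object.__new__(ClonalTree)
        new.K = self.K
        new.parent = self.parent.copy()
        new.branch_of_mutation = self.branch_of_mutation.copy()
        new._leaf_mask = None
        new._Z = None
        return new

    # -- construction ------------------------------------------------------

    @staticmethod
    def random_topology(K: int, rng: np.random.Generator) -> np.ndarray:
        """Uniform random rooted bifurcating topology over K labeled leaves.

        Sequential random addition: each tumor leaf attaches to a uniformly
        chosen existing tumor-subtree edge, which yields the uniform
        distribution over rooted labeled topologies.
        """
        n_nodes = 2 * K - 1
        parent = np.full(n_nodes, -1, dtype=np.int64)
        parent[1] = 0
        parent[2] = 0
        if K == 2:
            return parent
        edges = [2]  # child ids of current tumor-subtree edges
        leaves = list(range(3, K + 1))
        rng.shuffle(leaves)
        next_internal = K + 1
        for leaf in leaves:
            c = edges[rng.integers(len(edges))]
            v = next_internal
            next_internal += 1
            parent[v] = parent[c]
            parent[c] = v
            parent[leaf] = v
            edges.extend([leaf, v])
        return parent

    # -- invariant checking ------------------------------------------------

    def violations(self) -> list[str]:
        return validate_tree(self)

    def is_valid(self) -> bool:
        return not self.violations()

    def newick(self, labels: Sequence[str] | None = None) -> str:
        """Serialize the topology as a Newick string with clone labels on leaves."""
        if labels is None:
            labels = ["normal"] + [f"clone{k}" for k in range(2, self.K + 1)]
        ch = self.children()

        def rec(v: int) -> str:
            if not ch[v]:
                return str(labels[v - 1])
            return "(" + ",".join(rec(c) for c in ch[v]) + ")"

        return rec(0) + ";"


# -- carrier matrices ------------------------------------------------------

def carrier_matrix_cells(tree: ClonalTree, cells: CellAssignment) -> np.ndarray:
    """Binary (M, N) matrix Q^s = Z P^s: does the clone of cell n carry mutation m?"""
    if tree.K != cells.K:
        raise DimensionError(f"tree has K={tree.K} clones but cells have K={cells.K}")
    return tree.Z[:, cells.clone_index]


def carrier_fraction_bulk(tree: ClonalTree, bulk: BulkComposition) -> np.ndarray:
    """(M, T) matrix Q^b = Z P^b: fraction of cells in sample t carrying mutation m."""
    if tree.K != bulk.K:
        raise DimensionError(f"tree has K={tree.K} clones but bulk has K={bulk.K}")
    return tree.Z.astype(float) @ bulk.P_b


# -- validation ------------------------------------------------------------

def _laminar_violation(Z: np.ndarray) -> bool:
    """True if some pair of carrier sets (rows of Z) crosses (neither nested
    nor disjoint) — a violation of the perfect-phylogeny property."""
    B = Z.astype(bool)
    M = B.shape[0]
    for i in range(M):
        for j in range(i + 1, M):
            inter = (B[i] & B[j]).any()
            if inter and not ((B[i] | B[j]) == B[i]).all() \
                    and not ((B[i] | B[j]) == B[j]).all():
                return True
    return False


def validate_tree(tree) -> list[str]:
    """Report violated clonal-tree invariants; empty list means valid.

    Accepts a :class:`ClonalTree` or a raw binary Z matrix (M x K). Checks:
    the normal clone carries no mutations; carrier sets form a laminar family;
    every internal tumor edge carries at least one mutation (tree input only);
    all clone columns of Z are pairwise distinct (identifiability).
    """
    out: list[str] = []
    if isinstance(tree, ClonalTree):
        Z = tree.Z
        counts = np.bincount(tree.branch_of_mutation, minlength=tree.n_nodes)
        if (counts[tree.internal_tumor_edges] == 0).any():
            out.append("internal tumor edge carries no mutations")
    else:
        Z = np.asarray(tree)
        if Z.ndim != 2:
            return ["Z must be a 2-d binary matrix"]
        if not np.isin(Z, (0, 1)).all():
            out.append("Z is not binary")
    if Z.shape[0] and Z[:, 0].any():
        out.append("normal clone carries mutations")
    if _laminar_violation(Z):
        out.append("carrier sets are not laminar (perfect-phylogeny violation)")
    K = Z.shape[1]
    cols = {tuple(Z[:, k]) for k in range(K)}
    if len(cols) < K:
        out.append("clone columns of Z are not distinct (unidentifiable clones)")
    return out
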