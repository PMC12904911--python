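"""Scoring inferred clonal configurations and validating cell assignments.

Clone labels are arbitrary up to permutation (label switching), so estimated
and true configurations are compared modulo relabeling of the tumor clones.
The normal clone is structurally identified by its empty mutation set and is
never permuted.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np

from .tree import ClonalTree, DimensionError


@dataclass
class ReconstructionError:
    """Mean absolute entrywise errors under the best clone relabeling.

    A single permutation — the one minimizing the Z distance, ties broken
    toward the lexicographically first — is applied to all three matrices so
    the errors describe one coherent relabeling.
    """

    error_Z: float
    error_Ps: float
    error_Pb: float
    best_permutation: tuple


def _mean_abs(a: np.ndarray, b: np.ndarray) -> float:
    if a.size == 0:
        return 0.0
    return float(np.mean(np.abs(np.asarray(a, dtype=float)
                                - np.asarray(b, dtype=float))))


def reconstruction_error(est, truth) -> ReconstructionError:
    """Reconstruction error modulo permutation of the tumor clones.

    ``est`` and ``truth`` are (Z, P_s, P_b) triples: Z is M x K binary, P_s is
    K x N one-hot, P_b is K x T on the simplex. The search is exhaustive over
    the (K-1)! permutations of clones 2..K with the normal clone fixed.
    """
    Z_e, Ps_e, Pb_e = (np.asarray(m) for m in est)
    Z_t, Ps_t, Pb_t = (np.asarray(m) for m in truth)
    if Z_e.shape != Z_t.shape or Ps_e.shape != Ps_t.shape \
            or Pb_e.shape != Pb_t.shape:
        raise DimensionError("estimate and truth dimensions differ")
    K = Z_e.shape[1]
    if Ps_e.shape[0] != K or Pb_e.shape[0] != K:
        raise DimensionError("K differs across matrices")
    best_perm, best_dz = None, np.inf
    for sigma in permutations(range(1, K)):
        perm = (0,) + sigma  # est clone perm[k] is compared to truth clone k
        dz = _mean_abs(Z_e[:, perm], Z_t)
        if dz < best_dz - 1e-15:
            best_dz, best_perm = dz, perm
    perm = np.asarray(best_perm)
    return ReconstructionError(
        error_Z=_mean_abs(Z_e[:, perm], Z_t),
        error_Ps=_mean_abs(Ps_e[perm, :], Ps_t),
        error_Pb=_mean_abs(Pb_e[perm, :], Pb_t),
        best_permutation=best_perm,
    )


def correct_configuration(est, truth) -> bool:
    """True iff the clonal configuration Z is exactly recovered modulo
    permutation."""
    return reconstruction_error(est, truth).error_Z == 0.0


@dataclass
class AssignmentValidation:
    """Per-cell clonal membership derived from observed mutation profiles.

    ``clone_index`` holds 0-based clone indices (0 = normal) or -1 for cells
    whose profiles span diverging branches and cannot be placed on any single
    clone.
    """

    clone_index: np.ndarray
    status: list

    @property
    def unassigned_fraction(self) -> float:
        n = self.clone_index.size
        return float(np.sum(self.clone_index == -1)) / n if n else 0.0


def assign_cells(tree: ClonalTree, cell_profiles: np.ndarray) -> AssignmentValidation:
    """Validate cell-to-clone assignment from binary mutation profiles.

    A cell with no mutations is a member of the normal clone. Otherwise the
    cell belongs to the clone whose root-to-leaf mutation set is the minimal
    superset of the cell's profile (ties toward the shallowest clone, i.e.
    the one carrying fewest mutations, then the smallest clone index). If no
    clone's mutation set contains the profile — the profile mixes mutations
    from two or more diverging branches — the cell is left unassigned.
    """
    profiles = np.asarray(cell_profiles)
    if profiles.ndim != 2 or profiles.shape[0] != tree.M:
        raise DimensionError(f"profiles must be M x N with M={tree.M}")
    Z = tree.Z.astype(bool)
    sizes = Z.sum(axis=0)
    idx = np.empty(profiles.shape[1], dtype=np.int64)
    status = []
    for n in range(profiles.shape[1]):
        prof = profiles[:, n].astype(bool)
        if not prof.any():
            idx[n] = 0
            status.append("normal")
            continue
        superset = [k for k in range(tree.K) if (Z[:, k] | prof == Z[:, k]).all()]
        if not superset:
            idx[n] = -1
            status.append("unassigned")
        else:
            k = min(superset, key=lambda k: (sizes[k], k))
            idx[n] = k
            status.append(f"clone{k + 1}")
    return AssignmentValidation(clone_index=idx, status=status)
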