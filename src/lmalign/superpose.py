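"""Assembly RMSD, Kabsch/SVD superposition, and the two baselines.

The optimal-superposition problem for assemblies of N like molecules is

    min over P, R, t  of  sum_k sum_l || x_l^k - (R (y_l^{P_k} - ybar) + t) ||^2

where P is a molecule-to-molecule mapping (permutation), R a proper
rotation and t a translation.  With both assemblies centered at their
geometric centers the optimal translation is zero, and for a fixed P the
optimal R is given in closed form by the SVD (Kabsch) construction.

Two exact but naive strategies are provided here:

* the *simple* algorithm pairs chains by equal chain ID and runs one SVD
  (fast, but wrong whenever the chain labelling differs between files);
* the *reference* algorithm enumerates all N! mappings and keeps the
  best, yielding the global-minimum RMSD (RMSDr) at factorial cost.

The permutation-free algorithms (LMADA, LMAGDA) live in their own
modules and reuse :func:`kabsch_superpose`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .assembly import Assembly, center_assembly
from .errors import (
    ChainIDMismatchError,
    DimensionMismatchError,
    PermutationGuardError,
)

__all__ = [
    "SuperpositionResult",
    "assembly_rmsd",
    "kabsch_rotation",
    "kabsch_superpose",
    "simple_superpose",
    "reference_superpose",
    "as_permutation",
    "DEFAULT_MAX_N",
]

DEFAULT_MAX_N = 8


@dataclass
class SuperpositionResult:
    """Outcome of superposing assembly y onto reference assembly x.

    ``R`` and ``t`` act on y's original (uncentered) coordinates:
    x ~ R @ y + t.  ``mapping[k]`` is the index of the y-molecule
    matched to x-molecule k.  ``rmsd`` is in Angstroms.  ``extras``
    carries method-specific diagnostics (RMSDd, RMSDphi, Phi, the
    optimized quaternion, mappings examined, ...).
    """

    R: np.ndarray
    t: np.ndarray
    mapping: np.ndarray
    rmsd: float
    method: str
    extras: dict = field(default_factory=dict)


def as_permutation(P: Sequence[int], N: int) -> np.ndarray:
    """Validate P as a permutation of 0..N-1 and return it as an int array."""
    P = np.asarray(P, dtype=int)
    if P.shape != (N,) or not np.array_equal(np.sort(P), np.arange(N)):
        raise ValueError(f"mapping {P!r} is not a permutation of 0..{N - 1}")
    return P


def _check_like(x: Assembly, y: Assembly) -> None:
    if x.N != y.N or x.n != y.n:
        raise DimensionMismatchError(
            f"assemblies differ in shape: ({x.N}, {x.n}) vs ({y.N}, {y.n})"
        )


def assembly_rmsd(x: Assembly, y: Assembly, P: Sequence[int]) -> float:
    """RMSD over all N*n point pairs, x-molecule k paired with y-molecule P[k].

    Coordinates must already be in a common frame; no superposition is done.
    """
    _check_like(x, y)
    P = as_permutation(P, x.N)
    diff = x.coords - y.coords[P]
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=-1))))


def kabsch_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing sum ||a_i - R b_i||^2 for centered clouds.

    Uses the SVD of the covariance B^T A with the determinant sign
    correction: if the raw solution is a reflection, the axis of the
    smallest singular value is flipped, so a proper rotation is always
    returned (the global optimum among rotations, even for degenerate
    point clouds).
    """
    C = B.T @ A
    U, _, Vt = np.linalg.svd(C)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _full_transform(x: Assembly, y: Assembly, R: np.ndarray) -> np.ndarray:
    """Translation mapping y's original frame onto x's: t = cx - R @ cy."""
    cx = x.centroid if x.centroid is not None else np.zeros(3)
    cy = y.centroid if y.centroid is not None else np.zeros(3)
    return cx - R @ cy


def kabsch_superpose(x: Assembly, y: Assembly, P: Sequence[int]) -> SuperpositionResult:
    """Optimal rigid superposition of y onto x under a fixed mapping P.

    Both assemblies are expected centered (the optimal translation is then
    zero); uncentered input is centered on the fly.  Returns the proper
    rotation that is the global optimum for this mapping.
    """
    _check_like(x, y)
    if not x.is_centered():
        x, _ = center_assembly(x)
    if not y.is_centered():
        y, _ = center_assembly(y)
    P = as_permutation(P, x.N)
    A = x.points
    B = y.coords[P].reshape(-1, 3)
    R = kabsch_rotation(A, B)
    y_rot = y.with_coords(y.coords @ R.T)
    rmsd = assembly_rmsd(x, y_rot, P)
    return SuperpositionResult(
        R=R, t=_full_transform(x, y, R), mapping=P, rmsd=rmsd, method="kabsch"
    )


def simple_superpose(x: Assembly, y: Assembly) -> SuperpositionResult:
    """Superpose pairing chains by equal chain ID (RMSDs).

    This is the naive baseline: it is exact only when the chain labels
    of the two files happen to agree with the best molecule mapping.
    """
    _check_like(x, y)
    if set(x.chain_ids) != set(y.chain_ids):
        raise ChainIDMismatchError(
            f"chain ID sets differ: {sorted(x.chain_ids)} vs {sorted(y.chain_ids)}"
        )
    P = np.array([y.chain_ids.index(cid) for cid in x.chain_ids])
    res = kabsch_superpose(x, y, P)
    res.method = "simple"
    return res


def reference_superpose(
    x: Assembly,
    y: Assembly,
    max_N: int = DEFAULT_MAX_N,
) -> SuperpositionResult:
    """Global-minimum superposition by enumerating all N! molecule mappings.

    Each mapping is solved by :func:`kabsch_superpose`; the lowest-RMSD
    result (RMSDr) is returned.  Permutations are visited in
    lexicographic order and the first minimum is kept on exact ties.
    Refuses N > max_N (default 8), where the factorial count makes bulk
    use impractical; pass a larger max_N to force.
    """
    _check_like(x, y)
    N = x.N
    if N > max_N:
        raise PermutationGuardError(N, math.factorial(N), max_N)
    if not x.is_centered():
        x, _ = center_assembly(x)
    if not y.is_centered():
        y, _ = center_assembly(y)
    best: Optional[SuperpositionResult] = None
    count = 0
    for perm in itertools.permutations(range(N)):
        count += 1
        res = kabsch_superpose(x, y, np.array(perm))
        if best is None or res.rmsd < best.rmsd:
            best = res
    best.method = "reference"
    best.extras["n_mappings"] = count
    return best
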