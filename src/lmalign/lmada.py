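"""LMADA: Like-Molecule Assembly Distance Alignment.

The algorithm sidesteps the N! mapping search in three steps:

1. build a fixed 374-point grid of quaternion components covering
   rotation space (see :mod:`lmalign.rotation`);
2. at each grid rotation, compute the N x N matrix of molecule-to-molecule
   distances, derive a mapping greedily from the sorted distances, and
   score it with RMSDd; keep the grid point with the lowest RMSDd;
3. run one SVD (Kabsch) superposition with the retained mapping.

Cost scales with N^2 per grid point and exactly one SVD overall, versus
N! SVDs for the brute-force reference algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .assembly import Assembly, center_assembly
from .errors import DimensionMismatchError
from .rotation import quaternion_grid, rotation_matrix
from .superpose import SuperpositionResult, as_permutation, kabsch_superpose

__all__ = [
    "GridScanState",
    "molecule_distance_matrix",
    "greedy_mapping",
    "rmsd_d",
    "grid_scan",
    "lmada_superpose",
]


@dataclass
class GridScanState:
    """Running minimum of the grid scan.

    best_rmsd_d is RMSDd at the best grid point seen so far;
    best_mapping and best_quaternion are the mapping and the (raw, grid)
    quaternion that achieved it; grid_index is its position in the
    lexicographic grid ordering.
    """

    best_rmsd_d: float
    best_mapping: np.ndarray
    best_quaternion: np.ndarray
    grid_index: int


def _sq_distance_matrix(x: Assembly, y: Assembly, R: np.ndarray) -> np.ndarray:
    """Mean squared point distance between every (reference, rotated) chain pair."""
    y_rot = y.coords @ np.asarray(R, dtype=float).T
    diff = x.coords[:, None, :, :] - y_rot[None, :, :, :]
    return np.mean(np.sum(diff * diff, axis=-1), axis=-1)


def molecule_distance_matrix(x: Assembly, y: Assembly, R: np.ndarray) -> np.ndarray:
    """N x N matrix d with d[i, j] = RMS distance between reference molecule i
    and rotated superposed molecule j.

    Points are paired by within-chain index; both assemblies must be in
    centered frames (no translation is applied).
    """
    if x.N != y.N or x.n != y.n:
        raise DimensionMismatchError(
            f"assemblies differ in shape: ({x.N}, {x.n}) vs ({y.N}, {y.n})"
        )
    return np.sqrt(_sq_distance_matrix(x, y, R))


def greedy_mapping(d: np.ndarray) -> np.ndarray:
    """Mapping from the globally sorted distance list.

    Entries of d are visited from smallest to largest (ties broken by
    row index, then column index); a pair (i, j) is accepted unless i or
    j already appeared.  The result, sorted by reference index, is a
    permutation P with P[i] = matched superposed-molecule index.
    """
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError(f"distance matrix must be square, got {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ValueError("distance matrix contains non-finite entries")
    N = d.shape[0]
    order = np.argsort(d, axis=None, kind="stable")  # stable: ties in (i, j) order
    P = np.full(N, -1, dtype=int)
    used_j = np.zeros(N, dtype=bool)
    assigned = 0
    for flat in order:
        i, j = divmod(int(flat), N)
        if P[i] >= 0 or used_j[j]:
            continue
        P[i] = j
        used_j[j] = True
        assigned += 1
        if assigned == N:
            break
    return P


def rmsd_d(d: np.ndarray, P: np.ndarray) -> float:
    """Assembly-level distance estimate: sqrt(mean_i d[i, P[i]]^2)."""
    d = np.asarray(d, dtype=float)
    N = d.shape[0]
    P = as_permutation(P, N)
    matched = d[np.arange(N), P]
    return float(np.sqrt(np.mean(matched * matched)))


def grid_scan(
    x: Assembly, y: Assembly, trace: list | None = None
) -> GridScanState:
    """Scan all 374 grid rotations; return the state with minimal RMSDd.

    The update is strict improvement, so on exact RMSDd ties the earlier
    grid point (lexicographic quaternion order) wins.  If a list is
    passed as ``trace``, one (grid_index, q0, qx, qy, qz, rmsd_d) tuple
    per grid point is appended to it.
    """
    if x.N != y.N or x.n != y.n:
        raise DimensionMismatchError(
            f"assemblies differ in shape: ({x.N}, {x.n}) vs ({y.N}, {y.n})"
        )
    grid = quaternion_grid()
    rotations = rotation_matrix(grid)
    state: GridScanState | None = None
    for idx, (q, R) in enumerate(zip(grid, rotations)):
        d2 = _sq_distance_matrix(x, y, R)
        P = greedy_mapping(d2)  # monotone in d, so squared entries sort alike
        val = float(np.sqrt(np.mean(d2[np.arange(x.N), P])))
        if trace is not None:
            trace.append((idx, *q, val))
        if state is None or val < state.best_rmsd_d:
            state = GridScanState(
                best_rmsd_d=val, best_mapping=P, best_quaternion=q, grid_index=idx
            )
    return state


def lmada_superpose(
    x: Assembly, y: Assembly, trace: list | None = None
) -> SuperpositionResult:
    """Full LMADA run: grid scan then a single SVD with the scanned mapping.

    The returned rmsd is RMSD1; extras carry the scan's RMSDd minimum,
    mapping and quaternion.
    """
    if not x.is_centered():
        x, _ = center_assembly(x)
    if not y.is_centered():
        y, _ = center_assembly(y)
    state = grid_scan(x, y, trace=trace)
    res = kabsch_superpose(x, y, state.best_mapping)
    res.method = "lmada"
    res.extras.update(
        rmsd_d=state.best_rmsd_d,
        quaternion=state.best_quaternion,
        grid_index=state.grid_index,
    )
    return res
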