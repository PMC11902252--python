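"""Quaternion grid and quaternion -> rotation-matrix conversion.

A rotation is parameterized by a quaternion q = q0 + i*qx + j*qy + k*qz,
stored here as a length-4 float array in the order (q0, qx, qy, qz).
After normalization, q0 = cos(theta/2) and (qx, qy, qz) is sin(theta/2)
times the Euler axis, theta in [0, 360) degrees.

Orientation space is scanned over a fixed lattice of quaternion
components: q0 in {0, 0.5, 1} and each imaginary component in
{-1, -0.5, 0, 0.5, 1}, with the all-zero point removed, giving
3 * 5**3 - 1 = 374 points.  The lattice intentionally keeps scalar
multiples that normalize to the same unit quaternion: the scan cost is
negligible and the fixed count keeps the procedure reproducible.
"""

from __future__ import annotations

import numpy as np

from .errors import SingularQuaternionError

__all__ = ["quaternion_grid", "normalize", "rotation_matrix", "GRID_SIZE"]

GRID_SIZE = 374

_HALF_STEPS = np.array([0.0, 0.5, 1.0])
_FULL_STEPS = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])


def quaternion_grid() -> np.ndarray:
    """Return the 374-point quaternion component grid, shape (374, 4).

    Points are ordered lexicographically in (q0, qx, qy, qz) so that
    downstream tie-breaking is deterministic.
    """
    q0, qx, qy, qz = np.meshgrid(
        _HALF_STEPS, _FULL_STEPS, _FULL_STEPS, _FULL_STEPS, indexing="ij"
    )
    grid = np.stack([q0, qx, qy, qz], axis=-1).reshape(-1, 4)
    nonzero = ~np.all(grid == 0.0, axis=1)
    return grid[nonzero]


def normalize(q: np.ndarray) -> np.ndarray:
    """Normalize quaternion(s) to unit length.

    Accepts a single quaternion (4,) or a batch (..., 4).
    Raises SingularQuaternionError on any zero-length quaternion.
    """
    q = np.asarray(q, dtype=float)
    norm = np.linalg.norm(q, axis=-1, keepdims=True)
    if np.any(norm == 0.0):
        raise SingularQuaternionError("cannot normalize a zero quaternion")
    return q / norm


def rotation_matrix(q: np.ndarray) -> np.ndarray:
    """Rotation matrix of quaternion(s); normalization applied internally.

    For input shape (4,) returns (3, 3); for (m, 4) returns (m, 3, 3).
    The matrix is the standard homogeneous quadratic form in the unit
    quaternion components, proper orthogonal by construction.
    """
    qn = normalize(q)
    single = qn.ndim == 1
    qn = np.atleast_2d(qn)
    a, b, c, d = qn[:, 0], qn[:, 1], qn[:, 2], qn[:, 3]
    R = np.empty((qn.shape[0], 3, 3))
    R[:, 0, 0] = a * a + b * b - c * c - d * d
    R[:, 0, 1] = 2 * (b * c - a * d)
    R[:, 0, 2] = 2 * (b * d + a * c)
    R[:, 1, 0] = 2 * (c * b + a * d)
    R[:, 1, 1] = a * a - b * b + c * c - d * d
    R[:, 1, 2] = 2 * (c * d - a * b)
    R[:, 2, 0] = 2 * (d * b - a * c)
    R[:, 2, 1] = 2 * (d * c + a * b)
    R[:, 2, 2] = a * a - b * b - c * c + d * d
    return R[0] if single else R
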