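"""Seeded generator of like-molecule assemblies with known ground truth.

The fixtures emulate the geometry that assembly-superposition algorithms
actually consume: N copies of an extended n-point chain stacked into a
beta-ladder-like arrangement, and a counterpart obtained by applying a
known chain permutation, an optional reversal of the point order of
selected chains (opposite chain direction), a known rigid transform and
optional isotropic Gaussian coordinate noise.  Everything is driven by
explicit integer seeds, so tests and drivers are fully reproducible.

Default geometry: 3.8 A point spacing (the Calpha-Calpha virtual bond
length of a trans peptide group), 4.8 A inter-chain pitch (typical
beta-sheet strand separation), and a 2.4 A per-strand shear (stagger)
along the chain axis, as in sheared beta-sheet packing.

The stagger matters for ground truth: a perfectly flat ladder of
collinear chains is carried onto itself by a 180-degree rotation about
the chain axis combined with reversing the chain order, so the "true"
molecule mapping of a permuted copy is not unique and no algorithm can
be expected to recover it.  The shear removes that degeneracy with a
margin large enough that the correct mapping is identifiable even at
the finite angular resolution of the quaternion grid scan.  Pass
``stagger=0`` to generate the degenerate flat ladder deliberately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .assembly import Assembly
from .rotation import normalize, rotation_matrix
from .superpose import as_permutation

__all__ = [
    "PerturbationSpec",
    "GroundTruth",
    "make_chain_template",
    "make_ladder_assembly",
    "perturb",
    "random_rotation_quaternion",
    "make_pair",
    "CA_SPACING",
    "LADDER_PITCH",
    "STRAND_STAGGER",
]

CA_SPACING = 3.8
LADDER_PITCH = 4.8
STRAND_STAGGER = 2.4
_CHAIN_IDS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


@dataclass
class PerturbationSpec:
    """Recipe for deriving a perturbed counterpart of an assembly.

    permutation[j] = index of the source chain placed in output slot j
    (None = identity).  rotation is a quaternion (q0, qx, qy, qz),
    translation a 3-vector in Angstroms.  noise_sd is the per-coordinate
    isotropic Gaussian noise, applied after the rigid transform.
    flip_chains lists output slots whose point order is reversed
    (opposite chain direction).  seed drives the noise stream.
    """

    permutation: Optional[np.ndarray] = None
    rotation: Optional[np.ndarray] = None
    translation: Optional[np.ndarray] = None
    noise_sd: float = 0.0
    flip_chains: frozenset = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What a perfect superposition of the perturbed copy should recover.

    true_mapping is the inverse of the applied permutation: the mapping
    P with P[k] = output slot holding source chain k, i.e. the best
    molecule mapping when the noise is small.
    """

    true_mapping: np.ndarray
    rotation: np.ndarray
    translation: np.ndarray
    noise_sd: float


def make_chain_template(n: int, spacing: float = CA_SPACING) -> np.ndarray:
    """Centered collinear chain of n points along x at the given spacing."""
    if n < 1 or spacing <= 0:
        raise ValueError("need n >= 1 and spacing > 0")
    xs = spacing * (np.arange(n) - (n - 1) / 2.0)
    pts = np.zeros((n, 3))
    pts[:, 0] = xs
    return pts


def make_ladder_assembly(
    N: int,
    n: int,
    spacing: float = CA_SPACING,
    pitch: float = LADDER_PITCH,
    stagger: float = STRAND_STAGGER,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> Assembly:
    """N template chains stacked along y at the given pitch, sheared by
    ``stagger`` along x per chain, with optional seeded Gaussian jitter.

    Chain i (0-based) sits at y = (i - (N - 1)/2) * pitch and is offset
    by (i - (N - 1)/2) * stagger along the chain axis; chains are
    labelled A, B, C, ...  The assembly is returned centered.
    """
    if N < 1 or pitch <= 0:
        raise ValueError("need N >= 1 and pitch > 0")
    if N > len(_CHAIN_IDS):
        raise ValueError(f"at most {len(_CHAIN_IDS)} chains supported")
    template = make_chain_template(n, spacing)
    coords = np.stack([template.copy() for _ in range(N)])
    offsets = np.arange(N) - (N - 1) / 2.0
    coords[:, :, 1] += pitch * offsets[:, None]
    coords[:, :, 0] += stagger * offsets[:, None]
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        coords = coords + rng.normal(scale=jitter_sd, size=coords.shape)
    # the centered frame is the assembly's canonical frame
    coords = coords - coords.reshape(-1, 3).mean(axis=0)
    return Assembly(coords=coords, chain_ids=tuple(_CHAIN_IDS[:N]))


def perturb(a: Assembly, spec: PerturbationSpec) -> tuple[Assembly, GroundTruth]:
    """Apply permutation, chain flips, rigid transform and noise to a copy.

    Output chain slot j receives source chain permutation[j]; slot
    labels keep the original ordering (A, B, ...), so the chain IDs no
    longer track the source chains — exactly the situation the
    permutation-free algorithms are for.
    """
    N = a.N
    perm = (
        np.arange(N)
        if spec.permutation is None
        else as_permutation(spec.permutation, N)
    )
    coords = a.coords[perm].copy()
    for j in spec.flip_chains:
        coords[j] = coords[j, ::-1]
    if spec.rotation is not None:
        R = rotation_matrix(np.asarray(spec.rotation, dtype=float))
        quat = normalize(np.asarray(spec.rotation, dtype=float))
    else:
        R = np.eye(3)
        quat = np.array([1.0, 0.0, 0.0, 0.0])
    t = (
        np.zeros(3)
        if spec.translation is None
        else np.asarray(spec.translation, dtype=float)
    )
    coords = coords @ R.T + t
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        coords = coords + rng.normal(scale=spec.noise_sd, size=coords.shape)
    out = Assembly(coords=coords, chain_ids=a.chain_ids, source=a.source)
    truth = GroundTruth(
        true_mapping=np.argsort(perm),
        rotation=quat,
        translation=t,
        noise_sd=spec.noise_sd,
    )
    return out, truth


def random_rotation_quaternion(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via a normalized 4-D Gaussian quaternion."""
    return normalize(rng.normal(size=4))


def make_pair(
    N: int,
    n: int = 6,
    noise_sd: float = 0.3,
    jitter_sd: float = 0.3,
    seed: int = 0,
    nontrivial_permutation: bool = True,
) -> tuple[Assembly, Assembly, GroundTruth]:
    """Convenience: a jittered ladder and a permuted/rotated/noisy copy.

    All randomness (jitter, permutation, rotation, translation, noise)
    derives from the single seed.  With nontrivial_permutation and
    N >= 2, the drawn permutation is guaranteed not to be the identity.
    """
    rng = np.random.default_rng(seed)
    x = make_ladder_assembly(N, n, jitter_sd=jitter_sd, seed=int(rng.integers(2**31)))
    perm = rng.permutation(N)
    if nontrivial_permutation and N >= 2:
        while np.array_equal(perm, np.arange(N)):
            perm = rng.permutation(N)
    spec = PerturbationSpec(
        permutation=perm,
        rotation=random_rotation_quaternion(rng),
        translation=rng.uniform(-20.0, 20.0, size=3),
        noise_sd=noise_sd,
        seed=int(rng.integers(2**31)),
    )
    y, truth = perturb(x, spec)
    return x, y, truth
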