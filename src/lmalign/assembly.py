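"""Assemblies of like molecules: the container plus PDB/mmCIF I/O.

An assembly is N chains ("molecules") of identical composition, each
reduced to n points (Calpha atoms by default).  Coordinates are held as
an (N, n, 3) array in Angstroms; chain order follows file order so that
a reported molecule mapping is stable.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import EmptyInputError, ParseError, UnlikeMoleculesError

__all__ = ["Assembly", "read_assembly", "center_assembly", "write_superposed"]

_CENTER_TOL = 1e-10


@dataclass(frozen=True)
class Assembly:
    """N like molecules of n points each.

    Attributes
    ----------
    coords : (N, n, 3) float array, Angstroms.
    chain_ids : unique labels, one per molecule, in file order.
    centroid : overall geometric center recorded by :func:`center_assembly`
        (the offset that was subtracted), or None if never centered.
    source : optional provenance string (path + model number).
    """

    coords: np.ndarray
    chain_ids: tuple[str, ...]
    centroid: Optional[np.ndarray] = None
    source: Optional[str] = None

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coords must be (N, n, 3), got {coords.shape}")
        if coords.shape[0] < 1 or coords.shape[1] < 1:
            raise EmptyInputError("assembly needs N >= 1 chains of n >= 1 points")
        object.__setattr__(self, "coords", coords)
        ids = tuple(str(c) for c in self.chain_ids)
        if len(ids) != coords.shape[0]:
            raise ValueError("one chain ID per molecule required")
        if len(set(ids)) != len(ids):
            raise ValueError(f"chain IDs not unique: {ids}")
        object.__setattr__(self, "chain_ids", ids)

    @property
    def N(self) -> int:
        """Number of molecules."""
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        """Points per molecule."""
        return self.coords.shape[1]

    @property
    def points(self) -> np.ndarray:
        """All N*n points as a flat (N*n, 3) view."""
        return self.coords.reshape(-1, 3)

    def is_centered(self, tol: float = _CENTER_TOL) -> bool:
        return bool(np.all(np.abs(self.points.mean(axis=0)) <= tol))

    def with_coords(self, coords: np.ndarray) -> "Assembly":
        """Copy with new coordinates; the recorded centroid is dropped,
        since arbitrary new coordinates define a new frame."""
        return replace(self, coords=coords, centroid=None)


def center_assembly(a: Assembly) -> tuple[Assembly, np.ndarray]:
    """Shift an assembly to its geometric center.

    Returns the centered assembly and the centroid that was subtracted
    (the mean over all N*n points).  Idempotent: centering a centered
    assembly subtracts (numerically) zero.
    """
    centroid = a.points.mean(axis=0)
    prior = a.centroid if a.centroid is not None else np.zeros(3)
    return (
        replace(a, coords=a.coords - centroid, centroid=prior + centroid),
        centroid,
    )


def _select_points(residues, selector: str) -> list[gemmi.Atom]:
    """First-altloc atoms matching the selector, in residue order."""
    picked = []
    for res in residues:
        seen = set()
        for atom in res:
            if atom.name in seen:
                continue  # altlocs come grouped; keep the first
            if selector == "heavy":
                if atom.element == gemmi.Element("H"):
                    continue
            elif atom.name != selector:
                continue
            seen.add(atom.name)
            picked.append(atom)
    return picked


def read_assembly(
    path: str | os.PathLike,
    selector: str = "CA",
    model: int = 1,
) -> Assembly:
    """Read an assembly from a PDB or mmCIF file.

    Parameters
    ----------
    selector : atom name to extract per residue (default "CA"), or
        "heavy" for all non-hydrogen atoms.
    model : 1-based model number (default: first model).

    Raises
    ------
    UnlikeMoleculesError if the chains yield unequal point counts,
    EmptyInputError on zero chains/atoms, ParseError on unreadable files.
    """
    path = os.fspath(path)
    try:
        st = gemmi.read_structure(path)
    except (RuntimeError, ValueError, OSError) as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyInputError(f"{path}: no models")
    if model < 1 or model > len(st):
        raise ParseError(f"{path}: model {model} not present (file has {len(st)})")
    mdl = st[model - 1]

    chain_ids: list[str] = []
    chain_points: list[np.ndarray] = []
    for chain in mdl:
        atoms = _select_points(chain, selector)
        if not atoms:
            continue
        chain_ids.append(chain.name)
        chain_points.append(
            np.array([[at.pos.x, at.pos.y, at.pos.z] for at in atoms])
        )
    if not chain_points:
        raise EmptyInputError(f"{path}: no atoms matched selector {selector!r}")

    counts = {cid: pts.shape[0] for cid, pts in zip(chain_ids, chain_points)}
    if len(set(counts.values())) > 1:
        detail = ", ".join(f"{cid}: {cnt}" for cid, cnt in counts.items())
        raise UnlikeMoleculesError(
            f"{path}: unlike molecules — selected-point counts differ ({detail})"
        )
    return Assembly(
        coords=np.stack(chain_points),
        chain_ids=tuple(chain_ids),
        source=f"{path}#model{model}",
    )


def _build_model(a: Assembly, coords: np.ndarray, name: str) -> gemmi.Model:
    mdl = gemmi.Model(name)
    for cid, pts in zip(a.chain_ids, coords):
        chain = gemmi.Chain(cid)
        for i, xyz in enumerate(pts, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*xyz)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
            chain.add_residue(res)
        mdl.add_chain(chain)
    return mdl


def write_assembly(a: Assembly, path: str | os.PathLike) -> None:
    """Write an assembly as a pseudo-Calpha PDB file (one CA per residue)."""
    st = gemmi.Structure()
    st.name = "lmalign"
    st.add_model(_build_model(a, a.coords, "1"))
    st.setup_entities()
    st.write_pdb(os.fspath(path))


def write_superposed(
    a: Assembly,
    R: np.ndarray,
    t: np.ndarray,
    P: Optional[Sequence[int]],
    path: str | os.PathLike,
    relabel: bool = False,
    reference: Optional[Assembly] = None,
) -> None:
    """Write the transformed assembly (R @ y + t) in PDB format.

    With ``relabel`` and a mapping P, the superposed chains are renamed
    so that the chain matched to reference molecule k carries the
    reference's k-th chain ID.  If a reference assembly is given it is
    written alongside as MODEL 2.
    """
    R = np.asarray(R, dtype=float)
    if not (
        np.allclose(R.T @ R, np.eye(3), atol=1e-9)
        and abs(np.linalg.det(R) - 1.0) < 1e-9
    ):
        raise ValueError("R must be a proper rotation (orthogonal, det +1)")
    moved = a.coords @ R.T + np.asarray(t, dtype=float)

    out = a
    if relabel and P is not None:
        ref_ids = reference.chain_ids if reference is not None else a.chain_ids
        new_ids = list(a.chain_ids)
        for k, pk in enumerate(P):
            new_ids[pk] = ref_ids[k]
        out = replace(a, chain_ids=tuple(new_ids))

    st = gemmi.Structure()
    st.name = "lmalign superposition"
    st.add_model(_build_model(out, moved, "1"))
    if reference is not None:
        ref_coords = reference.coords + (
            reference.centroid if reference.centroid is not None else 0.0
        )
        st.add_model(_build_model(reference, ref_coords, "2"))
    st.setup_entities()
    st.write_pdb(os.fspath(path))
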