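"""Ensemble-level evaluation of superposition methods.

Given per-pair RMSDs from a fast method and from the brute-force
reference algorithm, the comparison statistics are the mean and sample
standard deviation of the differences RMSDx - RMSDr and of the relative
differences (RMSDx - RMSDr)/RMSDr, plus the rejection percentage: the
share of pairs that are similar under the reference RMSD (< cutoff) but
classified dissimilar (>= cutoff) by the fast method.  The default
cutoff of 6 A is the classical threshold below which two random
structures are unlikely to superpose.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .assembly import Assembly
from .errors import DimensionMismatchError, UndefinedRateError
from .lmada import lmada_superpose
from .lmagda import GaussianObjectiveConfig, lmagda_superpose
from .superpose import reference_superpose, simple_superpose

__all__ = [
    "EnsembleStats",
    "delta_stats",
    "rejection_rate",
    "ensemble_stats",
    "all_pairs",
    "rmsd_matrix",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 6.0


@dataclass
class EnsembleStats:
    """Summary of one method against the reference over Np pairs.

    mean_delta / sd_delta are in Angstroms; the relative variants are
    dimensionless; rejection_pct is a percentage (None if not computed).
    """

    mean_delta: float
    mean_rel_delta: float
    sd_delta: float
    sd_rel_delta: float
    n_pairs: int
    rejection_pct: Optional[float] = None
    cutoff: float = DEFAULT_CUTOFF


def _paired(rmsd_x, rmsd_r) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(rmsd_x, dtype=float)
    r = np.asarray(rmsd_r, dtype=float)
    if x.shape != r.shape or x.ndim != 1:
        raise ValueError(f"RMSD lists must be equal-length 1-D, got {x.shape} vs {r.shape}")
    return x, r


def delta_stats(rmsd_x: Sequence[float], rmsd_r: Sequence[float]) -> EnsembleStats:
    """Mean/SD of the absolute and relative RMSD excesses over the reference.

    SDs use the sample (Np - 1) denominator and require Np >= 2; the
    relative terms require every reference RMSD to be positive.
    """
    x, r = _paired(rmsd_x, rmsd_r)
    if x.size < 2:
        raise ValueError("need at least 2 pairs for sample standard deviations")
    if np.any(r <= 0):
        raise ValueError("relative differences undefined: zero reference RMSD present")
    delta = x - r
    rel = delta / r
    return EnsembleStats(
        mean_delta=float(delta.mean()),
        mean_rel_delta=float(rel.mean()),
        sd_delta=float(delta.std(ddof=1)),
        sd_rel_delta=float(rel.std(ddof=1)),
        n_pairs=int(x.size),
    )


def rejection_rate(
    rmsd_x: Sequence[float],
    rmsd_r: Sequence[float],
    cutoff: float = DEFAULT_CUTOFF,
) -> float:
    """Percentage of reference-similar pairs rejected by the fast method.

    100 * |{i: rmsd_x[i] >= cutoff and rmsd_r[i] < cutoff}| / |{i: rmsd_r[i] < cutoff}|.
    Similarity is strict (< cutoff), rejection inclusive (>= cutoff).
    Raises UndefinedRateError when no pair is reference-similar.
    """
    x, r = _paired(rmsd_x, rmsd_r)
    similar = r < cutoff
    denom = int(similar.sum())
    if denom == 0:
        raise UndefinedRateError(
            f"no pair has reference RMSD below the {cutoff} A cutoff"
        )
    rejected = int(np.sum(similar & (x >= cutoff)))
    return 100.0 * rejected / denom


def ensemble_stats(
    rmsd_x: Sequence[float],
    rmsd_r: Sequence[float],
    cutoff: float = DEFAULT_CUTOFF,
) -> EnsembleStats:
    """delta_stats plus the rejection percentage at the given cutoff."""
    stats = delta_stats(rmsd_x, rmsd_r)
    stats.rejection_pct = rejection_rate(rmsd_x, rmsd_r, cutoff)
    stats.cutoff = cutoff
    return stats


def _method_runner(method: str, cfg: Optional[GaussianObjectiveConfig]) -> Callable:
    if method == "simple":
        return simple_superpose
    if method == "reference":
        return reference_superpose
    if method == "lmada":
        return lmada_superpose
    if method == "lmagda":
        return lambda x, y: lmagda_superpose(x, y, cfg)
    raise ValueError(f"unknown method {method!r}")


def all_pairs(
    ensemble: Sequence[Assembly],
    methods: Sequence[str] = ("lmada",),
    names: Optional[Sequence[str]] = None,
    cfg: Optional[GaussianObjectiveConfig] = None,
) -> pd.DataFrame:
    """Superpose every unordered pair of an ensemble with each method.

    Returns a long-format table with one row per (pair, method):
    pair_id, struct_a, struct_b, method, rmsd, rmsd_d, rmsd_phi, mapping.
    An ensemble of Np structures yields Np * (Np - 1) / 2 pairs.
    """
    ensemble = list(ensemble)
    if len(ensemble) < 2:
        raise ValueError("need at least 2 assemblies")
    shapes = {(a.N, a.n) for a in ensemble}
    if len(shapes) > 1:
        raise DimensionMismatchError(f"ensemble members differ in shape: {shapes}")
    if names is None:
        names = [a.source or f"structure_{i}" for i, a in enumerate(ensemble)]
    rows = []
    for pair_id, (i, j) in enumerate(combinations(range(len(ensemble)), 2)):
        for method in methods:
            res = _method_runner(method, cfg)(ensemble[i], ensemble[j])
            rows.append(
                {
                    "pair_id": pair_id,
                    "struct_a": names[i],
                    "struct_b": names[j],
                    "method": method,
                    "rmsd": res.rmsd,
                    "rmsd_d": res.extras.get("rmsd_d", np.nan),
                    "rmsd_phi": res.extras.get("rmsd_phi", np.nan),
                    "mapping": ",".join(map(str, res.mapping)),
                }
            )
    return pd.DataFrame(rows)


def rmsd_matrix(table: pd.DataFrame, method: str, n_structures: int) -> np.ndarray:
    """Square symmetric RMSD matrix (zero diagonal) from an all_pairs table."""
    M = np.zeros((n_structures, n_structures))
    sub = table[table["method"] == method]
    for pair_id, rmsd in zip(sub["pair_id"], sub["rmsd"]):
        i, j = _pair_from_id(int(pair_id), n_structures)
        M[i, j] = M[j, i] = rmsd
    return M


def _pair_from_id(pair_id: int, n: int) -> tuple[int, int]:
    for k, (i, j) in enumerate(combinations(range(n), 2)):
        if k == pair_id:
            return i, j
    raise ValueError(f"pair_id {pair_id} out of range for {n} structures")
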