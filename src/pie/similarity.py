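"""Pocket Similarity Index: descriptor pruning, scaling, Gaussian kernel.

Descriptor columns that are mostly zero carry little comparative signal
and are dropped (kept only when non-zero in strictly more than 95% of
the sample). The remaining columns are re-scaled to zero mean and unit
variance so that no descriptor dominates the Euclidean metric, then

    PSI_ij = exp(-d_ij^2 / (2 sigma^2))

with d_ij the Euclidean distance between pocket rows i and j and sigma
the standard deviation of d over all unordered pairs i != j. PSI is 1
for identical pockets and decays towards 0 with descriptor-space
distance; the kernel is strictly decreasing, so ranking neighbors by
PSI and by distance is the same thing.

Population (not sample) standard deviation is used both for column
scaling and for sigma; a ``ddof`` switch is exposed for either choice.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

MIN_NONZERO_FRAC = 0.95


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray          # (n, n) symmetric, zero diagonal
    sigma: float           # population std of upper-triangle distances

    @property
    def n(self) -> int:
        return len(self.ids)


@dataclass
class PSIMatrix:
    ids: list[str]
    psi: np.ndarray        # (n, n) in (0, 1], diagonal 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.psi, index=self.ids, columns=self.ids)

    def value(self, id_a: str, id_b: str) -> float:
        ia, ib = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.psi[ia, ib])


def _check_frame(m: pd.DataFrame) -> None:
    if m.index.duplicated().any():
        dup = m.index[m.index.duplicated()].tolist()
        raise ValueError(f"duplicate pocket ids: {dup}")


def prune_descriptors(m: pd.DataFrame,
                      min_nonzero_frac: float = MIN_NONZERO_FRAC,
                      ) -> tuple[pd.DataFrame, list[str]]:
    """Keep columns non-zero in strictly more than ``min_nonzero_frac``
    of the rows; returns (pruned matrix, dropped column names)."""
    _check_frame(m)
    if len(m) < 2:
        raise ValueError("need at least two pockets to prune")
    nonzero_frac = (m != 0).sum(axis=0) / len(m)
    keep = nonzero_frac > min_nonzero_frac
    dropped = [c for c, k in zip(m.columns, keep) if not k]
    if not keep.any():
        raise ValueError("all descriptor columns dropped by pruning")
    return m.loc[:, keep], dropped


def standardize(m: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Column-wise (x - mean) / std; constant columns are dropped with a
    warning since they cannot be scaled to unit variance."""
    _check_frame(m)
    if len(m) < 2:
        raise ValueError("need at least two pockets to standardize")
    std = m.std(axis=0, ddof=ddof)
    constant = std[std == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping constant descriptor columns: {constant}",
                      stacklevel=2)
        m = m.drop(columns=constant)
        std = std.drop(constant)
    if m.shape[1] == 0:
        raise ValueError("no non-constant descriptor columns left")
    return (m - m.mean(axis=0)) / std


def pairwise_distances(m: pd.DataFrame, ddof: int = 0) -> DistanceMatrix:
    """Euclidean distances between pocket rows; sigma is the population
    standard deviation of the n(n-1)/2 unordered pair distances."""
    _check_frame(m)
    if len(m) < 2:
        raise ValueError("need at least two pockets for distances")
    condensed = pdist(m.to_numpy(dtype=float), metric="euclidean")
    d = squareform(condensed)
    sigma = float(np.std(condensed, ddof=ddof))
    return DistanceMatrix(ids=[str(i) for i in m.index], d=d, sigma=sigma)


def psi(dm: DistanceMatrix) -> PSIMatrix:
    """Gaussian-kernel transform of a distance matrix into similarities."""
    if dm.sigma <= 0:
        raise ValueError("degenerate pocket set: sigma of pairwise "
                         "distances is zero")
    mat = np.exp(-dm.d ** 2 / (2.0 * dm.sigma ** 2))
    np.fill_diagonal(mat, 1.0)
    return PSIMatrix(ids=list(dm.ids), psi=mat)


def psi_pipeline(m: pd.DataFrame,
                 min_nonzero_frac: float = MIN_NONZERO_FRAC,
                 ddof: int = 0) -> tuple[PSIMatrix, DistanceMatrix, list[str]]:
    """prune -> standardize -> distances -> PSI on a raw descriptor matrix.

    Returns (psi matrix, distance matrix, dropped column names).
    """
    numeric = m.select_dtypes(include=[np.number])
    pruned, dropped = prune_descriptors(numeric,
                                        min_nonzero_frac=min_nonzero_frac)
    scaled = standardize(pruned, ddof=ddof)
    dm = pairwise_distances(scaled, ddof=ddof)
    return psi(dm), dm, dropped


def nearest_neighbors(psim: PSIMatrix, pocket_id: str,
                      k: int) -> list[tuple[str, float]]:
    """The k most similar other pockets, by descending PSI; exact ties
    are broken by lexicographic pocket id for determinism."""
    if pocket_id not in psim.ids:
        raise KeyError(f"unknown pocket id {pocket_id!r}")
    n = len(psim.ids)
    if not 1 <= k < n:
        raise ValueError(f"k must be in [1, {n - 1}]")
    row = psim.psi[psim.ids.index(pocket_id)]
    others = [(other, float(row[j])) for j, other in enumerate(psim.ids)
              if other != pocket_id]
    others.sort(key=lambda t: (-t[1], t[0]))
    return others[:k]
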