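"""Representational dissimilarity matrices: computation, vectorisation, comparison.

An RDM stores pairwise dissimilarities between condition-evoked activation
patterns. Dissimilarity is correlation distance, 1 − r, with r the Pearson
correlation between voxel patterns, so entries lie in [0, 2]. All RDM-to-RDM
comparisons operate on the upper-triangle vector (diagonal excluded) in a
fixed row-major pair order (1,2), (1,3), …, (n−1,n).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RDM",
    "compute_rdm",
    "vectorize_upper",
    "devectorize_upper",
    "correlate_rdms",
    "average_rdms",
    "pair_index",
]

_SYMMETRY_TOL = 1e-12


def pair_index(n: int) -> list:
    """Row-major upper-triangle pair order (i, j), i < j, 0-based."""
    return [(i, j) for i in range(n) for j in range(i + 1, n)]


@dataclass(frozen=True)
class RDM:
    """Symmetric zero-diagonal dissimilarity matrix with condition labels."""

    labels: tuple
    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("RDM matrix must be square")
        if len(self.labels) != m.shape[0]:
            raise ValueError("label count must match matrix size")
        if not np.all(np.isfinite(m)):
            raise ValueError("RDM entries must be finite")
        if np.abs(m - m.T).max() > _SYMMETRY_TOL:
            raise ValueError("RDM must be symmetric")
        if np.abs(np.diag(m)).max() > _SYMMETRY_TOL:
            raise ValueError("RDM diagonal must be zero")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.labels), columns=list(self.labels))

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "RDM":
        if list(df.index) != list(df.columns):
            raise ValueError("RDM table must have matching row and column labels")
        return cls(labels=tuple(df.index), matrix=df.to_numpy(dtype=float))


def compute_rdm(
    patterns: np.ndarray, labels: Sequence[str] | None = None, zscore_voxels: bool = False
) -> RDM:
    """Correlation-distance RDM from a condition × voxel pattern matrix.

    Parameters
    ----------
    patterns
        Array of shape (n_conditions, n_voxels) of beta estimates for one
        subject, region, and task phase.
    labels
        Condition labels; defaults to ``C1..Cn``.
    zscore_voxels
        If True, z-score each voxel across conditions before computing
        dissimilarities (off by default: inputs are taken to be normalised
        beta estimates already).

    Raises
    ------
    ValueError
        On fewer than 2 conditions, fewer than 3 voxels, or any
        zero-variance condition pattern (correlation undefined), naming the
        offending condition.
    """
    p = np.asarray(patterns, dtype=float)
    if p.ndim != 2:
        raise ValueError("patterns must be a 2-D condition × voxel array")
    n_cond, n_vox = p.shape
    if n_cond < 2:
        raise ValueError("need at least 2 conditions")
    if n_vox < 3:
        raise ValueError("need at least 3 voxels")
    if labels is None:
        labels = [f"C{i + 1}" for i in range(n_cond)]
    if len(labels) != n_cond:
        raise ValueError("label count must match number of conditions")

    if zscore_voxels:
        sd = p.std(axis=0, ddof=0)
        if np.any(sd == 0):
            raise ValueError("cannot z-score: some voxel is constant across conditions")
        p = (p - p.mean(axis=0)) / sd

    sds = p.std(axis=1)
    bad = np.where(sds == 0)[0]
    if bad.size:
        raise ValueError(
            f"zero-variance pattern for condition {labels[bad[0]]!r}; "
            "correlation distance is undefined"
        )
    corr = np.corrcoef(p)
    matrix = 1.0 - corr
    np.fill_diagonal(matrix, 0.0)
    return RDM(labels=tuple(labels), matrix=matrix)


def vectorize_upper(rdm: RDM | np.ndarray) -> np.ndarray:
    """Upper-triangle vector (diagonal excluded) in row-major pair order.

    Accepts an :class:`RDM`, any RDM-like object with a ``matrix`` attribute
    (e.g. a factor model RDM), or a bare square array.
    """
    m = np.asarray(getattr(rdm, "matrix", rdm), dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("input must be a square matrix")
    return m[np.triu_indices(m.shape[0], k=1)]


def devectorize_upper(values: np.ndarray, labels: Sequence[str] | None = None) -> RDM:
    """Rebuild a symmetric zero-diagonal RDM from an upper-triangle vector."""
    v = np.asarray(values, dtype=float)
    n = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if n * (n - 1) // 2 != v.size:
        raise ValueError(f"vector length {v.size} is not a triangular number")
    m = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    m[iu] = v
    m = m + m.T
    if labels is None:
        labels = [f"C{i + 1}" for i in range(n)]
    return RDM(labels=tuple(labels), matrix=m)


def _check_comparable(a: RDM, b: RDM) -> None:
    if a.labels != b.labels:
        raise ValueError(f"RDM labels differ: {a.labels} vs {b.labels}")


def correlate_rdms(a, b, method: str = "pearson") -> float:
    """Correlation between two RDMs' upper-triangle vectors.

    Accepts :class:`RDM` or RDM-like objects (``labels`` + ``matrix``).
    ``method`` is ``"pearson"`` (default) or ``"spearman"``. A constant
    vector raises rather than silently returning NaN.
    """
    _check_comparable(a, b)
    va, vb = vectorize_upper(a), vectorize_upper(b)
    for name, v in (("first", va), ("second", vb)):
        if np.ptp(v) == 0:
            raise ValueError(f"{name} RDM has a constant upper-triangle vector")
    if method == "pearson":
        return float(stats.pearsonr(va, vb).statistic)
    if method == "spearman":
        return float(stats.spearmanr(va, vb).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def average_rdms(rdms: Sequence[RDM]) -> RDM:
    """Entrywise arithmetic mean of RDMs sharing one label set."""
    if len(rdms) == 0:
        raise ValueError("cannot average an empty list of RDMs")
    first = rdms[0]
    for r in rdms[1:]:
        _check_comparable(first, r)
    stack = np.stack([r.matrix for r in rdms])
    return RDM(labels=first.labels, matrix=stack.mean(axis=0))
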