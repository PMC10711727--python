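"""Second-order RSA: inter-region representational similarity.

Group-average RDMs (one per ROI and phase) are compared with one another by
correlating their upper-triangle vectors, yielding ROI × ROI similarity
matrices within each phase and across the planning/execution phase pair.
Significance uses either the t transform of the correlation coefficient
(df = n_pairs − 2; the RDM entries are not strictly independent, so this is
approximate) or a seeded condition-label permutation test, both with
Bonferroni correction over the number of unique ROI pairs. Within-phase
structure is summarised by average-linkage hierarchical clustering and
classical (Torgerson) multidimensional scaling on distance 1 − r.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .rdm import RDM, vectorize_upper

__all__ = [
    "SecondOrderResult",
    "inter_roi_matrix",
    "cross_phase_matrix",
    "hierarchical_cluster",
    "mds_embed",
    "correlation_pvalue",
]


@dataclass(frozen=True)
class SecondOrderResult:
    """Inter-ROI correlation structure for one phase pair."""

    phase_pair: tuple
    rois: tuple
    matrix: pd.DataFrame
    p_matrix: pd.DataFrame
    significant_mask: pd.DataFrame
    n_tests: int
    alpha: float
    edge_list: pd.DataFrame  # roi_a, roi_b, r, p, significant
    linkage: np.ndarray | None = None
    linkage_labels: tuple | None = None
    embedding: pd.DataFrame | None = None  # roi, x, y


def correlation_pvalue(
    r: float,
    n: int,
    va: np.ndarray | None = None,
    vb: np.ndarray | None = None,
    method: str = "pearson",
    test: str = "parametric",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> float:
    """Two-tailed p for a correlation between RDM vectors of length ``n``.

    ``test="parametric"`` applies the t transform t = r·sqrt((n−2)/(1−r²))
    with n − 2 degrees of freedom. ``test="permutation"`` permutes condition
    labels of one RDM (rows and columns jointly, so the permutation respects
    RDM structure) and recomputes the correlation; requires ``va``/``vb`` as
    full RDM matrices.
    """
    if test == "parametric":
        if abs(r) >= 1.0:
            return 0.0
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    if test == "permutation":
        if va is None or vb is None:
            raise ValueError("permutation test needs the full RDM matrices")
        rng = np.random.default_rng(seed)
        k = va.shape[0]
        obs = _vec_corr(vectorize_upper(va), vectorize_upper(vb), method)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(k)
            r_p = _vec_corr(
                vectorize_upper(va[np.ix_(perm, perm)]), vectorize_upper(vb), method
            )
            if abs(r_p) >= abs(obs) - 1e-15:
                count += 1
        return float((count + 1) / (n_permutations + 1))
    raise ValueError(f"unknown test {test!r}")


def _vec_corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant RDM vector; correlation is undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def _pairwise(
    rdms_a: Mapping[str, RDM],
    rdms_b: Mapping[str, RDM],
    method: str,
    test: str,
    n_permutations: int,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    rois_a = list(rdms_a)
    rois_b = list(rdms_b)
    r_mat = pd.DataFrame(np.nan, index=rois_a, columns=rois_b)
    p_mat = pd.DataFrame(np.nan, index=rois_a, columns=rois_b)
    for ra in rois_a:
        for rb in rois_b:
            va, vb = rdms_a[ra], rdms_b[rb]
            if va.labels != vb.labels:
                raise ValueError(f"condition labels differ between {ra!r} and {rb!r}")
            r = _vec_corr(vectorize_upper(va), vectorize_upper(vb), method)
            n = va.n * (va.n - 1) // 2
            p = correlation_pvalue(
                r, n, va.matrix, vb.matrix,
                method=method, test=test,
                n_permutations=n_permutations,
                seed=seed + zlib.crc32(f"{ra}|{rb}".encode()) % (2**16),
            )
            r_mat.loc[ra, rb] = r
            p_mat.loc[ra, rb] = p
    return r_mat, p_mat


def inter_roi_matrix(
    avg_rdms: Mapping[str, RDM],
    phase: str = "planning",
    method: str = "pearson",
    alpha: float = 0.05,
    test: str = "parametric",
    n_permutations: int = 10_000,
    seed: int = 0,
    embed: bool = True,
) -> SecondOrderResult:
    """Within-phase ROI × ROI correlation structure with Bonferroni mask.

    Bonferroni correction uses m = R(R−1)/2 unique pairs. The diagonal is 1
    by construction and excluded from testing. Clustering and the 2-D
    embedding are attached when ``embed`` is true and at least 3 ROIs are
    present.
    """
    rois = list(avg_rdms)
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")
    r_mat, p_mat = _pairwise(avg_rdms, avg_rdms, method, test, n_permutations, seed)
    r = r_mat.to_numpy()
    r_mat.loc[:, :] = (r + r.T) / 2.0
    np.fill_diagonal(r_mat.values, 1.0)
    p = p_mat.to_numpy()
    p_mat.loc[:, :] = (p + p.T) / 2.0
    np.fill_diagonal(p_mat.values, 0.0)

    m = len(rois) * (len(rois) - 1) // 2
    mask = p_mat < alpha / m
    np.fill_diagonal(mask.values, False)

    edges = []
    for ra, rb in itertools.combinations(rois, 2):
        edges.append(
            {
                "roi_a": ra,
                "roi_b": rb,
                "r": r_mat.loc[ra, rb],
                "p": p_mat.loc[ra, rb],
                "significant": bool(mask.loc[ra, rb]),
            }
        )
    edge_list = pd.DataFrame(edges, columns=["roi_a", "roi_b", "r", "p", "significant"])

    linkage = labels = embedding = None
    if embed and len(rois) >= 3:
        linkage, labels = hierarchical_cluster(r_mat)
        embedding = mds_embed(r_mat)

    return SecondOrderResult(
        phase_pair=(phase, phase),
        rois=tuple(rois),
        matrix=r_mat,
        p_matrix=p_mat,
        significant_mask=mask,
        n_tests=m,
        alpha=alpha,
        edge_list=edge_list,
        linkage=linkage,
        linkage_labels=labels,
        embedding=embedding,
    )


def cross_phase_matrix(
    avg_rdms_planning: Mapping[str, RDM],
    avg_rdms_execution: Mapping[str, RDM],
    method: str = "pearson",
    alpha: float = 0.05,
    test: str = "parametric",
    n_permutations: int = 10_000,
    seed: int = 0,
) -> SecondOrderResult:
    """Cross-phase ROI × ROI correlations (rows: planning, columns: execution).

    The full R × R matrix, including diagonal self-pairs, is tested with
    Bonferroni correction over m = R² comparisons. The edge list contains
    every pair, flagged by significance, for Sankey-style reporting.
    """
    if set(avg_rdms_planning) != set(avg_rdms_execution):
        raise ValueError("planning and execution phases must share one ROI set")
    rois = list(avg_rdms_planning)
    ordered_exec = {roi: avg_rdms_execution[roi] for roi in rois}
    r_mat, p_mat = _pairwise(
        avg_rdms_planning, ordered_exec, method, test, n_permutations, seed
    )
    m = len(rois) ** 2
    mask = p_mat < alpha / m
    edges = [
        {
            "roi_a": ra,
            "roi_b": rb,
            "r": r_mat.loc[ra, rb],
            "p": p_mat.loc[ra, rb],
            "significant": bool(mask.loc[ra, rb]),
        }
        for ra in rois
        for rb in rois
    ]
    edge_list = pd.DataFrame(edges, columns=["roi_a", "roi_b", "r", "p", "significant"])
    return SecondOrderResult(
        phase_pair=("planning", "execution"),
        rois=tuple(rois),
        matrix=r_mat,
        p_matrix=p_mat,
        significant_mask=mask,
        n_tests=m,
        alpha=alpha,
        edge_list=edge_list,
    )


def hierarchical_cluster(matrix: pd.DataFrame, linkage_method: str = "average"):
    """Agglomerative clustering of ROIs on distance 1 − r.

    ROIs are sorted by label before linkage so the tree is a pure function of
    the correlation structure (deterministic tie-break by label). Returns
    (scipy linkage array, tuple of leaf labels in the sorted input order).
    """
    if linkage_method not in ("average", "single", "complete"):
        raise ValueError(f"unsupported linkage {linkage_method!r}")
    m = matrix.to_numpy(dtype=float)
    if m.shape[0] != m.shape[1] or np.abs(m - m.T).max() > 1e-10:
        raise ValueError("correlation matrix must be square and symmetric")
    order = np.argsort(np.asarray(matrix.index, dtype=object))
    labels = tuple(matrix.index[order])
    dist = 1.0 - m[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    link = hierarchy.linkage(condensed, method=linkage_method)
    return link, labels


def mds_embed(matrix: pd.DataFrame, n_dims: int = 2) -> pd.DataFrame:
    """Classical (Torgerson) MDS of ROIs on distance 1 − r.

    Double-centres the squared distance matrix, takes the top eigenvectors,
    and clips negative eigenvalues to zero. Coordinates are centred at the
    origin; each axis's sign is fixed so that the coordinate of largest
    magnitude on that axis is positive (deterministic orientation up to the
    remaining rigid ambiguity inherent to MDS).
    """
    rois = list(matrix.index)
    if len(rois) < 3:
        raise ValueError("MDS embedding needs at least 3 ROIs")
    m = matrix.to_numpy(dtype=float)
    if np.abs(m - m.T).max() > 1e-10:
        raise ValueError("correlation matrix must be symmetric")
    d = 1.0 - m
    np.fill_diagonal(d, 0.0)
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    idx = np.argsort(eigval)[::-1][:n_dims]
    lam = np.clip(eigval[idx], 0.0, None)
    coords = eigvec[:, idx] * np.sqrt(lam)[None, :]
    coords -= coords.mean(axis=0, keepdims=True)
    for k in range(coords.shape[1]):
        pivot = np.argmax(np.abs(coords[:, k]))
        if coords[pivot, k] < 0:
            coords[:, k] *= -1
    return pd.DataFrame({"roi": rois, "x": coords[:, 0], "y": coords[:, 1]})
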