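"""First-order RSA: model-RDM to neural-RDM comparison with group inference.

For each region of interest (ROI) and task phase, each subject's neural RDM
is correlated with each factor model RDM (upper triangles only). Group-level
significance uses one-tailed Wilcoxon signed-rank tests of the per-subject
correlations against zero, with Benjamini–Hochberg false-discovery-rate
correction across the configured test family. Noise ceilings bound the
correlation attainable by any model given between-subject variability: the
upper bound correlates each subject's RDM with the grand-mean RDM, the lower
bound with the leave-one-out mean of the other subjects' RDMs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .design import FACTORS, StudyDesign, model_rdm
from .rdm import RDM, compute_rdm, correlate_rdms, vectorize_upper
from .synth import PatternSet

__all__ = [
    "NoiseCeiling",
    "RSAResult",
    "model_data_correlations",
    "noise_ceiling",
    "wilcoxon_greater",
    "fdr_bh",
    "run_first_order",
    "results_table",
    "bootstrap_ci",
]

FDR_FAMILIES = ("per_model_phase", "per_phase", "global")

# exact Wilcoxon p-values are used up to this sample size (no ties)
_EXACT_N_MAX = 25


@dataclass(frozen=True)
class NoiseCeiling:
    lower: float
    upper: float

    def __post_init__(self):
        for v in (self.lower, self.upper):
            if not -1.0 - 1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError("noise-ceiling bounds must lie in [-1, 1]")


@dataclass(frozen=True)
class RSAResult:
    """Group RSA outcome for one ROI × phase × model cell."""

    roi: str
    phase: str
    model_name: str
    subject_correlations: np.ndarray
    mean_correlation: float
    wilcoxon_statistic: float
    p_raw: float
    p_fdr: float
    significant: bool
    ceiling: NoiseCeiling | None


def model_data_correlations(
    subject_rdms: Sequence[RDM], model: RDM, method: str = "pearson"
) -> np.ndarray:
    """One model–data correlation per subject."""
    if len(subject_rdms) == 0:
        raise ValueError("need at least one subject RDM")
    return np.array([correlate_rdms(r, model, method=method) for r in subject_rdms])


def _corr_vec(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant RDM vector; correlation is undefined")
    if method == "pearson":
        return float(stats.pearsonr(a, b).statistic)
    if method == "spearman":
        return float(stats.spearmanr(a, b).statistic)
    raise ValueError(f"unknown correlation method {method!r}")


def noise_ceiling(subject_rdms: Sequence[RDM], method: str = "pearson") -> NoiseCeiling:
    """Upper/lower noise-ceiling bounds from between-subject RDM agreement.

    Upper: mean over subjects of corr(subject RDM, grand-mean RDM).
    Lower: mean over subjects of corr(subject RDM, mean RDM of the others).
    """
    n = len(subject_rdms)
    if n < 2:
        raise ValueError("noise ceiling needs at least 2 subjects")
    vectors = np.stack([vectorize_upper(r) for r in subject_rdms])
    total = vectors.sum(axis=0)
    grand_mean = total / n
    if np.ptp(grand_mean) == 0:
        raise ValueError("grand-mean RDM vector is constant")
    upper = np.mean([_corr_vec(v, grand_mean, method) for v in vectors])
    lower = np.mean(
        [_corr_vec(v, (total - v) / (n - 1), method) for v in vectors]
    )
    return NoiseCeiling(lower=float(lower), upper=float(upper))


def wilcoxon_greater(
    values: Sequence[float], zero_method: str = "wilcox"
) -> tuple[float, float]:
    """One-tailed Wilcoxon signed-rank test of H1: location > 0.

    Returns (W+, p). The p-value is exact (full sign-pattern distribution)
    when, after zero handling, n ≤ 25 and the absolute values are untied;
    otherwise a normal approximation with tie and continuity corrections is
    used. ``zero_method`` is ``"wilcox"`` (discard zeros, default) or
    ``"pratt"``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0 or np.all(v == 0):
        raise ValueError("all values are zero; the signed-rank test is undefined")
    nonzero = v[v != 0]
    ties = np.unique(np.abs(nonzero)).size < nonzero.size
    has_zeros = nonzero.size < v.size
    if zero_method == "wilcox" and not has_zeros and nonzero.size <= _EXACT_N_MAX and not ties:
        method = "exact"
    else:
        method = "approx"
    res = stats.wilcoxon(
        v,
        zero_method=zero_method,
        alternative="greater",
        correction=(method == "approx"),
        method=method,
    )
    return float(res.statistic), float(res.pvalue)


def fdr_bh(p_values: Sequence[float], q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR: (adjusted p, rejection mask at level q)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def _subject_rdms(
    patterns: PatternSet, design: StudyDesign, zscore_voxels: bool = False
) -> dict:
    """{(roi, phase): [RDM per subject]} computed once from the pattern set."""
    labels = design.condition_labels
    out = {}
    for roi in patterns.rois:
        for phase in patterns.phases:
            out[(roi, phase)] = [
                compute_rdm(
                    patterns.get(subject, roi, phase),
                    labels=labels,
                    zscore_voxels=zscore_voxels,
                )
                for subject in patterns.subjects
            ]
    return out


def run_first_order(
    patterns: PatternSet,
    design: StudyDesign,
    method: str = "pearson",
    alpha: float = 0.05,
    fdr_family: str = "per_model_phase",
    zero_method: str = "wilcox",
    zscore_voxels: bool = False,
    models: Sequence[str] = FACTORS,
) -> list[RSAResult]:
    """Full first-order RSA over every ROI × phase × model cell.

    ``fdr_family`` sets the scope of the Benjamini–Hochberg correction:
    ``per_model_phase`` (across ROIs, separately per model and phase,
    default), ``per_phase``, or ``global``. With a single subject the noise
    ceiling is unavailable and reported as None.
    """
    if fdr_family not in FDR_FAMILIES:
        raise ValueError(f"fdr_family must be one of {FDR_FAMILIES}")
    rdms = _subject_rdms(patterns, design, zscore_voxels=zscore_voxels)
    model_rdms = {name: model_rdm(design, name) for name in models}

    cells = []
    for roi in patterns.rois:
        for phase in patterns.phases:
            subject_rdms = rdms[(roi, phase)]
            try:
                ceiling = noise_ceiling(subject_rdms, method=method)
            except ValueError:
                ceiling = None
            for name, m in model_rdms.items():
                corrs = model_data_correlations(subject_rdms, m, method=method)
                w, p = wilcoxon_greater(corrs, zero_method=zero_method)
                cells.append(
                    {
                        "roi": roi,
                        "phase": phase,
                        "model": name,
                        "corrs": corrs,
                        "W": w,
                        "p": p,
                        "ceiling": ceiling,
                    }
                )

    def family_key(cell):
        if fdr_family == "per_model_phase":
            return (cell["model"], cell["phase"])
        if fdr_family == "per_phase":
            return (cell["phase"],)
        return ()

    keys = sorted({family_key(c) for c in cells})
    p_adj = {}
    for key in keys:
        members = [i for i, c in enumerate(cells) if family_key(c) == key]
        adj, _ = fdr_bh([cells[i]["p"] for i in members], q=alpha)
        for i, a in zip(members, adj):
            p_adj[i] = a

    results = []
    for i, c in enumerate(cells):
        results.append(
            RSAResult(
                roi=c["roi"],
                phase=c["phase"],
                model_name=c["model"],
                subject_correlations=c["corrs"],
                mean_correlation=float(np.mean(c["corrs"])),
                wilcoxon_statistic=c["W"],
                p_raw=c["p"],
                p_fdr=float(p_adj[i]),
                significant=bool(p_adj[i] < alpha),
                ceiling=c["ceiling"],
            )
        )
    return results


RESULTS_COLUMNS = [
    "roi", "phase", "model", "mean_r", "n", "W",
    "p_raw", "p_fdr", "significant", "ceiling_lower", "ceiling_upper",
]


def results_table(results: Sequence[RSAResult]) -> pd.DataFrame:
    """Flat results table with a pinned column schema."""
    rows = []
    for r in results:
        rows.append(
            {
                "roi": r.roi,
                "phase": r.phase,
                "model": r.model_name,
                "mean_r": r.mean_correlation,
                "n": len(r.subject_correlations),
                "W": r.wilcoxon_statistic,
                "p_raw": r.p_raw,
                "p_fdr": r.p_fdr,
                "significant": r.significant,
                "ceiling_lower": r.ceiling.lower if r.ceiling else np.nan,
                "ceiling_upper": r.ceiling.upper if r.ceiling else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=RESULTS_COLUMNS)


def bootstrap_ci(
    values: Sequence[float],
    n_boot: int = 10_000,
    ci: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    v = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    means = rng.choice(v, size=(n_boot, v.size), replace=True).mean(axis=1)
    lo, hi = np.quantile(means, [(1 - ci) / 2, 1 - (1 - ci) / 2])
    return float(lo), float(hi)
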