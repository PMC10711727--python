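"""Grasp-comfort analysis: factor contrasts, comfort RDMs, and RSA links.

Subjects rate each of the nine grasps for comfort on a 1–10 scale. The
analysis asks (a) whether ratings differ between the two levels of each
grasp factor (paired two-tailed t tests on per-subject level means),
(b) which factor model RDMs the comfort geometry resembles (per-subject
comfort-RDM–model-RDM correlations tested with the one-tailed Wilcoxon
signed-rank test), and (c) which brain regions carry comfort-like geometry
(the group-average comfort RDM correlated with each subject's neural RDM
per ROI and phase, with FDR-corrected Wilcoxon inference as in the
first-order analysis). A comfort RDM is the absolute difference between
condition ratings, which is symmetric and non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import FACTORS, StudyDesign, model_rdm
from .first_order import fdr_bh, noise_ceiling, wilcoxon_greater
from .rdm import RDM, compute_rdm, correlate_rdms
from .synth import ComfortRatings, PatternSet

__all__ = [
    "ComfortResult",
    "level_contrast_ttest",
    "comfort_rdm",
    "comfort_model_correlations",
    "comfort_neural_rsa",
    "run_comfort_analysis",
]


@dataclass(frozen=True)
class ComfortResult:
    """All comfort analyses bundled: contrasts, RDMs, model and neural links."""

    factor_contrasts: pd.DataFrame  # factor, t, df, p
    subject_rdms: dict  # subject -> RDM
    avg_rdm: RDM
    model_correlations: pd.DataFrame  # model, r_avg, mean_r, W, p
    neural_correlations: pd.DataFrame | None  # roi/phase table as in first_order


def _ratings_matrix(ratings: ComfortRatings, design: StudyDesign) -> pd.DataFrame:
    """subject × condition rating matrix, validated against the design."""
    wide = ratings.ratings.pivot(index="subject", columns="condition_id", values="rating")
    expected = [c.condition_id for c in design.conditions]
    missing = [c for c in expected if c not in wide.columns]
    if missing or wide.isna().any().any():
        raise ValueError(f"ratings incomplete: missing conditions {missing or 'values'}")
    return wide[expected]


def level_contrast_ttest(
    ratings: ComfortRatings, design: StudyDesign, factor: str
) -> tuple[float, int, float]:
    """Paired two-tailed t test between a factor's two rating level means.

    Ratings are first averaged within each level per subject; the one-sample
    t on the per-subject differences (first level minus second) has
    df = n − 1. Zero variance of the differences raises.
    """
    wide = _ratings_matrix(ratings, design)
    bits = design.level_bits(factor)
    level0 = wide.loc[:, bits == 0].mean(axis=1)
    level1 = wide.loc[:, bits == 1].mean(axis=1)
    diff = (level0 - level1).to_numpy()
    if np.ptp(diff) == 0:
        raise ValueError(
            f"zero variance of level differences for factor {factor!r}; t undefined"
        )
    res = stats.ttest_1samp(diff, 0.0)
    return float(res.statistic), diff.size - 1, float(res.pvalue)


def comfort_rdm(ratings: pd.Series | Mapping, design: StudyDesign) -> RDM:
    """One subject's comfort RDM: |rating_i − rating_j| over condition pairs."""
    values = []
    for c in design.conditions:
        if c.condition_id not in ratings:
            raise ValueError(f"missing rating for condition {c.condition_id}")
        values.append(float(ratings[c.condition_id]))
    v = np.array(values)
    matrix = np.abs(v[:, None] - v[None, :])
    return RDM(labels=tuple(design.condition_labels), matrix=matrix)


def comfort_model_correlations(
    avg_comfort_rdm: RDM,
    subject_comfort_rdms: Sequence[RDM],
    design: StudyDesign,
    method: str = "pearson",
) -> pd.DataFrame:
    """Comfort-RDM versus model-RDM correlations per factor.

    Per-subject correlations are tested against zero with the one-tailed
    Wilcoxon signed-rank test; the group-average comfort RDM's correlation
    is reported descriptively alongside.
    """
    rows = []
    for factor in FACTORS:
        m = model_rdm(design, factor)
        m_rdm = RDM(labels=m.labels, matrix=m.matrix.astype(float))
        r_avg = correlate_rdms(avg_comfort_rdm, m_rdm, method=method)
        subject_rs = np.array(
            [correlate_rdms(r, m_rdm, method=method) for r in subject_comfort_rdms]
        )
        if np.all(subject_rs == 0):
            # exactly orthogonal geometry: no evidence above zero
            w, p = 0.0, 1.0
        else:
            w, p = wilcoxon_greater(subject_rs)
        rows.append(
            {
                "model": factor,
                "r_avg": r_avg,
                "mean_r": float(subject_rs.mean()),
                "W": w,
                "p": p,
            }
        )
    return pd.DataFrame(rows, columns=["model", "r_avg", "mean_r", "W", "p"])


def comfort_neural_rsa(
    avg_comfort_rdm: RDM,
    patterns: PatternSet,
    design: StudyDesign,
    method: str = "pearson",
    alpha: float = 0.05,
    fdr_family: str = "per_phase",
    zscore_voxels: bool = False,
) -> pd.DataFrame:
    """Correlate each subject's neural RDM with the group-average comfort RDM.

    Group inference per ROI × phase mirrors the first-order analysis:
    one-tailed Wilcoxon on the per-subject correlations, FDR-corrected
    across ROIs (per phase by default, or globally).
    """
    labels = design.condition_labels
    if np.ptp(avg_comfort_rdm.matrix) == 0:
        raise ValueError("average comfort RDM is constant; correlations undefined")
    cells = []
    for roi in patterns.rois:
        for phase in patterns.phases:
            subject_rdms = [
                compute_rdm(patterns.get(s, roi, phase), labels=labels,
                            zscore_voxels=zscore_voxels)
                for s in patterns.subjects
            ]
            corrs = np.array(
                [correlate_rdms(r, avg_comfort_rdm, method=method) for r in subject_rdms]
            )
            w, p = wilcoxon_greater(corrs)
            try:
                ceiling = noise_ceiling(subject_rdms, method=method)
                lower, upper = ceiling.lower, ceiling.upper
            except ValueError:
                lower = upper = np.nan
            cells.append(
                {
                    "roi": roi,
                    "phase": phase,
                    "mean_r": float(corrs.mean()),
                    "n": corrs.size,
                    "W": w,
                    "p_raw": p,
                    "ceiling_lower": lower,
                    "ceiling_upper": upper,
                }
            )
    df = pd.DataFrame(cells)
    if fdr_family == "per_phase":
        adjusted = np.empty(len(df))
        for phase in df["phase"].unique():
            sel = df.index[df["phase"] == phase]
            adj, _ = fdr_bh(df.loc[sel, "p_raw"], q=alpha)
            adjusted[sel] = adj
        df["p_fdr"] = adjusted
    elif fdr_family == "global":
        df["p_fdr"], _ = fdr_bh(df["p_raw"], q=alpha)
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")
    df["significant"] = df["p_fdr"] < alpha
    return df[
        ["roi", "phase", "mean_r", "n", "W", "p_raw", "p_fdr", "significant",
         "ceiling_lower", "ceiling_upper"]
    ]


def run_comfort_analysis(
    ratings: ComfortRatings,
    design: StudyDesign,
    patterns: PatternSet | None = None,
    method: str = "pearson",
    alpha: float = 0.05,
) -> ComfortResult:
    """Factor contrasts, comfort RDMs, and model/neural comfort correlations."""
    contrasts = []
    for factor in FACTORS:
        t, df_, p = level_contrast_ttest(ratings, design, factor)
        contrasts.append({"factor": factor, "t": t, "df": df_, "p": p})
    wide = _ratings_matrix(ratings, design)
    subject_rdms = {
        int(s): comfort_rdm(wide.loc[s], design) for s in wide.index
    }
    stack = np.mean([r.matrix for r in subject_rdms.values()], axis=0)
    avg_rdm = RDM(labels=tuple(design.condition_labels), matrix=stack)
    model_corrs = comfort_model_correlations(
        avg_rdm, list(subject_rdms.values()), design, method=method
    )
    neural = None
    if patterns is not None:
        neural = comfort_neural_rsa(
            avg_rdm, patterns, design, method=method, alpha=alpha
        )
    return ComfortResult(
        factor_contrasts=pd.DataFrame(contrasts, columns=["factor", "t", "df", "p"]),
        subject_rdms=subject_rdms,
        avg_rdm=avg_rdm,
        model_correlations=model_corrs,
        neural_correlations=neural,
    )
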