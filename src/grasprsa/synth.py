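"""Synthetic voxel beta patterns and comfort ratings with planted structure.

The generator emulates the study's data at the level the analysis consumes:
condition-wise multivoxel beta patterns per subject, region of interest
(ROI), and task phase, plus per-subject grasp-comfort ratings. Ground truth
is planted as weighted mixtures of the three binary grasp-factor model RDMs
(grasp axis, grasp size, object mass), so recovery, selectivity, and
false-positive behaviour of the downstream analyses can be verified exactly.

Construction per (ROI, phase): each factor level gets one random unit voxel
vector; a condition's mean pattern is the weighted sum of its levels'
vectors, with weights taken from the planted-effect map. A subject's pattern
adds a subject-specific geometry perturbation (``subject_sd``, emulating
between-subject variability, which lowers the noise ceiling) and independent
measurement noise (``voxel_sd``). Comfort ratings are a baseline minus
per-factor penalties plus noise, clipped to the 1–10 scale, with object mass
dominating by default (heavy objects are rated much less comfortable).

The default planted-effect map follows the study's qualitative findings:
grasp axis in dorsal-stream and early visual regions during planning, grasp
size across ventral and premotor regions in both phases, and object mass in
ventral and sensorimotor regions during execution only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .design import FACTORS, StudyDesign, model_rdm
from .rdm import RDM

__all__ = [
    "DEFAULT_ROIS",
    "PHASES",
    "GeneratorConfig",
    "PatternSet",
    "ComfortRatings",
    "planted_geometry",
    "generate_patterns",
    "generate_comfort_ratings",
]

DEFAULT_ROIS = ("V1", "LOC", "pFS", "PPA", "SPOC", "aIPS", "PMv", "PMd", "M1/S1")
PHASES = ("planning", "execution")

# Which (ROI, phase) cells carry each factor by default, mirroring the
# study's reported significance pattern (axis: dorsal + early visual during
# planning; size: ventral + premotor across phases; mass: execution only).
DEFAULT_PLANTED_CELLS = {
    "grasp_axis": {
        "planning": ("V1", "LOC", "SPOC", "aIPS", "PMv", "PMd", "M1/S1"),
        "execution": ("V1", "LOC"),
    },
    "grasp_size": {
        "planning": ("LOC", "pFS", "PPA", "aIPS", "PMd"),
        "execution": ("V1", "LOC", "PPA", "PMv", "PMd"),
    },
    "object_mass": {
        "planning": (),
        "execution": ("pFS", "PPA", "aIPS", "PMd", "M1/S1"),
    },
}

DEFAULT_PLANTED_WEIGHT = 1.0


def default_planted_weights(
    rois: Sequence[str] = DEFAULT_ROIS,
    weight: float = DEFAULT_PLANTED_WEIGHT,
) -> dict:
    """Planted-effect map {(roi, phase, factor): weight} from the default cells."""
    weights = {}
    for factor, per_phase in DEFAULT_PLANTED_CELLS.items():
        for phase, cells in per_phase.items():
            for roi in cells:
                if roi in rois:
                    weights[(roi, phase, factor)] = weight
    return weights


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic dataset.

    Defaults reproduce the study's dimensions: 21 subjects, 9 ROIs, two task
    phases, 65 voxels per ROI (a 15-mm-diameter sphere at 3-mm isotropic
    resolution), and planted effects in the cells where the study reported
    significant model correlations. Noise standard deviations are per voxel,
    on the scale of unit-norm level vectors.
    """

    n_subjects: int = 21
    rois: tuple = DEFAULT_ROIS
    phases: tuple = PHASES
    n_voxels: int = 65
    planted_weights: Mapping | None = None  # (roi, phase, factor) -> weight
    subject_sd: float = 0.3
    voxel_sd: float = 0.3
    rating_baseline: float = 8.0
    rating_weights: Mapping = field(
        default_factory=lambda: {
            "grasp_axis": 0.6,
            "grasp_size": 0.0,
            "object_mass": 2.5,
        }
    )
    rating_sd: float = 1.0
    rating_integer: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if self.n_voxels < 3:
            raise ValueError("n_voxels must be >= 3")
        for name in ("subject_sd", "voxel_sd", "rating_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.planted_weights is not None:
            for key, w in self.planted_weights.items():
                if w < 0:
                    raise ValueError(f"planted weight for {key} must be non-negative")

    def resolved_weights(self) -> dict:
        if self.planted_weights is None:
            return default_planted_weights(self.rois)
        return dict(self.planted_weights)

    def to_yaml(self) -> str:
        d = {
            "n_subjects": self.n_subjects,
            "rois": list(self.rois),
            "phases": list(self.phases),
            "n_voxels": self.n_voxels,
            "planted_weights": {
                "|".join(k): float(v) for k, v in (self.planted_weights or {}).items()
            }
            or None,
            "subject_sd": self.subject_sd,
            "voxel_sd": self.voxel_sd,
            "rating_baseline": self.rating_baseline,
            "rating_weights": dict(self.rating_weights),
            "rating_sd": self.rating_sd,
            "rating_integer": self.rating_integer,
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        d = yaml.safe_load(text) or {}
        if d.get("planted_weights"):
            d["planted_weights"] = {
                tuple(k.split("|")): v for k, v in d["planted_weights"].items()
            }
        for key in ("rois", "phases"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


class PatternSet:
    """Beta patterns on a complete (subject, roi, phase, condition, voxel) grid."""

    def __init__(
        self,
        betas: np.ndarray,
        subjects: Sequence[int],
        rois: Sequence[str],
        phases: Sequence[str],
        condition_ids: Sequence[int],
        provenance: str = "synthetic",
        metadata: dict | None = None,
    ):
        betas = np.asarray(betas, dtype=float)
        expected = (len(subjects), len(rois), len(phases), len(condition_ids))
        if betas.ndim != 5 or betas.shape[:4] != expected:
            raise ValueError(
                f"betas shape {betas.shape} incompatible with index sizes {expected}"
            )
        if not np.all(np.isfinite(betas)):
            raise ValueError("beta values must be finite")
        self.betas = betas
        self.subjects = list(subjects)
        self.rois = list(rois)
        self.phases = list(phases)
        self.condition_ids = list(condition_ids)
        self.provenance = provenance
        self.metadata = metadata or {}

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[4]

    def get(self, subject: int, roi: str, phase: str) -> np.ndarray:
        """Condition × voxel pattern matrix for one subject, ROI, and phase."""
        return self.betas[
            self.subjects.index(subject),
            self.rois.index(roi),
            self.phases.index(phase),
        ]

    def to_dataframe(self) -> pd.DataFrame:
        ns, nr, np_, nc, nv = self.betas.shape
        idx = pd.MultiIndex.from_product(
            [self.subjects, self.rois, self.phases, self.condition_ids, range(1, nv + 1)],
            names=["subject", "roi", "phase", "condition_id", "voxel"],
        )
        return pd.DataFrame({"beta": self.betas.ravel()}, index=idx).reset_index()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, provenance: str = "file") -> "PatternSet":
        required = ["subject", "roi", "phase", "condition_id", "voxel", "beta"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"pattern table is missing columns: {missing}")
        if not np.issubdtype(np.asarray(df["beta"]).dtype, np.number):
            raise ValueError("beta column must be numeric")
        keys = ["subject", "roi", "phase", "condition_id", "voxel"]
        if df.duplicated(subset=keys).any():
            dup = df[df.duplicated(subset=keys)].iloc[0]
            raise ValueError(
                "duplicate pattern rows, first at "
                f"(subject={dup['subject']}, roi={dup['roi']}, phase={dup['phase']}, "
                f"condition={dup['condition_id']}, voxel={dup['voxel']})"
            )
        subjects = sorted(df["subject"].unique())
        rois = list(pd.unique(df["roi"]))  # preserve file order for labels
        phases = list(pd.unique(df["phase"]))
        condition_ids = sorted(df["condition_id"].unique())
        voxels = sorted(df["voxel"].unique())
        expected = len(subjects) * len(rois) * len(phases) * len(condition_ids) * len(voxels)
        if len(df) != expected:
            counts = df.groupby(["subject", "roi", "phase", "condition_id"]).size()
            full = pd.MultiIndex.from_product(
                [subjects, rois, phases, condition_ids],
                names=["subject", "roi", "phase", "condition_id"],
            )
            missing_cells = full.difference(counts.index)
            if len(missing_cells):
                s, r, p, c = missing_cells[0]
                raise ValueError(
                    f"incomplete pattern table: missing cell "
                    f"(subject={s}, roi={r}, phase={p}, condition={c})"
                )
            raise ValueError("incomplete pattern table: uneven voxel counts")
        full = pd.MultiIndex.from_product(
            [subjects, rois, phases, condition_ids, voxels], names=keys
        )
        pivot = (
            df.set_index(keys)["beta"]
            .reindex(full)
            .to_numpy()
            .reshape(len(subjects), len(rois), len(phases), len(condition_ids), len(voxels))
        )
        return cls(pivot, subjects, rois, phases, condition_ids, provenance=provenance)


@dataclass(frozen=True)
class ComfortRatings:
    """Per-subject comfort ratings on the 1–10 scale, one per condition."""

    ratings: pd.DataFrame  # columns: subject, condition_id, rating

    def __post_init__(self):
        required = {"subject", "condition_id", "rating"}
        if not required.issubset(self.ratings.columns):
            raise ValueError(f"ratings table needs columns {sorted(required)}")
        vals = self.ratings["rating"]
        if vals.min() < 1 or vals.max() > 10:
            raise ValueError("ratings must lie in [1, 10]")

    @property
    def subjects(self) -> list:
        return sorted(self.ratings["subject"].unique())

    def for_subject(self, subject: int) -> pd.Series:
        sub = self.ratings[self.ratings["subject"] == subject]
        return sub.set_index("condition_id")["rating"].sort_index()


def planted_geometry(weights: Mapping, design: StudyDesign) -> RDM:
    """Ground-truth target RDM: weighted sum of factor model RDMs.

    The weighted sum is rescaled so its maximum entry is 1 (when any weight
    is positive); with all weights zero the RDM is identically zero.
    """
    for factor, w in weights.items():
        if factor not in FACTORS:
            raise KeyError(f"unknown factor {factor!r}")
        if w < 0:
            raise ValueError(f"weight for {factor!r} must be non-negative")
    total = np.zeros((design.n_conditions, design.n_conditions))
    for factor in FACTORS:
        w = weights.get(factor, 0.0)
        if w > 0:
            total = total + w * model_rdm(design, factor).matrix
    if total.max() > 0:
        total = total / total.max()
    return RDM(labels=tuple(design.condition_labels), matrix=total)


def generate_patterns(config: GeneratorConfig, design: StudyDesign) -> PatternSet:
    """Draw a complete synthetic PatternSet, reproducible from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    n_sub, n_vox = config.n_subjects, config.n_voxels
    n_cond = design.n_conditions
    weights = config.resolved_weights()
    for roi, phase, factor in weights:
        if roi not in config.rois:
            raise ValueError(f"planted weight for unknown ROI {roi!r}")
        if phase not in config.phases:
            raise ValueError(f"planted weight for unknown phase {phase!r}")
        if factor not in FACTORS:
            raise ValueError(f"planted weight for unknown factor {factor!r}")

    bits = {f: design.level_bits(f) for f in FACTORS}
    betas = np.empty((n_sub, len(config.rois), len(config.phases), n_cond, n_vox))
    for ri, roi in enumerate(config.rois):
        for pi, phase in enumerate(config.phases):
            level_vecs = {}
            for factor in FACTORS:
                vecs = rng.standard_normal((2, n_vox))
                vecs /= np.linalg.norm(vecs, axis=1, keepdims=True)
                level_vecs[factor] = vecs
            means = np.zeros((n_cond, n_vox))
            for factor in FACTORS:
                w = weights.get((roi, phase, factor), 0.0)
                if w > 0:
                    means += w * level_vecs[factor][bits[factor]]
            subject_shift = rng.standard_normal((n_sub, n_cond, n_vox)) * config.subject_sd
            noise = rng.standard_normal((n_sub, n_cond, n_vox)) * config.voxel_sd
            betas[:, ri, pi] = means[None] + subject_shift + noise

    return PatternSet(
        betas,
        subjects=list(range(1, n_sub + 1)),
        rois=config.rois,
        phases=config.phases,
        condition_ids=[c.condition_id for c in design.conditions],
        provenance="synthetic",
        metadata={"seed": config.seed, "config": config.to_yaml()},
    )


def generate_comfort_ratings(config: GeneratorConfig, design: StudyDesign) -> ComfortRatings:
    """Draw synthetic comfort ratings, reproducible from ``config.seed``.

    rating(subject, c) = baseline − Σ_f w_f · [condition c is at the
    penalised level of factor f] + noise, clipped to [1, 10]. The penalised
    level is the second of each factor's level pair (ccw45, large aperture,
    heavy); defaults penalise mass strongly, axis weakly, and size not at
    all, matching the reported comfort structure.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 9173)))
    bits = {f: design.level_bits(f) for f in FACTORS}
    rows = []
    for subject in range(1, config.n_subjects + 1):
        noise = rng.standard_normal(design.n_conditions) * config.rating_sd
        for ci, cond in enumerate(design.conditions):
            value = config.rating_baseline + noise[ci]
            for factor in FACTORS:
                value -= config.rating_weights.get(factor, 0.0) * bits[factor][ci]
            if config.rating_integer:
                value = round(value)
            rows.append(
                {
                    "subject": subject,
                    "condition_id": cond.condition_id,
                    "rating": float(np.clip(value, 1.0, 10.0)),
                }
            )
    return ComfortRatings(ratings=pd.DataFrame(rows))
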