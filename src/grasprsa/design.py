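"""Experimental design: grasp conditions, binary model RDMs, and trial sequences.

The study crosses three L-shaped objects (one beech-wood, two wood/brass in
different orientations) with three preselected grasps each, giving nine
conditions. Each condition is characterised by three binary grasp factors:

* ``grasp_axis`` — thumb–finger opposition axis rotated 45° clockwise or
  counterclockwise about vertical,
* ``grasp_size`` — grip aperture of 2.5 cm or 7.5 cm,
* ``object_mass`` — 67 g (wood) or 557 g (wood/brass).

Object mass is fixed by the object (the wood object is light, both brass
objects heavy), so the mass model RDM is fixed. The axis and size level
assignments were chosen so that the three binary model RDMs are mutually
uncorrelated over condition pairs, which makes the factors linearly
independent predictors of neural dissimilarity. The exact assignment is
recovered here by exhaustive search (:func:`search_orthogonal_assignment`)
and pinned in :data:`DEFAULT_AXIS_LEVELS` / :data:`DEFAULT_SIZE_LEVELS`.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FACTORS",
    "FACTOR_LEVELS",
    "Condition",
    "StudyDesign",
    "ModelRDM",
    "TrialSequence",
    "build_default_design",
    "model_rdm",
    "check_orthogonality",
    "search_orthogonal_assignment",
    "generate_trial_sequence",
]

FACTORS = ("grasp_axis", "grasp_size", "object_mass")

FACTOR_LEVELS = {
    "grasp_axis": ("cw45", "ccw45"),
    "grasp_size": ("small_2.5cm", "large_7.5cm"),
    "object_mass": ("light_67g", "heavy_557g"),
}

OBJECTS = ("Wood", "BrassUp", "BrassDown")

N_CONDITIONS = 9
_PAIRS = list(itertools.combinations(range(N_CONDITIONS), 2))
_I_IDX = np.array([i for i, _ in _PAIRS])
_J_IDX = np.array([j for _, j in _PAIRS])

# Axis / size level bits per condition (1..9), found by
# search_orthogonal_assignment(tolerance=0) and pinned for a stable default
# design. Bit 1 maps to the second level of the factor. Among all exact-zero
# solutions the most level-balanced one is taken (ties broken by bit pattern).
DEFAULT_AXIS_LEVELS = (0, 0, 0, 0, 0, 0, 1, 1, 1)
DEFAULT_SIZE_LEVELS = (0, 0, 1, 1, 1, 1, 0, 0, 1)

# Trial timing (seconds)
PLANNING_DURATIONS_S = (6, 8, 10, 12)
EXECUTION_DURATION_S = 7
ITI_CHOICES_S = (10, 11, 12)
N_RUNS = 4
TRIALS_PER_CONDITION_PER_RUN = 2


@dataclass(frozen=True)
class Condition:
    """One of the nine object × grasp conditions."""

    condition_id: int
    object: str
    grasp_slot: int
    levels: dict = field(hash=False)

    def __post_init__(self):
        if not 1 <= self.condition_id <= 9:
            raise ValueError(f"condition_id must be 1..9, got {self.condition_id}")
        if self.object not in OBJECTS:
            raise ValueError(f"unknown object {self.object!r}")
        for factor in FACTORS:
            if self.levels.get(factor) not in FACTOR_LEVELS[factor]:
                raise ValueError(
                    f"condition {self.condition_id}: invalid level "
                    f"{self.levels.get(factor)!r} for factor {factor!r}"
                )

    @property
    def label(self) -> str:
        return f"{self.object}-{self.grasp_slot}"


@dataclass(frozen=True)
class StudyDesign:
    """Ordered set of the nine conditions (Wood 1–3, BrassUp 4–6, BrassDown 7–9)."""

    conditions: tuple

    def __post_init__(self):
        ids = [c.condition_id for c in self.conditions]
        if ids != list(range(1, len(self.conditions) + 1)):
            raise ValueError("condition ids must be 1..n consecutive")
        combos = {(c.object, c.grasp_slot) for c in self.conditions}
        if len(combos) != len(self.conditions):
            raise ValueError("duplicate (object, grasp_slot) combination")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def condition_labels(self) -> list:
        return [c.label for c in self.conditions]

    def level_bits(self, factor_name: str) -> np.ndarray:
        """0/1 level indicator per condition (1 = second level of the factor)."""
        if factor_name not in FACTORS:
            raise KeyError(f"unknown factor {factor_name!r}")
        second = FACTOR_LEVELS[factor_name][1]
        return np.array(
            [int(c.levels[factor_name] == second) for c in self.conditions]
        )

    def to_json(self) -> str:
        payload = [
            {
                "condition_id": c.condition_id,
                "object": c.object,
                "grasp_slot": c.grasp_slot,
                "levels": dict(c.levels),
            }
            for c in self.conditions
        ]
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StudyDesign":
        payload = json.loads(text)
        conditions = tuple(
            Condition(
                condition_id=item["condition_id"],
                object=item["object"],
                grasp_slot=item["grasp_slot"],
                levels=item["levels"],
            )
            for item in payload
        )
        return cls(conditions=conditions)


@dataclass(frozen=True)
class ModelRDM:
    """Binary hypothesis RDM for one grasp factor: 1 where levels differ."""

    factor_name: str
    matrix: np.ndarray
    labels: tuple

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("model RDM must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("model RDM must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("model RDM diagonal must be zero")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("model RDM entries must be binary")

    @property
    def upper(self) -> np.ndarray:
        m = np.asarray(self.matrix)
        return m[np.triu_indices(m.shape[0], k=1)]


def _build_design(axis_bits: Sequence[int], size_bits: Sequence[int]) -> StudyDesign:
    conditions = []
    for idx in range(N_CONDITIONS):
        obj = OBJECTS[idx // 3]
        mass = "light_67g" if obj == "Wood" else "heavy_557g"
        conditions.append(
            Condition(
                condition_id=idx + 1,
                object=obj,
                grasp_slot=idx % 3 + 1,
                levels={
                    "grasp_axis": FACTOR_LEVELS["grasp_axis"][axis_bits[idx]],
                    "grasp_size": FACTOR_LEVELS["grasp_size"][size_bits[idx]],
                    "object_mass": mass,
                },
            )
        )
    return StudyDesign(conditions=tuple(conditions))


def build_default_design() -> StudyDesign:
    """The nine-condition design with mutually uncorrelated model RDMs.

    Mass is fixed by object (3 light, 6 heavy); axis and size assignments are
    the pinned output of :func:`search_orthogonal_assignment`, for which all
    three pairwise model-RDM Pearson correlations are exactly zero.
    """
    return _build_design(DEFAULT_AXIS_LEVELS, DEFAULT_SIZE_LEVELS)


def model_rdm(design: StudyDesign, factor_name: str) -> ModelRDM:
    """Binary RDM for one factor: entry (i, j) = 1 iff levels of i and j differ."""
    bits = design.level_bits(factor_name)
    matrix = (bits[:, None] != bits[None, :]).astype(int)
    return ModelRDM(
        factor_name=factor_name,
        matrix=matrix,
        labels=tuple(design.condition_labels),
    )


def _upper_vector(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix, dtype=float)
    return m[np.triu_indices(m.shape[0], k=1)]


def check_orthogonality(rdms: Sequence[ModelRDM]) -> pd.DataFrame:
    """Pairwise Pearson correlations between model-RDM upper-triangle vectors.

    Raises
    ------
    ValueError
        If fewer than two RDMs are given, sizes differ, or any RDM's
        upper-triangle vector is constant (correlation undefined).
    """
    if len(rdms) < 2:
        raise ValueError("need at least two RDMs")
    vectors = [_upper_vector(r.matrix) for r in rdms]
    sizes = {v.size for v in vectors}
    if len(sizes) != 1:
        raise ValueError("RDMs must have equal size")
    for r, v in zip(rdms, vectors):
        if np.ptp(v) == 0:
            raise ValueError(
                f"model RDM {r.factor_name!r} has a constant upper-triangle "
                "vector; correlation is undefined"
            )
    names = [r.factor_name for r in rdms]
    corr = np.corrcoef(np.stack(vectors))
    return pd.DataFrame(corr, index=names, columns=names)


@dataclass(frozen=True)
class AssignmentResult:
    """One axis/size level assignment and its worst pairwise model-RDM |r|."""

    axis_bits: tuple
    size_bits: tuple
    max_abs_r: float


def search_orthogonal_assignment(
    tolerance: float = 1e-12, max_results: int | None = None
) -> list:
    """Exhaustively search axis/size assignments giving uncorrelated model RDMs.

    Mass levels are fixed by the objects (3 light / 6 heavy). All 2^9 × 2^9
    joint binary assignments of axis and size levels are enumerated;
    assignments whose RDM vector is constant (all conditions share a level)
    are excluded because their correlation is undefined. Covariances are
    computed in exact integer arithmetic, so correlations of exactly zero are
    detected without rounding error.

    Returns results sorted by (max pairwise |r|, level imbalance, bit
    pattern) — deterministic. An empty list (not an exception) means no
    assignment meets the tolerance.
    """
    n = N_CONDITIONS
    n_pairs = len(_PAIRS)
    all_bits = ((np.arange(512)[:, None] >> np.arange(n)[None, :]) & 1).astype(np.int64)
    vectors = all_bits[:, _I_IDX] ^ all_bits[:, _J_IDX]  # 512 x 36
    sums = vectors.sum(axis=1)
    valid = (sums > 0) & (sums < n_pairs)

    design = _build_design([0] * n, [0] * n)
    mass_bits = design.level_bits("object_mass")
    mass_vec = mass_bits[_I_IDX] ^ mass_bits[_J_IDX]
    mass_sum = int(mass_vec.sum())

    # integer covariance numerators: n_pairs * (u.v) - sum(u) * sum(v)
    cov_mass = n_pairs * (vectors @ mass_vec) - sums * mass_sum
    cross = n_pairs * (vectors @ vectors.T) - np.outer(sums, sums)

    var = n_pairs * (vectors * vectors).sum(axis=1) - sums**2
    mass_var = n_pairs * int(mass_vec @ mass_vec) - mass_sum**2
    with np.errstate(divide="ignore", invalid="ignore"):
        r_mass = cov_mass / np.sqrt(var.astype(float) * mass_var)
        denom = np.sqrt(np.outer(var, var).astype(float))
        r_cross = cross / denom

    results = []
    idx_valid = np.where(valid)[0]
    abs_r_mass = np.abs(r_mass)
    for a in idx_valid:
        if abs_r_mass[a] > tolerance:
            continue
        ok = idx_valid[
            (np.abs(r_cross[a, idx_valid]) <= tolerance)
            & (abs_r_mass[idx_valid] <= tolerance)
        ]
        for s in ok:
            max_r = max(abs_r_mass[a], abs_r_mass[s], abs(r_cross[a, s]))
            results.append(
                AssignmentResult(
                    axis_bits=tuple(int(b) for b in all_bits[a]),
                    size_bits=tuple(int(b) for b in all_bits[s]),
                    max_abs_r=float(max_r),
                )
            )

    def imbalance(bits):
        return abs(2 * sum(bits) - n)

    results.sort(
        key=lambda r: (
            r.max_abs_r,
            imbalance(r.axis_bits) + imbalance(r.size_bits),
            r.axis_bits,
            r.size_bits,
        )
    )
    if max_results is not None:
        results = results[:max_results]
    return results


@dataclass(frozen=True)
class TrialSequence:
    """A full session: 4 runs × 18 trials with pseudorandomised order and timing."""

    trials: pd.DataFrame  # run, trial_index, condition_id, planning_s, execution_s, iti_s, onset_s
    seed: int

    def __len__(self) -> int:
        return len(self.trials)

    def to_csv(self, path) -> None:
        self.trials.to_csv(path, index=False)


def _counterbalanced_order(design: StudyDesign, rng: np.random.Generator) -> list:
    """Greedy first-order counterbalancing of condition order across the session.

    Each condition appears exactly twice per run. The next condition is drawn
    from those still available in the run, preferring the least-used
    condition→condition transition so far (ties broken at random), which
    spreads transition counts as evenly as possible.
    """
    n = design.n_conditions
    transitions = np.zeros((n, n), dtype=int)
    order = []
    prev = None
    for _ in range(N_RUNS):
        remaining = {c: TRIALS_PER_CONDITION_PER_RUN for c in range(n)}
        for _ in range(n * TRIALS_PER_CONDITION_PER_RUN):
            avail = [c for c, k in remaining.items() if k > 0]
            if prev is None:
                pick = avail[rng.integers(len(avail))]
            else:
                costs = np.array([transitions[prev, c] for c in avail])
                # prefer rare transitions, then conditions with more remaining
                best = costs.min()
                tied = [
                    c for c, cost in zip(avail, costs)
                    if cost == best
                ]
                max_rem = max(remaining[c] for c in tied)
                tied = [c for c in tied if remaining[c] == max_rem]
                pick = tied[rng.integers(len(tied))]
                transitions[prev, pick] += 1
            remaining[pick] -= 1
            order.append(pick + 1)
            prev = pick
    return order


def generate_trial_sequence(
    design: StudyDesign, seed: int, method: str = "counterbalanced"
) -> TrialSequence:
    """Generate a pseudorandom session: 4 runs × 18 trials (72 total).

    Each condition appears exactly twice per run. Planning duration is drawn
    uniformly from {6, 8, 10, 12} s, execution lasts 7 s, and the intertrial
    interval is drawn uniformly from {10, 11, 12} s, so onset-to-onset
    spacing falls in [23, 31] s. ``method`` selects the ordering scheme:
    ``"counterbalanced"`` (greedy first-order transition balancing, default)
    or ``"shuffle"`` (plain within-run shuffling).
    """
    rng = np.random.default_rng(seed)
    if method == "counterbalanced":
        order = _counterbalanced_order(design, rng)
    elif method == "shuffle":
        order = []
        base = [c.condition_id for c in design.conditions] * TRIALS_PER_CONDITION_PER_RUN
        for _ in range(N_RUNS):
            run_order = list(base)
            rng.shuffle(run_order)
            order.extend(run_order)
    else:
        raise ValueError(f"unknown sequencing method {method!r}")

    n_per_run = design.n_conditions * TRIALS_PER_CONDITION_PER_RUN
    rows = []
    onset = 0.0
    for t, condition_id in enumerate(order):
        run = t // n_per_run + 1
        trial_index = t % n_per_run + 1
        if trial_index == 1:
            onset = 0.0  # onsets restart per run
        planning = int(rng.choice(PLANNING_DURATIONS_S))
        iti = int(rng.choice(ITI_CHOICES_S))
        rows.append(
            {
                "run": run,
                "trial_index": trial_index,
                "condition_id": condition_id,
                "planning_s": planning,
                "execution_s": EXECUTION_DURATION_S,
                "iti_s": iti,
                "onset_s": onset,
            }
        )
        onset += planning + EXECUTION_DURATION_S + iti
    return TrialSequence(trials=pd.DataFrame(rows), seed=seed)
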