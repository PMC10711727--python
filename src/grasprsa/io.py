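"""File I/O: long-format CSV interchange for patterns, ratings, and results.

The canonical interchange is plain CSV. Beta patterns travel as long tables
(subject, roi, phase, condition_id, voxel, beta); ratings as (subject,
condition_id, rating); the design as JSON. Result tables written by the
pipeline carry a leading ``#``-comment line with the configuration hash and
seed, which pandas skips on read.

Volume-format inputs (NIfTI betas plus ROI masks) are out of scope here; to
import such data, average nothing — extract each ROI's voxel values per
condition into the long table above (one row per subject, ROI, phase,
condition, voxel) and the pipeline consumes it unchanged.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .design import StudyDesign
from .synth import ComfortRatings, PatternSet

__all__ = [
    "read_patterns",
    "write_patterns",
    "read_ratings",
    "write_ratings",
    "read_design",
    "write_design",
    "write_table",
    "read_table",
    "config_hash",
]


def config_hash(payload: str) -> str:
    """Short stable digest of a serialized configuration."""
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    """Write a result CSV with an optional leading metadata comment line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            fields = " ".join(f"{k}={v}" for k, v in meta.items())
            fh.write(f"# {fields}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_patterns(patterns: PatternSet, path, meta: dict | None = None) -> None:
    write_table(patterns.to_dataframe(), path, meta=meta)


def read_patterns(path) -> PatternSet:
    """Read a long-format beta table, validating a complete index crossing.

    Raises ``ValueError`` on missing columns, non-numeric betas, duplicate
    index rows, or missing (subject, roi, phase, condition) cells — each
    error names the offending column or cell.
    """
    df = read_table(path)
    return PatternSet.from_dataframe(df, provenance=str(path))


def write_ratings(ratings: ComfortRatings, path, meta: dict | None = None) -> None:
    write_table(ratings.ratings, path, meta=meta)


def read_ratings(path) -> ComfortRatings:
    df = read_table(path)
    required = ["subject", "condition_id", "rating"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"ratings table is missing columns: {missing}")
    return ComfortRatings(ratings=df[required])


def write_design(design: StudyDesign, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(design.to_json())


def read_design(path) -> StudyDesign:
    return StudyDesign.from_json(Path(path).read_text())


def write_json(payload: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
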