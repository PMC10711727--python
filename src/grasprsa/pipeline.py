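"""End-to-end pipeline: design → (simulate) → first-order → second-order → comfort."""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .comfort import run_comfort_analysis
from .config import PipelineConfig
from .design import (
    StudyDesign,
    build_default_design,
    check_orthogonality,
    generate_trial_sequence,
    model_rdm,
)
from .first_order import results_table, run_first_order, _subject_rdms
from .rdm import average_rdms
from .second_order import cross_phase_matrix, inter_roi_matrix
from .synth import generate_comfort_ratings, generate_patterns

__all__ = ["run_pipeline", "PipelineError"]

logger = logging.getLogger("grasprsa")


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


def _load_or_simulate(config: PipelineConfig, design: StudyDesign):
    if config.patterns_path:
        patterns = io.read_patterns(config.patterns_path)
    else:
        patterns = generate_patterns(config.generator, design)
    if config.ratings_path:
        ratings = io.read_ratings(config.ratings_path)
    else:
        ratings = generate_comfort_ratings(config.generator, design)
    return patterns, ratings


def run_pipeline(config: PipelineConfig, stages: tuple = ("all",)) -> Path:
    """Run the requested stages and write all tables under ``output_dir``.

    Every table carries a comment line with the configuration hash and seed,
    so identical configurations produce byte-identical outputs. Returns the
    output directory. Raises :class:`PipelineError` naming the failing stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    # hash covers analysis-relevant fields only, not where results are written
    hashed = "\n".join(
        line for line in config.to_yaml().splitlines()
        if not line.startswith("output_dir:")
    )
    meta = {"config_hash": io.config_hash(hashed), "seed": config.seed}
    want = set(stages)

    def wanted(stage):
        return "all" in want or stage in want

    try:
        design = (
            io.read_design(config.design_path)
            if config.design_path
            else build_default_design()
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("design", exc) from exc

    if wanted("design"):
        try:
            logger.info("design: writing design, model RDMs, trial sequence")
            io.write_design(design, out / "design.json")
            rdms = [model_rdm(design, f) for f in ("grasp_axis", "grasp_size", "object_mass")]
            ortho = check_orthogonality(rdms)
            io.write_table(ortho.reset_index(names="factor"),
                           out / "model_rdm_orthogonality.csv", meta=meta)
            for r in rdms:
                df = pd.DataFrame(r.matrix, index=r.labels, columns=r.labels)
                io.write_table(df.reset_index(names="condition"),
                               out / f"model_rdm_{r.factor_name}.csv", meta=meta)
            seq = generate_trial_sequence(design, seed=config.seed)
            io.write_table(seq.trials, out / "trial_sequence.csv", meta=meta)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("design", exc) from exc

    try:
        patterns, ratings = _load_or_simulate(config, design)
        if wanted("simulate") and not config.patterns_path:
            logger.info("simulate: writing synthetic patterns and ratings")
            io.write_patterns(patterns, out / "patterns.csv", meta=meta)
            io.write_ratings(ratings, out / "ratings.csv", meta=meta)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("simulate", exc) from exc

    report: dict = {"config": config.to_yaml(), **meta}

    if wanted("rsa"):
        try:
            logger.info("rsa: first-order model correlations")
            results = run_first_order(
                patterns,
                design,
                method=config.rdm_method,
                alpha=config.alpha,
                fdr_family=config.fdr_family,
                zero_method=config.wilcoxon_zero_method,
                zscore_voxels=config.zscore_voxels,
            )
            table = results_table(results)
            io.write_table(table, out / "first_order.csv", meta=meta)
            report["first_order_significant"] = int(table["significant"].sum())
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("rsa", exc) from exc

    if wanted("second-order"):
        try:
            logger.info("second-order: inter-ROI similarity")
            subject_rdms = _subject_rdms(patterns, design, config.zscore_voxels)
            avg = {
                phase: {
                    roi: average_rdms(subject_rdms[(roi, phase)])
                    for roi in patterns.rois
                }
                for phase in patterns.phases
            }
            for phase in patterns.phases:
                res = inter_roi_matrix(
                    avg[phase],
                    phase=phase,
                    method=config.rdm_method,
                    alpha=config.alpha,
                    test=config.second_order_test,
                    n_permutations=config.second_order_permutations,
                    seed=config.seed,
                )
                tag = phase.replace("/", "_")
                io.write_table(res.matrix.reset_index(names="roi"),
                               out / f"second_order_{tag}_r.csv", meta=meta)
                io.write_table(res.edge_list, out / f"second_order_{tag}_edges.csv",
                               meta=meta)
                if res.embedding is not None:
                    io.write_table(res.embedding, out / f"second_order_{tag}_mds.csv",
                                   meta=meta)
                report[f"second_order_{tag}_significant"] = int(
                    res.edge_list["significant"].sum()
                )
            if set(patterns.phases) >= {"planning", "execution"}:
                cross = cross_phase_matrix(
                    avg["planning"],
                    avg["execution"],
                    method=config.rdm_method,
                    alpha=config.alpha,
                    test=config.second_order_test,
                    n_permutations=config.second_order_permutations,
                    seed=config.seed,
                )
                io.write_table(cross.matrix.reset_index(names="roi"),
                               out / "second_order_cross_phase_r.csv", meta=meta)
                io.write_table(cross.edge_list,
                               out / "second_order_cross_phase_edges.csv", meta=meta)
                report["second_order_cross_phase_significant"] = int(
                    cross.edge_list["significant"].sum()
                )
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("second-order", exc) from exc

    if wanted("comfort"):
        try:
            logger.info("comfort: rating contrasts and comfort RSA")
            res = run_comfort_analysis(
                ratings, design, patterns,
                method=config.rdm_method, alpha=config.alpha,
            )
            io.write_table(res.factor_contrasts, out / "comfort_contrasts.csv", meta=meta)
            io.write_table(res.model_correlations, out / "comfort_model_corr.csv",
                           meta=meta)
            if res.neural_correlations is not None:
                io.write_table(res.neural_correlations, out / "comfort_neural.csv",
                               meta=meta)
            avg_df = res.avg_rdm.to_dataframe().reset_index(names="condition")
            io.write_table(avg_df, out / "comfort_avg_rdm.csv", meta=meta)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("comfort", exc) from exc

    if wanted("report"):
        try:
            io.write_json(report, out / "report.json")
            lines = ["# RSA pipeline report", ""]
            for k, v in report.items():
                if k == "config":
                    continue
                lines.append(f"- {k}: {v}")
            (out / "report.md").write_text("\n".join(lines) + "\n")
        except Exception as exc:  # noqa: BLE001
            raise PipelineError("report", exc) from exc

    return out
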