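"""First-order RSA: Wilcoxon inference, FDR, noise ceilings, full runs."""

import itertools

import numpy as np
import pytest
from scipy.stats import rankdata

from grasprsa import (
    GeneratorConfig,
    RDM,
    compute_rdm,
    fdr_bh,
    generate_patterns,
    model_data_correlations,
    noise_ceiling,
    results_table,
    run_first_order,
    wilcoxon_greater,
)
from grasprsa.first_order import RESULTS_COLUMNS, bootstrap_ci
from grasprsa.synth import PatternSet

from conftest import random_rdm


def wilcoxon_enumeration_oracle(values):
    """Exact one-tailed p by brute-force enumeration of all sign patterns."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    ranks = rankdata(np.abs(v))
    w_obs = ranks[v > 0].sum()
    count = 0
    for signs in itertools.product((0, 1), repeat=v.size):
        w = ranks[np.array(signs, dtype=bool)].sum()
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** v.size


def bh_stepup_oracle(p):
    """Definitional Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * p[i] / rank_from_top)
        adj[i] = running
    return adj


class TestWilcoxonGreater:
    def test_all_positive_five_values(self):
        w, p = wilcoxon_greater([1, 2, 3, 4, 5])
        assert w == 15.0
        assert p == pytest.approx(1 / 32)

    def test_all_negative_gives_p_one(self):
        _, p = wilcoxon_greater([-1, -2, -3])
        assert p == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = rng.integers(4, 13)
            v = rng.standard_normal(n)
            _, p = wilcoxon_greater(v)
            assert p == pytest.approx(wilcoxon_enumeration_oracle(v), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_greater([0.0, 0.0])

    def test_large_n_uses_valid_approximation(self):
        rng = np.random.default_rng(22)
        v = rng.standard_normal(40) + 0.5
        _, p = wilcoxon_greater(v)
        assert 0 < p < 0.05

    def test_pratt_zero_handling_available(self):
        _, p = wilcoxon_greater([0.0, 1.0, 2.0, 3.0, -1.0], zero_method="pratt")
        assert 0 < p <= 1


class TestFdrBH:
    def test_worked_stepup_example(self):
        adj, reject = fdr_bh([0.001, 0.013, 0.04, 0.1], q=0.05)
        assert adj == pytest.approx([0.004, 0.026, 0.04 * 4 / 3, 0.1])
        assert reject.tolist() == [True, True, False, False]

    def test_single_p_identity(self):
        adj, _ = fdr_bh([0.5])
        assert adj == pytest.approx([0.5])

    def test_ties_all_equal(self):
        adj, _ = fdr_bh([0.03, 0.03, 0.03])
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            fdr_bh([0.5, 1.5])

    def test_matches_definitional_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            p = rng.uniform(0, 1, size=rng.integers(1, 30))
            adj, _ = fdr_bh(p)
            assert np.allclose(adj, bh_stepup_oracle(p), atol=1e-12)

    def test_adjusted_never_below_raw_and_monotone_in_q(self):
        rng = np.random.default_rng(24)
        p = rng.uniform(0, 1, size=25)
        adj, reject_05 = fdr_bh(p, q=0.05)
        assert (adj >= p - 1e-15).all()
        _, reject_01 = fdr_bh(p, q=0.01)
        assert (reject_01 <= reject_05).all()


class TestNoiseCeiling:
    def test_identical_subjects_give_unit_bounds(self):
        rng = np.random.default_rng(25)
        rdm = random_rdm(rng)
        nc = noise_ceiling([rdm] * 5)
        assert nc.lower == pytest.approx(1.0)
        assert nc.upper == pytest.approx(1.0)

    def test_two_anticorrelated_subjects_lower_below_upper(self):
        v1 = np.array([0.2, 0.8, 0.5])
        v2 = np.array([0.8, 0.2, 0.45])  # negatively correlated upper triangles
        m1, m2 = np.zeros((3, 3)), np.zeros((3, 3))
        iu = np.triu_indices(3, k=1)
        m1[iu], m2[iu] = v1, v2
        rdms = [
            RDM(labels=("a", "b", "c"), matrix=m1 + m1.T),
            RDM(labels=("a", "b", "c"), matrix=m2 + m2.T),
        ]
        nc = noise_ceiling(rdms)
        assert nc.lower < nc.upper
        assert nc.lower < 0  # each subject against the other: negative r

    def test_bounds_tend_to_one_as_noise_vanishes(self, design, model_rdms):
        lowers = []
        for sd in (0.3, 0.05):
            cfg = GeneratorConfig(
                n_subjects=8, rois=("A",), phases=("planning",), n_voxels=40,
                planted_weights={("A", "planning", "grasp_axis"): 1.0},
                subject_sd=sd, voxel_sd=sd, seed=4,
            )
            patterns = generate_patterns(cfg, design)
            rdms = [
                compute_rdm(patterns.get(s, "A", "planning"), labels=design.condition_labels)
                for s in patterns.subjects
            ]
            nc = noise_ceiling(rdms)
            lowers.append(nc.lower)
            assert nc.lower <= nc.upper + 1e-12
        assert lowers[1] > lowers[0]
        assert lowers[1] > 0.95

    def test_fewer_than_two_subjects_rejected(self):
        rng = np.random.default_rng(26)
        with pytest.raises(ValueError, match="2 subjects"):
            noise_ceiling([random_rdm(rng)])


class TestModelDataCorrelations:
    def test_subjects_identical_to_model_give_one(self, model_rdms):
        m = model_rdms["grasp_axis"]
        corrs = model_data_correlations([m] * 4, m)
        assert np.allclose(corrs, 1.0)

    def test_orthogonal_subjects_give_zero(self, model_rdms):
        # size model is exactly orthogonal to the axis model by design
        corrs = model_data_correlations(
            [model_rdms["grasp_size"]] * 3, model_rdms["grasp_axis"]
        )
        assert np.allclose(corrs, 0.0, atol=1e-12)

    def test_noiseless_planted_factor_recovers(self, design, model_rdms):
        cfg = GeneratorConfig(
            n_subjects=3, rois=("A",), phases=("planning",), n_voxels=30,
            planted_weights={("A", "planning", "grasp_axis"): 1.0},
            subject_sd=0.0, voxel_sd=0.0, seed=8,
        )
        patterns = generate_patterns(cfg, design)
        rdms = [
            compute_rdm(patterns.get(s, "A", "planning"), labels=design.condition_labels)
            for s in patterns.subjects
        ]
        corrs = model_data_correlations(rdms, model_rdms["grasp_axis"])
        assert (corrs > 0.99).all()


@pytest.fixture(scope="module")
def planted_run(design):
    cfg = GeneratorConfig(
        n_subjects=10,
        rois=("SPOC", "aIPS", "LOC"),
        n_voxels=40,
        planted_weights={
            ("SPOC", "planning", "grasp_axis"): 1.0,
            ("aIPS", "planning", "grasp_axis"): 1.0,
        },
        subject_sd=0.08,
        voxel_sd=0.08,
        seed=12,
    )
    patterns = generate_patterns(cfg, design)
    return patterns, run_first_order(patterns, design)


class TestRunFirstOrder:
    def test_planted_cells_significant(self, planted_run):
        _, results = planted_run
        sig = {
            (r.roi, r.phase)
            for r in results
            if r.model_name == "grasp_axis" and r.significant
        }
        assert {("SPOC", "planning"), ("aIPS", "planning")} <= sig
        assert ("LOC", "execution") not in sig

    def test_fdr_never_below_raw(self, planted_run):
        _, results = planted_run
        assert all(r.p_fdr >= r.p_raw - 1e-15 for r in results)

    def test_results_cover_all_cells(self, planted_run):
        patterns, results = planted_run
        assert len(results) == len(patterns.rois) * len(patterns.phases) * 3

    def test_invariant_to_subject_and_roi_order(self, design):
        cfg = GeneratorConfig(n_subjects=4, rois=("A", "B"), n_voxels=20, seed=13)
        patterns = generate_patterns(cfg, design)
        shuffled = PatternSet(
            patterns.betas[::-1][:, ::-1],
            subjects=patterns.subjects[::-1],
            rois=patterns.rois[::-1],
            phases=patterns.phases,
            condition_ids=patterns.condition_ids,
        )
        base = {
            (r.roi, r.phase, r.model_name): (r.mean_correlation, r.p_raw, r.p_fdr)
            for r in run_first_order(patterns, design)
        }
        perm = {
            (r.roi, r.phase, r.model_name): (r.mean_correlation, r.p_raw, r.p_fdr)
            for r in run_first_order(shuffled, design)
        }
        assert base.keys() == perm.keys()
        for key in base:
            assert base[key] == pytest.approx(perm[key], abs=1e-12)

    def test_single_subject_reports_no_ceiling(self, design):
        cfg = GeneratorConfig(n_subjects=2, rois=("A",), n_voxels=20, seed=14)
        patterns = generate_patterns(cfg, design)
        solo = PatternSet(
            patterns.betas[:1],
            subjects=patterns.subjects[:1],
            rois=patterns.rois,
            phases=patterns.phases,
            condition_ids=patterns.condition_ids,
        )
        results = run_first_order(solo, design)
        assert len(results) == 6
        assert all(r.ceiling is None for r in results)

    def test_results_table_schema_pinned(self, planted_run):
        _, results = planted_run
        table = results_table(results)
        assert list(table.columns) == RESULTS_COLUMNS

    def test_unknown_fdr_family_rejected(self, design):
        cfg = GeneratorConfig(n_subjects=2, rois=("A",), n_voxels=20, seed=15)
        patterns = generate_patterns(cfg, design)
        with pytest.raises(ValueError, match="fdr_family"):
            run_first_order(patterns, design, fdr_family="per_roi")


def test_bootstrap_ci_brackets_mean():
    rng = np.random.default_rng(30)
    v = rng.standard_normal(50) + 1.0
    lo, hi = bootstrap_ci(v, n_boot=2000, seed=1)
    assert lo < v.mean() < hi
    assert hi - lo < 1.0
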