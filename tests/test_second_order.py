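"""Second-order RSA: inter-ROI matrices, clustering, classical MDS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial import procrustes
from scipy.spatial.distance import cdist

from grasprsa import (
    RDM,
    cross_phase_matrix,
    hierarchical_cluster,
    inter_roi_matrix,
    mds_embed,
)
from grasprsa.second_order import correlation_pvalue

from conftest import random_rdm


def _roi_rdms(rng, rois, base=None, jitter=0.0):
    out = {}
    for roi in rois:
        if base is None:
            out[roi] = random_rdm(rng)
        else:
            v = base + rng.normal(0, jitter, size=base.shape) if jitter else base
            m = np.zeros((9, 9))
            iu = np.triu_indices(9, k=1)
            m[iu] = np.clip(v, 0.01, 1.99)
            out[roi] = RDM(labels=tuple(f"C{i+1}" for i in range(9)), matrix=m + m.T)
    return out


class TestInterRoiMatrix:
    def test_shared_rdm_gives_unit_correlations(self):
        rng = np.random.default_rng(31)
        base = rng.uniform(0.1, 1.9, size=36)
        res = inter_roi_matrix(_roi_rdms(rng, ["A", "B", "C"], base=base))
        off = res.matrix.to_numpy()[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_bonferroni_m_for_nine_rois(self):
        rng = np.random.default_rng(32)
        res = inter_roi_matrix(_roi_rdms(rng, [f"R{i}" for i in range(9)]))
        assert res.n_tests == 36
        assert len(res.edge_list) == 36

    def test_mask_matches_threshold(self):
        rng = np.random.default_rng(33)
        res = inter_roi_matrix(_roi_rdms(rng, [f"R{i}" for i in range(5)]))
        expected = (res.p_matrix < res.alpha / res.n_tests).to_numpy()
        np.fill_diagonal(expected, False)
        assert np.array_equal(res.significant_mask.to_numpy(), expected)

    def test_matrix_exactly_symmetric(self):
        rng = np.random.default_rng(34)
        res = inter_roi_matrix(_roi_rdms(rng, ["A", "B", "C", "D"]))
        m = res.matrix.to_numpy()
        assert np.array_equal(m, m.T)

    def test_fewer_than_two_rois_rejected(self):
        rng = np.random.default_rng(35)
        with pytest.raises(ValueError, match="2 ROIs"):
            inter_roi_matrix({"A": random_rdm(rng)})


class TestCorrelationPvalue:
    def test_t_transform_closed_form(self):
        # r=0.5 with 36 pair entries: t = 0.5 * sqrt(34 / 0.75) ~ 3.3665, df=34
        p = correlation_pvalue(0.5, 36)
        t = 0.5 * np.sqrt(34 / 0.75)
        assert t == pytest.approx(3.3665, abs=1e-3)
        assert p == pytest.approx(2 * stats.t.sf(t, df=34), abs=1e-15)
        assert p == pytest.approx(0.0019, abs=2e-4)

    def test_permutation_test_is_seeded_and_valid(self):
        rng = np.random.default_rng(36)
        a, b = random_rdm(rng), random_rdm(rng)
        kwargs = dict(method="pearson", test="permutation", n_permutations=200, seed=5)
        p1 = correlation_pvalue(0.0, 36, a.matrix, b.matrix, **kwargs)
        p2 = correlation_pvalue(0.0, 36, a.matrix, b.matrix, **kwargs)
        assert p1 == p2
        assert 1 / 201 <= p1 <= 1.0

    def test_permutation_detects_identical_rdms(self):
        rng = np.random.default_rng(37)
        a = random_rdm(rng)
        p = correlation_pvalue(
            1.0, 36, a.matrix, a.matrix, test="permutation", n_permutations=200, seed=1
        )
        assert p < 0.02


class TestCrossPhase:
    def test_identical_phase_sets_give_unit_diagonal(self):
        rng = np.random.default_rng(38)
        rdms = _roi_rdms(rng, ["A", "B", "C"])
        res = cross_phase_matrix(rdms, rdms)
        assert np.allclose(np.diag(res.matrix.to_numpy()), 1.0)
        assert res.n_tests == 9
        assert len(res.edge_list) == 9

    def test_swapping_phases_transposes_matrix(self):
        rng = np.random.default_rng(39)
        plan = _roi_rdms(rng, ["A", "B", "C"])
        execu = _roi_rdms(rng, ["A", "B", "C"])
        fwd = cross_phase_matrix(plan, execu).matrix.to_numpy()
        rev = cross_phase_matrix(execu, plan).matrix.to_numpy()
        assert np.allclose(fwd, rev.T)

    def test_roi_set_mismatch_rejected(self):
        rng = np.random.default_rng(40)
        with pytest.raises(ValueError, match="ROI set"):
            cross_phase_matrix(_roi_rdms(rng, ["A", "B"]), _roi_rdms(rng, ["A", "C"]))

    def test_planted_shared_geometry_is_top_edge(self):
        rng = np.random.default_rng(41)
        shared = rng.uniform(0.1, 1.9, size=36)
        plan = _roi_rdms(rng, ["V1", "SPOC"])
        plan["aIPS"] = _roi_rdms(rng, ["x"], base=shared, jitter=0.05)["x"]
        execu = _roi_rdms(rng, ["V1", "aIPS"])
        execu["SPOC"] = _roi_rdms(rng, ["x"], base=shared, jitter=0.05)["x"]
        res = cross_phase_matrix(plan, execu)
        top = res.edge_list.loc[res.edge_list["r"].idxmax()]
        assert (top["roi_a"], top["roi_b"]) == ("aIPS", "SPOC")


class TestHierarchicalCluster:
    def test_block_structure_merges_within_blocks_first(self):
        rois = ["A1", "A2", "B1", "B2"]
        m = np.array(
            [
                [1.0, 0.95, 0.05, 0.05],
                [0.95, 1.0, 0.05, 0.05],
                [0.05, 0.05, 1.0, 0.95],
                [0.05, 0.05, 0.95, 1.0],
            ]
        )
        link, labels = hierarchical_cluster(pd.DataFrame(m, index=rois, columns=rois))
        first_pair = {labels[int(link[0, 0])], labels[int(link[0, 1])]}
        second_pair = {labels[int(link[1, 0])], labels[int(link[1, 1])]}
        assert first_pair in ({"A1", "A2"}, {"B1", "B2"})
        assert second_pair in ({"A1", "A2"}, {"B1", "B2"})

    def test_closest_pair_merges_first(self):
        rois = ["x", "y", "z"]
        m = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.1], [0.1, 0.1, 1.0]])
        link, labels = hierarchical_cluster(pd.DataFrame(m, index=rois, columns=rois))
        first = {labels[int(link[0, 0])], labels[int(link[0, 1])]}
        assert first == {"x", "y"}

    def test_leaf_count_equals_roi_count(self):
        rng = np.random.default_rng(42)
        n = 7
        r = rng.uniform(-0.5, 0.9, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        rois = [f"R{i}" for i in range(n)]
        link, labels = hierarchical_cluster(pd.DataFrame(r, index=rois, columns=rois))
        assert len(labels) == n
        assert link.shape == (n - 1, 4)

    def test_invariant_to_roi_permutation(self):
        rng = np.random.default_rng(43)
        n = 6
        r = rng.uniform(-0.5, 0.9, size=(n, n))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        rois = [f"R{i}" for i in range(n)]
        df = pd.DataFrame(r, index=rois, columns=rois)
        perm = rng.permutation(n)
        df_perm = df.iloc[perm, perm]
        link_a, labels_a = hierarchical_cluster(df)
        link_b, labels_b = hierarchical_cluster(df_perm)
        assert labels_a == labels_b
        assert np.allclose(link_a, link_b)

    def test_asymmetric_input_rejected(self):
        m = pd.DataFrame([[1.0, 0.2], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="symmetric"):
            hierarchical_cluster(m)


class TestMDS:
    @staticmethod
    def _corr_from_points(points):
        d = cdist(points, points)
        return pd.DataFrame(
            1.0 - d,
            index=[f"R{i}" for i in range(len(points))],
            columns=[f"R{i}" for i in range(len(points))],
        )

    def test_collinear_points_reconstructed(self):
        pts = np.array([[0.0, 0.0], [0.1, 0.0], [0.25, 0.0], [0.4, 0.0]])
        emb = mds_embed(self._corr_from_points(pts))
        d_in = cdist(pts, pts)
        coords = emb[["x", "y"]].to_numpy()
        assert np.abs(cdist(coords, coords) - d_in).max() < 1e-8

    def test_known_planar_configuration_procrustes(self):
        rng = np.random.default_rng(44)
        pts = rng.uniform(0, 0.4, size=(6, 2))
        emb = mds_embed(self._corr_from_points(pts))
        _, _, disparity = procrustes(pts, emb[["x", "y"]].to_numpy())
        assert np.sqrt(disparity) < 1e-8

    def test_equilateral_from_equal_distances(self):
        m = self._corr_from_points(np.zeros((3, 2)))
        m.loc[:, :] = 1.0 - 0.5 * (1 - np.eye(3))
        emb = mds_embed(m)
        coords = emb[["x", "y"]].to_numpy()
        d = cdist(coords, coords)[np.triu_indices(3, k=1)]
        assert np.allclose(d, d[0], atol=1e-10)

    def test_fewer_than_three_rois_rejected(self):
        m = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="3 ROIs"):
            mds_embed(m)

    def test_embedding_centered_and_deterministically_oriented(self):
        rng = np.random.default_rng(45)
        pts = rng.uniform(0, 0.4, size=(5, 2))
        emb = mds_embed(self._corr_from_points(pts))
        coords = emb[["x", "y"]].to_numpy()
        assert np.allclose(coords.mean(axis=0), 0, atol=1e-12)
        for k in range(2):
            assert coords[np.argmax(np.abs(coords[:, k])), k] >= 0
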