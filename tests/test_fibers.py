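"""Tests of ridge enhancement, masking, skeleton decomposition, granules."""

import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from conftest import random_tree_mask
from vimtrace.fibers import (
    decompose_segments,
    detect_granules,
    enhance_ridges,
    segment_fibers,
    skeletonize_mask,
    threshold_fibers,
)
from vimtrace.simulate import SimulationConfig, generate_field


def brute_force_tubeness(image, sigma):
    """Independent dense evaluation: Gaussian-derivative Hessian at every
    pixel, closed-form 2x2 eigenvalues, clamp(-lambda_min, 0) * sigma^2."""
    img = np.asarray(image, float)
    hrr = ndi.gaussian_filter(img, sigma, order=(2, 0))
    hrc = ndi.gaussian_filter(img, sigma, order=(1, 1))
    hcc = ndi.gaussian_filter(img, sigma, order=(0, 2))
    tr = hrr + hcc
    disc = np.sqrt((hrr - hcc) ** 2 + 4 * hrc ** 2)
    lam_min = (tr - disc) / 2.0
    return np.clip(-lam_min, 0.0, None) * sigma ** 2


class TestRidgeEnhancement:
    def test_constant_image_zero_response(self):
        resp = enhance_ridges(np.full((64, 64), 37.0))
        assert np.allclose(resp, 0.0, atol=1e-9)

    def test_matches_dense_hessian_oracle_on_gaussian_line(self):
        rr = np.arange(80)[:, None]
        image = 100.0 * np.exp(-((rr - 40.0) ** 2) / (2 * 2.0 ** 2))
        image = np.broadcast_to(image, (80, 120)).copy()
        resp = enhance_ridges(image, scales=[2.0])
        oracle = brute_force_tubeness(image, 2.0)
        # the two Gaussian-derivative discretizations differ slightly
        # (single-pass versus cascaded smoothing); any error in the
        # operator, eigenvalue choice, clamping or normalization would
        # show up at the scale of the response itself
        np.testing.assert_allclose(resp, oracle, atol=0.01 * oracle.max())
        # response is maximal on the centerline
        interior = resp[:, 10:-10]
        assert np.all(np.argmax(interior, axis=0) == 40)

    def test_invariant_to_constant_offset(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (64, 64))
        np.testing.assert_allclose(enhance_ridges(img),
                                   enhance_ridges(img + 123.0), atol=1e-8)

    def test_rejects_bad_scales(self):
        with pytest.raises(ValueError):
            enhance_ridges(np.ones((8, 8)), scales=[0.0])


class TestThreshold:
    def test_zero_response_gives_empty_mask(self):
        fm = threshold_fibers(np.zeros((32, 32)))
        assert not fm.mask.any()

    def test_mask_covers_ground_truth_centerlines(self):
        cfg = SimulationConfig(field_shape=(512, 512), n_nuclei=4,
                               fibers_per_cell=10.0, seed=1)
        img, gt = generate_field(cfg)
        fm = threshold_fibers(enhance_ridges(img.fiber_channel))
        covered = ndi.binary_dilation(fm.mask, iterations=2)
        hits = total = 0
        for poly in gt.fiber_centerlines:
            idx = np.rint(poly).astype(int)
            hits += covered[idx[:, 0], idx[:, 1]].sum()
            total += len(idx)
        assert total > 0
        assert hits / total >= 0.90

    def test_mask_invariant_to_response_scaling(self):
        rng = np.random.default_rng(1)
        resp = rng.exponential(1.0, (128, 128))
        resp[40:90, 60:64] += 50.0
        m1 = threshold_fibers(resp).mask
        m2 = threshold_fibers(2.0 * resp).mask
        np.testing.assert_array_equal(m1, m2)


class TestSkeleton:
    def test_straight_bar_single_path(self):
        m = np.zeros((40, 120), bool)
        m[18:23, 10:110] = True
        g = skeletonize_mask(m)
        assert len(g.edges) == 1
        assert len(g.endpoints) == 2
        assert g.n_branchpoints == 0

    def test_plus_shape_one_branch_cluster_four_arms(self):
        m = np.zeros((121, 121), bool)
        m[58:63, 10:110] = True
        m[10:110, 58:63] = True
        g = skeletonize_mask(m)
        assert g.n_branchpoints == 1
        assert len(g.endpoints) == 4
        assert decompose_segments(g, pixel_size=0.325).total_count == 4

    def test_networkx_export_of_plus_shape(self):
        import networkx as nx

        m = np.zeros((121, 121), bool)
        m[58:63, 10:110] = True
        m[10:110, 58:63] = True
        g = skeletonize_mask(m).to_networkx()
        assert isinstance(g, nx.MultiGraph)
        assert g.number_of_edges() == 4
        assert g.degree[1] == 4  # the single branchpoint cluster

    def test_idempotent_on_existing_skeleton(self):
        mask, _ = random_tree_mask(17)
        g = skeletonize_mask(mask, spur_prune_px=5)
        g2 = skeletonize_mask(g.skeleton, spur_prune_px=0)
        np.testing.assert_array_equal(g.skeleton, g2.skeleton)

    def test_pixel_partition_conservation(self):
        """Edge pixels plus branchpoint pixels tile the skeleton exactly."""
        for seed in (2, 9, 23):
            mask, _ = random_tree_mask(seed)
            g = skeletonize_mask(mask)
            n_edge_px = sum(len(e.pixels) for e in g.edges)
            n_node_px = int((g.node_labels > 0).sum())
            assert n_edge_px + n_node_px == int(g.skeleton.sum())

    def test_empty_mask_yields_empty_graph(self):
        g = skeletonize_mask(np.zeros((16, 16), bool))
        assert len(g.edges) == 0
        assert decompose_segments(g, pixel_size=0.325).total_count == 0


class TestDecomposition:
    def test_segment_count_equals_tree_edge_count(self):
        """Branchpoint decomposition recovers the generating tree topology
        exactly on 50 random synthetic skeleton trees."""
        for seed in range(50):
            mask, n_edges = random_tree_mask(seed)
            g = skeletonize_mask(mask, spur_prune_px=5)
            ss = decompose_segments(g, pixel_size=0.325, min_segment_length=1.0)
            assert ss.total_count == n_edges, f"tree seed {seed}"

    def test_lengths_reported_in_micrometres(self):
        m = np.zeros((40, 120), bool)
        m[20, 10:110] = True
        g = skeletonize_mask(m, spur_prune_px=0)
        ss = decompose_segments(g, pixel_size=0.5)
        assert len(ss.segments) == 1
        assert ss.segments[0].length_um == pytest.approx(99 * 0.5, rel=0.02)

    def test_measured_counts_track_density(self):
        """Spearman correlation between true and measured segment counts
        across fiber densities is near-perfect."""
        from scipy.stats import spearmanr

        true, measured = [], []
        for fpc in (1.0, 8.0, 25.0):
            for s in range(6):
                cfg = SimulationConfig(field_shape=(384, 384), n_nuclei=5,
                                       fibers_per_cell=fpc, seed=700 + s)
                img, gt = generate_field(cfg)
                segs, _, _ = segment_fibers(img.fiber_channel,
                                            pixel_size=cfg.pixel_size)
                true.append(gt.true_segment_count)
                measured.append(segs.total_count)
        rho = spearmanr(true, measured).statistic
        assert rho > 0.95


class TestGranules:
    def test_no_granules_detected_on_clean_field(self, small_config):
        img, _ = generate_field(small_config.with_(granule_rate=0.0), seed=4)
        gs = detect_granules(img.fiber_channel)
        assert len(gs) <= 1  # at most an isolated noise coincidence

    def test_recall_and_precision_against_simulator_log(self):
        rec, prec = [], []
        for s in range(5):
            cfg = SimulationConfig(field_shape=(512, 512), n_nuclei=8,
                                   fibers_per_cell=3.0, granule_rate=4.0,
                                   seed=600 + s)
            img, gt = generate_field(cfg)
            gs = detect_granules(img.fiber_channel)
            det = np.array([[g.row, g.col] for g in gs.granules])
            tru = np.array(gt.granule_positions)
            assert len(det) and len(tru)
            rec.append(np.mean(cKDTree(det).query(tru)[0] <= 3))
            prec.append(np.mean(cKDTree(tru).query(det)[0] <= 3))
        assert np.mean(rec) >= 0.9
        assert np.mean(prec) >= 0.9

    def test_detections_invariant_to_intensity_offset(self):
        cfg = SimulationConfig(field_shape=(256, 256), n_nuclei=4,
                               fibers_per_cell=2.0, granule_rate=3.0, seed=11)
        img, _ = generate_field(cfg)
        base = np.asarray(img.fiber_channel, float)
        g1 = detect_granules(base)
        g2 = detect_granules(base + 500.0)
        assert len(g1) == len(g2)
        for a, b in zip(g1.granules, g2.granules):
            assert (a.row, a.col) == (b.row, b.col)
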