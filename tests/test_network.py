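"""Tests of ROI pooling, coverage masking, and network statistics."""

import numpy as np
import pandas as pd
import pytest

from syncnet import rois as roilib
from syncnet.network import (
    RoiNetwork,
    apply_coverage_mask,
    band_time_average,
    exclusion_report,
    hub_test,
    node_strength,
    pool_across_subjects,
    pool_to_roi_pair,
    strength_timecourse,
    strength_zmap,
    summed_weight_test,
)
from syncnet.synchrony import PairSyncStat


def _stat(roi_a, roi_b, d, null):
    return PairSyncStat("p", roi_a, roi_b, np.asarray(d), np.asarray(null))


class TestPoolToRoiPair:
    def test_single_pair_identity(self):
        d = np.full((1, 1), 0.3)
        null = np.random.default_rng(0).standard_normal((10, 1, 1))
        pool = pool_to_roi_pair([_stat("A", "B", d, null)])
        key = ("A", "B")
        assert np.allclose(pool[key][0], d)
        assert np.allclose(pool[key][1], null)

    def test_mean_of_two_pairs(self):
        null = np.zeros((5, 1, 1))
        pool = pool_to_roi_pair(
            [_stat("A", "B", [[0.2]], null), _stat("B", "A", [[0.4]], null)]
        )
        assert pool[("A", "B")][0] == pytest.approx(0.3)

    def test_null_averaged_replicate_by_replicate(self):
        """Averaging two independent nulls shrinks the sd by ~sqrt(2)."""
        rng = np.random.default_rng(1)
        n1 = rng.standard_normal((4000, 1, 1))
        n2 = rng.standard_normal((4000, 1, 1))
        pool = pool_to_roi_pair(
            [_stat("A", "B", [[0.0]], n1), _stat("A", "B", [[0.0]], n2)]
        )
        ratio = n1.std() / pool[("A", "B")][1].std()
        assert ratio == pytest.approx(np.sqrt(2), rel=0.05)

    def test_self_pairs_dropped(self):
        pool = pool_to_roi_pair([_stat("A", "A", [[1.0]], np.zeros((3, 1, 1)))])
        assert pool == {}


def _exact_network(weights, rois, pairs, n_perm=500, subject_count=None):
    """Network whose z-scores equal ``weights`` exactly (crafted nulls)."""
    null_vec = np.tile([-1.0, 1.0], n_perm // 2)
    sd = null_vec.std(ddof=1)
    E = len(pairs)
    d_null = np.tile(null_vec[None, :, None, None], (E, 1, 1, 1))
    d_true = np.asarray(weights, float).reshape(E, 1, 1) * sd
    return RoiNetwork(
        rois=list(rois), pairs=list(pairs), d_true=d_true, d_null=d_null,
        subject_count=np.asarray(subject_count if subject_count is not None
                                 else [8] * E),
        freqs=np.array([6.0]), window_starts_ms=np.array([0.0]),
    )


class TestPoolAcrossSubjects:
    def test_identical_subjects_reproduce_single_subject_z(self):
        rng = np.random.default_rng(2)
        d = rng.standard_normal((2, 3))
        null = rng.standard_normal((100, 2, 3))
        pool = {("A", "B"): (d, null)}
        net1 = pool_across_subjects([pool], ["A", "B"], np.arange(2), np.arange(3))
        net3 = pool_across_subjects([pool] * 3, ["A", "B"], np.arange(2), np.arange(3))
        assert np.allclose(net1.zscores()[0], net3.zscores()[0], atol=1e-5)
        assert net3.subject_count[0] == 3

    def test_brute_force_recomputation_small_instance(self):
        """Pooled z equals nested-mean recomputation done by hand."""
        rng = np.random.default_rng(3)
        subj_pools = []
        raw = []
        for _ in range(3):
            stats = [
                _stat("A", "B", rng.standard_normal((1, 1)),
                      rng.standard_normal((50, 1, 1)))
                for _ in range(2)
            ]
            raw.append(stats)
            subj_pools.append(pool_to_roi_pair(stats))
        net = pool_across_subjects(subj_pools, ["A", "B"], [6.0], [0.0])
        d_hand = np.mean([np.mean([s.d_true for s in ss], 0) for ss in raw], 0)
        null_hand = np.mean([np.mean([s.d_null for s in ss], 0) for ss in raw], 0)
        z_hand = (d_hand - null_hand.mean(0)) / null_hand.std(0, ddof=1)
        assert np.allclose(net.zscores()[0][0], z_hand, atol=1e-10)


class TestCoverageMask:
    def test_threshold_boundary(self):
        net = _exact_network([1.0, 2.0], ["A", "B", "C"],
                             [("A", "B"), ("A", "C")], subject_count=[7, 6])
        masked = apply_coverage_mask(net, min_subjects=7)
        assert masked.covered.tolist() == [True, False]
        z, _ = masked.zscores()
        assert z[1, 0, 0] == 0.0 and z[0, 0, 0] != 0.0

    def test_all_below_threshold_masks_everything(self):
        net = _exact_network([1.0], ["A", "B"], [("A", "B")], subject_count=[6])
        assert not apply_coverage_mask(net, 7).covered.any()

    def test_exclusion_report_interhemispheric_accounting(self):
        rois = ["L-hippocampus", "L-uncus", "R-hippocampus", "R-uncus"]
        pairs = [("L-hippocampus", "L-uncus"), ("L-hippocampus", "R-uncus"),
                 ("L-uncus", "R-hippocampus")]
        net = _exact_network([1.0, 1.0, 1.0], rois, pairs,
                             subject_count=[8, 2, 3])
        rep = exclusion_report(apply_coverage_mask(net, 7))
        assert rep["n_possible_pairs"] == 6
        assert rep["n_excluded"] == 2
        assert rep["n_excluded_interhemispheric"] == 2
        assert rep["interhemispheric_fraction_pct"] == pytest.approx(100.0)


class TestBandTimeAverage:
    def test_single_cell_identity(self):
        net = _exact_network([1.5], ["A", "B"], [("A", "B")])
        avg = band_time_average(net, (5.0, 7.0))
        assert np.allclose(avg.zscores()[0], net.zscores()[0])

    def test_z_of_average_differs_from_average_of_z(self):
        """Constructed counterexample: averaging D first rescales the null."""
        rng = np.random.default_rng(4)
        E, P = 1, 400
        null = np.stack(
            [rng.standard_normal((P, 1)), 5.0 * rng.standard_normal((P, 1))],
            axis=-1,
        )[None]  # (E, P, 1, 2) two windows with very different null scales
        d_true = np.array([[[1.0, 5.0]]])
        net = RoiNetwork(
            rois=["A", "B"], pairs=[("A", "B")], d_true=d_true, d_null=null,
            subject_count=np.array([8]), freqs=np.array([6.0]),
            window_starts_ms=np.array([0.0, 200.0]),
        )
        z_cells, _ = net.zscores()
        mean_of_z = z_cells.mean()
        z_of_mean = band_time_average(net).zscores()[0][0, 0, 0]
        assert abs(mean_of_z - z_of_mean) > 0.1


class TestNodeStrength:
    def _toy(self):
        return _exact_network(
            [1.0, 2.0, -1.0], ["A", "B", "C"],
            [("A", "B"), ("A", "C"), ("B", "C")],
        )

    def test_hand_computed_strengths(self):
        net = self._toy()
        k_pos = node_strength(net, "+")
        assert k_pos.tolist() == pytest.approx([3.0, 1.0, 2.0], abs=1e-9)
        k_neg = node_strength(net, "-")
        assert k_neg.tolist() == pytest.approx([0.0, -1.0, -1.0], abs=1e-9)

    def test_handshake_identity(self):
        net = self._toy()
        k_all = node_strength(net, None)
        z, _ = net.zscores()
        assert k_all.sum() == pytest.approx(2 * z.sum(), abs=1e-9)

    def test_relabeling_permutes_strengths(self):
        net = self._toy()
        perm = _exact_network(
            [1.0, 2.0, -1.0], ["C", "B", "A"],
            [("C", "B"), ("C", "A"), ("B", "A")],
        )
        k1 = node_strength(net, "+")
        k2 = node_strength(perm, "+")
        assert k1["A"] == k2["C"] and k1["C"] == k2["A"]


def bh_stepup(pvals, alpha):
    """Independent Benjamini-Hochberg oracle (step-up by hand)."""
    p = np.asarray(pvals)
    order = np.argsort(p)
    m = p.size
    thresh = alpha * (np.arange(1, m + 1)) / m
    below = p[order] <= thresh
    k = np.max(np.nonzero(below)[0]) + 1 if below.any() else 0
    reject = np.zeros(m, bool)
    reject[order[:k]] = True
    return reject


class TestHubTest:
    def test_bh_correction_matches_stepup_oracle(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.02, 0.04, 0.5]
        reject, _, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert reject.tolist() == [True, True, False, False]
        rng = np.random.default_rng(5)
        for _ in range(20):
            pv = rng.uniform(0, 1, 15)
            rej, _, _, _ = multipletests(pv, alpha=0.05, method="fdr_bh")
            assert np.array_equal(rej, bh_stepup(pv, 0.05))

    def test_strong_edge_makes_both_endpoints_hubs(self):
        weights = [8.0] + [0.0] * 5
        rois = ["A", "B", "C", "D"]
        pairs = [("A", "B"), ("A", "C"), ("A", "D"), ("B", "C"), ("B", "D"),
                 ("C", "D")]
        net = _exact_network(weights, rois, pairs)
        # randomize nulls so strength nulls are nondegenerate
        rng = np.random.default_rng(6)
        net.d_null = rng.standard_normal(net.d_null.shape)
        net.d_true = net.d_true + 0.0
        table = hub_test(net, "+", alpha=0.05)
        assert set(table.loc[table.hub, "roi"]) == {"A", "B"}


class TestSummedWeight:
    def test_all_zero_network(self):
        net = _exact_network([0.0, 0.0], ["A", "B", "C"],
                             [("A", "B"), ("B", "C")])
        net.d_null = np.zeros_like(net.d_null)
        res = summed_weight_test(net, "+")
        assert res["z"] == 0.0 and res["p"] == pytest.approx(1.0, abs=0.01)

    def test_positive_signal_detected(self):
        rng = np.random.default_rng(7)
        E = 6
        d_null = rng.standard_normal((E, 500, 1, 1)) * 0.1
        d_true = np.full((E, 1, 1), 0.5)
        net = RoiNetwork(
            rois=["A", "B", "C", "D"], pairs=[("A", "B"), ("A", "C"), ("A", "D"),
                                              ("B", "C"), ("B", "D"), ("C", "D")],
            d_true=d_true, d_null=d_null, subject_count=np.full(E, 8),
            freqs=np.array([6.0]), window_starts_ms=np.array([0.0]),
        )
        assert summed_weight_test(net, "+")["p"] < 0.01
        assert summed_weight_test(net, "-")["p"] > 0.5


def test_strength_timecourse_shape_and_regions():
    rng = np.random.default_rng(8)
    E, P, F, W = 3, 200, 2, 4
    net = RoiNetwork(
        rois=["L-hippocampus", "L-uncus", "R-insula"],
        pairs=[("L-hippocampus", "L-uncus"), ("L-hippocampus", "R-insula"),
               ("L-uncus", "R-insula")],
        d_true=rng.standard_normal((E, F, W)),
        d_null=rng.standard_normal((E, P, F, W)),
        subject_count=np.full(E, 8),
        freqs=np.array([5.0, 6.0]),
        window_starts_ms=np.array([0.0, 200.0, 400.0, 600.0]),
    )
    tc = strength_timecourse(net, band=(3.0, 8.0), sign="+")
    assert len(tc) == 3 * W
    assert set(tc.region) == {"L-mtl", "R-insula"}
    zmap = strength_zmap(net)
    assert zmap.shape == (3, F, W)
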