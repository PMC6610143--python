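"""Segmentation, ring masks, ratios, run-off curves, distributions, lineages."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from livespot import quantify, synth


def disk_label(shape, centers_radii):
    lab = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for i, (cx, cy, r) in enumerate(centers_radii, start=1):
        lab[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = i
    return lab


def brute_force_ring(mask, outer, inner):
    """Oracle: pixels within Euclidean distance `outer` of the mask but not
    within `inner` (pixel-offset metric, matching a disk structuring element)."""
    h, w = mask.shape
    pts = np.argwhere(mask)
    out = np.zeros_like(mask, dtype=bool)
    for y in range(h):
        for x in range(w):
            d2 = ((pts[:, 0] - y) ** 2 + (pts[:, 1] - x) ** 2).min()
            out[y, x] = (d2 <= outer**2) and not (d2 <= inner**2)
    return out


class TestSegmentNuclei:
    def test_two_disks_two_labels(self):
        img = np.where(disk_label((64, 64), [(16, 16, 8), (48, 48, 8)]) > 0, 500.0, 20.0)
        labels = quantify.segment_nuclei(img)
        assert labels.max() == 2

    def test_uniform_frame_no_labels(self):
        assert quantify.segment_nuclei(np.full((32, 32), 5.0)).max() == 0

    def test_embryo_frame_centroids_within_one_px(self):
        movie, truth = synth.make_embryo_sequence(n_frames=11, division_period_frames=10, seed=1)
        labels = quantify.segment_nuclei(movie.frame(10, 0))
        t = truth[truth.frame == 10]
        assert labels.max() == len(t) == 8
        from skimage.measure import regionprops

        centroids = np.array([p.centroid[::-1] for p in regionprops(labels)])  # (x, y)
        for _, row in t.iterrows():
            d = np.hypot(centroids[:, 0] - row.x_px, centroids[:, 1] - row.y_px).min()
            assert d < 1.0

    def test_min_area_discards_specks(self):
        img = np.full((32, 32), 10.0)
        img[5, 5] = 1000.0  # single-pixel speck
        img[20:28, 20:28] = 1000.0
        labels = quantify.segment_nuclei(img, min_area=20)
        assert labels.max() == 1


class TestCytoplasmRing:
    def test_matches_brute_force_enumeration(self):
        lab = disk_label((64, 64), [(30, 30, 10)])
        rings = quantify.cytoplasm_ring(lab, 4, 1)
        oracle = brute_force_ring(lab > 0, 4, 1)
        np.testing.assert_array_equal(rings > 0, oracle)

    def test_ring_disjoint_from_dilated_nucleus(self):
        lab = disk_label((96, 96), [(30, 30, 10), (60, 60, 8), (30, 70, 6)])
        rings = quantify.cytoplasm_ring(lab, 4, 1)
        from skimage.morphology import dilation, disk as disk_se

        dilated = dilation(lab > 0, disk_se(1))
        assert not np.any((rings > 0) & dilated)

    def test_overlapping_rings_assigned_to_nearer_nucleus(self):
        # two nuclei 12 px apart with 4-px rings: the midline pixels must
        # split deterministically by distance
        lab = disk_label((48, 64), [(20, 24, 5), (36, 24, 5)])
        rings = quantify.cytoplasm_ring(lab, 4, 1)
        ys, xs = np.nonzero(rings)
        for y, x in zip(ys, xs):
            d1 = np.hypot(x - 20, y - 24) - 5
            d2 = np.hypot(x - 36, y - 24) - 5
            assert rings[y, x] == (1 if d1 < d2 else 2) or abs(d1 - d2) < 1.5

    def test_edge_clipping_shrinks_ring(self):
        interior = disk_label((64, 64), [(30, 30, 8)])
        edge = disk_label((64, 64), [(3, 30, 8)])
        a = (quantify.cytoplasm_ring(interior) == 1).sum()
        b = (quantify.cytoplasm_ring(edge) == 1).sum()
        assert b < a

    def test_equal_dilations_rejected(self):
        with pytest.raises(ValueError):
            quantify.cytoplasm_ring(disk_label((32, 32), [(16, 16, 5)]), 4, 4)


class TestRegionRatio:
    def test_uniform_image_unity_ratio(self):
        lab = disk_label((64, 64), [(20, 20, 8), (44, 44, 8)])
        rings = quantify.cytoplasm_ring(lab)
        meas = quantify.region_ratio(np.full((64, 64), 123.0), lab, rings)
        assert np.allclose(meas.ratio, 1.0)

    def test_constructed_twofold_ratio(self):
        lab = disk_label((64, 64), [(30, 30, 8)])
        rings = quantify.cytoplasm_ring(lab)
        img = np.full((64, 64), 50.0)
        img[lab == 1] = 100.0
        meas = quantify.region_ratio(img, lab, rings)
        assert meas.ratio[0] == pytest.approx(2.0)

    def test_positive_scale_invariance(self):
        lab = disk_label((64, 64), [(30, 30, 8)])
        rings = quantify.cytoplasm_ring(lab)
        rng = np.random.default_rng(0)
        img = rng.uniform(10, 100, (64, 64))
        a = quantify.region_ratio(img, lab, rings).ratio[0]
        b = quantify.region_ratio(img * 7.3, lab, rings).ratio[0]
        assert a == pytest.approx(b, rel=1e-12)

    def test_background_mask_mode(self):
        lab = disk_label((64, 64), [(30, 30, 8)])
        img = np.full((64, 64), 10.0)
        img[lab == 1] = 47.0
        bg = np.zeros((64, 64), bool)
        bg[:, :5] = True
        meas = quantify.region_ratio(img, lab, background_mask=bg)
        assert meas.ratio[0] == pytest.approx(4.7)

    def test_embryo_final_frame_ratio(self):
        movie, truth = synth.make_embryo_sequence(n_frames=12, division_period_frames=20, seed=2)
        labels = quantify.segment_nuclei(movie.frame(11, 0))
        rings = quantify.cytoplasm_ring(labels)
        meas = quantify.region_ratio(movie.frame(11, 1), labels, rings)
        true_ratio = truth[truth.frame == 11].true_ratio.iloc[0]
        assert meas.ratio.mean() == pytest.approx(true_ratio, rel=0.10)


class TestRatioOfMeans:
    def test_worked_example_fold_amplification(self):
        # 16.6 ± 1.5 over 3.5 ± 0.2 -> 4.7 ± 0.5 at one-decimal rounding
        r = quantify.ratio_of_means(16.6, 1.5, 3.5, 0.2)
        assert round(r.ratio, 1) == 4.7
        assert round(r.sem, 1) == 0.5

    def test_zero_sem_passthrough(self):
        r = quantify.ratio_of_means(5.0, 0.0, 5.0, 0.0)
        assert (r.ratio, r.sem) == (1.0, 0.0)

    def test_delta_method_single_term(self):
        r = quantify.ratio_of_means(10.0, 1.0, 5.0, 0.0)
        assert r.ratio == pytest.approx(2.0)
        assert r.sem == pytest.approx(0.2)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            quantify.ratio_of_means(1.0, 0.1, 0.0, 0.1)


class TestRunoffCurve:
    @staticmethod
    def counts_table(per_cell_counts, dt=10.0):
        rows = []
        for cell, series in enumerate(per_cell_counts):
            for frame, n in enumerate(series):
                rows.append((cell, frame * dt, n))
        return pd.DataFrame(rows, columns=["cell_id", "time_s", "count"])

    def test_constant_counts_give_unity_curve(self):
        curve = quantify.runoff_curve(self.counts_table([[5] * 8, [9] * 8]), drug_time_s=40.0)
        assert np.allclose(curve["mean"], 1.0) and np.allclose(curve["sem"], 0.0)

    def test_pre_drug_segment_mean_is_one(self):
        rng = np.random.default_rng(0)
        tables = [[int(n) for n in rng.poisson(20, 10)] for _ in range(5)]
        curve = quantify.runoff_curve(self.counts_table(tables), drug_time_s=50.0)
        pre = curve[curve.time_s < 50.0]
        assert pre.groupby("channel")["mean"].mean().iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_synthetic_scene_survival_and_mrna_persistence(self):
        rate = 0.05
        scene = synth.RunoffScene(
            n_cells=6, spots_per_cell=30, n_frames=20, drug_time_s=50.0, runoff_rate=rate
        )
        optics = synth.Optics(field_px=(128, 128), frame_interval_s=10.0)
        _, truth = synth.make_runoff_scene(scene, optics, seed=3)
        counts = quantify.spot_counts(truth, scene.n_frames, optics.frame_interval_s)
        curve = quantify.runoff_curve(counts, scene.drug_time_s)
        nascent = curve[curve.channel == 0]
        for _, row in nascent[nascent.time_s > 50.0].iterrows():
            expected = np.exp(-rate * (row.time_s - 50.0))
            assert abs(row["mean"] - expected) <= 2 * max(row["sem"], 0.02)
        mrna = curve[curve.channel == 1]
        assert np.allclose(mrna["mean"], 1.0)

    def test_cell_without_pre_drug_spots_excluded(self):
        t = self.counts_table([[0, 0, 5, 5], [4, 4, 4, 4]], dt=10.0)
        curve = quantify.runoff_curve(t, drug_time_s=20.0)
        assert (curve["count"] == 1).all()  # only the second cell remains


class TestColocalizeSpots:
    @staticmethod
    def table(xy, frame=0):
        return pd.DataFrame(
            {"frame": frame, "x_um": [p[0] for p in xy], "y_um": [p[1] for p in xy]}
        )

    def test_identical_tables_fraction_one(self):
        a = self.table([(1.0, 1.0), (2.0, 2.0), (3.0, 1.0)])
        _, frac = quantify.colocalize_spots(a, a.copy(), radius_um=0.25)
        assert frac == 1.0

    def test_distant_tables_fraction_zero(self):
        a = self.table([(1.0, 1.0)])
        b = self.table([(2.0, 1.0)])
        _, frac = quantify.colocalize_spots(a, b, radius_um=0.25)
        assert frac == 0.0

    def test_seventy_percent_overlap_recovered(self):
        rng = np.random.default_rng(4)
        n = 200
        b_xy = rng.uniform(0, 50, (n, 2))
        a_xy = b_xy.copy()
        miss = rng.choice(n, size=60, replace=False)  # 30% displaced far away
        a_xy[miss] += 5.0
        a = self.table([tuple(p) for p in a_xy])
        b = self.table([tuple(p) for p in b_xy])
        _, frac = quantify.colocalize_spots(a, b, radius_um=0.3)
        assert frac == pytest.approx(0.7, abs=0.05)

    def test_empty_table_reports_missing(self):
        a = self.table([])
        b = self.table([(1.0, 1.0)])
        _, frac = quantify.colocalize_spots(a, b, radius_um=0.25)
        assert np.isnan(frac)


class TestSummarizeDistribution:
    def test_linear_interpolation_order_statistics(self):
        s = quantify.summarize_distribution(np.arange(1, 101))
        assert s["median"] == 50.5
        assert s["p25"] == 25.75
        assert s["p75"] == 75.25

    def test_single_value(self):
        s = quantify.summarize_distribution([7.0])
        assert all(s[k] == 7.0 for k in ("median", "p5", "p25", "p75", "p95", "mean"))
        assert s["sem"] == 0.0 and s["n"] == 1

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30))
    def test_permutation_invariance(self, values):
        import random

        shuffled = values[:]
        random.Random(0).shuffle(shuffled)
        a = quantify.summarize_distribution(values)
        b = quantify.summarize_distribution(shuffled)
        assert a == pytest.approx(b)


class TestTrackNuclei:
    def test_stationary_nuclei_single_lineages(self):
        lab = disk_label((64, 64), [(20, 20, 6), (44, 44, 6)])
        lineages = quantify.track_nuclei([lab] * 5)
        assert lineages.lineage_id.nunique() == 2
        assert (lineages.groupby("lineage_id").size() == 5).all()

    def test_embryo_division_counts_and_area(self):
        movie, _ = synth.make_embryo_sequence(
            n_start_nuclei=4, division_period_frames=10, n_frames=21, seed=0
        )
        labelings = [quantify.segment_nuclei(movie.frame(t, 0)) for t in range(movie.n_frames)]
        probe = [movie.frame(t, 1) for t in range(movie.n_frames)]
        lineages = quantify.track_nuclei(labelings, probe)
        series = quantify.nucleus_count_series(lineages)
        assert list(series["count"].iloc[[0, 10, 20]]) == [4, 8, 16]
        # area roughly halves at each division
        a0, a1, a2 = series["mean_area_px2"].iloc[[0, 10, 20]]
        assert a1 == pytest.approx(a0 / 2, rel=0.2)
        assert a2 == pytest.approx(a1 / 2, rel=0.2)
        # daughters are recorded against their parent lineage
        divided = lineages[lineages.parent_lineage >= 0]
        assert set(divided.frame.unique()) == {10, 20}

    def test_empty_frame_terminates_lineages(self):
        lab = disk_label((48, 48), [(24, 24, 6)])
        lineages = quantify.track_nuclei([lab, np.zeros_like(lab), lab])
        assert lineages.lineage_id.nunique() == 2  # restarted after the gap
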