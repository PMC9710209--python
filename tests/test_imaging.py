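"""Spot detection, per-condition summaries, clustering and morphometrics."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from oligoflux import (
    InvalidInputError,
    MissingDataError,
    ShapeGroundTruth,
    SpotGroundTruth,
    average_stack,
    cluster_localizations,
    detect_spots,
    gen_localizations,
    gen_spot_counts,
    gen_tirf_stack,
    shape_metrics,
    spots_summary,
)
from oligoflux.imaging import LocalizationTable
from oligoflux.synthetic import random_spot_positions


def match_spots(truth_pos, detected, radius=1.0):
    """Greedy 1-px matching; returns (n_matched, n_true, n_detected)."""
    if len(detected) == 0:
        return 0, len(truth_pos), 0
    tree = cKDTree(detected)
    used = set()
    matched = 0
    for p in truth_pos:
        dist, idx = tree.query(p, k=min(4, len(detected)))
        for d, i in zip(np.atleast_1d(dist), np.atleast_1d(idx)):
            if d <= radius and i not in used:
                used.add(i)
                matched += 1
                break
    return matched, len(truth_pos), len(detected)


class TestAverageStack:
    def test_identical_frames_average_to_one_frame(self):
        frame = np.arange(64.0 * 64).reshape(64, 64)
        stack = np.stack([frame] * 5)
        np.testing.assert_array_equal(average_stack(stack), frame)

    def test_single_frame_is_identity(self):
        frame = np.random.default_rng(0).normal(size=(64, 64))
        np.testing.assert_array_equal(average_stack(frame[None]), frame)

    def test_averaging_fifty_frames_reduces_noise_by_sqrt_n(self):
        truth = SpotGroundTruth(
            positions=np.empty((0, 2)), background=100.0, read_noise_sd=20.0,
            n_frames=50, seed=9,
        )
        stack = gen_tirf_stack(truth, shape=(128, 128))
        resid_sd = np.std(average_stack(stack) - 100.0)
        expected = 20.0 / np.sqrt(50)
        assert resid_sd == pytest.approx(expected, rel=0.05)


class TestDetectSpots:
    def test_single_spot_on_zero_background_is_found_exactly(self):
        img = np.zeros((64, 64))
        img[40, 21] = 50.0
        spots = detect_spots(img)
        assert spots.count == 1
        assert spots.spots[0][:2] == (40.0, 21.0)

    def test_constant_image_yields_zero_spots(self):
        assert detect_spots(np.full((64, 64), 7.0)).count == 0

    def test_planted_spots_are_recovered_with_high_fidelity(self):
        pos = random_spot_positions(100, (512, 512), seed=1)
        truth = SpotGroundTruth(
            positions=pos, amplitude=200.0, read_noise_sd=20.0, n_frames=50,
            seed=1,
        )
        img = average_stack(gen_tirf_stack(truth))
        det = detect_spots(img).coordinates()
        matched, n_true, n_det = match_spots(pos, det)
        assert matched / n_true >= 0.95
        assert matched / n_det >= 0.95

    def test_translation_equivariance(self):
        pos = random_spot_positions(20, (128, 128), seed=3, margin=30.0)
        truth = SpotGroundTruth(positions=pos, read_noise_sd=5.0, n_frames=10,
                                seed=3)
        img = average_stack(gen_tirf_stack(truth, shape=(128, 128)))
        shifted = np.roll(img, (7, -5), axis=(0, 1))
        a = {tuple(rc) for rc in detect_spots(img).coordinates()}
        b = {(r - 7, c + 5) for r, c in
             ((rc[0], rc[1]) for rc in detect_spots(shifted).coordinates())}
        # compare away from the wrapped borders
        interior = lambda s: {p for p in s if 15 < p[0] < 113 and 15 < p[1] < 113}
        assert interior(a) == interior(b)

    def test_count_is_monotone_in_planted_spot_number(self):
        counts = []
        for n in (10, 40, 80):
            pos = random_spot_positions(n, (256, 256), seed=5)
            truth = SpotGroundTruth(positions=pos, read_noise_sd=10.0,
                                    n_frames=20, seed=5)
            img = average_stack(gen_tirf_stack(truth, shape=(256, 256)))
            counts.append(detect_spots(img).count)
        assert counts[0] < counts[1] < counts[2]


class TestSpotsSummary:
    def test_basic_statistics(self):
        df = spots_summary({"A": [10, 10, 10]})
        row = df.iloc[0]
        assert row["mean"] == 10 and row["sd"] == 0 and row["n"] == 3

    def test_identical_groups_have_unit_fold(self):
        df = spots_summary({"A": [5, 6, 7], "B": [5, 6, 7]}, reference="B")
        assert df.loc[df.condition == "A", "fold_vs_reference"].iloc[0] == 1.0

    def test_serum_vs_csf_like_generators_recover_the_fold_difference(self):
        serum = gen_spot_counts(370.0, 130.0, n_fields=12, seed=21)
        csf = gen_spot_counts(27.0, 16.0, n_fields=12, seed=22)
        df = spots_summary({"PD_serum": serum, "PD_CSF": csf}, reference="PD_CSF")
        fold = df.loc[df.condition == "PD_serum", "fold_vs_reference"].iloc[0]
        assert fold == pytest.approx(370.0 / 27.0, rel=0.5)

    def test_empty_group_raises(self):
        with pytest.raises(MissingDataError):
            spots_summary({"A": []})


class TestClustering:
    def test_two_distant_clouds_make_two_clusters(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 20, size=(50, 2))
        b = rng.normal(0, 20, size=(50, 2)) + [1000.0, 0.0]
        xy = np.vstack([a, b])
        tab = LocalizationTable(xy[:, 0], xy[:, 1], np.arange(100), np.ones(100))
        clusters = cluster_localizations(tab, link_radius_nm=100.0, min_size=20)
        assert len(clusters) == 2

    def test_a_chain_within_radius_is_one_cluster(self):
        x = np.arange(0.0, 1000.0, 40.0)
        tab = LocalizationTable(x, np.zeros_like(x), np.arange(x.size),
                                np.ones_like(x))
        clusters = cluster_localizations(tab, link_radius_nm=50.0, min_size=10)
        assert len(clusters) == 1
        assert len(clusters[0]) == x.size

    def test_five_planted_rods_are_recovered_with_memberships(self):
        tables, labels = [], []
        for i in range(5):
            truth = ShapeGroundTruth(
                kind="rod", length_nm=300.0, n_localizations=80,
                precision_nm=10.0, seed=30 + i,
                center_nm=(2000.0 * i, 1000.0 * (i % 2)),
            )
            t = gen_localizations(truth)
            tables.append(t)
            labels.extend([i] * len(t))
        xy = np.vstack([t.xy() for t in tables])
        tab = LocalizationTable(xy[:, 0], xy[:, 1],
                                np.arange(xy.shape[0]), np.ones(xy.shape[0]))
        clusters = cluster_localizations(tab, link_radius_nm=50.0, min_size=20)
        assert len(clusters) == 5
        sizes = sorted(len(c) for c in clusters)
        assert sizes == [80] * 5


class TestShapeMetrics:
    def test_noiseless_disc_is_round(self):
        truth = ShapeGroundTruth(kind="disc", diameter_nm=300.0,
                                 n_localizations=500, precision_nm=0.0, seed=7)
        shape = shape_metrics(gen_localizations(truth))
        assert shape.eccentricity < 0.15
        assert shape.circularity > 0.85

    def test_noiseless_rod_is_elongated_with_the_right_length(self):
        truth = ShapeGroundTruth(kind="rod", length_nm=400.0,
                                 n_localizations=500, precision_nm=0.0, seed=7)
        shape = shape_metrics(gen_localizations(truth))
        assert shape.eccentricity > 0.9
        assert shape.length_nm == pytest.approx(400.0, rel=0.05)
        assert shape.degenerate  # perfectly collinear points
        assert np.isnan(shape.circularity)

    def test_blurred_rod_length_within_a_quarter(self):
        truth = ShapeGroundTruth(kind="rod", length_nm=200.0,
                                 n_localizations=500, precision_nm=20.0, seed=3)
        shape = shape_metrics(gen_localizations(truth))
        assert shape.length_nm == pytest.approx(200.0, rel=0.25)

    def test_isotropic_cloud_has_low_eccentricity(self):
        eccs = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            xy = rng.normal(0.0, 50.0, size=(1000, 2))
            eccs.append(shape_metrics(xy).eccentricity)
        assert np.median(eccs) < 0.2

    def test_rotation_invariance_within_two_percent(self):
        truth = ShapeGroundTruth(kind="rod", length_nm=300.0,
                                 n_localizations=400, precision_nm=15.0, seed=11)
        xy = gen_localizations(truth).xy()
        base = shape_metrics(xy)
        rng = np.random.default_rng(1)
        for _ in range(5):
            th = rng.uniform(0, 2 * np.pi)
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            s = shape_metrics(xy @ rot.T)
            assert s.length_nm == pytest.approx(base.length_nm, rel=0.02)
            assert s.eccentricity == pytest.approx(base.eccentricity, rel=0.02)
            assert s.circularity == pytest.approx(base.circularity, rel=0.02)

    def test_raster_fallback_agrees_qualitatively(self):
        truth = ShapeGroundTruth(kind="disc", diameter_nm=300.0,
                                 n_localizations=800, precision_nm=5.0, seed=13)
        tab = gen_localizations(truth)
        hull = shape_metrics(tab, method="hull")
        raster = shape_metrics(tab, method="raster", render_nm=10.0)
        assert raster.length_nm == pytest.approx(hull.length_nm, rel=0.2)
        assert raster.eccentricity < 0.3

    def test_too_small_cluster_rejected(self):
        with pytest.raises(InvalidInputError):
            shape_metrics(np.zeros((5, 2)))
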