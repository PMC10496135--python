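import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seb3r import (
    ClusteringConfig,
    TrackingSession,
    concat_sessions,
    elbow_kmeans,
    extract_postures,
    pairwise_z_differences,
)
from seb3r.errors import Seb3rError
from seb3r.posture_extraction import PAIR_INDEX, summarize_postures


class TestConcatSessions:
    def test_stacks_in_order_with_origins(self):
        s1 = TrackingSession("m", "s1", np.ones((100, 6)))
        s2 = TrackingSession("m", "s2", np.zeros((50, 6)))
        z, mask, origin = concat_sessions([s1, s2])
        assert z.shape == (150, 6)
        assert origin[0] == ("s1", 1) and origin[99] == ("s1", 100)
        assert origin[100] == ("s2", 1) and origin[-1] == ("s2", 50)

    def test_single_session_identity(self):
        s = TrackingSession("m", "s1", np.arange(12.0).reshape(2, 6))
        z, _, origin = concat_sessions([s])
        np.testing.assert_array_equal(z, s.z)
        assert origin == [("s1", 1), ("s1", 2)]

    def test_subject_mismatch_errors(self):
        a = TrackingSession("a", "s1", np.ones((2, 6)))
        b = TrackingSession("b", "s1", np.ones((2, 6)))
        with pytest.raises(Seb3rError, match="different subjects"):
            concat_sessions([a, b])


class TestPairwiseZDifferences:
    def test_fifteen_columns(self, rng):
        f = pairwise_z_differences(rng.normal(size=(37, 6)))
        assert f.values.shape == (37, 15)

    def test_all_equal_heights_give_zeros(self):
        f = pairwise_z_differences(np.zeros((1, 6)))
        np.testing.assert_array_equal(f.values, np.zeros((1, 15)))

    def test_staircase_frame_matches_enumeration(self):
        # independent brute force over all i<j pairs of (5,4,3,2,1,0)
        z = np.array([[5.0, 4.0, 3.0, 2.0, 1.0, 0.0]])
        expected = [
            z[0, i] - z[0, j] for i in range(6) for j in range(i + 1, 6)
        ]
        assert expected == [1, 2, 3, 4, 5, 1, 2, 3, 4, 1, 2, 3, 1, 2, 1]
        f = pairwise_z_differences(z)
        np.testing.assert_array_equal(f.values[0], expected)

    def test_wrong_column_count(self):
        with pytest.raises(Seb3rError):
            pairwise_z_differences(np.zeros((3, 5)))

    def test_absolute_mode(self):
        z = np.array([[0.0, 1.0, 0, 0, 0, 0]])
        f = pairwise_z_differences(z, absolute=True)
        assert (f.values >= 0).all()
        assert f.values[0, 0] == 1.0

    @given(st.integers(0, 5), st.integers(0, 5), st.data())
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_swapping_hotspots_negates_their_column(self, a, b, data):
        """Antisymmetry: exchanging two hotspots negates the (a, b) feature."""
        if a == b:
            return
        i, j = min(a, b), max(a, b)
        z = np.array(
            [data.draw(st.lists(st.floats(-10, 10), min_size=6, max_size=6))]
        )
        zs = z.copy()
        zs[0, [i, j]] = zs[0, [j, i]]
        col = PAIR_INDEX.index((i, j))
        f1 = pairwise_z_differences(z)
        f2 = pairwise_z_differences(zs)
        assert f2.values[0, col] == pytest.approx(-f1.values[0, col], abs=1e-12)

    def test_additive_offset_cancels(self, rng):
        """Two animals differing only by body size give identical features."""
        z = rng.normal(size=(40, 6))
        f1 = pairwise_z_differences(z)
        f2 = pairwise_z_differences(z + 3.7)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)


def _planted_clusters(rng, centers, n_per, sd):
    rows = []
    labels = []
    for c_idx, c in enumerate(centers):
        rows.append(c + rng.normal(0, sd, size=(n_per, centers.shape[1])))
        labels += [c_idx] * n_per
    return np.vstack(rows), np.array(labels)


class TestElbowKmeans:
    def test_identical_rows_k1(self, cluster_config):
        x = np.tile(np.arange(15.0), (10, 1))
        labels, k, wcss = elbow_kmeans(x, cluster_config)
        assert k == 1 and wcss[0] == 0.0
        assert (labels == 1).all()

    def test_single_row(self, cluster_config):
        labels, k, _ = elbow_kmeans(np.zeros((1, 15)), cluster_config)
        assert k == 1 and labels.tolist() == [1]

    def test_three_planted_clusters_recovered(self, rng, cluster_config):
        centers = rng.normal(size=(3, 15)) * 100
        x, planted = _planted_clusters(rng, centers, n_per=100, sd=1.0)
        labels, k, wcss = elbow_kmeans(x, cluster_config)
        assert k == 3
        # partition equality up to relabeling
        mapping = {}
        for lab, true in zip(labels, planted):
            mapping.setdefault(lab, true)
            assert mapping[lab] == true
        assert len(mapping) == 3

    def test_missing_frames_labeled_zero(self, rng, cluster_config):
        centers = rng.normal(size=(2, 15)) * 100
        x, _ = _planted_clusters(rng, centers, n_per=20, sd=0.5)
        x[5] = np.nan
        labels, k, _ = elbow_kmeans(x, cluster_config)
        assert labels[5] == 0
        assert (labels[np.arange(len(labels)) != 5] > 0).all()

    def test_all_missing_errors(self, cluster_config):
        with pytest.raises(Seb3rError):
            elbow_kmeans(np.full((4, 15), np.nan), cluster_config)

    def test_deterministic_under_seed(self, rng):
        x = rng.normal(size=(120, 15))
        cfg = ClusteringConfig(seed=99, variance_cutoff=0.6)
        out1 = elbow_kmeans(x, cfg)
        out2 = elbow_kmeans(x, cfg)
        np.testing.assert_array_equal(out1[0], out2[0])
        assert out1[1] == out2[1]
        np.testing.assert_array_equal(out1[2], out2[2])

    def test_wcss_non_increasing_and_v_bounds(self, rng, cluster_config):
        centers = rng.normal(size=(4, 15)) * 50
        x, _ = _planted_clusters(rng, centers, n_per=50, sd=2.0)
        _, _, wcss = elbow_kmeans(x, cluster_config, full_curve=True)
        assert (np.diff(wcss) <= wcss[0] * 1e-9).all()
        v = 1 - wcss / wcss[0]
        assert v[0] == 0.0
        assert ((v >= -1e-12) & (v <= 1 + 1e-12)).all()

    def test_labels_ordered_by_descending_count(self, rng, cluster_config):
        centers = rng.normal(size=(2, 15)) * 100
        x = np.vstack(
            [
                centers[0] + rng.normal(0, 0.1, size=(30, 15)),
                centers[1] + rng.normal(0, 0.1, size=(10, 15)),
            ]
        )
        labels, k, _ = elbow_kmeans(x, cluster_config)
        assert k == 2
        assert (labels[:30] == 1).all() and (labels[30:] == 2).all()


class TestExtractPostures:
    def test_centroids_are_member_means(self, rng, cluster_config):
        z = np.vstack(
            [
                rng.normal(0, 0.2, size=(50, 6)) + np.arange(6) * 10,
                rng.normal(0, 0.2, size=(50, 6)) + np.arange(6)[::-1] * 10,
            ]
        )
        s = TrackingSession("m", "s1", z)
        summary, clustered, features = extract_postures([s], cluster_config)
        labels = np.concatenate([c.postures for c in clustered])
        for pid, centroid in zip(summary.posture_ids, summary.centroids):
            member_mean = features.values[labels == pid].mean(axis=0)
            np.testing.assert_allclose(centroid, member_mean, rtol=1e-9)

    def test_counts_sum_to_nonmissing(self, rng, cluster_config):
        z = rng.normal(size=(60, 6))
        z[3] = np.nan
        s = TrackingSession("m", "s1", z)
        summary, _, _ = extract_postures([s], ClusteringConfig(seed=1, variance_cutoff=0.5))
        assert summary.counts.sum() == 59

    def test_output_files_row_counts(self, tmp_path, rng, cluster_config):
        from seb3r import io_dlc

        centers = rng.normal(size=(3, 6)) * 40
        z = np.vstack([c + rng.normal(0, 0.3, size=(40, 6)) for c in centers])
        s = TrackingSession("156", "OF", z)
        summary, _, _ = extract_postures(
            [s],
            cluster_config,
            subject_dir=tmp_path / "156",
            mean_distances_dir=tmp_path / "Mean Distances",
        )
        sid, centroids, pids = io_dlc.read_mean_distances(
            tmp_path / "Mean Distances" / "Mouse156DistMean.csv"
        )
        assert centroids.shape[0] == summary.n_postures
        sid, z2, postures = io_dlc.read_clustered(
            tmp_path / "156" / "Clustered_OF.csv"
        )
        assert len(postures) == 120


def test_summarize_postures_requires_assigned_frames():
    from seb3r.posture_extraction import DistanceFeatureMatrix

    f = DistanceFeatureMatrix(values=np.zeros((3, 15)))
    with pytest.raises(Seb3rError):
        summarize_postures("m", f, np.zeros(3, dtype=int))
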