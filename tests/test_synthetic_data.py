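import numpy as np
import pytest

from seb3r import (
    SimulationConfig,
    default_archetypes,
    discover_layout,
    feature_separation,
    pairwise_z_differences,
    simulate_cohort,
    simulate_subject,
)
from seb3r.errors import Seb3rError
from seb3r.synthetic_data import ArchetypeSet


class TestArchetypes:
    def test_rows_distinct_and_named(self):
        a = default_archetypes(9)
        assert a.n_archetypes == 9
        assert len(set(a.names)) == 9

    def test_duplicate_rows_rejected(self):
        with pytest.raises(Seb3rError):
            ArchetypeSet(archetypes=np.ones((2, 6)))

    def test_separation_scales_linearly(self):
        s1 = feature_separation(default_archetypes(9, scale=1.0))
        s2 = feature_separation(default_archetypes(9, scale=2.0))
        assert s2 == pytest.approx(2 * s1)

    def test_default_separation_well_clear_of_noise(self):
        """Min archetype separation is ~10x the within-cluster spread at the
        default tracking noise (the planted clusters are unambiguous)."""
        sep = feature_separation(default_archetypes(9))
        noise = SimulationConfig().noise_sd
        within_rms = np.sqrt(15 * 2 * noise**2)
        assert sep >= 10 * within_rms


class TestSimulateSubject:
    def test_deterministic_under_seed(self):
        a = default_archetypes(4)
        cfg = SimulationConfig(n_subjects=1, n_sessions=2, frames_per_session=200,
                               min_expressed=3, seed=5)
        s1, t1 = simulate_subject(a, cfg, "x", np.random.default_rng(5))
        s2, t2 = simulate_subject(a, cfg, "x", np.random.default_rng(5))
        for a_, b_ in zip(s1, s2):
            np.testing.assert_array_equal(a_.z, b_.z)
        for a_, b_ in zip(t1, t2):
            np.testing.assert_array_equal(a_, b_)

    def test_noiseless_limit_reproduces_archetypes(self):
        a = default_archetypes(3)
        cfg = SimulationConfig(
            n_subjects=1, n_sessions=1, frames_per_session=300,
            noise_sd=0.0, offset_sd=0.0, missing_prob=0.0, min_expressed=3,
        )
        sessions, truth = simulate_subject(a, cfg, "x", np.random.default_rng(0))
        expected = a.archetypes[truth[0] - 1]
        np.testing.assert_allclose(sessions[0].z, expected)

    def test_min_expressed_exceeding_archetypes(self):
        a = default_archetypes(3)
        cfg = SimulationConfig(min_expressed=4)
        with pytest.raises(Seb3rError):
            simulate_subject(a, cfg, "x", np.random.default_rng(0))

    def test_dwell_mean_matches_geometric_law(self):
        """Empirical mean bout length over >= 1e4 bouts within 5% of target."""
        from seb3r.bout_metrics import run_length_encode

        a = default_archetypes(5)
        cfg = SimulationConfig(
            n_subjects=1, n_sessions=1, frames_per_session=120_000,
            mean_bout_frames=10.0, noise_sd=0.0, missing_prob=0.0,
            min_expressed=5, seed=11,
        )
        _, truth = simulate_subject(a, cfg, "x", np.random.default_rng(11))
        table = run_length_encode(truth[0])
        lengths = [b.length_frames for b in table.bouts[:-1]]  # last is censored
        assert len(lengths) >= 10_000
        mean = np.mean(lengths)
        assert abs(mean - 10.0) / 10.0 < 0.05

    def test_offset_cancels_in_features(self):
        """Subjects differing only by body size have identical feature rows."""
        a = default_archetypes(4)
        base = dict(n_subjects=1, n_sessions=1, frames_per_session=400,
                    noise_sd=0.0, missing_prob=0.0, min_expressed=4, seed=3)
        small = SimulationConfig(offset_sd=0.0, **base)
        big = SimulationConfig(offset_sd=5.0, **base)
        s_small, _ = simulate_subject(a, small, "x", np.random.default_rng(3))
        s_big, _ = simulate_subject(a, big, "x", np.random.default_rng(3))
        f_small = pairwise_z_differences(s_small[0].z)
        f_big = pairwise_z_differences(s_big[0].z)
        np.testing.assert_allclose(f_small.values, f_big.values, atol=1e-12)


class TestSimulateCohort:
    def test_layout_round_trip(self, small_cohort):
        root, truth, archetypes, config = small_cohort
        layout = discover_layout(root)
        assert len(layout.subjects) == config.n_subjects
        assert layout.n_sessions == config.n_sessions

    def test_ground_truth_alongside_not_inside(self, small_cohort):
        root, truth, _, config = small_cohort
        assert (root / "ground_truth").is_dir()
        layout = discover_layout(root)
        for paths in layout.subjects.values():
            assert all("truth" not in p.name for p in paths)

    def test_missing_fraction_binomial(self, tmp_path):
        a = default_archetypes(3)
        cfg = SimulationConfig(
            n_subjects=2, n_sessions=2, frames_per_session=5000,
            missing_prob=0.01, min_expressed=3, seed=21,
        )
        from seb3r import load_cohort

        simulate_cohort(a, cfg, tmp_path / "c")
        sessions = load_cohort(discover_layout(tmp_path / "c"))
        n = sum(s.n_frames for ss in sessions.values() for s in ss)
        miss = sum(int(s.missing_mask.sum()) for ss in sessions.values() for s in ss)
        se = np.sqrt(0.01 * 0.99 / n)
        assert abs(miss / n - 0.01) <= 3 * se

    def test_refuses_nonempty_target(self, tmp_path):
        a = default_archetypes(2)
        cfg = SimulationConfig(n_subjects=1, n_sessions=1, frames_per_session=10,
                               min_expressed=2, seed=1)
        (tmp_path / "d").mkdir()
        (tmp_path / "d" / "junk.txt").write_text("x")
        with pytest.raises(Seb3rError, match="force"):
            simulate_cohort(a, cfg, tmp_path / "d")
        simulate_cohort(a, cfg, tmp_path / "d", force=True)  # no raise

    def test_bit_identical_under_seed(self, tmp_path):
        a = default_archetypes(3)
        cfg = SimulationConfig(n_subjects=2, n_sessions=1, frames_per_session=100,
                               min_expressed=3, seed=9)
        simulate_cohort(a, cfg, tmp_path / "one")
        simulate_cohort(a, cfg, tmp_path / "two")
        f1 = sorted((tmp_path / "one").rglob("*.csv"))
        f2 = sorted((tmp_path / "two").rglob("*.csv"))
        assert [p.name for p in f1] == [p.name for p in f2]
        for p1, p2 in zip(f1, f2):
            assert p1.read_text() == p2.read_text()
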