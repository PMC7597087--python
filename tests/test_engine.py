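"""Engine semantics: attacks, synchronous steps, convergence, win sources."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bandgrowcut import (
    EngineConfig,
    GrowCut,
    NeighbourhoodSpec,
    SeedMap,
    run,
    segment_3d,
    step,
)
from bandgrowcut.engine import (
    AutomatonState,
    attack_matrix,
    attack_strength,
    classify_win,
    g_default,
)
from bandgrowcut.fixtures import disconnected_scene, worked_example
from bandgrowcut.seeding import BACKGROUND_LABEL, FOREGROUND_LABEL


class TestAttenuation:
    @pytest.mark.parametrize(
        "x, expected", [(0.0, 1.0), (0.9, 0.1), (1.0, 0.0), (0.5, 0.5)]
    )
    def test_values(self, x, expected):
        assert g_default(x, 1.0) == pytest.approx(expected)

    def test_domain_error_beyond_max_diff(self):
        with pytest.raises(ValueError):
            g_default(1.5, 1.0)

    @given(st.floats(0, 1), st.floats(0, 1))
    @settings(max_examples=50, deadline=None)
    def test_non_increasing(self, x, y):
        lo, hi = sorted((x, y))
        assert g_default(lo) >= g_default(hi)


class TestWorkedExample:
    """The four-pixel automaton, checked against its published evolution."""

    def test_attack_matrices_entry_for_entry(self):
        ex = worked_example()
        state = AutomatonState.from_seeds(ex.image, ex.seeds)
        np.testing.assert_allclose(
            attack_matrix(state), ex.attack_matrix_iter1, atol=1e-12
        )
        state2, _, captures = step(state, EngineConfig())
        assert captures == 2
        np.testing.assert_allclose(
            attack_matrix(state2), ex.attack_matrix_iter2, atol=1e-12
        )

    def test_state_after_first_iteration(self):
        ex = worked_example()
        state = AutomatonState.from_seeds(ex.image, ex.seeds)
        np.testing.assert_allclose(state.strength, ex.initial_strengths)
        state2, _, _ = step(state, EngineConfig())
        np.testing.assert_allclose(state2.strength, ex.strengths_after_iter1)
        np.testing.assert_array_equal(state2.labels, ex.labels_after_iter1)

    def test_convergence_and_mislabeling(self):
        ex = worked_example()
        res = GrowCut(ex.image, ex.seeds).fit()
        assert res.converged
        assert res.iterations_used == ex.convergence_iteration
        # B and C end up mislabelled relative to intensity-defined truth
        np.testing.assert_array_equal(res.labels, ex.labels_after_iter1)
        seg = res.foreground_mask().astype(int)
        assert seg[0, 1] == 0 and ex.gt[0, 1] == 1
        assert seg[0, 2] == 1 and ex.gt[0, 2] == 0

    def test_second_step_has_no_successful_attacks(self):
        ex = worked_example()
        state = AutomatonState.from_seeds(ex.image, ex.seeds)
        state2, _, _ = step(state, EngineConfig())
        _, _, captures = step(state2, EngineConfig())
        assert captures == 0

    def test_attack_strength_examples(self):
        ex = worked_example()
        state = AutomatonState.from_seeds(ex.image, ex.seeds)
        assert attack_strength((0, 0), (0, 1), state) == pytest.approx(0.1)
        # unlabelled attacker has zero strength, never captures
        assert attack_strength((0, 1), (0, 0), state) == 0.0
        state2, _, _ = step(state, EngineConfig())
        assert attack_strength((0, 1), (0, 0), state2) == pytest.approx(0.01)


class TestClassifyWin:
    @pytest.mark.parametrize(
        "local, remote, defense, expected",
        [
            (0.5, None, 0.2, "local"),
            (None, 0.5, 0.2, "remote"),
            (0.4, 0.6, 0.3, "override"),
            (0.6, 0.4, 0.3, "local"),
            (0.5, 0.5, 0.3, "local"),  # ties go to the local neighbour
            (0.1, 0.1, 0.5, "none"),
            (None, None, 0.0, "none"),
        ],
    )
    def test_classification(self, local, remote, defense, expected):
        assert classify_win(local, remote, defense) == expected


class TestRun:
    def test_fully_seeded_image_converges_immediately(self):
        image = np.full((5, 5), 0.5)
        coords = np.array(list(np.ndindex(5, 5)))
        seeds = SeedMap(coords, np.ones(25, dtype=int))
        res = run(image, seeds, EngineConfig())
        assert res.converged and res.iterations_used == 1
        assert res.win_stats.total_wins == 0

    def test_no_seeds_means_no_captures(self):
        image = np.random.default_rng(0).random((4, 4))
        seeds = SeedMap(np.empty((0, 2), int), np.empty(0, int))
        res = run(image, seeds, EngineConfig())
        assert res.converged and res.win_stats.total_wins == 0
        assert (res.labels == 0).all()

    def test_determinism_bit_identical(self):
        image, gt, seeds = disconnected_scene()
        cfg = EngineConfig(NeighbourhoodSpec(remote_band=(2, 6)), seed=42)
        a = run(image, seeds, cfg)
        b = run(image, seeds, cfg)
        np.testing.assert_array_equal(a.labels, b.labels)
        assert a.win_stats.as_dict() == b.win_stats.as_dict()
        assert a.iterations_used == b.iterations_used

    def test_shape_mismatch_and_bad_labels_rejected(self):
        image = np.zeros((4, 4))
        with pytest.raises(ValueError):
            run(image, SeedMap(np.array([[0, 0, 0]]), np.array([1])))
        with pytest.raises(ValueError):
            run(image, SeedMap(np.array([[9, 9]]), np.array([1])))
        with pytest.raises(ValueError):
            SeedMap(np.array([[0, 0]]), np.array([0]))

    def test_strengths_stay_in_unit_interval(self):
        rng = np.random.default_rng(3)
        image = rng.random((8, 8))
        seeds = SeedMap(np.array([[0, 0], [7, 7]]), np.array([1, 2]))
        state = AutomatonState.from_seeds(image, seeds)
        cfg = EngineConfig(NeighbourhoodSpec(remote_band=(2, 4), k=3), seed=0)
        g = np.random.default_rng(0)
        for _ in range(15):
            state, _, _ = step(state, cfg, g)
            assert state.strength.min() >= 0.0
            assert state.strength.max() <= 1.0

    def test_classical_runs_are_all_local_wins(self):
        image, gt, seeds = disconnected_scene()
        res = run(image, seeds, EngineConfig())
        assert res.win_stats.total_wins > 0
        assert res.win_stats.remote_wins == 0
        assert res.win_stats.remote_overrides == 0
        assert res.win_stats.local_fraction == 1.0

    def test_converged_state_is_fixed_point_of_classical_step(self):
        image, gt, seeds = disconnected_scene()
        res = run(image, seeds, EngineConfig())
        assert res.converged
        state = AutomatonState.from_seeds(image, seeds)
        for _ in range(res.iterations_used):
            state, _, _ = step(state, EngineConfig())
        again, _, captures = step(state, EngineConfig())
        assert captures == 0
        np.testing.assert_array_equal(again.labels, state.labels)

    def test_summary_mentions_convergence_and_wins(self):
        ex = worked_example()
        res = GrowCut(ex.image, ex.seeds).fit()
        text = res.summary()
        assert "converged" in text and "local wins" in text


class TestDisconnectedRescue:
    """A remote band can bridge a background gap; classical GrowCut cannot."""

    def seedless_mask(self):
        image, gt, seeds = disconnected_scene()
        mask = np.zeros_like(gt, bool)
        mask[14:26, 21:33] = True
        return image, gt, seeds, mask

    def test_classical_labels_seedless_component_background(self):
        image, gt, seeds, mask = self.seedless_mask()
        res = run(image, seeds, EngineConfig())
        assert (res.labels[mask] == FOREGROUND_LABEL).mean() == 0.0

    def test_bridging_band_rescues_majority(self):
        image, gt, seeds, mask = self.seedless_mask()
        cfg = NeighbourhoodSpec(remote_band=(2, 6))
        rescued = 0
        for s in range(10):
            res = run(image, seeds, EngineConfig(cfg, seed=s))
            rescued += (res.labels[mask] == FOREGROUND_LABEL).mean() > 0.5
        assert rescued >= 9

    def test_non_bridging_band_matches_classical_here(self):
        image, gt, seeds, mask = self.seedless_mask()
        res = run(image, seeds, EngineConfig(NeighbourhoodSpec(remote_band=(2, 4))))
        assert (res.labels[mask] == FOREGROUND_LABEL).mean() == 0.0


class TestThreeD:
    def make_volume(self, n_slices=4):
        image, gt, seeds2d = disconnected_scene()
        volume = np.repeat(image[None], n_slices, axis=0)
        coords3 = np.hstack(
            [
                np.repeat(np.arange(n_slices), len(seeds2d))[:, None],
                np.tile(seeds2d.coords, (n_slices, 1)),
            ]
        )
        labels3 = np.tile(seeds2d.labels, n_slices)
        return volume, SeedMap(coords3, labels3), seeds2d, image

    def test_stitch_of_identical_slices_matches_2d(self):
        volume, seeds3, seeds2d, image = self.make_volume()
        res3 = segment_3d(volume, seeds3, EngineConfig(), mode="stitch")
        res2 = run(image, seeds2d, EngineConfig())
        for z in range(volume.shape[0]):
            np.testing.assert_array_equal(res3.labels[z], res2.labels)

    def test_full_mode_interior_voxel_has_26_neighbours(self):
        from bandgrowcut.neighbourhoods import enumerate_moore

        assert len(enumerate_moore((4, 4, 4), 1, (9, 9, 9))) == 26

    def test_classical_stitch_and_full_agree_on_axis_uniform_volume(self):
        rng = np.random.default_rng(5)
        base = rng.random((8, 8))
        volume = np.repeat(base[None], 4, axis=0)
        seeds2d = SeedMap(np.array([[0, 0], [7, 7]]), np.array([1, 2]))
        coords3 = np.hstack(
            [
                np.repeat(np.arange(4), 2)[:, None],
                np.tile(seeds2d.coords, (4, 1)),
            ]
        )
        seeds3 = SeedMap(coords3, np.tile(seeds2d.labels, 4))
        stitch = segment_3d(volume, seeds3, EngineConfig(), mode="stitch")
        full = segment_3d(volume, seeds3, EngineConfig(), mode="full")
        np.testing.assert_array_equal(stitch.labels, full.labels)

    def test_unseeded_slice_left_unlabelled_with_warning(self):
        volume, seeds3, _, _ = self.make_volume()
        keep = seeds3.coords[:, 0] != 2
        partial = SeedMap(seeds3.coords[keep], seeds3.labels[keep])
        with pytest.warns(UserWarning, match="slice 2"):
            res = segment_3d(volume, partial, EngineConfig(), mode="stitch")
        assert (res.labels[2] == 0).all()
        assert (res.labels[1] != 0).any()
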