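"""Simulator unit and property tests: placement, actions, rendering, sets."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chisquare

from numerosense import scenes
from numerosense.scenes import (ActionKind, InvalidActionError, PlacementError,
                                SceneState)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestPlacement:
    def test_regime_a_object_is_fixed_size_full_contrast(self, rng):
        cfg = scenes.regime_a()
        obj = scenes.place_object(SceneState(), cfg, rng)
        assert obj.size == 15.0
        assert obj.contrast == 1.0

    def test_regime_b_draws_cover_stated_ranges(self, rng):
        cfg = scenes.regime_b()
        sizes, contrasts = [], []
        state = SceneState()
        for _ in range(10_000):
            o = scenes.place_object(state, cfg, rng)
            sizes.append(o.size)
            contrasts.append(o.contrast)
        assert 10.0 <= min(sizes) and max(sizes) <= 30.0
        assert 0.098 <= min(contrasts) and max(contrasts) <= 1.0
        # draws actually span the ranges, not a sliver of them
        assert min(sizes) < 10.5 and max(sizes) > 29.5
        assert min(contrasts) < 0.12 and max(contrasts) > 0.98

    def test_objects_stay_inside_bounds(self, rng):
        cfg = scenes.regime_b()
        state = SceneState()
        for _ in range(200):
            o = scenes.place_object(state, cfg, rng)
            assert o.center_x - o.size / 2 >= 0
            assert o.center_x + o.size / 2 <= cfg.image_size
            assert o.center_y - o.size / 2 >= 0

    def test_overfull_scene_raises_placement_error(self, rng):
        cfg = scenes.SceneConfig(image_size=40, margin=3.0, regime="A",
                                 size_range=(15.0, 15.0), contrast_range=(1.0, 1.0),
                                 retry_cap=200)
        state = SceneState()
        with pytest.raises(PlacementError):
            for _ in range(31):
                obj = scenes.place_object(state, cfg, rng)
                state = SceneState(state.objects + (obj,))

    def test_uniform_placement_chi_square(self, rng):
        """Single-object centers are uniform over the admissible band."""
        cfg = scenes.regime_a()
        half = 7.5
        lo, hi = half, cfg.image_size - half
        xs = np.array([scenes.place_object(SceneState(), cfg, rng).center_x
                       for _ in range(10_000)])
        counts, _ = np.histogram(xs, bins=10, range=(lo, hi))
        assert chisquare(counts).pvalue > 0.01


class TestActions:
    def test_put_take_shake_count_deltas(self, rng):
        cfg = scenes.desk_config("A")
        state = scenes.apply_action(SceneState(), ActionKind.PUT, cfg, rng)
        assert state.count == 1
        state3 = SceneState(state.objects)
        for _ in range(2):
            state3 = scenes.apply_action(state3, ActionKind.PUT, cfg, rng)
        assert state3.count == 3
        assert scenes.apply_action(state3, ActionKind.SHAKE, cfg, rng).count == 3
        assert scenes.apply_action(state3, ActionKind.TAKE, cfg, rng).count == 2

    def test_take_on_empty_scene_is_invalid(self, rng):
        cfg = scenes.desk_config("A")
        with pytest.raises(InvalidActionError):
            scenes.apply_action(SceneState(), ActionKind.TAKE, cfg, rng)

    def test_shake_moves_objects_but_keeps_appearance(self, rng):
        cfg = scenes.regime_b()
        state = SceneState()
        for _ in range(3):
            state = scenes.apply_action(state, ActionKind.PUT, cfg, rng)
        shaken = scenes.apply_action(state, ActionKind.SHAKE, cfg, rng)
        assert shaken.count == 3
        assert sorted(o.size for o in shaken.objects) == \
            sorted(o.size for o in state.objects)
        assert sorted(o.contrast for o in shaken.objects) == \
            sorted(o.contrast for o in state.objects)
        before = {(o.center_x, o.center_y) for o in state.objects}
        after = {(o.center_x, o.center_y) for o in shaken.objects}
        assert before != after

    def test_clearance_invariant_over_many_random_states(self, rng):
        cfg = scenes.desk_config("A")
        for _ in range(1000):
            state = SceneState()
            for _ in range(int(rng.integers(2, 7))):
                obj = scenes.place_object(state, cfg, rng)
                state = SceneState(state.objects + (obj,))
            assert state.min_gap() >= cfg.margin - 1e-9

    @pytest.mark.parametrize("count,expected", [
        (0, {ActionKind.PUT, ActionKind.SHAKE}),
        (3, {ActionKind.TAKE, ActionKind.SHAKE}),
        (2, {ActionKind.PUT, ActionKind.TAKE, ActionKind.SHAKE}),
    ])
    def test_valid_action_support_and_uniformity(self, rng, count, expected):
        cfg = scenes.desk_config("A", max_objects=3)
        state = SceneState()
        for _ in range(count):
            obj = scenes.place_object(state, cfg, rng)
            state = SceneState(state.objects + (obj,))
        draws = [scenes.sample_valid_action(state, cfg, rng) for _ in range(10_000)]
        observed = {a: draws.count(a) for a in set(draws)}
        assert set(observed) == expected
        assert chisquare(list(observed.values())).pvalue > 0.01

    def test_imprecise_actions_change_count_by_multiplicity(self, rng):
        cfg = scenes.desk_config("A", max_objects=8, multiplicity_choices=(1, 2, 3))
        deltas = set()
        for _ in range(200):
            state = scenes.apply_action(SceneState(), ActionKind.PUT, cfg, rng)
            deltas.add(state.count)
        assert deltas == {1, 2, 3}


class TestRender:
    def test_empty_scene_renders_all_zero(self):
        cfg = scenes.regime_a()
        img = scenes.render(SceneState(), cfg)
        assert img.shape == (244, 244)
        assert not img.any()

    def test_single_square_covers_exactly_size_squared_pixels(self, rng):
        cfg = scenes.regime_a()
        for _ in range(20):
            obj = scenes.place_object(SceneState(), cfg, rng)
            img = scenes.render(SceneState((obj,)), cfg)
            assert (img > 0).sum() == 15 * 15
            assert img.max() == 1.0

    def test_render_is_additive_for_disjoint_squares(self, rng):
        cfg = scenes.desk_config("A")
        state = SceneState()
        for _ in range(2):
            obj = scenes.place_object(state, cfg, rng)
            state = SceneState(state.objects + (obj,))
        total = scenes.render(state, cfg)
        parts = sum(scenes.render(SceneState((o,)), cfg) for o in state.objects)
        np.testing.assert_array_equal(total, parts)

    @settings(max_examples=50, derandomize=True)
    @given(size=st.integers(4, 30),
           fx=st.floats(0, 1, allow_nan=False), fy=st.floats(0, 1, allow_nan=False),
           contrast=st.floats(0.098, 1.0, allow_nan=False))
    def test_integer_square_always_covers_size_squared_pixels(self, size, fx, fy,
                                                              contrast):
        """The half-open pixel-center rule makes coverage independent of
        sub-pixel position for integer sizes."""
        cfg = scenes.SceneConfig(image_size=64, regime="B", size_range=(4.0, 30.0),
                                 contrast_range=(0.098, 1.0))
        cx = size / 2 + fx * (64 - size)
        cy = size / 2 + fy * (64 - size)
        obj = scenes.SceneObject(cx, cy, float(size), contrast)
        img = scenes.render(scenes.SceneState((obj,)), cfg)
        assert (img > 0).sum() == size * size
        assert img.max() == np.float32(contrast)

    def test_intensity_positive_iff_nonempty(self, rng):
        cfg = scenes.desk_config("B")
        assert scenes.render(SceneState(), cfg).sum() == 0
        obj = scenes.place_object(SceneState(), cfg, rng)
        assert scenes.render(SceneState((obj,)), cfg).sum() > 0


class TestSequences:
    def test_sequence_length_chaining_and_count_replay(self, rng):
        cfg = scenes.desk_config("A")
        records = scenes.generate_training_sequence(cfg, 180, rng)
        assert len(records) == 180
        assert records[0].state_before.count == 0
        count = 0
        for prev, nxt in zip(records, records[1:]):
            assert nxt.state_before is prev.state_after
            assert nxt.image_before is prev.image_after
        for r in records:
            delta = {ActionKind.PUT: 1, ActionKind.TAKE: -1, ActionKind.SHAKE: 0}[r.action]
            count += delta
            assert r.state_after.count == count
            assert 0 <= count <= cfg.max_objects

    def test_identical_seeds_reproduce_sequences_bitwise(self):
        cfg = scenes.desk_config("B")
        a = scenes.generate_training_sequence(cfg, 50, np.random.default_rng(7))
        b = scenes.generate_training_sequence(cfg, 50, np.random.default_rng(7))
        assert [r.action for r in a] == [r.action for r in b]
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.image_after, rb.image_after)


class TestBalancedSets:
    def test_exact_balance_and_correct_labels(self, rng):
        cfg = scenes.desk_config("A")
        out = scenes.generate_balanced_test_set(cfg, [0, 3, 7, 12], 25, rng)
        assert len(out) == 100
        for c in (0, 3, 7, 12):
            assert (out.counts == c).sum() == 25
        for img, c, state in zip(out.images, out.counts, out.states):
            assert state.count == c
            assert (img.sum() > 0) == (c > 0)

    def test_intensity_covariate_regimes(self, rng):
        cfg_a = scenes.desk_config("A")
        rep_a = scenes.intensity_covariate_report(
            scenes.generate_balanced_test_set(cfg_a, range(9), 30, rng))
        assert rep_a.spearman_rho == pytest.approx(1.0)
        assert rep_a.table.loc[0, "mean"] == 0.0
        # regime B: adjacent-count intensity distributions overlap
        cfg_b = scenes.desk_config("B")
        rep_b = scenes.intensity_covariate_report(
            scenes.generate_balanced_test_set(cfg_b, range(1, 9), 50, rng))
        t = rep_b.table
        overlaps = [(t.loc[c, "max"] > t.loc[c + 1, "min"]) for c in range(1, 8)]
        assert all(overlaps)


class TestDiskFormat:
    def test_sequence_roundtrip(self, rng, tmp_path):
        cfg = scenes.desk_config("B")
        records = scenes.generate_training_sequence(cfg, 12, rng)
        scenes.save_sequence(records, tmp_path / "seq")
        loaded = scenes.load_sequence_images(tmp_path / "seq")
        original = scenes.records_image_set(records)
        assert len(loaded) == 13
        np.testing.assert_array_equal(loaded.counts, original.counts)
        # 8-bit quantization error only
        assert np.abs(loaded.images - original.images).max() <= 1 / 255 + 1e-6
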