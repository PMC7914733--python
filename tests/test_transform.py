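"""Walker-local transformation: sparsify, track, rotate, resample, unroll."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import gaitfloor as gf
from gaitfloor.transform import preprocess_sparse_series, track


def sparse(positions, c, threshold=0.03):
    return gf.SparseState(np.asarray(positions, float), np.asarray(c, float), threshold)


class TestSparsify:
    def test_strict_threshold(self, small_layout):
        s = gf.init_state(small_layout)
        c = np.array([0.02, 0.03, 0.5, 0, 0, 0, 0, 0])
        s = gf.apply_message(s, gf.SensorMessage(0.0, "m0_0", c))
        sp = gf.sparsify(s, 0.03)
        assert len(sp) == 1 and sp.c[0] == pytest.approx(0.5)

    def test_all_zero_state_gives_empty(self, small_layout):
        assert len(gf.sparsify(gf.init_state(small_layout), 0.03)) == 0

    def test_zero_threshold_keeps_strictly_positive(self, small_layout):
        s = gf.init_state(small_layout)
        c = np.array([0.0, 1e-9, 0.1, 0, 0, 0, 0, 0])
        s = gf.apply_message(s, gf.SensorMessage(0.0, "m0_0", c))
        assert len(gf.sparsify(s, 0.0)) == 2

    def test_invalid_threshold_rejected(self, small_layout):
        with pytest.raises(gf.ValidationError):
            gf.sparsify(gf.init_state(small_layout), 1.0)


class TestTrackedPosition:
    def test_single_field_is_its_position(self):
        assert np.allclose(gf.tracked_position(sparse([(1, 2)], [0.5])), (1, 2))

    def test_weighted_mean(self):
        # weights 0.1 and 0.3 -> x = 0.3/0.4 = 0.75
        p = gf.tracked_position(sparse([(0, 0), (1, 0)], [0.1, 0.3]))
        assert np.allclose(p, (0.75, 0.0))

    def test_equal_weights_give_midpoint(self):
        p = gf.tracked_position(sparse([(0, 0), (2, 4)], [0.2, 0.2]))
        assert np.allclose(p, (1, 2))

    def test_empty_state_signals_no_position(self):
        assert gf.tracked_position(sparse(np.empty((0, 2)), [])) is None

    @given(seed=st.integers(0, 1000))
    def test_inside_convex_hull_bounding_box(self, seed):
        r = np.random.default_rng(seed)
        pos = r.uniform(-3, 3, (5, 2))
        c = r.uniform(0.05, 1.0, 5)
        p = gf.tracked_position(sparse(pos, c))
        assert np.all(p >= pos.min(axis=0) - 1e-12)
        assert np.all(p <= pos.max(axis=0) + 1e-12)


class TestWalkingAngle:
    def test_aligned_with_y_axis_is_zero(self):
        assert gf.walking_angle((0, 0), (0, 1)) == pytest.approx(0.0)

    def test_antiparallel_is_pi(self):
        assert abs(gf.walking_angle((0, 0), (0, -1))) == pytest.approx(np.pi)

    def test_rotation_maps_direction_onto_plus_y(self):
        theta = gf.walking_angle((0, 0), (1, 0))
        mapped = gf.rotation_matrix(theta) @ np.array([1.0, 0.0])
        assert np.allclose(mapped, (0, 1), atol=1e-12)

    @given(angle=st.floats(0, 2 * np.pi, exclude_max=True))
    def test_rotation_property_any_direction(self, angle):
        d = np.array([np.cos(angle), np.sin(angle)])
        theta = gf.walking_angle((0.0, 0.0), d)
        assert np.allclose(gf.rotation_matrix(theta) @ d, (0, 1), atol=1e-9)
        # magnitude agrees with the unsigned arccos formulation
        assert abs(theta) == pytest.approx(np.arccos(np.clip(d[1], -1, 1)), abs=1e-9)

    def test_zero_displacement_rejected(self):
        with pytest.raises(gf.DegenerateWalkError):
            gf.walking_angle((1, 1), (1, 1))


class TestToLocal:
    def test_field_at_tracked_position_maps_to_origin(self):
        for theta in (0.0, 0.7, -2.0):
            loc = gf.to_local(sparse([(3, 4)], [0.5]), np.array([3, 4]), theta, 1.0)
            assert np.allclose(loc.positions[0], (0, 0), atol=1e-12)

    def test_distant_fields_removed(self):
        loc = gf.to_local(sparse([(0, 2.0)], [0.5]), np.array([0, 0]), 0.0, 1.0)
        assert len(loc) == 0

    def test_cutoff_is_strict(self):
        loc = gf.to_local(sparse([(0, 1.0), (0, 0.999)], [0.5, 0.5]), np.array([0, 0]), 0.0, 1.0)
        assert len(loc) == 1

    @given(seed=st.integers(0, 500))
    def test_rigid_motion_preserves_pairwise_distances(self, seed):
        r = np.random.default_rng(seed)
        pos = r.uniform(-0.5, 0.5, (4, 2))
        sp = sparse(pos, r.uniform(0.1, 1, 4))
        loc = gf.to_local(sp, r.uniform(-0.2, 0.2, 2), r.uniform(-np.pi, np.pi), 5.0)
        d_before = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        d_after = np.linalg.norm(loc.positions[:, None] - loc.positions[None, :], axis=-1)
        assert np.allclose(d_before, d_after, atol=1e-9)


class TestGrid:
    def test_nine_point_lattice(self):
        g = gf.make_grid(1.0, 1.5)
        pts = {tuple(p) for p in g.spec.points}
        assert pts == {(x, y) for x in (-1.0, 0.0, 1.0) for y in (-1.0, 0.0, 1.0)}
        assert np.all(g.values == 0.0)

    def test_tiny_radius_keeps_only_origin(self):
        g = gf.make_grid(1.0, 0.5)
        assert g.spec.n_points == 1
        assert tuple(g.spec.points[0]) == (0.0, 0.0)

    def test_meander_order_is_row_major_alternating(self):
        pts = gf.make_grid(1.0, 1.5).spec.points
        expected = [
            (-1, -1), (0, -1), (1, -1),
            (1, 0), (0, 0), (-1, 0),
            (-1, 1), (0, 1), (1, 1),
        ]
        assert [tuple(p) for p in pts] == [(float(x), float(y)) for x, y in expected]

    def test_invalid_parameters_rejected(self):
        with pytest.raises(gf.InvalidGridError):
            gf.make_grid(0.0, 1.0)
        with pytest.raises(gf.InvalidGridError):
            gf.make_grid(0.1, -1.0)

    def test_point_set_depends_only_on_spec(self):
        assert np.array_equal(gf.GridSpec(0.1, 1.0).points, gf.GridSpec(0.1, 1.0).points)


class TestResample:
    def local(self, positions, c, r_s=1.5):
        return gf.LocalSparseState(np.asarray(positions, float), np.asarray(c, float), r_s)

    def test_entry_on_grid_point_takes_value(self):
        g = gf.resample(self.local([(1.0, 0.0)], [0.6]), gf.make_grid(1.0, 1.5))
        pts = [tuple(p) for p in g.spec.points]
        assert g.values[pts.index((1.0, 0.0))] == pytest.approx(0.6)
        assert g.values.sum() == pytest.approx(0.6)

    def test_empty_local_state_keeps_zero_grid(self):
        g = gf.resample(self.local(np.empty((0, 2)), []), gf.make_grid(1.0, 1.5))
        assert np.all(g.values == 0.0)

    def test_collision_keeps_maximum(self):
        g = gf.resample(
            self.local([(0.1, 0.1), (-0.1, 0.05)], [0.4, 0.7]), gf.make_grid(1.0, 1.5)
        )
        pts = [tuple(p) for p in g.spec.points]
        assert g.values[pts.index((0.0, 0.0))] == pytest.approx(0.7)
        assert np.count_nonzero(g.values) == 1

    def test_exact_tie_resolves_to_lower_x(self):
        g = gf.resample(self.local([(0.5, 0.0)], [0.9]), gf.make_grid(1.0, 1.5))
        pts = [tuple(p) for p in g.spec.points]
        assert g.values[pts.index((0.0, 0.0))] == pytest.approx(0.9)
        assert g.values[pts.index((1.0, 0.0))] == 0.0

    def test_mismatched_radius_rejected(self):
        with pytest.raises(gf.InvalidGridError):
            gf.resample(self.local([(0, 0)], [0.5], r_s=2.0), gf.make_grid(1.0, 1.5))

    @given(seed=st.integers(0, 300))
    def test_fine_grid_conserves_capacitance_multiset(self, seed):
        # entries placed on distinct coarse cells; a fine enough lattice must
        # keep every value (no collisions, no loss)
        r = np.random.default_rng(seed)
        cells = r.choice(25, size=6, replace=False)
        pos = np.column_stack([(cells % 5) * 0.2 - 0.4, (cells // 5) * 0.2 - 0.4])
        pos = pos + r.uniform(-0.02, 0.02, pos.shape)
        c = r.uniform(0.1, 1.0, len(pos))
        g = gf.resample(gf.LocalSparseState(pos, c, 1.0), gf.make_grid(0.05, 1.0))
        nz = np.sort(g.values[g.values > 0])
        assert np.allclose(nz, np.sort(c))


class TestUnroll:
    def test_vector_length_equals_point_count(self):
        g = gf.make_grid(1.0, 1.5)
        assert len(gf.unroll(g)) == 9
        assert np.all(gf.unroll(g) == 0.0)

    def test_deterministic(self):
        loc = gf.LocalSparseState(np.array([[0.2, 0.3]]), np.array([0.8]), 1.5)
        g1 = gf.resample(loc, gf.make_grid(1.0, 1.5))
        g2 = gf.resample(loc, gf.make_grid(1.0, 1.5))
        assert np.array_equal(gf.unroll(g1), gf.unroll(g2))


def footstep_sparse_series(shift=(0.0, 0.0), rotate=0.0, n_steps=8):
    """Synthetic alternating-footfall sparse series, optionally rigidly moved."""
    R = gf.rotation_matrix(rotate)
    series = []
    for k in range(n_steps):
        y = 0.35 * k
        foot_x = -0.06 if k % 2 == 0 else 0.06
        pos = np.array(
            [[foot_x, y], [foot_x + 0.13, y + 0.06], [-foot_x, y - 0.35]]
        )
        pos = pos @ R.T + np.asarray(shift)
        series.append(gf.SparseState(pos, np.array([0.8, 0.4, 0.6]), 0.03))
    return series


class TestPreprocessSeries:
    def test_translation_invariance_bit_exact(self):
        v0, _, _ = preprocess_sparse_series(footstep_sparse_series())
        v1, _, _ = preprocess_sparse_series(footstep_sparse_series(shift=(13.7, -4.2)))
        assert v0.shape == v1.shape
        assert np.array_equal(v0, v1)

    def test_rotation_invariance(self):
        v0, _, _ = preprocess_sparse_series(footstep_sparse_series())
        v1, _, _ = preprocess_sparse_series(footstep_sparse_series(rotate=1.1))
        assert np.allclose(v0, v1, atol=1e-9)

    def test_reversed_walk_gives_same_local_pattern(self):
        v0, _, _ = preprocess_sparse_series(footstep_sparse_series())
        v1, _, _ = preprocess_sparse_series(footstep_sparse_series(rotate=np.pi))
        assert np.allclose(v0, v1, atol=1e-9)

    def test_activations_concentrate_near_local_y_axis(self):
        v, _, theta = preprocess_sparse_series(footstep_sparse_series(rotate=0.8))
        grid = gf.GridSpec()
        xs = grid.points[:, 0]
        mass = v.sum(axis=0)
        mean_abs_x = np.abs(xs[mass > 0]).mean()
        assert mean_abs_x < 0.35  # footfalls hug the walking axis

    def test_empty_mid_state_yields_zero_vector_carry_forward(self):
        series = footstep_sparse_series()
        series[3] = gf.SparseState(np.empty((0, 2)), np.array([]), 0.03)
        v, traj, _ = preprocess_sparse_series(series)
        assert len(v) == len(series)
        assert np.all(v[3] == 0.0)
        assert not traj.fresh[3] and traj.valid[3]
        assert np.allclose(traj.positions[3], traj.positions[2])

    def test_standing_person_has_no_direction(self):
        one = footstep_sparse_series(n_steps=1) * 5
        with pytest.raises(gf.DegenerateWalkError):
            preprocess_sparse_series(one)

    def test_vector_width_constant_for_one_spec(self):
        v, _, _ = preprocess_sparse_series(footstep_sparse_series())
        assert v.shape[1] == gf.GridSpec().n_points

    def test_track_total_capacitance(self):
        series = footstep_sparse_series(n_steps=3)
        traj = track(series)
        assert np.allclose(traj.total_capacitance, 1.8)
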