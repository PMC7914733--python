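"""Synthetic gait generator: footfalls, capacitance model, emission, cohorts."""

import math

import numpy as np
import pytest

import gaitfloor as gf
from gaitfloor.simulate import draw_participant, sample_capacitances


class TestFootfalls:
    def test_noise_free_gait_is_perfectly_periodic(self, rng):
        p = gf.GaitParams(step_length_sd=0.0, step_width_sd=0.0, step_time_cv=0.0,
                          sway_amplitude=0.0)
        ff = gf.simulate_footfalls(p, 6.0, rng)
        ys = [f.center[1] for f in ff]
        assert np.allclose(np.diff(ys), p.step_length)
        ts = [f.t_down for f in ff]
        assert np.allclose(np.diff(ts), p.step_time)
        sides = [np.sign(f.center[0]) for f in ff]
        assert sides == [(-1.0 if k % 2 == 0 else 1.0) for k in range(len(ff))]

    def test_six_metre_path_has_expected_step_count(self, rng):
        p = gf.GaitParams(step_length=0.7, step_length_sd=0.0, step_width_sd=0.0,
                          step_time_cv=0.0, sway_amplitude=0.0)
        ff = gf.simulate_footfalls(p, 6.0, rng)
        # floor(6/0.7)+1 = 9 footfalls in total, 4-5 per foot
        assert len(ff) == 9

    def test_monte_carlo_step_length_matches_configuration(self):
        rng = np.random.default_rng(0)
        p = gf.GaitParams(step_length=0.7, step_length_sd=0.05, sway_amplitude=0.0)
        diffs = []
        while len(diffs) < 1000:
            ff = gf.simulate_footfalls(p, 50.0, rng)
            ys = [f.center[1] for f in ff]
            diffs.extend(np.diff(ys))
        diffs = np.asarray(diffs[:1000])
        se = np.std(diffs) / math.sqrt(len(diffs))
        # consecutive-difference mean is unbiased for the configured step length
        assert abs(diffs.mean() - 0.7) < 2 * se + 1e-3

    def test_stance_overlap_follows_double_support(self):
        p = gf.GaitParams(step_length_sd=0.0, step_width_sd=0.0, step_time_cv=0.0,
                          double_support=0.2)
        ff = gf.simulate_footfalls(p, 3.0, np.random.default_rng(0))
        overlap = ff[0].t_up - ff[1].t_down
        stride = 2 * p.step_time
        # stance = (0.5 + ds) * stride, next foot lands one step later
        assert overlap == pytest.approx((0.5 + 0.2) * stride - p.step_time)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(gf.ConfigError):
            gf.GaitParams(speed=0.0)
        with pytest.raises(gf.ConfigError):
            gf.GaitParams(double_support=1.0)
        with pytest.raises(gf.ConfigError):
            gf.simulate_footfalls(gf.GaitParams(), 0.0, np.random.default_rng(0))


class TestFootprintCapacitance:
    def test_foot_outside_floor_touches_nothing(self, small_layout):
        ff = gf.Footfall("L", np.array([10.0, 10.0]), 0.0, 0.0, 1.0)
        idx, c = gf.footprint_to_capacitance(ff, small_layout)
        assert len(idx) == 0

    def test_fully_covered_field_reaches_gain(self):
        # tiny module: each triangle fits entirely under the foot ellipse
        lay = gf.FloorLayout((gf.ModuleGeometry("m", (0.0, 0.0), 0.06),))
        ff = gf.Footfall("L", np.array([0.0, 0.0]), 0.0, 0.0, 1.0)
        # fine sub-sampling: the module is far below the realistic field size
        idx, c = gf.footprint_to_capacitance(ff, lay, gain=0.9, n_grid=60)
        assert len(idx) == 8
        assert np.allclose(c, 0.9, atol=0.05)

    def test_contribution_clipped_at_one(self):
        lay = gf.FloorLayout((gf.ModuleGeometry("m", (0.0, 0.0), 0.06),))
        ff = gf.Footfall("L", np.array([0.0, 0.0]), 0.0, 0.0, 1.0)
        _, c = gf.footprint_to_capacitance(ff, lay, gain=5.0)
        assert np.all(c <= 1.0)

    def test_overlap_against_monte_carlo_area_oracle(self, small_layout):
        rng = np.random.default_rng(42)
        a, b = 0.13, 0.05
        ellipse_area = math.pi * a * b
        for _ in range(10):
            center = rng.uniform([0.1, 0.1], [0.66, 1.04])
            heading = rng.uniform(0, 2 * math.pi)
            ff = gf.Footfall("L", center, heading, 0.0, 1.0)
            idx, c = gf.footprint_to_capacitance(ff, small_layout, gain=1.0)
            # dense random oracle for the same placements
            n_mc = 40_000
            u = rng.normal(size=(n_mc, 2))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            u *= np.sqrt(rng.uniform(size=(n_mc, 1)))
            cos_h, sin_h = math.cos(heading), math.sin(heading)
            rot = np.array([[cos_h, sin_h], [-sin_h, cos_h]])
            pts = center + (u * np.array([b, a])) @ rot.T
            tri_area = gf.field_area(0.38)
            for fi, cv in zip(idx, c):
                mod = small_layout.modules[fi // 8]
                tri = gf.field_triangles(mod)[fi % 8]
                from gaitfloor.simulate import _points_in_triangle

                frac = _points_in_triangle(pts, tri).mean()
                mc_overlap = frac * ellipse_area
                ours = cv * tri_area  # invert the coverage normalisation
                assert abs(ours - mc_overlap) <= 0.05 * ellipse_area


class TestEmission:
    def test_constant_series_emits_nothing(self, small_layout):
        times = np.arange(0, 1.0, 0.1)
        series = np.zeros((len(times), small_layout.n_fields))
        assert gf.emit_messages(times, series, small_layout, 0.02) == []

    def test_single_step_produces_messages(self, small_layout, rng):
        p = gf.GaitParams()
        ff = [gf.Footfall("L", np.array([0.38, 0.5]), 0.0, 0.2, 0.8)]
        sim = gf.SimConfig(noise_sd=0.0)
        times, series = sample_capacitances(ff, small_layout, sim, rng)
        msgs = gf.emit_messages(times, series, small_layout, sim.emission_threshold)
        assert len(msgs) >= 1
        assert all(m.module in {mm.module_id for mm in small_layout.modules} for m in msgs)

    def test_round_trip_bounded_by_threshold(self, small_layout):
        rng = np.random.default_rng(3)
        ff = gf.simulate_footfalls(gf.GaitParams(), 0.9, rng, start=(0.38, 0.2))
        sim = gf.SimConfig()
        times, series = sample_capacitances(ff, small_layout, sim, rng)
        msgs = gf.emit_messages(times, series, small_layout, sim.emission_threshold)
        # reconstruct the state at each tick from the message stream
        recon = np.zeros(small_layout.n_fields)
        mi = 0
        for k, t in enumerate(times):
            while mi < len(msgs) and msgs[mi].t <= t:
                sl = small_layout.module_slice(msgs[mi].module)
                recon[sl] = msgs[mi].c
                mi += 1
            assert np.max(np.abs(recon - series[k])) <= sim.emission_threshold + 1e-12


class TestCohort:
    def test_same_seed_gives_identical_datasets(self):
        lay = gf.FloorLayout.grid(2, 6, edge=0.38)
        sim = gf.SimConfig(n_participants=1, reps_per_mode=1)
        a, _ = gf.generate_cohort(lay, sim, mode_subset=["normal"], seed=5)
        b, _ = gf.generate_cohort(lay, sim, mode_subset=["normal"], seed=5)
        assert len(a) == len(b) == 1
        assert len(a[0].messages) == len(b[0].messages)
        for ma, mb in zip(a[0].messages, b[0].messages):
            assert ma.t == mb.t and ma.module == mb.module
            assert np.array_equal(ma.c, mb.c)

    def test_manifest_product_count(self):
        lay = gf.FloorLayout.grid(2, 6, edge=0.38)
        sim = gf.SimConfig(n_participants=3, reps_per_mode=5)
        recs, traits = gf.generate_cohort(
            lay, sim, mode_subset=["normal", "closed_eyes"], seed=0
        )
        assert len(recs) == 3 * 2 * 5
        assert len(traits) == 3
        from gaitfloor.simulate import cohort_manifest

        mf = cohort_manifest(recs)
        assert len(mf) == 30 and mf["participant"].nunique() == 3

    def test_uhr_counts_bounded_and_strength_driven(self):
        sim = gf.SimConfig(uhr_noise_sd=2.0)
        rng = np.random.default_rng(0)
        traits = [draw_participant(f"p{i}", sim, rng) for i in range(200)]
        uhr = np.array([t.uhr_right for t in traits])
        strength = np.array([t.strength for t in traits])
        assert uhr.min() >= 10 and uhr.max() <= 45
        assert np.corrcoef(strength, uhr)[0, 1] > 0.9

    def test_zero_coupling_leaves_gait_independent_of_strength(self):
        sim = gf.SimConfig(uhr_gait_coupling=0.0)
        rng = np.random.default_rng(0)
        traits = [draw_participant(f"p{i}", sim, rng) for i in range(300)]
        sl = np.array([t.baseline.step_length for t in traits])
        s = np.array([t.strength for t in traits])
        assert abs(np.corrcoef(s, sl)[0, 1]) < 0.15

    def test_footfall_map_clusters_match_simulated_footfalls(self, sim_recording):
        layout, messages = sim_recording
        fmap = gf.footfall_map(list(gf.iter_replay(layout, messages)))
        pos = fmap[["x", "y"]].to_numpy()
        max_c = fmap["max_c"].to_numpy()
        # ground truth footfalls of the same seeded recording
        rng = np.random.default_rng(7)
        p = gf.GaitParams()
        ff = gf.simulate_footfalls(p, 6.08 - 0.9, rng, start=(0.76, 0.45))
        diag = 0.38 * math.sqrt(2)
        for f in ff:
            near = np.linalg.norm(pos - f.center, axis=1) < diag
            active = near & (max_c > 0.1)
            assert active.any()
            centroid = (pos[active] * max_c[active, None]).sum(0) / max_c[active].sum()
            assert np.linalg.norm(centroid - f.center) < diag

    def test_wider_step_spread_increases_lateral_activation_variance(self):
        lay = gf.corridor_layout(n_long=10)
        spreads = []
        for width_sd in (0.005, 0.06):
            xs_all = []
            rng = np.random.default_rng(11)
            for _ in range(25):
                p = gf.GaitParams(step_width_sd=width_sd)
                msgs = gf.simulate_recording(lay, p, gf.SimConfig(noise_sd=0.005), rng)
                rec = gf.Recording("r", "p", "normal", 0, msgs, 20, 20)
                for w in gf.preprocess_recording(rec, lay):
                    grid_x = gf.GridSpec().points[:, 0]
                    mass = w.vectors.sum(axis=0)
                    if mass.sum() > 0:
                        xs_all.append(
                            np.sqrt(np.sum(mass * grid_x**2) / mass.sum())
                        )
            spreads.append(np.mean(xs_all))
        assert spreads[1] > spreads[0]
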