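import numpy as np
import pytest

from orbitduel import (ViewingCondition, eye_centered_path, eye_trace,
                       make_preset, relative_path, retinal_path)
from orbitduel.kinematics import orbit_position
from orbitduel.perceive import compute_frames

from conftest import ALL_PRESETS, CONDITIONS


class TestEyeTrace:
    def test_fixation_eye_displacement_is_zero(self, presets):
        cond = ViewingCondition(mode="fixate", fixation_point=(1.0, 2.0))
        trace = eye_trace(cond, presets["movie2"])
        assert np.allclose(trace.eye, [1.0, 2.0])
        assert np.allclose(trace.efference, 0.0)

    def test_fixate_forces_zero_pursuit_gain(self):
        cond = ViewingCondition(mode="fixate", pursuit_gain=0.7)
        assert cond.pursuit_gain == 0.0

    def test_perfect_target_pursuit_matches_target_path(self, presets):
        stim = presets["movie2"]
        trace = eye_trace(ViewingCondition(mode="pursue_target"), stim)
        assert np.allclose(trace.eye, stim.target_trajectory().xy, atol=1e-12)

    def test_half_gain_pursuit_halves_the_eye_orbit(self, presets):
        stim = presets["movie2"]
        trace = eye_trace(ViewingCondition(mode="pursue_target", pursuit_gain=0.5), stim)
        center = np.asarray(stim.target.center)
        # direct evaluation of the scaled displacement formula
        expected = center + 0.5 * (orbit_position(stim.target, stim.t) - center)
        assert np.allclose(trace.eye, expected, atol=1e-12)
        r = np.linalg.norm(trace.eye - center, axis=1)
        assert np.allclose(r, 0.5 * stim.target.radius, atol=1e-12)

    def test_pursuit_latency_clamps_at_start(self, presets):
        stim = presets["movie2"]
        tau = 10 * stim.dt
        trace = eye_trace(ViewingCondition(mode="pursue_target", pursuit_latency=tau), stim)
        # during the first tau the eye sits at the object's t=0 position
        assert np.allclose(trace.eye[:10], trace.eye[0])
        # afterwards it lags the target by exactly tau
        target = stim.target_trajectory().xy
        assert np.allclose(trace.eye[10:], target[:-10], atol=1e-12)

    def test_efference_scales_with_gain(self, presets):
        stim = presets["movie2"]
        full = eye_trace(ViewingCondition(mode="pursue_target"), stim)
        partial = eye_trace(ViewingCondition(mode="pursue_target", efference_gain=0.8), stim)
        assert np.allclose(partial.efference, 0.8 * full.efference, atol=1e-12)

    def test_inducer_index_out_of_range(self, presets):
        cond = ViewingCondition(mode="pursue_inducer", inducer_index=7)
        with pytest.raises(IndexError):
            eye_trace(cond, presets["movie2"])

    @pytest.mark.parametrize("bad", [dict(pursuit_gain=1.2), dict(efference_gain=1.6),
                                     dict(pursuit_latency=-0.1), dict(mode="stare")])
    def test_invalid_conditions_rejected(self, bad):
        kw = dict(mode="pursue_target")
        kw.update(bad)
        with pytest.raises(ValueError):
            ViewingCondition(**kw)


class TestRetinalPath:
    def test_fixation_translates_world_path(self, presets):
        stim = presets["movie2"]
        cond = ViewingCondition(mode="fixate", fixation_point=(2.0, -3.0))
        world = stim.target_trajectory()
        ret = retinal_path(world, eye_trace(cond, stim))
        assert np.allclose(ret.xy, world.xy - np.array([2.0, -3.0]), atol=1e-12)

    def test_perfect_pursuit_stabilises_target_on_retina(self, presets):
        stim = presets["movie2"]
        eyes = eye_trace(ViewingCondition(mode="pursue_target"), stim)
        ret = retinal_path(stim.target_trajectory(), eyes)
        assert np.allclose(ret.xy, ret.xy[0], atol=1e-12)

    def test_inducer_pursuit_gives_relative_curve_on_retina(self, presets):
        """With the eye on an inducer, the retinal target path is the
        world-frame difference target - inducer, up to a constant."""
        stim = presets["movie2"]
        eyes = eye_trace(ViewingCondition(mode="pursue_inducer", inducer_index=1), stim)
        ret = retinal_path(stim.target_trajectory(), eyes)
        diff = stim.target_trajectory().xy - stim.inducer_trajectory(1).xy
        assert np.allclose(ret.xy - ret.xy[0], diff - diff[0], atol=1e-9)

    def test_mismatched_time_base_rejected(self, presets):
        stim = presets["movie2"]
        other = make_preset("movie2", samples_per_common_period=1440)
        eyes = eye_trace(ViewingCondition(), other)
        with pytest.raises(ValueError):
            retinal_path(stim.target_trajectory(), eyes)


class TestEyeCenteredPath:
    @pytest.mark.parametrize("cond_name", list(CONDITIONS))
    @pytest.mark.parametrize("name", ALL_PRESETS)
    def test_frame_closure_every_preset_and_condition(self, presets, name, cond_name):
        """With a perfect efference copy the eye-centered path equals the
        world path up to a constant translation."""
        stim = presets[name]
        cond = CONDITIONS[cond_name]
        if cond.mode == "pursue_inducer" and stim.n_inducers == 0:
            pytest.skip("no inducer to pursue")
        eyes = eye_trace(cond, stim)
        world = stim.target_trajectory()
        ec = eye_centered_path(retinal_path(world, eyes), eyes)
        offset = ec.xy[0] - world.xy[0]
        assert np.max(np.abs(ec.xy - world.xy - offset)) < 1e-9 * stim.target.radius

    def test_fixation_eye_centered_equals_retinal(self, presets):
        stim = presets["movie3"]
        eyes = eye_trace(ViewingCondition(mode="fixate", fixation_point=(4.0, 0.0)), stim)
        ret = retinal_path(stim.target_trajectory(), eyes)
        ec = eye_centered_path(ret, eyes)
        assert np.array_equal(ec.xy, ret.xy)

    def test_imperfect_efference_shrinks_the_circle(self, presets):
        """Perfect pursuit with efference gain 0.8 leaves a circular
        eye-centered path of 0.8x the orbit radius."""
        stim = presets["movie2"]
        eyes = eye_trace(ViewingCondition(mode="pursue_target", efference_gain=0.8), stim)
        ec = eye_centered_path(retinal_path(stim.target_trajectory(), eyes), eyes)
        r = np.linalg.norm(ec.xy - ec.xy.mean(axis=0), axis=1)
        assert np.allclose(r, 0.8 * stim.target.radius, atol=1e-9)


class TestRelativePath:
    def test_identical_orbits_cancel_exactly(self):
        """Common motion cancels: target and inducers on the same orbit
        template leave zero relative displacement."""
        stim = make_preset("movie2")
        from dataclasses import replace
        same = replace(stim, inducer_orbit=replace(
            stim.target, center=(0.0, 0.0)))
        paths = compute_frames(same, ViewingCondition())
        assert np.allclose(paths.relative.displacements(), 0.0, atol=1e-12)

    def test_movie2_relative_is_horizontal_segment_of_half_length_2r(self, presets):
        """Trig oracle: r(sin a - sin(-a), cos a - cos(-a)) = (2r sin a, 0)."""
        paths = compute_frames(presets["movie2"], ViewingCondition())
        disp = paths.relative.displacements()
        r = presets["movie2"].target.radius
        theta = 2 * np.pi * presets["movie2"].t / presets["movie2"].target.period
        assert np.allclose(disp[:, 0], 2 * r * np.sin(theta), atol=1e-9)
        assert np.allclose(disp[:, 1], 0.0, atol=1e-9)
        assert np.max(disp[:, 0]) == pytest.approx(2 * r, abs=1e-3)

    def test_movie3_relative_is_vertical_segment(self, presets):
        paths = compute_frames(presets["movie3"], ViewingCondition())
        disp = paths.relative.displacements()
        r = presets["movie3"].target.radius
        assert np.allclose(disp[:, 0], 0.0, atol=1e-9)
        assert np.max(np.abs(disp[:, 1])) == pytest.approx(2 * r, abs=1e-3)

    def test_relative_identical_across_all_four_inducers(self, presets):
        for name in ("movie2", "movie3", "movie4", "movie5", "movie6"):
            stim = presets[name]
            eyes = eye_trace(ViewingCondition(), stim)
            tec = eye_centered_path(retinal_path(stim.target_trajectory(), eyes), eyes)
            rels = []
            for j in range(4):
                iec = eye_centered_path(
                    retinal_path(stim.inducer_trajectory(j), eyes), eyes)
                rels.append(relative_path(tec, iec).xy)
            for other in rels[1:]:
                assert np.allclose(other, rels[0], atol=1e-12)

    @pytest.mark.parametrize("phase", [0.0, 30.0, 90.0, 135.0, 180.0, 270.0])
    def test_equal_speed_opposite_direction_relative_is_a_line_at_half_phase(self, phase):
        """Principal-axis fit: the relative path is a straight segment
        oriented at phase/2 from horizontal (mod 180), residual < 1e-9 r."""
        from conftest import movie2_with_phase
        stim = movie2_with_phase(phase)
        paths = compute_frames(stim, ViewingCondition())
        disp = paths.relative.displacements()
        cov = disp.T @ disp / len(disp)
        evals, evecs = np.linalg.eigh(cov)
        # residual = RMS projection onto the minor axis
        resid = np.sqrt(np.mean((disp @ evecs[:, 0]) ** 2))
        assert resid < 1e-9 * stim.target.radius  # collinear
        ang = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])) % 180.0
        assert ang == pytest.approx((-phase / 2) % 180.0, abs=1e-6)
        half_len = np.max(np.linalg.norm(disp, axis=1))
        assert half_len == pytest.approx(2 * stim.target.radius, abs=1e-3)
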