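"""Forward RF model: echo placement, attenuation, noise and presets."""

import numpy as np
import pytest

from memsus import (
    MotionModel,
    Scatterer,
    SimulationConfig,
    make_preset,
    simulate_rf_frame,
    simulate_sequence,
)
from memsus.phantom_sim import PRESET_NAMES


def quiet(**kw) -> SimulationConfig:
    base = dict(noise_rms=0.0, dc_offset=0.0, rng_seed=0)
    base.update(kw)
    return SimulationConfig(**base)


class TestSimulateFrame:
    def test_empty_phantom_all_zero(self, spec, geom):
        fr = simulate_rf_frame([], spec, geom, quiet())
        assert np.all(fr.samples == 0.0)

    def test_on_axis_echo_at_time_of_flight(self, spec, deep_geom):
        # place the scatterer on the beam axis of line 62
        th = deep_geom.line_angles(0)[62]
        r = 8e-3
        sc = Scatterer(position=(r * np.sin(th), r * np.cos(th)))
        fr = simulate_rf_frame([sc], spec, deep_geom, quiet())
        env = np.abs(fr.samples[62])
        j_peak = int(np.argmax(env))
        rng = r + deep_geom.pivot_standoff
        j_true = round(2.0 * rng / spec.sound_speed * deep_geom.sample_rate)
        assert abs(j_peak - j_true) <= 1

    def test_dc_offset_sets_line_mean(self, spec, geom):
        sim = SimulationConfig(noise_rms=0.01, dc_offset=0.05, rng_seed=7)
        fr = simulate_rf_frame([], spec, geom, sim)
        tol = 3.0 * 0.01 / np.sqrt(geom.samples_per_line)
        assert np.allclose(fr.samples.mean(axis=1), 0.05, atol=tol)

    def test_reflectivity_linearity(self, spec, deep_geom):
        sc1 = [Scatterer(position=(0.0, 8e-3), reflectivity=1.0)]
        sc3 = [Scatterer(position=(0.0, 8e-3), reflectivity=3.0)]
        f1 = simulate_rf_frame(sc1, spec, deep_geom, quiet())
        f3 = simulate_rf_frame(sc3, spec, deep_geom, quiet())
        assert np.allclose(f3.samples, 3.0 * f1.samples, atol=1e-12)

    def test_seed_reproducibility(self, spec, geom):
        sim = SimulationConfig(rng_seed=11)
        sc = [Scatterer(position=(0.0, 3e-3))]
        a = simulate_rf_frame(sc, spec, geom, sim, frame_index=4)
        b = simulate_rf_frame(sc, spec, geom, sim, frame_index=4)
        assert np.array_equal(a.samples, b.samples)

    def test_behind_mirror_scatterer_excluded(self, spec, geom):
        sc = [Scatterer(position=(0.0, -2e-3))]
        fr = simulate_rf_frame(sc, spec, geom, quiet())
        assert fr.excluded_scatterers == 1
        assert np.all(fr.samples == 0.0)

    def test_attenuation_matches_closed_form(self, spec, deep_geom):
        # both scatterers on one beam axis so the lateral beam term cancels
        th = deep_geom.line_angles(0)[62]
        r1, r2 = 5e-3, 10e-3
        phantom = [
            Scatterer(position=(r1 * np.sin(th), r1 * np.cos(th))),
            Scatterer(position=(r2 * np.sin(th), r2 * np.cos(th))),
        ]
        fr = simulate_rf_frame(phantom, spec, deep_geom,
                               quiet(attenuation_coeff=0.5))
        fs, c = deep_geom.sample_rate, spec.sound_speed
        from scipy.signal import hilbert
        env = np.abs(hilbert(fr.samples[62]))
        peaks = []
        for r in (r1, r2):
            j = round(2.0 * (r + deep_geom.pivot_standoff) / c * fs)
            peaks.append(env[j - 80:j + 80].max())
        dr_cm = (r2 - r1) * 100.0
        expected = 10.0 ** (-2.0 * 0.5 * (spec.center_frequency / 1e6)
                            * dr_cm / 20.0)
        assert peaks[1] / peaks[0] == pytest.approx(expected, rel=0.05)


class TestSimulateSequence:
    def test_sweep_count_and_display_pairing(self, spec, geom):
        sc = [Scatterer(position=(0.0, 3e-3))]
        seq = simulate_sequence(sc, spec, geom, quiet(), duration=1.0)
        assert len(seq.frames) == 80
        assert len(seq.forward_frames()) == 40

    def test_static_phantom_backward_sweep_mirrors_forward(self, spec, geom):
        sc = [Scatterer(position=(1e-3, 3e-3))]
        seq = simulate_sequence(sc, spec, geom, quiet(), duration=1.5 / 40.0)
        fwd, bwd = seq.frames[0], seq.frames[1]
        # the backward sweep retraces the forward angles in reverse order,
        # offset by at most one firing interval of mirror phase
        step = np.abs(np.diff(fwd.angles)).max()
        assert np.allclose(bwd.angles[::-1], fwd.angles, atol=step)
        # echo arrival time per line is angle-independent for a static target
        j_fwd = np.argmax(np.abs(fwd.samples), axis=1)
        j_bwd = np.argmax(np.abs(bwd.samples[::-1]), axis=1)
        strong = np.abs(fwd.samples).max(axis=1) > \
            0.1 * np.abs(fwd.samples).max()
        assert np.all(np.abs(j_fwd[strong] - j_bwd[strong]) <= 1)

    def test_periodic_motion_period_in_depth_trace(self, spec, geom):
        motion = MotionModel(kind="sinusoidal", frequency=3.7,
                             amplitude=0.5e-3, axis=(0.0, 1.0))
        sc = [Scatterer(position=(0.0, 3e-3), motion=motion)]
        seq = simulate_sequence(sc, spec, geom, quiet(), duration=10.0,
                                sweeps="forward")
        line = int(np.argmin(np.abs(geom.line_angles(0))))
        depth = np.array([
            np.argmax(np.abs(f.samples[line])) for f in seq.frames
        ], dtype=float)
        depth -= depth.mean()
        # autocorrelation peaks at the motion period
        ac = np.correlate(depth, depth, mode="full")[depth.size - 1:]
        lag = np.argmax(ac[5:]) + 5  # skip the zero-lag lobe
        assert lag / 40.0 == pytest.approx(1.0 / 3.7, abs=0.025)

    def test_too_short_duration_rejected(self, spec, geom):
        with pytest.raises(ValueError):
            simulate_sequence([], spec, geom, quiet(), duration=0.01)


class TestMotionModel:
    def test_irregular_event_adds_local_bump(self):
        m = MotionModel(kind="sinusoidal", frequency=2.0, amplitude=0.0,
                        irregular_events=((3.0, 1e-3),))
        _, dz_at = m.displacement(3.0)
        _, dz_far = m.displacement(6.0)
        assert dz_at == pytest.approx(1e-3, rel=1e-6)
        assert abs(dz_far) < 1e-9

    def test_pulse_train_rests_between_beats(self):
        m = MotionModel(kind="pulse_train", frequency=2.0, amplitude=1e-3)
        t = np.linspace(0.0, 1.0, 2001)
        _, dz = m.displacement(t)
        assert dz.max() == pytest.approx(1e-3, rel=1e-3)
        assert (dz < 1e-12).mean() > 0.5  # resting most of the cycle

    def test_invalid_kind_rejected(self):
        with pytest.raises(ValueError):
            MotionModel(kind="brownian", frequency=1.0)


class TestPresets:
    @pytest.mark.parametrize("name", PRESET_NAMES)
    def test_presets_build(self, name, spec, geom):
        phantom, sim = make_preset(name, spec, geom)
        assert len(phantom) >= 1
        assert sim.noise_rms >= 0

    def test_wire_is_single_focal_scatterer(self, spec, geom):
        phantom, _ = make_preset("wire", spec, geom)
        assert len(phantom) == 1
        x, z = phantom[0].position
        assert x == 0.0
        assert z == pytest.approx(spec.focal_length - geom.pivot_standoff)

    def test_mouse_heart_walls_3mm_apart_in_antiphase(self, spec, geom):
        phantom, _ = make_preset("mouse_heart", spec, geom)
        depths = sorted({sc.position[1] for sc in phantom})
        assert depths[-1] - depths[0] == pytest.approx(3e-3)
        axes = {sc.motion.axis[1] for sc in phantom}
        assert axes == {1.0, -1.0}
        assert all(sc.motion.frequency == 3.7 for sc in phantom)
        assert any(sc.motion.irregular_events for sc in phantom)

    def test_radial_artery_walls_modulate_at_1_1_hz(self, spec, geom):
        phantom, _ = make_preset("radial_artery", spec, geom)
        assert all(sc.motion.frequency == 1.1 for sc in phantom)
        axes = {sc.motion.axis[1] for sc in phantom}
        assert axes == {1.0, -1.0}  # diameter modulation

    def test_unknown_preset_rejected(self, spec, geom):
        with pytest.raises(ValueError, match="unknown preset"):
            make_preset("zebrafish", spec, geom)
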