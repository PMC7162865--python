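"""A-line processing chain: DC removal, band-pass, TGC, envelope, log."""

import numpy as np
import pytest
from scipy.signal import hilbert

from memsus import (
    PipelineParams,
    RFFrame,
    Scatterer,
    SimulationConfig,
    apply_tgc,
    bandpass,
    envelope,
    log_compress,
    process_frame,
    remove_dc,
    simulate_rf_frame,
)


def make_frame(geom, line_signal) -> RFFrame:
    samples = np.tile(np.asarray(line_signal, dtype=float),
                      (geom.lines_per_frame, 1))
    return RFFrame(samples=samples, geometry=geom, timestamp=0.0,
                   frame_index=0)


@pytest.fixture()
def tone_frame(spec, geom):
    t = np.arange(geom.samples_per_line) / geom.sample_rate
    return make_frame(geom, np.cos(2 * np.pi * spec.center_frequency * t))


class TestRemoveDC:
    def test_constant_line_zeroed(self, geom):
        out = remove_dc(make_frame(geom, np.full(geom.samples_per_line, 5.0)))
        assert np.allclose(out.values, 0.0, atol=1e-12)
        assert out.stage == "dc_removed"

    def test_offset_sinusoid_preserved(self, spec, geom):
        t = np.arange(geom.samples_per_line) / geom.sample_rate
        sine = np.sin(2 * np.pi * spec.center_frequency * t)
        sine -= sine.mean()
        out = remove_dc(make_frame(geom, sine + 0.05))
        assert np.max(np.abs(out.values[0] - sine)) < 1e-12

    def test_output_line_means_are_zero(self, spec, geom):
        rng = np.random.default_rng(0)
        fr = make_frame(geom, rng.normal(0.3, 1.0, geom.samples_per_line))
        out = remove_dc(fr)
        rms = np.sqrt(np.mean(fr.samples**2))
        assert np.all(np.abs(out.values.mean(axis=1)) <= 1e-12 * rms)


class TestBandpass:
    def tone_gain(self, spec, geom, freq):
        t = np.arange(geom.samples_per_line) / geom.sample_rate
        tone = np.cos(2 * np.pi * freq * t)
        img = remove_dc(make_frame(geom, tone))
        out = bandpass(img, spec)
        core = slice(200, -200)  # exclude filter edge transients
        return (np.sqrt(np.mean(out.values[0, core] ** 2))
                / np.sqrt(np.mean(tone[core] ** 2)))

    def test_center_frequency_preserved(self, spec, geom):
        gain = self.tone_gain(spec, geom, spec.center_frequency)
        assert 20 * np.log10(gain) == pytest.approx(0.0, abs=1.0)

    def test_out_of_band_tone_rejected(self, spec, geom):
        gain = self.tone_gain(spec, geom, spec.center_frequency / 4.0)
        assert 20 * np.log10(gain) < -40.0

    def test_stopband_attenuation_at_band_shoulders(self, spec, geom):
        low = spec.center_frequency * (1 - spec.fractional_bandwidth)
        high = spec.center_frequency * (1 + spec.fractional_bandwidth)
        assert 20 * np.log10(self.tone_gain(spec, geom, 0.5 * low)) < -40.0
        assert 20 * np.log10(self.tone_gain(spec, geom, 1.5 * high)) < -40.0

    def test_invalid_band_rejected(self, spec, geom, tone_frame):
        img = remove_dc(tone_frame)
        with pytest.raises(ValueError):
            bandpass(img, spec, low=30e6, high=10e6)

    def test_stage_order_enforced(self, spec, tone_frame):
        img = remove_dc(tone_frame)
        filt = bandpass(img, spec)
        with pytest.raises(ValueError, match="stage"):
            bandpass(filt, spec)


class TestTGC:
    def test_zero_alpha_is_identity(self, spec, geom, tone_frame):
        img = bandpass(remove_dc(tone_frame), spec)
        out = apply_tgc(img, 0.0, spec)
        assert np.array_equal(out.values, img.values)

    def test_gain_clipped_at_max(self, spec, deep_geom):
        fr = make_frame(deep_geom, np.ones(deep_geom.samples_per_line))
        img = bandpass(remove_dc(fr), spec)
        img.values = np.ones_like(img.values)  # unit input to read off gain
        out = apply_tgc(img, 1.0, spec, max_gain=40.0)
        z_cm = deep_geom.sample_ranges(spec.sound_speed) * 100.0
        unclipped = 2.0 * 1.0 * (spec.center_frequency / 1e6) * z_cm
        j_clip = np.argmax(unclipped > 40.0)
        assert np.allclose(out.values[:, j_clip:], 10 ** (40.0 / 20.0))

    def test_negative_alpha_rejected(self, spec, tone_frame):
        img = bandpass(remove_dc(tone_frame), spec)
        with pytest.raises(ValueError):
            apply_tgc(img, -0.1, spec)

    def test_equalizes_identical_scatterers_at_depth(self, spec, deep_geom):
        # two equal reflectors on one beam axis, alpha = 0.5 dB/(cm MHz)
        th = deep_geom.line_angles(0)[62]
        phantom = [
            Scatterer(position=(5e-3 * np.sin(th), 5e-3 * np.cos(th))),
            Scatterer(position=(10e-3 * np.sin(th), 10e-3 * np.cos(th))),
        ]
        sim = SimulationConfig(noise_rms=0.0, dc_offset=0.02,
                               attenuation_coeff=0.5, rng_seed=0)
        fr = simulate_rf_frame(phantom, spec, deep_geom, sim)
        img = apply_tgc(bandpass(remove_dc(fr), spec), 0.5, spec)
        env = envelope(img, spec).values[62]
        fs, c = deep_geom.sample_rate, spec.sound_speed
        peaks = [
            env[j - 80:j + 80].max()
            for j in (
                round(2 * (r + deep_geom.pivot_standoff) / c * fs)
                for r in (5e-3, 10e-3)
            )
        ]
        assert peaks[1] / peaks[0] == pytest.approx(1.0, abs=0.05)


class TestEnvelope:
    def test_pure_tone_envelope_constant(self, spec, geom, tone_frame):
        img = apply_tgc(bandpass(remove_dc(tone_frame), spec), 0.0, spec)
        env = envelope(img, spec).values
        interior = env[:, 300:-300]
        # tone amplitude after the zero-phase band-pass
        ref = np.abs(hilbert(img.values[0]))[300:-300].mean()
        assert np.max(np.abs(interior - ref)) / ref < 0.01

    def test_matches_hilbert_oracle_on_echoes(self, spec, deep_geom):
        phantom = [Scatterer(position=(0.0, 5e-3)),
                   Scatterer(position=(0.0, 10e-3))]
        fr = simulate_rf_frame(
            phantom, spec, deep_geom,
            SimulationConfig(noise_rms=0.0, dc_offset=0.02, rng_seed=0))
        img = apply_tgc(bandpass(remove_dc(fr), spec), 0.5, spec)
        e = envelope(img, spec).values
        h = np.abs(hilbert(img.values, axis=1))
        g = slice(100, -100)
        rel = (np.sqrt(np.mean((e[:, g] - h[:, g]) ** 2))
               / np.sqrt(np.mean(h[:, g] ** 2)))
        assert rel < 0.02

    def test_envelope_peak_at_time_of_flight(self, spec, deep_geom):
        phantom = [Scatterer(position=(0.0, 8e-3))]
        fr = simulate_rf_frame(
            phantom, spec, deep_geom,
            SimulationConfig(noise_rms=0.0, dc_offset=0.0, rng_seed=0))
        img = apply_tgc(bandpass(remove_dc(fr), spec), 0.0, spec)
        env = envelope(img, spec).values
        line = int(np.argmax(env.max(axis=1)))
        j_true = round(2 * (8e-3 + deep_geom.pivot_standoff)
                       / spec.sound_speed * deep_geom.sample_rate)
        assert abs(int(np.argmax(env[line])) - j_true) <= 1

    def test_invariant_to_carrier_phase(self, spec, geom):
        t = np.arange(geom.samples_per_line) / geom.sample_rate
        envs = []
        for phase in (0.0, 1.1):
            tone = np.cos(2 * np.pi * spec.center_frequency * t + phase)
            img = apply_tgc(bandpass(remove_dc(make_frame(geom, tone)),
                                     spec), 0.0, spec)
            envs.append(envelope(img, spec).values[0, 300:-300])
        assert np.max(np.abs(envs[0] - envs[1])) / envs[0].mean() < 0.01

    def test_zero_input_zero_envelope(self, spec, geom):
        fr = make_frame(geom, np.zeros(geom.samples_per_line))
        img = apply_tgc(bandpass(remove_dc(fr), spec), 0.5, spec)
        assert np.allclose(envelope(img, spec).values, 0.0, atol=1e-12)


class TestLogCompress:
    def make_env(self, geom, values):
        fr = make_frame(geom, np.zeros(geom.samples_per_line))
        img = remove_dc(fr)
        img.stage = "envelope"
        img.values = values
        return img

    def test_reference_levels(self, geom):
        env = np.full((geom.lines_per_frame, geom.samples_per_line), 0.25)
        env[0, 0] = 1.0
        env[0, 1] = 0.5
        out = log_compress(self.make_env(geom, env), 40.0)
        assert out.values[0, 0] == 0.0
        assert out.values[0, 1] == pytest.approx(-6.0206, abs=1e-3)

    def test_floor_clipping(self, geom):
        env = np.ones((geom.lines_per_frame, geom.samples_per_line))
        env[0, 0] = 10.0 ** (-60.0 / 20.0)  # far below a 40 dB window
        out = log_compress(self.make_env(geom, env), 40.0)
        assert out.values[0, 0] == -40.0

    def test_all_zero_frame_floors_with_warning(self, geom):
        env = np.zeros((geom.lines_per_frame, geom.samples_per_line))
        with pytest.warns(UserWarning):
            out = log_compress(self.make_env(geom, env), 40.0)
        assert np.all(out.values == -40.0)

    def test_monotone_db_mapping(self, geom):
        rng = np.random.default_rng(3)
        env = rng.uniform(0.0, 1.0,
                          (geom.lines_per_frame, geom.samples_per_line))
        out = log_compress(self.make_env(geom, env), 40.0).values
        order = np.argsort(env, axis=None)
        assert np.all(np.diff(out.flatten()[order]) >= 0.0)


class TestProcessFrame:
    def test_zero_frame_gives_uniform_floor(self, spec, geom):
        fr = make_frame(geom, np.zeros(geom.samples_per_line))
        with pytest.warns(UserWarning):
            out = process_frame(fr, spec)
        assert np.all(out.values == -40.0)
        assert out.stage == "log"

    def test_single_scatterer_dominant_blob_at_time_of_flight(
            self, spec, deep_geom):
        phantom = [Scatterer(position=(0.0, 8e-3))]
        fr = simulate_rf_frame(
            phantom, spec, deep_geom,
            SimulationConfig(noise_rms=1e-4, dc_offset=0.05, rng_seed=1))
        out = process_frame(fr, spec)
        line, j = np.unravel_index(np.argmax(out.values), out.values.shape)
        j_true = round(2 * (8e-3 + deep_geom.pivot_standoff)
                       / spec.sound_speed * deep_geom.sample_rate)
        assert abs(int(j) - j_true) <= 1
        assert abs(int(line) - 62) <= 1  # the line whose axis passes closest

    def test_deterministic(self, spec, deep_geom):
        phantom = [Scatterer(position=(0.0, 8e-3))]
        fr = simulate_rf_frame(
            phantom, spec, deep_geom,
            SimulationConfig(noise_rms=1e-4, dc_offset=0.05, rng_seed=1))
        a = process_frame(fr, spec).values
        b = process_frame(fr, spec).values
        assert np.array_equal(a, b)

    def test_canonical_order_keeps_line_means_unbiased(self, spec, geom):
        # a DC-laden frame processed in canonical order has ~zero-mean
        # filtered RF; TGC first would grow the offset with depth instead
        t = np.arange(geom.samples_per_line) / geom.sample_rate
        rf = 0.3 * np.cos(2 * np.pi * spec.center_frequency * t) + 0.1
        fr = make_frame(geom, rf)
        canonical = apply_tgc(bandpass(remove_dc(fr), spec), 0.5, spec)
        rms = np.sqrt(np.mean(canonical.values**2))
        canonical_bias = np.abs(canonical.values.mean(axis=1)).max() / rms
        assert canonical_bias < 5e-3
        # swap: scale raw by the TGC curve, then remove DC per line
        z_cm = geom.sample_ranges(spec.sound_speed) * 100.0
        gain = 10 ** (np.minimum(
            2 * 0.5 * (spec.center_frequency / 1e6) * z_cm, 40.0) / 20.0)
        swapped = fr.samples * gain
        swapped -= swapped.mean(axis=1, keepdims=True)
        # depth-growing DC bias survives: deep half biased vs shallow half
        half = geom.samples_per_line // 2
        bias = np.abs(swapped[:, half:].mean() - swapped[:, :half].mean())
        bias /= np.sqrt(np.mean(swapped**2))
        assert bias > 20 * canonical_bias

    def test_pipeline_params_yaml_round_trip(self):
        params = PipelineParams(band_low=8e6, band_high=25e6,
                                normalization="sequence")
        assert PipelineParams.from_yaml_dict(params.to_yaml_dict()) == params
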