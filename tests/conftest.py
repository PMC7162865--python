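"""Shared fixtures.

The heavy in-silico acquisitions (mouse heart, aortic arch, radial artery,
wire phantom) are session-scoped so the M-mode and resolution tests reuse
one simulation each.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from memsus import (
    PipelineParams,
    ScanGeometry,
    TransducerSpec,
    make_preset,
    process_frame,
    process_sequence,
    scan_convert,
    simulate_sequence,
)
from memsus.config import derive_seed


@pytest.fixture(scope="session")
def spec() -> TransducerSpec:
    return TransducerSpec.default()


@pytest.fixture(scope="session")
def geom(spec) -> ScanGeometry:
    return ScanGeometry.default(spec)


@pytest.fixture(scope="session")
def deep_geom(spec) -> ScanGeometry:
    """4096-sample geometry whose window reaches past the focal range."""
    return ScanGeometry.default(spec, samples_per_line=4096)


@pytest.fixture(scope="session")
def wire_geom(spec) -> ScanGeometry:
    """Fine-sampling wire-characterization scan: slow 10 Hz sweep (500
    lines per frame) and a deep sampling window."""
    return ScanGeometry.default(spec, samples_per_line=4096,
                                mirror_frequency=10.0)


def _rate_images(preset: str, duration: float, spec, geom, seed: int = 42):
    phantom, sim = make_preset(preset, spec, geom)
    sim = replace(sim, rng_seed=derive_seed(seed, "simulate"))
    seq = simulate_sequence(phantom, spec, geom, sim, duration,
                            sweeps="forward")
    return process_sequence(seq, PipelineParams(normalization="sequence"))


@pytest.fixture(scope="session")
def mouse_heart_images(spec, geom):
    """10 s of displayed frames of the 3.7 Hz beating-walls phantom."""
    return _rate_images("mouse_heart", 10.0, spec, geom)


@pytest.fixture(scope="session")
def aortic_arch_images(spec, geom):
    """25 s of displayed frames of the 4.12 Hz pulsating-vessel phantom."""
    return _rate_images("aortic_arch", 25.0, spec, geom)


@pytest.fixture(scope="session")
def radial_artery_images(spec, geom):
    """10 s of displayed frames of the 1.1 Hz arterial phantom."""
    return _rate_images("radial_artery", 10.0, spec, geom)


@pytest.fixture(scope="session")
def wire_bmode(spec, wire_geom):
    """Wire phantom simulated, processed and converted at 10 um pitch."""
    phantom, sim = make_preset("wire", spec, wire_geom)
    sim = replace(sim, rng_seed=derive_seed(0, "resolution"))
    seq = simulate_sequence(phantom, spec, wire_geom, sim,
                            duration=1.0 / wire_geom.mirror_frequency,
                            sweeps="forward")
    polar = process_frame(seq.frames[0], spec)
    r_focus = spec.focal_length - wire_geom.pivot_standoff
    return scan_convert(polar, nx=240, nz=240, pixel_spacing=(10e-6, 10e-6),
                        z_start=r_focus - 1.2e-3,
                        sound_speed=spec.sound_speed)


def centroid_position(img, threshold_frac: float = 0.25):
    """Intensity-weighted blob centroid of a B-mode image, in m."""
    lin = 10.0 ** (img.pixels / 20.0) * img.valid_mask
    lin = np.where(lin > lin.max() * threshold_frac, lin, 0.0)
    xg, zg = np.meshgrid(img.x_axis, img.z_axis, indexing="ij")
    total = lin.sum()
    return float((lin * xg).sum() / total), float((lin * zg).sum() / total)
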