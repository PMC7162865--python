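"""Point-scatterer pulse-echo RF simulator.

Stands in for the pulser-receiver / digitizer hardware: given a phantom
(point scatterers, optionally moving), a transducer and a scan geometry it
produces raw RF frames with the statistical structure the reconstruction
chain assumes — a constant DC offset, band-limited echoes, depth-dependent
attenuation, and additive white Gaussian noise.

Forward model for one A-line fired at time t with beam angle theta::

    s(t') = sum_i a_i * p(t' - 2 R_i / c) * B(d_i, R_i)
                * 10^(-2 alpha f_c R_i / 20)  +  dc  +  n(t')

where ``R_i`` is the one-way path length from the transducer face to
scatterer i along the folded beam, ``d_i`` its perpendicular offset from
the beam axis, ``p`` the two-way Gaussian-cosine pulse, ``B`` a parametric
Gaussian lateral beam-sensitivity profile focused at the geometric focus,
``alpha`` the attenuation coefficient in dB/(cm MHz) (applied two-way),
and ``n`` white Gaussian noise.  Scatterer positions are evaluated at each
line's firing time, so fast motion produces realistic intra-frame skew.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .acoustics import (
    TransducerSpec,
    focal_zone_length,
    pulse_envelope_sigma,
    theoretical_resolution,
)
from .scan_geometry import ScanGeometry

__all__ = [
    "MotionModel",
    "Scatterer",
    "SimulationConfig",
    "RFFrame",
    "RFSequence",
    "simulate_rf_frame",
    "simulate_sequence",
    "make_preset",
    "PRESET_NAMES",
    "synthetic_mmode_matrix",
]


@dataclass(frozen=True)
class MotionModel:
    """Periodic displacement of a scatterer, plus optional aperiodic events.

    kind
        ``sinusoidal`` — pure tone displacement A sin(2 pi f t + phase);
        ``pulse_train`` — periodic raised-cosine excursions of duty cycle
        0.3 (systole-like: a fast excursion then a long rest).
    irregular_events
        List of ``(time_s, extra_displacement_m)`` transients (e.g.
        respiration); each is a Gaussian bump of 0.15 s temporal sigma
        along the motion axis.
    """

    kind: str = "sinusoidal"
    frequency: float = 1.0
    amplitude: float = 0.0
    axis: tuple[float, float] = (0.0, 1.0)
    phase: float = 0.0
    irregular_events: tuple[tuple[float, float], ...] = ()
    duty: float = 0.3
    event_sigma: float = 0.15

    def __post_init__(self) -> None:
        if self.kind not in ("sinusoidal", "pulse_train"):
            raise ValueError(f"unknown motion kind {self.kind!r}")
        if self.frequency <= 0:
            raise ValueError("frequency must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")
        norm = math.hypot(*self.axis)
        if norm == 0:
            raise ValueError("axis must be a non-zero vector")
        object.__setattr__(self, "axis", (self.axis[0] / norm, self.axis[1] / norm))
        object.__setattr__(
            self, "irregular_events", tuple(map(tuple, self.irregular_events))
        )

    def displacement(self, t) -> tuple[np.ndarray, np.ndarray]:
        """(dx, dz) displacement in m at time(s) t."""
        t = np.asarray(t, dtype=float)
        if self.kind == "sinusoidal":
            u = self.amplitude * np.sin(
                2.0 * np.pi * self.frequency * t + self.phase
            )
        else:  # pulse_train
            frac = np.mod(self.frequency * t + self.phase / (2.0 * np.pi), 1.0)
            u = np.where(
                frac < self.duty,
                0.5 * self.amplitude * (1.0 - np.cos(2.0 * np.pi * frac / self.duty)),
                0.0,
            )
        for t_ev, extra in self.irregular_events:
            u = u + extra * np.exp(-((t - t_ev) ** 2) / (2.0 * self.event_sigma**2))
        return u * self.axis[0], u * self.axis[1]


@dataclass(frozen=True)
class Scatterer:
    """Idealized point reflector in sector coordinates (x lateral, z depth)."""

    position: tuple[float, float]
    reflectivity: float = 1.0
    motion: MotionModel | None = None

    def __post_init__(self) -> None:
        if self.reflectivity < 0:
            raise ValueError("reflectivity must be non-negative")

    def position_at(self, t):
        """(x, z) at time(s) t, broadcasting over t."""
        x0, z0 = self.position
        if self.motion is None:
            t = np.asarray(t, dtype=float)
            return np.broadcast_to(x0, t.shape).copy(), np.broadcast_to(
                z0, t.shape
            ).copy()
        dx, dz = self.motion.displacement(t)
        return x0 + dx, z0 + dz


@dataclass(frozen=True)
class SimulationConfig:
    """Medium and digitizer model.

    attenuation_coeff
        dB/(cm MHz), applied two-way; 0.5 is a soft-tissue default.
    noise_rms
        RMS of the additive white Gaussian RF noise (digitizer-referred,
        arbitrary amplitude units shared with reflectivity).
    dc_offset
        Constant offset added to every sample.
    beam_waist_scale
        Multiplies the -6 dB focal beam width of the parametric beam model;
        1.0 reproduces the diffraction estimate lambda F / D.
    """

    attenuation_coeff: float = 0.5
    noise_rms: float = 0.05
    dc_offset: float = 0.05
    beam_waist_scale: float = 1.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.attenuation_coeff < 0:
            raise ValueError("attenuation_coeff must be non-negative")
        if self.noise_rms < 0:
            raise ValueError("noise_rms must be non-negative")

    def to_yaml_dict(self) -> dict:
        return {
            "attenuation_db_cm_mhz": self.attenuation_coeff,
            "noise_rms": self.noise_rms,
            "dc_offset": self.dc_offset,
            "beam_waist_scale": self.beam_waist_scale,
            "rng_seed": self.rng_seed,
        }

    @classmethod
    def from_yaml_dict(cls, block: dict) -> "SimulationConfig":
        return cls(
            attenuation_coeff=block.get("attenuation_db_cm_mhz", 0.5),
            noise_rms=block.get("noise_rms", 0.05),
            dc_offset=block.get("dc_offset", 0.05),
            beam_waist_scale=block.get("beam_waist_scale", 1.0),
            rng_seed=int(block.get("rng_seed", 0)),
        )


@dataclass
class RFFrame:
    """One sweep of raw RF data: lines x samples."""

    samples: np.ndarray
    geometry: ScanGeometry
    timestamp: float
    frame_index: int
    excluded_scatterers: int = 0

    def __post_init__(self) -> None:
        expected = (self.geometry.lines_per_frame, self.geometry.samples_per_line)
        if self.samples.shape != expected:
            raise ValueError(
                f"samples shape {self.samples.shape} does not match geometry "
                f"{expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("RF samples must be finite")

    @property
    def angles(self) -> np.ndarray:
        return self.geometry.line_angles(self.frame_index)

    @property
    def is_forward(self) -> bool:
        return self.geometry.is_forward(self.frame_index)


@dataclass
class RFSequence:
    """A time-ordered list of RF sweep frames sharing one configuration."""

    frames: list[RFFrame]
    geometry: ScanGeometry
    spec: TransducerSpec
    sim: SimulationConfig

    def __len__(self) -> int:
        return len(self.frames)

    def forward_frames(self) -> list[RFFrame]:
        """Frames of the displayed (forward) sweep direction, at the
        mirror frequency."""
        return [f for f in self.frames if f.is_forward]


def _beam_width(spec: TransducerSpec, sim: SimulationConfig, rng: np.ndarray):
    """-6 dB two-way lateral beam width (m) vs one-way path length."""
    lat, _ = theoretical_resolution(spec)
    fz = focal_zone_length(spec)
    w_focus = sim.beam_waist_scale * lat
    return w_focus * (1.0 + np.abs(rng - spec.focal_length) / fz)


def simulate_rf_frame(
    phantom: list[Scatterer],
    spec: TransducerSpec,
    geom: ScanGeometry,
    sim: SimulationConfig,
    t0: float = 0.0,
    frame_index: int = 0,
) -> RFFrame:
    """Simulate one sweep frame of raw RF.

    ``t0`` is the firing time of the frame's first line; pass
    ``frame_index * geom.sweep_period`` to keep phase with the resonant
    sweep.  Noise is reproducible: it derives from
    ``(sim.rng_seed, frame_index)`` only.

    Scatterers behind the mirror plane (z <= 0 at firing time) are excluded
    and counted in ``RFFrame.excluded_scatterers``.
    """
    n_lines = geom.lines_per_frame
    n_samp = geom.samples_per_line
    c = spec.sound_speed
    fs = geom.sample_rate
    t_lines = t0 + np.arange(n_lines) / geom.prf
    theta = geom.angle_at(t_lines)

    rng = np.random.default_rng([int(sim.rng_seed), int(frame_index)])
    if sim.noise_rms > 0:
        frame = rng.standard_normal((n_lines, n_samp)) * sim.noise_rms
    else:
        frame = np.zeros((n_lines, n_samp))
    frame += sim.dc_offset

    sigma_t = pulse_envelope_sigma(spec)
    half_window = int(math.ceil(4.5 * sigma_t * fs))
    win = np.arange(2 * half_window + 1)
    line_idx = np.arange(n_lines)[:, None]
    alpha = sim.attenuation_coeff * spec.center_frequency / 1e6  # dB/cm
    excluded = 0

    for sc in phantom:
        if sc.reflectivity == 0:
            continue
        sx, sz = sc.position_at(t_lines)
        behind = sz <= 0
        if np.any(behind):
            excluded += int(np.any(behind))
        r = np.hypot(sx, sz)  # radial distance from the apex
        R = r + geom.pivot_standoff  # one-way path from transducer face
        phi = np.arctan2(sx, sz)
        d = r * np.sin(phi - theta)  # perpendicular offset from beam axis
        w = _beam_width(spec, sim, R)
        sigma_b = w / (2.0 * math.sqrt(2.0 * math.log(2.0)))
        amp = (
            sc.reflectivity
            * np.exp(-(d**2) / (2.0 * sigma_b**2))
            * 10.0 ** (-2.0 * alpha * (R * 100.0) / 20.0)
        )
        amp = np.where(behind, 0.0, amp)

        tau = 2.0 * R / c  # echo round-trip time, s
        j0 = np.round(tau * fs).astype(int) - half_window
        idx = j0[:, None] + win  # (n_lines, window)
        t_rel = idx / fs - tau[:, None]
        echo = (
            amp[:, None]
            * np.cos(2.0 * np.pi * spec.center_frequency * t_rel)
            * np.exp(-(t_rel**2) / (2.0 * sigma_t**2))
        )
        valid = (idx >= 0) & (idx < n_samp)
        np.add.at(frame, (np.broadcast_to(line_idx, idx.shape)[valid],
                          idx[valid]), echo[valid])

    return RFFrame(
        samples=frame,
        geometry=geom,
        timestamp=t0,
        frame_index=frame_index,
        excluded_scatterers=excluded,
    )


def simulate_sequence(
    phantom: list[Scatterer],
    spec: TransducerSpec,
    geom: ScanGeometry,
    sim: SimulationConfig,
    duration: float,
    sweeps: str = "both",
) -> RFSequence:
    """Simulate ``floor(duration * 2 * mirror_frequency)`` sweep frames.

    Per-line firing times are exact, so periodic motion is coherently
    sampled across frames.  ``sweeps='forward'`` simulates only the
    displayed (forward) sweeps — half the frames at the mirror frequency —
    with frame indices and timestamps identical to the corresponding
    frames of a full simulation.
    """
    if duration < 1.0 / geom.mirror_frequency:
        raise ValueError("duration must cover at least one mirror period")
    if sweeps not in ("both", "forward"):
        raise ValueError("sweeps must be 'both' or 'forward'")
    n_sweeps = int(math.floor(duration * 2.0 * geom.mirror_frequency))
    indices = range(n_sweeps)
    if sweeps == "forward":
        indices = [m for m in indices if geom.is_forward(m)]
    frames = [
        simulate_rf_frame(
            phantom, spec, geom, sim, t0=m * geom.sweep_period, frame_index=m
        )
        for m in indices
    ]
    return RFSequence(frames=frames, geometry=geom, spec=spec, sim=sim)


# ---------------------------------------------------------------------------
# Presets emulating the platform's characterization and in-vivo experiments.
# ---------------------------------------------------------------------------

PRESET_NAMES = (
    "wire",
    "leaf",
    "mouse_heart",
    "aortic_arch",
    "radial_artery",
    "wrist_compression",
)

# Echoes at 16.7 MHz lose ~25 dB over a 1.5 cm two-way path at
# 0.5 dB/(cm MHz); wall reflectivities are scaled so the raw echo-to-noise
# ratio at the target is ~20 dB with the default noise floor.
_WALL_REFLECTIVITY = 12.0


def _wall(z0: float, motion: MotionModel | None, n: int = 7,
          pitch: float = 0.5e-3, reflectivity: float = _WALL_REFLECTIVITY):
    """A short horizontal line of scatterers emulating a tissue interface."""
    xs = (np.arange(n) - (n - 1) / 2) * pitch
    return [
        Scatterer(position=(float(x), z0), reflectivity=reflectivity,
                  motion=motion)
        for x in xs
    ]


def make_preset(
    name: str,
    spec: TransducerSpec | None = None,
    geom: ScanGeometry | None = None,
) -> tuple[list[Scatterer], SimulationConfig]:
    """Deterministic phantom + simulation config for a named experiment.

    wire
        Single point target at the focal range on axis (50 um tungsten
        wire; below both resolutions, modeled as an ideal point).
    leaf
        Curved planar mesh of scatterers (leaf-skeleton stand-in).
    mouse_heart
        Two myocardial walls 3 mm apart pulsing in antiphase at 3.7 Hz
        (222 bpm under anesthesia) with a respiration transient at 3 s.
    aortic_arch
        Vessel wall pair pulsing at 4.12 Hz (247 bpm) with respiration
        transients at 1.8 s and 5 s.
    radial_artery
        Arterial wall pair with diameter modulation at 1.1 Hz (66 bpm).
    wrist_compression
        Radial artery plus a vein whose walls collapse under a slow
        compression schedule.
    """
    if spec is None:
        spec = TransducerSpec.default()
    if geom is None:
        geom = ScanGeometry.default(spec)

    sim = SimulationConfig(rng_seed=0)
    r_focus = spec.focal_length - geom.pivot_standoff

    if name == "wire":
        # Characterization scan: low noise floor so the point target stays
        # isolated after the ~36 dB of TGC gain at the focal range.
        phantom = [Scatterer(position=(0.0, r_focus), reflectivity=1.0)]
        sim = replace(sim, noise_rms=5e-4, dc_offset=0.05)
    elif name == "leaf":
        xs = np.linspace(-5e-3, 5e-3, 41)
        zs = 3.0e-3 + 1.2e-3 * np.cos(xs / 5e-3 * np.pi / 2.0)
        phantom = [
            Scatterer(position=(float(x), float(z)),
                      reflectivity=_WALL_REFLECTIVITY)
            for x, z in zip(xs, zs)
        ]
    elif name == "mouse_heart":
        resp = ((3.0, 0.4e-3),)
        anterior = MotionModel(
            kind="pulse_train", frequency=3.7, amplitude=0.5e-3,
            axis=(0.0, 1.0), irregular_events=resp,
        )
        posterior = MotionModel(
            kind="pulse_train", frequency=3.7, amplitude=0.5e-3,
            axis=(0.0, -1.0), irregular_events=resp,
        )
        phantom = _wall(2.0e-3, anterior) + _wall(5.0e-3, posterior)
    elif name == "aortic_arch":
        resp = ((1.8, 0.3e-3), (5.0, 0.3e-3))
        upper = MotionModel(
            kind="pulse_train", frequency=4.12, amplitude=0.4e-3,
            axis=(0.0, 1.0), irregular_events=resp,
        )
        lower = MotionModel(
            kind="pulse_train", frequency=4.12, amplitude=0.4e-3,
            axis=(0.0, -1.0), irregular_events=resp,
        )
        phantom = _wall(2.5e-3, upper) + _wall(4.3e-3, lower)
    elif name == "radial_artery":
        anterior = MotionModel(
            kind="pulse_train", frequency=1.1, amplitude=0.3e-3,
            axis=(0.0, 1.0),
        )
        posterior = MotionModel(
            kind="pulse_train", frequency=1.1, amplitude=0.3e-3,
            axis=(0.0, -1.0),
        )
        phantom = _wall(2.5e-3, anterior) + _wall(4.5e-3, posterior)
    elif name == "wrist_compression":
        artery_a = MotionModel(
            kind="pulse_train", frequency=1.1, amplitude=0.3e-3, axis=(0.0, 1.0)
        )
        artery_p = MotionModel(
            kind="pulse_train", frequency=1.1, amplitude=0.3e-3, axis=(0.0, -1.0)
        )
        # Vein walls close under a slow 0.2 Hz compress/relax schedule.
        vein_a = MotionModel(
            kind="pulse_train", frequency=0.2, amplitude=0.7e-3,
            axis=(0.0, 1.0), duty=0.5,
        )
        vein_p = MotionModel(
            kind="pulse_train", frequency=0.2, amplitude=0.7e-3,
            axis=(0.0, -1.0), duty=0.5,
        )
        phantom = (
            _wall(2.5e-3, artery_a, n=5, pitch=0.4e-3)
            + _wall(4.0e-3, artery_p, n=5, pitch=0.4e-3)
            + [
                Scatterer(position=(3.5e-3, 2.2e-3),
                          reflectivity=_WALL_REFLECTIVITY, motion=vein_a),
                Scatterer(position=(3.5e-3, 3.8e-3),
                          reflectivity=_WALL_REFLECTIVITY, motion=vein_p),
            ]
        )
    else:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(PRESET_NAMES)}"
        )
    return phantom, sim


def synthetic_mmode_matrix(
    frequency: float,
    duration: float,
    frame_rate: float = 40.0,
    depth_span: float = 4e-3,
    n_depth: int = 200,
    ridge_depth: float = 2e-3,
    excursion: float = 0.5e-3,
    ridge_sigma: float = 60e-6,
    noise_rms: float = 0.05,
    motion_kind: str = "pulse_train",
    irregular_events: tuple[tuple[float, float], ...] = (),
    seed: int = 0,
    dynamic_range: float = 40.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Directly synthesized log-compressed M-mode matrix (time x depth).

    A single Gaussian echo ridge moves according to a :class:`MotionModel`;
    white noise is added in the linear envelope domain before log
    compression.  Used to exercise the rate estimator across frequencies
    and seeds without running the full RF chain.

    Returns (values_db, depth_axis_m).
    """
    motion = MotionModel(
        kind=motion_kind, frequency=frequency, amplitude=excursion,
        axis=(0.0, 1.0), irregular_events=irregular_events,
    )
    n_t = int(round(duration * frame_rate))
    t = np.arange(n_t) / frame_rate
    _, dz = motion.displacement(t)
    depth = np.linspace(0.0, depth_span, n_depth)
    ridge = ridge_depth + dz
    env = np.exp(-((depth[None, :] - ridge[:, None]) ** 2)
                 / (2.0 * ridge_sigma**2))
    rng = np.random.default_rng(seed)
    env = np.abs(env + noise_rms * rng.standard_normal(env.shape))
    peak = env.max()
    values = 20.0 * np.log10(np.maximum(env, peak * 10.0 ** (-dynamic_range / 20.0 - 2)) / peak)
    return np.maximum(values, -dynamic_range), depth
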