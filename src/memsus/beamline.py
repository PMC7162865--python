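"""Per-frame RF processing chain.

Raw RF sweeps are turned into display-ready polar images in a fixed order:

    raw -> DC removal -> band-pass -> TGC -> envelope -> log compression

Each stage is a pure function from :class:`PolarImage` to
:class:`PolarImage`; stage tags are enforced so the chain cannot be run out
of order (TGC before DC removal, for instance, would turn the DC offset
into a depth-growing bias).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
from scipy import signal

from .acoustics import TransducerSpec
from .phantom_sim import RFFrame, RFSequence
from .scan_geometry import ScanGeometry

__all__ = [
    "PolarImage",
    "PipelineParams",
    "remove_dc",
    "bandpass",
    "apply_tgc",
    "envelope",
    "log_compress",
    "process_frame",
    "process_sequence",
]

STAGES = ("raw", "dc_removed", "filtered", "tgc", "envelope", "log")


@dataclass
class PolarImage:
    """Lines x samples image in beam (angle, range) coordinates.

    ``values`` hold RF amplitude up to the ``envelope`` stage and dB in
    [-dynamic_range, 0] after log compression.
    """

    values: np.ndarray
    stage: str
    geometry: ScanGeometry
    frame_index: int = 0
    timestamp: float = 0.0
    dynamic_range: float | None = None

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")

    @property
    def angles(self) -> np.ndarray:
        return self.geometry.line_angles(self.frame_index)

    @property
    def is_forward(self) -> bool:
        return self.geometry.is_forward(self.frame_index)

    def _advance(self, values: np.ndarray, stage: str, **kw) -> "PolarImage":
        out = dc_replace(self, **kw)
        out.values = values
        out.stage = stage
        return out


def _require_stage(img: PolarImage, allowed: tuple[str, ...], op: str) -> None:
    if img.stage not in allowed:
        raise ValueError(
            f"{op} expects stage in {allowed}, got {img.stage!r}; the chain "
            "must run in pipeline order"
        )


@dataclass(frozen=True)
class PipelineParams:
    """Tunables of the processing chain (``pipeline:`` YAML block).

    Band edges default to f_c (1 +/- fractional bandwidth); TGC gain is the
    exact inverse of the simulator's two-way attenuation model, clipped at
    ``tgc_max_db``; ``normalization`` chooses whether log compression
    references the per-frame maximum (real-time display) or a
    sequence-global maximum (M-mode consistency).
    """

    band_low: float | None = None
    band_high: float | None = None
    tgc_db_per_cm_mhz: float = 0.5
    tgc_max_db: float = 40.0
    dynamic_range_db: float = 40.0
    normalization: str = "frame"

    def __post_init__(self) -> None:
        if self.normalization not in ("frame", "sequence"):
            raise ValueError("normalization must be 'frame' or 'sequence'")
        if self.dynamic_range_db <= 0:
            raise ValueError("dynamic_range_db must be positive")

    def band_edges(self, spec: TransducerSpec) -> tuple[float, float]:
        low = self.band_low
        high = self.band_high
        if low is None:
            low = spec.center_frequency * (1.0 - spec.fractional_bandwidth)
        if high is None:
            high = spec.center_frequency * (1.0 + spec.fractional_bandwidth)
        return low, high

    def to_yaml_dict(self) -> dict:
        return {
            "band_low_mhz": None if self.band_low is None else self.band_low / 1e6,
            "band_high_mhz": None if self.band_high is None else self.band_high / 1e6,
            "tgc_db_per_cm_mhz": self.tgc_db_per_cm_mhz,
            "tgc_max_db": self.tgc_max_db,
            "dynamic_range_db": self.dynamic_range_db,
            "normalization": self.normalization,
        }

    @classmethod
    def from_yaml_dict(cls, block: dict) -> "PipelineParams":
        known = {
            "band_low_mhz", "band_high_mhz", "tgc_db_per_cm_mhz",
            "tgc_max_db", "dynamic_range_db", "normalization",
        }
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown pipeline keys: {sorted(unknown)}")
        low = block.get("band_low_mhz")
        high = block.get("band_high_mhz")
        return cls(
            band_low=None if low is None else low * 1e6,
            band_high=None if high is None else high * 1e6,
            tgc_db_per_cm_mhz=block.get("tgc_db_per_cm_mhz", 0.5),
            tgc_max_db=block.get("tgc_max_db", 40.0),
            dynamic_range_db=block.get("dynamic_range_db", 40.0),
            normalization=block.get("normalization", "frame"),
        )


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def remove_dc(frame: RFFrame) -> PolarImage:
    """Subtract each A-line's own mean (the digitizer DC offset)."""
    values = frame.samples - frame.samples.mean(axis=1, keepdims=True)
    return PolarImage(
        values=values,
        stage="dc_removed",
        geometry=frame.geometry,
        frame_index=frame.frame_index,
        timestamp=frame.timestamp,
    )


def _bandpass_sos(low: float, high: float, fs: float):
    if not 0.0 < low < high < fs / 2.0:
        raise ValueError(
            f"band [{low:g}, {high:g}] Hz must satisfy 0 < low < high < "
            f"Nyquist ({fs / 2:g} Hz)"
        )
    # Order-6 Butterworth applied forward-backward: ~72 dB/octave per edge
    # after the zero-phase double pass, comfortably past 40 dB at 0.5*low
    # and 1.5*high.
    return signal.butter(6, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass(
    img: PolarImage,
    spec: TransducerSpec,
    low: float | None = None,
    high: float | None = None,
) -> PolarImage:
    """Zero-phase band-pass along the sample axis.

    Default edges f_c (1 +/- fractional bandwidth).  Zero-phase
    (forward-backward) application keeps echo arrival times unshifted.
    """
    _require_stage(img, ("dc_removed",), "bandpass")
    if low is None:
        low = spec.center_frequency * (1.0 - spec.fractional_bandwidth)
    if high is None:
        high = spec.center_frequency * (1.0 + spec.fractional_bandwidth)
    sos = _bandpass_sos(low, high, img.geometry.sample_rate)
    values = signal.sosfiltfilt(sos, img.values, axis=1)
    return img._advance(values, "filtered")


def apply_tgc(
    img: PolarImage,
    attenuation_coeff: float,
    spec: TransducerSpec,
    max_gain: float = 40.0,
) -> PolarImage:
    """Time gain compensation: undo two-way tissue attenuation vs depth.

    Sample j (one-way path z_j) is amplified by
    10^(2 * alpha * f_c[MHz] * z_j[cm] / 20) dB, clipped at ``max_gain``.
    """
    _require_stage(img, ("filtered",), "apply_tgc")
    if attenuation_coeff < 0:
        raise ValueError("attenuation_coeff must be non-negative")
    z_cm = img.geometry.sample_ranges(spec.sound_speed) * 100.0
    gain_db = 2.0 * attenuation_coeff * (spec.center_frequency / 1e6) * z_cm
    gain_db = np.minimum(gain_db, max_gain)
    values = img.values * 10.0 ** (gain_db / 20.0)[None, :]
    return img._advance(values, "tgc")


def envelope(img: PolarImage, spec: TransducerSpec) -> PolarImage:
    """Envelope via quadrature demodulation at the carrier frequency.

    Each line is mixed with a complex carrier at f_c, low-pass filtered
    (zero-phase Butterworth) and the magnitude doubled.  Agrees with the
    analytic-signal (Hilbert) envelope to well under 2 % RMS for
    band-limited echoes.
    """
    _require_stage(img, ("tgc",), "envelope")
    fs = img.geometry.sample_rate
    fc = spec.center_frequency
    t = np.arange(img.geometry.samples_per_line) / fs
    mixed = img.values * np.exp(-2j * np.pi * fc * t)[None, :]
    cutoff = min(1.25 * spec.fractional_bandwidth * fc, 0.75 * fc)
    sos = signal.butter(5, cutoff, btype="lowpass", fs=fs, output="sos")
    baseband = signal.sosfiltfilt(sos, mixed, axis=1)
    values = 2.0 * np.abs(baseband)
    return img._advance(values, "envelope")


def log_compress(
    img: PolarImage,
    dynamic_range: float = 40.0,
    reference: float | None = None,
) -> PolarImage:
    """Map envelope to dB relative to the frame (or supplied) maximum.

    out = max(20 log10(env / ref), -dynamic_range); the reference maps to
    0 dB.  An all-zero frame returns the display floor everywhere.
    """
    _require_stage(img, ("envelope",), "log_compress")
    if dynamic_range <= 0:
        raise ValueError("dynamic_range must be positive")
    env = img.values
    ref = float(env.max()) if reference is None else float(reference)
    if ref <= 0:
        warnings.warn("all-zero envelope; returning the display floor")
        values = np.full_like(env, -dynamic_range)
    else:
        with np.errstate(divide="ignore"):
            values = 20.0 * np.log10(env / ref)
        values = np.clip(values, -dynamic_range, 0.0)
    return img._advance(values, "log", dynamic_range=dynamic_range)


def process_frame(
    frame: RFFrame,
    spec: TransducerSpec,
    params: PipelineParams | None = None,
    reference: float | None = None,
) -> PolarImage:
    """Run the full chain on one frame, returning the log-stage image."""
    if params is None:
        params = PipelineParams()
    low, high = params.band_edges(spec)
    img = remove_dc(frame)
    img = bandpass(img, spec, low, high)
    img = apply_tgc(img, params.tgc_db_per_cm_mhz, spec, params.tgc_max_db)
    img = envelope(img, spec)
    return log_compress(img, params.dynamic_range_db, reference=reference)


def process_sequence(
    seq: RFSequence,
    params: PipelineParams | None = None,
    sweeps: str = "forward",
) -> list[PolarImage]:
    """Process a sequence into log-stage polar images.

    ``sweeps='forward'`` keeps only displayed (forward) frames, giving one
    image per mirror period.  With ``normalization='sequence'`` the log
    stage references the global envelope maximum so M-mode traces are not
    modulated by per-frame normalization.
    """
    if params is None:
        params = PipelineParams()
    frames = seq.forward_frames() if sweeps == "forward" else seq.frames
    low, high = params.band_edges(seq.spec)
    envs = []
    for frame in frames:
        img = remove_dc(frame)
        img = bandpass(img, seq.spec, low, high)
        img = apply_tgc(img, params.tgc_db_per_cm_mhz, seq.spec,
                        params.tgc_max_db)
        env = envelope(img, seq.spec)
        env.values = env.values.astype(np.float32)  # bound sequence memory
        envs.append(env)
    reference = None
    if params.normalization == "sequence" and envs:
        reference = max(float(e.values.max()) for e in envs)
    return [log_compress(e, params.dynamic_range_db, reference=reference)
            for e in envs]
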