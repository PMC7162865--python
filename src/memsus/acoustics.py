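"""Transducer physics for a spherically focused single-element probe.

The transducer is described by its center frequency ``f``, circular aperture
diameter ``D``, geometric focal length ``F``, two-way (pulse-echo) -6 dB
fractional bandwidth, and the sound speed ``c`` of the coupling medium.
From these the module derives the classical single-element quantities:

* near-field (natural focus) length  ``N = D^2 f / (4 c)``
* focal-zone (depth-of-focus) length ``F_Z = N (F/N)^2 [2 / (1 + 0.5 F/N)]``
* diffraction-limit resolution estimates (lateral ``lambda F / D``, axial
  ``c / (2 f B)`` with ``B`` the fractional bandwidth)
* a Gaussian-enveloped cosine pulse model whose -6 dB spectral width
  matches the requested fractional bandwidth.

All computation is in SI units (m, s, Hz); YAML serialization uses the
human-scale units conventional on transducer data sheets (MHz, mm, %).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "TransducerSpec",
    "near_field_length",
    "focal_zone_length",
    "theoretical_resolution",
    "pulse_waveform",
    "pulse_envelope_sigma",
]

#: Conventional soft-tissue sound speed (m/s); used when a medium does not
#: specify its own value.
SOFT_TISSUE_SOUND_SPEED = 1540.0


@dataclass(frozen=True)
class TransducerSpec:
    """Physical description of a focused single-element transducer.

    Parameters
    ----------
    center_frequency : float
        Center frequency ``f`` in Hz.
    aperture_diameter : float
        Active element diameter ``D`` in m.
    focal_length : float
        Geometric focal length ``F`` in m.
    fractional_bandwidth : float
        Two-way (pulse-echo) -6 dB fractional bandwidth, dimensionless
        (e.g. 0.517 for 51.7 %).
    sound_speed : float
        Medium sound speed ``c`` in m/s.  Defaults to 1540 m/s.
    """

    center_frequency: float
    aperture_diameter: float
    focal_length: float
    fractional_bandwidth: float
    sound_speed: float = SOFT_TISSUE_SOUND_SPEED

    def __post_init__(self) -> None:
        for name in (
            "center_frequency",
            "aperture_diameter",
            "focal_length",
            "fractional_bandwidth",
            "sound_speed",
        ):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if not 0.0 < self.fractional_bandwidth < 2.0:
            raise ValueError(
                "fractional_bandwidth must lie in (0, 2), got "
                f"{self.fractional_bandwidth!r}"
            )
        if not self.focal_length > self.aperture_diameter / 2:
            raise ValueError(
                "focal_length must exceed aperture_diameter/2 for a realizable "
                "spherical focus"
            )

    @property
    def wavelength(self) -> float:
        """Carrier wavelength ``c / f`` in m."""
        return self.sound_speed / self.center_frequency

    def with_sound_speed(self, sound_speed: float) -> "TransducerSpec":
        return replace(self, sound_speed=sound_speed)

    # -- YAML (de)serialization -------------------------------------------
    def to_yaml_dict(self) -> dict:
        """Human-readable ``transducer:`` block (MHz / mm / %)."""
        return {
            "center_frequency_mhz": self.center_frequency / 1e6,
            "aperture_diameter_mm": self.aperture_diameter * 1e3,
            "focal_length_mm": self.focal_length * 1e3,
            "fractional_bandwidth_pct": self.fractional_bandwidth * 100.0,
            "bandwidth_convention": "two-way",
            "sound_speed_m_s": self.sound_speed,
        }

    @classmethod
    def from_yaml_dict(cls, block: dict) -> "TransducerSpec":
        known = {
            "center_frequency_mhz",
            "aperture_diameter_mm",
            "focal_length_mm",
            "fractional_bandwidth_pct",
            "bandwidth_convention",
            "sound_speed_m_s",
        }
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown transducer keys: {sorted(unknown)}")
        return cls(
            center_frequency=block["center_frequency_mhz"] * 1e6,
            aperture_diameter=block["aperture_diameter_mm"] / 1e3,
            focal_length=block["focal_length_mm"] / 1e3,
            fractional_bandwidth=block["fractional_bandwidth_pct"] / 100.0,
            sound_speed=block.get("sound_speed_m_s", SOFT_TISSUE_SOUND_SPEED),
        )

    @classmethod
    def default(cls) -> "TransducerSpec":
        """The toolkit's reference 16.7 MHz LiNbO3 probe."""
        return cls(
            center_frequency=16.7e6,
            aperture_diameter=9e-3,
            focal_length=21.8e-3,
            fractional_bandwidth=0.517,
        )


def near_field_length(spec: TransducerSpec) -> float:
    """Near-field (natural focus) length ``N = D^2 f / (4 c)`` in m."""
    return spec.aperture_diameter**2 * spec.center_frequency / (4.0 * spec.sound_speed)


def focal_zone_length(spec: TransducerSpec) -> float:
    """Depth-of-focus ``F_Z = N (F/N)^2 [2 / (1 + 0.5 (F/N))]`` in m.

    ``N`` is the near-field length and ``F`` the geometric focal length.
    For the reference probe this evaluates to 4.1 mm.
    """
    n = near_field_length(spec)
    sf = spec.focal_length / n
    return n * sf**2 * (2.0 / (1.0 + 0.5 * sf))


def theoretical_resolution(spec: TransducerSpec) -> tuple[float, float]:
    """Diffraction-limit (lateral, axial) resolution estimates in m.

    lateral = lambda * F / D, the -6 dB beam width at the geometric focus;
    axial = c / (2 f B), the envelope length set by the pulse bandwidth.
    """
    lateral = spec.wavelength * spec.focal_length / spec.aperture_diameter
    axial = spec.sound_speed / (
        2.0 * spec.center_frequency * spec.fractional_bandwidth
    )
    return lateral, axial


def pulse_envelope_sigma(spec: TransducerSpec) -> float:
    """Temporal sigma (s) of the Gaussian pulse envelope.

    A Gaussian envelope exp(-t^2 / 2 sigma_t^2) has amplitude spectrum
    exp(-(f - f_c)^2 / 2 sigma_f^2) with sigma_f = 1 / (2 pi sigma_t); its
    -6 dB (half-amplitude) full spectral width is 2 sigma_f sqrt(2 ln 2).
    Setting that width to B * f_c gives sigma_t.
    """
    sigma_f = spec.fractional_bandwidth * spec.center_frequency / (
        2.0 * math.sqrt(2.0 * math.log(2.0))
    )
    return 1.0 / (2.0 * math.pi * sigma_f)


def pulse_waveform(
    spec: TransducerSpec,
    sample_rate: float,
    duration: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sampled two-way (pulse-echo) excitation pulse.

    Gaussian-enveloped cosine at the center frequency, zero carrier phase at
    the envelope peak, peak amplitude exactly 1.  The -6 dB full width of its
    amplitude spectrum equals ``fractional_bandwidth * center_frequency``.

    Parameters
    ----------
    sample_rate : float
        Must be at least 4x the center frequency.
    duration : float, optional
        Window length in s; defaults to 9 envelope sigmas (amplitude at the
        window edge below 0.004 % of peak).

    Returns
    -------
    (t, p) : tuple of ndarray
        Time axis (s, envelope peak at t = 0) and amplitude series.
    """
    if sample_rate < 4.0 * spec.center_frequency:
        raise ValueError(
            "sample_rate must be >= 4x center_frequency to sample the carrier "
            f"(got {sample_rate:g} Hz for f_c = {spec.center_frequency:g} Hz)"
        )
    sigma_t = pulse_envelope_sigma(spec)
    if duration is None:
        duration = 9.0 * sigma_t
    n = max(int(round(duration * sample_rate)), 3)
    # Grid contains t = 0 exactly so the unit peak is hit exactly.
    t = (np.arange(n) - n // 2) / sample_rate
    p = np.cos(2.0 * np.pi * spec.center_frequency * t) * np.exp(
        -(t**2) / (2.0 * sigma_t**2)
    )
    return t, p
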