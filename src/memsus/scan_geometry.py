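"""Geometry of the 45-degree-folded, resonantly swept acoustic path.

The transducer fires along a fixed axis onto a resonant scanning mirror
whose rest pose folds the beam by 90 degrees (45 degrees between beam and
mirror).  A mechanical mirror tilt of ``delta`` about the rest pose rotates
the reflected beam by ``2 delta`` (law of reflection), so a sinusoidal
mechanical oscillation of amplitude ``delta_max`` sweeps the beam over
``+/- 2 delta_max`` about the nominal folded axis.

Conventions
-----------
* The sector apex is the mirror pivot.  ``x`` is lateral (scan direction,
  positive toward increasing beam angle), ``z`` is depth away from the
  mirror; both in m.  Line and sample indices are 0-based.
* ``range`` is the one-way acoustic path length from the transducer face,
  i.e. pivot_standoff + radial distance from the apex.
* One frame is one half oscillation of the mirror (one sweep).  Even frame
  indices sweep forward (angle increasing), odd ones backward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .acoustics import SOFT_TISSUE_SOUND_SPEED, TransducerSpec

__all__ = ["ScanGeometry", "lines_per_frame"]


def lines_per_frame(prf: float, mirror_frequency: float) -> int:
    """Number of A-lines fired during one half oscillation of the mirror.

    floor(prf / (2 * mirror_frequency)); e.g. a 10 kHz PRF against a 40 Hz
    resonant mirror yields 125 lines per sweep.
    """
    if prf <= 0 or mirror_frequency <= 0:
        raise ValueError("prf and mirror_frequency must be positive")
    n = math.floor(prf / (2.0 * mirror_frequency))
    if n < 1:
        raise ValueError(
            f"PRF {prf:g} Hz is too low for a {mirror_frequency:g} Hz mirror: "
            "fewer than one line per sweep"
        )
    return n


@dataclass(frozen=True)
class ScanGeometry:
    """Angular line schedule and sampling layout of the sector scan."""

    prf: float
    mirror_frequency: float
    lines_per_frame: int
    samples_per_line: int
    sample_rate: float
    mirror_half_angle_mech: float
    pivot_standoff: float = 10e-3
    sweep_phase: str = "forward"

    def __post_init__(self) -> None:
        if self.sweep_phase not in ("forward", "backward"):
            raise ValueError("sweep_phase must be 'forward' or 'backward'")
        expected = lines_per_frame(self.prf, self.mirror_frequency)
        if self.lines_per_frame != expected:
            raise ValueError(
                f"lines_per_frame must equal floor(prf / (2 mirror_frequency)) "
                f"= {expected}, got {self.lines_per_frame}"
            )
        if self.samples_per_line < 1 or self.sample_rate <= 0:
            raise ValueError("samples_per_line and sample_rate must be positive")
        if not 0.0 < self.mirror_half_angle_mech < math.pi / 8:
            raise ValueError(
                "mirror_half_angle_mech must lie in (0, pi/8) so the beam "
                "stays within the 45-degree fold"
            )
        if self.pivot_standoff < 0:
            raise ValueError("pivot_standoff must be non-negative")

    # -- derived quantities ------------------------------------------------
    @property
    def beam_half_angle(self) -> float:
        """Optical (beam) half angle: twice the mechanical tilt amplitude."""
        return 2.0 * self.mirror_half_angle_mech

    @property
    def sweep_period(self) -> float:
        """Duration of one half oscillation (one frame) in s."""
        return 1.0 / (2.0 * self.mirror_frequency)

    @property
    def frame_rate(self) -> float:
        """Displayed frame rate: one frame per full mirror oscillation."""
        return self.mirror_frequency

    def max_range(self, sound_speed: float = SOFT_TISSUE_SOUND_SPEED) -> float:
        """One-way path length covered by a full line of samples, m."""
        return sound_speed * self.samples_per_line / (2.0 * self.sample_rate)

    # -- schedules ---------------------------------------------------------
    def line_times(self, frame_index: int = 0) -> np.ndarray:
        """Absolute firing time of each line of a frame, s."""
        t0 = frame_index * self.sweep_period
        return t0 + np.arange(self.lines_per_frame) / self.prf

    def angle_at(self, t) -> np.ndarray:
        """Beam angle (rad) at absolute time t.

        Sinusoidal resonant sweep with phase -pi/2 at t = 0 so frame 0
        starts at -beam_half_angle and sweeps forward.
        """
        t = np.asarray(t, dtype=float)
        return self.beam_half_angle * np.sin(
            2.0 * np.pi * self.mirror_frequency * t - np.pi / 2.0
        )

    def line_angles(self, frame_index: int = 0) -> np.ndarray:
        """Beam angle of each line of a frame, in firing order.

        Even frames are monotone increasing (forward sweep); odd frames
        monotone decreasing.  Display code reverses odd frames so that all
        displayed frames share one spatial orientation.
        """
        return self.angle_at(self.line_times(frame_index))

    def is_forward(self, frame_index: int) -> bool:
        return frame_index % 2 == 0

    def sample_ranges(
        self, sound_speed: float = SOFT_TISSUE_SOUND_SPEED
    ) -> np.ndarray:
        """One-way path length (m) from the transducer face per sample."""
        j = np.arange(self.samples_per_line)
        return sound_speed * j / (2.0 * self.sample_rate)

    def beam_to_cartesian(self, angle, rng):
        """Unfold the mirror: map (beam angle, range) to sector (x, z).

        The beam vertex is the mirror pivot; ranges shorter than the pivot
        standoff lie on the pre-mirror segment and map to x = 0 with
        non-positive z (non-imaging region).

        Returns (x, z) arrays in m.
        """
        angle = np.asarray(angle, dtype=float)
        rng = np.asarray(rng, dtype=float)
        if np.any(rng < 0):
            raise ValueError("range must be non-negative")
        r = rng - self.pivot_standoff
        imaging = r >= 0
        x = np.where(imaging, r * np.sin(angle), 0.0)
        z = np.where(imaging, r * np.cos(angle), r)
        if x.ndim == 0:
            return float(x), float(z)
        return x, z

    def cartesian_to_beam(self, x, z):
        """Inverse of :meth:`beam_to_cartesian` for points with z >= 0.

        Returns (angle, range); the sector apex maps to range =
        pivot_standoff, angle 0.
        """
        x = np.asarray(x, dtype=float)
        z = np.asarray(z, dtype=float)
        angle = np.arctan2(x, z)
        rng = np.hypot(x, z) + self.pivot_standoff
        if angle.ndim == 0:
            return float(angle), float(rng)
        return angle, rng

    # -- construction ------------------------------------------------------
    @classmethod
    def default(
        cls,
        spec: TransducerSpec | None = None,
        fov_width: float = 13e-3,
        pivot_standoff: float = 10e-3,
        prf: float = 10e3,
        mirror_frequency: float = 40.0,
        samples_per_line: int = 2048,
        sample_rate: float = 100e6,
    ) -> "ScanGeometry":
        """Reference geometry: 10 kHz PRF, 40 Hz resonant mirror, 125 x 2048
        frames at 100 MS/s.

        The mechanical tilt amplitude is chosen so the swept arc spans
        ``fov_width`` laterally at the transducer's focal range (13 mm
        default, the scanner's maximum lateral range).
        """
        if spec is None:
            spec = TransducerSpec.default()
        r_focus = spec.focal_length - pivot_standoff
        if r_focus <= 0:
            raise ValueError("focal length must exceed the pivot standoff")
        s = fov_width / (2.0 * r_focus)
        if s >= 1.0:
            raise ValueError("requested FOV is wider than the focal arc allows")
        half_angle_mech = math.asin(s) / 2.0
        return cls(
            prf=prf,
            mirror_frequency=mirror_frequency,
            lines_per_frame=lines_per_frame(prf, mirror_frequency),
            samples_per_line=samples_per_line,
            sample_rate=sample_rate,
            mirror_half_angle_mech=half_angle_mech,
            pivot_standoff=pivot_standoff,
        )

    def with_samples(self, samples_per_line: int) -> "ScanGeometry":
        return replace(self, samples_per_line=samples_per_line)

    # -- YAML --------------------------------------------------------------
    def to_yaml_dict(self) -> dict:
        return {
            "prf_hz": self.prf,
            "mirror_hz": self.mirror_frequency,
            "lines_per_frame": self.lines_per_frame,
            "samples_per_line": self.samples_per_line,
            "sample_rate_hz": self.sample_rate,
            "half_angle_deg_mech": math.degrees(self.mirror_half_angle_mech),
            "pivot_standoff_mm": self.pivot_standoff * 1e3,
            "phase": self.sweep_phase,
        }

    @classmethod
    def from_yaml_dict(cls, block: dict) -> "ScanGeometry":
        known = {
            "prf_hz",
            "mirror_hz",
            "lines_per_frame",
            "samples_per_line",
            "sample_rate_hz",
            "half_angle_deg_mech",
            "pivot_standoff_mm",
            "phase",
        }
        unknown = set(block) - known
        if unknown:
            raise ValueError(f"unknown scan keys: {sorted(unknown)}")
        return cls(
            prf=block["prf_hz"],
            mirror_frequency=block["mirror_hz"],
            lines_per_frame=int(block["lines_per_frame"]),
            samples_per_line=int(block["samples_per_line"]),
            sample_rate=block["sample_rate_hz"],
            mirror_half_angle_mech=math.radians(block["half_angle_deg_mech"]),
            pivot_standoff=block["pivot_standoff_mm"] / 1e3,
            sweep_phase=block.get("phase", "forward"),
        )
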