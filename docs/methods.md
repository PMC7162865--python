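# Methods

This note documents the models behind `memsus`, the defaults and why they
were chosen, what the synthetic phantoms do and do not emulate, and the
numerical choices that matter when interpreting its output.

## System model

A single spherically focused element (center frequency f = 16.7 MHz,
aperture D = 9 mm, focal length F = 21.8 mm, two-way −6 dB fractional
bandwidth B = 51.7 %) fires along a fixed axis onto a resonant scanning
mirror whose rest pose makes 45° with the beam. By the law of reflection a
mechanical tilt δ(t) rotates the reflected beam by 2δ(t); the mirror
oscillates sinusoidally at 40 Hz, so the beam angle is
θ(t) = 2δ_max·sin(2π·40·t − π/2). At a 10 kHz PRF each half-oscillation
contains ⌊10000/80⌋ = 125 A-lines — one sector frame. Forward
half-sweeps are displayed (40 frames/s); backward sweeps retrace the same
arc in reverse order, offset by one firing interval of mirror phase, and
are simulated but not displayed by default. Both readings of the sweep
give 125 × 2048 frames; displaying only forward sweeps is the one
consistent with a 40 Hz display rate, so it is the default, and
`ScanGeometry.sweep_phase` selects the other.

Coordinates: the sector apex is the mirror pivot; x is lateral (scan
direction), z is depth; `range` is the one-way acoustic path from the
transducer face, i.e. `pivot_standoff` + radial distance from the apex.
All internal computation is SI (m, s, Hz); YAML/JSON interfaces use
MHz/mm/% for readability.

### Parameters and defaults

| parameter | default | why |
|---|---|---|
| sound speed c | 1540 m/s | soft-tissue convention; with it the depth-of-focus formula evaluates to the probe's nominal 4.1 mm. A config field, not a constant. |
| bandwidth convention | two-way | the probe is characterized in pulse-echo mode; recorded in the YAML block. |
| pivot standoff | 10 mm | a plausible transducer-face-to-mirror distance for a handheld fold; not derivable from the probe data sheet. |
| mechanical half-angle δ_max | 16.7° (derived) | chosen at construction so the swept arc spans the scanner's 13 mm maximum lateral range at the focal range; stored explicitly so the geometry is reproducible. |
| band-pass edges | f(1±B) ≈ [8.1, 25.3] MHz | the pulse's ±1-bandwidth support; order-6 Butterworth applied forward-backward (zero phase) so echo arrival times are unshifted; ≥ 40 dB at 0.5·low and 1.5·high. |
| TGC curve | 10^(2αf·z/20), clip 40 dB | the exact inverse of the simulator's two-way attenuation (α in dB/(cm·MHz), default 0.5), making compensation testable against ground truth. An exponential-in-depth curve; the alternative linear-in-depth gain is not implemented. |
| dynamic range | 40 dB | common B-mode display window. |
| log normalization | per frame | matches real-time display; `normalization="sequence"` references the sequence-global envelope maximum and is used for M-mode, where per-frame normalization would modulate the trace. |
| mosaic σ | 0.25 × tile width | Gaussian weights fall to ~e⁻² ≈ 0.14 at tile edges — seams suppressed without starving tile centers. |

## Pulse and beam models

The two-way pulse is a Gaussian-enveloped cosine with zero carrier phase
at the envelope peak. Its envelope sigma is fixed by requiring the −6 dB
full width of the amplitude spectrum to equal B·f:
σ_t = √(2 ln 2)/(π·B·f). No attempt is made to model the physical
excitation or the transducer's impulse response beyond this bandwidth
constraint.

The lateral beam is parametric, not diffractive: a Gaussian two-way
sensitivity whose −6 dB width at the focus equals the diffraction estimate
λF/D (scaled by `beam_waist_scale`), growing linearly with defocus as
w(R) = w_focus·(1 + |R − F|/F_Z). This keeps per-frame simulation in the
millisecond range while preserving the focus-dependent lateral blur the
resolution metrics need. Full spatial-impulse-response or Rayleigh-integral
beam models, nonlinear propagation, multiple scattering and elevational
beam structure are out of scope.

Attenuation is applied as the amplitude factor 10^(−2αf·R/20).
Mirror motion during one echo's round trip is ignored (a ~16 mm round trip
takes ~21 µs, during which the 40 Hz mirror turns by ~10⁻³ of its sweep).

## Synthetic phantoms

Presets reproduce the platform's characterization and in-vivo experiments
in idealized form:

* `wire` — one ideal point scatterer at the focal range (the physical
  50 µm tungsten wire is below both resolutions, so a point is adequate).
  Simulated as a low-noise characterization scan with a slow (10 Hz)
  sweep for fine angular sampling.
* `leaf` — a curved arc of scatterers standing in for a leaf skeleton.
* `mouse_heart` — two myocardial interfaces 3 mm apart pulsing in
  antiphase at 3.7 Hz with 0.5 mm excursions and a respiration transient
  at t = 3 s.
* `aortic_arch` — a vessel wall pair at 4.12 Hz with respiration
  transients at 1.8 s and 5 s.
* `radial_artery` — an arterial wall pair with 1.1 Hz diameter
  modulation; `wrist_compression` adds a vein that collapses under a slow
  compress/relax schedule.

Wall motion uses a raised-cosine pulse train (duty 0.3) rather than a pure
sinusoid: physiological wall motion is a fast excursion followed by
diastolic rest, and this waveform also keeps the spectral fundamental
dominant. Reflectivities are scaled so the raw echo-to-noise ratio at the
target is ≈ 20 dB after ~25 dB of two-way attenuation at 16.7 MHz; noise
is additive white Gaussian on the RF (digitizer-referred) plus a constant
DC offset. Speckle, clutter, phase aberration, refraction and reverberation
are **not** modeled, so passing tests demonstrate the correctness of the
processing chain on band-limited echoes in white noise — not performance
on real tissue.

Amplitudes are arbitrary units: the physical digitizer's 400 mV range has
no absolute mapping onto reflectivity.

## M-mode rate estimation

The M-mode trace stacks one fixed A-line across displayed frames (40 Hz
sampling; log-compressed, sequence-normalized). For each depth row the
one-sided Hann-windowed periodogram is computed; the row with maximal
in-band power is selected and its in-band peak frequency reported as
round(60·f) beats/min. Physiologic search bands default to 2–15 Hz
(mouse) and 0.7–3 Hz (human).

Peak picking is harmonic-aware: an interface oscillating through a fixed
depth crosses it twice per cycle, so midline rows carry most of their
power at 2f. If an integer subharmonic (f/2 or f/3) inside the band
carries ≥ 20 % of the peak's power (summed over ±1 bin), the subharmonic
is reported — standard practice in spectral heart-rate estimation. A
trace whose best in-band peak is less than 12 dB above the in-band median
power of its row is declared aperiodic rather than assigned a number.

Analysis durations are chosen so the target frequencies are bin-aligned:
10 s at 40 frames/s gives 0.1 Hz bins (3.7 and 1.1 Hz exact), 25 s gives
0.04 Hz bins (4.12 Hz exact). Peak picking is plain argmax over bins;
sub-bin interpolation is deliberately not applied since the fixtures are
bin-aligned and real traces would be dominated by physiological
variability anyway. Aperiodic respiration transients (Gaussian bumps of
0.15 s sigma) inject low-frequency energy below the search bands and do
not displace the peak.

## Scan conversion

Destination-driven: each Cartesian pixel inside the swept sector is
inverse-mapped to (angle, range) and bilinearly interpolated between the
two nearest lines and two nearest samples. Because the resonant sweep is
sinusoidal in time the angular grid is non-uniform; the fractional line
index is found by interpolating the actual angle schedule (monotone within
a frame) rather than assuming uniform spacing. Out-of-sector pixels are
masked and hold −dynamic_range. The default grid is 260 × 320 pixels at
50 µm pitch (13 × 16 mm), finer than both system resolutions; the wire
resolution workflow reconstructs a small region at 10 µm pitch.

Note one geometric consequence of the recorded window: 2048 samples at
100 MS/s span 15.77 mm of one-way path from the transducer face, which
includes the 10 mm pivot standoff, so tissue targets must sit within
≈ 5.8 mm of the apex under the default geometry. Workflows that need the
focal range (e.g. the wire scan) use a 4096-sample window.

## Mosaicking

B-mode frames acquired at successive elevational (Y) stage positions stack
into a local volume; local volumes at successive lateral (X) positions
merge into a global volume. Merging operates on log-compressed (dB)
voxels, matching a process-then-merge pipeline; a linear-domain merge can
be had by de-logging before calling it. Each tile is weighted along X by a
Gaussian centered on the tile (σ = `sigma_frac` × tile width) and voxels
are weight-normalized sums, so merging identical tiles returns the data
exactly and the X extent obeys width + (n−1)·step. Tapering is X-only:
tiles abut only along X in the layouts modeled here. A hard-cut
("nearest tile") merge is provided as the seam-prone reference for the
seam metric (mean |∂v/∂x| within ±1 voxel of the seam planes). Tile
offsets must lie on the voxel lattice; resampling of off-lattice tiles is
not implemented. Inter-tile motion artifacts are not corrected.

## Resolution metrics

The wire image is de-logged to **linear envelope amplitude** and the
lateral/axial profiles through the (centroid-refined) peak are fitted with
Gaussians; FWHM = 2√(2 ln 2)·σ. Fitting in amplitude matches the
convention under which the axial estimate c/(2fB) is a −6 dB envelope
width; fitting intensity would report widths √2 narrower. A model-free
half-maximum crossing width is returned alongside; disagreement (visible
in the fit residual) flags a non-Gaussian LSF. The measurement insists on
a single isolated target: any connected component within 20 dB of the
peak other than the peak's own blob, or a peak on the image border, is an
error.

Measured values for the default simulation land near, not on, the
diffraction estimates — axial ≈ 0.88× c/(2fB) because a Gaussian pulse's
envelope FWHM is 2 ln 2/π ≈ 0.88 of the c/(2fB) convention, lateral
within a few percent of λF/D. The platform's printed bench values (203 µm
lateral, 100 µm axial) depend on the physical pulse shape and beam and are
treated as tolerance bands, not exact targets.

## Determinism and problem sizes

All randomness flows from one global seed through documented sha256-based
per-stage child seeds (`derive_seed`); per-frame noise streams derive from
(seed, frame index), so any frame can be re-simulated in isolation and
identical seeds give bit-identical RF. The rate analyses simulate 400
(10 s) or 1000 (25 s) displayed frames of 125 × 2048 samples — the full
acquisition the display would show — and run in about a minute each on one
CPU; the estimator sweep test uses directly synthesized M-mode matrices
(`synthetic_mmode_matrix`) to cover 6 frequencies × 20 seeds cheaply.

## Known limitations

* Parametric beam: no sidelobes, no elevational structure, no aberration —
  lateral-resolution numbers inherit the model's idealism.
* No speckle statistics unless dense scatterer fields are supplied
  explicitly; SNR-dependent behavior on real data is untested territory.
* The throat-experiment tiling (nine local datasets spanning 29 mm) is
  geometrically underdetermined from the available description; the merge
  API supports arbitrary 1-D X lattices and 3-D offsets, but only the
  leaf (6 × 10 mm @ 4 mm) and heart (4 × 13 mm @ 4 mm) layouts are pinned
  by tests.
* Manual event annotation (compression/relaxation marks) is reproduced
  from the fixture schedule, not detected from the images.
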