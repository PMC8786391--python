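# Methods

## Acquisition model

The simulator reproduces the geometry and signal chain of a resonant-scanned
microscope whose stage position encoders are sampled on the scanner's line
trigger.

**Fast axis.** The resonant mirror's normalized position at sample phase
`s ∈ [0, S]` within a line is `p(s) = −cos(πs/S)`; `S` samples are clocked
uniformly in time per line (3328 at defaults, i.e. a 79.872 MHz sample clock
at 24,000 lines/s). Only the central `fill_fraction` of the sweep amplitude
maps onto the pixel field (default 0.8; the sinusoid's slow turnaround edges
are discarded), so the physical fast-axis deflection is
`u(s) = p(s) · K·pitch / (2·fill_fraction)` for `K` pixels at `pitch` µm.
Bidirectional scanning alternates sweep direction line by line. All
geometric results are invariant to `fill_fraction` because simulator and
reconstructor share the same map.

**Slow axis.** A strip trajectory is ramp-up / cruise / ramp-down. The stage
specification fixes three ramp constants — duration `T` (58 ms), distance
`D` (175 µm), and end velocity `V` (6.25 mm/s) — which constant acceleration
cannot satisfy simultaneously (it would cover `V·T/2 = 181 µm`). The
simulator uses the unique single-exponent power-law ramp
`v(t) = V·(t/T)^p` with `p = V·T/D − 1 ≈ 1.071`, which meets both
constraints; the ramp-down is its time mirror. The reconstruction must not
and does not depend on this choice — it sees motion only through the encoder
trace, and a test drives the pipeline with a raised-cosine ramp to prove it.

**Encoder.** One reading per line, taken at the line trigger and quantized
to `encoder_resolution` (100 nm default) with round-half-even. No intra-line
encoder samples exist, matching the trigger-clocked hardware.

**Intra-line motion.** The stage keeps moving within a line (≈ one 260-nm
pixel per line at cruise). The simulator renders it; the reconstruction, like
the hardware, assigns one position per line. The resulting sub-pixel blur is
accepted, not corrected: content within a line is acquired on average half a
line period after the trigger, a constant half-pixel slow-axis offset at
cruise plus a column-dependent ripple that alternates sign with sweep
direction and largely averages out across lines. This bounds pixelwise
round-trip fidelity at full cruise velocity to about 2 % of peak for
micron-scale beads, while geometric (centroid) accuracy remains at the
tens-of-nanometre level.

**Axis misalignment.** The stage travel axis is tilted by `θ` (0.8° default)
from the scanner's slow axis, so a feature's apparent column drifts by
`+d·sinθ` as the stage travels `d`. The shear correction shifts each row's
content by `−(row_y − origin_y)·tanθ` along the fast axis. The reconstructed
slow coordinate is stage-axis travel `d` (what the encoder measures), not
its projection `d·cosθ`; at 0.8° the difference is 1×10⁻⁴ relative (≈25 nm
over 257.6 µm), far below the one-pixel validation bound. Frame mode rasters
with the galvo in the scanner frame and is undistorted in this model; the
rigid-rotation correction applies when frames are placed into
stage-coordinate mosaics.

**Noise.** Photon counting is Poisson per sample on the noise-free
expectation, seeded through one `numpy` generator per acquisition. Detector
electronics (saturation, excess noise, afterpulsing) are out of scope.

**Phantoms.** Beads are isotropic Gaussians (amplitude = expected photons
per sample at the peak), standing in for fluorophore distribution convolved
with the PSF; no optical model of the polymer beads is attempted. Points
outside the phantom extent return the uniform background.

## Reconstruction

1. `dewarp_fast_axis` — each line is interpolated at the fractional sample
   indices `s_k = (S/π)·arccos(−q_k)`; backward lines are sampled at the
   mirrored indices `S − s_k` so every output line shares one orientation.
2. `fit_line_positions` — a sliding centered least-squares straight-line fit
   (default window 65 lines ≈ 2.7 ms, shifted windows at the ends; the
   polyorder-1 Savitzky–Golay filter) evaluated at each line index.
   Quantization noise (RMS `LSB/√12` ≈ 29 nm) averages down by roughly
   `√window`, giving ≈4 nm RMSE at cruise; the window is short enough that
   ramp curvature contributes <40 nm bias at the steepest point of the
   default ramp. Larger windows help on constant-velocity data until motion
   curvature dominates.
3. `resample_slow_axis` — per-column cubic Hermite interpolation from the
   fitted (nonuniform) line positions onto a uniform grid at the target
   pitch, anchored at the first fitted line position. Lines with identical
   fitted positions are averaged first; grid rows with fewer than four
   neighbours (outside the second…second-to-last node) are dropped, never
   extrapolated.
4. `correct_axis_misalignment` — Hermite row shear (strips) or bicubic
   rotation (frames, via scikit-image).

### Interpolation kernel

Uniform nodes: Catmull–Rom tangents `m_i = (y_{i+1} − y_{i−1})/2`, one-sided
at the boundaries; exact at nodes and for affine data; interior midpoint
weights are `(−1/16, 9/16, 9/16, −1/16)`. Nonuniform nodes: spacing-weighted
tangents `m_i = (h_{i−1}Δ_i + h_iΔ_{i−1})/(h_{i−1} + h_i)` with
`Δ_i = (y_{i+1} − y_i)/h_i`, which reduce to the uniform rule on constant
spacing. The same kernel serves both passes; no extrapolation anywhere.

### Numerical choices

- **Monotonic clamp.** Near zero velocity (strip ends) quantization noise
  can make the fitted track non-monotone at the sub-nanometre level; the
  pipeline applies a running maximum before resampling (deviations are far
  below the encoder LSB).
- **Tie handling.** Exactly equal fitted positions are averaged before
  interpolation.
- **Oversampled ramps.** Interpolation (not averaging) is the default in the
  ramp region, preserving geometry; an optional pre-average of lines falling
  within the same output pixel (`preaverage_lines`) trades a little geometry
  for noise reduction and is off by default.
- **Shear edges.** Rows shifted past the fast-axis edge are filled with 0
  (no extrapolation); comparisons use interior regions.
- **Grid anchoring.** Row 0 of a strip sits at the first fitted line
  position (first emitted row: the first interior grid point), so
  separations are comparable across runs; origins are carried in physical µm
  and used directly for mosaic placement.
- **Quantization rounding** is round-half-even (bias < 0.5 LSB either way).
- **Bidirectional phase error** is assumed zero: simulator and reconstructor
  share the arccosine map. Phase calibration of real hardware is out of
  scope.

## Timing model

- Frame mode: `N = round(row_length / ((1−overlap)·FOV))` frames per row
  (the move to the row start is charged once per mosaic, not per row),
  `N·(lines_per_frame + flyback)/line_rate` acquisition and
  `(N−1)·t_translate` translation.
- Strip mode: `2T + (L − 2D)/V` acquisition plus one translation; totals are
  ramp-placement-invariant because the ramp-down mirrors the ramp-up.
- **Efficiency** is unique-pixel imaging time over total time: the time to
  image the length's unique lines at one pixel pitch per line
  (`(L/pitch)/line_rate`) for frames, `L/V` for strips.
  `average_pixel_rate` is emitted image pixels (flyback excluded, ramp
  overscan included) per second of total time.
- Reported values carry full precision; rounding to printed figures happens
  only in display formatting.

## Stitching

Strips are placed at `round((origin − mosaic_origin)/pitch)` — encoder
positions are authoritative. Blends: overwrite, unweighted average
(default), or edge-distance feathering. The optional 1-D refinement
estimates the strip-axis offset between adjacent strips from their
overlapping column bands: mean-subtracted, Hann-windowed cross-correlation
with upsampled-DFT subpixel peak localization
(`skimage.registration.phase_cross_correlation`, `normalization=None`).
Whitened phase correlation with parabolic refinement was evaluated first and
rejected: whitening is fragile under photon noise and parabolic fits on
finite smooth bands biased estimates by up to half a pixel, versus ≤0.1 px
for the windowed upsampled-DFT estimator. A featureless overlap returns zero
with a low-confidence flag. Full 2-D iterative registration is deliberately
absent — avoiding it is the point of encoder-based placement.

## Metrology

Beads are detected as connected components above a threshold fraction of the
(background-subtracted) peak; centroids are intensity-weighted (no Gaussian
fitting, for robustness at modest SNR) and reported in physical µm; FWHMs
come from half-max crossings of 1-D profiles through the centroid. Matching
against ground truth uses a greedy one-to-one gate of 3 pixels; unmatched
beads are reported and excluded from the RMS.

## Validation scenarios and problem sizes

The canned two-bead scenario simulates a 600-µm strip (3,744 lines × 3,328
samples) containing 2-µm (σ = 1 µm) Gaussian beads of 500 expected photons
per sample over a background of 2: one bead 40 µm into the 175-µm
acceleration ramp, the second 257.6 µm further along the travel axis, in the
cruise region. With Poisson noise, 100-nm encoder quantization, and the 0.8°
misalignment, the reconstructed centroid separation stays within ~120 nm
(half a pixel) of truth across seeds; the acceptance bound is one pixel
(260 nm). The bead-grid scenario (21 beads spanning ramp and cruise) yields
≈0.11 µm RMS position error. The acceptance script runs ten seeded
repetitions of the two-bead scenario (~1 min on one CPU).

## What the synthetic testbed does and does not show

The generator emulates sampling geometry, stage dynamics, encoder
quantization, axis misalignment, and shot noise — the error sources the
reconstruction claims to remove or tolerate. It does not model optical
aberrations or field distortion, vignetting, defocus or axial structure,
detector saturation and excess noise, stage vibration or drift between
acquisitions, or bidirectional phase miscalibration. Passing tests therefore
demonstrate the correctness of the reconstruction given trustworthy encoder
data and an ideal optical train; they do not bound accuracy on a physical
instrument, where lens distortion and drift dominate the residual error
budget.

## Known limitations

- Intra-line motion blur is accepted, not corrected (see above); at cruise
  this is sub-pixel by construction.
- Strip rows measure stage-axis travel, not its cosine projection onto the
  specimen frame (1×10⁻⁴ relative at the default misalignment).
- The fitted-position precision claim is asserted only as <10 nm RMSE on the
  simulated default conditions, not as a statement about any hardware trace.
- Real-time (streaming) reconstruction and GPU execution are out of scope.
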