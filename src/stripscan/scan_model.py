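"""Scanner and stage parameterization plus the mosaic acquisition timing model.

A resonant scanner sweeps the beam sinusoidally at a fixed line rate, so
samples clocked uniformly in time are nonuniform in space; the arccosine map
computed here tells the reconstruction where in the sample stream each
uniformly spaced output pixel lives.  The module also contains the analytic
timing/efficiency model comparing conventional frame (tile) mosaicking with
continuous strip (push-broom) scanning: frames pay a stage translation per
tile plus overlap pixels for stitching, while a strip pays one translation
per strip plus two acceleration ramps, so strips win for everything except a
single-tile mosaic.

Units: distances in micrometres (um), times in seconds, rates in Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScannerParams",
    "StageParams",
    "TimingReport",
    "resonant_pixel_map",
    "frame_acquisition_time",
    "frame_row_report",
    "strip_report",
    "pixel_pitch_from_velocity",
    "peak_pixel_rate",
]


@dataclass(frozen=True)
class ScannerParams:
    """Resonant scan-head configuration.

    Defaults describe a 24,000 lines/s bidirectional resonant scanner whose
    lines are digitized 3328 times each (79.872 MHz sample clock) and
    interpolated down to 2048 uniformly spaced pixels at 260 nm pitch.

    Parameters
    ----------
    line_rate : float
        Bidirectional line rate, lines/s.
    samples_per_line : int
        A/D samples clocked per resonant half-period.
    pixels_per_line : int
        Uniformly spaced output pixels per dewarped line.
    pixel_pitch : float
        Output pixel pitch on the fast axis, um.
    fill_fraction : float
        Fraction of the full mirror sweep amplitude mapped onto the pixel
        field; the sinusoid's slow turnaround edges are discarded.
    bidirectional : bool
        Use both sweep directions (alternate lines spatially reversed).
    flyback_lines : int
        Slow-axis retrace line periods per frame (frame mode only); they
        consume time but produce no pixels.
    """

    line_rate: float = 24_000.0
    samples_per_line: int = 3328
    pixels_per_line: int = 2048
    pixel_pitch: float = 0.260
    fill_fraction: float = 0.8
    bidirectional: bool = True
    flyback_lines: int = 20

    def __post_init__(self) -> None:
        if self.line_rate <= 0:
            raise ValueError("line_rate must be positive")
        if self.samples_per_line < 4:
            raise ValueError("samples_per_line must be >= 4")
        if self.pixels_per_line < 1:
            raise ValueError("pixels_per_line must be >= 1")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if not (0.0 < self.fill_fraction <= 1.0):
            raise ValueError("fill_fraction must lie in (0, 1]")
        if self.flyback_lines < 0:
            raise ValueError("flyback_lines must be >= 0")

    @property
    def field_of_view(self) -> float:
        """Fast-axis field of view, um (532.48 um at defaults)."""
        return self.pixels_per_line * self.pixel_pitch

    @property
    def line_period(self) -> float:
        """Duration of one line, s."""
        return 1.0 / self.line_rate

    @property
    def sweep_half_width(self) -> float:
        """Half-width of the full mirror sweep in um.

        The pixel field covers ``fill_fraction`` of the sweep amplitude, so
        the full sweep is wider than the field of view.
        """
        return self.field_of_view / (2.0 * self.fill_fraction)


@dataclass(frozen=True)
class StageParams:
    """Translation stage configuration.

    Defaults describe a stage cruising at 6.25 mm/s (one 260-nm pixel per
    line at 24 kHz) that takes 58 ms and 175 um to reach cruise velocity,
    with 100-nm optical position encoders and a 0.8 degree misalignment
    between the stage travel axis and the scanner slow axis.
    """

    cruise_velocity: float = 6250.0  # um/s
    accel_duration: float = 0.058  # s
    accel_distance: float = 175.0  # um
    translate_time: float = 0.250  # s per reposition
    encoder_resolution: float = 0.100  # um
    misalignment_angle: float = 0.8  # degrees

    def __post_init__(self) -> None:
        if self.cruise_velocity <= 0:
            raise ValueError("cruise_velocity must be positive")
        if self.accel_duration <= 0:
            raise ValueError("accel_duration must be positive")
        if not (0.0 < self.accel_distance < self.cruise_velocity * self.accel_duration):
            raise ValueError(
                "accel_distance must satisfy 0 < accel_distance < "
                "cruise_velocity * accel_duration (ramp slower than cruise on average)"
            )
        if self.translate_time < 0:
            raise ValueError("translate_time must be >= 0")
        if self.encoder_resolution <= 0:
            raise ValueError("encoder_resolution must be positive")


@dataclass(frozen=True)
class TimingReport:
    """Analytic acquisition-time budget for one mosaic row.

    ``efficiency`` is the fraction of total time attributable to imaging
    unique pixels; ``average_pixel_rate`` is emitted image pixels per second
    of total time.
    """

    mode: str  # "frame" or "strip"
    length: float  # um
    n_units: int  # frames or strips
    acquisition_time: float  # s
    translation_time: float  # s
    total_time: float  # s
    efficiency: float
    average_pixel_rate: float  # pixels/s

    def __post_init__(self) -> None:
        if not math.isclose(
            self.total_time, self.acquisition_time + self.translation_time,
            rel_tol=1e-12, abs_tol=1e-12,
        ):
            raise ValueError("total_time must equal acquisition_time + translation_time")
        if not (0.0 <= self.efficiency <= 1.0):
            raise ValueError("efficiency must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "length_um": self.length,
            "n_units": self.n_units,
            "acquisition_time_s": self.acquisition_time,
            "translation_time_s": self.translation_time,
            "total_time_s": self.total_time,
            "efficiency": self.efficiency,
            "average_pixel_rate_per_s": self.average_pixel_rate,
        }


def resonant_pixel_map(scanner: ScannerParams) -> np.ndarray:
    """Fractional sample indices of uniformly spaced pixel centers.

    The normalized mirror position at sample phase ``s`` in ``[0, S]`` is
    ``p(s) = -cos(pi * s / S)``.  Pixel-center targets are
    ``q_k = fill_fraction * (-1 + (2k + 1) / K)`` for ``k = 0 .. K-1``,
    uniformly spaced in position, and the map inverts the cosine:
    ``s_k = (S / pi) * arccos(-q_k)``.

    Returns a strictly increasing array of length ``pixels_per_line``
    satisfying the sweep symmetry ``s_k + s_{K-1-k} = S``.
    """
    S = scanner.samples_per_line
    K = scanner.pixels_per_line
    k = np.arange(K)
    q = scanner.fill_fraction * (-1.0 + (2.0 * k + 1.0) / K)
    return (S / np.pi) * np.arccos(-q)


def frame_acquisition_time(scanner: ScannerParams, lines_per_frame: int) -> float:
    """Time to acquire one frame of ``lines_per_frame`` lines plus flyback."""
    if lines_per_frame < 0:
        raise ValueError("lines_per_frame must be >= 0")
    return (lines_per_frame + scanner.flyback_lines) / scanner.line_rate


def frame_row_report(
    scanner: ScannerParams,
    stage: StageParams,
    row_length: float,
    overlap: float = 0.20,
) -> TimingReport:
    """Time budget for a row of overlapping square frames covering ``row_length``.

    The frame count is ``N = round(row_length / ((1 - overlap) * field_of_view))``
    with ``N - 1`` inter-frame stage translations; the single move to the row's
    start position is charged once per mosaic, not per row.  Efficiency divides
    the time needed to image the row's unique lines (one line per pixel pitch)
    by the total row time.
    """
    fov = scanner.field_of_view
    if row_length < fov:
        raise ValueError(
            "row_length must be >= one field of view; a single-frame row is degenerate"
        )
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must lie in [0, 1)")
    step = (1.0 - overlap) * fov
    n = max(1, int(np.rint(row_length / step)))
    lines_per_frame = scanner.pixels_per_line  # square frames
    acq = n * frame_acquisition_time(scanner, lines_per_frame)
    trans = (n - 1) * stage.translate_time
    total = acq + trans
    unique_time = (row_length / scanner.pixel_pitch) / scanner.line_rate
    emitted_pixels = n * lines_per_frame * scanner.pixels_per_line
    return TimingReport(
        mode="frame",
        length=row_length,
        n_units=n,
        acquisition_time=acq,
        translation_time=trans,
        total_time=total,
        efficiency=min(1.0, unique_time / total),
        average_pixel_rate=emitted_pixels / total,
    )


def strip_report(
    scanner: ScannerParams,
    stage: StageParams,
    strip_length: float,
) -> TimingReport:
    """Time budget for one continuous strip of ``strip_length`` um.

    Acquisition spans a ramp-up (``accel_duration`` covering
    ``accel_distance``), a cruise segment at ``cruise_velocity``, and a
    time-mirrored ramp-down, followed by one stage translation.  Efficiency
    divides the time the same length would take at cruise velocity (the
    unique-pixel imaging time) by the total.
    """
    if strip_length < 2.0 * stage.accel_distance:
        raise ValueError("strip_length must cover both acceleration ramps")
    acq = (
        2.0 * stage.accel_duration
        + (strip_length - 2.0 * stage.accel_distance) / stage.cruise_velocity
    )
    trans = stage.translate_time
    total = acq + trans
    unique_time = strip_length / stage.cruise_velocity
    emitted_pixels = acq * scanner.line_rate * scanner.pixels_per_line
    return TimingReport(
        mode="strip",
        length=strip_length,
        n_units=1,
        acquisition_time=acq,
        translation_time=trans,
        total_time=total,
        efficiency=min(1.0, unique_time / total),
        average_pixel_rate=emitted_pixels / total,
    )


def pixel_pitch_from_velocity(velocity: float, line_rate: float) -> float:
    """Slow-axis pixel pitch (um) for a stage moving at ``velocity`` um/s."""
    if line_rate <= 0:
        raise ValueError("line_rate must be positive")
    return velocity / line_rate


def peak_pixel_rate(scanner: ScannerParams) -> float:
    """Instantaneous imaging rate while scanning, pixels/s."""
    return scanner.line_rate * scanner.pixels_per_line
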