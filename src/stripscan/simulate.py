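"""Synthetic phantoms and physics-faithful raw acquisitions.

This module is the testbed standing in for the microscope.  It renders
Gaussian bead phantoms through the full acquisition geometry: a cosine fast
axis sampled uniformly in time, a stage that accelerates/cruises/decelerates
along the slow axis (motion continuing *within* each line), a position
encoder quantized to ``encoder_resolution`` and sampled once per line on the
line trigger, a small misalignment angle between the stage travel axis and
the scanner slow axis, and optional Poisson photon noise.

Geometry convention: the scanner frame is the specimen frame.  The fast axis
is x; stage travel by ``d`` um moves the imaged point to
``(x0 + u - d*sin(theta), y0 + d*cos(theta))`` where ``u`` is the fast-axis
deflection and ``theta`` the misalignment angle.  A feature's apparent
column therefore drifts by ``+d*sin(theta)`` as the stage travels — the
shear that reconstruction removes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .scan_model import ScannerParams, StageParams, resonant_pixel_map

__all__ = [
    "Bead",
    "BeadPhantom",
    "MotionProfile",
    "LinearProfile",
    "RawAcquisition",
    "make_motion_profile",
    "sample_specimen",
    "simulate_strip",
    "simulate_frame",
    "two_bead_phantom",
    "bead_grid_phantom",
    "quantize",
]

_LINE_CHUNK = 256  # lines rendered per block to bound memory


@dataclass(frozen=True)
class Bead:
    """One Gaussian bead: center (um), radial sigma (um), peak amplitude
    (expected photons per sample at the center), and channel index."""

    x: float
    y: float
    sigma: float
    amplitude: float
    channel: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("bead sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("bead amplitude must be >= 0")
        if self.channel < 0:
            raise ValueError("bead channel must be >= 0")


@dataclass(frozen=True)
class BeadPhantom:
    """A field of Gaussian beads over a uniform background.

    ``extent`` is ``(x_min, x_max, y_min, y_max)`` in um; points outside it
    return pure background.  Bead profiles model the fluorophore distribution
    convolved with the PSF as a single Gaussian.
    """

    beads: tuple[Bead, ...]
    n_channels: int = 1
    extent: tuple[float, float, float, float] = (-500.0, 500.0, -500.0, 500.0)
    background: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "beads", tuple(self.beads))
        x_min, x_max, y_min, y_max = self.extent
        if not (x_min < x_max and y_min < y_max):
            raise ValueError("extent must be (x_min, x_max, y_min, y_max) with min < max")
        if self.background < 0:
            raise ValueError("background must be >= 0")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        for b in self.beads:
            if b.channel >= self.n_channels:
                raise ValueError("bead channel exceeds n_channels")
            if not (x_min <= b.x <= x_max and y_min <= b.y <= y_max):
                raise ValueError("bead center outside extent")

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "extent": list(self.extent),
            "background": self.background,
            "beads": [
                {"x": b.x, "y": b.y, "sigma": b.sigma,
                 "amplitude": b.amplitude, "channel": b.channel}
                for b in self.beads
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BeadPhantom":
        return cls(
            beads=tuple(Bead(**b) for b in d.get("beads", [])),
            n_channels=int(d.get("n_channels", 1)),
            extent=tuple(d.get("extent", (-500.0, 500.0, -500.0, 500.0))),
            background=float(d.get("background", 0.0)),
        )


@dataclass(frozen=True)
class MotionProfile:
    """Ramp-up / cruise / ramp-down slow-axis trajectory of one strip.

    The ramp velocity is the power law ``v(t) = V * (t/T)**p`` with
    ``p = V*T/D - 1`` (``V`` cruise velocity, ``T`` ramp duration, ``D`` ramp
    distance), the unique single-exponent ramp satisfying both the
    end-velocity and ramp-distance constraints; the ramp-down is its time
    mirror.  Queryable at arbitrary times; position is clamped to the ends.
    """

    cruise_velocity: float
    accel_duration: float
    accel_distance: float
    total_distance: float

    def __post_init__(self) -> None:
        if self.total_distance < 2.0 * self.accel_distance:
            raise ValueError("total_distance must cover both ramps")
        if self.exponent <= 0:
            raise ValueError("inconsistent stage parameters: ramp exponent <= 0")

    @property
    def exponent(self) -> float:
        """Ramp power-law exponent p = V*T/D - 1 (about 1.07 at defaults)."""
        return (
            self.cruise_velocity * self.accel_duration / self.accel_distance - 1.0
        )

    @property
    def cruise_duration(self) -> float:
        return (self.total_distance - 2.0 * self.accel_distance) / self.cruise_velocity

    @property
    def total_duration(self) -> float:
        return 2.0 * self.accel_duration + self.cruise_duration

    def position(self, t):
        """Slow-axis position (um) at time ``t`` (scalar or array), clamped."""
        t = np.asarray(t, dtype=float)
        T = self.accel_duration
        D = self.accel_distance
        V = self.cruise_velocity
        p1 = self.exponent + 1.0
        t_cr_end = T + self.cruise_duration
        tt = np.clip(t, 0.0, self.total_duration)
        out = np.empty_like(tt)

        ramp_up = tt < T
        cruise = (tt >= T) & (tt < t_cr_end)
        ramp_dn = tt >= t_cr_end

        out[ramp_up] = D * (tt[ramp_up] / T) ** p1
        out[cruise] = D + V * (tt[cruise] - T)
        s = (self.total_duration - tt[ramp_dn]) / T  # mirrored time fraction
        out[ramp_dn] = self.total_distance - D * s ** p1
        return out if out.ndim else float(out)

    def velocity(self, t):
        """Slow-axis velocity (um/s) at time ``t``, zero outside the profile."""
        t = np.asarray(t, dtype=float)
        T = self.accel_duration
        V = self.cruise_velocity
        p = self.exponent
        t_cr_end = T + self.cruise_duration
        out = np.zeros_like(t)

        ramp_up = (t >= 0) & (t < T)
        cruise = (t >= T) & (t < t_cr_end)
        ramp_dn = (t >= t_cr_end) & (t <= self.total_duration)

        out[ramp_up] = V * (t[ramp_up] / T) ** p
        out[cruise] = V
        s = (self.total_duration - t[ramp_dn]) / T
        out[ramp_dn] = V * s ** p
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class LinearProfile:
    """Constant-velocity (or parked, velocity=0) trajectory for tests and
    cruise-only acquisitions."""

    velocity: float
    total_duration: float
    start: float = 0.0

    @property
    def total_distance(self) -> float:
        return self.velocity * self.total_duration

    def position(self, t):
        t = np.asarray(t, dtype=float)
        out = self.start + self.velocity * np.clip(t, 0.0, self.total_duration)
        return out if out.ndim else float(out)

    def velocity_at(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where((t >= 0) & (t <= self.total_duration), self.velocity, 0.0)
        return out if out.ndim else float(out)


@dataclass
class RawAcquisition:
    """One raw acquisition: the per-line sample matrix plus per-line trigger
    times, sweep directions, and quantized encoder readings.

    ``samples`` has shape ``(L, S, C)`` (lines, samples/line, channels) and
    holds expected or Poisson-drawn photon counts.  ``encoder_y`` is the
    stage-travel coordinate sampled on each line trigger and quantized to
    ``stage.encoder_resolution`` (round-half-even).
    """

    samples: np.ndarray
    trigger_times: np.ndarray
    directions: np.ndarray
    encoder_x: np.ndarray
    encoder_y: np.ndarray
    scanner: ScannerParams
    stage: StageParams
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 2:
            self.samples = self.samples[:, :, None]
        L = self.samples.shape[0]
        if self.samples.shape[1] != self.scanner.samples_per_line:
            raise ValueError("samples_per_line mismatch between data and ScannerParams")
        for name in ("trigger_times", "directions", "encoder_x", "encoder_y"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (L,):
                raise ValueError(f"{name} must have one entry per line")
            setattr(self, name, arr)
        if not np.all(np.isin(self.directions, (-1, 1))):
            raise ValueError("directions must be +1 or -1")

    @property
    def n_lines(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[2]


def quantize(values, resolution: float):
    """Quantize to integer multiples of ``resolution`` (round-half-even)."""
    return np.round(np.asarray(values, dtype=float) / resolution) * resolution


def make_motion_profile(stage: StageParams, strip_length: float) -> MotionProfile:
    """Build the stage trajectory for a strip of ``strip_length`` um."""
    if strip_length < 2.0 * stage.accel_distance:
        raise ValueError("strip_length must cover both acceleration ramps")
    return MotionProfile(
        cruise_velocity=stage.cruise_velocity,
        accel_duration=stage.accel_duration,
        accel_distance=stage.accel_distance,
        total_distance=strip_length,
    )


def sample_specimen(phantom: BeadPhantom, x, y, channel: int = 0):
    """Expected photons per sample at specimen position(s) ``(x, y)``.

    Background plus the sum of Gaussian bead responses of the requested
    channel; points outside the phantom extent return pure background.
    Deterministic; vectorized over array inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x_min, x_max, y_min, y_max = phantom.extent
    inside = (x >= x_min) & (x <= x_max) & (y >= y_min) & (y <= y_max)
    out = np.full(np.broadcast(x, y).shape, float(phantom.background))
    for b in phantom.beads:
        if b.channel != channel:
            continue
        r2 = (x - b.x) ** 2 + (y - b.y) ** 2
        out += np.where(inside, b.amplitude * np.exp(-r2 / (2.0 * b.sigma ** 2)), 0.0)
    return out if out.ndim else float(out)


def _fast_axis_offsets(scanner: ScannerParams) -> tuple[np.ndarray, np.ndarray]:
    """Fast-axis deflection u(s) in um for forward and backward sweeps."""
    s = np.arange(scanner.samples_per_line, dtype=float)
    p = -np.cos(np.pi * s / scanner.samples_per_line)  # normalized [-1, 1)
    u_fwd = p * scanner.sweep_half_width
    return u_fwd, -u_fwd


def _render_block(
    phantom: BeadPhantom,
    x_coords: np.ndarray,
    y_coords: np.ndarray,
) -> np.ndarray:
    """Expected photons for a block of sample coordinates, all channels.

    Renders the background everywhere and each bead only inside its own
    6-sigma bounding box of lines, which keeps large acquisitions cheap when
    beads are sparse.
    """
    n_lines, n_samp = x_coords.shape
    # background applies everywhere (out-of-extent points read pure background)
    out = np.full((n_lines, n_samp, phantom.n_channels), float(phantom.background))
    x_min, x_max, y_min, y_max = phantom.extent
    line_y_lo = y_coords.min(axis=1)
    line_y_hi = y_coords.max(axis=1)
    for b in phantom.beads:
        reach = 6.0 * b.sigma
        rows = np.nonzero((line_y_hi >= b.y - reach) & (line_y_lo <= b.y + reach))[0]
        if rows.size == 0:
            continue
        r0, r1 = rows[0], rows[-1] + 1
        xs = x_coords[r0:r1]
        ys = y_coords[r0:r1]
        r2 = (xs - b.x) ** 2 + (ys - b.y) ** 2
        block = b.amplitude * np.exp(-r2 / (2.0 * b.sigma ** 2))
        ins = (
            (xs >= x_min) & (xs <= x_max) & (ys >= y_min) & (ys <= y_max)
        )
        out[r0:r1, :, b.channel] += np.where(ins, block, 0.0)
    return out


def _directions(scanner: ScannerParams, n_lines: int) -> np.ndarray:
    if scanner.bidirectional:
        d = np.ones(n_lines, dtype=np.int8)
        d[1::2] = -1
        return d
    return np.ones(n_lines, dtype=np.int8)


def simulate_strip(
    phantom: BeadPhantom,
    scanner: ScannerParams,
    stage: StageParams,
    profile,
    noise: str = "off",
    seed: int | None = None,
    origin: tuple[float, float] = (0.0, 0.0),
) -> RawAcquisition:
    """Simulate a strip acquisition under the given motion profile.

    The stage moves continuously, including within each line; the encoder is
    read once per line on the line trigger and quantized.  ``profile`` is any
    object exposing ``total_duration`` and ``position(t)`` — the
    reconstruction must work for any ramp shape, so the simulator does not
    assume one.

    Parameters
    ----------
    noise : {"off", "poisson"}
        Poisson noise requires ``seed``.
    origin : (x0, y0)
        Specimen coordinates of the fast-axis sweep center at stage travel 0.
    """
    if noise not in ("off", "poisson"):
        raise ValueError("noise must be 'off' or 'poisson'")
    if noise == "poisson" and seed is None:
        raise ValueError("seed is required when noise is enabled")
    rng = np.random.default_rng(seed) if noise == "poisson" else None

    S = scanner.samples_per_line
    L = int(math.ceil(profile.total_duration * scanner.line_rate))
    x0, y0 = origin
    theta = math.radians(stage.misalignment_angle)
    sin_t, cos_t = math.sin(theta), math.cos(theta)

    u_fwd, u_bwd = _fast_axis_offsets(scanner)
    directions = _directions(scanner, L)
    trigger_times = np.arange(L) / scanner.line_rate
    sample_dt = np.arange(S) / (S * scanner.line_rate)

    samples = np.empty((L, S, phantom.n_channels))
    for start in range(0, L, _LINE_CHUNK):
        stop = min(start + _LINE_CHUNK, L)
        t = trigger_times[start:stop, None] + sample_dt[None, :]
        d = np.asarray(profile.position(t))
        u = np.where(
            (directions[start:stop] > 0)[:, None], u_fwd[None, :], u_bwd[None, :]
        )
        x = x0 + u - d * sin_t
        y = y0 + d * cos_t
        block = _render_block(phantom, x, y)
        if rng is not None:
            block = rng.poisson(block).astype(float)
        samples[start:stop] = block

    d_trig = np.asarray(profile.position(trigger_times))
    encoder_y = quantize(d_trig, stage.encoder_resolution)
    encoder_x = np.zeros(L)  # stage x parked at 0 during a strip
    return RawAcquisition(
        samples=samples,
        trigger_times=trigger_times,
        directions=directions,
        encoder_x=encoder_x,
        encoder_y=encoder_y,
        scanner=scanner,
        stage=stage,
        meta={
            "mode": "strip",
            "origin": [x0, y0],
            "noise": noise,
            "seed": seed,
            "n_channels": phantom.n_channels,
        },
    )


def simulate_frame(
    phantom: BeadPhantom,
    scanner: ScannerParams,
    stage: StageParams,
    origin: tuple[float, float] = (0.0, 0.0),
    n_lines: int | None = None,
    noise: str = "off",
    seed: int | None = None,
) -> RawAcquisition:
    """Simulate a frame (galvo raster) acquisition with the stage parked.

    The slow-axis galvo steps one pixel pitch per line, so line ``k`` images
    slow position ``origin_y + k * pixel_pitch``; encoder readings are
    constant.  Flyback lines consume time in the timing model but are never
    rendered here.
    """
    if noise not in ("off", "poisson"):
        raise ValueError("noise must be 'off' or 'poisson'")
    if noise == "poisson" and seed is None:
        raise ValueError("seed is required when noise is enabled")
    rng = np.random.default_rng(seed) if noise == "poisson" else None

    S = scanner.samples_per_line
    L = scanner.pixels_per_line if n_lines is None else int(n_lines)
    if L < 1:
        raise ValueError("n_lines must be >= 1")
    x0, y0 = origin

    u_fwd, u_bwd = _fast_axis_offsets(scanner)
    directions = _directions(scanner, L)
    trigger_times = np.arange(L) / scanner.line_rate
    line_y = y0 + np.arange(L) * scanner.pixel_pitch

    samples = np.empty((L, S, phantom.n_channels))
    for start in range(0, L, _LINE_CHUNK):
        stop = min(start + _LINE_CHUNK, L)
        u = np.where(
            (directions[start:stop] > 0)[:, None], u_fwd[None, :], u_bwd[None, :]
        )
        x = x0 + u
        y = np.broadcast_to(line_y[start:stop, None], x.shape)
        block = _render_block(phantom, x, y)
        if rng is not None:
            block = rng.poisson(block).astype(float)
        samples[start:stop] = block

    encoder_y = np.full(L, quantize(y0, stage.encoder_resolution))
    encoder_x = np.zeros(L)
    return RawAcquisition(
        samples=samples,
        trigger_times=trigger_times,
        directions=directions,
        encoder_x=encoder_x,
        encoder_y=encoder_y,
        scanner=scanner,
        stage=stage,
        meta={
            "mode": "frame",
            "origin": [x0, y0],
            "noise": noise,
            "seed": seed,
            "n_channels": phantom.n_channels,
        },
    )


def two_bead_phantom(
    separation: float = 257.6,
    y_first: float = 40.0,
    x: float = 0.0,
    sigma: float = 1.0,
    amplitude: float = 500.0,
    background: float = 2.0,
) -> BeadPhantom:
    """Two beads separated by ``separation`` um along the slow axis.

    The default places the first bead inside the acceleration ramp (40 um of
    a 175-um ramp) and the second in the cruise region, the geometry used to
    validate that encoder-based reconstruction preserves long distances.
    """
    beads = (
        Bead(x=x, y=y_first, sigma=sigma, amplitude=amplitude),
        Bead(x=x, y=y_first + separation, sigma=sigma, amplitude=amplitude),
    )
    pad = 50.0
    return BeadPhantom(
        beads=beads,
        n_channels=1,
        extent=(-400.0, 400.0, y_first - pad, y_first + separation + pad),
        background=background,
    )


def bead_grid_phantom(
    nx: int = 3,
    ny: int = 5,
    spacing: float = 60.0,
    x_start: float = -60.0,
    y_start: float = 30.0,
    sigma: float = 1.0,
    amplitude: float = 500.0,
    background: float = 2.0,
) -> BeadPhantom:
    """Regular bead grid for distortion mapping across ramp and cruise."""
    beads = tuple(
        Bead(x=x_start + i * spacing, y=y_start + j * spacing,
             sigma=sigma, amplitude=amplitude)
        for i in range(nx)
        for j in range(ny)
    )
    x_lo = x_start - 20.0
    x_hi = x_start + (nx - 1) * spacing + 20.0
    y_lo = y_start - 20.0
    y_hi = y_start + (ny - 1) * spacing + 20.0
    return BeadPhantom(
        beads=beads,
        n_channels=1,
        extent=(min(x_lo, -400.0), max(x_hi, 400.0), y_lo, y_hi),
        background=background,
    )
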