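"""Shared fixtures: full-scale defaults and a scaled-down scanner/stage pair
for fast property tests (same physics, fewer samples)."""

import numpy as np
import pytest

from stripscan import Bead, BeadPhantom, ScannerParams, StageParams


@pytest.fixture(scope="session")
def scanner_default() -> ScannerParams:
    return ScannerParams()


@pytest.fixture(scope="session")
def stage_default() -> StageParams:
    return StageParams()


@pytest.fixture(scope="session")
def scanner_small() -> ScannerParams:
    """Scaled scanner: 2 kHz lines, 128 samples -> 64 px at 1-um pitch."""
    return ScannerParams(
        line_rate=2000.0,
        samples_per_line=128,
        pixels_per_line=64,
        pixel_pitch=1.0,
        fill_fraction=0.8,
        bidirectional=True,
        flyback_lines=4,
    )


@pytest.fixture(scope="session")
def stage_small() -> StageParams:
    """Stage cruising at one 1-um pixel per line, 0.25-um encoder."""
    return StageParams(
        cruise_velocity=2000.0,
        accel_duration=0.020,
        accel_distance=30.0,
        translate_time=0.100,
        encoder_resolution=0.250,
        misalignment_angle=0.8,
    )


@pytest.fixture
def single_bead_phantom_small() -> BeadPhantom:
    """One bead in the cruise region of a small strip."""
    return BeadPhantom(
        beads=(Bead(x=0.0, y=70.0, sigma=3.0, amplitude=400.0),),
        extent=(-60.0, 60.0, 0.0, 140.0),
        background=1.0,
    )
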