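"""Position-based mosaic assembly.

Because every strip carries an absolute physical origin recovered from the
stage encoders, mosaics are assembled by direct placement — no iterative
registration.  Encoder-derived placement is authoritative by default; an
optional 1-D phase-correlation refinement along strip overlaps is provided
for hardware whose encoders are less trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .reconstruct import StripImage

__all__ = [
    "Mosaic",
    "OffsetEstimate",
    "assemble",
    "refine_offset_1d",
]


@dataclass(frozen=True)
class Placement:
    """Where one source image landed on the canvas (pixel offsets)."""

    source: int
    row: int
    col: int
    refined: bool = False


@dataclass
class Mosaic:
    """Assembled canvas with physical origin/pitch and placement provenance."""

    canvas: np.ndarray
    origin: tuple[float, float]
    pitch: float
    placements: list[Placement] = field(default_factory=list)

    def as_strip_image(self) -> StripImage:
        return StripImage(
            pixels=self.canvas, origin=self.origin, pitch=self.pitch,
            provenance={"mode": "mosaic", "n_sources": len(self.placements)},
        )


@dataclass(frozen=True)
class OffsetEstimate:
    """Signed subpixel offset correction along the strip axis."""

    offset: float
    confident: bool = True


def assemble(images: list[StripImage], blend: str = "average") -> Mosaic:
    """Place images on a common canvas by their physical origins.

    Each image lands at ``round((origin - mosaic_origin) / pitch)``; the
    canvas is the bounding box of all inputs.  Overlapping pixels are
    combined per ``blend``:

    - ``overwrite``: later images win;
    - ``average``: unweighted mean of contributors (default);
    - ``feather``: mean weighted by distance to each image's edge, hiding
      seams cosmetically.
    """
    if not images:
        raise ValueError("need at least one image")
    if blend not in ("overwrite", "average", "feather"):
        raise ValueError("blend must be 'overwrite', 'average', or 'feather'")
    pitch = images[0].pitch
    n_ch = images[0].pixels.shape[2]
    for img in images[1:]:
        if not math.isclose(img.pitch, pitch, rel_tol=1e-9):
            raise ValueError("all images must share one pixel pitch")
        if img.pixels.shape[2] != n_ch:
            raise ValueError("all images must share the channel count")

    x0 = min(img.origin[0] for img in images)
    y0 = min(img.origin[1] for img in images)
    rows = []
    cols = []
    for img in images:
        r = int(round((img.origin[1] - y0) / pitch))
        c = int(round((img.origin[0] - x0) / pitch))
        rows.append(r)
        cols.append(c)
    H = max(r + img.pixels.shape[0] for r, img in zip(rows, images))
    W = max(c + img.pixels.shape[1] for c, img in zip(cols, images))

    canvas = np.zeros((H, W, n_ch))
    placements = []
    if blend == "overwrite":
        for k, (img, r, c) in enumerate(zip(images, rows, cols)):
            h, w = img.pixels.shape[:2]
            canvas[r:r + h, c:c + w] = img.pixels
            placements.append(Placement(source=k, row=r, col=c))
    else:
        weight = np.zeros((H, W, 1))
        for k, (img, r, c) in enumerate(zip(images, rows, cols)):
            h, w = img.pixels.shape[:2]
            if blend == "feather":
                wr = np.minimum(np.arange(h) + 1, h - np.arange(h))
                wc = np.minimum(np.arange(w) + 1, w - np.arange(w))
                w2d = (wr[:, None] * wc[None, :]).astype(float)[:, :, None]
            else:
                w2d = np.ones((h, w, 1))
            canvas[r:r + h, c:c + w] += img.pixels * w2d
            weight[r:r + h, c:c + w] += w2d
            placements.append(Placement(source=k, row=r, col=c))
        np.divide(canvas, weight, out=canvas, where=weight > 0)
    return Mosaic(canvas=canvas, origin=(x0, y0), pitch=pitch,
                  placements=placements)


def refine_offset_1d(
    a: StripImage,
    b: StripImage,
    nominal_overlap_px: int,
) -> OffsetEstimate:
    """Refine the relative strip-axis offset of two laterally adjacent strips.

    ``b`` is nominally placed to ``a``'s right with ``nominal_overlap_px``
    shared columns: ``a``'s last columns image the same specimen as ``b``'s
    first columns.  The shared bands are mean-subtracted, Hann-windowed, and
    cross-correlated with upsampled-DFT subpixel peak refinement; only the
    strip-axis (row) component of the shift is returned, as the signed
    correction to the nominal placement (positive: ``b``'s content leads,
    its origin must move toward larger row positions).

    A flat (featureless) overlap returns offset 0 with ``confident=False``.
    """
    if nominal_overlap_px < 16:
        raise ValueError("overlap must be >= 16 pixels")
    if not math.isclose(a.pitch, b.pitch, rel_tol=1e-9):
        raise ValueError("strips must share one pixel pitch")
    band_a = a.pixels[:, -nominal_overlap_px:].sum(axis=2)
    band_b = b.pixels[:, :nominal_overlap_px].sum(axis=2)
    n = min(band_a.shape[0], band_b.shape[0])
    band_a = band_a[:n] - band_a[:n].mean()
    band_b = band_b[:n] - band_b[:n].mean()
    if band_a.std() < 1e-12 or band_b.std() < 1e-12:
        return OffsetEstimate(offset=0.0, confident=False)

    from skimage.registration import phase_cross_correlation

    win = np.hanning(n)[:, None] * np.hanning(band_a.shape[1])[None, :]
    shift, _, _ = phase_cross_correlation(
        band_a * win, band_b * win, upsample_factor=100, normalization=None
    )
    return OffsetEstimate(offset=float(shift[0]), confident=True)
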