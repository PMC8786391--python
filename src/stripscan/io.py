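"""File formats: raw acquisitions, strip TIFFs, configs, and run manifests.

Raw acquisitions are stored as a directory of three text-auditable pieces:

- ``lines.u16`` — little-endian unsigned 16-bit samples, row-major
  ``(L, S, C)``;
- ``meta.json`` — shapes, dtype, scanner/stage parameters, provenance;
- ``encoder.csv`` — per-line trigger time, encoder x/y (um, full decimal
  precision), and sweep direction.

Strip images are TIFFs whose ImageDescription holds a JSON record of pixel
pitch (um), physical origin (um), and processing provenance.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .reconstruct import StripImage
from .scan_model import ScannerParams, StageParams
from .simulate import RawAcquisition

__all__ = [
    "write_raw",
    "read_raw",
    "write_strip",
    "read_strip",
    "load_config",
    "write_manifest",
]

_RAW_BIN = "lines.u16"
_RAW_META = "meta.json"
_RAW_ENCODER = "encoder.csv"


def write_raw(acq: RawAcquisition, path) -> Path:
    """Write a raw acquisition to directory ``path`` (created if needed).

    Samples are stored as little-endian u16; values are rounded and must fit
    in [0, 65535].  Encoder positions are written as decimal text to avoid
    binary-float drift across platforms.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    samples = np.round(acq.samples)
    if samples.min() < 0 or samples.max() > np.iinfo(np.uint16).max:
        raise ValueError("sample counts do not fit in u16")
    samples.astype("<u2").tofile(out / _RAW_BIN)

    L, S, C = acq.samples.shape
    meta = {
        "n_lines": L,
        "samples_per_line": S,
        "n_channels": C,
        "dtype": "<u2",
        "scanner": dataclasses.asdict(acq.scanner),
        "stage": dataclasses.asdict(acq.stage),
        "meta": acq.meta,
    }
    (out / _RAW_META).write_text(json.dumps(meta, indent=1))

    pd.DataFrame(
        {
            "line_index": np.arange(L),
            "trigger_time_s": acq.trigger_times,
            "encoder_x_um": acq.encoder_x,
            "encoder_y_um": acq.encoder_y,
            "direction": acq.directions,
        }
    ).to_csv(out / _RAW_ENCODER, index=False, float_format="%.12g")
    return out


def read_raw(path) -> RawAcquisition:
    """Read a raw acquisition directory written by :func:`write_raw`."""
    src = Path(path)
    meta_path = src / _RAW_META
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path}")
    meta = json.loads(meta_path.read_text())
    L = int(meta["n_lines"])
    S = int(meta["samples_per_line"])
    C = int(meta["n_channels"])

    data = np.fromfile(src / _RAW_BIN, dtype=meta.get("dtype", "<u2"))
    if data.size != L * S * C:
        raise ValueError(
            f"binary size mismatch: {_RAW_BIN} holds {data.size} samples, "
            f"sidecar promises {L}x{S}x{C} = {L * S * C}"
        )
    samples = data.reshape(L, S, C).astype(float)

    enc = pd.read_csv(src / _RAW_ENCODER)
    if len(enc) != L:
        raise ValueError(
            f"encoder CSV has {len(enc)} lines, sidecar promises {L}"
        )
    return RawAcquisition(
        samples=samples,
        trigger_times=enc["trigger_time_s"].to_numpy(),
        directions=enc["direction"].to_numpy().astype(np.int8),
        encoder_x=enc["encoder_x_um"].to_numpy(),
        encoder_y=enc["encoder_y_um"].to_numpy(),
        scanner=ScannerParams(**meta["scanner"]),
        stage=StageParams(**meta["stage"]),
        meta=meta.get("meta", {}),
    )


def write_strip(image: StripImage, path) -> Path:
    """Write a strip/mosaic image as TIFF with physical metadata.

    Pixels keep their in-memory dtype; pitch, origin, and provenance go into
    the ImageDescription as JSON so the round trip preserves geometry.
    """
    out = Path(path)
    desc = json.dumps(
        {
            "pitch_um": image.pitch,
            "origin_um": list(image.origin),
            "provenance": image.provenance,
        }
    )
    pixels = image.pixels
    if pixels.shape[2] == 1:
        pixels = pixels[:, :, 0]
    tifffile.imwrite(out, pixels, description=desc)
    return out


def read_strip(path) -> StripImage:
    """Read a strip TIFF written by :func:`write_strip`."""
    src = Path(path)
    with tifffile.TiffFile(src) as tif:
        page = tif.pages[0]
        desc = page.description
        pixels = tif.asarray()
    try:
        meta = json.loads(desc) if desc else {}
    except json.JSONDecodeError:
        meta = {}
    if "pitch_um" not in meta:
        raise ValueError(
            f"{src} lacks pitch metadata; was it written by stripscan? "
            "(expected JSON ImageDescription with 'pitch_um')"
        )
    return StripImage(
        pixels=pixels,
        origin=tuple(meta.get("origin_um", (0.0, 0.0))),
        pitch=float(meta["pitch_um"]),
        provenance=meta.get("provenance", {}),
    )


def load_config(path) -> tuple[ScannerParams, StageParams]:
    """Load scanner/stage parameters from a TOML or YAML config file.

    The file holds ``[scanner]`` and ``[stage]`` tables using the dataclass
    field names; missing tables or fields fall back to defaults.
    """
    src = Path(path)
    text = src.read_text()
    if src.suffix.lower() == ".toml":
        import tomllib

        cfg = tomllib.loads(text)
    elif src.suffix.lower() in (".yaml", ".yml"):
        cfg = yaml.safe_load(text) or {}
    else:
        raise ValueError(f"unsupported config format: {src.suffix}")
    scanner = ScannerParams(**cfg.get("scanner", {}))
    stage = StageParams(**cfg.get("stage", {}))
    return scanner, stage


def write_manifest(path, payload: dict) -> Path:
    """Write a run manifest (JSON) recording parameters, seeds, and paths."""
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)

    def _default(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return dataclasses.asdict(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        raise TypeError(f"not JSON serializable: {type(obj)}")

    out.write_text(json.dumps(payload, indent=1, default=_default))
    return out
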