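"""Stack I/O and provenance: multi-page TIFF images, JSON sidecars.

Holograms are stored as 16-bit multi-page TIFF (one page per frame);
complex field stacks as 32-bit float TIFF with alternating amplitude and
phase pages (amplitude of frame t on page 2t, phase on page 2t + 1).
Every writer drops a JSON sidecar (``<stem>.json``) with grid metadata and
the hash of the instrument configuration that produced the data.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .model import CameraModel, ComplexField, HologramFrame, OpticalConfig

__all__ = [
    "config_hash",
    "write_hologram_stack",
    "read_hologram_stack",
    "write_field_stack",
    "read_field_stack",
    "write_provenance",
]


def config_hash(optical: OpticalConfig, camera: CameraModel) -> str:
    payload = {
        "optical": dataclasses.asdict(optical),
        "camera": dataclasses.asdict(camera),
    }
    text = yaml.safe_dump(json.loads(json.dumps(payload)), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_hologram_stack(
    path,
    frames: list[HologramFrame],
    optical: OpticalConfig | None = None,
    camera: CameraModel | None = None,
) -> None:
    path = Path(path)
    camera = camera or frames[0].camera
    tifffile.imwrite(
        path,
        np.stack([f.dn for f in frames]).astype(np.uint16),
        photometric="minisblack",
    )
    meta = {
        "kind": "hologram",
        "n_frames": len(frames),
        "bit_depth": camera.bit_depth,
        "full_well": camera.full_well,
    }
    if optical is not None:
        meta["config_hash"] = config_hash(optical, camera)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_hologram_stack(path, camera: CameraModel | None = None) -> list[HologramFrame]:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if not np.issubdtype(data.dtype, np.integer):
        raise ValueError(f"{path}: hologram stack must be integer-typed")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
        camera = camera or CameraModel(
            full_well=meta.get("full_well", 100_000.0),
            bit_depth=meta.get("bit_depth", 12),
        )
    elif camera is None:
        warnings.warn(f"{side} missing; assuming default camera model", stacklevel=2)
        camera = CameraModel()
    return [
        HologramFrame(dn=frame.astype(np.uint16), timestamp_index=t, camera=camera)
        for t, frame in enumerate(data)
    ]


def write_field_stack(path, fields: list[ComplexField], extra_meta: dict | None = None):
    path = Path(path)
    pages = []
    for f in fields:
        pages.append(np.abs(f.values).astype(np.float32))
        pages.append(np.angle(f.values).astype(np.float32))
    tifffile.imwrite(path, np.stack(pages), photometric="minisblack")
    first = fields[0]
    meta = {
        "kind": "complex_field",
        "page_order": "amplitude, phase per frame",
        "n_frames": len(fields),
        "channel": first.channel,
        "sample_plane_pixel_nm": first.sample_plane_pixel,
        "wavelength_nm": first.wavelength,
        "medium_index": first.medium_index,
        "z_offset_nm": first.z_offset,
    }
    if extra_meta:
        meta.update(extra_meta)
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_field_stack(path) -> list[ComplexField]:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] % 2:
        raise ValueError(f"{path}: field stack needs paired amplitude/phase pages")
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        warnings.warn(f"{side} missing; assuming default grid metadata", stacklevel=2)
        meta = {}
    fields = []
    for t in range(data.shape[0] // 2):
        amp = data[2 * t].astype(float)
        phase = data[2 * t + 1].astype(float)
        fields.append(
            ComplexField(
                values=amp * np.exp(1j * phase),
                channel=meta.get("channel", "fs"),
                sample_plane_pixel=meta.get("sample_plane_pixel_nm", 9000.0 / 208.0),
                wavelength=meta.get("wavelength_nm", 515.0),
                medium_index=meta.get("medium_index", 1.33),
                z_offset=meta.get("z_offset_nm", 0.0),
            )
        )
    return fields


def write_provenance(path, stage: str, params: dict, cfg_hash: str | None = None):
    payload = {"stage": stage, "params": params}
    if cfg_hash:
        payload["config_hash"] = cfg_hash
    Path(path).write_text(json.dumps(payload, indent=1, default=str))
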