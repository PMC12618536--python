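"""Shared domain types: optical configuration, camera model, frames and fields.

The instrument records two off-axis fringe systems (a transmission, forward-
scattering channel and an epi, backward-scattering channel) on one sensor.
Every stage of the pipeline — simulation, demultiplexing, refocusing,
noise calibration — shares the constants defined here.

Conventions
-----------
* Images are indexed ``(row, col)`` from the top-left corner.
* Spatial frequencies live on the centered (fftshifted) grid, in cycles/pixel.
* Lengths are in nanometres unless a name says otherwise.
* All pixel crops use half-open ranges.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import yaml

Channel = Literal["fs", "bs"]

#: nm per micron, for the odd conversion.
NM_PER_UM = 1000.0


@dataclass(frozen=True)
class CameraModel:
    """Linear electron/digital-number model of the image sensor.

    gain (electrons per digital number) is ``full_well / 2**bit_depth``;
    digital numbers are clipped to ``[0, 2**bit_depth - 1]``.  Read noise
    defaults to 0: the instrument is treated as shot-noise limited.
    """

    full_well: float = 100_000.0
    bit_depth: int = 12
    read_noise: float = 0.0

    @property
    def gain(self) -> float:
        return self.full_well / 2**self.bit_depth

    @property
    def dn_max(self) -> int:
        return 2**self.bit_depth - 1

    def electrons_to_dn(self, electrons: np.ndarray) -> np.ndarray:
        """Round electrons to digital numbers, clipped to the bit depth."""
        dn = np.rint(np.asarray(electrons, dtype=float) / self.gain)
        return np.clip(dn, 0, self.dn_max).astype(np.uint16)


@dataclass(frozen=True)
class OpticalConfig:
    """Instrument constants of the bidirectional holographic microscope.

    ``alpha_fs``/``alpha_bs`` are the field transmittance and reflectivity of
    the glass sample holder (1 and 0.07: full transmission vs. the weak
    coverslip-water reflection).  ``carrier_fs``/``carrier_bs`` are the
    off-axis fringe carriers in cycles/pixel; ``aperture_radius_px`` is the
    numerical-aperture window radius in spatial-frequency pixels.

    ``sensor_pixel_pitch`` is not a published instrument constant; the
    default 9000 nm is inferred from the 44 um field of view at 208x
    magnification (44 um * 208 / 1024 px ~= 8.9 um) and flagged as such.
    """

    wavelength: float = 515.0
    medium_index: float = 1.33
    collection_na: float = 1.33
    magnification: float = 208.0
    alpha_fs: float = 1.0
    alpha_bs: float = 0.07
    sensor_shape: tuple[int, int] = (1024, 1024)
    sensor_pixel_pitch: float = 9000.0  # nm; inferred, see docstring
    aperture_radius_px: float = 115.0
    carrier_fs: tuple[float, float] = (0.25, 0.0)
    carrier_bs: tuple[float, float] = (0.0, 0.25)
    frame_rate: float = 500.0

    def __post_init__(self) -> None:
        for name in ("alpha_fs", "alpha_bs"):
            a = getattr(self, name)
            if not 0.0 < a <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1], got {a}")
        if self.collection_na > self.medium_index:
            raise ValueError("collection NA cannot exceed the medium index")
        ny = min(self.sensor_shape) / 2.0
        r = self.aperture_radius_px
        centers = [np.zeros(2)] + [
            np.asarray(c, dtype=float) * min(self.sensor_shape)
            for c in (self.carrier_fs, self.carrier_bs)
        ]
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < 2 * r:
                    raise ValueError(
                        "carrier lobes (dilated by the aperture radius) overlap; "
                        "increase carrier separation or shrink the aperture"
                    )
        for c in (self.carrier_fs, self.carrier_bs):
            lobe = np.asarray(c, dtype=float) * min(self.sensor_shape)
            if np.linalg.norm(lobe) + r > ny:
                raise ValueError("aperture does not fit inside the Nyquist square")

    @property
    def sample_pixel(self) -> float:
        """Sample-plane pixel size in nm (sensor pitch demagnified)."""
        return self.sensor_pixel_pitch / self.magnification

    def alpha(self, channel: Channel) -> float:
        return self.alpha_fs if channel == "fs" else self.alpha_bs

    def carrier(self, channel: Channel) -> tuple[float, float]:
        return self.carrier_fs if channel == "fs" else self.carrier_bs

    @property
    def sensor_pixel_count(self) -> int:
        return int(self.sensor_shape[0]) * int(self.sensor_shape[1])


@dataclass(frozen=True)
class HologramFrame:
    """One camera frame of digital numbers carrying both fringe systems."""

    dn: np.ndarray
    timestamp_index: int = 0
    camera: CameraModel = field(default_factory=CameraModel)

    def __post_init__(self) -> None:
        dn = np.asarray(self.dn)
        if dn.ndim != 2:
            raise ValueError("hologram frame must be a 2-D array")
        if not np.issubdtype(dn.dtype, np.integer):
            raise ValueError("hologram digital numbers must be integers")
        if dn.min() < 0 or dn.max() > self.camera.dn_max:
            raise ValueError(
                f"digital numbers outside [0, {self.camera.dn_max}] for "
                f"{self.camera.bit_depth}-bit camera"
            )
        object.__setattr__(self, "dn", dn)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dn.shape


@dataclass
class ComplexField:
    """Reconstructed complex amplitude on the sample-plane grid.

    Instances represent measured fields with and without a sample
    (E_sample, E_bg), particle/no-particle pairs, or simulated ground truth.
    ``sample_plane_pixel`` is the demagnified pixel size in nm; ``z_offset``
    tracks computational refocus distance.
    """

    values: np.ndarray
    channel: Channel
    sample_plane_pixel: float
    wavelength: float
    medium_index: float
    z_offset: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=complex)
        if v.ndim != 2:
            raise ValueError("complex field must be 2-D")
        if not np.all(np.isfinite(v)):
            raise ValueError("complex field contains non-finite values")
        self.values = v

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def like(self, values: np.ndarray, z_offset: float | None = None) -> "ComplexField":
        """New field sharing this field's grid and channel metadata."""
        return ComplexField(
            values=values,
            channel=self.channel,
            sample_plane_pixel=self.sample_plane_pixel,
            wavelength=self.wavelength,
            medium_index=self.medium_index,
            z_offset=self.z_offset if z_offset is None else z_offset,
        )


def dn_to_electrons(frame: HologramFrame) -> np.ndarray:
    """Convert a frame of digital numbers to photo-electron counts.

    The inverse mapping (``CameraModel.electrons_to_dn``) rounds and clips, so
    dn -> electrons -> dn is the identity for in-range integers.
    """
    return frame.dn.astype(float) * frame.camera.gain


def aperture_pixel_count(radius_px: float) -> int:
    """Analytic spatial-frequency aperture area, ``round(pi/4 * (2r)^2)``.

    This is the pixel count entering the shot-noise floor; the analytic disc
    area is used rather than a lattice-point count (which differs by O(D)).
    """
    if radius_px <= 0:
        raise ValueError("aperture radius must be positive")
    return int(round(np.pi / 4.0 * (2.0 * radius_px) ** 2))


def fresnel_amplitude_reflectivity(n1: float, n2: float) -> float:
    """Normal-incidence Fresnel amplitude reflectivity |n1-n2|/(n1+n2).

    For the glass-water interface (1.52, 1.33) this gives ~0.07, the epi
    channel's background field reflectivity alpha.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("refractive indices must be positive")
    return abs(n1 - n2) / (n1 + n2)


def half_pitch_resolution(wavelength: float, na: float) -> float:
    """Coherent half-pitch resolution lambda / (2 NA), in the units of lambda."""
    if na <= 0:
        raise ValueError("NA must be positive")
    return wavelength / (2.0 * na)


# ---------------------------------------------------------------------------
# Config file I/O


def save_config(path, optical: OpticalConfig, camera: CameraModel) -> None:
    """Write the instrument constants as a YAML file."""
    payload = {
        "optical": _to_plain(dataclasses.asdict(optical)),
        "camera": _to_plain(dataclasses.asdict(camera)),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> tuple[OpticalConfig, CameraModel]:
    """Read instrument constants; missing fields fall back to the defaults."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    opt = dict(payload.get("optical", {}))
    for key in ("sensor_shape", "carrier_fs", "carrier_bs"):
        if key in opt:
            opt[key] = tuple(opt[key])
    return OpticalConfig(**opt), CameraModel(**payload.get("camera", {}))


def _to_plain(obj):
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj
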