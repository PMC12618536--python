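"""Hologram demultiplexing, refocusing, drift correction and SA images.

The recorded hologram carries two off-axis fringe systems.  Fourier
transforming it places each channel's information in a separate spectral
lobe; translating a lobe to the origin and keeping only the numerical-
aperture disc yields that channel's complex amplitude.  Computational
refocusing uses the angular-spectrum propagator.  Residual interferometer
drift between sample and background acquisitions (a global phase offset
plus a linear phase ramp) is fitted over sample-free pixels and removed.

The scattering-field amplitude (SA) is

    SA = |E_s| / |E_i| = alpha * |E_sample - E_bg| / |E_bg|

with ``alpha`` the background field transmittance (forward channel, 1) or
reflectivity (backward channel, 0.07).  By construction 0 <= SA <= 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .model import Channel, ComplexField, HologramFrame, OpticalConfig, dn_to_electrons

__all__ = [
    "SAImage",
    "demultiplex",
    "demultiplex_electrons",
    "propagate",
    "autofocus",
    "correct_phase_drift",
    "compute_sa",
    "auto_sample_free_mask",
    "normalize_to_background",
]


@dataclass
class SAImage:
    """Nonnegative scattering-field-amplitude map, dimensionless in [0, 2]."""

    values: np.ndarray
    channel: Channel
    sample_plane_pixel: float
    provenance: dict = dc_field(default_factory=dict)
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _carrier_ramp(shape: tuple[int, int], carrier: tuple[float, float]) -> np.ndarray:
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    return np.exp(-2j * np.pi * (carrier[0] * rows + carrier[1] * cols))


def _aperture_mask(shape: tuple[int, int], radius_px: float) -> np.ndarray:
    fy = np.fft.fftfreq(shape[0])[:, None] * shape[0]
    fx = np.fft.fftfreq(shape[1])[None, :] * shape[1]
    return fy**2 + fx**2 <= radius_px**2


def demultiplex_electrons(
    electrons: np.ndarray,
    config: OpticalConfig,
    channels: tuple[Channel, ...] = ("fs", "bs"),
) -> tuple[ComplexField, ...]:
    """Demodulate a raw electron image into the two channel fields.

    For each channel the spectrum is translated so its carrier sits at the
    origin (implemented as a pre-FFT phase ramp, exact for any carrier),
    everything outside the NA disc of ``aperture_radius_px`` is zeroed, and
    the result is inverse transformed.  Both outputs share one sample-plane
    grid.
    """
    electrons = np.asarray(electrons, dtype=float)
    out = []
    mask = _aperture_mask(electrons.shape, config.aperture_radius_px)
    for channel in channels:
        demod = electrons * _carrier_ramp(electrons.shape, config.carrier(channel))
        spec = np.fft.fft2(demod)
        power = np.abs(spec) ** 2
        lobe_peak = np.max(power[mask])
        # empty-lobe test against the out-of-window floor and the global peak
        threshold = max(10.0 * np.median(power[~mask]), 1e-12 * power.max())
        if power.max() > 0 and lobe_peak <= threshold:
            warnings.warn(
                f"{channel} carrier lobe barely above the surrounding spectrum; "
                "check the carrier configuration",
                stacklevel=2,
            )
        field = np.fft.ifft2(np.where(mask, spec, 0.0))
        out.append(
            ComplexField(
                values=field,
                channel=channel,  # type: ignore[arg-type]
                sample_plane_pixel=config.sample_pixel,
                wavelength=config.wavelength,
                medium_index=config.medium_index,
            )
        )
    return tuple(out)


def demultiplex(
    frame: HologramFrame, config: OpticalConfig
) -> tuple[ComplexField, ComplexField]:
    """Demodulate a camera frame into forward and backward channel fields."""
    return demultiplex_electrons(dn_to_electrons(frame), config)


def propagate(field: ComplexField, z: float, z_max: float = 1e6) -> ComplexField:
    """Angular-spectrum propagation of the field by ``z`` (nm).

    The spectrum is multiplied by ``exp(i 2 pi z sqrt((n/lambda)^2 - f^2))``;
    evanescent components (negative radicand) are zeroed.  Energy in the
    propagating band is conserved, so propagate(+z) then propagate(-z) is
    the identity for band-limited fields.
    """
    if not np.isfinite(z):
        raise ValueError("propagation distance must be finite")
    if abs(z) > z_max:
        raise ValueError(f"|z| exceeds the configured validity bound {z_max} nm")
    p = field.sample_plane_pixel
    fy = np.fft.fftfreq(field.shape[0], d=p)[:, None]
    fx = np.fft.fftfreq(field.shape[1], d=p)[None, :]
    radicand = (field.medium_index / field.wavelength) ** 2 - fy**2 - fx**2
    propagating = radicand > 0
    kz = np.sqrt(np.where(propagating, radicand, 0.0))
    kernel = np.where(propagating, np.exp(2j * np.pi * z * kz), 0.0)
    spec = np.fft.fft2(field.values) * kernel
    return field.like(np.fft.ifft2(spec), z_offset=field.z_offset + z)


def _focus_metric(amplitude: np.ndarray, metric: str) -> float:
    a = amplitude.ravel()
    if metric == "kurtosis":
        m = a.mean()
        v = np.mean((a - m) ** 2)
        if v <= 0:
            return 0.0
        return float(np.mean((a - m) ** 4) / v**2)
    if metric == "peak":
        return float(np.max(a**2))
    if metric == "tamura":
        m = a.mean()
        return float(np.sqrt(a.std() / m)) if m > 0 else 0.0
    if metric == "gradient":
        gy, gx = np.gradient(amplitude)
        return float(np.mean(gy**2 + gx**2))
    raise ValueError(f"unknown focus metric {metric!r}")


def autofocus(
    field: ComplexField,
    z_range: tuple[float, float],
    z_step: float,
    metric: str = "kurtosis",
) -> tuple[float, dict]:
    """Find the refocus distance maximizing a sharpness metric.

    ``field`` should be the differential field (sample minus background) so
    that the metric responds to the scatterer alone.  Returns the best z and
    a provenance dict with the scanned grid and metric values.  A flat
    metric (no scatterer) returns 0 with a warning.
    """
    z_lo, z_hi = z_range
    zs = np.arange(z_lo, z_hi + 0.5 * z_step, z_step)
    if len(zs) < 3:
        raise ValueError("autofocus range must contain at least 3 steps")
    scores = np.array(
        [_focus_metric(np.abs(propagate(field, z).values), metric) for z in zs]
    )
    spread = scores.max() - scores.min()
    if spread <= 1e-12 * max(abs(scores.max()), 1e-30):
        warnings.warn("flat focus metric: no scatterer found, returning z = 0",
                      stacklevel=2)
        return 0.0, {"metric": metric, "z_grid": zs, "scores": scores}
    best = float(zs[int(np.argmax(scores))])
    return best, {"metric": metric, "z_grid": zs, "scores": scores}


def auto_sample_free_mask(ratio: ComplexField, percentile: float = 20.0) -> np.ndarray:
    """Pixels whose complex ratio deviates least from 1 (likely sample-free)."""
    dev = np.abs(ratio.values - 1.0)
    return dev <= np.percentile(dev, percentile)


def correct_phase_drift(
    ratio: ComplexField, sample_free_mask: np.ndarray
) -> tuple[ComplexField, tuple[float, float, float]]:
    """Remove the inter-acquisition phase drift from a ratio field.

    Fits ``a + b*x + c*y`` (x = column, y = row index) by least squares to
    the wrapped phase of ``ratio = E_sample / E_bg`` over the sample-free
    mask, then returns ``ratio * exp(-i (a + b x + c y))`` together with the
    fitted coefficients.  Valid in the small-drift regime where the wrapped
    phase stays inside (-pi, pi) over the mask.
    """
    mask = np.asarray(sample_free_mask, dtype=bool)
    if mask.shape != ratio.shape:
        raise ValueError("mask shape does not match the field")
    n_masked = int(mask.sum())
    if n_masked < 0.01 * mask.size or n_masked < 3:
        raise ValueError("sample-free mask must cover at least 1% of the pixels")
    rows, cols = np.nonzero(mask)
    X = np.column_stack([np.ones(n_masked), cols.astype(float), rows.astype(float)])
    if np.linalg.matrix_rank(X) < 3:
        raise ValueError("sample-free mask pixels are collinear; cannot fit a plane")
    phase = np.angle(ratio.values[mask])
    coeffs, *_ = np.linalg.lstsq(X, phase, rcond=None)
    a, b, c = (float(v) for v in coeffs)
    yy = np.arange(ratio.shape[0])[:, None].astype(float)
    xx = np.arange(ratio.shape[1])[None, :].astype(float)
    corrected = ratio.values * np.exp(-1j * (a + b * xx + c * yy))
    return ratio.like(corrected), (a, b, c)


def normalize_to_background(
    sample: ComplexField, background: ComplexField
) -> ComplexField:
    """Divide out the spatial-mean complex ratio to the background.

    Removes global laser-power and path-length fluctuations between the two
    acquisitions before any drift fitting.
    """
    ratio_mean = np.mean(sample.values / background.values)
    return sample.like(sample.values / ratio_mean)


def compute_sa(
    e_sample: ComplexField,
    e_bg: ComplexField,
    alpha: float,
    floor_rel: float = 1e-6,
) -> SAImage:
    """Scattering-field amplitude ``alpha |E_sample - E_bg| / |E_bg|``.

    Values outside [0, 2] are reported as-is with a warning (they indicate a
    misconfigured alpha rather than data to clip).  Pixels where |E_bg| falls
    below ``floor_rel`` times its median are flagged invalid.
    """
    if e_sample.channel != e_bg.channel:
        raise ValueError("sample and background fields are from different channels")
    if e_sample.shape != e_bg.shape:
        raise ValueError("sample and background fields have different shapes")
    mag_bg = np.abs(e_bg.values)
    floor = floor_rel * np.median(mag_bg)
    invalid = mag_bg <= floor
    denom = np.where(invalid, 1.0, mag_bg)
    sa = alpha * np.abs(e_sample.values - e_bg.values) / denom
    sa[invalid] = 0.0
    if np.any(sa > 2.0 + 1e-9):
        warnings.warn(
            "SA values above 2 encountered; alpha is likely misconfigured",
            stacklevel=2,
        )
    return SAImage(
        values=sa,
        channel=e_sample.channel,
        sample_plane_pixel=e_sample.sample_plane_pixel,
        provenance={"alpha": alpha, "refocus_z": e_sample.z_offset},
        invalid=invalid if invalid.any() else None,
    )
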