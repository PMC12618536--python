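"""Per-pixel temporal-frequency-band fluctuation maps.

From an SA time series (500 fps, typically 5000 frames) the motion of
intracellular structures is mapped in two bands: 1-10 Hz (low frequency,
LF — microscale structure motion above stage-drift timescales) and
100-250 Hz (high frequency, HF — fast nanoscale fluctuations).  Pipeline:

1. per-frame normalization by the spatial mean (amplitude ratio and phase
   offset), removing laser flicker and global path-length noise;
2. subtraction of each pixel's 11 x 11 neighborhood mean, removing
   spatially smooth long-term background variation;
3. per-pixel brick-wall spectral band selection on both quadratures of the
   complex series (temporal mean removed);
4. per-pixel temporal standard deviation, quadrature-combined and scaled
   by alpha into SA units.

The brick-wall filter is exactly testable: disjoint bands are additive in
power (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "DynamicMap",
    "normalize_frames",
    "subtract_local_mean",
    "bandpass_std_map",
    "region_timecourse",
]


@dataclass
class DynamicMap:
    """Band-limited temporal fluctuation STD per pixel, in SA units."""

    values: np.ndarray
    band: tuple[float, float]
    channel: str
    n_frames: int
    fps: float

    def __post_init__(self) -> None:
        f_lo, f_hi = self.band
        if not 0 < f_lo < f_hi <= self.fps / 2:
            raise ValueError("band must satisfy 0 < f_lo < f_hi <= fps/2")
        self.values = np.asarray(self.values, dtype=float)


def _as_array(stack) -> np.ndarray:
    arr = np.asarray(
        [getattr(f, "values", f) for f in stack]
        if isinstance(stack, (list, tuple))
        else stack
    )
    if arr.ndim != 3:
        raise ValueError("stack must be (time, rows, cols)")
    return arr


def normalize_frames(stack) -> np.ndarray:
    """Divide each frame's amplitude by, and subtract each frame's phase's,
    spatial mean — removing spatially uniform frame-to-frame variation."""
    arr = _as_array(stack).astype(complex)
    amp = np.abs(arr)
    mean_amp = amp.mean(axis=(1, 2), keepdims=True)
    if np.any(mean_amp == 0):
        raise ValueError("frame with zero mean amplitude cannot be normalized")
    phase = np.angle(arr)
    mean_phase = phase.mean(axis=(1, 2), keepdims=True)
    return (amp / mean_amp) * np.exp(1j * (phase - mean_phase))


def subtract_local_mean(stack, kernel: int = 11) -> np.ndarray:
    """Subtract each pixel's centered ``kernel x kernel`` neighborhood mean.

    Applied to both quadratures of the complex stack, per frame, with mirror
    padding at the borders.  Removes the spatially global slow background
    pattern while leaving point-like signals (a single impulse keeps a
    fraction 1 - 1/kernel^2 of its value).
    """
    if kernel < 3 or kernel % 2 == 0:
        raise ValueError("kernel must be an odd integer >= 3")
    arr = _as_array(stack)
    if kernel > min(arr.shape[1], arr.shape[2]):
        raise ValueError("kernel larger than the image")
    out = np.empty_like(arr, dtype=complex)
    for t in range(arr.shape[0]):
        frame = arr[t].astype(complex)
        mean_re = ndimage.uniform_filter(frame.real, size=kernel, mode="mirror")
        mean_im = ndimage.uniform_filter(frame.imag, size=kernel, mode="mirror")
        out[t] = frame - (mean_re + 1j * mean_im)
    return out


def bandpass_std_map(
    stack,
    f_lo: float,
    f_hi: float,
    fps: float,
    alpha: float = 1.0,
    channel: str = "fs",
    quadrature: str = "complex",
    min_periods: float = 2.0,
) -> DynamicMap:
    """Brick-wall band-pass each pixel's time series; map the temporal STD.

    The per-pixel temporal mean is removed, the discrete spectrum is
    truncated to ``f_lo <= f <= f_hi`` (zero-phase brick wall), and the
    standard deviation of the filtered series is taken per quadrature.  The
    map value is ``alpha * sqrt(std_re^2 + std_im^2)`` (``quadrature`` can
    restrict to ``"amplitude"`` — the real part of the detrended ratio — or
    ``"phase"`` — the imaginary part).  By Parseval this equals the square
    root of band-limited power, so disjoint band maps add in quadrature to
    the total variance.
    """
    arr = _as_array(stack).astype(complex)
    n = arr.shape[0]
    if not 0 < f_lo < f_hi <= fps / 2:
        raise ValueError("band must satisfy 0 < f_lo < f_hi <= fps/2")
    if n < min_periods * fps / f_lo:
        raise ValueError(
            f"need >= {min_periods} periods of {f_lo} Hz: "
            f"{int(np.ceil(min_periods * fps / f_lo))} frames, got {n}"
        )
    arr = arr - arr.mean(axis=0, keepdims=True)
    freqs = np.fft.rfftfreq(n, d=1.0 / fps)
    keep = (freqs >= f_lo) & (freqs <= f_hi)

    def band_std(series: np.ndarray) -> np.ndarray:
        spec = np.fft.rfft(series, axis=0)
        spec[~keep] = 0.0
        return np.fft.irfft(spec, n=n, axis=0).std(axis=0)

    if quadrature == "complex":
        value = np.sqrt(band_std(arr.real) ** 2 + band_std(arr.imag) ** 2)
    elif quadrature == "amplitude":
        value = band_std(arr.real)
    elif quadrature == "phase":
        value = band_std(arr.imag)
    else:
        raise ValueError(f"unknown quadrature {quadrature!r}")
    return DynamicMap(
        values=alpha * value, band=(f_lo, f_hi), channel=channel, n_frames=n, fps=fps
    )


def region_timecourse(maps, roi) -> pd.Series:
    """Spatial mean of a region across a time-lapse of dynamic maps.

    ``maps`` is a sequence of DynamicMap (or arrays) on identical grids;
    ``roi`` is a boolean mask or an ``(rows, cols)`` slice pair.  Returns a
    Series indexed by time-lapse position.
    """
    values = [getattr(m, "values", m) for m in maps]
    shapes = {np.asarray(v).shape for v in values}
    if len(shapes) != 1:
        raise ValueError("dynamic maps have inconsistent shapes")
    out = []
    for v in values:
        v = np.asarray(v)
        region = v[roi]
        if np.size(region) == 0:
            raise ValueError("empty ROI")
        out.append(float(np.mean(region)))
    return pd.Series(out, name="mean_dynamic_sa")
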