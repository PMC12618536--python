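"""Particle detection, scattering cross-sections, and RI/size inversion.

A localized scatterer's forward (FS) and backward (BS) scattering cross-
sections are obtained by spatially integrating the squared SA image,

    sigma = integral |SA|^2 dx dy ,

either through a radial Gaussian fit (beads on clean substrates) or by
direct pixel summation over the particle's region (intracellular BS, where
membrane fluctuations spoil Gaussian fits).  Cross-sections are normalized
channel-wise by the mean of a reference bead population (150-nm polystyrene).

The FS/BS pair is inverted for refractive index and diameter through a Mie
forward model: partial-wave angular amplitudes integrated over the forward
and backward collection caps.  In the Rayleigh limit (d << lambda) the two
caps receive equal power, so sigma_FS/sigma_BS -> 1; for Mie-regime
particles forward scattering dominates, and the (sigma_FS, sigma_BS) pair
decouples index from size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import ndimage, optimize

from .mie import mie_S1_S2
from .model import ComplexField, OpticalConfig
from .reconstruction import SAImage

__all__ = [
    "ParticleRecord",
    "ScatterModelGrid",
    "flow_background",
    "static_background",
    "differential_sa",
    "detect_particles",
    "cross_section",
    "normalize_cross_sections",
    "forward_model",
    "invert_ri_size",
]


@dataclass
class ParticleRecord:
    """One localized particle with cross-sections and inverted properties."""

    frame: int
    center: tuple[float, float]
    sigma_fs: float = np.nan
    sigma_bs: float = np.nan
    sigma_fs_norm: float = np.nan
    sigma_bs_norm: float = np.nan
    fit: tuple[float, float, float] | None = None  # (amplitude, width, offset)
    n_est: float = np.nan
    d_est: float = np.nan
    n_err: float = np.nan
    d_err: float = np.nan
    flags: list[str] = dc_field(default_factory=list)


# ---------------------------------------------------------------------------
# Background estimation


def _stack_values(field_stack) -> np.ndarray:
    if len(field_stack) == 0:
        raise ValueError("empty field stack")
    first = field_stack[0]
    if isinstance(first, ComplexField):
        return np.stack([f.values for f in field_stack])
    return np.asarray(field_stack)


def _like_first(field_stack, values: np.ndarray):
    first = field_stack[0]
    if isinstance(first, ComplexField):
        return first.like(values)
    return values


def flow_background(field_stack, t: int, offset: int = 200, n_avg: int = 100):
    """Particle-free background around frame ``t`` of a flowing sample.

    Averages the ``n_avg`` frames ending ``offset`` frames before ``t``
    (frames t-offset .. t-offset+n_avg-1) and the ``n_avg`` frames starting
    ``offset - n_avg + 1`` after (frames t+offset-n_avg+1 .. t+offset), then
    averages the two means.  With the defaults this is the 401-frame window
    spanning 200 frames on either side of the particle frame, using its
    outermost 100 frames per side.
    """
    values = _stack_values(field_stack)
    n = values.shape[0]
    lo = t - offset
    hi = t + offset
    if lo < 0 or hi >= n:
        raise ValueError(
            f"flow background needs frames [{lo}, {hi}] but the stack has "
            f"{n} frames; require t >= {offset} and t <= n - 1 - {offset}"
        )
    before = values[lo : lo + n_avg].mean(axis=0)
    after = values[hi - n_avg + 1 : hi + 1].mean(axis=0)
    return _like_first(field_stack, 0.5 * (before + after))


def static_background(field_stack):
    """Long-time complex mean; particle contrast cancels as its phase walks."""
    values = _stack_values(field_stack)
    if values.shape[0] < 2:
        raise ValueError("static background needs at least 2 frames")
    return _like_first(field_stack, values.mean(axis=0))


def differential_sa(
    e_particle: ComplexField,
    e_no_particle: ComplexField,
    e_bg: ComplexField,
    alpha: float,
    floor_rel: float = 1e-6,
) -> SAImage:
    """Temporal-differential SA, ``alpha |E_particle - E_no_particle| / |E_bg|``.

    ``e_bg`` is a background field from a cell-free region; it sets the
    incident-field magnitude but is not subtracted, so static substrate and
    cell structure cancel through ``e_no_particle`` instead.
    """
    if not (e_particle.channel == e_no_particle.channel == e_bg.channel):
        raise ValueError("fields must come from the same channel")
    if not (e_particle.shape == e_no_particle.shape == e_bg.shape):
        raise ValueError("fields must be co-registered (same shape)")
    mag_bg = np.abs(e_bg.values)
    invalid = mag_bg <= floor_rel * np.median(mag_bg)
    denom = np.where(invalid, 1.0, mag_bg)
    sa = alpha * np.abs(e_particle.values - e_no_particle.values) / denom
    sa[invalid] = 0.0
    return SAImage(
        values=sa,
        channel=e_particle.channel,
        sample_plane_pixel=e_particle.sample_plane_pixel,
        provenance={"alpha": alpha, "differential": True},
        invalid=invalid if invalid.any() else None,
    )


# ---------------------------------------------------------------------------
# Detection and cross-sections


def detect_particles(
    sa: SAImage, min_sa: float, min_separation: float
) -> list[tuple[float, float]]:
    """Local maxima above ``min_sa`` with non-maximum suppression.

    Returns sub-pixel (row, col) centers refined by an SA^2-weighted
    centroid in a window of ``min_separation`` around each surviving peak.
    """
    if min_sa <= 0 or min_separation <= 0:
        raise ValueError("thresholds must be positive")
    img = sa.values
    size = max(3, int(round(min_separation)) | 1)
    local_max = (img == ndimage.maximum_filter(img, size=size)) & (img >= min_sa)
    peaks = np.argwhere(local_max)
    if len(peaks) == 0:
        return []
    order = np.argsort(img[tuple(peaks.T)])[::-1]
    peaks = peaks[order]
    kept: list[np.ndarray] = []
    for p in peaks:
        if all(np.hypot(*(p - q)) >= min_separation for q in kept):
            kept.append(p)
    half = max(1, int(round(min_separation)))
    centers = []
    for r, c in kept:
        r0, r1 = max(0, r - half), min(img.shape[0], r + half + 1)
        c0, c1 = max(0, c - half), min(img.shape[1], c + half + 1)
        patch = img[r0:r1, c0:c1] ** 2
        total = patch.sum()
        if total <= 0:
            centers.append((float(r), float(c)))
            continue
        rr, cc = np.mgrid[r0:r1, c0:c1]
        centers.append(
            (float((rr * patch).sum() / total), float((cc * patch).sum() / total))
        )
    return centers


def _gaussian_fit(img: np.ndarray, center: tuple[float, float]):
    rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)

    def residuals(p):
        amp, s, off, r0, c0 = p
        model = amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * s**2)) + off
        return (model - img).ravel()

    amp0 = float(img.max() - np.median(img))
    p0 = [max(amp0, 1e-12), 2.0, float(np.median(img)), center[0], center[1]]
    res = optimize.least_squares(residuals, p0, max_nfev=2000)
    return res


def cross_section(
    sa: SAImage,
    center: tuple[float, float],
    mode: str = "gauss",
    roi_radius: float = 10.0,
    adaptive: bool = False,
) -> tuple[float, tuple[float, float, float] | None]:
    """Integrated squared SA of one particle, in sample-plane pixel^2 units.

    ``gauss`` mode fits ``SA(r) = A exp(-r^2 / (2 s^2)) + offset`` around the
    center and returns the analytic integral ``A^2 pi s^2`` (the offset
    suppresses background); a failed fit falls back to pixel mode with a
    warning.  ``pixel`` mode sums SA^2 over the ROI disc, or — with
    ``adaptive`` — over the connected component above 3x the local median
    absolute deviation around the detection (for intracellular backward-
    channel particles, where fits are unreliable).

    Multiply by ``sa.sample_plane_pixel ** 2`` for physical (nm^2) units.
    """
    r0, c0 = center
    if not (0 <= r0 < sa.shape[0] and 0 <= c0 < sa.shape[1]):
        raise ValueError("particle center outside the image")
    half = int(round(roi_radius))
    rlo, rhi = max(0, int(r0) - half), min(sa.shape[0], int(r0) + half + 1)
    clo, chi = max(0, int(c0) - half), min(sa.shape[1], int(c0) + half + 1)
    patch = sa.values[rlo:rhi, clo:chi]

    if mode == "gauss":
        res = _gaussian_fit(patch, (r0 - rlo, c0 - clo))
        amp, s, off = res.x[0], abs(res.x[1]), res.x[2]
        if res.success and amp > 0 and 0.3 < s < max(patch.shape):
            return float(amp**2 * np.pi * s**2), (float(amp), float(s), float(off))
        warnings.warn("Gaussian fit did not converge; falling back to pixel mode",
                      stacklevel=2)
        mode = "pixel"

    if mode != "pixel":
        raise ValueError(f"unknown cross-section mode {mode!r}")

    if adaptive:
        med = np.median(patch)
        mad = np.median(np.abs(patch - med))
        thresh = med + 3.0 * max(mad, 1e-30)
        above = patch > thresh
        labels, _ = ndimage.label(above)
        lab = labels[int(round(r0 - rlo)), int(round(c0 - clo))]
        if lab == 0:
            warnings.warn("no connected component at the detection; using ROI disc",
                          stacklevel=2)
        else:
            region = labels == lab
            return float(np.sum(patch[region] ** 2)), None
    rr, cc = np.mgrid[rlo:rhi, clo:chi].astype(float)
    disc = (rr - r0) ** 2 + (cc - c0) ** 2 <= roi_radius**2
    return float(np.sum(patch[disc] ** 2)), None


def normalize_cross_sections(
    records: pd.DataFrame,
    reference_mean_fs: float,
    reference_mean_bs: float,
    particle_column: str | None = "particle",
) -> pd.DataFrame:
    """Normalize cross-sections by the reference-population channel means.

    If ``particle_column`` names a column, per-particle cross-sections are
    first averaged over their frames (the ~100-frame temporal average) and
    one row per particle is returned.
    """
    if reference_mean_fs <= 0 or reference_mean_bs <= 0:
        raise ValueError("reference means must be positive")
    df = records.copy()
    if len(df) and particle_column and particle_column in df.columns:
        keep = [
            c
            for c in df.columns
            if c == particle_column or np.issubdtype(df[c].dtype, np.number)
        ]
        df = df[keep].groupby(particle_column, as_index=False).mean()
    df["sigma_fs_norm"] = df["sigma_fs"] / reference_mean_fs
    df["sigma_bs_norm"] = df["sigma_bs"] / reference_mean_bs
    return df


# ---------------------------------------------------------------------------
# Forward model and inversion


def _cap_quadrature(theta_max: float, n_points: int = 64):
    mu_lo = np.cos(theta_max)
    nodes, weights = leggauss(n_points)
    # forward cap: mu in [cos(theta_max), 1]; backward cap mirrored.
    mu_f = 0.5 * (1 - mu_lo) * nodes + 0.5 * (1 + mu_lo)
    w = 0.5 * (1 - mu_lo) * weights
    return mu_f, -mu_f, w


def forward_model(
    n: float, d, config: OpticalConfig, n_quad: int = 64
) -> tuple[np.ndarray, np.ndarray]:
    """Model (sigma_FS, sigma_BS) in nm^2 for a sphere of index n, diameter d.

    Mie amplitudes S1, S2 (relative index n/n_med, size parameter
    ``pi d n_med / lambda``) are integrated over the forward collection cap
    theta in [0, theta_max] and the backward cap [pi - theta_max, pi], with
    ``theta_max = arcsin(min(NA / n_med, 1))`` — 90 degrees for a water-
    immersed NA of 1.33, i.e. full fore and aft hemispheres:

        sigma = (pi / k^2) * integral_cap (|S1|^2 + |S2|^2) dmu ,

    which reduces to the standard total scattering cross-section when the
    two caps are summed.  ``d`` may be an array.
    """
    d = np.atleast_1d(np.asarray(d, dtype=float))
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    if n < config.medium_index - 0.05:
        raise ValueError("index too far below the medium index")
    m = n / config.medium_index
    k = 2 * np.pi * config.medium_index / config.wavelength
    x = np.pi * d * config.medium_index / config.wavelength
    theta_max = np.arcsin(min(config.collection_na / config.medium_index, 1.0))
    mu_f, mu_b, w = _cap_quadrature(theta_max, n_quad)
    if abs(m - 1.0) < 1e-12:
        zero = np.zeros_like(x)
        return zero, zero
    S1f, S2f = mie_S1_S2(m, x, mu_f)
    S1b, S2b = mie_S1_S2(m, x, mu_b)
    sigma_fs = (np.pi / k**2) * np.sum(
        w[None, :] * (np.abs(S1f) ** 2 + np.abs(S2f) ** 2), axis=1
    )
    sigma_bs = (np.pi / k**2) * np.sum(
        w[None, :] * (np.abs(S1b) ** 2 + np.abs(S2b) ** 2), axis=1
    )
    if sigma_fs.size == 1:
        return float(sigma_fs[0]), float(sigma_bs[0])
    return sigma_fs, sigma_bs


@dataclass
class ScatterModelGrid:
    """Tabulated model cross-sections on an (index, diameter) grid."""

    n_grid: np.ndarray
    d_grid: np.ndarray
    sigma_fs: np.ndarray  # shape (len(n_grid), len(d_grid))
    sigma_bs: np.ndarray
    config: OpticalConfig

    @classmethod
    def build(
        cls,
        config: OpticalConfig,
        n_range: tuple[float, float] = (1.34, 1.70),
        n_step: float = 0.002,
        d_range: tuple[float, float] = (20.0, 1000.0),
        d_step: float = 2.0,
    ) -> "ScatterModelGrid":
        n_grid = np.arange(n_range[0], n_range[1] + 0.5 * n_step, n_step)
        d_grid = np.arange(d_range[0], d_range[1] + 0.5 * d_step, d_step)
        sig_f = np.empty((n_grid.size, d_grid.size))
        sig_b = np.empty_like(sig_f)
        for i, n in enumerate(n_grid):
            sig_f[i], sig_b[i] = forward_model(n, d_grid, config)
        return cls(n_grid, d_grid, sig_f, sig_b, config)


def invert_ri_size(
    sigma_fs_norm: float,
    sigma_bs_norm: float,
    grid: ScatterModelGrid,
    reference: tuple[float, float],
    bounds: tuple[float, float] | None = None,
    sigma_rel_err: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """Invert normalized (sigma_FS, sigma_BS) for refractive index and size.

    ``reference`` is the model (sigma_FS, sigma_BS) of the normalization
    bead, so the grid can be compared on the same normalized scale.  The
    squared log-distance between measurement and model is minimized over the
    grid (optionally restricted to index ``bounds``, e.g. the physiological
    1.38-1.54 for intracellular particles), then refined locally with a
    simplex search on the continuous forward model.  Uncertainties are
    propagated from relative cross-section errors through the local
    Jacobian of (log sigma_FS, log sigma_BS) w.r.t. (n, d).
    """
    if sigma_fs_norm <= 0 or sigma_bs_norm <= 0:
        raise ValueError("normalized cross-sections must be positive")
    ref_fs, ref_bs = reference
    log_meas = np.array([np.log(sigma_fs_norm * ref_fs), np.log(sigma_bs_norm * ref_bs)])

    n_lo = grid.n_grid[0] if bounds is None else max(bounds[0], grid.n_grid[0])
    n_hi = grid.n_grid[-1] if bounds is None else min(bounds[1], grid.n_grid[-1])
    sel = (grid.n_grid >= n_lo - 1e-12) & (grid.n_grid <= n_hi + 1e-12)
    if not sel.any():
        raise ValueError("index bounds lie outside the model grid")
    with np.errstate(divide="ignore"):
        cost = (np.log(grid.sigma_fs[sel]) - log_meas[0]) ** 2 + (
            np.log(grid.sigma_bs[sel]) - log_meas[1]
        ) ** 2
    i, j = np.unravel_index(np.argmin(cost), cost.shape)
    n0 = grid.n_grid[sel][i]
    d0 = grid.d_grid[j]

    d_lo, d_hi = grid.d_grid[0], grid.d_grid[-1]

    def objective(p):
        nn = np.clip(p[0], n_lo, n_hi)
        dd = np.clip(p[1], d_lo, d_hi)
        sf, sb = forward_model(nn, dd, grid.config)
        return (np.log(sf) - log_meas[0]) ** 2 + (np.log(sb) - log_meas[1]) ** 2

    res = optimize.minimize(
        objective, [n0, d0], method="Nelder-Mead",
        options={"xatol": 1e-5, "fatol": 1e-14, "maxiter": 400},
    )
    n_est = float(np.clip(res.x[0], n_lo, n_hi))
    d_est = float(np.clip(res.x[1], d_lo, d_hi))

    flags = []
    edge_tol_n = 2e-4
    edge_tol_d = 1e-2
    if (
        min(n_est - n_lo, n_hi - n_est) < edge_tol_n
        or min(d_est - d_lo, d_hi - d_est) < edge_tol_d
    ):
        flags.append("boundary estimate")

    # Jacobian of log sigma w.r.t. (n, d) by central differences.
    dn, dd = 1e-3, 1.0
    J = np.zeros((2, 2))
    for col, (pn, pd_) in enumerate([(dn, 0.0), (0.0, dd)]):
        hi = np.log(forward_model(n_est + pn, d_est + pd_, grid.config))
        lo = np.log(forward_model(n_est - pn, d_est - pd_, grid.config))
        J[:, col] = (np.asarray(hi) - np.asarray(lo)) / (2 * (pn + pd_))
    err = np.array([0.0, 0.0])
    if any(e > 0 for e in sigma_rel_err):
        try:
            err = np.abs(np.linalg.solve(J, np.asarray(sigma_rel_err, dtype=float)))
        except np.linalg.LinAlgError:
            flags.append("singular Jacobian")
    return {
        "n": n_est,
        "d": d_est,
        "n_err": float(err[0]),
        "d_err": float(err[1]),
        "flags": flags,
    }
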