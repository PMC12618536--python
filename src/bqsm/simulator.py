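"""Physics-based hologram simulator with known ground truth.

Renders spatial-frequency-multiplexed off-axis holograms of bead scenes:
two fringe carriers (forward and backward channel) on one sensor, unit-
modulus background fields with static substrate-roughness speckle, slow
interferometer phase drift (global offset + linear ramp, accumulated per
frame), diffraction-limited defocusable bead fields scaled to a Mie forward
model, Poisson shot noise under the electron camera model, and bit-depth
quantization.  Every random element is driven by the scene seed, so a scene
renders bit-identically.

Cross terms between the two channels' object fields and between the two
references are omitted — in the instrument they are suppressed by the
source's short coherence length; here this is a documented simplification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from . import particles as _particles
from .model import CameraModel, Channel, ComplexField, HologramFrame, OpticalConfig

__all__ = [
    "BeadSpec",
    "SimScene",
    "scattered_field",
    "background_field",
    "channel_field",
    "render_expected_electrons",
    "render_hologram",
    "simulate_timeseries",
    "brownian_trajectory",
    "flow_trajectory",
]

logger = logging.getLogger(__name__)


@dataclass
class BeadSpec:
    """A spherical scatterer: diameter (nm), refractive index, trajectory.

    ``trajectory`` is an (T, 3) array of per-frame positions: lateral (row,
    col) in sample-plane pixels, axial z in nm.  A single position is
    broadcast to all frames.  ``index == medium_index`` is a null scatterer.
    """

    diameter: float
    index: float
    trajectory: np.ndarray

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("bead diameter must be positive")
        traj = np.atleast_2d(np.asarray(self.trajectory, dtype=float))
        if traj.shape[1] == 2:
            traj = np.column_stack([traj, np.zeros(len(traj))])
        if traj.shape[1] != 3:
            raise ValueError("trajectory must have columns (row, col, z)")
        self.trajectory = traj

    def position(self, frame_index: int) -> np.ndarray:
        if len(self.trajectory) == 1:
            return self.trajectory[0]
        return self.trajectory[min(frame_index, len(self.trajectory) - 1)]


@dataclass
class SimScene:
    """A renderable scene: beads, noise sources, drift, photon budget.

    ``visibility`` and ``illumination`` are per-channel dicts; illumination
    is the expected background electrons per pixel contributed by that
    channel's DC term.  ``background_roughness_rms`` is the rms of the
    static substrate speckle in SA-equivalent units (per channel, divided by
    that channel's alpha to convert to field units).  ``drift`` is the
    per-frame increment of (global phase offset [rad], phase gradient
    [rad/pixel, 2-vector]), accumulated over frames.
    """

    beads: list[BeadSpec] = dc_field(default_factory=list)
    background_roughness_rms: float = 0.0
    drift_phase_per_frame: float = 0.0
    drift_gradient_per_frame: tuple[float, float] = (0.0, 0.0)
    visibility: dict = dc_field(default_factory=lambda: {"fs": 0.4, "bs": 0.4})
    illumination: dict = dc_field(
        default_factory=lambda: {"fs": 20_000.0, "bs": 20_000.0}
    )
    scatter_phase: complex = 1j  # phase of E_s relative to E_bg (phase object)
    seed: int = 0

    def __post_init__(self) -> None:
        for ch, v in self.visibility.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"visibility[{ch!r}] must lie in [0, 1]")


def _pupil_mask_and_defocus(
    shape: tuple[int, int], config: OpticalConfig, z: float
) -> tuple[np.ndarray, np.ndarray]:
    p = config.sample_pixel
    fy = np.fft.fftfreq(shape[0], d=p)[:, None]
    fx = np.fft.fftfreq(shape[1], d=p)[None, :]
    f2 = fy**2 + fx**2
    pupil = f2 <= (config.collection_na / config.wavelength) ** 2
    radicand = (config.medium_index / config.wavelength) ** 2 - f2
    if z != 0.0 and np.any(pupil & (radicand <= 0)):
        raise ValueError("defocus pushes pupil components evanescent")
    kz = np.sqrt(np.where(radicand > 0, radicand, 0.0))
    return pupil, np.exp(2j * np.pi * z * kz)


def scattered_field(
    bead: BeadSpec,
    config: OpticalConfig,
    channel: Channel,
    defocus: float = 0.0,
    shape: tuple[int, int] | None = None,
    position: tuple[float, float] | None = None,
) -> ComplexField:
    """Coherent point-spread field of one bead, scaled to the Mie model.

    The field is the inverse transform of a circular pupil of the collection
    NA with an angular-spectrum defocus phase, centered on the bead.  Its
    amplitude is scaled so that the integrated squared SA equals the forward
    model's cross-section for this channel:

        sum |alpha * E_s|^2 * pixel_area  =  sigma_channel(n, d) .

    Multiple beads superpose linearly (see :func:`channel_field`).
    """
    shape = shape or config.sensor_shape
    if position is None:
        position = tuple(bead.position(0)[:2])
    r0, c0 = position
    if not (0 <= r0 < shape[0] and 0 <= c0 < shape[1]):
        raise ValueError("bead outside the field of view")
    pupil, defocus_phase = _pupil_mask_and_defocus(shape, config, defocus)
    p = config.sample_pixel
    fy = np.fft.fftfreq(shape[0], d=p)[:, None]
    fx = np.fft.fftfreq(shape[1], d=p)[None, :]
    shift = np.exp(-2j * np.pi * (fy * r0 * p + fx * c0 * p))
    spec = np.where(pupil, defocus_phase * shift, 0.0)
    psf = np.fft.ifft2(spec)

    sigma_fs, sigma_bs = _particles.forward_model(bead.index, bead.diameter, config)
    sigma = sigma_fs if channel == "fs" else sigma_bs
    alpha = config.alpha(channel)
    energy = np.sum(np.abs(psf) ** 2) * p**2  # defocus-independent (unitary)
    scale = 0.0 if sigma == 0.0 else np.sqrt(sigma / energy) / alpha
    return ComplexField(
        values=scale * psf,
        channel=channel,
        sample_plane_pixel=p,
        wavelength=config.wavelength,
        medium_index=config.medium_index,
    )


def _roughness(
    scene: SimScene, config: OpticalConfig, channel: Channel, shape: tuple[int, int]
) -> np.ndarray:
    """Static, seed-fixed, band-limited complex speckle (field units)."""
    if scene.background_roughness_rms <= 0:
        return np.zeros(shape, dtype=complex)
    rng = np.random.default_rng([scene.seed, 971, 0 if channel == "fs" else 1])
    white = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
    p = config.sample_pixel
    fy = np.fft.fftfreq(shape[0], d=p)[:, None]
    fx = np.fft.fftfreq(shape[1], d=p)[None, :]
    band = fy**2 + fx**2 <= (config.collection_na / config.wavelength) ** 2
    speckle = np.fft.ifft2(np.where(band, np.fft.fft2(white), 0.0))
    rms = np.sqrt(np.mean(np.abs(speckle) ** 2))
    target = scene.background_roughness_rms / config.alpha(channel)
    return speckle * (target / rms)


def background_field(
    scene: SimScene,
    config: OpticalConfig,
    channel: Channel,
    frame_index: int = 0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Unit-modulus background plus roughness speckle and accumulated drift."""
    shape = shape or config.sensor_shape
    bg = 1.0 + _roughness(scene, config, channel, shape)
    phi = frame_index * scene.drift_phase_per_frame
    gy, gx = (frame_index * g for g in scene.drift_gradient_per_frame)
    if phi or gy or gx:
        rows = np.arange(shape[0])[:, None]
        cols = np.arange(shape[1])[None, :]
        bg = bg * np.exp(1j * (phi + gy * rows + gx * cols))
    return bg


def channel_field(
    scene: SimScene,
    config: OpticalConfig,
    channel: Channel,
    frame_index: int = 0,
    shape: tuple[int, int] | None = None,
    include_beads: bool = True,
) -> ComplexField:
    """Ground-truth total field E_bg + sum of bead fields for one channel."""
    shape = shape or config.sensor_shape
    total = background_field(scene, config, channel, frame_index, shape)
    if include_beads:
        for bead in scene.beads:
            pos = bead.position(frame_index)
            if not (0 <= pos[0] < shape[0] and 0 <= pos[1] < shape[1]):
                logger.info(
                    "bead left the field of view at frame %d; skipping", frame_index
                )
                continue
            s = scattered_field(
                bead, config, channel, defocus=pos[2], shape=shape,
                position=(pos[0], pos[1]),
            )
            total = total + scene.scatter_phase * s.values
    return ComplexField(
        values=total,
        channel=channel,
        sample_plane_pixel=config.sample_pixel,
        wavelength=config.wavelength,
        medium_index=config.medium_index,
    )


def render_expected_electrons(
    scene: SimScene,
    config: OpticalConfig,
    frame_index: int = 0,
    shape: tuple[int, int] | None = None,
) -> np.ndarray:
    """Noise-free expected electron image of one frame.

    Expected electrons are

        N_fs |u_fs|^2 + N_bs |u_bs|^2
        + sum_c  2 nu_c N_eff Re[u_c R_c*] ,      N_eff = (N_fs + N_bs) / 2,

    with plane-wave references R_c at the two carriers.  Weighting the AC
    terms by N_eff makes nu_c exactly the per-channel fringe visibility a
    lobe-ratio estimator measures against the shared DC, and reduces to the
    textbook ``N (1 + nu cos)`` for a single-channel scene.
    """
    shape = shape or config.sensor_shape
    n_fs = scene.illumination.get("fs", 0.0)
    n_bs = scene.illumination.get("bs", 0.0)
    n_eff = 0.5 * (n_fs + n_bs)
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    intensity = np.zeros(shape, dtype=float)
    for channel, n_ch in (("fs", n_fs), ("bs", n_bs)):
        if n_ch <= 0:
            continue
        u = channel_field(scene, config, channel, frame_index, shape).values
        carrier = config.carrier(channel)
        ref = np.exp(2j * np.pi * (carrier[0] * rows + carrier[1] * cols))
        nu = scene.visibility.get(channel, 0.0)
        intensity += n_ch * np.abs(u) ** 2
        intensity += 2.0 * nu * n_eff * np.real(u * np.conj(ref))
    if np.any(intensity < 0):
        logger.warning("negative expected electrons clipped to 0 (visibility too high)")
        intensity = np.clip(intensity, 0.0, None)
    return intensity


def render_hologram(
    scene: SimScene,
    config: OpticalConfig,
    camera: CameraModel,
    frame_index: int = 0,
    shape: tuple[int, int] | None = None,
    shot_noise: bool = True,
) -> HologramFrame:
    """Render one camera frame: expected electrons, Poisson sample, quantize.

    Deterministic given (scene.seed, frame_index).  Expected electrons above
    the full well are clipped with a saturation warning.
    """
    expected = render_expected_electrons(scene, config, frame_index, shape)
    if np.any(expected > camera.full_well):
        logger.warning(
            "frame %d: %d pixels exceed the full well; clipping",
            frame_index,
            int(np.sum(expected > camera.full_well)),
        )
        expected = np.clip(expected, 0.0, camera.full_well)
    if shot_noise:
        rng = np.random.default_rng([scene.seed, frame_index])
        electrons = rng.poisson(expected).astype(float)
    else:
        electrons = expected
    return HologramFrame(
        dn=camera.electrons_to_dn(electrons),
        timestamp_index=frame_index,
        camera=camera,
    )


# ---------------------------------------------------------------------------
# Motion models and time series


def brownian_trajectory(
    n_frames: int,
    start: tuple[float, float],
    diffusion_um2_s: float,
    config: OpticalConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """2-D Brownian walk in sample-plane pixels; MSD slope = 4 D."""
    dt = 1.0 / config.frame_rate
    step_um = np.sqrt(2.0 * diffusion_um2_s * dt)
    step_px = step_um * 1000.0 / config.sample_pixel
    steps = rng.standard_normal((n_frames - 1, 2)) * step_px
    lateral = np.vstack([np.asarray(start, dtype=float), steps]).cumsum(axis=0)
    return np.column_stack([lateral, np.zeros(n_frames)])


def flow_trajectory(
    n_frames: int,
    start: tuple[float, float],
    velocity_px_frame: tuple[float, float],
) -> np.ndarray:
    """Constant-velocity lateral drift (a bead flowing through the FOV)."""
    t = np.arange(n_frames)[:, None]
    lateral = np.asarray(start, dtype=float) + t * np.asarray(velocity_px_frame)
    return np.column_stack([lateral, np.zeros(n_frames)])


def simulate_timeseries(
    scene: SimScene,
    config: OpticalConfig,
    camera: CameraModel,
    n_frames: int,
    motion: str = "none",
    velocity_px_frame: tuple[float, float] = (0.0, 0.0),
    diffusion_um2_s: float = 0.0,
    shape: tuple[int, int] | None = None,
    shot_noise: bool = True,
) -> tuple[list[HologramFrame], pd.DataFrame]:
    """Render a hologram time series and its ground-truth trajectory table.

    ``motion`` is ``none`` (trajectories as given), ``flow`` (constant
    velocity applied to every bead from its first position) or ``brownian``
    (Gaussian increments with diffusion coefficient ``diffusion_um2_s``).
    Drift accumulates per frame.  Returns (frames, table) where the table
    has columns frame, bead, row, col, z, diameter, index and a ``time``
    column in seconds.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if motion not in ("none", "flow", "brownian"):
        raise ValueError(f"unknown motion model {motion!r}")
    beads = []
    for b_id, bead in enumerate(scene.beads):
        start = bead.position(0)
        if motion == "flow":
            traj = flow_trajectory(n_frames, start[:2], velocity_px_frame)
            traj[:, 2] = start[2]
        elif motion == "brownian":
            rng = np.random.default_rng([scene.seed, 7_001, b_id])
            traj = brownian_trajectory(
                n_frames, start[:2], diffusion_um2_s, config, rng
            )
            traj[:, 2] = start[2]
        elif motion == "none":
            traj = bead.trajectory
        else:
            raise ValueError(f"unknown motion model {motion!r}")
        beads.append(BeadSpec(bead.diameter, bead.index, traj))
    moving = SimScene(
        beads=beads,
        background_roughness_rms=scene.background_roughness_rms,
        drift_phase_per_frame=scene.drift_phase_per_frame,
        drift_gradient_per_frame=scene.drift_gradient_per_frame,
        visibility=scene.visibility,
        illumination=scene.illumination,
        scatter_phase=scene.scatter_phase,
        seed=scene.seed,
    )
    frames = [
        render_hologram(moving, config, camera, t, shape, shot_noise=shot_noise)
        for t in range(n_frames)
    ]
    rows = []
    for t in range(n_frames):
        for b_id, bead in enumerate(beads):
            pos = bead.position(t)
            rows.append(
                {
                    "frame": t,
                    "time": t / config.frame_rate,
                    "bead": b_id,
                    "row": pos[0],
                    "col": pos[1],
                    "z": pos[2],
                    "diameter": bead.diameter,
                    "index": bead.index,
                }
            )
    return frames, pd.DataFrame(rows)
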