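# bqsm — bidirectional quantitative scattering microscopy

`bqsm` is a toolkit for label-free microscopy that images forward-scattered
(FS, transmission) and backward-scattered (BS, epi) light from the same
field of view simultaneously, encoded on one camera frame by off-axis
holography with two fringe carriers.  It is written for microscopists and
image analysts working with quantitative phase imaging (QPM) and
interferometric scattering (iSCAT) who want both modalities on a common
quantitative scale.

Both channels are reduced to the **scattering-field amplitude**

```
SA = |E_s| / |E_i| = alpha * |E_sample - E_bg| / |E_bg| ,    0 <= SA <= 2,
```

where `E_sample`/`E_bg` are the reconstructed complex fields with and
without the sample and `alpha` is the background's field transmittance
(FS: 1) or the glass–water reflectivity (BS: 0.07).  Because the BS
background carries only `alpha^2 ~ 1/204` of the photons, the epi channel
tolerates ~204x stronger illumination and reaches a shot-noise floor ~14x
below the transmission channel — nanoscale particles and microscale cell
structure become visible in one shot.  The shot-noise floor follows

```
dSA_shot = 2 sqrt( (4 - pi) A_aperture / (2 nu^2 N_electron A_sensor) )
```

(`nu` fringe visibility, `N_electron` mean electrons/pixel, `A_aperture`
the NA window in frequency pixels).  FS–BS cross-section pairs
(`sigma = ∬ |SA|^2 dx dy`) are inverted through a Mie forward model to
recover particle refractive index and diameter.

The package contains:

- `bqsm.model` — instrument constants, camera electron model, domain types
- `bqsm.simulator` — physics-based hologram simulator with ground truth
  (beads, Poisson noise, substrate roughness, drift, flow/Brownian motion)
- `bqsm.reconstruction` — demultiplexing, angular-spectrum refocusing,
  autofocus, phase-drift correction, SA images
- `bqsm.noise` — temporal noise maps, visibility/electron estimation, the
  analytic shot-noise floor
- `bqsm.particles` — detection, cross-sections, backgrounds (flow window /
  long-time mean), Mie forward model, (n, d) inversion
- `bqsm.dynamics` — band-limited temporal fluctuation maps (LF 1–10 Hz,
  HF 100–250 Hz at 500 fps)
- `bqsm.cellmaps` — dry-mass maps/totals from phase, fringe-count height
- `bqsm.io` / `bqsm.cli` — TIFF/JSON I/O and the `bqsm` command line

## Worked example

Simulate shot-noise-limited no-sample stacks for both channels at equal
photon budget (20,000 e⁻/px, visibility 0.5, 256×256 px, 200 frames) and
compare the measured temporal SA noise with the analytic floor; then
characterize a 203-nm silica bead from its noise-free cross-section pair:

```python
import numpy as np
from bqsm import (OpticalConfig, CameraModel, SimScene, render_hologram,
                  noise_report_from_holograms, forward_model,
                  ScatterModelGrid, invert_ri_size)

cfg = OpticalConfig(sensor_shape=(256, 256), sensor_pixel_pitch=7000.0,
                    aperture_radius_px=28.0,
                    carrier_fs=(0.3125, 0.0), carrier_bs=(0.0, 0.3125))
cam = CameraModel()

for ch in ("fs", "bs"):
    vis = {"fs": 0.0, "bs": 0.0}; ill = {"fs": 0.0, "bs": 0.0}
    vis[ch], ill[ch] = 0.5, 20_000.0
    scene = SimScene(visibility=vis, illumination=ill, seed=1)
    frames = [render_hologram(scene, cfg, cam, t) for t in range(200)]
    rep = noise_report_from_holograms(frames, cfg, ch, window=200)
    print(f"{ch}: measured {rep.scalar_noise:.3e}  theory {rep.theory_floor:.3e}")

grid = ScatterModelGrid.build(cfg, n_step=0.004, d_step=5.0)
ref  = forward_model(1.598, 151.0, cfg)   # 150-nm polystyrene reference
meas = forward_model(1.43, 203.0, cfg)    # "measured" silica bead
res  = invert_ri_size(meas[0]/ref[0], meas[1]/ref[1], grid, ref)
print(f"inverted: n = {res['n']:.3f}, d = {res['d']:.1f} nm")
```

Output:

```
fs: measured 3.582e-03  theory 3.592e-03
bs: measured 2.513e-04  theory 2.515e-04
inverted: n = 1.430, d = 203.0 nm
```

The measured noise matches the shot-noise theory within 0.3% in both
channels, and their ratio (3.582e-3 / 2.513e-4 ≈ 14.3) is the dynamic-range
expansion factor.  The inversion recovers the bead's refractive index and
diameter exactly from the normalized FS/BS cross-section pair.

The same pipelines are scriptable from a shell:

```
bqsm simulate --seed 3 --n-frames 500 --bead 203,1.43,512,512 --out-dir sim
bqsm reconstruct --holograms sim/holograms.tif --background bg/holograms.tif
bqsm noise-floor --stack bg/holograms.tif --channel bs
bqsm dynamics --stack fields.tif --band 1:10 --band 100:250
```

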