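# Methods

## The measurement model

The instrument records forward-scattered (FS, transmission) and
backward-scattered (BS, epi) light from the same field of view on a single
camera, using off-axis digital holography with two distinct fringe
carriers (spatial-frequency multiplexing).  Both channels are reduced to a
common dimensionless observable, the scattering-field amplitude

    SA = |E_s| / |E_i| = alpha * |E_sample - E_bg| / |E_bg| ,

where `E_sample` and `E_bg` are the measured complex fields with and
without the sample, `E_s = E_sample - E_bg` the scattered field, `E_i` the
incident field, and `alpha` the field transmittance (FS, `alpha = 1`) or
the glass/water reflectivity (BS, `alpha = 0.07`, the normal-incidence
Fresnel coefficient of a 1.52/1.33 interface).  `0 <= SA <= 2` by
definition; the maximum is attained when the sample field exactly opposes
the background.

Because the BS background carries `alpha^2 ~ 1/204` of the photons, the
epi illumination can be raised ~204-fold before saturating the sensor,
which lowers the minimum detectable SA by `1/alpha ~ 14` relative to the
transmission channel at the same full well.  This dynamic-range expansion
is the package's central quantitative claim, and `scripts/acceptance.py`
re-measures it end to end through the simulator and pipeline.

## Reconstruction

1. **Demultiplexing** — the hologram (in photo-electrons) is multiplied by
   `exp(-i 2 pi f_c . r)` for the channel's carrier `f_c`, Fourier
   transformed, truncated to the numerical-aperture disc
   (`aperture_radius_px`, 115 px on the 1024-px instrument grid, i.e.
   `round(pi/4 * 230^2) = 41,548` retained frequency pixels), and inverse
   transformed.  The pre-FFT phase ramp makes the lobe translation exact
   for any carrier.
2. **Refocusing** — angular-spectrum propagation,
   `exp(i 2 pi z sqrt((n/lambda)^2 - f^2))`, evanescent components zeroed.
   Autofocus maximizes a sharpness metric of the differential field
   `|E_sample - E_bg|` over a z grid; the default metric is amplitude
   kurtosis (Tamura, gradient energy and peak intensity are selectable).
3. **Drift correction** — the inter-acquisition phase drift is modeled as
   a global offset plus a linear ramp, fitted by least squares to the
   wrapped phase of `E_sample / E_bg` over sample-free pixels (user mask
   or automatically the 20th percentile of `|ratio - 1|`).  No unwrapping
   is performed; the model assumes drift well below pi across the frame.

## Noise model

Temporal noise is measured exactly as an instrument operator would:
consecutive-frame differential SA images (N frames give N-1
differentials), per-pixel temporal standard deviation, spatial mean over a
200 x 200 window.  Under shot-noise-limited operation the expected floor is

    dSA_shot = 2 sqrt( (4 - pi) A_aperture / (2 nu^2 N_electron A_sensor) )

with `nu` the fringe visibility (AC/DC spectral-lobe amplitude ratio,
factor 2 because each AC lobe carries half the modulation), `N_electron`
the mean electrons per pixel (digital numbers times the gain,
`full_well / 2^bit_depth = 100,000 / 4096 ~ 24.4 e-/DN`), and
`A_aperture / A_sensor` the retained fraction of frequency pixels.  The
`sqrt((4-pi)/2)` factor is the standard deviation of the modulus of a
circular Gaussian perturbation (Rayleigh statistics); the formula is
validated as a whole against Monte-Carlo simulation (5% criterion) rather
than re-derived term by term.  Per channel the floor scales by `alpha`,
giving the factor-14 FS/BS ratio at equal photon budgets.

## Simulator

The bundled simulator emulates, per channel: a unit-modulus background
field; optional static substrate-roughness speckle (complex Gaussian,
band-limited to the NA, seed-fixed, rms specified in SA units); cumulative
phase drift (global offset + linear ramp per frame); and bead fields.  A
bead's field is the inverse transform of a hard-edged NA pupil with an
angular-spectrum defocus phase, scaled so its integrated squared SA equals
the Mie forward model's cross-section for that channel.  Expected
electrons per pixel are

    N(x) = N_fs |u_fs|^2 + N_bs |u_bs|^2
           + sum_c 2 nu_c N_eff Re[u_c R_c*] ,   N_eff = (N_fs + N_bs)/2 ,

with plane-wave references `R_c` at the carriers; weighting the AC terms
by `N_eff` makes `nu_c` exactly the visibility the AC/DC estimator
measures and reduces to `N (1 + nu cos)` for a single channel.  Poisson
shot noise and 12-bit quantization at a 100 ke- full well follow;
`(seed, frame_index)` fully determine each frame.  Motion models: none,
constant-velocity flow, and Brownian steps (Gaussian increments,
`MSD = 4 D tau` laterally).

Simplifications, stated: cross terms between the two channels' object
fields and between the two references are omitted (suppressed in the
instrument by the source's short coherence length); image formation is
scalar and aberration-free; the tilted epi illumination geometry is not
modeled.  Consequently the simulator does not exercise polarization or
aberration robustness, and passing tests say nothing about those aspects
of real data.

Two geometric facts discovered during validation and worth keeping in
mind when configuring scenes: carriers should sit on integer DFT bins
(otherwise the non-demodulated hologram terms are non-periodic on the
grid and their spectral leakage contaminates the lobes), and the carrier
offset should exceed the aperture radius plus twice the NA bandwidth so
the object fields' second-order self-interference halo stays clear of the
AC lobes.  The instrument-scale default configuration and the test
geometries satisfy both.

## Particle characterization

Cross-sections integrate the squared SA image (`sigma = ∬ |SA|^2 dx dy`,
sample-plane px^2, convertible to nm^2 via the 9 um / 208x ~ 43 nm pixel).
Two estimators: a radial Gaussian fit returning the analytic
`A^2 pi s^2` (beads; the fitted offset suppresses background), and direct
pixel summation over the ROI disc or over the connected component above
3x the local median absolute deviation (intracellular BS particles, where
membrane fluctuations spoil fits).  Backgrounds: the flow protocol
averages the outer 100-frame blocks of a 401-frame window centered on the
particle frame (frames -200..-101 and +101..+200); the intracellular BS
background is the long-time (5000-frame) complex mean, which cancels a
particle whose scattered phase walks.

The forward model is a Mie partial-wave series (implemented in-package on
scipy spherical Bessel functions; coefficients by downward recurrence of
the logarithmic derivative) integrated over the forward and backward
collection caps, `theta_max = arcsin(NA/n_med)` — full hemispheres for
NA 1.33 in water.  It reproduces the Rayleigh closed form below x ~ 0.1
and the independent `Qsca` coefficient identity at all sizes.  In the
Rayleigh limit `sigma_FS/sigma_BS -> 1` and `sigma ∝ d^6`; in the Mie
regime forward scattering dominates and the backward-cap integral
oscillates above d ~ 210 nm (the physical reason the epi channel
saturates for large objects).  Because of those oscillations the
`(sigma_FS, sigma_BS) -> (n, d)` map is not globally injective; inversion
is therefore reported with a residual, and exact parameter recovery is
only guaranteed on the injective domain (roughly d <= 250 nm at these
wavelengths).

Inversion minimizes the squared log-distance between measured and model
cross-section pairs — log space because sigma spans orders of magnitude —
over a precomputed `(n, d)` grid, followed by Nelder-Mead refinement on
the continuous model.  Default grid: `n` in [1.34, 1.70] step 0.002
(widened above the polystyrene index ~1.598 at 515 nm so that noisy
reference-bead estimates are not truncated at the edge, which would bias
population means), `d` in [20, 1000] nm step 2 nm; intracellular analyses
can restrict `n` to the physiological [1.38, 1.54].  Uncertainties
propagate input relative cross-section errors through the local Jacobian
of `(log sigma_FS, log sigma_BS)`.  Measurements are normalized channel-
wise by the mean cross-section of a 150-nm polystyrene reference
population (index 1.598 at 515 nm, configurable — the value is a standard
dispersion-table figure, not measured here), after per-particle temporal
averaging (~100 frames).

The population-recovery validation draws bead diameters from the nominal
distributions (151 +- 3 nm polystyrene, 203 +- 12 nm silica) and applies
lognormal measurement noise with a 20% coefficient of variation per
channel.  That single calibration, chosen once, reproduces a realistic
measured silica size spread (~18 nm at a 12-nm intrinsic spread) and a
characteristic overlap of FS cross-section distributions alongside clean
BS separation; under it the inversion recovers both population means
within 0.01 refractive-index units and 10 nm.

## Dynamic maps

Time series of complex ratio fields are processed per the instrument's
recipe: per-frame normalization by the spatial mean (amplitude ratio and
phase offset), subtraction of each pixel's 11 x 11 neighborhood mean
(mirror padding) to remove slow spatially-global background variation,
then a per-pixel brick-wall Fourier band selection (temporal mean removed;
no further detrending — the 1 Hz lower band edge already excludes drift)
and the temporal standard deviation.  The reported value combines both
quadratures, `alpha * sqrt(std_re^2 + std_im^2)` (amplitude-only and
phase-only variants selectable), because the instrument's band-passed
observable is not specified more precisely; the quadrature-combined form
is invariant to the perturbation's phase direction.  The brick-wall filter
makes the maps exactly testable: a fixed-direction perturbation of peak
modulus A at an in-band frequency yields A/sqrt(2); disjoint bands add in
power (Parseval).  Standard bands: 1-10 Hz (LF) and 100-250 Hz (HF) at
500 fps.

## Cell-scale maps

Dry-mass surface density from unwrapped FS phase:
`rho = lambda phi / (2 pi gamma)` with refraction increment
`gamma = 0.18 mL/g` (standard protein value, configurable); totals are
sums over a required cell mask times the pixel area.  Cell height from the
epi channel's Newton's-ring-like fringes is a deliberately minimal
estimator: count fringe extrema along a profile, `lambda / (2 n_med)`
(~193.6 nm in water) of height per full fringe.  No 2-D height map and no
RI/thickness decoupling are attempted.

## Problem sizes and numerical choices

Validation runs use scaled-down geometries that preserve the instrument's
dimensionless relationships (NA window within the carrier separation,
carriers within Nyquist): 256 x 256 or 128 x 128 sensors, 28- or 14-px
apertures, carriers at 0.3125 cycles/px, 100-300 frame stacks, 60-bead
populations, and a coarse model grid (0.004 / 5 nm) whose local
refinement step removes any dependence on grid pitch.  The acceptance
script uses 250 frames per channel at 256 x 256 with a 20,000 e-/px
budget and visibility 0.5.  Ties in non-maximum suppression resolve by
descending peak value; Gaussian fits that fail fall back to pixel
summation with a warning; background magnitudes below 1e-6 of their
median flag pixels invalid rather than dividing; SA values outside [0, 2]
are reported unclipped with a warning, since they indicate a
misconfigured alpha rather than data.
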