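# Methods

`elastofun` implements a complete analysis chain for *concurrent* functional
MRI / functional MR elastography (fMRI–fMRE): a single complex-valued
acquisition whose magnitude carries a BOLD-weighted fMRI signal and whose
phase carries motion-encoded shear-wave displacement. Because no public
dataset exists for this experiment type, the package ships a digital phantom
that generates the full raw data with a known ground truth; every downstream
stage is validated against it.

## The experiment being modelled

A 12-slice, 64×64, 3.5 mm isotropic slab over the visual cortex is imaged
while a pneumatic driver vibrates the head at 60 Hz. Motion is encoded with
four Hadamard-combined MEG directions and three phase offsets over one
vibration period (16.67 ms); one magnitude frame is produced per second and
one elastogram per 12 s bin (12 frames = 4 MEG × 3 offsets). The stimulus is
a 16-block × 24 s ON/OFF checkerboard paradigm (384 s, so 384 magnitude
frames and 32 elastogram bins per scan), run once at each of four luminance-
matched contrast levels (5, 20, 60, 100%).

## Digital phantom (`phantom`)

**Tissue model.** Uniform baseline shear stiffness `mu_background_kpa`
(default 3.0 kPa, a conventional brain value) and density 1000 kg/m³. A box
ROI standing in for V1 (default: matrix/4 in-plane, all but the outermost
slices — large enough that the 7×7×5 smoothing support leaves an
uncontaminated core) carries the functional effects.

**Effects.** Inside the ROI, stiffness per 12 s bin is
`mu_bg · (1 + dmu_frac · cr(c) · m(t))` where `m(t)` is the paradigm boxcar
convolved with the slow stiffness-response kernel (below), peak-normalised
and sampled at bin centres; magnitude per 1 s frame is
`M0 · (1 + bold_frac · cr(c) · h(t))` with `h` the canonical HRF
convolution. The contrast response `cr(c) = (0.03 + 0.0013·c)/0.16` and the
peak effects (`dmu_frac = 0.16/3 ≈ 5.3%` stiffness, `bold_frac = 0.9%`
magnitude at 100% contrast) reproduce the published group-level
contrast-response relation Δµ = 0.0013·c + 0.03 kPa for a 3 kPa baseline.

**Wave model.** The displacement field is a superposition of `n_sources`
(default 4) transverse plane waves with random directions, polarizations and
phases. Each wave's phase is a straight-ray path integral of the local
wavenumber `k(x) = ω√(ρ/µ(x))` (an eikonal solution with straight rays), so
the field is continuous across stiffness interfaces and its local phase
gradient equals the local wavenumber — the regime direct inversion assumes.
For the two-valued maps the generator produces this reduces to
`k_bg(n̂·x) + Δk·L(x)` with `L` the ray chord length through the ROI
(computed numerically by trilinear ray marching at half-voxel steps, once
per source per subject). Refraction, scattering, attenuation and mode
conversion are not modelled; the local-homogeneity assumption that justifies
this is the same one direct inversion makes.

**Encoding and noise.** Voxel phase is `enc · (H·u)(t_j)` with `H` the
tetrahedral Hadamard matrix [[+,+,+],[+,−,−],[−,+,−],[−,−,+]] and offsets at
0, T/3, 2T/3; the default `enc = 0.05 rad/µm` with ~10 µm waves keeps peak
phase ≈ 1.5 rad, below the wrap limit (tests raise it deliberately to
exercise unwrapping). i.i.d. Gaussian noise of standard deviation
`noise_sd · M0` is added to the real and imaginary channels. The default
`noise_sd = 0.01` is calibrated so the per-subject-per-contrast scatter of
recovered Δµ (~0.03 kPa) matches the dispersion the published fit reports
(RMS error 0.03 kPa).

**What passing tests do and do not show.** The phantom is motion-free,
drift-free, already "preprocessed" (no slice timing, realignment or
normalization is needed or implemented), has white complex noise, and a
box-shaped effect region with a uniform effect. Recovery results therefore
demonstrate correctness of the analysis chain, not robustness to
physiological noise, motion, B0 inhomogeneity or realistic wave scattering.

## Reconstruction (`recon`)

Order of operations: phase extraction → unwrap → Hadamard decode →
in-plane high-pass → curl → first-harmonic extraction → quartic smoothing.

- **Unwrapping** uses reliability-ordered unwrapping (scikit-image), with a
  fast path that returns the volume unchanged when no neighbour jump
  exceeds π. It is applied to the four *measured* phase volumes before the
  linear decode, because wrapping does not commute with the pseudo-inverse;
  at sub-π encoded phase both orders coincide.
- **Decode** applies `pinv(H)` (= Hᵀ/4); measured phase noise σ² becomes
  σ²/4 per displacement component (3σ²/4 total).
- **High-pass** subtracts a per-slice Gaussian low-pass with
  σ = 0.8 × the background shear wavelength (≈ 23 mm by default) and then
  zeroes the slice DC exactly. Shear waves at the operating wavelength pass
  with sub-10⁻⁴ amplitude loss; components propagating near the slice
  normal (small in-plane wavenumber) are attenuated — an intrinsic property
  of any in-plane filter applied to 3-D wave fields.
- **Curl** is 2nd-order central differences; it suppresses the
  (curl-free) longitudinal wave contribution and annihilates the per-slice
  constants the high-pass step introduces.
- **First harmonic** over the three offsets is scaled so `A·cos(ωt+φ)`
  yields `A·e^{iφ}`; DC is rejected exactly at evenly spaced offsets.
- **Smoothing** uses a 7×7×5 quartic (biweight) kernel
  `w ∝ (1 − (d/d_max)²)²` with anisotropy-corrected distance and unit sum,
  applied as a normalized convolution so constants survive at the volume
  boundary. The returned interior mask excludes the smoothing half-support
  plus the finite-difference rims; those voxels are never trusted
  downstream.

## Direct inversion (`invert`)

Each curl component obeys the Helmholtz equation locally, giving
`µ_c = −ρω² q_c/∇²q_c`. Components are combined with weights `|∇²q_c|²`
(algebraically `−ρω² Σ q_c conj(∇²q_c) / Σ|∇²q_c|²`, avoiding per-component
division); the reported stiffness is `|µ|` in kPa. Voxels whose Laplacian
magnitude falls below 10⁻⁸ of the field scale are marked invalid rather
than clipped. ρ defaults to 1000 kg/m³.

Numerical caveat: the central-difference Laplacian of `e^{ikx}` is
`−(2−2cos kh)/h²`, underestimating `k²` and hence overestimating µ by
≈ (kh)²/12 per axis — about 4% at 3.5 mm voxels for a 3 kPa / 60 Hz wave.
Accuracy oracles therefore use ≥ 15–20 voxels per wavelength, where the
bias is sub-percent; at acquisition resolution the bias is a known,
direction-dependent few-percent effect shared by baseline and activation
states, so *fractional* stiffness changes are nearly unaffected.

## GLM (`glm`)

Both branches fit voxelwise OLS with task, optional time/dispersion
derivative columns (finite differences in the kernel's peak delay and
dispersion), and an intercept. t = β/SE with two-sided Student-t p-values;
the activation mask is p < 0.001 (uncorrected) *and* β > 0, matching how
stimulus-locked increases are reported; percent signal change is
`100 · β_task · max(task)/β_intercept` (SPM-style event scaling).

Response kernels are differences of gamma densities parameterised by their
modes (shape = 1 + delay/dispersion, scale = dispersion): the canonical
kernel peaks at 6 s with a 16 s undershoot; the stiffness-response kernel
moves the peak to 8 s and lengthens peak-to-undershoot to 100 s (undershoot
mode 108 s, kernel length 128 s). An alternative reading with the
undershoot at 100 s absolute is available as
`DoubleGammaParams.stiffness_response_absolute_undershoot`.

Design columns are sampled at frame/bin centres, consistent with how the
phantom samples its effects; at 12 s bins this avoids a systematic
transition-edge bias in β. Drift and nuisance columns exist behind flags
but default off (the phantom is drift-free).

## Group statistics (`group`)

- **Bootstrap**: subjects are the exchangeable unit (within-subject rows
  travel together); 10,000 resamples by default; percentile 95% CIs. The
  95% CI for a 16-subject median covers the truth ~94% of the time in
  simulation — the small undercoverage of percentile bootstrap at n = 16 is
  a known property, documented rather than hidden.
- **Contrast regression**: OLS of the response on percent contrast across
  all subject×contrast rows, reporting slope, intercept, RMS residual and
  the slope's p-value.
- **Mixed model**: random-intercept REML via statsmodels MixedLM, Wald test
  on the contrast fixed effect.
- **Cohen's d**: one-sample d = mean/SD of per-subject values (the
  convention consistent with published mean ± SD pairs).
- **tSNR**: temporal mean / temporal SD; zero-variance voxels invalid.

## Per-subject stiffness-change summary

In simulation the effect ROI is known, so the per-scan Δµ summary is the
median of `β_task · max(task)` over the *ROI core*: the ROI eroded by the
smoothing half-support plus stencil rims (5, 5, 4 voxels per side). Voxels
nearer the ROI boundary are partial-volume diluted by the 7×7×5 kernel and
would bias recovery low; the eroded core is unbiased (noiseless recovery is
within ~7%, the residual being high-pass sideband attenuation and Laplacian
discretisation). In vivo one would summarise over the activation cluster
instead; the active-voxel median PSC reported alongside mirrors that and is
selection-biased at threshold, as in any thresholded analysis.

## Cohort simulation and problem sizes

The bundled cohort emulates 16 volunteers with ±10% baseline-stiffness and
±20% effect-size variation, 4 contrasts each, at full 64×64×12 resolution
(complex64 arithmetic; ~6 s per scan, ~7 min for the 64-scan cohort).
Operator unit tests run on 16–48 voxel grids where the physics is identical.
Statistical tests fix all seeds; stochastic assertions use binomial or
Monte-Carlo bounds stated in each test.

## Known limitations

- Plane-wave superposition with straight rays: no refraction at the ROI
  boundary, no attenuation, no compressional-to-shear conversion.
- The in-plane high-pass attenuates waves propagating near the slice
  normal; with isotropic source directions a few percent of wave energy is
  lost, part of the ~7% conservative bias in recovered Δµ.
- Direct inversion assumes local homogeneity; voxels within the smoothing
  support of the ROI boundary blend stiffnesses (handled by core erosion in
  summaries, visible as blur in maps).
- Elastogram GLM t-statistics are per-voxel calibrated, but smoothing
  correlates neighbouring voxels, so *counts* of active voxels have
  super-binomial variance (tests bound rates at the kernel-volume resel
  count).
- No multiple-comparison correction (by design: uncorrected p < 0.001), no
  AR(1) prewhitening (noise is white per construction), no spatial
  normalization or motion correction (the phantom provides none to correct).
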