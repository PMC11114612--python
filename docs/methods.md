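# Methods

This note records the models implemented in `crowdprf`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
validation does and does not establish.

## Visual-field raster and stimulus apertures

All stimuli live on a square raster of pixel centres spanning ±9° of
visual angle (the mapped stimulus radius), 101 × 101 pixels by default so
that one pixel sits exactly at fixation and the pixel pitch is 0.18°.
Apertures are binary: luminance, the 4 Hz counterphase flicker and gamma
correction of the physical display are not modelled (the display's Weber
contrast, |0.2 − 151.6|/151.6 ≈ 0.999, is carried as metadata only).

**Drifting bar (pRF mapping).** Bar width is 1/4 of the 9° stimulus radius
(2.25°). Eight sweep directions: the four cardinal directions plus the four
diagonals at 45° — the standard pRF-mapping arrangement. Each sweep holds
16 bar positions of 2 s each (one position per TR); the traverse runs
edge-to-edge over the first 8 positions and retraces in reverse over the
last 8, implementing the motion-direction reversal at the sweep midpoint.
Cardinal bars span the whole raster; diagonal bars are truncated at the
midline along their own length, so they cover only half the field. The
number of positions per sweep is a free design parameter (the acquisition
protocol fixes only the 2 s TR); 16 keeps one position per TR and a 256 s
run.

**Wedge + ring (retinotopy).** A 45°-wide wedge steps clockwise through
16 positions of 22.5° (48 s/cycle) while a 1.5°-wide ring covers 0.2–9°
in a 12-step expansion-plus-contraction cycle (36 s). Six wedge cycles and
eight ring cycles meet at a common 288 s run, so the two components are
exactly separable by Fourier frequency (6 vs 8 cycles/run). TR is 1.5 s.

**Localizer.** 16 s fixation / 16 s stimulation blocks; the stimulation
aperture is the crowding patch — three 0.75° elements, flankers 0.95° from
the target along the radial axis — centred 6.5° from fixation at polar
angle 65° (25° clockwise from the upper vertical meridian), i.e. at
(2.747°, 5.891°).

**Trial schedule.** 432 trials per sub-block, two sub-blocks per block, one
flanker configuration (radial or tangential) per block, two blocks per day
over four days, so each configuration accumulates 864 trials per day. The
printed spacing range "0.75° to 3° in steps of 0.5°" cannot balance 432
trials over spacing × gap-direction cells; the default level set is
therefore six equally spaced levels {0.75, 1.25, 1.75, 2.25, 2.75, 3.25}°
(18 repetitions × 6 levels × 4 gap directions = 432), overridable in the
configuration. Every sub-block is exactly balanced per cell and shuffled by
seed.

## Hemodynamics

The impulse response is the gamma-variate
h(t) = ((t−δ)/τ)^α · exp(−(t−δ)/τ) for t ≥ δ, zero before onset, with
δ = 2.25 s, τ = 1.25 s, α = 2 (peak at δ + ατ = 4.75 s), support 32 s.
The original description of this kernel family used the word "cumulative",
but a cumulative distribution never returns to baseline and cannot serve as
an impulse response; the density form above matches the (δ, τ, α)
parameterization and is what the package uses for both the localizer GLM
and the pRF forward model. Normalization is peak = 1 by default (unit sum
available); the convolution is causal, zero-padded before run onset,
computed on a fine grid no coarser than 0.1 s that divides both the frame
duration and the TR, scaled by the grid step so amplitudes approximate the
continuous integral, and read out at TR midpoints.

## pRF model and estimation

Each voxel's pRF is an isotropic 2D Gaussian, unnormalized (peak 1), with
parameters (x₀, y₀, σ). The neural response to a frame is the pixelwise
overlap between the Gaussian and the binary aperture; the BOLD prediction
is that series convolved with the canonical HRF and sampled at the TR.

Estimation is coarse-to-fine:

* **Coarse**: exhaustive search over a Cartesian (x₀, y₀) grid (1° spacing
  over ±9°) × 12 log-spaced σ values (0.2–9°). The criterion is the squared
  Pearson correlation between prediction and data — amplitude-free, so the
  grid stage needs no per-point regression. Ties are broken toward the
  smaller σ, then the smaller eccentricity. Grid predictions are computed
  once per (movie, HRF, grid) and shared across voxels.
* **Fine**: Nelder–Mead on (x₀, y₀, log σ), minimizing the residual sum of
  squares with amplitude β and baseline profiled out by ordinary least
  squares at every evaluation. The log-σ parameterization keeps σ positive;
  σ is additionally clipped to [0.05°, 18°] so near-flat voxels cannot send
  the simplex to a degenerate plateau. If the simplex fails to improve on
  the seed, the seed is returned (the reported SSR never exceeds the
  seed's). Convergence tolerances: 1e-3 on parameters, 1e-9 × total sum of
  squares on the objective, 400 iterations maximum; non-convergence is
  flagged, not raised.

HRF parameters are never searched. Voxels are retained when R² ≥ 0.05
(boundary inclusive) and β > 0; retained voxels are binned into seventeen
0.5°-wide eccentricity bins over [0.5°, 9°] (half-open intervals, last bin
closed) with per-bin mean σ, SE = sd/√n, and count.

## Phase-encoded retinotopy and field sign

The response phase is the argument of the discrete Fourier component at the
stimulus frequency (6 or 8 cycles/run); coherence is that component's
amplitude divided by the root-sum-square amplitude over all nonzero
frequencies, thresholded at 0.3 by default to admit a voxel into the maps
(a coherence criterion replaces a GLM significance map here because the
synthetic grids carry no nuisance structure). Phase is inverted through the
stimulus schedule after subtracting the hemodynamic delay (δ + ατ = 4.75 s
by default): wedge phase → polar angle of the wedge centre; ring phase →
eccentricity via the expansion half-cycle, with peak times landing in the
contraction half folded back.

One caveat is intrinsic to the ring schedule: a cycle containing both
expansion and contraction is time-symmetric, so a voxel driven by both
passes concentrates eccentricity information in the component's amplitude
and sign rather than its phase. The schedule inversion is exact for
expansion-driven responses and is validated end-to-end only for the wedge
(a simulated voxel at the trained locus is recovered within one 22.5°
wedge step); ring inversion is validated against the schedule itself.

The visual field sign at each node of a rectangular cortical grid is the
sign of the Jacobian determinant of the (polar angle, eccentricity) mapping
with respect to the grid's (x, y) coordinates, by central differences.
Border nodes and nodes with a missing 4-neighbour are undefined. The sign
is invariant to offsets and positive rescaling of either map and flips
across a mirror reversal, which is how area boundaries appear; boundary
*delineation* beyond the sign map (cutting, flattening, manual outlining)
is out of scope.

## Localizer GLM

Per-voxel OLS of the time series on the HRF-convolved boxcar plus
intercept; t = β/SE(β) with n − 2 degrees of freedom, two-sided p. A
linear-drift nuisance column is available behind a flag but off by default
(synthetic series carry no drift). Voxels are retained at p ≤ 0.001
(inclusive, uncorrected — a correction switch exists) with positive
stimulation β, since the contrast of interest is stimulation > fixation.

## Psychophysics

Proportion correct per spacing is fitted by maximum likelihood with
p(s) = γ + (1 − γ − λ)(1 − exp(−(s/θ)^β)), guess rate γ = 0.25 (4AFC) and
lapse rate λ fixed at 0.01; the binomial log-likelihood is maximized over
(log θ, log β) by Nelder–Mead. The 68% criterion sits near this family's
natural threshold for a 0.25 guess rate. Critical spacing is the
closed-form inverse of the fitted function at 68% correct; estimates
outside the tested spacing range are flagged and excluded, never
extrapolated. If the ML fit fails or lands absurdly outside the data range,
the package falls back to isotonic (monotone) interpolation of the observed
proportions, flagged as such. Per day, C_r and C_t are the means of the
day's sub-block estimates (a pooled-trials alternative exists behind a
flag) and C_a = (C_r − C_t)/(C_r + C_t).

## Inferential statistics

`paired_t_bca` computes the paired t on subject-level differences and a
95% BCa bootstrap interval for the t value: B = 10,000 resamples of the
differences by default, bias correction z₀ from the fraction of bootstrap
statistics below the observed one, acceleration from the jackknife skewness.
Degenerate inputs are flagged (all-zero differences: t = 0, p = 1;
constant nonzero differences: undefined). Shapiro–Wilk normality screening
is attached as an advisory flag; the pipeline never auto-switches tests.

`rmanova_gg` decomposes a complete balanced subject × 2 × 4 table into
within-subject sums of squares, testing each effect against its own
subject-by-effect interaction. Greenhouse–Geisser ε per effect comes from
the eigenvalues of the covariance of orthonormal (Helmert) contrast scores
— exactly 1 for 2-level factors, bounded below by 1/(k−1) — and corrected
p values use ε-deflated degrees of freedom. Mauchly's sphericity test is
attached as an advisory flag. Effect sizes: paired Cohen's d =
mean(diff)/sd(diff); partial η² = SS_effect/(SS_effect + SS_error). All p
values are two-sided and uncorrected for multiplicity.

## Synthetic generators

All generators are pure functions of (configuration, seed).

**Voxels.** True pRF sizes follow σ = intercept + slope·eccentricity with
a small Gaussian jitter (0.05°): intercept 0.8°, slope 0.025°/° for
V1-like ROIs (σ ≈ 0.8–1.0° over 0.5–9°) and intercept 1.0°, slope
0.055°/° for V2-like ROIs and the trained ROI (σ ≈ 1.0–1.5°), matching the
magnitudes such measurements typically produce. Ventral ROIs draw polar
angles in the upper field, dorsal in the lower field; trained-ROI centres
fall within 1.5° of the trained locus (2.747°, 5.891°). Post-training σ is
pre-training σ × (1 − effect) in designated ROIs (default 21% in the
trained ROI); an optional foveal centre shift is off by default. Time
series are baseline + β × prediction + noise, with β ~ U(0.8, 1.2) and
baseline ~ N(100, 10). Noise is white by default (AR(1) optional) with SD
0.5 × the voxel's signal SD per acquisition; because the mapping protocol
acquires the bar run four times per session and averages them, the
generator returns the 4-run average by default, i.e. averaged-noise SD =
sd_ratio/√4 × signal SD. The pipeline's injected-effect validation runs at
sd_ratio 0.1 — a deliberately clean condition for testing recovery of the
injected effect, not an estimate of empirical fMRI noise.

**Observers.** Day-by-orientation group-mean critical spacings default to
the printed day-1 and day-4 values (radial 2.39° → 1.60°, tangential
1.54° → 1.26°) with smoothly interpolated middle days (radial 2.05°,
1.80°; tangential 1.44°, 1.34°). Each subject carries one lognormal
proficiency factor (SD 0.2 on the log scale, matching the printed
between-subject SDs of roughly 0.2–0.4 × the mean) applied to every cell,
plus a 0.05 per-cell jitter. Because the factor is common to both
orientations it cancels in C_a, so the generative group C_a is the ratio
of means (0.216 on day 1, 0.119 on day 4). Responses are Bernoulli draws
from the Weibull psychometric whose 68% point sits at the subject's true
critical spacing (shape β = 3); errors spread uniformly over the three
wrong gap directions.

**Cortical grids.** Two regions with mirrored polar-angle progressions
along rows and a smooth eccentricity gradient along columns, with the
ground-truth boundary row stored; optional Gaussian map noise.

## What the validation shows — and does not

Passing tests establish that the estimation chain is *internally
consistent*: noiseless voxels are recovered to < 0.05° in every parameter,
the coarse stage agrees exactly with an exhaustive-search oracle, an
injected 21% σ reduction is reported as 21 ± 1% end-to-end with a
significant paired test at n = 15, the GLM's type-I error and the BCa
interval's coverage are calibrated, and simulated training produces the
expected decline in critical spacing and anisotropy. The generators do not
emulate physiological noise structure (cardiac/respiratory cycles, motion,
drift beyond optional AR(1)), receptive-field ellipticity or surround
suppression, cortical magnification or anatomical geometry, or fixational
eye movements — so passing tests demonstrate correctness of the analysis
given the model's assumptions, not robustness of the conclusions to
real-data violations of them.

## Problem sizes

The validation runs use desk-scale sizes chosen once: 41-pixel rasters in
the unit tests (101 in the pipeline default and the acceptance script),
8–12 voxels per ROI per subject for 15 simulated subjects (real trained
ROIs contain a few hundred voxels; a dozen suffices to test recovery of the
injected group effect), 2,000-resample bootstrap inside the 1,000-repeat
coverage study, and the full B = 10,000 elsewhere.

## Known limitations

* The isotropic Gaussian cannot express pRF shape changes; an elliptical
  or difference-of-Gaussians model is out of scope by design.
* Ring-phase eccentricity is ambiguous under the combined
  expansion/contraction cycle (above).
* The fine fit's simplex can stall on very low-SNR voxels; such voxels are
  typically removed by the R² filter, and the convergence flag is carried
  in the output.
* Out-of-range critical spacings are excluded rather than imputed, which
  can bias day-level means for observers whose true threshold sits at the
  edge of the tested spacing range.
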