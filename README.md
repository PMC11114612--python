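# crowdprf

Tools for studying how training on a peripheral **visual crowding** task
reshapes **population receptive fields (pRFs)** in early visual cortex —
implemented as a fully synthetic, ground-truth-validated pipeline.

Crowding is the breakdown of peripheral object recognition in clutter: a
Landolt C at 6.5° eccentricity that is easy to identify alone becomes hard
to identify when flanking rings sit within its *critical spacing* (the
centre-to-centre distance at which identification reaches 68% correct in a
4AFC task). Receptive-field theory predicts that crowding weakens when the
pRFs pooling target and flankers shrink. Testing that prediction requires
two measurement chains, both implemented here:

1. **fMRI chain** — binary stimulus apertures (drifting bars, a rotating
   wedge combined with an expanding/contracting ring, a block-design
   localizer), a gamma-variate hemodynamic response
   `h(t) = ((t−δ)/τ)^α e^−(t−δ)/τ` (δ = 2.25 s, τ = 1.25 s, α = 2), and an
   isotropic 2D-Gaussian pRF model `w(x,y) = exp(−((x−x₀)² + (y−y₀)²)/2σ²)`
   fitted voxel-by-voxel in two stages: a brute-force grid search on
   (x₀, y₀, σ) maximizing squared correlation, then a Nelder–Mead
   refinement minimizing residual sum of squares with amplitude and
   baseline profiled out by least squares. Voxels are kept when R² ≥ 0.05
   and β > 0, then summarized as mean σ in 0.5° eccentricity bins
   (0.5–9°). Phase-encoded retinotopy (Fourier phase at 6 wedge / 8 ring
   cycles per 288 s run) and a visual-field-sign map (sign of the Jacobian
   of the polar-angle/eccentricity mapping) locate area borders on a
   cortical grid; a p ≤ 0.001 block-design GLM defines the trained ROI.
2. **Psychophysics chain** — balanced 432-trial sub-blocks by the method
   of constant stimuli, maximum-likelihood cumulative-Weibull psychometric
   fits (guess rate 0.25), critical spacing at 68% correct, and the
   crowding anisotropy index `C_a = (C_r − C_t)/(C_r + C_t)` contrasting
   radial vs tangential flankers.

Inference uses paired t-tests with 10,000-sample BCa bootstrap confidence
intervals and 2 × 4 repeated-measures ANOVA with Greenhouse–Geisser
correction, plus Cohen's d and partial η².

Because no raw subject data accompany the design, every stage is validated
on synthetic data generated by the package itself: Gaussian-pRF voxels with
a configurable post-training σ reduction concentrated at the trained locus,
and simulated observers whose critical spacing shrinks over four training
days. The generators store their ground truth, so the pipeline's output can
be checked against what was injected.

## Worked example

```python
from crowdprf import run_full_pipeline

report = run_full_pipeline({"seed": 1,
                            "synthetic": {"n_subjects": 15,
                                          "n_per_roi": {"tROI": 12}}})
troi = report["prf"]["roi_summary"]["tROI"]
print(f"tROI pRF size: {troi['mean_sigma_pre']:.3f} -> "
      f"{troi['mean_sigma_post']:.3f} deg "
      f"({troi['percent_change']:.1f}% reduction), "
      f"t({troi['dof']}) = {troi['t']:.1f}, p = {troi['p']:.2g}")
ca = report["psychophysics"]["group_means"]
print(f"C_a day 1 = {ca['1']['C_a']:.3f}, day 4 = {ca['4']['C_a']:.3f}")
```

prints

```
tROI pRF size: 1.361 -> 1.075 deg (21.0% reduction), t(14) = 82.7, p = 3.1e-20
C_a day 1 = 0.195, day 4 = 0.110
```

i.e. the configured 21% pRF-size reduction injected into the trained ROI is
recovered by the full estimation chain across 15 simulated subjects, and
the simulated training effect (day-1 critical spacings 2.39°/1.54° falling
to 1.60°/1.26° by day 4) appears as the anisotropy index dropping by about
half. The same pipeline is available from the shell:

```bash
crowdprf all --seed 1 --out runs/demo      # full study, report + TSVs
crowdprf simulate --seed 1 --out runs/sim  # just the synthetic matrices
crowdprf psychophysics --seed 1 --out runs/psy
```

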