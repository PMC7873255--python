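# Methods

This note documents the models implemented in `chromokin`, the defaults
and their units, the numerical choices, and what the synthetic-data
generators do and do not emulate.

## Fast-tracking kinetic model

Tracks acquired at short exposures (default Δt = 15 ms) sample a mixture
of diffusive states. Jump lengths are collected for frame lags
k = 1…8, at most 4 jumps per track per lag (so long-lived immobile
tracks do not swamp the histograms), binned at 0.01 µm up to a maximum
jump of 5.05 µm. For a state with diffusion coefficient D, the 2D jump
length over lag kΔt, observed with independent Gaussian localization
error σ (default 0.04 µm) on each coordinate of both endpoints, is
Rayleigh with

    E[r²] = 4 D k Δt + 4 σ²,   CDF(r) = 1 − exp(−r² / (4 D k Δt + 4 σ²)).

The error term is lag-independent because a jump has exactly two
localized endpoints regardless of the lag; an alternative convention
that accumulates 4kσ² is available via `sigma_mode="per_lag"`.

**Defocalization.** Only molecules inside the axial detection slab
(depth dZ = 0.7 µm under HILO illumination) are observed, so diffusing
molecules are progressively lost at longer lags and an uncorrected fit
overstates the bound fraction. Two survival functions are implemented:

1. `defocalization_probability` — the classical continuous-time
   absorbing-slab eigenfunction series,
   S(t) = Σ_{n odd} 8/(nπ)² · exp(−(nπ)² D t / dZ²), truncated when
   terms fall below 1e−10. It is validated against an independent
   Monte-Carlo oracle (walkers with Brownian-bridge boundary-crossing
   corrections between substeps) to 0.5%.
2. A frame-sampled survival used inside the fit: the probability that a
   molecule starting uniformly in the slab is inside at each of k frame
   times (it may exit and re-enter between exposures), computed by
   iterating the Gaussian transition kernel on an 81-point grid over the
   slab. This matches how tracks actually terminate — presence is only
   checked at exposures.

The per-lag mixture weight of state i is
f_i · Z_i(k) / Σ_j f_j Z_j(k) with
Z_i(k) = (1/c) Σ_{j=0}^{c−1} S_i(k + j), c = 4 the per-track jump cap.
The sum accounts for track-length sampling: the expected number of lag-k
jumps a track contributes is Σ_j S(k+j), saturating at the cap for
long-lived (bound) tracks. Without this term, bound tracks (which
almost always contribute the full 4 jumps) would be over-weighted
relative to fast tracks (which rarely survive long enough to contribute
more than one), biasing the fitted bound fraction upward by several
percentage points. Photobleaching multiplies all states by a common
factor per lag and is therefore absorbed by the per-lag renormalization
to first order.

**Optimization.** The model CDF is fitted to the empirical per-lag CDFs
by bounded nonlinear least squares (`scipy.optimize.least_squares`,
trust-region reflective). State fractions use a stick-breaking
parameterization so they always form a simplex; diffusion coefficients
are bounded to [1e−4, 25] µm²/s. Three optimizer restarts from jittered
initial values are run (the restart RNG is fixed, so fits are
deterministic); the best solution is kept, ties broken by lowest
residual then lowest fast-state D. States are labelled by increasing D
(bound < slow < fast). When two states converge to the same D their
individual weights are unidentifiable; the weight is concentrated on one
of them as a gauge fix. CDF (rather than PDF) fitting is the default.

## Residence times and search times

In the slow-tracking regimes (0.5 s exposures at 2 Hz; 1 s at 0.03 Hz)
diffusing molecules blur out, so every linked track is treated as a
bound molecule and its duration as an apparent dwell time (minimum track
length 2 frames, configurable; gap frames contribute their full frame
interval, since excluding them would bias survival short). The
empirical survival S(t) = fraction of events with dwell ≥ t is fitted
with a biexponential whose components are normalized at the first
observed time t₁; the fit is unweighted least squares at the observed
event times (a binned log-space alternative is a flag). τ₂ > τ₁ by
labelling and the stable fraction is the long component's amplitude.

Because photobleaching is exponential and independent of binding, the
censored survival is again biexponential with rates shifted by
1/t_bleach and unchanged amplitudes — so the fitted stable fraction is
unbiased under censoring, and the bleach correction

    t_bound = t_dwell · t_bleach / (t_bleach − t_dwell)

applied to a fitted censored time constant recovers the true one
exactly. t_bleach is measured per experiment from an H2B control
(stably incorporated into chromatin for hours, so its track loss is
bleaching-dominated); it is estimated as the fitted single-exponential
survival constant rather than the sample mean, because the right tail
dominates the mean. When t_dwell ≥ t_bleach, or the corrected time
exceeds 2·t_bleach, the estimate is numerically unstable and the result
is reported as a bleach-limited flag (binding likely ≥ ~100 s for a
typical 50 s bleach time) rather than a number.

Target-search times come from the occupancy identity
f = t_bound/(t_bound + t_search), i.e. t_search = t_bound(1−f)/f, where
f is the fraction of all molecules in the bound state of interest. For
a factor with 13% total bound occupancy of which 4 points are the rare
stable state, the short-binding occupancy is 0.09; with a 1.5 s binding
time this gives ≈ 15 s. This decomposition of f is a reconstruction of
how the printed number arises, not a quoted computation.

## Abundance, occupancy and the ubiquitylation budget

Molecules per cell are estimated from in-gel fluorescence against ≥2
standards of known quantity (linear fit, inverted per sample lane,
replicate lanes averaged with a t-based 95% CI). Bound molecules =
total × SPT bound fraction. Bound molecules are apportioned over
ChIP-seq peaks proportionally to read counts — a deliberate *maximal*
occupancy estimate that assumes all binding is inside peaks. Densities
are molecules per kilobase (BED convention: length = end − start);
deciles are equal-count on per-peak density with ties broken by genomic
coordinate; per-allele values divide by ploidy (default 2). Two
conventions exist for the "mean density": total molecules / total peak
kb (default, conserves the total) and the unweighted mean of per-peak
densities; both are exposed.

The turnover budget chains printed constants: a 2n genome of
5,461,710,950 bp at 186.1 bp mean nucleosome spacing gives 2.9×10⁷
nucleosomes, 5.9×10⁷ H2A (2 per nucleosome), and at 10% ubiquitylation
5.9×10⁶ H2AK119ub1. A 90 min half-life gives a decay constant
ln2/5400 s ≈ 1.3×10⁻⁴ s⁻¹ and a steady-state replacement flux of ~750
modifications/s; a complex family carrying a share s of that flux with N
molecules deposits once every N/(s·flux) seconds per complex.
Modification counts at peaks additionally scale by the uniquely-mappable
genome fraction (0.88). Counts stay fractional internally and are
rounded only at report time.

## 3D nuclear bodies

Per-slice rolling-ball background subtraction (radius 4 px) precedes a
global Otsu threshold computed over nuclear voxels; the nucleus mask is
a required input (a DNA-stain Otsu helper exists but manual/external 3D
segmentation is assumed, matching practice). When the mask is supplied
to the background step, off-nucleus pixels are filled with the slice's
median nuclear intensity first so the ball does not dip to the dark
exterior at the nuclear rim and leave a bright shell artifact.
Components are 26-connected in 3D (the common plugin default); volumes
outside [0.029, 1.5] µm³ are discarded — below, segmentation is
unreliable; above, the object is almost certainly a nucleoplasmic
intensity fluctuation. The stack's mean off-nucleus intensity is
subtracted from all fluorescence measurements.

Summary identities: with volume fraction v and enrichment E (mean focus
density over non-focus nuclear density), the signal fraction is
vE/(vE + 1 − v) exactly when densities are uniform — a closed form used
as a test oracle and for desk calculations (v = 1.3%, E = 1.3 →
1.7%). Molecules per body = molecules per nucleus × signal fraction /
n bodies; concentration = N/(N_A·V) with V the body's own volume (10
molecules in 0.128 µm³ ≈ 130 nM). Quartile labels come from a
reference (untreated) distribution's boundaries. Deconvolution is out
of scope; stacks are assumed pre-deconvolved or simulated sharp.

## FRAP

Relative intensity = (bleached − background)/(unbleached − background),
scaled so the prebleach mean is exactly 1. The ratio is oriented so
recovery rises toward 1; the inverse orientation (which decays toward 1
from above) is available behind `literal_ratio=True`. Aggregation is a
pointwise mean ± SEM across cells sharing a time base. No
reaction–diffusion model is fitted.

## Synthetic-data generators

The simulators define the test conditions:

- **Tracks**: molecules hold one diffusive state for their whole
  lifetime (the kinetic model assumes state constancy over its ≤8-frame
  window; state switching is a documented non-feature). Defaults are
  the fast-tracking regime: Δt = 15 ms, fractions 0.20/0.30/0.50, D =
  0.03/0.5/3.5 µm²/s, σ = 40 nm, dZ = 0.7 µm. z motion is explicit 3D
  Brownian motion; detection requires |z| ≤ dZ/2 at each frame, and a
  track ends at its first failure (re-entries start new tracks).
  Bleaching is per-frame geometric — the discrete analogue of
  exponential bleaching under frame-based acquisition — with a default
  mean of 100 frames (1.5 s), a realistic lifetime for photoactivatable
  dyes under continuous high-power excitation; activation frames are
  uniform over a 4000-frame movie (densities and track-length
  distributions are free parameters of the regime, not measured
  quantities).
- **Dwell times**: a two-exponential binding mixture censored by
  exponential bleaching; the generator is the direct embodiment of the
  censoring identities above.
- **Nucleus stacks**: an ellipsoidal nucleus of uniform intensity that
  extends beyond the stack in z (as real nuclei usually do in confocal
  stacks; this also avoids degenerate polar-cap cross-sections),
  spherical foci of enrichment × baseline mean intensity placed with a
  minimum separation (overlapping placements are rejected — the ground
  truth would be ambiguous), Poisson shot noise plus Gaussian read
  noise as a standard EMCCD approximation. No PSF blurring: segmented
  volumes are sharp-boundary approximations.
- **FRAP traces**: prebleach plateau, instantaneous bleach, exponential
  recovery to a configured plateau above a floor, additive noise.

What passing tests therefore show: the estimators are correct for data
generated under their own assumptions (Brownian states, exponential
kinetics, uniform foci). They do not certify behaviour under anomalous
diffusion, state switching within tracks, blinking beyond a one-frame
gap, optical aberrations or chromatin drift — all real-data effects
outside the generators.

## Problem sizes and tolerances

Default verification sizes were chosen to make sampling error small
relative to the assertion tolerances: ≥50,000 jumps (≈25,000 simulated
molecules) for three-state recovery within ±3 percentage points of a
20% bound fraction; 5,000 dwell events per replicate, with stable
fractions asserted within ±5 points per run and ±2 points for the mean
over 20 replicates; bleach-corrected binding times asserted on the
replicate mean (the correction amplifies noise by (t_bleach/(t_bleach −
t_dwell))² ≈ 7 at the default 80 s/50 s, so single replicates scatter
by ~10%). The Monte-Carlo defocalization oracle uses 10⁵–10⁶ walkers
and 100 bridge-corrected substeps.
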