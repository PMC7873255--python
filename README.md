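# chromokin

Quantitative chromatin-binding kinetics from live-cell single-particle
tracking (SPT), built around the question: *how many molecules of a
chromatin factor are bound, for how long, and where?*  The package was
written for analysing Polycomb repressive complex 1 (PRC1) subunits
(RING1B, CBX7, PCGF1/2/3/6, RYBP) in mouse embryonic stem cells, but the
machinery is generic for any HaloTag-style nuclear factor.

It covers the full analysis chain:

- **Localization and tracking** — spot detection, elliptical-Gaussian
  sub-pixel localization, greedy nearest-neighbour linking with a
  one-frame blinking memory and regime-specific radii (768 nm at 67 Hz,
  192 nm at 2 Hz, 672 nm at 0.03 Hz).
- **Multi-state diffusion fitting** — per-track apparent diffusion
  coefficients, `D* = MSD/(4 dt) − σ²/dt`, and a 2-/3-state Brownian
  mixture fitted to jump-length CDFs over 8 frame lags, with localization
  error (σ = 40 nm) and axial defocalization correction (detection slab
  dZ = 0.7 µm), in the style of Spot-On.
- **Residence times** — survival curves of slow-tracking dwell times, a
  biexponential fit
  `y = A e^(−t/τ₁)/e^(−t₁/τ₁) + (1−A) e^(−t/τ₂)/e^(−t₁/τ₂)`,
  photobleaching correction via an H2B control,
  `t_bound = t_dwell·t_bleach/(t_bleach − t_dwell)`, and target-search
  times `t_search = t_bound (1−f)/f`.
- **Abundance → occupancy** — in-gel fluorescence standard curves to
  molecules per cell; bound molecules apportioned over ChIP-seq peaks in
  proportion to read counts, reported as molecules per kilobase and
  density deciles; nucleosome/H2AK119ub1 steady-state turnover budget.
- **3D nuclear bodies** — rolling-ball background subtraction, Otsu
  segmentation within a nucleus mask, 26-connected components, a
  [0.029, 1.5] µm³ volume window, and per-body molecule numbers and
  molar concentrations.
- **FRAP** — double normalization of recovery traces and across-cell
  mean ± SEM aggregation.
- **Synthetic data** — simulators for every input modality (fast-tracking
  trajectories in a finite detection slab, censored dwell times, nuclear
  z-stacks with spherical foci, FRAP traces) with ground truth, replacing
  the microscope in tests.

## Worked example

Simulate one fast-tracking experiment (15 ms frames, three states with a
20% bound fraction, D = 0.03/0.5/3.5 µm²/s) and fit it back:

```python
from chromokin.simulate import SimTrackConfig, simulate_tracks
from chromokin.kinetics import build_jump_histograms, fit_kinetic_model

tracks, truth = simulate_tracks(SimTrackConfig(n_molecules=25_000, seed=1))
fit = fit_kinetic_model(build_jump_histograms(tracks))
print(f"bound fraction: {fit.f_bound:.3f}")
print("diffusion coefficients:", [round(d, 3) for d in fit.diffusion_coeffs])
```

```
bound fraction: 0.202
diffusion coefficients: [0.029, 0.491, 3.424]
```

The fitted bound fraction (20.2%) recovers the configured 20%, and the
three diffusion coefficients land within a few percent of the simulated
values — the defocalization correction is what keeps the fast state from
being undercounted as it leaves the 0.7 µm detection slab.

Scalar bookkeeping works straight from measured inputs; with 63,000
molecules per cell and a 20% bound fraction there are ~12,600 bound
molecules, and the H2AK119ub1 steady state implies:

```python
from chromokin.occupancy import bound_molecules, h2aub_budget, deposition_interval

print(bound_molecules(63_000, 0.20))          # 12600
b = h2aub_budget()                            # 2n genome / 186.1 bp spacing
print(f"{b.total_h2aub:.2e}")                 # 5.87e+06 H2AK119ub1 molecules
print(f"{b.flux_per_s:.0f}")                  # 753 modifications lost per s
print(f"{deposition_interval(750, 0.5, 6000):.0f}")  # 16 s per complex
```

The same stages are available as a CLI
(`chromokin simulate|track|spoton-fit|dwell|occupancy|budget|foci|frap`);
every command writes a JSON sidecar with the config echo, seed and input
hashes so any artifact is reproducible.

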