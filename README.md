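# gridwave

Traveling-wave analysis of low-frequency oscillations recorded by 2D
electrode microgrids on neural tissue, for electrophysiologists studying
mesoscopic wave propagation (the motivating setting is a 4 × 8 surface
array at 2 mm pitch over the human hippocampus).

Low-frequency LFP oscillations often are not standing waves: their phase
advances systematically across the array, so cycle peaks sweep over the
tissue. `gridwave` quantifies this. At each timepoint the per-electrode
Hilbert phases φ_i are fit to a traveling plane wave

    φ_i ≈ φ0 − k_rad (x_i cos θ + y_i sin θ),

by exhaustive circular-linear regression over a lattice of directions θ
(1° steps) and spatial frequencies k (1 deg/mm steps up to the 90 deg/mm
spatial Nyquist limit of a 2 mm pitch), yielding the travel direction θ,
wavelength λ = 360/k, speed λ·f, and a goodness of fit R² (squared
circular–circular correlation) screened against a 200-iteration
electrode-location-shuffle null. Around this core the package provides:

- **`synth`** — a ground-truth synthetic LFP generator (planted plane
  waves, direction regimes, amplitude topographies, trial structure,
  1/f background) so every stage is testable without patient data;
- **`spectral`** — preferred-frequency discovery: Morlet wavelet spectra
  (211 log-spaced frequencies, 1–32 Hz), robust 1/f detrending, and the
  ≥ 5-channels-within-2-Hz consensus rule;
- **`dirstats`** — circular statistics: 10° binning with 60° circular
  smoothing, the 25% secondary-peak bimodality rule, Rayleigh and
  Hodges–Ajne uniformity tests, Fisher's common-median test, 45°
  angle splits;
- **`trials`** — event-locked directionality consistency (DC = mean
  resultant length of per-trial directions per timepoint) with
  Benjamini–Hochberg FDR and a shuffled-timepoint null band;
- **`classify`** — a 5-fold cross-validated linear SVM testing whether
  the amplitude topography over the grid predicts instantaneous travel
  direction, with a label-shuffle significance test;
- **`pipeline`** — HDF5 + JSON-sidecar I/O, line-length artifact
  screening, electrode subsetting/rotation, and end-to-end orchestration.

## Worked example

Synthesize a bidirectional 6 Hz traveling wave (directions alternating
30°/210° in 2 s segments, 60/40 mix, k = 15 deg/mm) and run the pipeline
stages:

```python
import numpy as np
import gridwave as gw

grid = gw.make_grid(4, 8, pitch=2.0)
c1 = gw.WaveComponent(center_freq=6.0, direction=30.0, spatial_freq=15.0, amplitude=10.0)
c2 = gw.WaveComponent(center_freq=6.0, direction=210.0, spatial_freq=15.0, amplitude=10.0)
schedule = gw.RegimeSchedule(
    segments=tuple((2*i, 2*(i+1), (0 if i % 5 < 3 else 1,)) for i in range(10)))
rec = gw.synthesize(grid, [c1, c2], schedule, noise_sd=5.0,
                    duration_s=20.0, fs=256.0, seed=42)

specs = [gw.detrend_and_score(s) for s in gw.wavelet_spectrum(rec)]
peaks = gw.find_consensus_peaks(specs)
f0 = peaks[0].center_freq
band = gw.extract_band(rec, f0, fs_analysis=30.0)
fits = gw.fit_series(band, grid, null_iters=200, ci_percent=99.0, seed=1)
dist = gw.build_distribution(fits.direction[fits.valid])
```

Printed output:

```
consensus peak: 6.12 Hz on 32 channels
valid timepoints: 540/600
median spatial frequency: 15.0 deg/mm
median wavelength: 24.0 mm, median speed: 147 mm/s
modality: bidirectional, modes: 30 deg, 210 deg (hodges_ajne p = 9.2e-09)
angle split: 327 vs 213 timepoints (ratio 0.61)
```

Reading this: the planted 6 Hz oscillation is found on all 32 channels;
90% of timepoints survive the amplitude gate and the electrode-shuffle
validity screen; the fitted spatial frequency matches the planted
15 deg/mm exactly (λ = 360/15 = 24 mm, speed = 24 mm × 6.12 Hz ≈
147 mm/s); the direction distribution is bidirectional with modes at the
planted 30°/210°, and the angle split recovers the planted 60/40 regime
ratio.

## Documentation

`docs/methods.md` describes the signal model, every estimator and its
defaults, the numerical conventions (tie-breaking, degenerate inputs,
p-value conventions), what the synthetic generator does and does not
emulate, and known limitations.
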