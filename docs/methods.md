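# Methods

`gridwave` analyzes traveling low-frequency oscillations recorded by a
2D electrode microgrid placed on neural tissue (the motivating setting is
a 4 × 8 hippocampal surface array at 2 mm pitch). The pipeline runs five
stages: oscillation-peak discovery, per-timepoint plane-wave fitting with
a permutation validity screen, circular direction statistics, event-locked
directionality consistency, and amplitude-topography direction decoding.
A synthetic-LFP generator with planted ground truth closes the loop for
validation.

## Signal model

A traveling plane wave at temporal frequency f with travel direction θ
(degrees, 0° = +x along the grid's long axis, counterclockwise positive)
and spatial frequency k (deg/mm) produces, at electrode i with position
(x_i, y_i) in mm,

    s_i(t) = A g_i cos(2π f t − k_rad (x_i cos θ + y_i sin θ) + φ0),

with k_rad = k·π/180 and g_i a unit-mean per-electrode gain (the
"amplitude topography"). Phase therefore *decreases* along the direction
of travel; wavelength is λ = 360/k mm and speed is λ·f mm/s. The spatial
Nyquist limit of a 2 mm pitch is 180/2 = 90 deg/mm, the ceiling of the
search lattice.

## Synthetic generator (`synth`)

The generator renders any number of wave components on a regular lattice,
adds an independent 1/f^α aperiodic background per channel (spectrally
shaped white noise, normalized to a target SD; α defaults to 2, a typical
LFP slope), and schedules component activity through non-overlapping time
segments with 0.1 s raised-cosine on/off ramps that limit switching
transients. Trial structure is emulated by event times plus an alignment
window: with probability `align_prob` per trial, the designated task
component overrides the segment schedule inside the window, producing
across-trial direction alignment. All randomness flows from one seed;
identical seeds give bit-identical recordings.

What the generator does *not* emulate: spatially correlated noise across
electrodes (off by default and unimplemented; real volume conduction
correlates neighboring channels), non-planar (spiral/radial) waves,
epileptiform discharges, and non-stationary 1/f slopes. Tests passing on
this generator therefore certify the estimator chain — not robustness to
every pathology of real recordings.

## Oscillation peaks (`spectral`)

Per channel: continuous Morlet transform (`cmor1.5-1.0`, fixed bandwidth
parameter) on 211 log-spaced frequencies over 1–32 Hz (42 voices per
octave), time-averaged power excluding artifact-annotated intervals and a
per-scale cone of influence (2 temporal σ at each edge; without this the
low-frequency estimator bias is shared across channels and masquerades as
consensus structure). A robust line (IRLS, Tukey bisquare) is fit to log
power vs log frequency, subtracted, and the residuals z-scored. Channel
peaks are strict local maxima above +1 SD (plateau ties break toward
lower frequency). Consensus clustering is greedy: the strongest
unassigned peak seeds a cluster that absorbs, per channel, the nearest
peak within ±1 Hz (total span ≤ 2 Hz); clusters with ≥ 5 distinct
channels become preferred center frequencies (mean of member peaks).

Known limitation: because the residual spectrum is z-scored to unit SD,
*every* channel has local maxima above +1 SD, and at low frequencies a
2 Hz window covers a large slice of the log grid, so purely aperiodic
input yields chance consensus peaks with high probability. The rule is
designed for recordings that actually contain oscillations — a genuine
bump inflates the residual SD and suppresses noise peaks — and spurious
peaks are caught downstream by the wave-fit validity screen. A perfect
power-law spectrum drives the robust scale to zero; its z-scores are
defined as 0 (no oscillatory structure).

## Plane-wave fitting (`wavefit`)

Band extraction: zero-phase 4th-order Butterworth band-pass at the center
frequency ± 1.5 Hz, Hilbert transform, polyphase (anti-aliased)
resampling of the analytic signal to the analysis rate (30 Hz baseline /
100 Hz trial data), amplitude z-scored within channel across the block.
Timepoint gating: the channel-mean raw envelope must exceed its 10th
percentile, inside a contiguous above-threshold run of at least
3/f seconds (three cycles); artifact intervals are invalid outright.

Fitting is an exhaustive search over a lattice of 360 directions (1°
steps) × 90 spatial frequencies (1 deg/mm steps to 90), maximizing the
mean resultant length of the phase residuals δ_i = φ_i + k_rad·proj_i(θ)
— the circular-linear regression score. The entire lattice is precomputed
as a complex design matrix so scoring all timepoints (or all permutations)
is a single BLAS matrix product in complex64. Ties resolve to the
smallest k, then the smallest θ; a spatially uniform phase field returns
k = 0 with undefined (NaN) direction and R² = 0.

Goodness of fit is reported as the squared circular–circular correlation
(Jammalamadaka–SenGupta) between observed and fitted phases: bounded in
[0, 1], exactly 1 for a noiseless planar field, and 0 by convention when
either side has no angular dispersion. The resultant-length score is used
only for optimization. Validity: the observed R² must exceed the 99th
percentile (configurable; the screening level used for results) of 200
refits with the electrode-to-coordinate assignment permuted, recomputed
per timepoint.

Numerical notes: at least 8 finite-phase usable electrodes are required
per fit; the permutation count below 20 only warns (unstable percentile).
Equivariances verified by tests: frame rotation by α shifts the fitted
direction by exactly −α at lattice resolution; coordinate translation and
global phase shifts move only the offset.

## Direction statistics (`dirstats`)

Valid-timepoint directions are binned in 10° steps and smoothed with a
60°-support circular moving average; since 60° spans six 10° bins (an
even number) the kernel is a symmetric 7-bin window with half-weight ends,
[0.5, 1, 1, 1, 1, 1, 0.5]/6, which conserves total count. Modes are
bin centers of smoothed circular local maxima (plateaus resolve to the
circular mean of tied centers). A distribution is bidirectional when the
secondary smoothed peak reaches 25% of the primary; bidirectional
distributions are tested with the Hodges–Ajne omnibus test, unidirectional
ones with the Rayleigh test.

Hodges–Ajne: the statistic m is the minimum count in a half-circle,
computed by sweeping boundaries at midpoints between the sorted data
angles and their antipodes (where closed and open half-circles coincide);
exact tail p = (n − 2m)·C(n, m)/2^(n−1) for n ≤ 50 (p = 1 whenever
2m ≥ n — a perfectly balanced sample is fully consistent with
uniformity), the standard asymptotic approximation beyond. Rayleigh:
z = n·R̄², with Zar's series-corrected p evaluated in log space so
extreme concentrations underflow gracefully. Between-condition direction
shifts use Fisher's common-circular-median χ² test (counts on either side
of the pooled circular median, r − 1 degrees of freedom; an empty side
returns p = 1).

The 45° angle split assigns valid timepoints to the wedge of either mode
and drops the rest; wedges must not overlap (modes ≥ 90° apart).

## Directionality consistency (`trials`)

Trial direction series are epoched around events (default ±2 s at
100 Hz); trials extending past the recording edge are dropped with a
warning, trials overlapping artifact intervals are excluded, and fewer
than 10 surviving trials is an error. DC(t) is the mean resultant length
of the per-trial directions at t — 0 for chance dispersion, 1 for perfect
alignment. Per-timepoint Rayleigh p-values are Benjamini–Hochberg
corrected across the window. Timepoints with invalid wave fits are
included (per-timepoint n is recorded), matching the convention of
reporting the mean R² trace separately; a flag (`fit_invalid=False` at the
fit stage) excludes them instead. The null band is the pooled 2.5/97.5
percentile of DC recomputed over 200 surrogates in which each trial's
series is circularly shifted by an independent random offset — preserving
within-trial autocorrelation while destroying event locking. Reaction-time
splits are at the median, ties to the fast half.

## Direction classifier (`classify`)

For a bidirectional frequency, per-electrode amplitude z-scores at the
angle-split timepoints (up to 32 features) predict the binary travel
direction. Classes are balanced by subsampling the majority once per run
(≥ 50 timepoints per class required), features are standardized, and a
linear-kernel SVM (default regularization, no hyperparameter search) is
scored by stratified 5-fold cross-validation (mean held-out accuracy;
each fold trains on 80% and tests on the held-out 20%). Significance: the identical procedure is repeated with permuted
labels (default 10,000 iterations; configurable down for speed) and the
observed accuracy must exceed the null's 99th percentile. Auxiliary
summaries per frequency: the toward/away timepoint ratio correlated with
frequency (Spearman), and the anterior-minus-posterior half-grid mean
amplitude contrasted between direction conditions (paired t, halves being
the 16 electrodes with largest/smallest x).

## Pipeline and I/O (`pipeline`)

The native container is an HDF5 channels × samples matrix plus a JSON
sidecar (fs, coordinates, bad channels, annotations, events). Artifact
screening computes per-channel sliding-window line length (Σ|Δv| over
1 s) and flags windows where any channel exceeds its own median + 8 MAD
— a default calibrated so clean 1/f recordings flag < 1% of time while a
planted 500 µV pop sits orders of magnitude above threshold. Electrode
subsetting returns both the sub-geometry and parent indices so full-grid
valid timepoints can be reused for subgrid refits; frame rotation is
passive (a grid physically rotated by α yields fitted directions shifted
by −α). `run_pipeline` chains the stages, skips the DC stage without
events, skips the classifier for unidirectional frequencies or
too-small classes, and skips peaks whose extraction band would cross DC.

## Key defaults

| parameter | default | meaning |
|---|---|---|
| spectral band | 1–32 Hz, 211 log freqs | wavelet analysis grid |
| extraction bandwidth | 3 Hz (± 1.5) | Hilbert band around each peak |
| analysis rate | 30 Hz (100 Hz trials) | above 2× the highest wave frequency |
| amplitude gate | lowest 10%, 3 cycles | low-power timepoint exclusion |
| permutation null | 200 iterations, 99th pct | electrode-shuffle validity |
| direction bins | 10°, 60° smoothing | circular histogram |
| bimodality rule | secondary ≥ 25% of primary | modality classification |
| angle split | ± 45° wedges | class definition for decoding |
| SVM null | 10,000 shuffles, 99th pct | decoding significance |

## Problem sizes used in tests

Validation runs use deliberately small but sufficient problem sizes: 20–24
s recordings at 256 Hz (600–720 analysis timepoints) for recovery and
end-to-end checks, 100–200 permutations per null, 1,000 label shuffles
for the classifier chance level, and Monte Carlo replicate counts in the
hundreds to low thousands with binomial tolerance bands at roughly ±3 SD.
The acceptance script uses 48 s of synthetic data (≈ 500 timepoints per
direction class) and 1,000 shuffle iterations.
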