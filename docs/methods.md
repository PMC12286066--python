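# Methods

This note records the models implemented in `cmcpipe`, their assumptions,
the defaults that matter, and the numerical choices made where the design
was genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Acquisition model

Sessions emulate a 32-channel EEG cap repurposed for simultaneous EEG+EMG:
PO7, Oz and PO8 are removed from the analysis set — Oz (hardware channel 16)
becomes the relocated common reference and PO7/PO8 (channels 31/32) carry
the bipolar EMG pair — leaving 29 EEG analysis channels. Electrode
coordinates are idealized: the standard 10-20 positions are sphere-fitted
and projected to the unit sphere (head frame: x right, y anterior,
z superior). The hardware front end is modeled as a causal 0.01–60 Hz
bandpass plus a 50 Hz notch at 500 Hz sampling. The wording of bipolar
EEG "relative to the reference" is treated as an ordinary common-reference
montage.

The force actuator chain is: symmetric strain on two BF350 gauges
(`Ei = 350 + g·F`, `Eo = 350 − g·F`, default sensitivity g = 0.05 Ω/N),
Wheatstone bridge with 360 Ω fixed arms excited at 5 V, AD620 gain
`1 + 49 400/RG` (412.67 at the default RG = 120 Ω), clamp to 0–5 V, 10-bit
quantization (Arduino-class ADC). The gauge sensitivity puts ADC full scale
near 34 N, above strong pinch grips. Maze paths are parametric re-creations
by difficulty class (plateau count, corridor width, ramp steepness), not
replicas of any particular screen; rest blocks between protocol tasks
default to 30 s and are configurable.

## Preprocessing

Beta-band filtering uses a 4th-order Butterworth applied forward-backward:
zero-phase filtering is required because every downstream quantity is a
phase, and a causal filter's group delay would bias it. Downsampling
500 → 60 Hz (a 3/25 polyphase ratio) uses a Kaiser-windowed FIR with a
≈0.2 Hz transition at the 30 Hz cutoff so the retained band's energy
survives; content above 30 Hz cannot be represented at 60 Hz and is
discarded by construction. ICA (FastICA, seeded) runs after downsampling.
Artifact components are scored, not auto-classified: focality
(max|topo|/Σ|topo|), high-frequency power ratio, frontal × low-frequency
score, and signed left-right frontal asymmetry operationalize the classic
visual criteria; an automatic threshold (0.8) exists for unattended runs,
and the removal list is otherwise the caller's.

## TDSEP and band selection

Separation whitens the data and jointly diagonalizes symmetrized lagged
covariances with Jacobi (Givens) rotations using the closed-form rotation
angle; the off-diagonal criterion is non-increasing by construction and
iteration stops at tolerance 1e-12 or 100 sweeps. Default lags are 1–20
samples at 60 Hz (≈17–333 ms), covering beta-band autocorrelation. Essays
(default 20) each draw a random 10-lag subset of 1–30; pooled sources are
single-linkage grouped at |r| ≥ 0.9 on time courses (essays share the time
axis) and each cluster's medoid represents it. Source-EMG coherence uses
Welch estimates (2 s Hann segments, 50% overlap) in 10 s windows advancing
5 s; the argmax over (source, frequency, window) inside 13–30 Hz selects
the band, reported as center ± 1 Hz to feed the RPA analysis filter.
Coherence is computed on grouped representatives, not on every essay.

## Reference Phase Analysis

The analysis band is a 2 Hz zero-phase Butterworth band around the chosen
center. Phases come from the Hilbert analytic signal; the leading and
trailing 5% of samples are flagged and excluded from PLV estimates. Because
the Hilbert transform is linear, the phase of `wᵀZ` equals the phase of
`wᵀ·analytic(Z)`, which makes the objective a cheap complex dot product and
lets all restarts of a window run as one batched computation.

Whitening is computed once per session and truncates to the components
explaining 99% of narrowband variance (configurable). Full-rank whitening
of narrowband data amplifies near-null noise directions to unit variance,
and the phase optimizer will then lock onto pure noise; truncation is the
standard guard.

The optimizer is projected gradient ascent on the unit sphere with a
numerical central-difference gradient (tangent-projected), an adaptive step
(×1.5 on acceptance, ×0.5 on rejection, start 0.1), and a monotonicity
contract: accepted steps never decrease the objective. Termination: accepted
improvement < 1e-5, step < 1e-9, or 150 iterations. Defaults: 50 restarts
per window, 5 s windows with 50% overlap, intra-window grouping at
|r| ≥ 0.85 on candidate time courses, inter-window grouping at |r| ≥ 0.70 on
topographies (time courses from different windows are not comparable).
Single-window families are retained but rank below recurring ones.

**PLV reporting.** Maximizing PLV over a d-dimensional filter on a short
narrowband window overfits badly: on 5 s windows the optimized value is
biased far above the true coupling (and is high even for pure noise), and
even a *fixed* filter's single-window PLV carries a finite-sample upward
bias because a 2 Hz-wide signal offers only a handful of independent phase
samples per window. Each family therefore carries three quantities: the
members' optimized PLVs (diagnostics), the per-window PLVs of the family's
fixed consensus filter (the transiency profile), and the headline `plv`
computed by pooling the consensus filter's phase differences across all
member windows — essentially out-of-sample and unbiased when the coupling
spans the windows. The consensus filter is the PLV-weighted, sign-aligned
mean of the member filters. Significance uses a circular-shift permutation
null (default 200 shifts of ≥1 s) of the same pooled statistic; the p-value
is `(1 + #null ≥ obs) / (1 + n_perm)`.

## Dipole localization

The forward model is the analytic series for a current dipole in three
concentric spheres (brain/skull/scalp radii 0.087/0.092/0.100 m,
conductivities 0.33/0.0042/0.33 S/m). Per harmonic order the radial
coefficients solve the boundary conditions directly (a 5×5 linear system in
scalp-normalized radii), which reduces to the closed-form homogeneous-sphere
factor (2n+1)/n when conductivities are equal — an identity the tests
assert. The series is truncated at 60 terms; with dipoles kept ≥4 mm below
the brain-shell boundary the truncation error is negligible. Both measured
and modeled topographies are average-referenced, making the fit
reference-free, and the goodness of fit (explained topography power) is
scale-invariant. Fitting scans a cached 1 cm grid of interior positions
(moment solved linearly via each point's precomputed orthonormal leadfield
basis), then refines with Nelder-Mead from the best grid point plus a small
seeded jitter. Labels are deliberately coarse — hemisphere × lobe from the
position's angular sector, plus a contralaterality flag given the moving
hand — because a spherical geometry without individual anatomy cannot
support atlas-level names.

## Synthetic sessions

The generator's purpose is parameter recovery with closed-form targets, not
biophysical realism. The planted coupling is a shared 20 Hz oscillator with
Wiener phase noise of 6 rad²/s — a Lorentzian linewidth of ≈1 Hz FWHM,
a realistic width for a beta peak (a much more coherent carrier would make
even time-shifted signals appear phase-locked). The EMG drive phase adds a
fixed lag plus a circular Langevin jitter whose stationary law is von
Mises(κ) — so the population PLV is exactly I₁(κ)/I₀(κ) — with a 0.5 s
correlation time, slow enough to survive the 2 Hz analysis filter (i.i.d.
per-sample jitter would be filtered away and the recovered PLV would not
match the Bessel target). Background activity: alpha-band narrowband
sources, 1/f broadband sources, blink / lateral eye / temporal-muscle /
impedance artifacts with their stereotyped topographies, 50 Hz line, and
sensor noise at a configurable SNR (default 20 dB). Cortical sources mix to
the sensors through spherical-model leadfield columns at seeded interior
positions; the coupled source sits at a left-motor-strip position by
default. The EMG channel is an envelope-modulated broadband carrier whose
beta band is phase-aligned to the drive, passed through the acquisition
chain.

What the generator does *not* emulate: nonstationary beta bursting,
task-locked coupling confined to force transitions (an epoch mask exists so
both confined and uniform coupling can be simulated), volume conduction of
the EMG into EEG electrodes, and realistic head geometry. Passing tests
therefore demonstrate correct recovery under linear instantaneous mixing
with known coupling statistics — not performance on clinical recordings.

## Problem sizes used in the tests

The acceptance suite runs the full chain on 90 s, 29-channel sessions at
the native 500 Hz (5 400 samples after downsampling), 50 restarts per 5 s
window, 200-shift permutation nulls, 50-seed noisy dipole studies, and a
10⁵-vector random-search oracle; smaller property tests use 8–16 channel
fixtures at 60 Hz, chosen to keep the whole suite in a few minutes on one
CPU while leaving every statistical tolerance at its stated value.

## Known limitations

- Single EMG reference; no multivariate references or cross-frequency
  coupling.
- Single-linkage grouping can chain families through intermediate mixture
  candidates when the channel count is small or windows straddle a change
  in the active source.
- The EDF writer covers the plain-EDF subset the pipeline needs (uniform
  rate, 16-bit); reading uses mne and accepts general EDF.
- The spherical head model supports hemisphere × lobe statements only;
  positions are not comparable to MRI-based coordinates.
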