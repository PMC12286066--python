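# cmcpipe

Corticomuscular phase-synchrony analysis for EEG-EMG recordings.

During fine motor control, cortical beta-band (13-30 Hz) oscillations couple
to the muscles they drive. Sensor-level corticomuscular coherence is blurred
by volume conduction, so `cmcpipe` works at the source level: it finds the
linear combination of EEG channels whose instantaneous phase is most tightly
locked to an EMG reference, quantified by the phase-locking value

    PLV = | (1/N) Σ_t exp(i Δφ(t)) |,   Δφ = φ_EEG − φ_EMG,

which is 1 for a rigid phase relation, ≈0 for independent phases, and
independent of signal amplitude. The toolkit covers the full experimental
chain for a pinch-grip biofeedback study:

- **actuator** — strain-gauge Wheatstone bridge + AD620 instrumentation
  amplifier (gain `1 + 49.4 kΩ/RG`, 413× at RG = 120 Ω) + 10-bit ADC; maze
  generation, cursor dynamics and in/out-of-path scoring for the tracking
  game; the five-task motor protocol (two 90 s maze tasks, two 15-cycle
  0.5 Hz paced tasks, one 15 s maximal contraction).
- **preprocess** — 4th-order zero-phase Butterworth 13-30 Hz bandpass,
  polyphase downsampling to 60 Hz (Nyquist-sufficient for a 30 Hz-limited
  signal), and ICA artifact screening scored against the classic signatures
  (focal impedance, temporal muscle, frontal blink, lateral eye movement).
- **tdsep** — blind source separation by joint diagonalization of
  time-lagged covariances (temporal decorrelation preserves phase structure,
  unlike higher-order ICA), repeated over ≥20 essays with |r| ≥ 0.9
  cross-correlation grouping, then sliding-window Welch coherence against
  the EMG to pick the analysis band and window.
- **rpa** — Reference Phase Analysis: per sliding window, 50 random-restart
  adaptive-step gradient ascents on the unit sphere maximize the PLV of the
  combined EEG signal against the EMG phase; candidates are grouped within
  windows (|r| ≥ 0.85 on time courses) and across windows (|r| ≥ 0.70 on
  topographies); the recurring family's PLV is re-estimated with its fixed
  consensus filter, pooled over member windows, with a circular-shift
  permutation null.
- **localize** — equivalent current dipole fit of the winning topography in
  an analytic three-shell spherical head model, with coarse hemisphere ×
  lobe labeling and a contralaterality flag.
- **synth** — seeded generator of full 29-channel EEG + EMG sessions with a
  planted phase coupling of known strength: a shared noisy 20 Hz oscillator
  with von Mises phase jitter of concentration κ, so the population PLV is
  the Bessel ratio I₁(κ)/I₀(κ) in closed form.

The estimator-style classes (`TDSEP`, `ArtifactICA`, `ReferencePhaseAnalysis`,
`DipoleFitter`) follow scikit-learn conventions (`fit`, fitted `_`
attributes, `get_params`); module-level functions wrap them for scripting.

## Worked example

Run the whole pipeline on a synthetic 90 s session with a κ = 2 coupling at
20 Hz planted at a left-motor-strip source (theoretical PLV
I₁(2)/I₀(2) ≈ 0.698):

```sh
cmcpipe run --out-dir demo --seed 7 --duration 90 --kappa 2
```

The final `demo/report.json`:

```json
{
 "best_family": {
  "mean_plv": 0.7054471281291432,
  "null_95": 0.15577993924507805,
  "occurrence": 35,
  "permutation_p": 0.004975124378109453
 },
 "chosen_band_hz": [18.5, 20.5],
 "dipole": {
  "contralateral": true,
  "gof": 0.9998446824629786,
  "position_m": [-0.0345, 0.0099, 0.0586],
  "region": "left central",
  ...
 },
 "seed": 7
}
```

Reading it: the coherence stage picked a 2 Hz band centered within 1 Hz of
the planted 20 Hz coupling; the best RPA family recurs in all 35 windows
with pooled PLV 0.705 — within 0.01 of the planted 0.698 — far above the
200-permutation null (95th percentile 0.156, p ≈ 0.005); and the dipole fit
lands ~2 mm from the planted position, in the left hemisphere, contralateral
to the simulated right hand. Re-running with the same seed reproduces the
report byte for byte.

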