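"""Seeded synthetic EEG-EMG-force sessions with known ground truth.

The generator plants one beta-band cortical source whose phase is coupled to
a simulated EMG through a shared noisy 20 Hz oscillator: the EMG drive phase
equals the oscillator phase plus a fixed lag plus a slowly varying circular
jitter whose stationary distribution is von Mises with concentration kappa.
The population phase-locking value of such a coupling is the Bessel ratio
I1(kappa)/I0(kappa), which gives every downstream estimator a closed-form
target. Background activity (alpha rhythms, 1/f-shaped broadband sources),
stereotyped artifacts (blinks, horizontal eye movements, temporal-muscle
bursts, impedance steps), and 50 Hz line interference are mixed to the
sensors by leadfield columns of the spherical head model; the acquisition
chain (0.01-60 Hz analog bandpass, 50 Hz notch, 500 Hz sampling) is applied
last, so preprocessing is exercised on realistic inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.special import i0, i1

from .actuator import (AmplifierConfig, BridgeConfig, MazePath,
                       affine_calibration, cursor_trace, force_to_adc,
                       score_performance)
from .localize import HeadModel, leadfield
from .recording import Montage, Recording, make_default_montage

__all__ = [
    "SynthConfig",
    "GroundTruth",
    "gen_coupled_pair",
    "gen_emg",
    "gen_session",
    "gen_force_session",
    "gen_paced_force",
    "theoretical_plv",
]


def theoretical_plv(kappa: float) -> float:
    """Population PLV of von Mises phase jitter: I1(kappa)/I0(kappa)."""
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    return float(i1(kappa) / i0(kappa))


@dataclass
class CouplingConfig:
    f0: float = 20.0            # Hz, shared oscillator frequency (beta band)
    kappa: float = 2.0          # von Mises concentration of the phase jitter
    lag_rad: float = 0.5        # fixed EEG->EMG phase lag
    jitter_tau_s: float = 0.5   # correlation time of the jitter diffusion
    # Wiener phase noise of the shared oscillator, rad^2/s. 6 rad^2/s gives a
    # Lorentzian linewidth of ~1 Hz FWHM, a realistic width for a beta peak;
    # the coupled pair shares the oscillator, so coupling PLV is unaffected.
    phase_diffusion: float = 6.0
    amplitude: float = 1.0
    position: tuple[float, float, float] = (-0.035, 0.01, 0.06)  # m, left motor strip

    def __post_init__(self) -> None:
        if not 13.0 < self.f0 < 30.0:
            raise ValueError("coupled source must sit inside the beta band")
        if self.kappa < 0:
            raise ValueError("kappa must be non-negative")


@dataclass
class BackgroundConfig:
    n_alpha: int = 3
    n_broadband: int = 8
    one_over_f_exponent: float = 1.0
    alpha_hz: float = 10.0


@dataclass
class ArtifactConfig:
    blink_rate: float = 0.15        # events/s
    eye_movement_rate: float = 0.05
    emg_burst_rate: float = 0.05
    impedance_rate: float = 0.02
    line_50hz_uv: float = 2.0


@dataclass
class EMGSynthConfig:
    carrier_band: tuple[float, float] = (20.0, 150.0)
    beta_gain: float = 1.0          # coupled beta component inside the EMG
    hf_gain: float = 1.0            # high-frequency (35+ Hz) carrier gain
    rest_level: float = 0.03        # envelope floor between bursts


@dataclass
class SynthConfig:
    duration_s: float = 90.0
    fs_native: float = 500.0
    n_eeg: int = 29
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    artifacts: ArtifactConfig = field(default_factory=ArtifactConfig)
    emg: EMGSynthConfig = field(default_factory=EMGSynthConfig)
    snr_db: float = 20.0            # mixed-signal power over sensor noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")


@dataclass
class GroundTruth:
    """Everything a test needs to score recovery on a generated session."""

    mixing: np.ndarray              # (n_eeg, n_sources)
    sources: np.ndarray             # (n_sources, n_samples) pre-mixing
    coupled_index: int
    coupling_mask: np.ndarray       # per-sample coupling on/off
    source_phase: np.ndarray        # oscillator phase at the cortical source
    emg_drive_phase: np.ndarray
    theoretical_plv: float
    coupled_position: np.ndarray
    artifact_times: dict = field(default_factory=dict)


def _vonmises_diffusion(n: int, fs: float, kappa: float, tau_s: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Langevin diffusion on the circle with stationary von Mises(0, kappa).

    d theta = -(s2/2) kappa sin(theta) dt + sqrt(s2) dW with s2 = 2/(tau*k')
    relaxes over ~tau seconds; its stationary density is exp(kappa cos t).
    For kappa = 0 this degenerates to free phase diffusion (uniform marginal).
    """
    s2 = 2.0 / (tau_s * max(kappa, 0.5))
    dt = 1.0 / fs
    theta = np.empty(n)
    theta[0] = rng.vonmises(0.0, kappa) if kappa > 0 else rng.uniform(-np.pi, np.pi)
    noise = rng.standard_normal(n - 1) * np.sqrt(s2 * dt)
    drift = 0.5 * s2 * kappa * dt
    for i in range(1, n):
        theta[i] = theta[i - 1] - drift * np.sin(theta[i - 1]) + noise[i - 1]
    return theta


def gen_coupled_pair(cfg: SynthConfig | None = None,
                     rng: np.random.Generator | None = None):
    """Shared-oscillator coupled pair: cortical source and EMG phase drive.

    Returns (source, emg_drive_phase, truth_dict); the empirical PLV between
    the source phase and the drive phase approaches I1(kappa)/I0(kappa).
    """
    cfg = cfg or SynthConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    c = cfg.coupling
    n = int(round(cfg.duration_s * cfg.fs_native))
    t = np.arange(n) / cfg.fs_native
    wiener = np.cumsum(rng.standard_normal(n)) * np.sqrt(
        c.phase_diffusion / cfg.fs_native)
    phase = 2 * np.pi * c.f0 * t + wiener
    jitter = _vonmises_diffusion(n, cfg.fs_native, c.kappa, c.jitter_tau_s, rng)
    source = c.amplitude * np.cos(phase)
    drive_phase = phase + c.lag_rad + jitter
    truth = {
        "source_phase": phase,
        "jitter": jitter,
        "theoretical_plv": theoretical_plv(c.kappa),
        "empirical_plv": float(np.abs(np.exp(1j * jitter).mean())),
    }
    return source, drive_phase, truth


def acquisition_chain(data: np.ndarray, fs: float) -> np.ndarray:
    """Emulated analog front end: 0.01-60 Hz bandpass + 50 Hz notch (causal)."""
    sos = signal.butter(2, [0.01, 60.0], btype="bandpass", fs=fs, output="sos")
    out = signal.sosfilt(sos, data, axis=-1)
    b, a = signal.iirnotch(50.0, 30.0, fs=fs)
    return signal.lfilter(b, a, out, axis=-1)


def _bandnoise(n: int, fs: float, band: tuple[float, float],
               rng: np.random.Generator, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n + 2000))[2000:]
    return x / (x.std() + 1e-30)


def gen_emg(drive_phase: np.ndarray, envelope: np.ndarray,
            cfg: SynthConfig | None = None,
            rng: np.random.Generator | None = None) -> np.ndarray:
    """Surface-EMG channel: envelope-modulated broadband carrier whose
    beta band is phase-aligned to the drive, passed through the acquisition
    chain."""
    cfg = cfg or SynthConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    envelope = np.asarray(envelope, dtype=float)
    if np.any(envelope < 0):
        raise ValueError("envelope must be non-negative")
    n = drive_phase.size
    if envelope.size != n:
        raise ValueError("envelope and drive phase must share the grid")
    e = cfg.emg
    hf_lo = max(35.0, cfg.emg.carrier_band[0])
    hf = _bandnoise(n, cfg.fs_native, (hf_lo, e.carrier_band[1]), rng)
    beta = np.cos(drive_phase)
    emg = envelope * (e.beta_gain * beta + e.hf_gain * hf)
    return acquisition_chain(emg[None, :], cfg.fs_native)[0]


def _one_over_f_noise(n: int, exponent: float,
                      rng: np.random.Generator) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n)
    return x / (x.std() + 1e-30)


def _blink_wave(fs: float) -> np.ndarray:
    """~300 ms biphasic blink transient."""
    t = np.arange(int(0.3 * fs)) / fs
    return np.sin(np.pi * t / 0.3) ** 2 * np.sign(np.sin(2 * np.pi * t / 0.3))


def _event_train(n: int, fs: float, rate: float, wave: np.ndarray,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    x = np.zeros(n)
    n_events = rng.poisson(rate * n / fs)
    times = np.sort(rng.uniform(0, n / fs, n_events))
    for t0 in times:
        i0_ = int(t0 * fs)
        seg = wave[: n - i0_]
        x[i0_:i0_ + seg.size] += seg
    return x, times


def gen_session(cfg: SynthConfig | None = None,
                montage: Montage | None = None):
    """Full synthetic session: (Recording, GroundTruth).

    Sources are mixed to the 29 EEG sensors by spherical-head leadfield
    columns at seeded random interior positions (the coupled source at a
    left-motor-strip position), sensor noise is added at ``snr_db``, the EMG
    is appended as its own channel, and the acquisition chain is applied.
    Bit-for-bit reproducible per seed.
    """
    cfg = cfg or SynthConfig()
    montage = montage or make_default_montage()
    rng = np.random.default_rng(cfg.seed)
    model = HeadModel()
    n = int(round(cfg.duration_s * cfg.fs_native))
    fs = cfg.fs_native
    bg = cfg.background

    source, drive_phase, pair_truth = gen_coupled_pair(cfg, rng)
    coupling_mask = np.ones(n, dtype=bool)

    sources = [source]
    positions = [np.asarray(cfg.coupling.position)]
    for _ in range(bg.n_alpha):
        sources.append(_bandnoise(n, fs, (bg.alpha_hz - 1, bg.alpha_hz + 1), rng))
        positions.append(_random_interior(rng, model))
    for _ in range(bg.n_broadband):
        sources.append(_one_over_f_noise(n, bg.one_over_f_exponent, rng))
        positions.append(_random_interior(rng, model))
    S = np.array(sources)

    F = model.transfer_coefficients()
    cols = []
    for p in positions:
        mom = _random_unit(rng) * 1e-8   # ~10 nA*m equivalent dipoles
        topo = leadfield(p, mom, montage, model, _F=F).values
        topo = topo / (np.abs(topo).max() + 1e-30) * 10.0   # ~10 µV scalp peaks
        cols.append(topo)
    A = np.column_stack(cols)

    X = A @ S

    # stereotyped artifacts
    labels = montage.eeg_labels
    pos = np.array([montage.positions[l] for l in labels])
    art = cfg.artifacts
    artifact_times: dict[str, np.ndarray] = {}
    frontal = np.exp(-((pos[:, 1] - 1.0) ** 2 + pos[:, 0] ** 2) / 0.25)
    blink, tb = _event_train(n, fs, art.blink_rate, 40.0 * _blink_wave(fs), rng)
    artifact_times["blink"] = tb
    X += np.outer(frontal, blink)
    lr = np.exp(-((pos[:, 1] - 0.9) ** 2) / 0.3) * np.sign(pos[:, 0])
    slow = np.repeat(rng.standard_normal(max(1, int(n / fs / 2)) + 1), int(2 * fs))[:n]
    eye, te = _event_train(n, fs, art.eye_movement_rate,
                           15.0 * np.hanning(int(1.0 * fs)), rng)
    artifact_times["eye_movement"] = te
    X += np.outer(lr, eye * np.sign(slow))
    temporal = np.exp(-((np.abs(pos[:, 0]) - 1.0) ** 2 + pos[:, 2] ** 2) / 0.15)
    burst_env, tm = _event_train(n, fs, art.emg_burst_rate,
                                 np.hanning(int(0.5 * fs)), rng)
    artifact_times["emg_burst"] = tm
    X += np.outer(temporal, 20.0 * burst_env * _bandnoise(n, fs, (30, 120), rng))
    imp_ch = int(rng.integers(len(labels)))
    steps, ti = _event_train(n, fs, art.impedance_rate,
                             30.0 * np.ones(int(2.0 * fs)), rng)
    artifact_times["impedance"] = ti
    X[imp_ch] += steps
    X += art.line_50hz_uv * np.sin(2 * np.pi * 50.0 * np.arange(n) / fs)[None, :]

    sig_power = np.mean(X ** 2)
    noise_sd = np.sqrt(sig_power / 10 ** (cfg.snr_db / 10.0))
    X += noise_sd * rng.standard_normal(X.shape)

    envelope = _default_envelope(n, fs, cfg, rng)
    emg = gen_emg(drive_phase, envelope, cfg, rng) * 50.0  # ~50 µV RMS bursts

    data = acquisition_chain(X, fs)
    data = np.vstack([data, emg[None, :]])
    rec = Recording(
        data, fs, labels + ["EMG1"], ["EEG"] * len(labels) + ["EMG"],
        meta={"seed": cfg.seed, "generator": "cmcpipe.synth.gen_session",
              "kappa": cfg.coupling.kappa, "f0_hz": cfg.coupling.f0,
              "impedance_channel": labels[imp_ch]},
    )
    truth = GroundTruth(
        mixing=A, sources=S, coupled_index=0, coupling_mask=coupling_mask,
        source_phase=pair_truth["source_phase"], emg_drive_phase=drive_phase,
        theoretical_plv=pair_truth["theoretical_plv"],
        coupled_position=np.asarray(cfg.coupling.position),
        artifact_times=artifact_times,
    )
    return rec, truth


def _default_envelope(n: int, fs: float, cfg: SynthConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Sustained-contraction envelope with slow physiological fluctuation."""
    slow = _bandnoise(n, fs, (0.05, 0.3), rng, order=2)
    env = 1.0 + 0.2 * slow
    return np.maximum(env, cfg.emg.rest_level)


def _random_interior(rng: np.random.Generator, model: HeadModel) -> np.ndarray:
    while True:
        p = rng.uniform(-1, 1, 3) * (model.brain_radius - 0.01)
        r = np.linalg.norm(p)
        if 0.02 < r < model.brain_radius - 0.01:
            return p


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def gen_paced_force(n_cycles: int = 15, rate_hz: float = 0.5,
                    fs: float = 500.0, peak_n: float = 15.0) -> np.ndarray:
    """Raised-cosine squeeze-release pulses: ``n_cycles`` at ``rate_hz``."""
    period = 1.0 / rate_hz
    t = np.arange(int(n_cycles * period * fs)) / fs
    phase = (t % period) / period
    return peak_n * 0.5 * (1 - np.cos(2 * np.pi * phase))


def gen_force_session(maze: MazePath, tracking_noise: float = 0.05,
                      cfg: SynthConfig | None = None,
                      force_max: float = 20.0,
                      seed: int | None = None):
    """Simulated maze-tracking run through the full actuator chain.

    The player's force follows the maze center (scaled to ``force_max``)
    plus low-pass tracking error of SD ``tracking_noise`` (normalized units);
    returns a dict with force, ADC counts, cursor, feedback and score.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    fs = 1.0 / np.median(np.diff(maze.t))
    n = maze.t.size
    target = maze.center * force_max
    if tracking_noise > 0:
        err = _bandnoise(n, fs, (0.1, min(2.0, fs / 2 - 0.1)), rng, order=2)
        force = np.maximum(target + tracking_noise * force_max * err, 0.0)
    else:
        force = target
    bridge, amp = BridgeConfig(), AmplifierConfig()
    counts = force_to_adc(force, bridge, amp, fs=fs)
    c0 = int(force_to_adc(np.zeros(1), bridge, amp, fs=fs)[0])
    c1 = int(force_to_adc(np.full(1, force_max), bridge, amp, fs=fs)[0])
    cursor = cursor_trace(counts, affine_calibration(c0, c1))
    score, feedback = score_performance(cursor, maze)
    return {
        "t": maze.t, "force": force, "counts": counts, "cursor": cursor,
        "feedback": feedback, "score": score,
    }
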