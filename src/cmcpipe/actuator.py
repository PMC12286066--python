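"""Signal model of the force biofeedback actuator and serious game.

A binder-clip pinch sensor carries two BF350 strain gauges (nominal 350 Ω)
wired into a Wheatstone bridge with two 360 Ω fixed resistors. Squeezing the
clip stretches one gauge and compresses the other symmetrically, unbalancing
the bridge; the differential voltage is amplified by an AD620 instrumentation
amplifier (gain-set by RG) and digitized by a 10-bit, 0-5 V microcontroller
ADC. The digitized force drives the vertical position of a game cursor that
must track a maze path; the player gets immediate in/out-of-path feedback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np

__all__ = [
    "BridgeConfig",
    "AmplifierConfig",
    "MazePath",
    "ProtocolSchedule",
    "TaskBlock",
    "Feedback",
    "bridge_voltage",
    "amplifier_gain",
    "force_to_adc",
    "make_maze",
    "cursor_trace",
    "score_performance",
    "protocol_schedule",
]


@dataclass
class BridgeConfig:
    """Wheatstone bridge with two strain gauges and two fixed resistors."""

    Ei0: float = 350.0        # Ω, nominal gauge resistance (BF350)
    Eo0: float = 350.0        # Ω
    R1: float = 360.0         # Ω, fixed
    R2: float = 360.0         # Ω, fixed
    V_plus: float = 5.0       # V, bridge excitation
    # Ω per newton of pinch force; with the 413x amplifier and a 0-5 V ADC
    # this puts full scale near 34 N, comfortably above strong pinch grips
    gauge_gain: float = 0.05

    def __post_init__(self) -> None:
        for name in ("Ei0", "Eo0", "R1", "R2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.V_plus <= 0:
            raise ValueError("V_plus must be positive")


@dataclass
class AmplifierConfig:
    """AD620 instrumentation amplifier plus microcontroller ADC."""

    RG: float = 120.0            # Ω, gain resistor
    internal_R: float = 49_400.0  # Ω, AD620 internal gain constant
    adc_bits: int = 10
    adc_vref: float = 5.0        # V full scale

    def __post_init__(self) -> None:
        if self.RG <= 0:
            raise ValueError("RG must be positive")


def bridge_voltage(Ei: float | np.ndarray, Eo: float | np.ndarray,
                   cfg: BridgeConfig | None = None) -> float | np.ndarray:
    """Differential bridge voltage V+ * (Ei/(Ei+R1) - Eo/(Eo+R2)).

    Zero at balance (Ei=Eo with R1=R2); antisymmetric under swapping the
    gauge arms when the fixed resistors are equal.
    """
    cfg = cfg or BridgeConfig()
    Ei = np.asarray(Ei, dtype=float)
    Eo = np.asarray(Eo, dtype=float)
    if np.any(Ei <= 0) or np.any(Eo <= 0):
        raise ValueError("gauge resistances must be positive")
    out = cfg.V_plus * (Ei / (Ei + cfg.R1) - Eo / (Eo + cfg.R2))
    return float(out) if out.ndim == 0 else out


def amplifier_gain(cfg: AmplifierConfig | None = None) -> float:
    """AD620 gain law G = 1 + internal_R / RG.

    With the default RG = 120 Ω this is 412.67, i.e. the familiar 413x
    board gain.
    """
    cfg = cfg or AmplifierConfig()
    if cfg.RG <= 0:
        raise ValueError("RG must be positive")
    return 1.0 + cfg.internal_R / cfg.RG


def force_to_adc(force: np.ndarray, bridge: BridgeConfig | None = None,
                 amp: AmplifierConfig | None = None,
                 fs: float = 500.0) -> np.ndarray:
    """Full sensing chain: pinch force (N) -> integer ADC counts.

    Symmetric strain: Ei = Ei0 + gauge_gain*force, Eo = Eo0 - gauge_gain*force.
    The amplified voltage is clamped to [0, adc_vref] and quantized to
    adc_bits.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    bridge = bridge or BridgeConfig()
    amp = amp or AmplifierConfig()
    force = np.asarray(force, dtype=float)
    if np.any(force < 0):
        raise ValueError("force must be non-negative")
    delta = bridge.gauge_gain * force
    Ei = bridge.Ei0 + delta
    Eo = np.maximum(bridge.Eo0 - delta, 1e-6)
    v = bridge_voltage(Ei, Eo, bridge) * amplifier_gain(amp)
    v = np.clip(v, 0.0, amp.adc_vref)
    full = 2 ** amp.adc_bits - 1
    return np.round(v / amp.adc_vref * full).astype(int)


@dataclass
class MazePath:
    """Target corridor for the tracking game, on a normalized 0-1 screen."""

    t: np.ndarray            # s, strictly increasing
    center: np.ndarray       # target cursor height in [0, 1]
    half_width: np.ndarray   # tolerance band, same grid
    difficulty: str = "A"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.center = np.asarray(self.center, dtype=float)
        self.half_width = np.asarray(self.half_width, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("maze time grid must be strictly increasing")
        lo = self.center - self.half_width
        hi = self.center + self.half_width
        if np.any(lo < -1e-9) or np.any(hi > 1 + 1e-9):
            raise ValueError("maze corridor must stay inside [0, 1]")

    def to_csv(self, path: str | Path) -> None:
        arr = np.c_[self.t, self.center, self.half_width]
        header = "t,center,half_width"
        np.savetxt(path, arr, delimiter=",", header=header, comments="")


#: per-difficulty maze shape: (plateaus per 30 s, half-width, ramp fraction)
_DIFFICULTY = {
    "A": dict(segments_per_30s=3, half_width=0.10, ramp_frac=0.35),
    "B": dict(segments_per_30s=5, half_width=0.06, ramp_frac=0.25),
    "C": dict(segments_per_30s=7, half_width=0.04, ramp_frac=0.20),
}


def make_maze(difficulty: str = "A", duration: float = 90.0, fs: float = 60.0,
              seed: int = 0) -> MazePath:
    """Seeded piecewise plateau/ramp maze.

    Higher difficulty means a narrower corridor and more, steeper force
    transitions. Deterministic per seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if difficulty not in _DIFFICULTY:
        raise ValueError(f"difficulty must be one of {sorted(_DIFFICULTY)}")
    p = _DIFFICULTY[difficulty]
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    n_seg = max(2, int(round(p["segments_per_30s"] * duration / 30.0)))
    hw = p["half_width"]
    levels = rng.uniform(hw + 0.05, 1.0 - hw - 0.05, size=n_seg)
    # segment boundaries with jitter so plateaus differ in length
    edges = np.linspace(0, duration, n_seg + 1)
    jitter = rng.uniform(-0.5, 0.5, size=n_seg - 1) * (duration / n_seg) * 0.4
    edges[1:-1] += jitter
    center = np.empty(n)
    ramp = p["ramp_frac"]
    for k in range(n_seg):
        seg = (t >= edges[k]) & (t < edges[k + 1] if k < n_seg - 1 else t <= edges[k + 1])
        ts = t[seg]
        if ts.size == 0:
            continue
        seg_len = edges[k + 1] - edges[k]
        rise = ramp * seg_len
        prev = levels[k - 1] if k > 0 else levels[0]
        frac = np.clip((ts - edges[k]) / max(rise, 1e-9), 0.0, 1.0)
        # smooth raised-cosine transition from the previous level
        center[seg] = prev + (levels[k] - prev) * 0.5 * (1 - np.cos(np.pi * frac))
    return MazePath(t, center, np.full(n, hw), difficulty)


def cursor_trace(counts: np.ndarray, calibration) -> np.ndarray:
    """Map ADC counts to normalized cursor height via a monotone calibration.

    ``calibration`` is any callable counts -> [0, 1]; tightening the clip
    (higher counts) raises the cursor.
    """
    counts = np.asarray(counts)
    out = np.clip(np.asarray(calibration(counts), dtype=float), 0.0, 1.0)
    return out


def affine_calibration(counts_min: int, counts_max: int):
    """Per-session min/max squeeze calibration: affine counts -> [0, 1]."""
    if counts_max <= counts_min:
        raise ValueError("counts_max must exceed counts_min")

    def cal(c):
        return (np.asarray(c, dtype=float) - counts_min) / (counts_max - counts_min)

    return cal


class Feedback(Enum):
    GREEN = 1   # cursor inside the corridor
    BLACK = 0   # cursor outside


def score_performance(cursor: np.ndarray, maze: MazePath):
    """In-path fraction and per-sample feedback state.

    feedback[i] is GREEN iff |cursor[i] - center[i]| <= half_width[i].
    """
    cursor = np.asarray(cursor, dtype=float)
    if cursor.shape != maze.center.shape:
        raise ValueError(
            f"cursor ({cursor.shape}) and maze ({maze.center.shape}) "
            "must share the time grid"
        )
    inside = np.abs(cursor - maze.center) <= maze.half_width
    feedback = [Feedback.GREEN if g else Feedback.BLACK for g in inside]
    return float(inside.mean()), feedback


@dataclass
class TaskBlock:
    task_id: int
    description: str
    duration: float          # s
    hand: str                # "dominant", "both"
    paced_rate: float | None  # Hz, for cued contraction tasks
    maze_id: str | None
    rest_after: float        # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("task duration must be positive")


@dataclass
class ProtocolSchedule:
    blocks: list[TaskBlock] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.blocks) and sum(1 for b in self.blocks) < 1:
            raise ValueError("empty schedule")

    @property
    def n_tasks(self) -> int:
        return len(self.blocks)

    @property
    def total_duration(self) -> float:
        return sum(b.duration + b.rest_after for b in self.blocks)

    def to_json(self, path: str | Path) -> None:
        obj = [
            {k: getattr(b, k) for k in (
                "task_id", "description", "duration", "hand", "paced_rate",
                "maze_id", "rest_after")}
            for b in self.blocks
        ]
        Path(path).write_text(json.dumps(obj, indent=1))


def protocol_schedule(rest_s: float = 30.0) -> ProtocolSchedule:
    """The five-task motor protocol.

    Tasks 1-2: maze-guided tracking, 90 s each (Task 1 bimanual); Tasks 3-4:
    15 contraction-relaxation cycles cued at 0.5 Hz (30 s), unimanual then
    bimanual; Task 5: 15 s maximal sustained contraction. Rest blocks of
    ``rest_s`` seconds separate the tasks.
    """
    cycles, rate = 15, 0.5
    paced_dur = cycles / rate
    return ProtocolSchedule([
        TaskBlock(1, "maze tracking, both hands", 90.0, "both", None, "A", rest_s),
        TaskBlock(2, "maze tracking, dominant hand", 90.0, "dominant", None, "B", rest_s),
        TaskBlock(3, "paced squeeze-release, dominant hand", paced_dur,
                  "dominant", rate, None, rest_s),
        TaskBlock(4, "paced squeeze-release, both hands", paced_dur,
                  "both", rate, None, rest_s),
        TaskBlock(5, "maximal sustained contraction", 15.0, "dominant", None,
                  None, rest_s),
    ])
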