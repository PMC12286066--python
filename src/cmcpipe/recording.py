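"""Core data containers and I/O for multichannel EEG/EMG/force recordings.

The acquisition layout emulated throughout the package is a 32-channel EEG cap
repurposed for simultaneous EEG+EMG: three occipito-parietal sites (PO7, Oz,
PO8) are taken out of the EEG analysis set — one becomes the new common
reference (hardware channel 16, relocated to the earlobe) and two carry the
bipolar EMG pair (hardware channels 31/32) — leaving 29 EEG analysis channels
sampled at 500 Hz.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "Montage",
    "Topography",
    "make_default_montage",
    "read_recording",
    "write_recording",
]

CH_TYPES = ("EEG", "EMG", "FORCE")

#: cap layout of a 32-channel extended 10-20 system (g.tec-style ordering,
#: 1-based hardware channel = position in this tuple + 1)
CAP32_LABELS = (
    "Fp1", "Fp2", "AF3", "AF4", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Oz", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO3", "PO4", "PO7", "PO8",
)
#: sites vacated for the reference (hardware ch 16) and the EMG pair (31/32)
REPURPOSED = {"reference": "Oz", "emg": ("PO7", "PO8")}


@dataclass
class Recording:
    """A labeled multichannel time series.

    data : (n_channels, n_samples) array, µV for EEG/EMG, V for force
    fs : sampling rate in Hz
    labels : unique per-channel names
    ch_types : per-channel kind, one of ``EEG``, ``EMG``, ``FORCE``
    meta : free-form provenance (task id, seed, filter history, ...)
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    ch_types: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.labels = list(self.labels)
        self.ch_types = list(self.ch_types)
        if len(set(self.labels)) != len(self.labels):
            dupes = {l for l in self.labels if self.labels.count(l) > 1}
            raise ValueError(f"duplicate channel labels: {sorted(dupes)}")
        if self.data.shape[0] != len(self.labels):
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.labels)} labels"
            )
        if len(self.ch_types) != len(self.labels):
            raise ValueError("ch_types length must match labels")
        bad = [t for t in self.ch_types if t not in CH_TYPES]
        if bad:
            raise ValueError(f"unknown channel types {bad}; expected {CH_TYPES}")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def pick(self, ch_type: str) -> "Recording":
        """Sub-recording holding only channels of the given type."""
        idx = [i for i, t in enumerate(self.ch_types) if t == ch_type]
        if not idx:
            raise ValueError(f"no channels of type {ch_type!r}")
        return Recording(
            self.data[idx].copy(),
            self.fs,
            [self.labels[i] for i in idx],
            [self.ch_types[i] for i in idx],
            dict(self.meta),
        )

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.fs, list(self.labels), list(self.ch_types),
            dict(self.meta),
        )


@dataclass
class Montage:
    """Scalp geometry: unit-sphere electrode positions plus the repurposed
    reference and EMG channel labels (head frame: x right, y anterior,
    z superior)."""

    positions: dict[str, np.ndarray]
    reference_label: str
    emg_labels: tuple[str, str]

    def __post_init__(self) -> None:
        self.positions = {
            k: np.asarray(v, dtype=float) for k, v in self.positions.items()
        }
        for lab, p in self.positions.items():
            if p.shape != (3,):
                raise ValueError(f"position of {lab} is not 3-D")
            if abs(np.linalg.norm(p) - 1.0) > 1e-9:
                raise ValueError(f"position of {lab} is not unit-norm")
        self.emg_labels = tuple(self.emg_labels)
        overlap = ({self.reference_label, *self.emg_labels}
                   & set(self.positions))
        if overlap:
            raise ValueError(
                f"reference/EMG labels must not be EEG analysis labels: {overlap}"
            )

    @property
    def eeg_labels(self) -> list[str]:
        return list(self.positions)

    def to_json(self, path: str | Path) -> None:
        obj = {
            "positions": {k: list(v) for k, v in self.positions.items()},
            "reference_label": self.reference_label,
            "emg_labels": list(self.emg_labels),
        }
        # insertion order is the channel order; keep it
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "Montage":
        obj = json.loads(Path(path).read_text())
        return cls(
            {k: np.array(v) for k, v in obj["positions"].items()},
            obj["reference_label"],
            tuple(obj["emg_labels"]),
        )


@dataclass
class Topography:
    """Scalp weight pattern of a source over the EEG analysis channels.

    Scale-free: comparisons between topographies use normalized correlation.
    """

    values: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        self.labels = list(self.labels)
        if len(self.values) != len(self.labels):
            raise ValueError("topography length must match label count")

    def corr(self, other: "Topography | np.ndarray") -> float:
        """Normalized (Pearson) correlation with another topography."""
        v = other.values if isinstance(other, Topography) else np.asarray(other)
        return float(np.corrcoef(self.values, v.ravel())[0, 1])


def _idealized_positions(labels: tuple[str, ...]) -> dict[str, np.ndarray]:
    """Unit-sphere 10-20 coordinates: standard montage positions sphere-fitted
    and projected onto the unit sphere."""
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        std = mne.channels.make_standard_montage("standard_1020")
    pos = std.get_positions()["ch_pos"]
    pts = np.array([pos[l] for l in labels])
    # least-squares sphere fit: ||p - c||^2 = r^2
    A = np.c_[2 * pts, np.ones(len(pts))]
    b = (pts ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    unit = pts - center
    unit /= np.linalg.norm(unit, axis=1, keepdims=True)
    return {l: unit[i] for i, l in enumerate(labels)}


def make_default_montage() -> Montage:
    """Default montage of the repurposed 32-channel cap.

    29 EEG analysis channels remain; the cap's Oz slot (hardware channel 16)
    is the relocated reference and PO7/PO8 (hardware channels 31/32) carry
    the EMG pair.
    """
    keep = tuple(
        l for l in CAP32_LABELS
        if l != REPURPOSED["reference"] and l not in REPURPOSED["emg"]
    )
    positions = _idealized_positions(keep)
    return Montage(positions, reference_label=REPURPOSED["reference"],
                   emg_labels=REPURPOSED["emg"])


def _infer_ch_type(label: str) -> str:
    u = label.upper()
    if u.startswith("EMG") or u in {"PO7", "PO8"}:
        return "EMG"
    if u.startswith("FORCE"):
        return "FORCE"
    return "EEG"


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a recording from ``csv`` (time-matrix dialect) or ``edf``.

    The CSV dialect is lossless: first column ``time`` in seconds, one header
    row of channel labels, '.' decimal, UTF-8. Channel types are restored from
    the ``# ch_types:`` comment line if present, else inferred from labels.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "csv":
        return _read_csv(path)
    if format in {"edf", "edf+"}:
        return _read_edf(path)
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(rec: Recording, path: str | Path,
                    format: str | None = None) -> None:
    """Write a recording as lossless CSV-matrix or 16-bit EDF.

    EDF quantizes to the declared physical range; samples outside an
    explicitly supplied range are clipped (with a warning and a meta note).
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    format = format.lower()
    if rec.n_samples == 0:
        raise ValueError("refusing to write an empty recording (0 samples)")
    if format == "csv":
        _write_csv(rec, path)
    elif format in {"edf", "edf+"}:
        from ._edf import write_edf

        write_edf(rec, path)
    else:
        raise ValueError(f"unknown recording format {format!r}")


def _write_csv(rec: Recording, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("# fs: %r\n" % rec.fs)
        fh.write("# ch_types: %s\n" % ",".join(rec.ch_types))
        fh.write("time," + ",".join(rec.labels) + "\n")
        t = rec.times
        for i in range(rec.n_samples):
            row = ",".join(repr(float(v)) for v in rec.data[:, i])
            fh.write(f"{float(t[i])!r},{row}\n")


def _read_csv(path: Path) -> Recording:
    fs = None
    ch_types = None
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "fs":
                fs = float(val)
            elif key.strip() == "ch_types":
                ch_types = [t.strip() for t in val.strip().split(",")]
    with open(path, encoding="utf-8") as fh:
        for _ in range(skip):
            fh.readline()
        header = fh.readline().strip().split(",")
    if header[0] != "time":
        raise ValueError(f"CSV-matrix must start with a 'time' column, "
                         f"got {header[0]!r}")
    labels = header[1:]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate channel label in CSV header")
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    t = df.iloc[:, 0].to_numpy()
    if fs is None:
        if len(t) < 2:
            raise ValueError("cannot infer fs from a single sample")
        fs = 1.0 / np.median(np.diff(t))
    data = df.iloc[:, 1:].to_numpy().T
    if ch_types is None:
        ch_types = [_infer_ch_type(l) for l in labels]
    return Recording(data, float(fs), labels, ch_types,
                     meta={"source": str(path), "format": "csv"})


def _read_edf(path: Path) -> Recording:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    labels = list(raw.ch_names)
    data = raw.get_data()  # volts for eeg-typed channels
    # mne scales EDF 'uV' dimensions to volts; store EEG/EMG back in µV
    ch_types = [_infer_ch_type(l) for l in labels]
    scale = np.array([1e6 if t in ("EEG", "EMG") else 1.0 for t in ch_types])
    data = data * scale[:, None]
    return Recording(data, float(raw.info["sfreq"]), labels, ch_types,
                     meta={"source": str(path), "format": "edf"})
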