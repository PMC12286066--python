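"""Beta-band preprocessing: zero-phase Butterworth filtering, polyphase
downsampling to 60 Hz, and ICA-based artifact screening.

The analysis band is 13-30 Hz (beta), the band classically tied to motor
execution and corticomuscular coupling. After band-limiting to 30 Hz, a
60 Hz rate satisfies the Nyquist criterion, so sessions are downsampled
(500 -> 60 Hz) before source separation. Artifactual independent components
are scored against the classic catalogue: focal impedance artifacts,
high-frequency temporal-muscle activity, frontal blink transients, and
left-right bipolar horizontal eye movements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator
from sklearn.decomposition import FastICA

from .recording import Montage, Recording

__all__ = [
    "FilterSpec",
    "bandpass",
    "notch",
    "downsample",
    "nyquist_rate",
    "ArtifactICA",
    "ICADecomposition",
    "ica_decompose",
    "artifact_scores",
    "remove_components",
]

BETA_BAND = (13.0, 30.0)


@dataclass
class FilterSpec:
    """Butterworth filter description (bandpass or notch)."""

    kind: str = "bandpass"
    order: int = 4
    band: tuple[float, float] = BETA_BAND
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("bandpass", "notch"):
            raise ValueError("kind must be 'bandpass' or 'notch'")
        lo, hi = self.band
        if not 0 < lo < hi:
            raise ValueError(f"invalid band {self.band}")

    def validate(self, fs: float) -> None:
        if self.band[1] >= fs / 2:
            raise ValueError(
                f"band edge {self.band[1]} Hz is at or above Nyquist "
                f"({fs / 2} Hz)"
            )


def nyquist_rate(band_high: float = BETA_BAND[1]) -> float:
    """Minimum sampling rate that represents a band-limited signal without
    aliasing: twice the highest frequency present."""
    return 2.0 * band_high


def _apply_sos(data: np.ndarray, sos: np.ndarray, zero_phase: bool) -> np.ndarray:
    if zero_phase:
        return signal.sosfiltfilt(sos, data, axis=-1)
    return signal.sosfilt(sos, data, axis=-1)


def bandpass(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Zero-phase Butterworth bandpass, default 4th order 13-30 Hz.

    Forward-backward application squares the magnitude response and cancels
    group delay, so downstream phase estimates are unbiased by the filter.
    """
    spec = spec or FilterSpec()
    spec.validate(rec.fs)
    sos = signal.butter(spec.order, spec.band, btype="bandpass", fs=rec.fs,
                        output="sos")
    out = rec.copy()
    out.data = _apply_sos(out.data, sos, spec.zero_phase)
    out.meta.setdefault("filters", []).append(
        {"kind": "bandpass", "band": list(spec.band), "order": spec.order,
         "zero_phase": spec.zero_phase}
    )
    return out


def notch(rec: Recording, freq: float = 50.0, q: float = 30.0) -> Recording:
    """IIR notch (line interference removal), zero-phase."""
    b, a = signal.iirnotch(freq, q, fs=rec.fs)
    out = rec.copy()
    out.data = signal.filtfilt(b, a, out.data, axis=-1)
    out.meta.setdefault("filters", []).append({"kind": "notch", "freq": freq})
    return out


def downsample(rec: Recording, target_fs: float = 60.0) -> Recording:
    """Polyphase resampling to ``target_fs`` (default 60 Hz).

    The caller is responsible for the data being band-limited below
    target_fs/2; the polyphase kernel (Kaiser window) provides the
    anti-alias guard for the non-integer 500 -> 60 ratio.
    """
    if target_fs >= rec.fs:
        raise ValueError(
            f"target_fs {target_fs} must be below current fs {rec.fs}"
        )
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(10_000)
    up, down = frac.numerator, frac.denominator
    # sharp anti-alias FIR (Kaiser-windowed, ~0.5 Hz transition at the new
    # Nyquist) so in-band energy survives the non-integer 500 -> 60 ratio
    cutoff = target_fs / 2.0
    numtaps = int(6.0 / (0.2 / (rec.fs * up / 2.0)))
    numtaps += 1 - numtaps % 2
    taps = signal.firwin(numtaps, cutoff, fs=rec.fs * up,
                         window=("kaiser", 8.0))
    out = rec.copy()
    out.data = signal.resample_poly(rec.data, up, down, axis=-1,
                                    window=taps)
    out.fs = rec.fs * up / down
    out.meta.setdefault("filters", []).append(
        {"kind": "resample", "from_fs": rec.fs, "to_fs": out.fs}
    )
    return out


@dataclass
class ICADecomposition:
    """Result of an ICA run on the EEG analysis channels."""

    unmixing: np.ndarray          # (n_comp, n_ch)
    mixing: np.ndarray            # (n_ch, n_comp)
    sources: np.ndarray           # (n_comp, n_samp)
    mean: np.ndarray              # per-channel mean removed before ICA
    labels: list[str]
    fs: float
    scores: pd.DataFrame | None = None

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def topography(self, k: int) -> np.ndarray:
        return self.mixing[:, k]


class ArtifactICA(BaseEstimator):
    """ICA artifact screener with an sklearn estimator surface.

    Decomposes EEG into independent components (FastICA, seeded), scores each
    component against the classic artifact signatures, and reconstructs the
    recording with chosen components removed.

    Parameters
    ----------
    n_components : int or None
        Components to extract (None: all channels, reduced on rank deficiency).
    random_state : int
        Seed; identical seeds give identical unmixing up to sign.
    auto_threshold : float
        Score above which a component is flagged by ``auto_select_``.
    """

    def __init__(self, n_components: int | None = None, random_state: int = 0,
                 auto_threshold: float = 0.8):
        self.n_components = n_components
        self.random_state = random_state
        self.auto_threshold = auto_threshold

    def fit(self, rec: Recording, montage: Montage | None = None):
        if any(t != "EEG" for t in rec.ch_types):
            raise ValueError("ArtifactICA expects EEG channels only")
        X = rec.data
        n_comp = self.n_components or X.shape[0]
        rank = np.linalg.matrix_rank(np.cov(X))
        if n_comp > rank:
            warnings.warn(
                f"rank-deficient data: reducing n_components {n_comp} -> {rank}",
                RuntimeWarning,
            )
            n_comp = rank
        mean = X.mean(axis=1)
        ica = FastICA(n_components=n_comp, random_state=self.random_state,
                      whiten="unit-variance", max_iter=1000, tol=1e-6)
        S = ica.fit_transform((X - mean[:, None]).T).T
        A, W = ica.mixing_, ica.components_
        # order components by explained variance (power of mixing column x source)
        power = (A ** 2).sum(axis=0) * (S ** 2).mean(axis=1)
        order = np.argsort(power)[::-1]
        self.decomposition_ = ICADecomposition(
            unmixing=W[order], mixing=A[:, order], sources=S[order],
            mean=mean, labels=list(rec.labels), fs=rec.fs,
        )
        if montage is not None:
            self.decomposition_.scores = artifact_scores(
                self.decomposition_, montage
            )
            sc = self.decomposition_.scores
            flag = (
                (sc[["focality", "hf_ratio", "frontal_score"]] >
                 self.auto_threshold).any(axis=1)
                | (sc["lateral_score"].abs() > self.auto_threshold)
            )
            self.auto_select_ = list(np.flatnonzero(flag.to_numpy()))
        return self

    def transform(self, rec: Recording, remove: list[int] | None = None) -> Recording:
        remove = self.auto_select_ if remove is None else remove
        return remove_components(rec, self.decomposition_, remove)


def ica_decompose(eeg: Recording, n_components: int | None = None,
                  seed: int = 0) -> ICADecomposition:
    """Functional wrapper over :class:`ArtifactICA` (decomposition only)."""
    est = ArtifactICA(n_components=n_components, random_state=seed)
    est.fit(eeg)
    return est.decomposition_


def _frontal_mask(labels: list[str], montage: Montage) -> np.ndarray:
    pos = np.array([montage.positions[l] for l in labels])
    return pos[:, 1] > 0.5  # anterior sector of the unit sphere


def artifact_scores(dec: ICADecomposition, montage: Montage) -> pd.DataFrame:
    """Score components against the artifact catalogue.

    focality : max|topo| / sum|topo| (1 for a one-hot impedance pattern)
    hf_ratio : spectral power above 20 Hz over total (muscle activity)
    frontal_score : mean |topo| over frontal channels, normalized, times the
        low-frequency (<5 Hz) power fraction (blinks, slow ocular drifts)
    lateral_score : signed left-right frontal asymmetry in [-1, 1]
        (horizontal eye movements)
    """
    frontal = _frontal_mask(dec.labels, montage)
    pos = np.array([montage.positions[l] for l in dec.labels])
    rows = []
    freqs, psd = signal.welch(dec.sources, fs=dec.fs,
                              nperseg=min(256, dec.sources.shape[1]))
    for k in range(dec.n_components):
        topo = dec.topography(k)
        a = np.abs(topo)
        total = a.sum() + 1e-30
        focality = float(a.max() / total)
        p = psd[k]
        ptot = p.sum() + 1e-30
        hf_ratio = float(p[freqs > 20.0].sum() / ptot)
        lf_frac = float(p[freqs < 5.0].sum() / ptot)
        w_front = a[frontal].mean() / (a.mean() + 1e-30)
        frontal_score = float(min(1.0, w_front * lf_frac))
        left = frontal & (pos[:, 0] < 0)
        right = frontal & (pos[:, 0] > 0)
        lr = (topo[left].mean() - topo[right].mean())
        lateral = float(np.clip(lr / (a.max() + 1e-30), -1, 1)) * lf_frac
        rows.append({"component": k, "focality": focality,
                     "hf_ratio": hf_ratio, "frontal_score": frontal_score,
                     "lateral_score": lateral})
    return pd.DataFrame(rows).set_index("component")


def remove_components(eeg: Recording, dec: ICADecomposition,
                      indices: list[int]) -> Recording:
    """Reconstruct the recording with the listed components excluded.

    Removing an empty set is the identity (within numerical tolerance);
    removing everything is refused as degenerate.
    """
    indices = sorted(set(int(i) for i in indices))
    if any(i < 0 or i >= dec.n_components for i in indices):
        raise IndexError(f"component index out of range: {indices}")
    if len(indices) == dec.n_components:
        raise ValueError("refusing to remove all components")
    keep = [i for i in range(dec.n_components) if i not in indices]
    recon = dec.mixing[:, keep] @ dec.sources[keep] + dec.mean[:, None]
    out = eeg.copy()
    out.data = recon
    out.meta.setdefault("ica_removed", []).extend(indices)
    return out
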