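"""Temporal-decorrelation source separation (TDSEP) and source-EMG coherence.

TDSEP separates sources by jointly diagonalizing a set of time-lagged
covariance matrices of the whitened data — it exploits temporal structure
rather than higher-order statistics, so it preserves the phase and coherence
relationships that matter for synchrony analysis. The separation is repeated
over many "essays" (each with a different random lag subset), recurring
sources are grouped by time-course correlation, and Welch magnitude-squared
coherence between the grouped sources and the EMG selects the frequency band
and time window for the subsequent reference phase analysis.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "WhitenedData",
    "SourceSet",
    "CoherenceMap",
    "whiten",
    "lagged_cov",
    "joint_diag",
    "TDSEP",
    "tdsep",
    "essay_group",
    "coherence_map",
]


@dataclass
class WhitenedData:
    """Sphering transform and whitened data (identity sample covariance)."""

    sphering: np.ndarray      # (r, n_ch)
    desphering: np.ndarray    # (n_ch, r), pseudo-inverse on retained subspace
    data: np.ndarray          # (r, n_samp)
    mean: np.ndarray          # removed channel means


@dataclass
class SourceSet:
    """Output of one separation: demixing/mixing matrices and sources."""

    demixing: np.ndarray      # (n_src, n_ch)
    mixing: np.ndarray        # (n_ch, n_src) topography columns
    sources: np.ndarray       # (n_src, n_samp)
    occurrence: np.ndarray | None = None   # per-source count after grouping


def whiten(X: np.ndarray, var_keep: float = 1.0) -> WhitenedData:
    """Zero-mean, identity-covariance (PCA) sphering.

    var_keep < 1 truncates to the leading components explaining that fraction
    of variance; near-zero-variance directions are dropped with a warning
    (whitening would otherwise blow their noise up to unit variance).
    """
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    C = Xc @ Xc.T / Xc.shape[1]
    zero = np.flatnonzero(np.diag(C) < 1e-24)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) at index {zero.tolist()}")
    ev, U = np.linalg.eigh(C)
    order = np.argsort(ev)[::-1]
    ev, U = ev[order], U[:, order]
    r = len(ev)
    if var_keep < 1.0:
        cum = np.cumsum(ev) / ev.sum()
        r = int(np.searchsorted(cum, var_keep) + 1)
    tiny = ev < ev[0] * 1e-12
    if tiny.any():
        r = min(r, int(np.argmax(tiny)))
        warnings.warn(
            f"rank-deficient covariance: keeping {r} of {len(ev)} dimensions",
            RuntimeWarning,
        )
    ev, U = ev[:r], U[:, :r]
    sph = (U / np.sqrt(ev)).T
    desph = U * np.sqrt(ev)
    return WhitenedData(sph, desph, sph @ Xc, mean)


def lagged_cov(Z: np.ndarray, lag: int) -> np.ndarray:
    """Symmetrized time-lagged covariance 0.5 * (C(tau) + C(tau)^T)."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[1]
    if lag >= n:
        raise ValueError(f"lag {lag} >= sample count {n}")
    if lag == 0:
        C = Z @ Z.T / n
    else:
        C = Z[:, :-lag] @ Z[:, lag:].T / (n - lag)
    return 0.5 * (C + C.T)


def _off_total(mats: np.ndarray) -> float:
    return float(sum(((M ** 2).sum() - (np.diag(M) ** 2).sum()) for M in mats))


def joint_diag(matrices, tol: float = 1e-12, max_sweeps: int = 100):
    """Approximate joint diagonalizer of symmetric matrices (Jacobi rotations).

    Returns an orthogonal V minimizing the summed squared off-diagonals of
    V^T M V. The criterion is non-increasing across sweeps by construction
    (each Givens rotation maximizes the pairwise on-diagonal energy).
    """
    mats = np.array([np.asarray(M, dtype=float) for M in matrices])
    if mats.ndim != 3 or mats.shape[1] != mats.shape[2]:
        raise ValueError("need a list of equally-sized square matrices")
    for M in mats:
        if not np.allclose(M, M.T, atol=1e-8 * max(1.0, np.abs(M).max())):
            raise ValueError("joint_diag requires symmetric matrices")
    d = mats.shape[1]
    V = np.eye(d)
    history = [_off_total(mats)]
    for sweep in range(max_sweeps):
        rotated = False
        for p in range(d - 1):
            for q in range(p + 1, d):
                # closed-form Givens angle (Cardoso & Souloumiac, real case)
                h1 = mats[:, p, p] - mats[:, q, q]
                h2 = mats[:, p, q] + mats[:, q, p]
                ton = float(h1 @ h1 - h2 @ h2)
                toff = 2.0 * float(h1 @ h2)
                theta = 0.5 * np.arctan2(toff, ton + np.hypot(ton, toff))
                c, s = np.cos(theta), np.sin(theta)
                if abs(s) > 1e-14:
                    rotated = True
                    # in-place Givens update: only rows/cols p, q change
                    rp, rq = mats[:, p, :].copy(), mats[:, q, :].copy()
                    mats[:, p, :] = c * rp + s * rq
                    mats[:, q, :] = -s * rp + c * rq
                    cp, cq = mats[:, :, p].copy(), mats[:, :, q].copy()
                    mats[:, :, p] = c * cp + s * cq
                    mats[:, :, q] = -s * cp + c * cq
                    vp, vq = V[:, p].copy(), V[:, q].copy()
                    V[:, p] = c * vp + s * vq
                    V[:, q] = -s * vp + c * vq
        history.append(_off_total(mats))
        if not rotated or history[-2] - history[-1] < tol:
            break
    return V, history


class TDSEP(BaseEstimator, TransformerMixin):
    """Temporal-decorrelation blind source separation.

    fit(X) whitens X (channels x samples), builds symmetrized lagged
    covariances for the configured lags, jointly diagonalizes them, and
    exposes ``demixing_`` (sources = demixing_ @ X), ``mixing_`` (topography
    columns), and ``sources_`` ordered by lag-1 autocorrelation (most
    temporally structured first).

    Parameters
    ----------
    lags : sequence of int
        Lags (samples) of the covariance set; default 1..20 at 60 Hz spans
        roughly 17-333 ms, covering beta-band autocorrelation.
    var_keep : float
        Whitening variance-retention fraction.
    """

    def __init__(self, lags=tuple(range(1, 21)), var_keep: float = 1.0):
        self.lags = lags
        self.var_keep = var_keep

    def fit(self, X: np.ndarray, y=None):
        X = np.asarray(X, dtype=float)
        if X.shape[0] < 2:
            raise ValueError("TDSEP needs at least 2 channels")
        wh = whiten(X, self.var_keep)
        mats = [lagged_cov(wh.data, int(l)) for l in self.lags]
        V, self.history_ = joint_diag(mats)
        demix = V.T @ wh.sphering
        mix = wh.desphering @ V
        S = demix @ (X - wh.mean[:, None])
        # order by lag-1 autocorrelation, descending
        ac = np.array([
            np.corrcoef(s[:-1], s[1:])[0, 1] if s.std() > 0 else -1.0
            for s in S
        ])
        order = np.argsort(ac)[::-1]
        self.whitened_ = wh
        self.demixing_ = demix[order]
        self.mixing_ = mix[:, order]
        self.sources_ = S[order]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.demixing_ @ (X - self.whitened_.mean[:, None])


def tdsep(X: np.ndarray, lags=tuple(range(1, 21)),
          var_keep: float = 1.0) -> SourceSet:
    """Functional wrapper over the :class:`TDSEP` estimator."""
    est = TDSEP(lags=lags, var_keep=var_keep).fit(X)
    return SourceSet(est.demixing_, est.mixing_, est.sources_)


def _single_linkage_clusters(sim: np.ndarray, threshold: float) -> list[list[int]]:
    """Single-linkage connected components of sim >= threshold (union-find)."""
    n = sim.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= threshold:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    return [sorted(v) for _, v in sorted(groups.items())]


def essay_group(source_sets: list[SourceSet], threshold: float = 0.9) -> SourceSet:
    """Group recurring sources across separation essays.

    All sources from all essays are pooled; pairs with absolute time-course
    correlation >= threshold are single-linkage clustered. The representative
    of each cluster is its medoid (largest summed similarity to members);
    clusters are ordered by occurrence (number of distinct essays) and carry
    that count.
    """
    if len(source_sets) < 2:
        raise ValueError("need at least 2 essays to group")
    srcs, topos, demixs, essay_of = [], [], [], []
    for e, ss in enumerate(source_sets):
        for k in range(ss.sources.shape[0]):
            srcs.append(ss.sources[k])
            topos.append(ss.mixing[:, k])
            demixs.append(ss.demixing[k])
            essay_of.append(e)
    S = np.array(srcs)
    Sn = (S - S.mean(axis=1, keepdims=True))
    Sn /= (np.linalg.norm(Sn, axis=1, keepdims=True) + 1e-30)
    sim = np.abs(Sn @ Sn.T)
    clusters = _single_linkage_clusters(sim, threshold)
    reps, rep_topo, rep_demix, occ = [], [], [], []
    for members in clusters:
        sub = sim[np.ix_(members, members)]
        medoid = members[int(np.argmax(sub.sum(axis=1)))]
        reps.append(S[medoid])
        rep_topo.append(topos[medoid])
        rep_demix.append(demixs[medoid])
        occ.append(len({essay_of[m] for m in members}))
    order = np.argsort(occ)[::-1]
    return SourceSet(
        demixing=np.array(rep_demix)[order],
        mixing=np.array(rep_topo).T[:, order],
        sources=np.array(reps)[order],
        occurrence=np.array(occ)[order],
    )


@dataclass
class CoherenceMap:
    """Sliding-window source-EMG coherence and the selected band/window."""

    frequencies: np.ndarray          # Hz
    window_starts: np.ndarray        # s
    values: np.ndarray               # (n_src, n_freq, n_win) in [0, 1]
    chosen_source: int = 0
    chosen_band: tuple[float, float] = (0.0, 0.0)   # center ± 1 Hz
    chosen_window: tuple[float, float] = (0.0, 0.0)  # s

    @property
    def chosen_center(self) -> float:
        return 0.5 * (self.chosen_band[0] + self.chosen_band[1])

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for s in range(self.values.shape[0]):
            for wi, w0 in enumerate(self.window_starts):
                for fi, f in enumerate(self.frequencies):
                    rows.append((s, w0, f, self.values[s, fi, wi]))
        pd.DataFrame(rows, columns=["source", "window_start", "frequency",
                                    "coherence"]).to_csv(path, index=False)

    def summary_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "chosen_source": int(self.chosen_source),
            "chosen_band_hz": list(self.chosen_band),
            "chosen_window_s": list(self.chosen_window),
        }, indent=1))


def coherence_map(sources: np.ndarray, emg: np.ndarray, fs: float,
                  window_s: float = 10.0, overlap: float = 0.5,
                  nperseg_s: float = 2.0,
                  band: tuple[float, float] = (13.0, 30.0),
                  band_halfwidth: float = 1.0) -> CoherenceMap:
    """Welch magnitude-squared coherence per sliding window.

    Coherence is estimated per (source, window) with ``nperseg_s``-second Hann
    segments at 50% overlap; the chosen band/window is the argmax of coherence
    inside ``band``, reported as center ± band_halfwidth to feed the 2 Hz
    analysis filter of the reference phase analysis.
    """
    sources = np.atleast_2d(np.asarray(sources, dtype=float))
    emg = np.asarray(emg, dtype=float).ravel()
    if sources.shape[1] != emg.size:
        raise ValueError("sources and EMG must have equal durations")
    win = int(round(window_s * fs))
    if win > emg.size:
        raise ValueError("window longer than signal")
    hop = max(1, int(round(win * (1 - overlap))))
    nperseg = min(int(round(nperseg_s * fs)), win)
    starts = np.arange(0, emg.size - win + 1, hop)
    vals = []
    for s0 in starts:
        f, cxy = signal.coherence(sources[:, s0:s0 + win], emg[s0:s0 + win],
                                  fs=fs, nperseg=nperseg, axis=-1)
        vals.append(np.clip(cxy, 0.0, 1.0))
    values = np.stack(vals, axis=-1)   # (n_src, n_freq, n_win)
    freqs = f
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    sub = np.where(in_band[None, :, None], values, -1.0)
    src, fi, wi = np.unravel_index(np.argmax(sub), sub.shape)
    f0 = float(freqs[fi])
    cm = CoherenceMap(
        frequencies=freqs, window_starts=starts / fs, values=values,
        chosen_source=int(src),
        chosen_band=(f0 - band_halfwidth, f0 + band_halfwidth),
        chosen_window=(float(starts[wi] / fs), float(starts[wi] / fs + window_s)),
    )
    return cm
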