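"""Reference Phase Analysis (RPA).

RPA finds the linear combination of EEG channels whose instantaneous phase is
maximally locked to an EMG reference. Phase locking is quantified by the
phase-locking value

    PLV = | (1/N) sum_t exp(i * dphi(t)) |,    dphi = phi_eeg - phi_emg,

which is 1 for a rigid phase relation, near 0 for independent phases, and by
construction independent of either signal's amplitude. Because corticomuscular
synchrony is transient, the analysis runs on sliding windows: in each window an
adaptive-step gradient ascent on the unit sphere maximizes the PLV of the
combined signal, restarted from many random initializations (the objective has
local maxima). Candidates are grouped within a window by time-course
correlation (|r| >= 0.85) and across windows by topography correlation
(|r| >= 0.70); the recurring family with the most member windows is the
synchronous source estimate.

Maximizing PLV over a high-dimensional filter on a short narrowband window
overfits (the optimized value is biased far above the true coupling), so each
family's reported per-window PLVs come from its fixed consensus filter
re-evaluated on every member window — an essentially out-of-sample, de-biased
estimate. The optimized values remain available on the candidates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .preprocess import FilterSpec, bandpass
from .recording import Recording
from .tdsep import WhitenedData, _single_linkage_clusters, whiten

__all__ = [
    "PhaseSeries",
    "RPAConfig",
    "SyncFamily",
    "RPAReport",
    "narrowband",
    "analytic_phase",
    "plv",
    "plv_objective",
    "gradient_ascent",
    "rpa_window",
    "group_intra",
    "group_inter",
    "ReferencePhaseAnalysis",
    "run_rpa",
]

_EDGE_FRACTION = 0.05  # analytic-signal edge samples excluded from PLV


@dataclass
class PhaseSeries:
    """Instantaneous phase of a narrowband signal, wrapped to (-pi, pi]."""

    phi: np.ndarray
    fs: float
    tag: str = ""
    edge_mask: np.ndarray | None = None   # True where edge-contaminated

    def __post_init__(self) -> None:
        self.phi = np.asarray(self.phi, dtype=float)
        if not np.isfinite(self.phi).all():
            raise ValueError("phase contains non-finite values")
        # wrap into (-pi, pi]
        self.phi = -np.angle(np.exp(-1j * self.phi))
        if self.edge_mask is None:
            self.edge_mask = np.zeros(self.phi.shape, dtype=bool)

    @property
    def interior(self) -> np.ndarray:
        return self.phi[~self.edge_mask]


@dataclass
class RPAConfig:
    """Tunables of the reference phase analysis."""

    n_essays: int = 50            # random restarts per window
    intra_threshold: float = 0.85  # within-window grouping |corr|
    inter_threshold: float = 0.70  # across-window grouping |corr|
    window_s: float = 5.0
    window_overlap: float = 0.5
    band_halfwidth: float = 1.0   # Hz; the 2 Hz analysis band
    filter_order: int = 4
    max_iters: int = 150
    plv_tol: float = 1e-5
    step_init: float = 0.1
    step_up: float = 1.5
    step_down: float = 0.5
    var_keep: float = 0.99        # whitening variance retention
    n_permutations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("intra_threshold", "inter_threshold"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.n_essays < 1:
            raise ValueError("n_essays must be >= 1")


def narrowband(rec: Recording, center_hz: float,
               cfg: RPAConfig | None = None) -> Recording:
    """Zero-phase Butterworth bandpass of width 2*band_halfwidth around the
    frequency of interest (default a 2 Hz band)."""
    cfg = cfg or RPAConfig()
    lo = center_hz - cfg.band_halfwidth
    hi = center_hz + cfg.band_halfwidth
    if lo <= 0 or hi >= rec.fs / 2:
        raise ValueError(
            f"band [{lo}, {hi}] Hz invalid for fs {rec.fs}"
        )
    return bandpass(rec, FilterSpec("bandpass", cfg.filter_order, (lo, hi)))


def analytic_phase(x: np.ndarray, fs: float, tag: str = "") -> PhaseSeries:
    """Instantaneous phase via the Hilbert-transform analytic signal.

    The leading and trailing 5% of samples are flagged as edge-contaminated
    and excluded from PLV estimation.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size <= 16:
        raise ValueError("signal too short for phase estimation")
    if np.ptp(x) < 1e-30:
        raise ValueError("constant signal: instantaneous phase undefined")
    phi = np.angle(sps.hilbert(x))
    n_edge = int(np.ceil(_EDGE_FRACTION * x.size))
    mask = np.zeros(x.size, dtype=bool)
    mask[:n_edge] = mask[x.size - n_edge:] = True
    return PhaseSeries(phi, fs, tag, mask)


def plv(phi1, phi2) -> float:
    """Phase-locking value |N^-1 sum exp(i (phi1 - phi2))| in [0, 1].

    Accepts PhaseSeries (edge-flagged samples of either series are excluded)
    or plain phase arrays.
    """
    if isinstance(phi1, PhaseSeries) and isinstance(phi2, PhaseSeries):
        if phi1.phi.size != phi2.phi.size:
            raise ValueError("phase series lengths differ")
        keep = ~(phi1.edge_mask | phi2.edge_mask)
        d = phi1.phi[keep] - phi2.phi[keep]
    else:
        a = phi1.phi if isinstance(phi1, PhaseSeries) else np.asarray(phi1, float)
        b = phi2.phi if isinstance(phi2, PhaseSeries) else np.asarray(phi2, float)
        if a.size != b.size:
            raise ValueError("phase series lengths differ")
        d = a - b
    if d.size < 2:
        raise ValueError("need at least 2 phase samples")
    return float(np.abs(np.exp(1j * d).mean()))


def _batch_objective(W: np.ndarray, u: np.ndarray) -> np.ndarray:
    """PLV of each row-filter in W against the reference folded into u.

    u = analytic(Z) * exp(-i * ref_phase): the phase of W @ u is already the
    phase difference, so the PLV is |mean of the unit phasor| per row.
    """
    s = W @ u
    a = np.abs(s)
    bad = a < 1e-30
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(bad, 0.0, s / np.where(bad, 1.0, a))
    return np.abs(p.mean(axis=-1))


def plv_objective(w: np.ndarray, Z: np.ndarray, ref_phase) -> float:
    """PLV between the phase of w^T Z and the reference phase.

    Z may be the real narrowband EEG matrix or its precomputed analytic
    signal. The Hilbert transform is linear, so analytic(w^T Z) = w^T
    analytic(Z); a degenerate (near-constant) combination scores 0 with a
    warning.
    """
    w = np.asarray(w, dtype=float).ravel()
    Z = np.asarray(Z)
    ref = ref_phase.phi if isinstance(ref_phase, PhaseSeries) else np.asarray(ref_phase)
    Za = Z if np.iscomplexobj(Z) else sps.hilbert(Z, axis=-1)
    s = w @ Za
    if np.abs(s).max() < 1e-30:
        warnings.warn("degenerate combination: constant w^T Z, PLV set to 0",
                      RuntimeWarning)
        return 0.0
    return float(_batch_objective(w[None, :], Za * np.exp(-1j * ref)[None, :])[0])


def _normalize_rows(W: np.ndarray) -> np.ndarray:
    return W / np.linalg.norm(W, axis=-1, keepdims=True)


def _batch_ascent(W0: np.ndarray, u: np.ndarray, cfg: RPAConfig):
    """Adaptive-step gradient ascent on the unit sphere, batched over
    restarts. Accepted steps never decrease the objective (reject-and-halve);
    the step grows on acceptance."""
    W = _normalize_rows(np.array(W0, dtype=float))
    m, d = W.shape
    f = _batch_objective(W, u)
    step = np.full(m, cfg.step_init)
    active = np.ones(m, dtype=bool)
    eps = 1e-5
    eye = np.eye(d)
    traj = [f.copy()]
    for _ in range(cfg.max_iters):
        if not active.any():
            break
        Wa = W[active]
        ma = Wa.shape[0]
        # central-difference gradient on the sphere
        Wp = _normalize_rows(Wa[:, None, :] + eps * eye[None])
        Wm = _normalize_rows(Wa[:, None, :] - eps * eye[None])
        fp = _batch_objective(Wp.reshape(ma * d, d), u).reshape(ma, d)
        fm = _batch_objective(Wm.reshape(ma * d, d), u).reshape(ma, d)
        G = (fp - fm) / (2 * eps)
        if not np.isfinite(G).all():
            raise FloatingPointError("non-finite gradient in RPA ascent")
        # tangent-space projection
        G -= (G * Wa).sum(axis=1, keepdims=True) * Wa
        cand = _normalize_rows(Wa + step[active, None] * G)
        fc = _batch_objective(cand, u)
        fa = f[active]
        improved = fc >= fa
        idx = np.flatnonzero(active)
        acc = idx[improved]
        rej = idx[~improved]
        gain = fc[improved] - fa[improved]
        W[acc] = cand[improved]
        f[acc] = fc[improved]
        step[acc] *= cfg.step_up
        step[rej] *= cfg.step_down
        # converged: negligible accepted improvement or vanishing step
        done = np.zeros(m, dtype=bool)
        done[acc] = gain < cfg.plv_tol
        done[rej] = step[rej] < 1e-9
        active &= ~done
        traj.append(f.copy())
    return W, f, np.array(traj)


def gradient_ascent(Z: np.ndarray, ref_phase, w0: np.ndarray,
                    cfg: RPAConfig | None = None):
    """Maximize the PLV objective from a single unit start vector.

    Returns (w*, plv*, trajectory of accepted objective values).
    """
    cfg = cfg or RPAConfig()
    ref = ref_phase.phi if isinstance(ref_phase, PhaseSeries) else np.asarray(ref_phase)
    Za = Z if np.iscomplexobj(Z) else sps.hilbert(np.asarray(Z, float), axis=-1)
    u = Za * np.exp(-1j * ref)[None, :]
    W, f, traj = _batch_ascent(np.atleast_2d(w0), u, cfg)
    return W[0], float(f[0]), traj[:, 0]


@dataclass
class Candidate:
    """One restart's solution inside a window."""

    w: np.ndarray             # unit filter in whitened space
    topography: np.ndarray    # sensor-space mixing column
    plv: float                # optimized (in-sample) PLV
    source: np.ndarray        # w^T Z within the window (real part)
    window: int = -1


def rpa_window(Z_window: np.ndarray, ref_window, cfg: RPAConfig | None = None,
               desphering: np.ndarray | None = None,
               seed: int | None = None) -> list[Candidate]:
    """Run ``cfg.n_essays`` seeded random restarts in one window.

    Z_window may be real narrowband EEG (channels x samples) or its analytic
    signal; topographies are obtained through the de-sphering pseudo-inverse
    (identity if no whitening was applied).
    """
    cfg = cfg or RPAConfig()
    ref = ref_window.phi if isinstance(ref_window, PhaseSeries) else np.asarray(ref_window)
    Za = Z_window if np.iscomplexobj(Z_window) else sps.hilbert(
        np.asarray(Z_window, float), axis=-1)
    n_ch, n_s = Za.shape
    if n_s < 2 * 60:
        warnings.warn("window shorter than 2 s at 60 Hz: phase estimates "
                      "will be unstable", RuntimeWarning)
    u = Za * np.exp(-1j * ref)[None, :]
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    W0 = _normalize_rows(rng.standard_normal((cfg.n_essays, n_ch)))
    W, f, _ = _batch_ascent(W0, u, cfg)
    desph = np.eye(n_ch) if desphering is None else desphering
    out = []
    for k in range(cfg.n_essays):
        topo = desph @ W[k]
        src = np.real(W[k] @ Za)
        out.append(Candidate(W[k], topo, float(f[k]), src))
    return out


def _corr_matrix(vectors: np.ndarray) -> np.ndarray:
    V = vectors - vectors.mean(axis=1, keepdims=True)
    V /= (np.linalg.norm(V, axis=1, keepdims=True) + 1e-30)
    return np.abs(V @ V.T)


def group_intra(candidates: list[Candidate],
                threshold: float = 0.85) -> list[list[Candidate]]:
    """Cluster one window's candidates by |corr| of their source time courses
    (single linkage); each cluster is ordered with its highest-PLV member
    (the representative) first. Cluster order is deterministic and invariant
    to candidate input order."""
    if not candidates:
        raise ValueError("no candidates to group")
    S = np.array([c.source for c in candidates])
    sim = _corr_matrix(S)
    clusters = []
    for members in _single_linkage_clusters(sim, threshold):
        group = sorted((candidates[m] for m in members),
                       key=lambda c: -c.plv)
        clusters.append(group)
    clusters.sort(key=lambda g: (-len(g), -g[0].plv))
    return clusters


@dataclass
class SyncFamily:
    """A recurring synchronous source across windows.

    ``window_plvs`` are the consensus filter's per-window PLVs (the
    transiency profile); short narrowband windows carry a substantial
    finite-sample upward bias, so the family's headline ``plv`` pools the
    phase differences of all member windows into a single estimate, which is
    unbiased when the coupling spans the windows.
    """

    topography: np.ndarray        # consensus sensor-space pattern
    filter_w: np.ndarray          # consensus unit filter (whitened space)
    member_windows: list[int]
    window_plvs: np.ndarray       # fixed-filter PLV per member window
    candidate_plvs: np.ndarray    # optimized PLV of each member representative
    plv: float = 0.0              # pooled fixed-filter PLV over member windows
    permutation_p: float | None = None
    null_95: float | None = None

    @property
    def occurrence(self) -> int:
        return len(set(self.member_windows))

    @property
    def mean_plv(self) -> float:
        """The family's PLV (pooled over member windows)."""
        return float(self.plv)

    @property
    def mean_window_plv(self) -> float:
        """Raw mean of the per-window PLVs (bias-prone on short windows)."""
        return float(np.mean(self.window_plvs))


def _consensus(vectors: list[np.ndarray],
               weights: list[float] | None = None) -> np.ndarray:
    """Sign-aligned (optionally weighted) mean of unit vectors.

    The member with the largest weight fixes the sign; weighting by each
    member's optimized PLV lets well-locked windows dominate the family's
    filter.
    """
    if weights is None:
        weights = [1.0] * len(vectors)
    ref = vectors[int(np.argmax(weights))]
    acc = np.zeros_like(ref)
    for v, wt in zip(vectors, weights):
        acc += wt * (v if np.dot(v, ref) >= 0 else -v)
    n = np.linalg.norm(acc)
    return acc / n if n > 0 else ref


def group_inter(per_window_clusters: list[list[list[Candidate]]],
                threshold: float = 0.70,
                window_eval=None) -> list[SyncFamily]:
    """Group window representatives into families by topography correlation.

    per_window_clusters : for each window, the intra-window clusters (their
        first element being the representative candidate).
    window_eval : optional callable (w, window_index) -> complex mean phasor
        of the consensus filter's phase difference in that window; its modulus
        is the window PLV and the family PLV pools the phasors over member
        windows. When omitted the representatives' optimized PLVs are
        reported instead.

    Families are sorted by occurrence, then PLV, descending; singleton
    (one-window) families rank below recurring ones by construction.
    """
    reps: list[Candidate] = []
    for wi, clusters in enumerate(per_window_clusters):
        for group in clusters:
            rep = group[0]
            rep.window = wi
            reps.append(rep)
    if not reps:
        raise ValueError("no window clusters to group")
    T = np.array([r.topography for r in reps])
    sim = _corr_matrix(T)
    families = []
    for members in _single_linkage_clusters(sim, threshold):
        mem = [reps[m] for m in members]
        wts = [m.plv for m in mem]
        w_fam = _consensus([m.w for m in mem], wts)
        topo = _consensus([m.topography / (np.linalg.norm(m.topography) + 1e-30)
                           for m in mem], wts)
        wins = sorted({m.window for m in mem})
        if window_eval is not None:
            phasors = np.array([window_eval(w_fam, w) for w in wins])
            pw = np.abs(phasors)
            pooled = float(np.abs(phasors.mean()))
        else:
            pw = np.array([m.plv for m in mem])
            pooled = float(np.mean(pw))
        families.append(SyncFamily(
            topography=topo, filter_w=w_fam, member_windows=wins,
            window_plvs=pw, candidate_plvs=np.array([m.plv for m in mem]),
            plv=pooled,
        ))
    families.sort(key=lambda f: (-f.occurrence, -f.plv))
    return families


@dataclass
class RPAReport:
    """Full RPA result: families, the best family, and window bookkeeping."""

    families: list[SyncFamily]
    window_starts_s: np.ndarray
    center_hz: float
    labels: list[str]
    config: RPAConfig

    @property
    def best(self) -> SyncFamily:
        return self.families[0]

    def to_json_dict(self) -> dict:
        return {
            "center_hz": self.center_hz,
            "labels": self.labels,
            "window_starts_s": [float(v) for v in self.window_starts_s],
            "families": [
                {
                    "topography": [float(v) for v in f.topography],
                    "member_windows": list(f.member_windows),
                    "occurrence": f.occurrence,
                    "window_plvs": [float(v) for v in f.window_plvs],
                    "plv": f.plv,
                    "mean_window_plv": f.mean_window_plv,
                    "permutation_p": f.permutation_p,
                    "null_95": f.null_95,
                }
                for f in self.families
            ],
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_dict(), indent=1, sort_keys=True)
        )


class ReferencePhaseAnalysis(BaseEstimator):
    """Sliding-window RPA with an sklearn estimator surface.

    fit(eeg, emg) narrowband-filters both inputs around ``center_hz``,
    whitens the EEG once for the session, maximizes windowed PLV with
    multi-restart ascent, groups candidates within and across windows, and
    exposes ``families_`` / ``report_``. All randomness derives from
    ``config.seed``.
    """

    def __init__(self, center_hz: float = 20.0,
                 config: RPAConfig | None = None,
                 window_range_s: tuple[float, float] | None = None,
                 compute_null: bool = False):
        self.center_hz = center_hz
        self.config = config
        self.window_range_s = window_range_s
        self.compute_null = compute_null

    def fit(self, eeg: Recording, emg: np.ndarray | Recording):
        cfg = self.config or RPAConfig()
        if isinstance(emg, Recording):
            emg_sig = emg.data[0] if emg.n_channels == 1 else \
                emg.pick("EMG").data[0]
        else:
            emg_sig = np.asarray(emg, dtype=float).ravel()
        if eeg.n_samples != emg_sig.size:
            raise ValueError("EEG and EMG must have equal durations")

        nb = narrowband(eeg, self.center_hz, cfg)
        emg_rec = Recording(emg_sig[None, :], eeg.fs, ["EMGref"], ["EMG"])
        emg_nb = narrowband(emg_rec, self.center_hz, cfg).data[0]

        wh = whiten(nb.data, var_keep=cfg.var_keep)
        Za = sps.hilbert(wh.data, axis=-1)
        ref = analytic_phase(emg_nb, eeg.fs, tag="EMG")

        fs = eeg.fs
        win = int(round(cfg.window_s * fs))
        hop = max(1, int(round(win * (1 - cfg.window_overlap))))
        lo, hi = 0, eeg.n_samples
        if self.window_range_s is not None:
            lo = int(round(self.window_range_s[0] * fs))
            hi = int(round(self.window_range_s[1] * fs))
        starts = np.arange(lo, hi - win + 1, hop)
        if starts.size == 0:
            raise ValueError("no analysis windows fit in the requested range")

        rng = np.random.default_rng(cfg.seed)
        per_window = []
        for s0 in starts:
            sl = slice(s0, s0 + win)
            cands = rpa_window(Za[:, sl], ref.phi[sl], cfg,
                               desphering=wh.desphering,
                               seed=int(rng.integers(2 ** 31)))
            per_window.append(group_intra(cands, cfg.intra_threshold))

        def window_eval(w, wi, phase_ref=None):
            """Mean unit phasor of the filter-vs-reference phase difference."""
            sl = slice(starts[wi], starts[wi] + win)
            r = ref.phi[sl] if phase_ref is None else phase_ref[sl]
            s = (w @ Za[:, sl]) * np.exp(-1j * r)
            a = np.abs(s)
            p = np.where(a < 1e-30, 0.0, s / np.where(a < 1e-30, 1.0, a))
            return complex(p.mean())

        families = group_inter(per_window, cfg.inter_threshold,
                               window_eval=window_eval)
        if self.compute_null and families:
            self._attach_null(families[0], window_eval, ref.phi, win, fs, cfg)
        self.whitened_ = wh
        self.families_ = families
        self.report_ = RPAReport(families, starts / fs, self.center_hz,
                                 list(eeg.labels), cfg)
        return self

    def _attach_null(self, fam: SyncFamily, window_eval, ref_phi,
                     win: int, fs: float, cfg: RPAConfig) -> None:
        """Circular-shift permutation null for the best family's pooled PLV."""
        rng = np.random.default_rng(cfg.seed + 101)
        n = ref_phi.size
        min_shift = int(fs)  # at least 1 s to break alignment
        null = np.empty(cfg.n_permutations)
        for p in range(cfg.n_permutations):
            shift = int(rng.integers(min_shift, n - min_shift))
            rolled = np.roll(ref_phi, shift)
            phasors = [window_eval(fam.filter_w, wi, phase_ref=rolled)
                       for wi in fam.member_windows]
            null[p] = np.abs(np.mean(phasors))
        obs = fam.plv
        fam.permutation_p = float((1 + np.sum(null >= obs)) /
                                  (1 + cfg.n_permutations))
        fam.null_95 = float(np.quantile(null, 0.95))


def run_rpa(eeg: Recording, emg, chosen_band: tuple[float, float] | float,
            chosen_window: tuple[float, float] | None = None,
            cfg: RPAConfig | None = None,
            compute_null: bool = False) -> RPAReport:
    """End-to-end RPA on preprocessed (60 Hz) inputs.

    chosen_band : (lo, hi) in Hz or a center frequency, typically from the
        TDSEP coherence stage.
    chosen_window : optional (start_s, stop_s) restriction of the analysis.
    """
    if np.iterable(chosen_band):
        lo, hi = chosen_band
        center = 0.5 * (lo + hi)
    else:
        center = float(chosen_band)
    est = ReferencePhaseAnalysis(center_hz=center, config=cfg,
                                 window_range_s=chosen_window,
                                 compute_null=compute_null)
    est.fit(eeg, emg)
    return est.report_
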