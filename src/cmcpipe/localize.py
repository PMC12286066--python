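"""Equivalent current dipole fitting in a three-shell spherical head model.

The forward model is the classical analytic series for a current dipole
inside concentric conducting spheres (brain, skull, scalp). For each spherical
harmonic order n the radial coefficients in every shell are obtained from the
boundary conditions (continuity of potential and of radial current at each
interface, zero current through the scalp surface), and the scalp potential is
the truncated series over Legendre terms evaluated at the electrode angles.
Fitting inverts this: a coarse grid search over positions inside the brain
shell (the moment is solved linearly at each position) followed by a local
simplex refinement. Scalp maps are compared in average reference, so the fit
is reference-free; goodness of fit is the explained fraction of topography
power. The anatomical output is deliberately coarse — hemisphere x lobe — as
appropriate for a spherical geometry without individual anatomy.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import optimize
from scipy.special import eval_legendre, lpmv
from sklearn.base import BaseEstimator

from .recording import Montage, Topography

__all__ = [
    "HeadModel",
    "DipoleFit",
    "leadfield",
    "DipoleFitter",
    "fit_dipole",
    "region_label",
]


@dataclass
class HeadModel:
    """Three-shell concentric sphere head model."""

    radii: tuple[float, float, float] = (0.087, 0.092, 0.100)   # m, brain/skull/scalp
    conductivities: tuple[float, float, float] = (0.33, 0.0042, 0.33)  # S/m
    n_terms: int = 60

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.radii, self.radii[1:])):
            raise ValueError("shell radii must be strictly increasing")
        if any(s <= 0 for s in self.conductivities):
            raise ValueError("conductivities must be positive")

    @property
    def brain_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    def transfer_coefficients(self) -> np.ndarray:
        """Per-order scalp transfer factors F_n.

        For a unit source coefficient (the r^-(n+1) term of the dipole's
        free-medium expansion, radii in scalp units) F_n is the resulting
        potential coefficient on the scalp surface. Solved per order from the
        interface boundary conditions; reduces to (2n+1)/n for a homogeneous
        sphere.
        """
        M = len(self.radii)
        rho = np.asarray(self.radii) / self.scalp_radius
        sig = np.asarray(self.conductivities)
        F = np.zeros(self.n_terms + 1)
        for n in range(1, self.n_terms + 1):
            # unknowns: A_1, (A_j, B_j) for j = 2..M   -> 2M-1
            nun = 2 * M - 1
            A = np.zeros((nun, nun))
            b = np.zeros(nun)

            def idx_A(j):  # layer j (1-based)
                return 0 if j == 1 else 1 + 2 * (j - 2)

            def idx_B(j):
                return 2 + 2 * (j - 2)

            row = 0
            for j in range(1, M):
                r = rho[j - 1]
                # potential continuity: V_j(r) = V_{j+1}(r)
                A[row, idx_A(j)] += r ** n
                if j > 1:
                    A[row, idx_B(j)] += r ** -(n + 1)
                A[row, idx_A(j + 1)] -= r ** n
                A[row, idx_B(j + 1)] -= r ** -(n + 1)
                if j == 1:
                    b[row] = -(r ** -(n + 1))   # source term lives in layer 1
                row += 1
                # radial current continuity: sig_j V_j' = sig_{j+1} V_{j+1}'
                dr_pos = n * r ** (n - 1)
                dr_neg = -(n + 1) * r ** -(n + 2)
                A[row, idx_A(j)] += sig[j - 1] * dr_pos
                if j > 1:
                    A[row, idx_B(j)] += sig[j - 1] * dr_neg
                A[row, idx_A(j + 1)] -= sig[j] * dr_pos
                A[row, idx_B(j + 1)] -= sig[j] * dr_neg
                if j == 1:
                    b[row] = -sig[0] * dr_neg
                row += 1
            # outer surface: no radial current at rho = 1
            A[row, idx_A(M)] = sig[M - 1] * n
            A[row, idx_B(M)] = -sig[M - 1] * (n + 1)
            sol = np.linalg.solve(A, b)
            F[n] = sol[idx_A(M)] + sol[idx_B(M)]   # at rho = 1
        return F


def _orthonormal_frame(ez: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, ez)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    ex = ref - np.dot(ref, ez) * ez
    ex /= np.linalg.norm(ex)
    return ex, np.cross(ez, ex)


def _lead_basis(position: np.ndarray, elec: np.ndarray, model: HeadModel,
                F: np.ndarray) -> np.ndarray:
    """(n_elec, 3) matrix L with V = L @ moment (head frame, average ref).

    One pass over the harmonic series serves all three moment directions:
    the angular terms are shared and the moment enters linearly through its
    radial/tangential components in the dipole frame.
    """
    position = np.asarray(position, dtype=float)
    b = np.linalg.norm(position)
    if b >= model.brain_radius:
        raise ValueError(
            f"dipole at |r|={b:.4f} m is not inside the brain shell "
            f"({model.brain_radius} m)"
        )
    R = model.scalp_radius
    if b < 1e-12:
        ez = np.array([0.0, 0.0, 1.0])
    else:
        ez = position / b
    ex, ey = _orthonormal_frame(ez)
    cos_t = np.clip(elec @ ez, -1.0, 1.0)
    az = np.arctan2(elec @ ey, elec @ ex)
    cos_az, sin_az = np.cos(az), np.sin(az)

    bs = b / R
    ns = np.arange(1, model.n_terms + 1)
    radial = bs ** (ns - 1) * F[1:]
    a_r = np.zeros(len(elec))   # multiplies q . ez
    a_t = np.zeros(len(elec))   # multiplies the tangential projections
    for i, n in enumerate(ns):
        a_r += radial[i] * n * eval_legendre(n, cos_t)
        a_t -= radial[i] * lpmv(1, n, cos_t)
    scale = 4.0 * np.pi * model.conductivities[0] * R ** 2
    L = (np.outer(a_r, ez) + np.outer(a_t * cos_az, ex)
         + np.outer(a_t * sin_az, ey)) / scale
    return L - L.mean(axis=0, keepdims=True)


def leadfield(position: np.ndarray, moment: np.ndarray, montage: Montage,
              model: HeadModel | None = None,
              _F: np.ndarray | None = None) -> Topography:
    """Scalp potential (average-referenced) of a dipole at ``position`` (m)
    with moment ``moment`` (A*m), at the montage's electrodes.

    Linear in the moment; raises if the position is not strictly inside the
    brain shell.
    """
    model = model or HeadModel()
    moment = np.asarray(moment, dtype=float)
    F = model.transfer_coefficients() if _F is None else _F
    labels = montage.eeg_labels
    elec = np.array([montage.positions[l] for l in labels])  # unit vectors
    L = _lead_basis(position, elec, model, F)
    return Topography(L @ moment, labels)


def region_label(position: np.ndarray, handedness_context: str | None = None):
    """Coarse anatomical label: {left|right|midline} x lobe, plus a
    contralaterality flag given the moving hand.

    Sectors are defined on the unit direction of the position (x right,
    y anterior, z superior): inferior-lateral -> temporal, anterior ->
    frontal, far posterior -> occipital, posterior-superior -> parietal,
    else central.
    """
    p = np.asarray(position, dtype=float)
    r = np.linalg.norm(p)
    d = p / r if r > 1e-12 else np.array([0.0, 0.0, 1.0])
    x, y, z = d
    if abs(x) < 1e-9:
        hemi = "midline"
    else:
        hemi = "left" if x < 0 else "right"
    if z < 0.25 and abs(x) > 0.5:
        lobe = "temporal"
    elif y > 0.35:
        lobe = "frontal"
    elif y < -0.6:
        lobe = "occipital"
    elif y < -0.15:
        lobe = "parietal"
    else:
        lobe = "central"
    label = f"{hemi} {lobe}" if hemi != "midline" else "midline"
    contralateral = False
    if handedness_context is not None and hemi != "midline":
        hand = handedness_context.lower()
        contralateral = (hand.startswith("right") and hemi == "left") or \
                        (hand.startswith("left") and hemi == "right")
    return label, contralateral


@dataclass
class DipoleFit:
    """Equivalent current dipole: position, moment, fit quality, region."""

    position: np.ndarray      # m, head frame
    moment: np.ndarray        # A*m (scale follows the topography's units)
    gof: float                # explained topography power, in [0, 1]
    region: str = ""
    contralateral: bool = False

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "position_m": [float(v) for v in self.position],
            "moment": [float(v) for v in self.moment],
            "gof": float(self.gof),
            "region": self.region,
            "contralateral": bool(self.contralateral),
        }, indent=1))


_GRID_CACHE: dict = {}


class DipoleFitter(BaseEstimator):
    """Single-dipole fit: coarse grid search plus simplex refinement.

    The grid (default 1 cm spacing, strictly inside the brain shell) caches
    an orthonormal basis of each point's three-column leadfield, so scanning
    a topography is a single tensor contraction; the best grid point seeds a
    Nelder-Mead refinement (with a small seeded jitter) in which the moment
    is re-solved linearly at every position.
    """

    def __init__(self, montage: Montage, model: HeadModel | None = None,
                 grid_spacing: float = 0.01, margin: float = 0.004,
                 seed: int = 0):
        self.montage = montage
        self.model = model or HeadModel()
        self.grid_spacing = grid_spacing
        self.margin = margin
        self.seed = seed

    def _ensure_grid(self) -> None:
        if hasattr(self, "_grid"):
            return
        self._F = self.model.transfer_coefficients()
        key = (self.model.radii, self.model.conductivities,
               self.model.n_terms, self.grid_spacing, self.margin,
               tuple(self.montage.eeg_labels))
        cached = _GRID_CACHE.get(key)
        if cached is not None:
            self._grid, self._grid_basis = cached
            return
        rmax = self.model.brain_radius - self.margin
        g = np.arange(-rmax, rmax + 1e-12, self.grid_spacing)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        pts = np.c_[X.ravel(), Y.ravel(), Z.ravel()]
        pts = pts[np.linalg.norm(pts, axis=1) < rmax]
        basis = np.empty((len(pts), len(self.montage.eeg_labels), 3))
        for i, p in enumerate(pts):
            L = self._lead_matrix(p)
            Q, _ = np.linalg.qr(L)
            basis[i] = Q
        self._grid = pts
        self._grid_basis = basis
        _GRID_CACHE[key] = (pts, basis)

    def _lead_matrix(self, position: np.ndarray) -> np.ndarray:
        if not hasattr(self, "_elec"):
            self._elec = np.array([self.montage.positions[l]
                                   for l in self.montage.eeg_labels])
        return _lead_basis(position, self._elec, self.model, self._F)

    def fit(self, topography: Topography | np.ndarray):
        v = topography.values if isinstance(topography, Topography) else \
            np.asarray(topography, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError("topography contains non-finite values")
        v = v - v.mean()
        norm2 = float(v @ v)
        if norm2 < 1e-30:
            raise ValueError("all-zero topography cannot be fit")
        self._ensure_grid()
        proj = np.einsum("pej,e->pj", self._grid_basis, v)
        explained = (proj ** 2).sum(axis=1)
        best = int(np.argmax(explained))
        rng = np.random.default_rng(self.seed)
        x0 = self._grid[best] + rng.normal(0, 1e-4, 3)
        rmax = self.model.brain_radius - self.margin

        def cost(p):
            r = np.linalg.norm(p)
            if r >= rmax:
                p = p * (rmax - 1e-6) / r
            L = self._lead_matrix(p)
            m, *_ = np.linalg.lstsq(L, v, rcond=None)
            resid = v - L @ m
            return float(resid @ resid) / norm2

        res = optimize.minimize(cost, x0, method="Nelder-Mead",
                                options=dict(xatol=1e-5, fatol=1e-12,
                                             maxiter=400))
        p = res.x
        r = np.linalg.norm(p)
        if r >= rmax:
            p = p * (rmax - 1e-6) / r
        L = self._lead_matrix(p)
        m, *_ = np.linalg.lstsq(L, v, rcond=None)
        gof = 1.0 - float((v - L @ m) @ (v - L @ m)) / norm2
        self.position_ = p
        self.moment_ = m
        self.gof_ = float(np.clip(gof, 0.0, 1.0))
        return self

    def to_fit(self, handedness_context: str | None = None) -> DipoleFit:
        region, contra = region_label(self.position_, handedness_context)
        return DipoleFit(self.position_, self.moment_, self.gof_, region,
                         contra)


def fit_dipole(topography: Topography | np.ndarray, montage: Montage,
               model: HeadModel | None = None, seed: int = 0,
               handedness_context: str | None = None) -> DipoleFit:
    """Functional wrapper over :class:`DipoleFitter`."""
    fitter = DipoleFitter(montage, model, seed=seed)
    fitter.fit(topography)
    return fitter.to_fit(handedness_context)
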