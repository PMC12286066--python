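"""Whitening, joint diagonalization, TDSEP recovery, essays, coherence."""

import itertools

import numpy as np
import pytest
from scipy.signal import butter, sosfilt

from cmcpipe.tdsep import (TDSEP, coherence_map, essay_group, joint_diag,
                           lagged_cov, tdsep, whiten)


def _narrowband(n, rng, band=(19, 21), fs=60.0):
    sos = butter(4, band, "bandpass", fs=fs, output="sos")
    x = sosfilt(sos, rng.standard_normal(n + 600))[600:]
    return x / x.std()


def _ar1(n, rng, rho=0.95):
    x = np.empty(n)
    x[0] = rng.standard_normal()
    e = rng.standard_normal(n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + e[i]
    return x / x.std()


def _planted_mixture(rng, n=6000):
    S = np.vstack([_narrowband(n, rng), _ar1(n, rng)])
    A = np.array([[1.0, 0.6], [-0.4, 1.0]])
    return A, S, A @ S


class TestWhiten:
    def test_identity_covariance(self, rng):
        X = rng.standard_normal((4, 4)) @ rng.standard_normal((4, 20_000))
        wh = whiten(X)
        C = np.cov(wh.data, bias=True)
        np.testing.assert_allclose(C, np.eye(4), atol=1e-6)

    def test_desphering_inverts_sphering(self, rng):
        X = rng.standard_normal((3, 3)) @ rng.standard_normal((3, 10_000))
        wh = whiten(X)
        back = wh.desphering @ wh.data + wh.mean[:, None]
        np.testing.assert_allclose(back, X, atol=1e-8 * np.abs(X).max())

    def test_already_white_data(self, rng):
        X = rng.standard_normal((3, 200_000))
        wh = whiten(X)
        # sphering of white data is orthogonal up to sampling noise
        M = wh.sphering @ wh.sphering.T
        np.testing.assert_allclose(M, np.eye(3), atol=0.05)

    def test_zero_variance_channel_named(self, rng):
        X = rng.standard_normal((3, 1000))
        X[1] = 5.0
        with pytest.raises(ValueError, match=r"\[1\]"):
            whiten(X)

    def test_rank_deficiency_reduces_dimension(self, rng):
        base = rng.standard_normal((2, 5000))
        X = np.vstack([base, base.sum(axis=0, keepdims=True) + 1e-14])
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            wh = whiten(X)
        assert wh.data.shape[0] == 2


class TestLaggedCov:
    def test_lag_zero_on_whitened_is_identity(self, rng):
        wh = whiten(rng.standard_normal((3, 50_000)))
        C = lagged_cov(wh.data, 0)
        np.testing.assert_allclose(C, np.eye(3), atol=1e-6)

    def test_white_noise_lagged_entries_scale(self, rng):
        n = 40_000
        Z = rng.standard_normal((3, n))
        C = lagged_cov(Z, 5)
        # entries are O(1/sqrt(N)): bound at 5 sigma
        assert np.abs(C).max() < 5.0 / np.sqrt(n)

    def test_ar1_diagonal_matches_autocovariance(self, rng):
        rho, lag = 0.9, 4
        x = _ar1(200_000, rng, rho)
        C = lagged_cov(x[None, :], lag)
        assert C[0, 0] == pytest.approx(rho ** lag, abs=0.02)

    def test_lag_exceeding_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            lagged_cov(rng.standard_normal((2, 10)), 10)


def _off_criterion(mats, V):
    tot = 0.0
    for M in mats:
        R = V.T @ M @ V
        tot += (R ** 2).sum() - (np.diag(R) ** 2).sum()
    return tot


class TestJointDiag:
    def test_single_matrix_is_eigendecomposition(self, rng):
        A = rng.standard_normal((4, 4))
        M = A + A.T
        V, hist = joint_diag([M])
        assert _off_criterion([M], V) < 1e-10

    def test_commuting_pair_diagonalized_exactly(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((4, 4)))
        M1 = Q @ np.diag([1.0, 2, 3, 4]) @ Q.T
        M2 = Q @ np.diag([4.0, 1, 9, 2]) @ Q.T
        V, _ = joint_diag([M1, M2])
        assert _off_criterion([M1, M2], V) < 1e-10

    def test_criterion_monotone_across_sweeps(self, rng):
        mats = []
        for _ in range(4):
            A = rng.standard_normal((5, 5))
            mats.append(A + A.T)
        _, hist = joint_diag(mats)
        diffs = np.diff(hist)
        assert np.all(diffs <= 1e-10 * max(1.0, hist[0]))

    def test_nonsymmetric_rejected(self, rng):
        with pytest.raises(ValueError, match="symmetric"):
            joint_diag([rng.standard_normal((3, 3))])

    def test_beats_grid_search_oracle_on_3x3(self, rng):
        """Jacobi result is at least as good as a dense rotation grid search."""
        mats = []
        for _ in range(3):
            A = rng.standard_normal((3, 3))
            mats.append(A + A.T + 2 * np.diag(rng.standard_normal(3)))
        V, _ = joint_diag(mats)
        ours = _off_criterion(mats, V)

        # oracle: exhaustive search over ZYZ Euler-angle rotations
        grid = np.linspace(0, np.pi, 60, endpoint=False)
        best = np.inf
        c, s = np.cos(grid), np.sin(grid)
        for i, a in enumerate(grid):
            Ra = np.array([[c[i], -s[i], 0], [s[i], c[i], 0], [0, 0, 1]])
            for j, b in enumerate(grid):
                Rb = np.array([[c[j], 0, s[j]], [0, 1, 0], [-s[j], 0, c[j]]])
                Rab = Ra @ Rb
                for k in range(len(grid)):
                    Rc = np.array([[c[k], -s[k], 0], [s[k], c[k], 0],
                                   [0, 0, 1]])
                    val = _off_criterion(mats, Rab @ Rc)
                    if val < best:
                        best = val
        assert ours <= best + 1e-9


class TestTDSEP:
    def test_recovers_planted_two_source_mixture(self, rng):
        A, S, X = _planted_mixture(rng)
        ss = tdsep(X)
        corr = np.abs(np.corrcoef(np.vstack([ss.sources, S]))[:2, 2:])
        assert corr.max(axis=0).min() > 0.99
        # mixing column of the narrowband source matches its planted column
        k = int(np.argmax(corr[:, 0]))
        col_corr = np.corrcoef(ss.mixing[:, k], A[:, 0])[0, 1]
        assert abs(col_corr) > 0.99

    def test_identity_mixing_recovered_up_to_perm_sign(self, rng):
        S = np.vstack([_narrowband(5000, rng), _ar1(5000, rng)])
        ss = tdsep(S.copy())
        corr = np.abs(np.corrcoef(np.vstack([ss.sources, S]))[:2, 2:])
        assert corr.max(axis=0).min() > 0.99

    def test_equivariance_under_invertible_mixing(self, rng):
        _, S, X = _planted_mixture(rng)
        B = np.array([[2.0, -1.0], [0.5, 1.5]])
        s1 = tdsep(X).sources
        s2 = tdsep(B @ X).sources
        corr = np.abs(np.corrcoef(np.vstack([s1, s2]))[:2, 2:])
        assert corr.max(axis=0).min() > 0.99

    def test_estimator_transform_matches_sources(self, rng):
        _, _, X = _planted_mixture(rng)
        est = TDSEP().fit(X)
        np.testing.assert_allclose(est.transform(X), est.sources_, atol=1e-10)


class TestEssayGroup:
    def test_identical_essays_full_occurrence(self, rng):
        _, _, X = _planted_mixture(rng)
        ss = tdsep(X)
        grouped = essay_group([ss] * 20)
        assert np.all(grouped.occurrence == 20)
        assert grouped.sources.shape[0] == 2

    def test_uncorrelated_extra_source_is_singleton(self, rng):
        _, _, X = _planted_mixture(rng)
        ss = tdsep(X)
        extra = type(ss)(
            demixing=np.vstack([ss.demixing, rng.standard_normal(2)]),
            mixing=np.column_stack([ss.mixing, rng.standard_normal(2)]),
            sources=np.vstack([ss.sources, rng.standard_normal(ss.sources.shape[1])]),
        )
        grouped = essay_group([ss, ss, extra])
        occ = sorted(grouped.occurrence)
        assert occ[0] == 1      # the noise singleton
        assert occ[-1] == 3

    def test_planted_source_has_max_occurrence_across_lag_subsets(self, rng):
        _, S, X = _planted_mixture(rng)
        essays = []
        for _ in range(20):
            lags = tuple(sorted(rng.choice(np.arange(1, 31), 10,
                                           replace=False).tolist()))
            essays.append(tdsep(X, lags=lags))
        grouped = essay_group(essays)
        corr = np.abs(np.corrcoef(np.vstack([grouped.sources[:1], S]))[0, 1:])
        assert grouped.occurrence[0] == max(grouped.occurrence)
        assert corr.max() > 0.99


class TestCoherence:
    def test_self_coherence_is_one(self, rng):
        x = _narrowband(6000, rng)
        cm = coherence_map(x, x, 60.0)
        assert np.all(cm.values > 0.999)

    def test_independent_noise_coherence_low(self, rng):
        x = rng.standard_normal(6000)
        y = rng.standard_normal(6000)
        cm = coherence_map(x, y, 60.0)
        assert np.median(cm.values) < 0.2

    def test_planted_coupling_selects_20hz_band(self, rng):
        n = 6000
        shared = _narrowband(n, rng)
        src = np.vstack([shared + 0.3 * rng.standard_normal(n),
                         rng.standard_normal(n)])
        emg = shared + 0.3 * rng.standard_normal(n)
        cm = coherence_map(src, emg, 60.0)
        assert cm.chosen_source == 0
        assert abs(cm.chosen_center - 20.0) <= 1.0

    def test_window_longer_than_signal_rejected(self, rng):
        with pytest.raises(ValueError, match="window"):
            coherence_map(rng.standard_normal(100), rng.standard_normal(100),
                          60.0, window_s=10.0)

    def test_values_clamped_to_unit_interval(self, rng):
        cm = coherence_map(rng.standard_normal(3000),
                           rng.standard_normal(3000), 60.0)
        assert cm.values.min() >= 0.0
        assert cm.values.max() <= 1.0
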