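"""Illumination estimation, gradient weights and the refinement solver,
checked against brute-force / dense linear-algebra oracles."""

import numpy as np
import pytest

from lumifuse.illumination import (
    GradientWeights,
    SolverParams,
    gradient_weights,
    gradients,
    initial_illumination,
    refine_illumination,
)
from lumifuse.imgio import EPS_T


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def _forward_diffs(t):
    h, w = t.shape
    dh = np.zeros_like(t)
    dv = np.zeros_like(t)
    for i in range(h):
        for j in range(w - 1):
            dh[i, j] = t[i, j + 1] - t[i, j]
    for i in range(h - 1):
        for j in range(w):
            dv[i, j] = t[i + 1, j] - t[i, j]
    return dh, dv


def weights_oracle(t_hat, p):
    """Direct double-loop windowed sums: Gaussian weights over the window
    clipped to the image, renormalized per pixel."""
    h, w = t_hat.shape
    dh, dv = _forward_diffs(t_hat)
    wh = np.empty_like(t_hat)
    wv = np.empty_like(t_hat)
    r = p.window_radius
    for i in range(h):
        for j in range(w):
            gs, sh, sv = 0.0, 0.0, 0.0
            for yi in range(max(0, i - r), min(h, i + r + 1)):
                for yj in range(max(0, j - r), min(w, j + r + 1)):
                    g = np.exp(-((yi - i) ** 2 + (yj - j) ** 2) / (2 * p.sigma**2))
                    gs += g
                    sh += g * dh[yi, yj]
                    sv += g * dv[yi, yj]
            wh[i, j] = 1.0 / (abs(sh / gs) + p.epsilon)
            wv[i, j] = 1.0 / (abs(sv / gs) + p.epsilon)
    return wh, wv


def _dense_diff_ops(h, w):
    n = h * w
    Dh = np.zeros((n, n))
    Dv = np.zeros((n, n))
    for j in range(w):
        for i in range(h):
            idx = i + j * h  # column-major vectorization
            if j < w - 1:
                Dh[idx, idx] = -1.0
                Dh[idx, idx + h] = 1.0
            if i < h - 1:
                Dv[idx, idx] = -1.0
                Dv[idx, idx + 1] = 1.0
    return Dh, Dv


def dense_refine_oracle(t_hat, w, p):
    """Dense direct solve of (I + alpha sum_d Dd' Diag(w~_d) Dd) t = t-hat."""
    h, wid = t_hat.shape
    dh, dv = _forward_diffs(t_hat)
    wt_h = (w.w_h / (np.abs(dh) + p.epsilon)).ravel(order="F")
    wt_v = (w.w_v / (np.abs(dv) + p.epsilon)).ravel(order="F")
    Dh, Dv = _dense_diff_ops(h, wid)
    A = np.eye(h * wid) + p.alpha * (Dh.T @ np.diag(wt_h) @ Dh + Dv.T @ np.diag(wt_v) @ Dv)
    t = np.linalg.solve(A, t_hat.ravel(order="F"))
    return A, np.clip(t.reshape(t_hat.shape, order="F"), EPS_T, 1.0)


def objective(t, t_hat, w, p):
    """The relaxed refinement energy (fixed weights from t-hat)."""
    dh0, dv0 = _forward_diffs(t_hat)
    dh, dv = _forward_diffs(t)
    smooth = (w.w_h * dh**2 / (np.abs(dh0) + p.epsilon)).sum()
    smooth += (w.w_v * dv**2 / (np.abs(dv0) + p.epsilon)).sum()
    return ((t_hat - t) ** 2).sum() + p.alpha * smooth


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestInitialIllumination:
    def test_channel_max(self):
        img = np.tile(np.array([0.2, 0.5, 0.3]), (4, 4, 1))
        np.testing.assert_allclose(initial_illumination(img), 0.5)

    def test_gray_identity_and_floor(self):
        np.testing.assert_allclose(initial_illumination(np.full((4, 4, 3), 0.6)), 0.6)
        assert initial_illumination(np.zeros((4, 4, 3))).min() == EPS_T

    def test_matches_loop_oracle(self, random_image):
        t = initial_illumination(random_image)
        for i in range(16):
            for j in range(16):
                assert t[i, j] == max(random_image[i, j].max(), EPS_T)


class TestGradients:
    def test_constant_map_zero(self):
        dh, dv = gradients(np.full((5, 5), 0.3))
        assert not dh.any() and not dv.any()

    def test_horizontal_ramp(self):
        t = np.tile(np.arange(6) * 0.1, (4, 1))
        dh, dv = gradients(t)
        np.testing.assert_allclose(dh[:, :-1], 0.1)
        np.testing.assert_allclose(dh[:, -1], 0.0)
        np.testing.assert_allclose(dv, 0.0)

    def test_matches_difference_oracle(self, rng):
        t = rng.uniform(0, 1, size=(4, 4))
        dh, dv = gradients(t)
        oh, ov = _forward_diffs(t)
        np.testing.assert_array_equal(dh, oh)
        np.testing.assert_array_equal(dv, ov)


class TestGradientWeights:
    def test_constant_map_gives_inverse_epsilon(self):
        p = SolverParams()
        gw = gradient_weights(np.full((8, 8), 0.5), p)
        np.testing.assert_allclose(gw.w_h, 1.0 / p.epsilon, rtol=1e-12)
        np.testing.assert_allclose(gw.w_v, 1.0 / p.epsilon, rtol=1e-12)

    def test_edge_suppresses_crossing_weight(self):
        # strong vertical edge: horizontal weight drops at the edge column
        t = np.full((8, 8), 0.2)
        t[:, 4:] = 0.9
        gw = gradient_weights(t, SolverParams())
        assert gw.w_h[:, 3].max() < 0.05 * gw.w_h[:, 0].min()
        assert gw.w_h.min() > 0 and gw.w_v.min() > 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.uniform(0, 1, size=(6, 6))
        p = SolverParams()
        gw = gradient_weights(t, p)
        oh, ov = weights_oracle(t, p)
        np.testing.assert_allclose(gw.w_h, oh, atol=1e-10)
        np.testing.assert_allclose(gw.w_v, ov, atol=1e-10)


class TestRefineIllumination:
    def test_alpha_zero_returns_t_hat_exactly(self, rng):
        t = rng.uniform(EPS_T, 1, size=(7, 7))
        gw = gradient_weights(t)
        p = SolverParams(alpha=0.0)
        np.testing.assert_array_equal(refine_illumination(t, gw, p), t)

    def test_constant_map_is_fixed_point(self):
        t = np.full((6, 6), 0.4)
        out = refine_illumination(t, gradient_weights(t), SolverParams(alpha=0.15))
        np.testing.assert_allclose(out, 0.4, atol=1e-10)

    @pytest.mark.parametrize("shape", [(5, 5), (12, 12), (5, 9)])
    def test_matches_dense_oracle(self, shape):
        rng = np.random.default_rng(hash(shape) % 2**31)
        t = rng.uniform(EPS_T, 1, size=shape)
        p = SolverParams(alpha=0.15)
        gw = gradient_weights(t, p)
        _, expected = dense_refine_oracle(t, gw, p)
        np.testing.assert_allclose(refine_illumination(t, gw, p), expected, atol=1e-8)

    def test_system_matrix_positive_definite(self, rng):
        t = rng.uniform(EPS_T, 1, size=(6, 6))
        p = SolverParams(alpha=0.3)
        A, _ = dense_refine_oracle(t, gradient_weights(t, p), p)
        np.testing.assert_allclose(A, A.T, atol=1e-12)
        assert np.linalg.eigvalsh(A).min() > 0.99  # I + PSD Laplacian

    def test_solution_minimizes_energy(self, rng):
        t = rng.uniform(EPS_T, 1, size=(8, 8))
        p = SolverParams(alpha=0.15)
        gw = gradient_weights(t, p)
        sol = refine_illumination(t, gw, p)
        assert objective(sol, t, gw, p) <= objective(t, t, gw, p) + 1e-12

    def test_total_variation_shrinks_with_alpha(self, rng):
        t = rng.uniform(EPS_T, 1, size=(10, 10))
        tvs = []
        for alpha in (0.0, 0.05, 0.15, 0.5, 2.0):
            p = SolverParams(alpha=alpha)
            sol = refine_illumination(t, gradient_weights(t, p), p)
            dh, dv = gradients(sol)
            tvs.append(np.abs(dh).sum() + np.abs(dv).sum())
        assert all(b <= a + 1e-9 for a, b in zip(tvs, tvs[1:]))

    def test_shape_mismatch_rejected(self, rng):
        t = rng.uniform(0, 1, size=(5, 5))
        gw = GradientWeights(w_h=np.ones((4, 5)), w_v=np.ones((5, 5)))
        with pytest.raises(ValueError):
            refine_illumination(t, gw, SolverParams())
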