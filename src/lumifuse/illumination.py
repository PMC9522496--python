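"""Illumination map estimation and structure-aware refinement.

The scene illumination ``T`` is estimated Retinex-style: the initial map
``T-hat`` is the per-pixel maximum over R, G, B (the illuminance at a pixel
is at least the largest channel), then refined by minimizing

    || T-hat - T ||_F^2 + alpha * || W o grad(T) ||_1

where the gradient weights ``W_h, W_v`` are small across genuine structure
edges and large on texture, so the solution keeps the overall lighting
structure while flattening texture detail.  The 1-norm term is relaxed to
a fixed-weight quadratic (weights computed once from T-hat), turning the
problem into a single sparse symmetric positive-definite linear solve

    (I + alpha * sum_d D_d' Diag(w~_d) D_d) t = t-hat,
    w~_d(x) = W_d(x) / (|grad_d T-hat(x)| + eps),

with ``D_d`` the forward-difference operator along direction ``d``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import cg, spsolve

from .imgio import EPS_T, validate_image, validate_plane

__all__ = [
    "SolverParams",
    "GradientWeights",
    "initial_illumination",
    "gradients",
    "gradient_weights",
    "refine_illumination",
]


@dataclass(frozen=True)
class SolverParams:
    """Parameters of the illumination refinement.

    alpha : smoothness weight (>= 0) balancing fidelity vs. smoothing.
    epsilon : small positive constant flooring denominators.
    sigma : spatial scale (pixels) of the Gaussian window in the weights.
    sigma_numerator : optional distinct bandwidth for the numerator window;
        defaults to ``sigma``.
    window_radius : half-width of the (2r+1)^2 weight window.
    """

    alpha: float = 0.15
    epsilon: float = 1e-3
    sigma: float = 2.0
    window_radius: int = 2
    sigma_numerator: float | None = None
    cg_tol: float = 1e-6
    dense_solve_limit: int = 1_000_000  # pixels; PCG fallback above

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.epsilon <= 0 or self.sigma <= 0:
            raise ValueError("epsilon and sigma must be positive")
        if self.window_radius < 1:
            raise ValueError("window_radius must be >= 1")


@dataclass(frozen=True)
class GradientWeights:
    """Horizontal/vertical gradient weight maps, strictly positive."""

    w_h: np.ndarray
    w_v: np.ndarray


def initial_illumination(img: np.ndarray) -> np.ndarray:
    """Initial illumination estimate: per-pixel channel maximum, floored
    at ``EPS_T`` so later divisions stay finite."""
    arr = validate_image(img)
    return np.maximum(arr.max(axis=2), EPS_T)


def gradients(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Forward differences with a zero (Neumann) last column/row.

    ``dh(i, j) = t(i, j+1) - t(i, j)``, ``dv(i, j) = t(i+1, j) - t(i, j)``.
    """
    arr = validate_plane(t, "T")
    dh = np.zeros_like(arr)
    dv = np.zeros_like(arr)
    dh[:, :-1] = arr[:, 1:] - arr[:, :-1]
    dv[:-1, :] = arr[1:, :] - arr[:-1, :]
    return dh, dv


def _gaussian_kernel(sigma: float, radius: int) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    return np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))


def gradient_weights(t_hat: np.ndarray, p: SolverParams = SolverParams()) -> GradientWeights:
    """Gaussian-weighted gradient weight matrices W_h, W_v.

    For each direction the weight at x is the ratio of two windowed sums
    over the (2r+1)^2 neighborhood Omega(x):

        W_d(x) = sum_y G(x,y) / ( | sum_y G(x,y) * grad_d(T-hat)(y) | + eps )

    with Gaussian window weights normalized per pixel over Omega(x)
    intersected with the image, so the numerator is exactly 1 everywhere
    (boundary windows included) and a constant map yields W = 1/eps.
    Both sums are evaluated as correlations.
    """
    arr = validate_plane(t_hat, "T_hat")
    dh, dv = gradients(arr)
    sig_den = p.sigma
    sig_num = p.sigma if p.sigma_numerator is None else p.sigma_numerator
    kern_den = _gaussian_kernel(sig_den, p.window_radius)
    coverage = ndimage.correlate(np.ones_like(arr), kern_den, mode="constant", cval=0.0)

    def weighted(grad: np.ndarray) -> np.ndarray:
        s = ndimage.correlate(grad, kern_den, mode="constant", cval=0.0)
        return s / coverage  # per-pixel renormalized window

    if sig_num != sig_den:
        kern_num = _gaussian_kernel(sig_num, p.window_radius)
        cov_num = ndimage.correlate(np.ones_like(arr), kern_num, mode="constant", cval=0.0)
        num = cov_num / cov_num  # = 1; kept explicit for the distinct-bandwidth hook
    else:
        num = np.ones_like(arr)
    w_h = num / (np.abs(weighted(dh)) + p.epsilon)
    w_v = num / (np.abs(weighted(dv)) + p.epsilon)
    return GradientWeights(w_h=w_h, w_v=w_v)


def _difference_operators(h: int, w: int) -> tuple[sparse.csr_matrix, sparse.csr_matrix]:
    """Sparse forward-difference matrices on the column-major (Fortran)
    vectorization, matching :func:`gradients` including the zero boundary."""
    n = h * w
    idx = np.arange(n)
    i = idx % h
    j = idx // h
    # horizontal: neighbor at column j+1 is idx + h
    mh = j < w - 1
    rows = np.concatenate([idx[mh], idx[mh]])
    cols = np.concatenate([idx[mh], idx[mh] + h])
    vals = np.concatenate([-np.ones(mh.sum()), np.ones(mh.sum())])
    dh = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    # vertical: neighbor at row i+1 is idx + 1
    mv = i < h - 1
    rows = np.concatenate([idx[mv], idx[mv]])
    cols = np.concatenate([idx[mv], idx[mv] + 1])
    vals = np.concatenate([-np.ones(mv.sum()), np.ones(mv.sum())])
    dv = sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))
    return dh, dv


def refine_illumination(
    t_hat: np.ndarray,
    w: GradientWeights,
    p: SolverParams = SolverParams(),
) -> np.ndarray:
    """Solve the relaxed refinement problem for the illumination map T.

    Builds the SPD system (identity plus a weighted graph Laplacian) and
    solves it by sparse direct factorization, falling back to diagonally
    preconditioned conjugate gradients above ``dense_solve_limit`` pixels.
    The result is clamped to ``[EPS_T, 1]``.  With ``alpha = 0`` the
    fidelity term alone is active and T-hat is returned unchanged.
    """
    arr = validate_plane(t_hat, "T_hat")
    if w.w_h.shape != arr.shape or w.w_v.shape != arr.shape:
        raise ValueError("weight maps must match the illumination map's shape")
    if p.alpha == 0:
        return np.clip(arr, EPS_T, 1.0)
    h_, w_ = arr.shape
    dh, dv = gradients(arr)
    wt_h = w.w_h / (np.abs(dh) + p.epsilon)
    wt_v = w.w_v / (np.abs(dv) + p.epsilon)
    n = h_ * w_
    Dh, Dv = _difference_operators(h_, w_)
    lap = Dh.T @ sparse.diags(wt_h.ravel(order="F")) @ Dh
    lap = lap + Dv.T @ sparse.diags(wt_v.ravel(order="F")) @ Dv
    A = (sparse.identity(n, format="csr") + p.alpha * lap).tocsc()
    rhs = arr.ravel(order="F")
    if n <= p.dense_solve_limit:
        t = spsolve(A, rhs)
    else:
        M = sparse.diags(1.0 / A.diagonal())
        t, info = cg(A, rhs, rtol=p.cg_tol, maxiter=10_000, M=M)
        if info != 0:
            raise RuntimeError(
                f"illumination solver did not converge (cg info={info}, n={n}, "
                f"alpha={p.alpha})"
            )
    return np.clip(t.reshape(arr.shape, order="F"), EPS_T, 1.0)
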