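"""Dual-exposure sampler and generator.

The enhancement pipeline synthesizes a second, virtual exposure of the
input scene through a brightness transfer function (BTF): for an exposure
ratio ``k`` the camera response model maps pixel values as

    g(P, k) = exp(b * (1 - k**a)) * P**(k**a)

with fixed camera parameters ``a = -0.3293``, ``b = 1.1258`` that fit most
consumer cameras.  The "sampler" chooses the exposure ratio k-hat that
maximizes the Shannon entropy of the brightened luminance — a well-exposed
image carries more histogram information than an under- or over-exposed
one — searching a bounded 1-D interval on a 50x50 downsampled luminance
for speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.transform import resize

from .imgio import validate_image, validate_plane

__all__ = [
    "CameraModel",
    "ExposureEstimate",
    "luminance",
    "image_entropy",
    "btf_apply",
    "find_optimal_exposure",
]


@dataclass(frozen=True)
class CameraModel:
    """BTF parameters ``(a, b)``; the derived quantities are
    ``gamma = k**a`` and ``beta = exp(b * (1 - k**a))``."""

    a: float = -0.3293
    b: float = 1.1258

    def __post_init__(self) -> None:
        if self.a == 0:
            raise ValueError("camera parameter a must be nonzero (k**a degenerate)")


@dataclass(frozen=True)
class ExposureEstimate:
    """Result of the entropy-maximizing exposure search."""

    k_hat: float
    entropy_at_k_hat: float
    search_lo: float
    search_hi: float


def luminance(img: np.ndarray, mode: str = "max") -> np.ndarray:
    """Luminance component B of an RGB image.

    ``mode='max'`` (default) takes the per-pixel channel maximum, matching
    the max-RGB convention of the initial illumination estimate;
    ``mode='mean'`` averages the channels.
    """
    arr = validate_image(img)
    if mode == "max":
        return arr.max(axis=2)
    if mode == "mean":
        return arr.mean(axis=2)
    raise ValueError(f"unknown luminance mode {mode!r}")


def image_entropy(b: np.ndarray, n_bins: int = 256) -> float:
    """Shannon entropy (bits) of the ``n_bins``-bin histogram of a plane.

    Values are binned uniformly on [0, 1] (last bin right-closed); empty
    bins contribute zero.  The result lies in ``[0, log2(n_bins)]``.
    """
    arr = validate_plane(b, "B")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts, _ = np.histogram(np.clip(arr, 0.0, 1.0), bins=n_bins, range=(0.0, 1.0))
    p = counts[counts > 0] / arr.size
    return float(-(p * np.log2(p)).sum())


def btf_apply(arr: np.ndarray, k: float, cam: CameraModel = CameraModel()) -> np.ndarray:
    """Apply the camera response g(P, k) elementwise; k > 1 brightens.

    The same parameters are used for all channels (typical cameras have
    near-identical per-channel response curves).  Output clamped to [0, 1].
    """
    if k <= 0:
        raise ValueError(f"exposure ratio must be positive, got {k}")
    a = np.asarray(arr, dtype=np.float64)
    gamma = k**cam.a
    beta = np.exp(cam.b * (1.0 - gamma))
    out = beta * np.power(np.clip(a, 0.0, 1.0), gamma)
    return np.clip(out, 0.0, 1.0)


def _resized_luminance(img: np.ndarray, size: int, mode: str) -> np.ndarray:
    b = luminance(img, mode=mode)
    if b.shape != (size, size):
        b = resize(b, (size, size), order=1, anti_aliasing=False, preserve_range=True)
    return np.clip(b, 0.0, 1.0)


def find_optimal_exposure(
    img: np.ndarray,
    cam: CameraModel = CameraModel(),
    *,
    k_lo: float = 1.0,
    k_hi: float = 10.0,
    n_grid: int = 20,
    n_bins: int = 256,
    optimize_size: int = 50,
    luminance_mode: str = "max",
) -> ExposureEstimate:
    """Entropy-maximizing exposure ratio k-hat.

    The luminance is resized to ``optimize_size`` squared, then
    ``H(g(B, k))`` is maximized over ``[k_lo, k_hi]``: a coarse log-spaced
    grid locates the peak (entropy rises then falls with k, but
    unimodality is only assumed, so the grid guards the bracket), and a
    bounded scalar optimization refines it.  The returned entropy is never
    below any grid evaluation.

    A constant (degenerate) image has identically zero entropy at every
    exposure; the search returns ``k_hat = 1`` with a warning.
    """
    if not k_lo < k_hi:
        raise ValueError("need k_lo < k_hi")
    b = _resized_luminance(img, optimize_size, luminance_mode)
    if b.max() - b.min() < 1e-12:
        warnings.warn("constant image: entropy is flat, returning k_hat = 1", stacklevel=2)
        return ExposureEstimate(1.0, 0.0, k_lo, k_hi)

    def neg_entropy(k: float) -> float:
        return -image_entropy(btf_apply(b, k, cam), n_bins=n_bins)

    grid = np.geomspace(k_lo, k_hi, n_grid)
    grid_h = np.array([-neg_entropy(k) for k in grid])
    i_best = int(np.argmax(grid_h))
    lo = grid[max(i_best - 1, 0)]
    hi = grid[min(i_best + 1, n_grid - 1)]
    best_k, best_h = float(grid[i_best]), float(grid_h[i_best])
    if hi > lo:
        res = minimize_scalar(
            neg_entropy, bounds=(lo, hi), method="bounded", options={"xatol": 1e-4}
        )
        if -res.fun > best_h:
            best_k, best_h = float(res.x), float(-res.fun)
    return ExposureEstimate(best_k, best_h, k_lo, k_hi)
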