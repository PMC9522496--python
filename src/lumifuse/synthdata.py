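"""Deterministic synthetic fixtures.

Real low-light photographs are not bundled with the package, so every
stage is exercised on synthetic scene pairs: a well-exposed scene with a
full-range histogram and known structure (edges, flat regions, texture),
and a low-light counterpart produced by running the pipeline's own camera
response model *backwards* (exposure ratio ``dark_k < 1`` darkens), with
optional radial vignetting for nonuniform lighting and additive Gaussian
sensor noise.  Because the degradation uses the same brightness transfer
function the enhancer inverts, the entropy-optimal exposure search has an
exact ground truth: the composition law g(g(P, k0), k) = g(P, k0*k) makes
k = 1/dark_k restore the original, entropy-maximal scene.

All randomness flows from the single seed in :class:`FixtureSpec`; an
identical spec yields a bit-identical fixture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exposure import (
    CameraModel,
    btf_apply,
    find_optimal_exposure,
    image_entropy,
    _resized_luminance,
)

__all__ = ["FixtureSpec", "make_scene", "degrade"]

_SCENES = ("gradient", "checkerboard", "blobs", "mixed")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one (clean, degraded) fixture pair.

    dark_k : darkening exposure ratio in (0, 1); 0.33 emulates a scene
        shot at roughly a third of the proper exposure.
    noise_sigma : additive Gaussian noise std in [0, 1] units; 0.01
        (about 2.5 digital numbers on an 8-bit sensor) is a realistic
        low-light read-noise level.
    vignette : apply a radial illumination falloff (corners at ~0.3x)
        before darkening, emulating nonuniform lighting.
    """

    seed: int = 0
    size: int = 128
    scene: str = "mixed"
    dark_k: float = 0.33
    noise_sigma: float = 0.01
    vignette: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.dark_k < 1:
            raise ValueError("dark_k must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.scene not in _SCENES:
            raise ValueError(f"scene must be one of {_SCENES}")
        if self.size < 8:
            raise ValueError("size must be >= 8")


def _ramp(n: int, lo: float = 0.02, hi: float = 0.98) -> np.ndarray:
    return np.linspace(lo, hi, n)


def _gradient_scene(n: int, rng: np.random.Generator) -> np.ndarray:
    x = _ramp(n)[None, :]
    y = _ramp(n)[:, None]
    r = np.broadcast_to(x, (n, n))
    g = np.broadcast_to(y, (n, n))
    b = 0.02 + 0.96 * (x + y) / (x[0, -1] + y[-1, 0])
    return np.stack([r, g, np.broadcast_to(b, (n, n))], axis=-1).copy()


def _checker_scene(n: int, rng: np.random.Generator) -> np.ndarray:
    tile = max(2, n // 8)
    ii, jj = np.indices((n, n))
    board = ((ii // tile + jj // tile) % 2).astype(float)
    los = rng.uniform(0.01, 0.05, size=3)
    his = rng.uniform(0.95, 0.99, size=3)
    return np.stack([np.where(board > 0, his[c], los[c]) for c in range(3)], axis=-1)


def _blob_scene(n: int, rng: np.random.Generator) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n] / n
    img = np.zeros((n, n, 3))
    for _ in range(6):
        cy, cx = rng.uniform(0.1, 0.9, size=2)
        w = rng.uniform(0.05, 0.2)
        amp = rng.uniform(0.4, 1.0, size=3)
        bump = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * w**2))
        img += bump[:, :, None] * amp[None, None, :]
    img /= max(img.max(), 1e-9)
    return 0.02 + 0.96 * img


def _mixed_scene(n: int, rng: np.random.Generator) -> np.ndarray:
    img = _gradient_scene(n, rng)
    h = n // 2
    img[:h, :h] = _checker_scene(n, rng)[:h, :h]
    img = 0.6 * img + 0.4 * _blob_scene(n, rng)
    img[:, h:] *= 0.85  # hard vertical step edge
    lo, hi = img.min(), img.max()
    return 0.02 + 0.96 * (img - lo) / (hi - lo)


def _entropy_normalize(img: np.ndarray, cam: CameraModel) -> np.ndarray:
    """Bring a scene to its entropy-optimal exposure.

    "Well-exposed" must mean the same thing to the generator and to the
    enhancer: a scene whose luminance entropy is maximal at unit exposure
    ratio.  Any residual exposure bias of the raw procedural scene is
    removed by pushing it through the camera model at its own
    entropy-optimal ratio; by the composition law the result then peaks
    at k = 1 along the exposure axis.
    """
    est = find_optimal_exposure(img, cam, k_lo=1.0 / 3.0, k_hi=3.0, n_grid=41)
    h_unit = image_entropy(_resized_luminance(img, 50, "max"))
    # scenes with exposure-invariant entropy (e.g. two-level boards) stay as built
    if est.entropy_at_k_hat <= h_unit + 1e-3:
        return img
    return btf_apply(img, est.k_hat, cam)


def make_scene(spec: FixtureSpec, cam: CameraModel = CameraModel()) -> np.ndarray:
    """Deterministic well-exposed scene; intensities span at least
    [0.05, 0.95] and luminance entropy peaks at unit exposure ratio."""
    rng = np.random.default_rng([spec.seed, 0])
    maker = {
        "gradient": _gradient_scene,
        "checkerboard": _checker_scene,
        "blobs": _blob_scene,
        "mixed": _mixed_scene,
    }[spec.scene]
    raw = np.clip(maker(spec.size, rng), 0.0, 1.0)
    out = _entropy_normalize(raw, cam)
    # affine stretch to the full-range span contract; preserves the
    # histogram's shape, so the entropy peak stays at unit exposure
    lo, hi = out.min(), out.max()
    return 0.02 + 0.96 * (out - lo) / (hi - lo)


def _vignette_mask(n: int) -> np.ndarray:
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    d2 = ((yy - c) ** 2 + (xx - c) ** 2) / (2 * c**2)  # 1 at corners
    return 0.3 + 0.7 * (1.0 - np.clip(d2, 0.0, 1.0))


def degrade(
    img: np.ndarray, spec: FixtureSpec, cam: CameraModel = CameraModel()
) -> np.ndarray:
    """Emulate a low-light capture of a well-exposed scene.

    Optional radial vignette (multiplier in [0.3, 1]), then the camera
    response at exposure ``dark_k < 1``, then seeded additive Gaussian
    noise; clamped to [0, 1].  With no vignette and zero noise the result
    is exactly ``btf_apply(img, dark_k)``.
    """
    out = np.asarray(img, dtype=np.float64).copy()
    if spec.vignette:
        out *= _vignette_mask(spec.size)[:, :, None]
    out = btf_apply(out, spec.dark_k, cam)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng([spec.seed, 1])
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)
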