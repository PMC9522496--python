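"""Objective image-quality metrics: lightness order error and visual
information fidelity.

LOE measures how well an enhancement preserves the *relative order* of
lightness between pixel pairs — the order encodes light-source direction
and naturalness, so fewer order flips mean a more natural result.  With
``Q`` and ``Q_r`` the per-pixel channel maxima of the enhanced and
reference images,

    LOE = (1/m) * sum_x sum_y [ U(Q(x), Q(y)) XOR U(Q_r(x), Q_r(y)) ],

where ``U(p, q) = 1`` iff ``p >= q`` and ``m`` is the pixel count at the
evaluation resolution.  The pair sum is quadratic in m, so both maps are
nearest-neighbour downsampled to ``eval_size`` per side first (nearest
sampling cannot create new intensity orderings).  Lower is better; 0
means the order is fully preserved.

VIF scores fidelity as the ratio of mutual information a Gaussian
scale-mixture observer extracts from the distorted versus the reference
image.  This implementation works in the pixel domain with a scalar GSM:
at each of four dyadic scales, windowed moments give the local reference
variance sigma_C^2 and a local gain/noise decomposition (g, sigma_V^2) of
the distorted image, and

    VIF = sum log2(1 + g^2 sigma_C^2 / (sigma_V^2 + sigma_N^2))
        / sum log2(1 + sigma_C^2 / sigma_N^2)

with visual-noise variance sigma_N^2 = 2 on the 0-255 intensity scale.
Identical images score exactly 1; added distortion lowers the score.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .imgio import validate_image, rgb_to_yuv

__all__ = [
    "MetricReport",
    "lightness_order_error",
    "visual_information_fidelity",
    "metric_report",
]

#: Visual-noise variance of the GSM observer model, on the 0-255 scale.
SIGMA_N_SQ = 2.0
_VAR_FLOOR = 1e-10


@dataclass(frozen=True)
class MetricReport:
    """LOE and VIF for one (enhanced, reference) pair."""

    loe: float
    vif: float
    loe_eval_size: int

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps({"loe": d["loe"], "vif": d["vif"], "eval_size": d["loe_eval_size"]})


def _channel_max(img: np.ndarray) -> np.ndarray:
    return validate_image(img).max(axis=2)


def _nearest_downsample(q: np.ndarray, m: int) -> np.ndarray:
    h, w = q.shape
    ri = np.minimum((np.floor((np.arange(m) + 0.5) * h / m)).astype(int), h - 1)
    ci = np.minimum((np.floor((np.arange(m) + 0.5) * w / m)).astype(int), w - 1)
    return q[np.ix_(ri, ci)]


def lightness_order_error(
    enhanced: np.ndarray, reference: np.ndarray, eval_size: int = 100
) -> float:
    """Lightness order error between an enhanced image and its reference.

    Images no larger than ``eval_size`` on both axes are compared at full
    resolution; larger images are nearest-neighbour downsampled to
    ``eval_size`` x ``eval_size``.  The double sum over all ordered pixel
    pairs is normalized by m (the pixel count), so the value ranges over
    ``[0, m]``.
    """
    if eval_size < 2:
        raise ValueError("eval_size must be >= 2")
    q = _channel_max(enhanced)
    qr = _channel_max(reference)
    if q.shape != qr.shape:
        raise ValueError(f"shape mismatch: {q.shape} vs {qr.shape}")
    if q.shape[0] > eval_size or q.shape[1] > eval_size:
        q = _nearest_downsample(q, eval_size)
        qr = _nearest_downsample(qr, eval_size)
    a = q.ravel()
    b = qr.ravel()
    m = a.size
    total = 0
    chunk = max(1, 2**22 // m)  # keep pairwise blocks ~ a few MB
    for s in range(0, m, chunk):
        ua = a[s : s + chunk, None] >= a[None, :]
        ub = b[s : s + chunk, None] >= b[None, :]
        total += int(np.count_nonzero(ua ^ ub))
    return total / m


def _gaussian_window(sigma: float = 1.5, radius: int = 4) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=np.float64)
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    k = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    return k / k.sum()


def _local_mean(x: np.ndarray, win: np.ndarray) -> np.ndarray:
    return ndimage.correlate(x, win, mode="reflect")


def visual_information_fidelity(enhanced: np.ndarray, reference: np.ndarray) -> float:
    """Pixel-domain multi-scale VIF of ``enhanced`` against ``reference``.

    Both images are converted to luminance on the 0-255 scale.  Four
    scales are visited, blurring and decimating by two between scales;
    scales smaller than 4 pixels per side are skipped.  Windows whose
    local reference variance is below a tiny floor carry no information
    and are excluded from both sums.  A reference with no local variance
    anywhere (constant image) has undefined fidelity.
    """
    e = validate_image(enhanced, "enhanced")
    r = validate_image(reference, "reference")
    if e.shape != r.shape:
        raise ValueError(f"shape mismatch: {e.shape} vs {r.shape}")
    ref = rgb_to_yuv(r)[0] * 255.0
    dist = rgb_to_yuv(e)[0] * 255.0
    win = _gaussian_window()
    num = 0.0
    den = 0.0
    for scale in range(4):
        if scale > 0:
            ref = _local_mean(ref, win)[::2, ::2]
            dist = _local_mean(dist, win)[::2, ::2]
        if min(ref.shape) < 4:
            break
        mu1 = _local_mean(ref, win)
        mu2 = _local_mean(dist, win)
        s1 = np.clip(_local_mean(ref * ref, win) - mu1 * mu1, 0.0, None)
        s2 = np.clip(_local_mean(dist * dist, win) - mu2 * mu2, 0.0, None)
        s12 = _local_mean(ref * dist, win) - mu1 * mu2
        mask = s1 > _VAR_FLOOR
        g = np.zeros_like(s1)
        np.divide(s12, s1, out=g, where=mask)
        g = np.clip(g, 0.0, None)
        sv = np.clip(s2 - g * s12, 0.0, None)
        num += float(np.log2(1.0 + (g * g * s1)[mask] / (sv[mask] + SIGMA_N_SQ)).sum())
        den += float(np.log2(1.0 + s1[mask] / SIGMA_N_SQ).sum())
    if den == 0.0:
        raise ValueError("reference image has no local variance; fidelity undefined")
    return num / den


def metric_report(
    enhanced: np.ndarray, reference: np.ndarray, eval_size: int = 100
) -> MetricReport:
    """Compute both metrics for an (enhanced, reference) pair."""
    return MetricReport(
        loe=lightness_order_error(enhanced, reference, eval_size=eval_size),
        vif=visual_information_fidelity(enhanced, reference),
        loe_eval_size=eval_size,
    )
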