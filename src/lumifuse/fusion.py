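"""Illumination-weighted exposure fusion.

The enhanced image is a per-pixel convex blend of the original image P and
the synthesized brighter exposure g(P, k-hat):

    R_c = W o P_c + (1 - W) o g(P_c, k-hat)

The fusion weight W is derived from the refined illumination map T as
``W = T**mu``: well-lit pixels (T near 1) keep the original values, while
underexposed pixels (T near 0) draw on the synthetic exposure.  The
gradient weight matrices of the illumination solve play no role here —
they only shape the smoothing.
"""

from __future__ import annotations

import numpy as np

from .config import PipelineConfig  # noqa: F401  (re-export: config lives with fusion)
from .imgio import EPS_T, validate_image, validate_plane

__all__ = ["PipelineConfig", "fusion_weight", "fuse"]


def fusion_weight(t: np.ndarray, mu: float = 1.0) -> np.ndarray:
    """Per-pixel fusion weight W = T**mu, in (0, 1].

    ``mu = 0`` returns all ones (pure original); ``mu = 1`` uses T itself;
    ``mu < 1`` softens the blend toward the original.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    arr = validate_plane(t, "T")
    return np.power(np.clip(arr, EPS_T, 1.0), mu)


def fuse(p: np.ndarray, p_syn: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Convex per-channel blend R = W o P + (1 - W) o P_syn, clamped to [0, 1]."""
    a = validate_image(p, "P")
    b = validate_image(p_syn, "P_syn")
    wm = validate_plane(w, "W")
    if a.shape != b.shape or wm.shape != a.shape[:2]:
        raise ValueError(f"shape mismatch: P {a.shape}, P_syn {b.shape}, W {wm.shape}")
    if wm.min() < -1e-12 or wm.max() > 1 + 1e-12:
        raise ValueError("fusion weight must lie in [0, 1]")
    w3 = np.clip(wm, 0.0, 1.0)[:, :, None]
    return np.clip(w3 * a + (1.0 - w3) * b, 0.0, 1.0)
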