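"""Raster image I/O and color-space plumbing.

Everything downstream works on floating-point RGB arrays in ``[0, 1]``
(shape ``(H, W, 3)``, channel order R, G, B) and single-channel "plane"
maps of shape ``(H, W)``.  The camera response model evaluates ``P**(k**a)``,
which is only well behaved on the unit interval, so images are normalized
to ``[0, 1]`` on load and clamped back on save.

YUV conversion uses the BT.601 full-range matrix with chroma centered at
zero (``U, V`` in ``[-0.5, 0.5]``), so a constant gray ``(g, g, g)`` maps to
``Y = g, U = V = 0`` exactly.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

__all__ = [
    "EPS_T",
    "load_image",
    "save_image",
    "rgb_to_yuv",
    "yuv_to_rgb",
    "validate_image",
    "validate_plane",
]

#: Floor applied to illumination maps wherever they divide or blend,
#: preventing division blow-up in near-black regions.
EPS_T = 1e-3

# BT.601 full-range: rows are Y, U (= B-Y scaled), V (= R-Y scaled).
_RGB2YUV = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.168736, -0.331264, 0.5],
        [0.5, -0.418688, -0.081312],
    ]
)
_YUV2RGB = np.linalg.inv(_RGB2YUV)


def validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    """Check an RGB image array and return it as float64.

    Requires shape (H, W, 3) with H, W >= 2 (the gradient operators need at
    least two pixels per axis), finite values inside [0, 1].
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{name}: expected (H, W, 3) array, got shape {arr.shape}")
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError(f"{name}: spatial size must be at least 2x2, got {arr.shape[:2]}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: contains non-finite values")
    if arr.min() < -1e-9 or arr.max() > 1 + 1e-9:
        raise ValueError(f"{name}: values outside [0, 1]")
    return np.clip(arr, 0.0, 1.0)


def validate_plane(plane: np.ndarray, name: str = "plane") -> np.ndarray:
    """Check a single-channel map and return it as float64."""
    arr = np.asarray(plane, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError(f"{name}: expected 2-D array, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError(f"{name}: empty map")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: contains non-finite values")
    return arr


def load_image(path: str | os.PathLike) -> np.ndarray:
    """Read a PNG/JPEG/TIFF file into a float RGB array in [0, 1].

    Integer samples are divided by the maximum representable value of
    their bit depth (255 or 65535).  Grayscale images are replicated to
    three channels; an alpha channel is dropped.
    """
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # codec-level failures
        raise IOError(f"cannot read image {path!r}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"{path!r}: zero-size image")
    if raw.ndim == 2:
        raw = np.stack([raw] * 3, axis=-1)
    if raw.ndim != 3:
        raise ValueError(f"{path!r}: unsupported image layout {raw.shape}")
    if raw.shape[2] == 1:
        raw = np.repeat(raw, 3, axis=2)
    elif raw.shape[2] >= 4:
        raw = raw[:, :, :3]
    if raw.dtype == np.uint8:
        arr = raw.astype(np.float64) / 255.0
    elif raw.dtype == np.uint16:
        arr = raw.astype(np.float64) / 65535.0
    else:
        arr = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return validate_image(arr, name=str(path))


def save_image(img: np.ndarray, path: str | os.PathLike) -> None:
    """Clamp to [0, 1], quantize to 8 bits and write in the format implied
    by the file extension."""
    arr = np.asarray(img, dtype=np.float64)
    q = np.clip(np.rint(np.clip(arr, 0.0, 1.0) * 255.0), 0, 255).astype(np.uint8)
    try:
        iio.imwrite(path, q)
    except Exception as exc:
        raise IOError(f"cannot write image {path!r}: {exc}") from exc


def rgb_to_yuv(img: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split an RGB image into (Y, U, V) planes.

    BT.601 full-range; Y in [0, 1], chroma centered at 0.
    """
    arr = validate_image(img)
    yuv = arr @ _RGB2YUV.T
    return yuv[:, :, 0], yuv[:, :, 1], yuv[:, :, 2]


def yuv_to_rgb(y: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Exact algebraic inverse of :func:`rgb_to_yuv`; output clamped to [0, 1]."""
    y = validate_plane(y, "Y")
    u = validate_plane(u, "U")
    v = validate_plane(v, "V")
    if not (y.shape == u.shape == v.shape):
        raise ValueError(f"plane shapes differ: {y.shape}, {u.shape}, {v.shape}")
    yuv = np.stack([y, u, v], axis=-1)
    rgb = yuv @ _YUV2RGB.T
    return np.clip(rgb, 0.0, 1.0)
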