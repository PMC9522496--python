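"""Full enhancement pipeline.

Stage order: entropy-optimal exposure search -> synthesize the virtual
second exposure -> initial illumination -> gradient weights -> refined
illumination -> fusion weight -> exposure fusion -> grayscale-range
adjustment -> illumination-balanced denoising.  The whole path is
deterministic: two runs on the same input and config are bit-identical.
"""

from __future__ import annotations

import time
from typing import Any

import numpy as np

from . import __version__
from .config import PipelineConfig
from .exposure import btf_apply, find_optimal_exposure, luminance
from .fusion import fuse, fusion_weight
from .illumination import gradient_weights, initial_illumination, refine_illumination
from .imgio import save_image, validate_image
from .postprocess import adjust_gray_range, denoise_recombine

__all__ = ["enhance"]


def enhance(
    img: np.ndarray,
    cfg: PipelineConfig = PipelineConfig(),
    *,
    debug_dir: str | None = None,
) -> tuple[np.ndarray, dict[str, Any]]:
    """Enhance a low-light RGB image.

    Returns the enhanced image and a run manifest (exposure found,
    per-stage wall times, config snapshot, tool version).  With
    ``debug_dir`` set, every intermediate image is dumped there as PNG.
    """
    arr = validate_image(img)
    manifest: dict[str, Any] = {"version": __version__, "config": cfg.to_dict(), "timings": {}}
    # the manifest's config snapshot must stay JSON-serializable
    manifest["config"]["denoise"]["backend"] = (
        None if cfg.denoise.backend is None else getattr(cfg.denoise.backend, "__name__", "custom")
    )

    def timed(name: str, fn, *args, **kw):
        t0 = time.perf_counter()
        try:
            out = fn(*args, **kw)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["timings"][name] = time.perf_counter() - t0
        return out

    est = timed(
        "find_optimal_exposure",
        find_optimal_exposure,
        arr,
        cfg.camera,
        k_lo=cfg.k_lo,
        k_hi=cfg.k_hi,
        n_grid=cfg.n_grid,
        n_bins=cfg.n_bins,
        optimize_size=cfg.optimize_size,
        luminance_mode=cfg.luminance_mode,
    )
    manifest["k_hat"] = est.k_hat
    manifest["entropy_at_k_hat"] = est.entropy_at_k_hat
    p_syn = timed("btf_apply", btf_apply, arr, est.k_hat, cfg.camera)
    t_hat = timed("initial_illumination", initial_illumination, arr)
    weights = timed("gradient_weights", gradient_weights, t_hat, cfg.solver)
    t_ref = timed("refine_illumination", refine_illumination, t_hat, weights, cfg.solver)
    w = timed("fusion_weight", fusion_weight, t_ref, cfg.mu)
    fused = timed("fuse", fuse, arr, p_syn, w)
    adjusted = timed(
        "adjust_gray_range", adjust_gray_range, fused, cfg.q_low, cfg.q_high, cfg.gamma_adjust
    )
    if cfg.denoise.enabled:
        final = timed("denoise_recombine", denoise_recombine, adjusted, t_ref, cfg.denoise)
    else:
        final = adjusted
    manifest["mean_luminance_in"] = float(luminance(arr).mean())
    manifest["mean_luminance_out"] = float(luminance(final).mean())

    if debug_dir is not None:
        import os

        os.makedirs(debug_dir, exist_ok=True)
        for name, im in [
            ("01_input", arr),
            ("02_synthesized", p_syn),
            ("03_t_hat", np.repeat(t_hat[:, :, None], 3, axis=2)),
            ("04_t_refined", np.repeat(t_ref[:, :, None], 3, axis=2)),
            ("05_fused", fused),
            ("06_adjusted", adjusted),
            ("07_final", final),
        ]:
            save_image(im, os.path.join(debug_dir, f"{name}.png"))
    return final, manifest
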