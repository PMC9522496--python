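"""Pipeline configuration.

Every free parameter of the enhancement pipeline lives here so runs are
reproducible from a single declarative file (YAML) plus CLI overrides.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from typing import Any

import yaml

from .exposure import CameraModel
from .illumination import SolverParams
from .postprocess import DenoiseParams

__all__ = ["PipelineConfig"]


@dataclass(frozen=True)
class PipelineConfig:
    """All tunables of the enhancement pipeline.

    mu : exponent of the fusion weight W = T**mu (>= 0); 1 uses the
        refined illumination directly.
    gamma_adjust : gamma of the grayscale-range adjustment (0.9 default).
    q_low, q_high : stretch quantiles of the adjustment (1% tails).
    n_bins : histogram bins for the entropy objective.
    k_lo, k_hi : exposure-ratio search interval (the method only
        brightens; well-exposed pixels are preserved by the fusion).
    n_grid : coarse grid points seeding the 1-D entropy maximization.
    optimize_size : downsample target (pixels per side) for the search.
    luminance_mode : 'max' (channel maximum) or 'mean'.
    loe_size : evaluation resolution (pixels per side) of the LOE metric.
    """

    mu: float = 1.0
    gamma_adjust: float = 0.9
    q_low: float = 0.01
    q_high: float = 0.99
    n_bins: int = 256
    k_lo: float = 1.0
    k_hi: float = 10.0
    n_grid: int = 20
    optimize_size: int = 50
    luminance_mode: str = "max"
    loe_size: int = 100
    camera: CameraModel = field(default_factory=CameraModel)
    solver: SolverParams = field(default_factory=SolverParams)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)

    def __post_init__(self) -> None:
        if not self.q_low < self.q_high:
            raise ValueError("need q_low < q_high")
        if not self.k_lo < self.k_hi:
            raise ValueError("need k_lo < k_hi")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (("camera", CameraModel), ("solver", SolverParams), ("denoise", DenoiseParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def with_overrides(self, **kwargs: Any) -> "PipelineConfig":
        """Return a copy with the given fields replaced (None ignored)."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return replace(self, **updates)
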