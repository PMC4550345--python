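"""Analysis configuration shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError
from .imaging import LUMINANCE_MODES
from .layout import ArrayLayout

THRESHOLD_METHODS = ("quantile", "otsu", "fixed")
INTERPOLATIONS = ("bilinear", "nearest")


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the analysis pipeline.

    Attributes
    ----------
    luminance_mode:
        RGB collapse; ``red_only`` by default (610 nm long-pass emission
        filter confines the quantum-dot signal to the red channel).
    threshold_method, threshold_value:
        Anchor-detection threshold. For ``quantile`` a value of None means
        the layout-adaptive default (1 - 1.5x expected spot fraction).
    min_area_frac:
        Minimum blob area as a fraction of the ellipse-ROI pixel count
        ("a certain minimum size" made layout-relative).
    margin_frac:
        Crop margin around the spot grid, in pitches.
    interpolation:
        Resampling kernel for the warps.
    inner_only:
        Aggregate only inner-rectangle spots (ring controls serve
        geometry, not the readout).
    """

    luminance_mode: str = "red_only"
    threshold_method: str = "quantile"
    threshold_value: float | None = None
    min_area_frac: float = 0.25
    margin_frac: float = 0.75
    interpolation: str = "bilinear"
    inner_only: bool = True

    def __post_init__(self) -> None:
        if self.luminance_mode not in LUMINANCE_MODES:
            raise ConfigError(f"unknown luminance mode {self.luminance_mode!r}")
        if self.threshold_method not in THRESHOLD_METHODS:
            raise ConfigError(f"unknown threshold method {self.threshold_method!r}")
        if self.interpolation not in INTERPOLATIONS:
            raise ConfigError(f"unknown interpolation {self.interpolation!r}")
        if not 0 < self.min_area_frac <= 1:
            raise ConfigError("min_area_frac must be in (0, 1]")
        if self.margin_frac < 0:
            raise ConfigError("margin_frac must be >= 0")

    def resolve_min_area(self, layout: ArrayLayout) -> int:
        """Minimum blob area in pixels for this layout."""
        a, b = layout.ellipse_semi_axes
        return max(1, int(round(self.min_area_frac * np.pi * a * b)))

    @classmethod
    def from_mapping(cls, data: dict) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_mapping(self) -> dict:
        return {
            "luminance_mode": self.luminance_mode,
            "threshold_method": self.threshold_method,
            "threshold_value": self.threshold_value,
            "min_area_frac": self.min_area_frac,
            "margin_frac": self.margin_frac,
            "interpolation": self.interpolation,
            "inner_only": self.inner_only,
        }
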