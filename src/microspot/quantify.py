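"""Per-spot quantification and control-based normalization.

On the standardized image every spot centroid sits on the regular reference
grid, so each spot is read out as the median luminance over a fixed ellipse
at its reference centroid. Medians are robust to saturated or dead pixels
inside a spot. Replicate spots of a role are averaged (mean +/- sample SD
over the inner-rectangle spots), the negative-control mean is subtracted as
background, and the result is expressed relative to the positive-control
span on the same chip:

    normalized(role) = (mean_role - mean_NEG) / (mean_POS - mean_NEG)

so POS maps to 1 and NEG to 0 by construction, and values may legitimately
be slightly negative for blank samples. This per-chip normalization is what
makes readouts comparable across chips, days and illumination levels.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .config import AnalysisConfig
from .errors import QCError, QuantError
from .layout import (
    BIOMARKER_ROLES,
    ArrayLayout,
    SpotRole,
    inner_positions,
    reference_centroids,
)


@dataclass(frozen=True)
class SpotMeasurement:
    """Median luminance of one spot's elliptical ROI."""

    grid_position: tuple[int, int]
    role: SpotRole
    median_luminance: float
    n_pixels: int


@dataclass(frozen=True)
class RoleAggregate:
    """Replicate-averaged readout for one role."""

    role: SpotRole
    mean_luminance: float
    sd_luminance: float
    n_spots: int


@dataclass(frozen=True)
class ChipResult:
    """Complete per-chip readout."""

    measurements: tuple[SpotMeasurement, ...]
    aggregates: dict[SpotRole, RoleAggregate]
    normalized: dict[SpotRole, float]
    qc: dict[str, float]


def ellipse_pixels(
    center: tuple[float, float],
    semi_axes: tuple[float, float],
    image_shape: tuple[int, int],
) -> list[tuple[int, int]]:
    """Integer pixels inside the ellipse, clipped to the image.

    A pixel ``(px, py)`` belongs to the ROI when
    ``((px - x)/a)^2 + ((py - y)/b)^2 <= 1``. Raises if the clipped set is
    empty (ROI entirely outside the image).
    """
    x, y = center
    a, b = semi_axes
    if a <= 0 or b <= 0:
        raise QuantError("ellipse semi-axes must be positive")
    h, w = image_shape
    x_lo = max(0, int(np.ceil(x - a)))
    x_hi = min(w - 1, int(np.floor(x + a)))
    y_lo = max(0, int(np.ceil(y - b)))
    y_hi = min(h - 1, int(np.floor(y + b)))
    pixels: list[tuple[int, int]] = []
    for py in range(y_lo, y_hi + 1):
        dy = (py - y) / b
        for px in range(x_lo, x_hi + 1):
            dx = (px - x) / a
            if dx * dx + dy * dy <= 1.0:
                pixels.append((px, py))
    if not pixels:
        raise QuantError(
            f"ROI outside image: ellipse at ({x}, {y}) covers no pixels"
        )
    return pixels


def measure_spot(
    img: np.ndarray,
    center: tuple[float, float],
    semi_axes: tuple[float, float],
) -> tuple[float, int]:
    """Median luminance over the elliptical ROI; returns (median, n_pixels).

    An even pixel count takes the mean of the two middle values.
    """
    pixels = ellipse_pixels(center, semi_axes, img.shape)
    values = np.asarray([img[py, px] for px, py in pixels], dtype=np.float64)
    return float(np.median(values)), len(pixels)


def measure_grid(img: np.ndarray, layout: ArrayLayout) -> list[SpotMeasurement]:
    """Measure every layout position at its reference centroid."""
    refs = reference_centroids(layout)
    out: list[SpotMeasurement] = []
    for pos in sorted(refs):
        try:
            median, n_pix = measure_spot(img, refs[pos], layout.ellipse_semi_axes)
        except QuantError as exc:
            raise QuantError(f"spot {pos}: {exc}")
        out.append(
            SpotMeasurement(
                grid_position=pos,
                role=layout.roles[pos],
                median_luminance=median,
                n_pixels=n_pix,
            )
        )
    return out


def aggregate(
    measurements: list[SpotMeasurement],
    layout: ArrayLayout,
    inner_only: bool = True,
) -> dict[SpotRole, RoleAggregate]:
    """Mean and sample SD (n-1 denominator) of the replicates per role.

    By default only inner-rectangle spots are aggregated: the outer-ring
    controls exist to define the grid, not the readout; the between-spot SD
    is the per-chip error bar.
    """
    scope = inner_positions(layout) if inner_only else set(layout.roles)
    by_role: dict[SpotRole, list[float]] = {}
    for m in measurements:
        if m.grid_position in scope:
            by_role.setdefault(m.role, []).append(m.median_luminance)
    out: dict[SpotRole, RoleAggregate] = {}
    for role, values in by_role.items():
        arr = np.asarray(values, dtype=np.float64)
        sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
        out[role] = RoleAggregate(
            role=role,
            mean_luminance=float(arr.mean()),
            sd_luminance=sd,
            n_spots=len(arr),
        )
    missing = [r for r in SpotRole if r not in out]
    if missing:
        raise QuantError(
            f"roles absent from aggregation scope: {[r.value for r in missing]}"
        )
    return out


def normalize_chip(
    aggregates: dict[SpotRole, RoleAggregate],
) -> tuple[dict[SpotRole, float], dict[str, float]]:
    """Background-subtract and normalize against the positive control.

    Returns (normalized values per role, qc block). Fails chip QC when the
    positive-control mean does not exceed the background: the positive
    control monitors whether fluorescence labelling worked at all.
    """
    if SpotRole.POS not in aggregates or SpotRole.NEG not in aggregates:
        raise QuantError("normalization needs POS and NEG aggregates")
    pos = aggregates[SpotRole.POS].mean_luminance
    neg = aggregates[SpotRole.NEG].mean_luminance
    if pos <= neg:
        raise QCError(
            "chip QC failure: positive control not above background "
            f"(POS mean {pos:.3f} <= NEG mean {neg:.3f})"
        )
    span = pos - neg
    normalized = {
        role: (agg.mean_luminance - neg) / span for role, agg in aggregates.items()
    }
    qc = {"pos_mean": pos, "neg_mean": neg, "pos_minus_neg": span}
    return normalized, qc


def combine_runs(values: list[float], decimals: int = 3) -> float:
    """Average replicate measurements, rounded half away from zero.

    Exact decimal arithmetic is used so the reported 3-decimal averages
    follow the half-away-from-zero convention regardless of binary float
    representation (e.g. mean(0.004, -0.007) = -0.0015 -> -0.002).
    """
    if not values:
        raise QuantError("combine_runs needs at least one value")
    total = sum(Decimal(repr(float(v))) for v in values)
    mean = total / len(values)
    quantum = Decimal(1).scaleb(-decimals)
    return float(mean.quantize(quantum, rounding=ROUND_HALF_UP))


def analyze_chip(
    image_path: str | Path,
    layout: ArrayLayout | None = None,
    config: AnalysisConfig | None = None,
) -> ChipResult:
    """Full pipeline: load -> luminance -> standardize -> measure -> normalize.

    Deterministic for fixed inputs and configuration.
    """
    from .geometry import standardize
    from .imaging import load_image, to_luminance
    from .layout import build_default_layout

    if layout is None:
        layout = build_default_layout()
    if config is None:
        config = AnalysisConfig()
    img = load_image(image_path)
    if img.ndim == 3:
        img = to_luminance(img, config.luminance_mode)
    standardized = standardize(img, layout, config)
    measurements = measure_grid(standardized, layout)
    aggregates = aggregate(measurements, layout, config.inner_only)
    normalized, qc = normalize_chip(aggregates)
    return ChipResult(
        measurements=tuple(measurements),
        aggregates=aggregates,
        normalized=normalized,
        qc=qc,
    )


def biomarker_values(result: ChipResult) -> dict[str, float]:
    """Normalized readouts of the biomarker roles only."""
    return {
        role.value: result.normalized[role]
        for role in BIOMARKER_ROLES
        if role in result.normalized
    }
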