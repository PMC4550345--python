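"""Synthetic smartphone-like microarray scenes with known ground truth.

No public raw chip images exist for this assay, so every pipeline stage is
validated against rendered scenes that emulate what the phone camera sees:
a 6x8 grid of flat elliptical spots (contact-printed plateaus) blurred at
the edges, bright positive controls, background-level negative controls,
intermediate biomarker spots, a sloped-and-vignetted background, a global
affine aberration (rotation/shear/scale/translation from chip seating) plus
a smooth quadratic "bow", sensor read noise and signal-proportional shot
noise, with the quantum-dot signal confined to the red channel.

The renderer records exact post-aberration spot centroids and the true
normalized value of every biomarker role, so recovery can be scored
end to end.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError
from .layout import (
    ArrayLayout,
    SpotRole,
    build_default_layout,
    reference_centroids,
)

#: Default per-role spot amplitudes (luminance units above background).
DEFAULT_AMPLITUDES = {
    SpotRole.POS: 180.0,
    SpotRole.NEG: 4.0,
    SpotRole.RBST: 120.0,
    SpotRole.IGF1_100: 60.0,
    SpotRole.IGF1_250: 90.0,
}


@dataclass(frozen=True)
class Aberration:
    """Geometric distortion applied to reference coordinates.

    The affine part (rotation, shear, anisotropic scale, translation) acts
    about the grid center; the quadratic part adds a bow displacement
    ``dx += bow_x * (y - cy)^2``, ``dy += bow_y * (x - cx)^2`` (units
    px^-1), emulating the slightly curved images from the simple lens.
    """

    rotation_deg: float = 0.0
    shear_deg: float = 0.0
    scale_x: float = 1.0
    scale_y: float = 1.0
    translation: tuple[float, float] = (0.0, 0.0)
    bow: tuple[float, float] = (0.0, 0.0)
    center: tuple[float, float] = (170.0, 130.0)

    def linear_matrix(self) -> np.ndarray:
        th = np.deg2rad(self.rotation_deg)
        sh = np.tan(np.deg2rad(self.shear_deg))
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shear = np.array([[1.0, sh], [0.0, 1.0]])
        scale = np.diag([self.scale_x, self.scale_y])
        return rot @ shear @ scale

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map reference (x, y) points to image coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        cx, cy = self.center
        rel = xy - (cx, cy)
        out = rel @ self.linear_matrix().T + (cx, cy) + self.translation
        bx, by = self.bow
        out[:, 0] += bx * (xy[:, 1] - cy) ** 2
        out[:, 1] += by * (xy[:, 0] - cx) ** 2
        return out


@dataclass(frozen=True)
class SceneSpec:
    """Complete description of one synthetic chip image."""

    layout: ArrayLayout = field(default_factory=build_default_layout)
    amplitudes: dict[SpotRole, float] = field(
        default_factory=lambda: dict(DEFAULT_AMPLITUDES)
    )
    spot_overrides: dict[tuple[int, int], float] = field(default_factory=dict)
    spot_scale: float = 1.25  # rendered spot semi-axes / ROI semi-axes
    blur_sigma: float = 1.5  # px, edge softness of the printed plateau
    background_base: float = 20.0
    background_gradient: tuple[float, float] = (0.01, 0.015)  # per px, (x, y)
    vignette_strength: float = 6.0  # luminance drop at the frame corner
    aberration: Aberration = field(default_factory=Aberration)
    noise_sd: float = 3.0  # additive read noise
    noise_scale: float = 0.05  # signal-proportional (shot) noise
    green_bleed: float = 0.10  # fraction of signal leaking to green
    image_shape: tuple[int, int] = (360, 440)  # (height, width)
    seed: int = 0

    def __post_init__(self) -> None:
        peak = max(self.amplitudes.values(), default=0.0)
        if self.spot_overrides:
            peak = max(peak, max(self.spot_overrides.values()))
        h, w = self.image_shape
        bg_max = (
            self.background_base
            + abs(self.background_gradient[0]) * w
            + abs(self.background_gradient[1]) * h
        )
        if peak + bg_max > 255.0:
            raise ConfigError(
                "amplitudes + background exceed 255 pre-noise "
                f"({peak + bg_max:.1f})"
            )
        if min(self.amplitudes.values(), default=0.0) < 0:
            raise ConfigError("amplitudes must be non-negative")
        _check_invertible(self.aberration, self.image_shape)

    def amplitude_at(self, pos: tuple[int, int]) -> float:
        if pos in self.spot_overrides:
            return self.spot_overrides[pos]
        return self.amplitudes[self.layout.roles[pos]]


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth recorded at render time."""

    centroids: dict[tuple[int, int], tuple[float, float]]  # image coords
    amplitudes: dict[tuple[int, int], float]
    normalized: dict[SpotRole, float]


def _check_invertible(aberration: Aberration, image_shape: tuple[int, int]) -> None:
    """Verify the aberration's Jacobian stays orientation-preserving."""
    h, w = image_shape
    xs = np.linspace(0, w - 1, 12)
    ys = np.linspace(0, h - 1, 12)
    gx, gy = np.meshgrid(xs, ys)
    lin = aberration.linear_matrix()
    bx, by = aberration.bow
    cx, cy = aberration.center
    # d(out)/d(ref) = lin + bow terms
    j00 = lin[0, 0]
    j11 = lin[1, 1]
    j01 = lin[0, 1] + 2 * bx * (gy - cy)
    j10 = lin[1, 0] + 2 * by * (gx - cx)
    det = j00 * j11 - j01 * j10
    if not np.all(det > 0.05):
        raise ConfigError(
            "aberration too strong: quadratic bow makes the coordinate map "
            "non-invertible over the image"
        )


def true_normalized(spec: SceneSpec) -> dict[SpotRole, float]:
    """Per-role truth: (amp_role - amp_NEG) / (amp_POS - amp_NEG)."""
    amp = spec.amplitudes
    span = amp[SpotRole.POS] - amp[SpotRole.NEG]
    if span == 0:  # degenerate scene (e.g. background-only): truth undefined
        return {role: float("nan") for role in SpotRole}
    return {role: (amp[role] - amp[SpotRole.NEG]) / span for role in SpotRole}


def render(spec: SceneSpec) -> tuple[np.ndarray, SceneTruth]:
    """Render the scene; returns (RGB uint8-scale float image, truth).

    Reference-grid spots are drawn as flat ellipses (axes transformed by
    the aberration's linear part) at their aberration-mapped centroids,
    blurred, laid over the background, and degraded with seeded noise.
    Identical specs render identical images.
    """
    layout = spec.layout
    h, w = spec.image_shape
    refs = reference_centroids(layout)
    positions = sorted(refs)
    ref_xy = np.asarray([refs[p] for p in positions])
    img_xy = spec.aberration.apply(ref_xy)

    a, b = layout.ellipse_semi_axes
    a *= spec.spot_scale
    b *= spec.spot_scale
    lin = spec.aberration.linear_matrix()
    lin_inv = np.linalg.inv(lin)

    signal = np.zeros((h, w), dtype=np.float64)
    centroids: dict[tuple[int, int], tuple[float, float]] = {}
    amplitudes: dict[tuple[int, int], float] = {}
    # local extent of the mapped ellipse, for the per-spot raster window
    extent = float(np.abs(lin @ np.diag([a, b])).sum(axis=1).max()) + 2.0
    for pos, (cx, cy) in zip(positions, img_xy):
        amp = spec.amplitude_at(pos)
        centroids[pos] = (float(cx), float(cy))
        amplitudes[pos] = amp
        if amp <= 0:
            continue
        x_lo, x_hi = int(np.floor(cx - extent)), int(np.ceil(cx + extent))
        y_lo, y_hi = int(np.floor(cy - extent)), int(np.ceil(cy + extent))
        x_lo, x_hi = max(0, x_lo), min(w - 1, x_hi)
        y_lo, y_hi = max(0, y_lo), min(h - 1, y_hi)
        if x_lo > x_hi or y_lo > y_hi:
            continue
        gy, gx = np.mgrid[y_lo : y_hi + 1, x_lo : x_hi + 1]
        rel = np.stack([gx - cx, gy - cy], axis=-1) @ lin_inv.T
        inside = (rel[..., 0] / a) ** 2 + (rel[..., 1] / b) ** 2 <= 1.0
        window = signal[y_lo : y_hi + 1, x_lo : x_hi + 1]
        np.maximum(window, np.where(inside, amp, 0.0), out=window)

    if spec.blur_sigma > 0:
        signal = ndimage.gaussian_filter(signal, spec.blur_sigma)

    gy, gx = np.mgrid[0:h, 0:w].astype(np.float64)
    gx_frac = gx / max(w - 1, 1)
    gy_frac = gy / max(h - 1, 1)
    background = (
        spec.background_base
        + spec.background_gradient[0] * gx
        + spec.background_gradient[1] * gy
        - spec.vignette_strength
        * ((gx_frac - 0.5) ** 2 + (gy_frac - 0.5) ** 2)
        / 0.5
    )

    rng = np.random.default_rng(spec.seed)
    channels = []
    for gain_signal, gain_bg in (
        (1.0, 1.0),  # red: QD emission + background
        (spec.green_bleed, 0.4),  # green: bleed + partial background
        (0.0, 0.2),  # blue: background only
    ):
        plane = gain_signal * signal + gain_bg * background
        if spec.noise_sd > 0 or spec.noise_scale > 0:
            plane = (
                plane
                + rng.normal(0.0, spec.noise_sd, size=plane.shape)
                + rng.normal(0.0, 1.0, size=plane.shape)
                * spec.noise_scale
                * plane
            )
        channels.append(plane)
    rgb = np.clip(np.stack(channels, axis=-1), 0.0, 255.0)
    rgb = np.round(rgb)  # 8-bit camera quantization

    truth = SceneTruth(
        centroids=centroids,
        amplitudes=amplitudes,
        normalized=true_normalized(spec),
    )
    return rgb, truth


def scene_ladder(
    seed: int,
    n_chips: int,
    truth_range: tuple[float, float] = (0.0, 1.0),
    noise_sd: float = 3.0,
) -> list[SceneSpec]:
    """Chips whose biomarker truth values evenly span ``truth_range``.

    Each chip gets a randomized mild aberration (shear <= 8 deg, bow
    displacing corners <= 6 px, small rotation/scale/translation) drawn
    from the given seed. All three biomarker roles share the chip's truth
    value. Used for end-to-end parameter-recovery checks.
    """
    if n_chips < 1:
        raise ConfigError("n_chips must be >= 1")
    rng = np.random.default_rng(seed)
    truths = (
        np.linspace(truth_range[0], truth_range[1], n_chips)
        if n_chips > 1
        else np.asarray([np.mean(truth_range)])
    )
    base = dict(DEFAULT_AMPLITUDES)
    span = base[SpotRole.POS] - base[SpotRole.NEG]
    specs: list[SceneSpec] = []
    for t in truths:
        amp_bio = base[SpotRole.NEG] + float(t) * span
        amplitudes = {
            SpotRole.POS: base[SpotRole.POS],
            SpotRole.NEG: base[SpotRole.NEG],
            SpotRole.RBST: amp_bio,
            SpotRole.IGF1_100: amp_bio,
            SpotRole.IGF1_250: amp_bio,
        }
        # corner bow displacement <= 6 px: |bow| * 170^2 <= 6
        bow_limit = 6.0 / 170.0**2
        aberration = Aberration(
            rotation_deg=float(rng.uniform(-3.0, 3.0)),
            shear_deg=float(rng.uniform(-8.0, 8.0)),
            scale_x=float(rng.uniform(0.95, 1.05)),
            scale_y=float(rng.uniform(0.95, 1.05)),
            translation=(
                float(rng.uniform(-10.0, 10.0)),
                float(rng.uniform(-10.0, 10.0)),
            ),
            bow=(
                float(rng.uniform(-bow_limit, bow_limit)),
                float(rng.uniform(-bow_limit, bow_limit)),
            ),
        )
        specs.append(
            SceneSpec(
                amplitudes=amplitudes,
                aberration=aberration,
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return specs


def truth_to_json(truth: SceneTruth) -> str:
    """Serialize truth deterministically (sorted keys, fixed precision)."""
    data = {
        "centroids": {
            f"{r},{c}": [round(x, 6), round(y, 6)]
            for (r, c), (x, y) in sorted(truth.centroids.items())
        },
        "amplitudes": {
            f"{r},{c}": v for (r, c), v in sorted(truth.amplitudes.items())
        },
        "normalized": {
            role.value: round(v, 9) for role, v in sorted(
                truth.normalized.items(), key=lambda kv: kv[0].value
            )
        },
    }
    return json.dumps(data, indent=2, sort_keys=True)
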