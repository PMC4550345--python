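"""Two-stage geometric correction.

Smartphone images of the chip show spatial aberrations: shear / rotation /
scale / translation from imperfect chip seating, plus a smooth curvature
from the simple lens. Correction runs in two stages, each fitted on the
detected positive-control centroids:

1. an affine transform (6 coefficients) removes the linear part and the
   image is cut to the spot area;
2. a quadratic polynomial transform (12 coefficients) removes the residual
   curvature, leaving every spot centroid on the regular standardized grid.

Both fits map detected image coordinates to reference (standardized)
coordinates. Resampling uses the numerically inverted map: closed-form for
the affine, per-pixel Newton iteration seeded at the affine-part inverse
for the quadratic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from . import detection
from .errors import DetectionError, GeometryError
from .layout import ArrayLayout, reference_centroids


@dataclass(frozen=True)
class AffineTransform:
    """2-D affine map ``(x, y) -> (a x + b y + c, d x + e y + f)``."""

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def __post_init__(self) -> None:
        if abs(self.determinant) < 1e-12:
            raise GeometryError("affine transform is singular")

    @property
    def determinant(self) -> float:
        return self.a * self.e - self.b * self.d

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 0.0, 1.0, 0.0)

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (N, 2) array of points."""
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        x, y = xy[:, 0], xy[:, 1]
        return np.column_stack(
            [self.a * x + self.b * y + self.c, self.d * x + self.e * y + self.f]
        )

    def invert(self) -> "AffineTransform":
        det = self.determinant
        ia, ib = self.e / det, -self.b / det
        id_, ie = -self.d / det, self.a / det
        return AffineTransform(
            ia, ib, -(ia * self.c + ib * self.f),
            id_, ie, -(id_ * self.c + ie * self.f),
        )


@dataclass(frozen=True)
class QuadraticTransform:
    """Degree-2 polynomial map over the monomial basis {1, x, y, x^2, xy, y^2}.

    ``px`` and ``py`` hold the six coefficients of the x' and y' outputs in
    basis order. With the quadratic coefficients zero it reduces to an
    affine transform.
    """

    px: tuple[float, float, float, float, float, float]
    py: tuple[float, float, float, float, float, float]

    def __post_init__(self) -> None:
        coeffs = np.array(self.px + self.py, dtype=np.float64)
        if not np.all(np.isfinite(coeffs)):
            raise GeometryError("quadratic transform has non-finite coefficients")

    def apply(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=np.float64))
        basis = _quad_basis(xy[:, 0], xy[:, 1])
        return np.column_stack(
            [basis @ np.asarray(self.px), basis @ np.asarray(self.py)]
        )

    def affine_part(self) -> AffineTransform:
        return AffineTransform(
            self.px[1], self.px[2], self.px[0],
            self.py[1], self.py[2], self.py[0],
        )

    def jacobian(self, x: np.ndarray, y: np.ndarray):
        """Per-point 2x2 Jacobian entries (dxdx, dxdy, dydx, dydy)."""
        p, q = self.px, self.py
        return (
            p[1] + 2 * p[3] * x + p[4] * y,
            p[2] + p[4] * x + 2 * p[5] * y,
            q[1] + 2 * q[3] * x + q[4] * y,
            q[2] + q[4] * x + 2 * q[5] * y,
        )


@dataclass(frozen=True)
class CropWindow:
    """Pixel window ``(x_min, y_min, x_max, y_max)``, max edges exclusive."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise GeometryError("crop window has zero area")


def _quad_basis(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def estimate_affine(
    pairs: list[tuple[tuple[float, float], tuple[float, float]]],
) -> AffineTransform:
    """Least-squares affine fit from (source, target) point pairs.

    Minimizes the summed squared distance between mapped sources and
    targets; with exactly three non-collinear pairs the fit interpolates.
    Needs at least three pairs with non-collinear sources.
    """
    if len(pairs) < 3:
        raise GeometryError(
            f"underdetermined affine: need >= 3 pairs, got {len(pairs)}"
        )
    src = np.asarray([p[0] for p in pairs], dtype=np.float64)
    dst = np.asarray([p[1] for p in pairs], dtype=np.float64)
    design = np.column_stack([src[:, 0], src[:, 1], np.ones(len(pairs))])
    if np.linalg.matrix_rank(design, tol=1e-9) < 3:
        raise GeometryError("underdetermined affine: source points are collinear")
    coef_x, *_ = np.linalg.lstsq(design, dst[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, dst[:, 1], rcond=None)
    return AffineTransform(
        coef_x[0], coef_x[1], coef_x[2], coef_y[0], coef_y[1], coef_y[2]
    )


def fit_quadratic(
    pairs: list[tuple[tuple[float, float], tuple[float, float]]],
) -> QuadraticTransform:
    """Least-squares degree-2 polynomial fit from (source, target) pairs.

    x' and y' are fitted independently over {1, x, y, x^2, xy, y^2}. Needs
    at least six pairs with a full-rank design; with exactly six
    rank-complete pairs the fit interpolates.
    """
    if len(pairs) < 6:
        raise GeometryError(
            f"underdetermined quadratic: need >= 6 pairs, got {len(pairs)}"
        )
    src = np.asarray([p[0] for p in pairs], dtype=np.float64)
    dst = np.asarray([p[1] for p in pairs], dtype=np.float64)
    design = _quad_basis(src[:, 0], src[:, 1])
    # rank tolerance scaled to the design magnitude (x^2 terms dominate)
    tol = 1e-9 * max(1.0, float(np.abs(design).max()))
    if np.linalg.matrix_rank(design, tol=tol) < 6:
        raise GeometryError("underdetermined quadratic: rank-deficient design")
    coef_x, *_ = np.linalg.lstsq(design, dst[:, 0], rcond=None)
    coef_y, *_ = np.linalg.lstsq(design, dst[:, 1], rcond=None)
    return QuadraticTransform(tuple(coef_x), tuple(coef_y))


def _invert_quadratic_grid(
    transform: QuadraticTransform,
    xt: np.ndarray,
    yt: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 20,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Solve T(x, y) = (xt, yt) per pixel by Newton iteration.

    Seeded at the inverse of the transform's affine part. Returns
    (x, y, converged) arrays of the target shape.
    """
    seed_aff = transform.affine_part().invert()
    seeded = seed_aff.apply(np.column_stack([xt.ravel(), yt.ravel()]))
    x = seeded[:, 0].copy()
    y = seeded[:, 1].copy()
    txt, tyt = xt.ravel(), yt.ravel()
    active = np.ones(x.shape, dtype=bool)
    for _ in range(max_iter):
        out = transform.apply(np.column_stack([x, y]))
        rx = out[:, 0] - txt
        ry = out[:, 1] - tyt
        err = np.hypot(rx, ry)
        active = err > tol
        if not active.any():
            break
        jxx, jxy, jyx, jyy = transform.jacobian(x[active], y[active])
        det = jxx * jyy - jxy * jyx
        det = np.where(np.abs(det) < 1e-12, np.nan, det)
        dx = (jyy * rx[active] - jxy * ry[active]) / det
        dy = (-jyx * rx[active] + jxx * ry[active]) / det
        x[active] -= dx
        y[active] -= dy
    out = transform.apply(np.column_stack([x, y]))
    converged = np.hypot(out[:, 0] - txt, out[:, 1] - tyt) <= tol
    converged &= np.isfinite(x) & np.isfinite(y)
    shape = xt.shape
    return x.reshape(shape), y.reshape(shape), converged.reshape(shape)


def warp_image(
    img: np.ndarray,
    transform: AffineTransform | QuadraticTransform,
    out_shape: tuple[int, int],
    interpolation: str = "bilinear",
) -> np.ndarray:
    """Resample ``img`` under ``transform`` (input -> output coordinates).

    Each output pixel takes the interpolated input value at the
    inverse-mapped coordinate; coordinates falling outside the input are
    filled with 0 (dark fluorescence background). ``interpolation`` is
    ``bilinear`` (default) or ``nearest``.
    """
    if interpolation not in ("bilinear", "nearest"):
        raise GeometryError(f"unknown interpolation {interpolation!r}")
    order = 1 if interpolation == "bilinear" else 0
    h, w = out_shape
    yt, xt = np.mgrid[0:h, 0:w].astype(np.float64)
    if isinstance(transform, AffineTransform):
        inv = transform.invert()
        src = inv.apply(np.column_stack([xt.ravel(), yt.ravel()]))
        xs = src[:, 0].reshape(out_shape)
        ys = src[:, 1].reshape(out_shape)
    else:
        xs, ys, converged = _invert_quadratic_grid(transform, xt, yt)
        bad = ~converged
        if bad.mean() > 0.01:
            raise GeometryError(
                "non-invertible warp over domain: inverse iteration failed "
                f"for {bad.mean():.1%} of pixels"
            )
        xs = np.where(bad, -1.0, xs)
        ys = np.where(bad, -1.0, ys)
    img = np.asarray(img, dtype=np.float64)
    return ndimage.map_coordinates(
        img, [ys, xs], order=order, mode="constant", cval=0.0, prefilter=False
    )


def crop_to_spots(
    img: np.ndarray,
    match: "detection.AnchorMatch",
    layout: ArrayLayout,
    margin_frac: float = 0.75,
) -> tuple[np.ndarray, CropWindow]:
    """Cut the image to the area containing the spot grid.

    The reference grid is mapped back into image coordinates through the
    inverse of the affine fitted on the anchor match; the crop window is
    that grid's bounding box extended by ``margin_frac * pitch`` on each
    side and clamped to the image bounds.
    """
    refs_by_pos = reference_centroids(layout)
    affine = estimate_affine(
        [(centroid, refs_by_pos[pos]) for pos, centroid in match.pairs]
    )
    inv = affine.invert()
    refs = np.asarray(list(reference_centroids(layout).values()))
    mapped = np.round(inv.apply(refs), 6)  # absorb lsq round-off before floor/ceil
    mx = margin_frac * layout.pitch_col
    my = margin_frac * layout.pitch_row
    h, w = img.shape
    x_min = int(np.floor(max(0.0, mapped[:, 0].min() - mx)))
    y_min = int(np.floor(max(0.0, mapped[:, 1].min() - my)))
    x_max = int(np.ceil(min(float(w), mapped[:, 0].max() + mx + 1)))
    y_max = int(np.ceil(min(float(h), mapped[:, 1].max() + my + 1)))
    window = CropWindow(x_min, y_min, x_max, y_max)
    return img[y_min:y_max, x_min:x_max], window


def standardized_shape(
    layout: ArrayLayout, margin_frac: float = 0.75
) -> tuple[int, int]:
    """Canvas shape of the standardized image.

    The canvas keeps the standardized coordinate origin at pixel (0, 0) so
    spot centroids land exactly on ``reference_centroids(layout)``; it
    extends ``margin_frac * pitch`` past the last grid line.
    """
    ox, oy = layout.origin
    x_max = ox + (layout.n_cols - 1) * layout.pitch_col + margin_frac * layout.pitch_col
    y_max = oy + (layout.n_rows - 1) * layout.pitch_row + margin_frac * layout.pitch_row
    return int(np.ceil(y_max)) + 1, int(np.ceil(x_max)) + 1


def standardize(
    img: np.ndarray,
    layout: ArrayLayout,
    config: "AnalysisConfig | None" = None,
) -> np.ndarray:
    """Full two-stage geometric correction onto the standardized grid.

    Pipeline: threshold -> blob detection -> anchor matching -> affine fit
    on matched positive controls -> warp/crop to the standardized canvas ->
    re-detect positive controls in the corrected image -> quadratic
    polynomial fit -> final warp. The result is an image in standardized
    coordinates where spot centroids sit at ``reference_centroids(layout)``.
    """
    from .config import AnalysisConfig

    if config is None:
        config = AnalysisConfig()
    refs = reference_centroids(layout)
    out_shape = standardized_shape(layout, config.margin_frac)

    # stage 1: detect anchors in the raw image, fit + apply the affine
    match = _detect_anchors(img, layout, config)
    pairs = [
        (centroid, refs[pos]) for pos, centroid in match.pairs
    ]
    affine = estimate_affine(pairs)
    corrected = warp_image(img, affine, out_shape, config.interpolation)

    # stage 2: re-detect in the corrected crop, fit + apply the quadratic
    match2 = _detect_anchors(corrected, layout, config)
    if len(match2.pairs) < 6:
        raise GeometryError(
            "quadratic fit needs >= 6 matched positive controls, "
            f"got {len(match2.pairs)} after affine correction"
        )
    pairs2 = [(centroid, refs[pos]) for pos, centroid in match2.pairs]
    quad = fit_quadratic(pairs2)
    return warp_image(corrected, quad, out_shape, config.interpolation)


def _detect_anchors(
    img: np.ndarray, layout: ArrayLayout, config: "AnalysisConfig"
) -> "detection.AnchorMatch":
    """Threshold, find blobs and match them to POS reference positions."""
    thr_value = config.threshold_value
    if config.threshold_method == "quantile" and thr_value is None:
        thr_value = detection.default_quantile(layout, img)
    mask = detection.threshold_mask(img, config.threshold_method, thr_value)
    min_area = config.resolve_min_area(layout)
    blobs = detection.find_blobs(mask, min_area)
    if len(blobs) < 4:
        raise DetectionError(
            f"insufficient anchors: found {len(blobs)} blobs "
            f"(threshold {config.threshold_method}, min_area {min_area})"
        )
    return detection.match_anchors(blobs, layout)
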