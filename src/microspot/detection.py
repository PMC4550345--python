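"""Bright-spot detection and anchor matching.

The sheep-IgG positive controls are always fluorescently labelled, so they
appear as bright connected regions wherever the chip sits in the frame.
They are found by thresholding and 8-connected component labeling, then
matched to the layout's POS positions: the four most corner-ward blobs are
assigned to the four corner POS spots (orientation-preserving), a
provisional affine is fitted on those four pairs, and the remaining blobs
are greedily matched to the nearest mapped POS reference within a radius of
0.4x the grid pitch. Negative controls are background-level by design and
are never used as anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigError, DetectionError
from .layout import ArrayLayout, SpotRole, reference_centroids

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)

#: Matching radius as a fraction of the smaller grid pitch.
MATCH_RADIUS_FRAC = 0.4


@dataclass(frozen=True)
class Blob:
    """A connected bright region."""

    centroid: tuple[float, float]  # (x, y), sub-pixel
    area: int
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max), inclusive

    def __post_init__(self) -> None:
        x, y = self.centroid
        x0, y0, x1, y1 = self.bbox
        if self.area < 1:
            raise DetectionError("blob area must be >= 1")
        if not (x0 - 0.5 <= x <= x1 + 0.5 and y0 - 0.5 <= y <= y1 + 0.5):
            raise DetectionError("blob centroid outside its bounding box")


@dataclass(frozen=True)
class AnchorMatch:
    """Blob-to-grid-position correspondences for the positive controls.

    ``pairs`` maps grid positions to detected centroids (each used at most
    once); ``residual`` is the RMS distance between mapped blobs and their
    reference centroids under the provisional affine, in standardized px.
    """

    pairs: tuple[tuple[tuple[int, int], tuple[float, float]], ...]
    residual: float

    def __post_init__(self) -> None:
        positions = [p for p, _ in self.pairs]
        centroids = [c for _, c in self.pairs]
        if len(set(positions)) != len(positions):
            raise DetectionError("anchor match reuses a grid position")
        if len(set(centroids)) != len(centroids):
            raise DetectionError("anchor match reuses a detected centroid")


def default_quantile(layout: ArrayLayout, img: np.ndarray) -> float:
    """Layout- and image-adaptive default threshold quantile.

    Floor: 1 - 1.5x the expected spot fraction (total ellipse-ROI area of
    the layout over the image area), so the threshold adapts to how much of
    the frame the array fills and survives global brightness shifts from
    variable LED intensity. On a sparsely lit chip (e.g. only the controls
    bright) that occupancy quantile would land inside the smooth background
    and flood the mask, so the quantile is raised to the fraction of pixels
    below the midpoint between the background level (median) and the bright
    peak (99.5th percentile).
    """
    a, b = layout.ellipse_semi_axes
    spot_area = np.pi * a * b * layout.n_spots
    frac = spot_area / img.size
    occupancy_q = 1.0 - 1.5 * frac
    midpoint = 0.5 * (np.median(img) + np.quantile(img, 0.995))
    midpoint_q = float(np.mean(img <= midpoint))
    return float(np.clip(max(occupancy_q, midpoint_q), 0.5, 0.995))


def threshold_mask(
    img: np.ndarray, method: str = "quantile", value: float | None = None
) -> np.ndarray:
    """Binary mask of "illuminating" pixels.

    ``fixed`` keeps pixels >= value (value in [0, 255]); ``quantile`` keeps
    pixels strictly above the given intensity quantile (value in (0, 1));
    ``otsu`` uses Otsu's bimodal split and rejects constant images.
    """
    img = np.asarray(img, dtype=np.float64)
    if method == "fixed":
        if value is None or not 0 <= value <= 255:
            raise ConfigError("fixed threshold requires a value in [0, 255]")
        return img >= value
    if method == "quantile":
        if value is None or not 0 < value < 1:
            raise ConfigError("quantile threshold requires a value in (0, 1)")
        return img > np.quantile(img, value)
    if method == "otsu":
        if np.ptp(img) == 0:
            raise DetectionError(
                "no bimodal separation: image is constant, cannot apply Otsu"
            )
        return img > threshold_otsu(img)
    raise ConfigError(f"unknown threshold method {method!r}")


def find_blobs(mask: np.ndarray, min_area: int = 1) -> list[Blob]:
    """8-connected components of the mask with area >= min_area.

    Centroids are the unweighted mean of member pixel coordinates. Blobs
    are returned sorted by centroid (y, then x), so the output is
    independent of labeling order.
    """
    if min_area < 1:
        raise ConfigError("min_area must be >= 1")
    labels, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_EIGHT_CONNECTED)
    if n == 0:
        return []
    areas = np.bincount(labels.ravel())[1:]
    keep = np.flatnonzero(areas >= min_area) + 1
    blobs: list[Blob] = []
    objects = ndimage.find_objects(labels)
    for lab in keep:
        sl_y, sl_x = objects[lab - 1]
        member_y, member_x = np.nonzero(labels[sl_y, sl_x] == lab)
        cy = float(member_y.mean() + sl_y.start)
        cx = float(member_x.mean() + sl_x.start)
        blobs.append(
            Blob(
                centroid=(cx, cy),
                area=int(areas[lab - 1]),
                bbox=(sl_x.start, sl_y.start, sl_x.stop - 1, sl_y.stop - 1),
            )
        )
    blobs.sort(key=lambda b: (b.centroid[1], b.centroid[0]))
    return blobs


def _corner_candidates(
    blobs: list[Blob],
) -> dict[tuple[int, int], Blob]:
    """Pick the 4 blobs extreme in the 4 quadrant directions.

    Returns a mapping from direction sign pair (sx, sy) to the blob
    maximizing ``sx*(x - cx) + sy*(y - cy)`` about the blob-cloud centroid.
    Raises on ambiguity (two blobs within 1 px of the same corner score) or
    if fewer than four distinct blobs are selected.
    """
    pts = np.asarray([b.centroid for b in blobs], dtype=np.float64)
    center = pts.mean(axis=0)
    rel = pts - center
    chosen: dict[tuple[int, int], Blob] = {}
    for sx, sy in ((-1, -1), (1, -1), (-1, 1), (1, 1)):
        scores = sx * rel[:, 0] + sy * rel[:, 1]
        order = np.argsort(scores)[::-1]
        if len(order) > 1 and scores[order[0]] - scores[order[1]] < 1.0:
            raise DetectionError(
                "degenerate anchor geometry: ambiguous corner candidate "
                f"in direction ({sx}, {sy})"
            )
        chosen[(sx, sy)] = blobs[int(order[0])]
    if len({b.centroid for b in chosen.values()}) < 4:
        raise DetectionError(
            "degenerate anchor geometry: corner candidates are not distinct"
        )
    return chosen


def match_anchors(blobs: list[Blob], layout: ArrayLayout) -> AnchorMatch:
    """Match detected blobs to the layout's positive-control positions.

    Corner-first strategy: the four quadrant-extreme blobs are assigned to
    the four corner POS positions preserving orientation (the top-left
    corner pairs with the blob extreme in the (-x, -y) direction, and so
    on); a provisional affine fitted on those four pairs maps every blob to
    standardized coordinates, where remaining blobs greedily claim the
    nearest unclaimed POS reference within 0.4x the minimum pitch.
    Unmatched POS references are allowed.
    """
    from .geometry import estimate_affine  # deferred: geometry imports this module

    if len(blobs) < 4:
        raise DetectionError(
            f"insufficient anchors: need >= 4 blobs, got {len(blobs)}"
        )
    refs = reference_centroids(layout)
    corner_refs = {
        (-1, -1): (0, 0),
        (1, -1): (0, layout.n_cols - 1),
        (-1, 1): (layout.n_rows - 1, 0),
        (1, 1): (layout.n_rows - 1, layout.n_cols - 1),
    }
    corners = _corner_candidates(blobs)
    corner_pairs = [
        (corners[d].centroid, refs[corner_refs[d]]) for d in corner_refs
    ]
    provisional = estimate_affine(corner_pairs)

    pos_positions = layout.positions_with_role(SpotRole.POS)
    pos_xy = np.asarray([refs[p] for p in pos_positions], dtype=np.float64)
    mapped = provisional.apply(np.asarray([b.centroid for b in blobs]))
    radius = MATCH_RADIUS_FRAC * min(layout.pitch_row, layout.pitch_col)

    dists = np.linalg.norm(mapped[:, None, :] - pos_xy[None, :, :], axis=2)
    candidates = np.argwhere(dists <= radius)
    order = np.argsort(dists[candidates[:, 0], candidates[:, 1]], kind="stable")
    used_blobs: set[int] = set()
    used_refs: set[int] = set()
    pairs: list[tuple[tuple[int, int], tuple[float, float]]] = []
    sq_err: list[float] = []
    for bi, ri in candidates[order]:
        if bi in used_blobs or ri in used_refs:
            continue
        used_blobs.add(int(bi))
        used_refs.add(int(ri))
        pairs.append((pos_positions[ri], blobs[bi].centroid))
        sq_err.append(float(dists[bi, ri] ** 2))
    if len(pairs) < 3:
        raise DetectionError(
            f"insufficient anchors: only {len(pairs)} blobs matched a "
            "positive-control position"
        )
    pairs.sort(key=lambda pc: pc[0])
    residual = float(np.sqrt(np.mean(sq_err)))
    return AnchorMatch(pairs=tuple(pairs), residual=residual)


def blob_table(blobs: list[Blob], match: AnchorMatch | None = None):
    """Blob summary as a pandas DataFrame (debug CSV output)."""
    import pandas as pd

    matched = {c: p for p, c in (match.pairs if match else ())}
    rows = []
    for b in blobs:
        pos = matched.get(b.centroid)
        rows.append(
            {
                "centroid_x": b.centroid[0],
                "centroid_y": b.centroid[1],
                "area": b.area,
                "matched_grid_row": pos[0] if pos else None,
                "matched_grid_col": pos[1] if pos else None,
            }
        )
    return pd.DataFrame(rows)
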