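"""Microarray layout model.

The chip carries a regular grid of protein spots. Five spot roles exist:
three biomarker conditions (rbST capture spots and anti-IGF-1 spots printed
at 100 and 250 ug/mL) plus sheep-IgG positive controls (always labelled;
used for geometry and normalization) and ovalbumin negative controls
(background reference). The canonical chip is a 6-row x 8-column grid of 48
spots: 6 replicates of each biomarker condition and 15 replicates of each
control, with the outer ring containing only controls and the four corners
positive controls so they can anchor the geometric correction.

Coordinate convention used throughout the package: x runs along columns,
y along rows, origin at the top-left, y increasing downward, 0-based pixel
centers at integer coordinates.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import InputError, LayoutError


class SpotRole(enum.Enum):
    """Role of a grid position on the chip."""

    RBST = "RBST"
    IGF1_100 = "IGF1_100"
    IGF1_250 = "IGF1_250"
    POS = "POS"
    NEG = "NEG"


#: Roles measuring a biomarker (everything that is not a control).
BIOMARKER_ROLES = (SpotRole.RBST, SpotRole.IGF1_100, SpotRole.IGF1_250)

#: Single-letter codes used in layout files.
ROLE_CODES = {
    "R": SpotRole.RBST,
    "I": SpotRole.IGF1_100,
    "J": SpotRole.IGF1_250,
    "P": SpotRole.POS,
    "N": SpotRole.NEG,
}
CODE_FOR_ROLE = {v: k for k, v in ROLE_CODES.items()}

# Canonical 6x8 arrangement: controls-only outer ring with POS corners and
# POS/NEG alternation, biomarkers in three column-pairs of the first three
# inner rows, and the six inner controls alternating along the last inner row.
_DEFAULT_ROLE_ROWS = (
    "PNPNNPNP",
    "NRRIIJJN",
    "PRRIIJJP",
    "PRRIIJJP",
    "NPNPNPNN",
    "PNPNNPNP",
)


@dataclass(frozen=True)
class ArrayLayout:
    """Grid geometry plus the role sitting at each position.

    Parameters
    ----------
    n_rows, n_cols:
        Grid dimensions.
    roles:
        Mapping ``(row, col) -> SpotRole`` covering every position.
    pitch_row, pitch_col:
        Reference centroid spacing in standardized pixels.
    origin:
        ``(x, y)`` standardized coordinate of spot ``(0, 0)``.
    ellipse_semi_axes:
        ``(a_col, b_row)`` semi-axes in standardized pixels of the
        quantification ROI; must stay below half the pitch so ROIs of
        adjacent spots never overlap.
    """

    n_rows: int
    n_cols: int
    roles: dict[tuple[int, int], SpotRole] = field(repr=False)
    pitch_row: float = 40.0
    pitch_col: float = 40.0
    origin: tuple[float, float] = (30.0, 30.0)
    ellipse_semi_axes: tuple[float, float] = (12.0, 9.0)

    def __post_init__(self) -> None:
        validate_layout(self)

    @property
    def n_spots(self) -> int:
        return self.n_rows * self.n_cols

    def role_counts(self) -> dict[SpotRole, int]:
        counts: dict[SpotRole, int] = {}
        for role in self.roles.values():
            counts[role] = counts.get(role, 0) + 1
        return counts

    def outer_ring(self) -> set[tuple[int, int]]:
        """All positions on the outermost rows/columns."""
        return {
            (r, c)
            for r in range(self.n_rows)
            for c in range(self.n_cols)
            if r in (0, self.n_rows - 1) or c in (0, self.n_cols - 1)
        }

    def corners(self) -> tuple[tuple[int, int], ...]:
        return (
            (0, 0),
            (0, self.n_cols - 1),
            (self.n_rows - 1, 0),
            (self.n_rows - 1, self.n_cols - 1),
        )

    def positions_with_role(self, role: SpotRole) -> list[tuple[int, int]]:
        return sorted(p for p, r in self.roles.items() if r is role)


def validate_layout(layout: ArrayLayout) -> None:
    """Check every ArrayLayout invariant; raise LayoutError naming the first violation."""
    if layout.n_rows < 1 or layout.n_cols < 1:
        raise LayoutError("grid dimensions must be positive")
    expected = {
        (r, c) for r in range(layout.n_rows) for c in range(layout.n_cols)
    }
    if set(layout.roles) != expected:
        raise LayoutError(
            "roles must cover every grid position exactly once "
            f"(expected {len(expected)} positions, got {len(layout.roles)})"
        )
    for ring_pos in layout.outer_ring():
        if layout.roles[ring_pos] not in (SpotRole.POS, SpotRole.NEG):
            raise LayoutError(
                f"outer-ring position {ring_pos} must be a control, "
                f"got {layout.roles[ring_pos].value}"
            )
    for corner in layout.corners():
        if layout.roles[corner] is not SpotRole.POS:
            raise LayoutError(f"corner position {corner} must be POS")
    if layout.pitch_row <= 0 or layout.pitch_col <= 0:
        raise LayoutError("pitch must be positive")
    a, b = layout.ellipse_semi_axes
    if a <= 0 or b <= 0:
        raise LayoutError("ellipse semi-axes must be positive")
    if a >= layout.pitch_col / 2 or b >= layout.pitch_row / 2:
        raise LayoutError(
            "ellipse semi-axes must be smaller than half the pitch "
            "(adjacent ROIs would overlap)"
        )


def build_default_layout() -> ArrayLayout:
    """Return the canonical 48-spot chip layout.

    6 rows x 8 columns; role counts RBST/IGF1_100/IGF1_250 = 6 each and
    POS/NEG = 15 each; outer ring contains only controls with POS at all
    four corners. Deterministic: the same layout is returned on every call.
    """
    roles = {
        (r, c): ROLE_CODES[code]
        for r, row in enumerate(_DEFAULT_ROLE_ROWS)
        for c, code in enumerate(row)
    }
    return ArrayLayout(n_rows=6, n_cols=8, roles=roles)


def reference_centroids(
    layout: ArrayLayout,
) -> dict[tuple[int, int], tuple[float, float]]:
    """Standardized ``(x, y)`` centroid of every grid position.

    The reference grid is regular and axis-aligned:
    ``centroid(r, c) = (origin_x + c * pitch_col, origin_y + r * pitch_row)``.
    """
    ox, oy = layout.origin
    return {
        (r, c): (ox + c * layout.pitch_col, oy + r * layout.pitch_row)
        for r in range(layout.n_rows)
        for c in range(layout.n_cols)
    }


def inner_positions(layout: ArrayLayout) -> set[tuple[int, int]]:
    """Positions of the inner rectangle (everything off the outer ring).

    Only these spots enter the reported aggregates; the ring spots serve
    geometry. Requires at least a 3x3 grid.
    """
    if layout.n_rows < 3 or layout.n_cols < 3:
        raise LayoutError("grid smaller than 3x3 has no inner rectangle")
    return {
        (r, c)
        for r in range(1, layout.n_rows - 1)
        for c in range(1, layout.n_cols - 1)
    }


def _layout_from_mapping(data: dict, source: str) -> ArrayLayout:
    try:
        n_rows = int(data["n_rows"])
        n_cols = int(data["n_cols"])
        role_rows = data["roles"]
    except KeyError as exc:
        raise LayoutError(f"{source}: missing required key {exc}")
    if len(role_rows) != n_rows:
        raise LayoutError(
            f"{source}: roles block has {len(role_rows)} rows, expected {n_rows}"
        )
    roles: dict[tuple[int, int], SpotRole] = {}
    for r, row in enumerate(role_rows):
        if len(row) != n_cols:
            raise LayoutError(
                f"{source}: roles row {r} has {len(row)} codes, expected {n_cols}"
            )
        for c, code in enumerate(row):
            if code not in ROLE_CODES:
                raise LayoutError(
                    f"{source}: unknown role code {code!r} at row {r}, col {c}"
                )
            roles[(r, c)] = ROLE_CODES[code]
    pitch = data.get("pitch", {})
    origin = data.get("origin", {})
    ellipse = data.get("ellipse", {})
    return ArrayLayout(
        n_rows=n_rows,
        n_cols=n_cols,
        roles=roles,
        pitch_row=float(pitch.get("row", 40.0)),
        pitch_col=float(pitch.get("col", 40.0)),
        origin=(float(origin.get("x", 30.0)), float(origin.get("y", 30.0))),
        ellipse_semi_axes=(
            float(ellipse.get("a", 12.0)),
            float(ellipse.get("b", 9.0)),
        ),
    )


def load_layout(path: str | Path) -> ArrayLayout:
    """Load and validate a layout from a YAML or JSON file."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"layout file not found: {path}", stage="layout")
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise LayoutError(f"{path}: layout file must contain a mapping")
    return _layout_from_mapping(data, str(path))


def save_layout(layout: ArrayLayout, path: str | Path) -> None:
    """Write a layout as YAML (round-trips through load_layout)."""
    rows = [
        "".join(CODE_FOR_ROLE[layout.roles[(r, c)]] for c in range(layout.n_cols))
        for r in range(layout.n_rows)
    ]
    data = {
        "n_rows": layout.n_rows,
        "n_cols": layout.n_cols,
        "pitch": {"row": layout.pitch_row, "col": layout.pitch_col},
        "origin": {"x": layout.origin[0], "y": layout.origin[1]},
        "ellipse": {
            "a": layout.ellipse_semi_axes[0],
            "b": layout.ellipse_semi_axes[1],
        },
        "roles": rows,
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
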