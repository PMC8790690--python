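"""In-line-of-sight prioritization of attributes in the Better-Worse plane.

When every attribute lands in the same Kano quadrant, categorization alone
cannot prioritize.  The in-line-of-sight method ranks attributes by how
close they sit to the quadrant's most characteristic corner ("point of
view", POV), breaking near-ties by direction:

    d     Euclidean distance from the attribute's (Worse, Better) coordinate
          to the POV corner
    alpha angle (degrees, 0..90) between the quadrant's reference boundary
          ray and the line from the corner to the coordinate
    f     ranking coefficient  f = d + (alpha / 90) * 0.05 * sqrt(2)

The angle term is scaled to 5% of the maximal in-square distance sqrt(2), so
it reorders only attributes whose distances are nearly identical.  Ranks are
assigned in ascending order of f (rank 1 = highest priority).

The four corners in signed (worse, better) coordinates are must-be (-1, 0),
attractive (0, 1), one-dimensional (-1, 1) and indifferent (0, 0).  For the
must-be POV the reference ray is the Worse axis, with alpha increasing
toward the one-dimensional corner: alpha = arctan(Better / (1 + Worse)).

One prose convention deserves a flag: published descriptions of the must-be
variant sometimes speak of "preferring less pronounced Worse values", which
reads opposite to what the formula above does (small alpha favors points
near the Worse axis, i.e. strongly dissatisfying-if-absent attributes).  The
implementation follows the formula, which is the definition validated
against the published ranking tables.
"""

from __future__ import annotations

import math
from collections.abc import Mapping
from dataclasses import dataclass, field

from .exceptions import KanosightError
from .timko import Coordinate

#: Scale of the angle term: 5% of the maximal in-square distance sqrt(2).
ANGLE_SCALE: float = 0.05 * math.sqrt(2)

CORNER_COORDS: dict[str, Coordinate] = {
    "must-be": Coordinate(-1.0, 0.0),
    "attractive": Coordinate(0.0, 1.0),
    "one-dimensional": Coordinate(-1.0, 1.0),
    "indifferent": Coordinate(0.0, 0.0),
}

#: Default angle reference per POV: the adjacent corner toward which the
#: alpha=0 boundary ray points.  must-be measures alpha from the Worse axis
#: (toward indifferent) increasing toward one-dimensional; attractive from
#: the Better axis increasing toward one-dimensional; the remaining two
#: reference must-be, the conservative choice for professional contexts.
DEFAULT_REFERENCE: dict[str, str] = {
    "must-be": "indifferent",
    "attractive": "indifferent",
    "one-dimensional": "must-be",
    "indifferent": "must-be",
}

_BOUNDS_TOL = 1e-9


@dataclass(frozen=True)
class CornerPOV:
    """A quadrant corner from which distances and angles are measured."""

    name: str
    corner: Coordinate = field(default=None)  # type: ignore[assignment]
    angle_reference: str = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.name not in CORNER_COORDS:
            raise KanosightError(
                f"unknown POV {self.name!r}; choose from {sorted(CORNER_COORDS)}"
            )
        if self.corner is None:
            object.__setattr__(self, "corner", CORNER_COORDS[self.name])
        if self.angle_reference is None:
            object.__setattr__(self, "angle_reference", DEFAULT_REFERENCE[self.name])
        if self.angle_reference not in CORNER_COORDS:
            raise KanosightError(f"unknown angle reference {self.angle_reference!r}")
        ref = CORNER_COORDS[self.angle_reference]
        if _adjacent(self.corner, ref) is None:
            raise KanosightError(
                f"angle reference {self.angle_reference!r} is not adjacent to "
                f"the {self.name!r} corner"
            )

    @property
    def _axes(self) -> tuple[tuple[float, float], tuple[float, float]]:
        """Unit vectors (u, v): alpha = 0 along u, alpha = 90 along v."""
        u = _adjacent(self.corner, CORNER_COORDS[self.angle_reference])
        other = next(
            name for name, c in CORNER_COORDS.items()
            if name != self.angle_reference and _adjacent(self.corner, c) is not None
        )
        v = _adjacent(self.corner, CORNER_COORDS[other])
        return u, v  # type: ignore[return-value]


def _adjacent(corner: Coordinate, other: Coordinate) -> tuple[float, float] | None:
    """Unit vector from ``corner`` to ``other`` if they share an edge."""
    dx, dy = other.worse - corner.worse, other.better - corner.better
    if (dx == 0) == (dy == 0):  # same corner or diagonal
        return None
    return (math.copysign(1.0, dx) if dx else 0.0,
            math.copysign(1.0, dy) if dy else 0.0)


@dataclass(frozen=True)
class RankingResult:
    """Distance, angle, coefficient and rank for one attribute."""

    attribute_id: str
    distance: float
    angle: float
    coefficient: float
    rank: int
    tied: bool = False


def _check_bounds(point: Coordinate) -> Coordinate:
    worse, better = float(point[0]), float(point[1])
    if not (-1 - _BOUNDS_TOL <= worse <= _BOUNDS_TOL
            and -_BOUNDS_TOL <= better <= 1 + _BOUNDS_TOL):
        raise KanosightError(
            f"coordinate ({worse}, {better}) outside the unit Better-Worse "
            "rectangle (worse in [-1, 0], better in [0, 1])"
        )
    return Coordinate(worse, better)


def distance_to_corner(point: Coordinate | tuple[float, float], pov: CornerPOV) -> float:
    """Euclidean distance from ``point`` to the POV corner."""
    p = _check_bounds(point)
    return math.hypot(p.worse - pov.corner.worse, p.better - pov.corner.better)


def angle_from_corner(point: Coordinate | tuple[float, float], pov: CornerPOV) -> float:
    """Angle alpha in degrees within [0, 90] as seen from the POV corner.

    alpha = 0 on the quadrant's reference boundary ray, 90 on the
    perpendicular boundary; the corner itself is assigned alpha = 0 (the
    directional limit does not exist, and 0 keeps "corner is best").
    """
    p = _check_bounds(point)
    dx, dy = p.worse - pov.corner.worse, p.better - pov.corner.better
    if dx == 0 and dy == 0:
        return 0.0
    u, v = pov._axes
    along = dx * u[0] + dy * u[1]
    across = dx * v[0] + dy * v[1]
    alpha = math.degrees(math.atan2(across, along))
    if not -_BOUNDS_TOL <= alpha <= 90 + _BOUNDS_TOL:
        raise KanosightError(
            f"point ({p.worse}, {p.better}) lies outside the [0, 90] degree "
            f"sector of the {pov.name!r} POV"
        )
    return min(max(alpha, 0.0), 90.0)


def ranking_coefficient(d: float, alpha: float) -> float:
    """f = d + (alpha / 90) * 0.05 * sqrt(2)."""
    if d < 0:
        raise KanosightError(f"distance must be non-negative, got {d}")
    if not 0 <= alpha <= 90:
        raise KanosightError(f"angle must be in [0, 90] degrees, got {alpha}")
    return d + (alpha / 90.0) * ANGLE_SCALE


def rank_attributes(coordinates: Mapping[str, Coordinate | tuple[float, float]],
                    pov: CornerPOV | str = "must-be") -> list[RankingResult]:
    """Rank attributes by ascending ranking coefficient from a POV corner.

    Exact ties in f keep input order and are flagged ``tied``; ranks are
    always the permutation 1..n.
    """
    if isinstance(pov, str):
        pov = CornerPOV(pov)
    if not coordinates:
        raise KanosightError("cannot rank an empty set of attributes")
    rows = []
    for attr, point in coordinates.items():
        d = distance_to_corner(point, pov)
        alpha = angle_from_corner(point, pov)
        rows.append((attr, d, alpha, ranking_coefficient(d, alpha)))
    order = sorted(range(len(rows)), key=lambda i: rows[i][3])  # stable
    f_values = [rows[i][3] for i in range(len(rows))]
    results = [None] * len(rows)
    for rank0, i in enumerate(order):
        attr, d, alpha, f = rows[i]
        tied = any(f == f_values[j] for j in range(len(rows)) if j != i)
        results[i] = RankingResult(attr, d, alpha, f, rank0 + 1, tied)
    return results  # type: ignore[return-value]
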