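"""Spherocylinder (capsule) geometry for rod-shaped cells.

The projected outline of a rod-shaped cyanobacterium is modelled as a
rectangle of length ``L - W`` and width ``W`` capped by two semicircles of
radius ``W / 2`` (a 2-D capsule).  All modules share one arc-length
convention: the normalized arc coordinate ``t`` in ``[0, 1)`` runs
counterclockwise (positive shoelace area in ``(x, y)`` pixel coordinates)
along the outline, starting from the midpoint of longitudinal side L1.

Side L1 is defined geometrically: after rotating the cell so that its major
axis is horizontal, L1 is the side with the smaller ``y`` coordinate.  With
axis unit vector ``u = (cos th, sin th)`` and normal ``v = (-sin th, cos th)``
this is the side at negative ``v`` coordinate.  Downstream statistics that
compare the two sides are made order-free (brighter/dimmer), so the
convention only fixes reproducibility, never results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "RodGeometry",
    "perimeter",
    "region_boundaries",
    "region_labels",
    "outline_points",
    "rasterize_footprint",
]

REGION_ORDER = ("L1", "P1", "L2", "P2")


@dataclass(frozen=True)
class RodGeometry:
    """Spherocylinder cell model in physical units.

    Parameters
    ----------
    center : (float, float)
        Planar position of the cell centroid, micrometres.
    orientation : float
        Angle of the long axis in degrees; normalized to ``[0, 180)``.
    length : float
        Tip-to-tip extent L, micrometres.
    width : float
        Diameter W, micrometres.  Requires ``L >= W > 0``.
    """

    center: tuple[float, float]
    orientation: float
    length: float
    width: float

    def __post_init__(self) -> None:
        if not (self.width > 0):
            raise ValueError(f"width must be positive, got {self.width}")
        if self.length < self.width:
            raise ValueError(
                f"length ({self.length}) must be >= width ({self.width})"
            )
        object.__setattr__(self, "orientation", float(self.orientation) % 180.0)
        object.__setattr__(self, "center", (float(self.center[0]), float(self.center[1])))

    @property
    def radius(self) -> float:
        return self.width / 2.0

    @property
    def side_length(self) -> float:
        """Length of one straight side, ``L - W``."""
        return self.length - self.width

    @property
    def perimeter_um(self) -> float:
        return perimeter(self.length, self.width)

    @property
    def axis_unit(self) -> np.ndarray:
        th = math.radians(self.orientation)
        return np.array([math.cos(th), math.sin(th)])

    @property
    def normal_unit(self) -> np.ndarray:
        """Unit normal; side L1 lies at negative coordinate along it."""
        th = math.radians(self.orientation)
        return np.array([-math.sin(th), math.cos(th)])

    def to_dict(self) -> dict:
        return {
            "center": list(self.center),
            "orientation": self.orientation,
            "length": self.length,
            "width": self.width,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RodGeometry":
        return cls(tuple(d["center"]), d["orientation"], d["length"], d["width"])


def perimeter(length: float, width: float) -> float:
    """Outline perimeter ``2 (L - W) + pi W``."""
    return 2.0 * (length - width) + math.pi * width


def region_boundaries(length: float, width: float) -> np.ndarray:
    """Cumulative arc fractions of the region boundaries from the anchor.

    Traversal order from the L1 midpoint is: second half of L1, pole P1,
    side L2, pole P2, first half of L1.  Returns the four fractions at which
    [L1->P1, P1->L2, L2->P2, P2->L1] transitions occur.
    """
    s = length - width
    r = width / 2.0
    p = perimeter(length, width)
    cuts = np.cumsum([s / 2.0, math.pi * r, s, math.pi * r]) / p
    return cuts


def region_labels(t: np.ndarray, length: float, width: float) -> np.ndarray:
    """Label arc fractions ``t`` in [0,1) with their region (L1/P1/L2/P2)."""
    t = np.asarray(t, dtype=float) % 1.0
    cuts = region_boundaries(length, width)
    labels = np.empty(t.shape, dtype=object)
    labels[t < cuts[0]] = "L1"
    labels[(t >= cuts[0]) & (t < cuts[1])] = "P1"
    labels[(t >= cuts[1]) & (t < cuts[2])] = "L2"
    labels[(t >= cuts[2]) & (t < cuts[3])] = "P2"
    labels[t >= cuts[3]] = "L1"
    return labels


def _outline_canonical(t: np.ndarray, length: float, width: float) -> np.ndarray:
    """Outline points in the canonical frame (axis along +x, centroid at 0).

    ``t`` is the normalized arc fraction of *this* outline.  Counterclockwise
    by the positive-shoelace convention, anchored at the L1 midpoint
    ``(0, -R)``.
    """
    s = length - width
    r = width / 2.0
    p = perimeter(length, width)
    arc = (np.asarray(t, dtype=float) % 1.0) * p

    x = np.empty_like(arc)
    y = np.empty_like(arc)

    b0 = s / 2.0
    b1 = b0 + math.pi * r
    b2 = b1 + s
    b3 = b2 + math.pi * r

    m = arc < b0  # second half of L1
    x[m] = arc[m]
    y[m] = -r

    m = (arc >= b0) & (arc < b1)  # pole P1
    phi = -math.pi / 2.0 + (arc[m] - b0) / r if r > 0 else arc[m] * 0
    x[m] = s / 2.0 + r * np.cos(phi)
    y[m] = r * np.sin(phi)

    m = (arc >= b1) & (arc < b2)  # side L2 (traversed -x)
    x[m] = s / 2.0 - (arc[m] - b1)
    y[m] = r

    m = (arc >= b2) & (arc < b3)  # pole P2
    phi = math.pi / 2.0 + (arc[m] - b2) / r if r > 0 else arc[m] * 0
    x[m] = -s / 2.0 + r * np.cos(phi)
    y[m] = r * np.sin(phi)

    m = arc >= b3  # first half of L1
    x[m] = -s / 2.0 + (arc[m] - b3)
    y[m] = -r

    return np.column_stack([x, y])


def outline_points(
    geometry: RodGeometry, t: np.ndarray, offset_um: float = 0.0
) -> np.ndarray:
    """World-frame (x, y) points on the outline, or on a parallel outline
    offset inward by ``offset_um`` (a concentric shell).

    The offset outline is itself a spherocylinder with ``L - 2 d`` and
    ``W - 2 d``; ``t`` is its own normalized arc fraction, anchored and
    oriented with the same convention as the cell outline.
    """
    L = geometry.length - 2.0 * offset_um
    W = geometry.width - 2.0 * offset_um
    if W <= 0:
        raise ValueError(
            f"offset {offset_um} um exceeds the cell half-width {geometry.radius} um"
        )
    pts = _outline_canonical(np.asarray(t, dtype=float), L, W)
    u = geometry.axis_unit
    v = geometry.normal_unit
    rot = np.column_stack([u, v])  # canonical (x', y') -> world
    return pts @ rot.T + np.asarray(geometry.center)


def rasterize_footprint(
    geometry: RodGeometry,
    shape: tuple[int, int],
    pixel_size_nm: float,
    origin_um: tuple[float, float] = (0.0, 0.0),
) -> np.ndarray:
    """Boolean capsule footprint on a pixel grid.

    A pixel (row, col) maps to the world point
    ``origin_um + pixel_size * (col + 0.5, row + 0.5)``; it is inside the
    cell iff its distance to the axis segment is at most ``W / 2``.
    """
    px_um = pixel_size_nm / 1000.0
    rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
    x = origin_um[0] + (cols + 0.5) * px_um
    y = origin_um[1] + (rows + 0.5) * px_um

    c = np.asarray(geometry.center)
    u = geometry.axis_unit
    half = geometry.side_length / 2.0
    dx = x - c[0]
    dy = y - c[1]
    proj = np.clip(dx * u[0] + dy * u[1], -half, half)
    qx = dx - proj * u[0]
    qy = dy - proj * u[1]
    dist2 = qx * qx + qy * qy
    return dist2 <= geometry.radius**2
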