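"""Cell detection, spherocylinder fitting, and anchored outline extraction.

Cells are segmented by global (Otsu) thresholding of the chlorophyll channel
(or an inverted TEM-like image), morphological cleanup and connected-component
labelling.  A :class:`~thylaquant.geometry.RodGeometry` is fitted to each mask
from second-order image moments, and the outline is extracted at subpixel
resolution by marching squares, then re-anchored so that vertex 0 sits at the
midpoint of longitudinal side L1 and traversal is counterclockwise — the fixed
start-site/direction convention every periphery profile shares.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString
from skimage.filters import threshold_otsu
from skimage.measure import find_contours, label, regionprops
from skimage.morphology import closing, disk
from scipy.ndimage import binary_fill_holes

from .geometry import RodGeometry, outline_points

__all__ = ["CellMask", "Contour", "segment_cells", "fit_rod", "extract_anchored_contour"]


@dataclass
class CellMask:
    """One segmented cell: a boolean raster plus its bounding box."""

    mask: np.ndarray  # full-size boolean raster, single connected component
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    touches_border: bool = False

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


@dataclass
class Contour:
    """Closed, simple, anchored cell outline.

    ``points`` are (x, y) pixel coordinates (subpixel); vertex 0 is the
    outline point nearest the L1 midpoint and traversal is counterclockwise
    (positive shoelace).  ``arclen`` holds the cumulative arc length per
    vertex starting at 0; the closing segment back to vertex 0 brings the
    total to ``total_length``.
    """

    points: np.ndarray  # (n, 2) float, (x, y) px
    arclen: np.ndarray  # (n,) cumulative, arclen[0] == 0

    def __post_init__(self) -> None:
        if np.any(np.diff(self.arclen) <= 0):
            raise ValueError("cumulative arc lengths must be strictly increasing")

    @property
    def total_length(self) -> float:
        closing = float(np.hypot(*(self.points[0] - self.points[-1])))
        return float(self.arclen[-1]) + closing

    def resample(self, n: int) -> np.ndarray:
        """(n, 2) points at equally spaced arc fractions k/n from the anchor."""
        total = self.total_length
        s = np.arange(n) / n * total
        # periodic linear interpolation over the closed polygon
        pts = np.vstack([self.points, self.points[:1]])
        arcs = np.append(self.arclen, total)
        x = np.interp(s, arcs, pts[:, 0])
        y = np.interp(s, arcs, pts[:, 1])
        return np.column_stack([x, y])


def segment_cells(
    image: np.ndarray,
    *,
    invert: bool = False,
    min_area_px: int = 200,
    exclude_border: bool = True,
    closing_radius: int = 2,
) -> list[CellMask]:
    """Detect cells as connected components above the Otsu threshold.

    ``invert=True`` segments dark-on-bright images (TEM-like thin sections).
    Returns an empty list on blank (constant) input.  Components are
    morphologically closed, hole-filled, and area-filtered; border-touching
    cells are flagged and, by default, excluded.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D intensity raster")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    if np.ptp(img) == 0:
        return []
    if invert:
        img = -img
    fg = img > threshold_otsu(img)
    if closing_radius > 0:
        fg = closing(fg, disk(closing_radius))
    fg = binary_fill_holes(fg)

    labels = label(fg)
    out: list[CellMask] = []
    for rp in regionprops(labels):
        if rp.area < min_area_px:
            continue
        m = labels == rp.label
        r0, c0, r1, c1 = rp.bbox
        touches = r0 == 0 or c0 == 0 or r1 == img.shape[0] or c1 == img.shape[1]
        if touches and exclude_border:
            continue
        out.append(CellMask(mask=m, bbox=rp.bbox, touches_border=touches))
    return out


def fit_rod(mask: CellMask, pixel_size_nm: float) -> RodGeometry:
    """Fit the spherocylinder model to a cell mask.

    Orientation comes from second-order image moments, length from the pixel
    extent along the major axis, and width from the area-preserving root of
    the capsule area identity ``A = (L - W) W + pi (W/2)^2``.
    """
    rows, cols = np.nonzero(mask.mask)
    if rows.size == 0:
        raise ValueError("empty mask")
    px_um = pixel_size_nm / 1000.0
    x = cols + 0.5
    y = rows + 0.5
    cx = x.mean()
    cy = y.mean()
    mu20 = np.mean((x - cx) ** 2)
    mu02 = np.mean((y - cy) ** 2)
    mu11 = np.mean((x - cx) * (y - cy))
    theta = 0.5 * math.atan2(2 * mu11, mu20 - mu02)
    u = np.array([math.cos(theta), math.sin(theta)])

    proj = (x - cx) * u[0] + (y - cy) * u[1]
    length_px = proj.max() - proj.min() + 1.0  # + 1 px for the pixel extent
    area_px = rows.size

    L = length_px * px_um
    A = area_px * px_um**2
    # (pi/4 - 1) W^2 + L W - A = 0; take the root in (0, L]
    c = math.pi / 4.0 - 1.0
    disc = L * L + 4.0 * c * A
    W = (-L + math.sqrt(max(disc, 0.0))) / (2.0 * c)
    W = min(max(W, 1e-9), L)

    center_um = (cx * px_um, cy * px_um)
    return RodGeometry(center_um, math.degrees(theta) % 180.0, L, W)


def _anchor_point_px(geometry: RodGeometry, pixel_size_nm: float) -> np.ndarray:
    """L1 midpoint of the fitted outline, pixel coordinates (x, y)."""
    p_um = outline_points(geometry, np.array([0.0]))[0]
    return p_um / (pixel_size_nm / 1000.0)


def extract_anchored_contour(
    mask: CellMask,
    geometry: RodGeometry,
    pixel_size_nm: float,
    *,
    smooth_sigma: float = 1.0,
) -> Contour:
    """Subpixel outline via marching squares at 0.5 on the smoothed mask,
    re-indexed to start at the L1 midpoint, traversed counterclockwise.

    Idempotent with respect to the anchoring convention: the vertex chosen
    as index 0 depends only on the geometry, not on the input ordering.
    Raises if the traced outline is not a simple closed curve.
    """
    soft = gaussian_filter(mask.mask.astype(float), smooth_sigma)
    contours = find_contours(soft, 0.5)
    if not contours:
        raise ValueError("no contour found at the 0.5 level")
    rc = max(contours, key=len)  # (row, col) vertices, closed (first == last)
    if not np.allclose(rc[0], rc[-1]):
        raise ValueError("contour is not closed (cell touches the image border?)")
    rc = rc[:-1]
    pts = np.column_stack([rc[:, 1], rc[:, 0]])  # -> (x, y)

    if not LineString(np.vstack([pts, pts[:1]])).is_simple:
        raise ValueError("outline is self-intersecting (non-simple polygon)")

    # counterclockwise = positive shoelace area in (x, y)
    x, y = pts[:, 0], pts[:, 1]
    area2 = np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if area2 < 0:
        pts = pts[::-1]

    anchor = _anchor_point_px(geometry, pixel_size_nm) - 0.5  # centre convention
    k = int(np.argmin(np.sum((pts - anchor) ** 2, axis=1)))
    pts = np.roll(pts, -k, axis=0)

    seg = np.hypot(*(np.diff(pts, axis=0).T))
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    return Contour(points=pts, arclen=arclen)
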