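"""Thylakoid layer counting and inter-layer spacing from thin-section images.

The concentric thylakoid layers of a rod-shaped cell present, on the
perpendicular transect through mid-cell, as a train of dark intensity minima
on each side of the cell axis.  Membrane positions are detected as prominent
local minima and refined to subpixel precision by three-point parabolic
interpolation; the outermost minimum on each side is the plasma membrane and
is excluded from layer counts.  Spacings are distances between adjacent
detected membranes on the same side; group summaries report mean, sample SD,
n, percent change versus a reference condition, and a pooled two-sided
two-sample t-test per pair.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates
from scipy.signal import find_peaks

from .cell_segmentation import segment_cells, fit_rod
from .distribution_statistics import TestResult, compare_groups
from .geometry import RodGeometry

__all__ = [
    "TransectProfile",
    "LayerPeaks",
    "LayerCounts",
    "GroupSpacing",
    "SpacingSummary",
    "midcell_transect",
    "detect_layer_peaks",
    "layer_counts",
    "spacing_summary",
    "measure_cell_spacings",
]


@dataclass
class TransectProfile:
    """Intensity along the mid-cell width axis; positions in nm, origin at
    the cell axis (negative = side 1)."""

    positions_nm: np.ndarray
    values: np.ndarray
    geometry: RodGeometry | None = None

    def __post_init__(self) -> None:
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.positions_nm) <= 0):
            raise ValueError("transect positions must be strictly increasing")


@dataclass
class LayerPeaks:
    """Detected membrane positions (nm, signed; negative = side 1), sorted."""

    positions_nm: np.ndarray
    prominences: np.ndarray

    def __post_init__(self) -> None:
        order = np.argsort(self.positions_nm)
        self.positions_nm = np.asarray(self.positions_nm, dtype=float)[order]
        self.prominences = np.asarray(self.prominences, dtype=float)[order]


@dataclass
class LayerCounts:
    """Thylakoid layer counts per longitudinal side (plasma membrane
    excluded); ``pm_missing`` flags sides without a detectable plasma
    membrane peak."""

    side1: int
    side2: int
    pm_missing: tuple[bool, bool] = (False, False)

    def __iter__(self):
        return iter((self.side1, self.side2))


def midcell_transect(
    image: np.ndarray,
    geometry: RodGeometry,
    pixel_size_nm: float,
    *,
    avg_width_px: int = 5,
    margin_nm: float = 60.0,
) -> TransectProfile:
    """Sample intensity along the line through the centroid perpendicular to
    the major axis, averaged over ``avg_width_px`` parallel lines; the span
    is the cell width plus ``margin_nm`` on each side."""
    img = np.asarray(image, dtype=float)
    px_um = pixel_size_nm / 1000.0
    half_nm = geometry.radius * 1000.0 + margin_nm
    step = pixel_size_nm
    pos = np.arange(-half_nm, half_nm + step / 2, step)

    c_px = np.asarray(geometry.center) / px_um - 0.5  # (x, y) index coords
    u = geometry.axis_unit
    v = geometry.normal_unit
    line_offsets = (np.arange(avg_width_px) - (avg_width_px - 1) / 2.0)

    vals = np.zeros(pos.shape)
    for off in line_offsets:
        base = c_px + off * u
        xy = base[None, :] + (pos / pixel_size_nm)[:, None] * v[None, :]
        rows = xy[:, 1]
        cols = xy[:, 0]
        if (
            rows.min() < 0
            or cols.min() < 0
            or rows.max() > img.shape[0] - 1
            or cols.max() > img.shape[1] - 1
        ):
            raise ValueError("transect exits the image")
        vals += map_coordinates(img, [rows, cols], order=1)
    vals /= avg_width_px
    return TransectProfile(positions_nm=pos, values=vals, geometry=geometry)


def detect_layer_peaks(
    transect: TransectProfile,
    *,
    prominence_frac: float = 0.2,
    min_separation_nm: float = 20.0,
) -> LayerPeaks:
    """Membranes = local intensity minima with prominence at least
    ``prominence_frac`` of the transect dynamic range and pairwise separation
    at least ``min_separation_nm``; positions refined by 3-point parabolic
    interpolation.  An empty result is allowed."""
    v = transect.values
    if v.size < 5:
        raise ValueError("transect too short for peak detection")
    rng = float(np.ptp(v))
    if rng == 0:
        return LayerPeaks(np.empty(0), np.empty(0))
    step = float(np.mean(np.diff(transect.positions_nm)))
    idx, props = find_peaks(
        -v,
        prominence=prominence_frac * rng,
        distance=max(int(math.ceil(min_separation_nm / step)), 1),
    )
    pos = []
    for i in idx:
        delta = 0.0
        if 0 < i < v.size - 1:
            denom = v[i - 1] - 2 * v[i] + v[i + 1]
            if denom != 0:
                delta = 0.5 * (v[i - 1] - v[i + 1]) / denom
                delta = float(np.clip(delta, -0.5, 0.5))
        pos.append(np.interp(i + delta, np.arange(v.size), transect.positions_nm))
    return LayerPeaks(np.asarray(pos), props["prominences"])


def layer_counts(
    peaks: LayerPeaks,
    geometry: RodGeometry,
    *,
    pm_tolerance_nm: float = 25.0,
) -> LayerCounts:
    """Count thylakoid layers per side after removing the plasma-membrane
    peaks (the outermost minima within ``pm_tolerance_nm`` of W/2)."""
    half_nm = geometry.radius * 1000.0
    pos = peaks.positions_nm
    counts = []
    missing = []
    for sign in (-1.0, 1.0):
        side = pos[np.sign(pos) == sign] if pos.size else np.empty(0)
        side = np.abs(side)
        pm_found = side.size > 0 and abs(side.max() - half_nm) <= pm_tolerance_nm
        if pm_found:
            side = np.delete(side, np.argmax(side))
        else:
            warnings.warn(
                f"plasma-membrane peak not found on side {1 if sign < 0 else 2}",
                stacklevel=2,
            )
        counts.append(int(side.size))
        missing.append(not pm_found)
    return LayerCounts(counts[0], counts[1], (missing[0], missing[1]))


@dataclass
class GroupSpacing:
    distances_nm: np.ndarray
    mean: float
    sd: float  # sample SD (ddof = 1)
    n: int


@dataclass
class SpacingSummary:
    groups: dict[str, GroupSpacing]
    reference: str
    percent_change: dict[str, float]  # 100 (mean - mean_ref) / mean_ref
    tests: dict[str, TestResult | None]  # None when a group is too small


def spacing_summary(groups: dict[str, list], reference: str) -> SpacingSummary:
    """Group statistics of inter-layer distances with percent change and a
    pooled t-test against the reference condition."""
    if reference not in groups:
        raise ValueError(f"unknown reference group {reference!r}")
    stats: dict[str, GroupSpacing] = {}
    for name, d in groups.items():
        arr = np.asarray(d, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {name!r} is empty")
        sd = float(arr.std(ddof=1)) if arr.size > 1 else float("nan")
        stats[name] = GroupSpacing(arr, float(arr.mean()), sd, int(arr.size))

    ref_mean = stats[reference].mean
    pct = {name: 100.0 * (g.mean - ref_mean) / ref_mean for name, g in stats.items()}
    tests: dict[str, TestResult | None] = {}
    for name, g in stats.items():
        if name == reference:
            continue
        if g.n >= 2 and stats[reference].n >= 2:
            tests[name] = compare_groups(g.distances_nm, stats[reference].distances_nm)
        else:
            tests[name] = None
    return SpacingSummary(stats, reference, pct, tests)


def measure_cell_spacings(
    image: np.ndarray,
    pixel_size_nm: float,
    *,
    avg_width_px: int = 5,
    prominence_frac: float = 0.2,
    min_separation_nm: float = 20.0,
    min_area_px: int = 2000,
) -> list[dict]:
    """Full per-image pipeline: segment (dark-on-bright), fit the rod model,
    take the mid-cell transect, detect membranes, count layers, and collect
    adjacent same-side inter-layer distances.

    Returns one record per cell with keys ``geometry``, ``counts``,
    ``positions_nm`` and ``spacings_nm``.
    """
    records = []
    for cm in segment_cells(image, invert=True, min_area_px=min_area_px):
        geometry = fit_rod(cm, pixel_size_nm)
        transect = midcell_transect(
            image, geometry, pixel_size_nm, avg_width_px=avg_width_px
        )
        peaks = detect_layer_peaks(
            transect,
            prominence_frac=prominence_frac,
            min_separation_nm=min_separation_nm,
        )
        counts = layer_counts(peaks, geometry)
        half_nm = geometry.radius * 1000.0
        spacings = []
        for sign in (-1.0, 1.0):
            side = peaks.positions_nm[np.sign(peaks.positions_nm) == sign]
            side = np.sort(np.abs(side))
            # drop the plasma membrane (outermost, near W/2) before spacing
            if side.size and abs(side[-1] - half_nm) <= 25.0:
                side = side[:-1]
            spacings.extend(np.diff(side).tolist())
        records.append(
            {
                "geometry": geometry,
                "counts": counts,
                "positions_nm": peaks.positions_nm,
                "spacings_nm": spacings,
            }
        )
    return records
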