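"""End-to-end drivers over simulated cohorts.

These helpers chain the library steps exactly the way the analysis scripts
and the acceptance checks run them: simulate a cell, segment it from its own
rendered image (never from ground truth), trace the anchored periphery,
and compute the distribution statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cell_segmentation import extract_anchored_contour, fit_rod, segment_cells
from .distribution_statistics import (
    patchiness,
    pearson_colocalization,
    side_asymmetry,
)
from .periphery_profiles import PeripheryProfile, partition_regions, sample_periphery
from .synthetic_scenes import (
    FluorescenceImage,
    ProteinDistributionParams,
    SceneSpec,
    make_scene,
    render_fluorescence,
)
from .tem_spacing import measure_cell_spacings
from .synthetic_scenes import OpticsNoiseParams, render_tem

__all__ = [
    "CellMeasurement",
    "measure_fluorescence_scene",
    "profile_cohort",
    "tem_spacing_cohort",
]


@dataclass
class CellMeasurement:
    """Per-cell periphery quantification from one simulated scene."""

    scene: SceneSpec
    profile: PeripheryProfile
    patchiness: float
    asymmetry: float
    brighter_side: str
    colocalization: float


def measure_fluorescence_scene(
    scene: SceneSpec,
    *,
    n_samples: int = 360,
    band_halfwidth_px: int = 1,
    min_area_px: int = 300,
) -> CellMeasurement:
    """Render, segment on the Chl channel, trace, and quantify one cell."""
    fl = render_fluorescence(scene)
    masks = segment_cells(fl.chl, min_area_px=min_area_px)
    if len(masks) != 1:
        raise RuntimeError(f"expected one segmented cell, found {len(masks)}")
    mask = masks[0]
    geometry = fit_rod(mask, fl.pixel_size_nm)
    contour = extract_anchored_contour(mask, geometry, fl.pixel_size_nm)
    profile = sample_periphery(
        fl.gfp,
        contour,
        band_halfwidth_px=band_halfwidth_px,
        n_samples=n_samples,
    )
    partition_regions(profile, geometry)
    p = patchiness(profile)
    a = side_asymmetry(profile)
    r = pearson_colocalization(fl.gfp, fl.chl, mask)
    return CellMeasurement(
        scene=scene,
        profile=profile,
        patchiness=p.value,
        asymmetry=a.value,
        brighter_side=a.brighter_side,
        colocalization=r,
    )


def profile_cohort(
    n_cells: int,
    *,
    preset: str = "GL",
    distribution: ProteinDistributionParams | None = None,
    optics: OpticsNoiseParams | None = None,
    seed: int = 0,
) -> list[CellMeasurement]:
    """Simulate and measure ``n_cells`` independent cells.

    Per-cell seeds derive deterministically from ``seed``.
    """
    out = []
    for k in range(n_cells):
        scene = make_scene(
            preset,
            distribution=distribution,
            optics=optics,
            seed=(int(seed) * 100003 + k) % 2**31,
        )
        out.append(measure_fluorescence_scene(scene))
    return out


def tem_spacing_cohort(
    n_cells: int,
    *,
    preset: str,
    seed: int = 0,
    optics: OpticsNoiseParams | None = None,
) -> dict:
    """Simulate ``n_cells`` thin-section-like cells of one condition and run
    the full spacing pipeline (segment, transect, peaks, counts) on each.

    Returns pooled inter-layer ``spacings_nm`` and per-cell layer ``counts``.
    """
    spacings: list[float] = []
    counts: list[tuple[int, int]] = []
    for k in range(n_cells):
        scene = make_scene(
            preset,
            distribution=ProteinDistributionParams(n_points=0),
            seed=(int(seed) * 100003 + 7919 + k) % 2**31,
        )
        tem = render_tem(scene, optics=optics)
        for rec in measure_cell_spacings(tem.image, tem.pixel_size_nm):
            spacings.extend(rec["spacings_nm"])
            counts.append(tuple(rec["counts"]))
    return {"spacings_nm": spacings, "counts": counts}
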