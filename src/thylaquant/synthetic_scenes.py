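"""Forward model for rod-shaped cyanobacterial cell images with ground truth.

Emulates the two kinds of micrograph the downstream quantification consumes:

* two-channel fluorescence images (GFP-tagged photosynthetic complexes and
  chlorophyll autofluorescence of the thylakoid shells), and
* thin-section TEM-like images (dark membrane lines on brighter cytoplasm).

A :class:`SceneSpec` records the complete ground truth of one simulated cell:
spherocylinder geometry, concentric thylakoid shells per longitudinal side,
protein point positions on the shells, optics, noise, and the seed.  The same
``(parameters, seed)`` always produce bitwise-identical scenes and images.

Condition presets encode the thylakoid arrangements observed under the
different light regimes: cells grown under standard growth light (GL) carry
3 concentric layers at 78.4 nm spacing; high-light-adapted (HL) cells carry a
single continuous layer plus a membrane fragment near the plasma membrane at
109.2 nm spacing; the low-light time course (LL1..LL5) interpolates back to
the GL phenotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import RodGeometry, outline_points, rasterize_footprint, region_labels

__all__ = [
    "Shell",
    "ShellSet",
    "ProteinDistributionParams",
    "OpticsNoiseParams",
    "SceneSpec",
    "FluorescenceImage",
    "TemImage",
    "PRESETS",
    "make_scene",
    "render_fluorescence",
    "render_tem",
]

PM_SHELL_INDEX = -1  # sentinel: point sits on the plasma membrane outline


@dataclass(frozen=True)
class Shell:
    """One thylakoid membrane arc on one longitudinal side.

    ``offset_nm`` is the inward offset from the plasma membrane.  The drawn
    arc is centred on the side midpoint of the (concentric) offset outline
    and spans ``arc_extent`` of that side's half-outline; ``arc_extent = 1``
    on both sides at the same offset composes a full continuous ring, while
    ``arc_extent < 1`` is a membrane fragment.
    """

    offset_nm: float
    arc_extent: float = 1.0

    def __post_init__(self) -> None:
        if self.offset_nm < 0:
            raise ValueError("shell offset must be >= 0")
        if not (0.0 < self.arc_extent <= 1.0):
            raise ValueError("arc_extent must be in (0, 1]")


@dataclass(frozen=True)
class ShellSet:
    """Per-side ordered thylakoid shells (offsets strictly increasing)."""

    side1: tuple[Shell, ...] = ()
    side2: tuple[Shell, ...] = ()

    def __post_init__(self) -> None:
        for side in (self.side1, self.side2):
            offs = [s.offset_nm for s in side]
            if any(b <= a for a, b in zip(offs, offs[1:])):
                raise ValueError("shell offsets must be strictly increasing")

    def validate_against(self, geometry: RodGeometry) -> None:
        half_nm = geometry.radius * 1000.0
        for side in (self.side1, self.side2):
            for s in side:
                if s.offset_nm >= half_nm:
                    raise ValueError(
                        f"shell offset {s.offset_nm} nm >= cell half width {half_nm} nm"
                    )

    @property
    def flat(self) -> list[tuple[int, Shell]]:
        """Flat (side, shell) list; indices order side1 then side2."""
        return [(1, s) for s in self.side1] + [(2, s) for s in self.side2]

    def to_dict(self) -> dict:
        return {
            "side1": [[s.offset_nm, s.arc_extent] for s in self.side1],
            "side2": [[s.offset_nm, s.arc_extent] for s in self.side2],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ShellSet":
        return cls(
            tuple(Shell(*v) for v in d["side1"]),
            tuple(Shell(*v) for v in d["side2"]),
        )


@dataclass(frozen=True)
class ProteinDistributionParams:
    """Arc distribution of labelled protein complexes along the periphery.

    The arc position of each point is drawn from a mixture: with probability
    ``kappa / (1 + kappa)`` from a wrapped-Gaussian cluster (one of
    ``n_clusters`` random centres, width ``cluster_sigma`` in arc fraction),
    otherwise uniformly.  ``kappa = 0`` reduces exactly to the uniform
    distribution.  ``side_asymmetry`` is the side-1/side-2 density ratio and
    ``polar_enrichment`` multiplies the density on the cap arcs.
    """

    n_points: int = 2000
    kappa: float = 0.0
    n_clusters: int = 3
    cluster_sigma: float = 0.03
    side_asymmetry: float = 1.0
    polar_enrichment: float = 1.0
    amplitude: float = 120.0

    def __post_init__(self) -> None:
        if self.n_points < 0:
            raise ValueError("n_points must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.side_asymmetry < 0 or self.polar_enrichment < 0:
            raise ValueError("density ratios must be >= 0")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_points": self.n_points,
            "kappa": self.kappa,
            "n_clusters": self.n_clusters,
            "cluster_sigma": self.cluster_sigma,
            "side_asymmetry": self.side_asymmetry,
            "polar_enrichment": self.polar_enrichment,
            "amplitude": self.amplitude,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProteinDistributionParams":
        return cls(**d)


@dataclass(frozen=True)
class OpticsNoiseParams:
    """Pixel size, blur and noise of the simulated detector.

    Noise is applied in a fixed order: PSF blur, background offset, Poisson
    shot noise (``poisson_gain`` counts per photon; 0 disables), then
    additive Gaussian read noise.
    """

    pixel_size_nm: float = 30.0
    psf_sigma_nm: float = 80.0
    background: float = 5.0
    poisson_gain: float = 1.0
    read_sigma: float = 2.0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be > 0")
        if self.psf_sigma_nm < 0 or self.read_sigma < 0 or self.poisson_gain < 0:
            raise ValueError("psf_sigma_nm, read_sigma, poisson_gain must be >= 0")

    def to_dict(self) -> dict:
        return {
            "pixel_size_nm": self.pixel_size_nm,
            "psf_sigma_nm": self.psf_sigma_nm,
            "background": self.background,
            "poisson_gain": self.poisson_gain,
            "read_sigma": self.read_sigma,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsNoiseParams":
        return cls(**d)


#: Default optics for the TEM-like renderer (5 nm pixels, thin PSF).
TEM_OPTICS = OpticsNoiseParams(
    pixel_size_nm=5.0, psf_sigma_nm=3.0, background=0.0, poisson_gain=1.0, read_sigma=4.0
)

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class SceneSpec:
    """Complete ground truth of one simulated cell."""

    geometry: RodGeometry
    shells: ShellSet
    proteins: np.ndarray  # (n, 3): arc fraction, flat shell index, amplitude
    distribution: ProteinDistributionParams
    optics: OpticsNoiseParams
    seed: int
    condition_preset: str = "custom"

    def __post_init__(self) -> None:
        self.shells.validate_against(self.geometry)
        pts = np.asarray(self.proteins, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "proteins", pts)

    def protein_positions_um(self) -> np.ndarray:
        """World-frame (x, y) positions of the protein points, micrometres."""
        if len(self.proteins) == 0:
            return np.empty((0, 2))
        flat = self.shells.flat
        pos = np.empty((len(self.proteins), 2))
        for i, (t, idx, _amp) in enumerate(self.proteins):
            off_um = 0.0 if idx < 0 else flat[int(idx)][1].offset_nm / 1000.0
            pos[i] = outline_points(self.geometry, np.array([t]), off_um)[0]
        return pos

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "geometry": self.geometry.to_dict(),
            "shells": self.shells.to_dict(),
            "proteins": self.proteins.tolist(),
            "distribution": self.distribution.to_dict(),
            "optics": self.optics.to_dict(),
            "seed": self.seed,
            "condition_preset": self.condition_preset,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SceneSpec":
        return cls(
            geometry=RodGeometry.from_dict(d["geometry"]),
            shells=ShellSet.from_dict(d["shells"]),
            proteins=np.asarray(d["proteins"], dtype=float).reshape(-1, 3),
            distribution=ProteinDistributionParams.from_dict(d["distribution"]),
            optics=OpticsNoiseParams.from_dict(d["optics"]),
            seed=int(d["seed"]),
            condition_preset=d["condition_preset"],
        )


@dataclass
class FluorescenceImage:
    """Rendered two-channel raster plus pixel-space ground truth."""

    gfp: np.ndarray
    chl: np.ndarray
    footprint: np.ndarray  # ground-truth boolean cell footprint
    pixel_size_nm: float
    origin_um: tuple[float, float]
    protein_px: np.ndarray  # (n, 2) fractional (row, col) point positions

    def um_to_px(self, xy_um: np.ndarray) -> np.ndarray:
        """World (x, y) um -> fractional (row, col) index coordinates."""
        px = self.pixel_size_nm / 1000.0
        xy = np.atleast_2d(xy_um)
        col = (xy[:, 0] - self.origin_um[0]) / px - 0.5
        row = (xy[:, 1] - self.origin_um[1]) / px - 0.5
        return np.column_stack([row, col])


@dataclass
class TemImage:
    """Rendered thin-section-like raster plus ground truth."""

    image: np.ndarray
    footprint: np.ndarray
    pixel_size_nm: float
    origin_um: tuple[float, float]
    # signed ground-truth membrane offsets from the cell axis along the
    # mid-cell transect, nm (negative = side 1); includes plasma membrane
    transect_positions_nm: np.ndarray


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

FIRST_OFFSET_NM = 40.0  # plasma membrane to first thylakoid layer

GL_SPACING_NM = 78.4
HL_SPACING_NM = 109.2
LL1_SPACING_NM = 110.6


def _layers(offsets_nm, extent=1.0):
    return tuple(Shell(o, extent) for o in offsets_nm)


def _preset_shells(name: str) -> ShellSet:
    f = FIRST_OFFSET_NM
    if name == "GL":
        offs = [f + k * GL_SPACING_NM for k in range(3)]
        return ShellSet(_layers(offs), _layers(offs))
    if name == "HL":
        # one continuous layer plus a fragment near the plasma membrane on
        # side 1; fragment-to-layer distance is the HL inter-layer spacing
        inner = f + HL_SPACING_NM
        return ShellSet(
            side1=(Shell(f, 0.35), Shell(inner, 1.0)),
            side2=(Shell(inner, 1.0),),
        )
    if name == "LL1":
        # the new layer grows on the fragment side; asymmetric arrangement
        inner = f + LL1_SPACING_NM
        return ShellSet(
            side1=(Shell(f, 0.8), Shell(inner, 1.0)),
            side2=(Shell(inner, 1.0),),
        )
    if name == "LL2":
        offs = [f, f + 95.0]
        return ShellSet(
            side1=_layers(offs) + (Shell(f + 2 * 95.0, 0.5),),
            side2=_layers(offs),
        )
    if name == "LL3":
        offs = [f + k * 85.0 for k in range(3)]
        return ShellSet(_layers(offs), _layers(offs))
    if name == "LL4":
        offs = [f + k * 80.0 for k in range(3)]
        return ShellSet(_layers(offs), _layers(offs))
    if name == "LL5":
        offs = [f + k * GL_SPACING_NM for k in range(3)]
        return ShellSet(_layers(offs), _layers(offs))
    raise ValueError(f"unknown preset {name!r}")


PRESETS = ("GL", "HL", "LL1", "LL2", "LL3", "LL4", "LL5")


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------

def _sample_arc_positions(
    dist: ProteinDistributionParams, geometry: RodGeometry, rng: np.random.Generator
) -> np.ndarray:
    """Draw arc fractions from the cluster mixture with side/pole weighting.

    Rejection sampling: a candidate from the mixture is accepted with
    probability proportional to its region weight (side 1: ``a``, side 2: 1,
    poles: ``polar_enrichment``).
    """
    n = dist.n_points
    if n == 0:
        return np.empty(0)

    centers = rng.uniform(0.0, 1.0, size=dist.n_clusters)
    p_cluster = dist.kappa / (1.0 + dist.kappa)
    w = {
        "L1": dist.side_asymmetry,
        "L2": 1.0,
        "P1": dist.polar_enrichment,
        "P2": dist.polar_enrichment,
    }
    wmax = max(w.values())
    if wmax <= 0:
        raise ValueError("all region weights are zero; no density to sample")

    out = np.empty(0)
    while out.size < n:
        m = max(4 * (n - out.size), 256)
        from_cluster = rng.uniform(size=m) < p_cluster
        t = rng.uniform(size=m)
        k = from_cluster.sum()
        if k:
            which = rng.integers(0, dist.n_clusters, size=k)
            t[from_cluster] = (
                centers[which] + rng.normal(0.0, dist.cluster_sigma, size=k)
            ) % 1.0
        labels = region_labels(t, geometry.length, geometry.width)
        weights = np.array([w[l] for l in labels])
        keep = rng.uniform(size=m) * wmax < weights
        out = np.concatenate([out, t[keep]])
    return out[:n]


def _assign_shells(
    t: np.ndarray, shells: ShellSet, rng: np.random.Generator
) -> np.ndarray:
    """Assign each arc position to a shell on its half of the outline.

    A point at arc ``t`` belongs to side 1 if it lies on the half-outline
    centred on the L1 midpoint (wrapped ``|t| <= 0.25``), else side 2.  Among
    that side's shells, only shells whose drawn arc covers ``t`` are eligible;
    with none, the point falls back to the plasma membrane outline.
    """
    flat = shells.flat
    idx = np.full(t.shape, PM_SHELL_INDEX, dtype=float)
    d1 = np.minimum(t % 1.0, 1.0 - t % 1.0)  # wrapped distance to side-1 mid
    on_side1 = d1 <= 0.25
    for i, ti in enumerate(t):
        side = 1 if on_side1[i] else 2
        mid = 0.0 if side == 1 else 0.5
        dist_mid = min(abs(ti - mid), 1.0 - abs(ti - mid))
        eligible = [
            j
            for j, (s, sh) in enumerate(flat)
            if s == side and dist_mid <= sh.arc_extent * 0.25
        ]
        if eligible:
            idx[i] = eligible[int(rng.integers(0, len(eligible)))]
    return idx


def make_scene(
    preset: str = "GL",
    *,
    distribution: ProteinDistributionParams | None = None,
    optics: OpticsNoiseParams | None = None,
    geometry: RodGeometry | None = None,
    shells: ShellSet | None = None,
    seed: int = 0,
) -> SceneSpec:
    """Generate one cell scene with full ground truth.

    With ``geometry=None`` the cell size is jittered around 3.0 x 1.0 um
    (length +-10%, width +-5%) with uniform random orientation.  Identical
    arguments and seed yield an identical scene.
    """
    if preset not in PRESETS and preset != "custom":
        raise ValueError(f"unknown preset {preset!r}; expected one of {PRESETS}")
    rng = np.random.default_rng(seed)
    if geometry is None:
        length = 3.0 * rng.uniform(0.9, 1.1)
        width = 1.0 * rng.uniform(0.95, 1.05)
        orientation = rng.uniform(0.0, 180.0)
        geometry = RodGeometry((0.0, 0.0), orientation, length, width)
    else:
        rng.uniform(size=3)  # keep the stream aligned with the jittered path
    if shells is None:
        if preset == "custom":
            raise ValueError("preset 'custom' requires explicit shells")
        shells = _preset_shells(preset)
    distribution = distribution or ProteinDistributionParams()
    optics = optics or OpticsNoiseParams()

    t = _sample_arc_positions(distribution, geometry, rng)
    shell_idx = _assign_shells(t, shells, rng)
    amps = np.full(t.shape, distribution.amplitude)
    proteins = np.column_stack([t, shell_idx, amps]) if t.size else np.empty((0, 3))

    return SceneSpec(
        geometry=geometry,
        shells=shells,
        proteins=proteins,
        distribution=distribution,
        optics=optics,
        seed=int(seed),
        condition_preset=preset,
    )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _grid_for(scene: SceneSpec, optics: OpticsNoiseParams):
    """Canvas shape and origin containing the cell plus a blur margin."""
    g = scene.geometry
    margin_um = max(3.0 * optics.psf_sigma_nm, 150.0) / 1000.0
    u = g.axis_unit
    half_s = g.side_length / 2.0
    hx = abs(u[0]) * half_s + g.radius + margin_um
    hy = abs(u[1]) * half_s + g.radius + margin_um
    px = optics.pixel_size_nm / 1000.0
    ncols = int(math.ceil(2 * hx / px))
    nrows = int(math.ceil(2 * hy / px))
    origin = (g.center[0] - ncols * px / 2.0, g.center[1] - nrows * px / 2.0)
    return (nrows, ncols), origin


def _check_grid(scene: SceneSpec, optics: OpticsNoiseParams, shape, origin) -> None:
    g = scene.geometry
    margin_um = 3.0 * optics.psf_sigma_nm / 1000.0
    px = optics.pixel_size_nm / 1000.0
    u = g.axis_unit
    half_s = g.side_length / 2.0
    hx = abs(u[0]) * half_s + g.radius + margin_um
    hy = abs(u[1]) * half_s + g.radius + margin_um
    if (
        g.center[0] - hx < origin[0]
        or g.center[1] - hy < origin[1]
        or g.center[0] + hx > origin[0] + shape[1] * px
        or g.center[1] + hy > origin[1] + shape[0] * px
    ):
        raise ValueError(
            "pixel grid too small to contain the cell plus a 3-sigma PSF margin"
        )


def _splat_points(img, row, col, weights) -> None:
    """Bilinear additive splat (conserves total intensity inside the grid)."""
    r0 = np.floor(row).astype(int)
    c0 = np.floor(col).astype(int)
    fr = row - r0
    fc = col - c0
    for dr, dc, w in (
        (0, 0, (1 - fr) * (1 - fc)),
        (0, 1, (1 - fr) * fc),
        (1, 0, fr * (1 - fc)),
        (1, 1, fr * fc),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < img.shape[0]) & (cc >= 0) & (cc < img.shape[1])
        np.add.at(img, (rr[ok], cc[ok]), (weights * w)[ok])


def _um_to_idx(xy_um, origin, px_um):
    col = (xy_um[:, 0] - origin[0]) / px_um - 0.5
    row = (xy_um[:, 1] - origin[1]) / px_um - 0.5
    return row, col


def _splat_shell_arcs(
    img, scene: SceneSpec, origin, px_um, line_density: float, include_pm: bool
) -> None:
    """Draw shell arcs (and optionally the plasma membrane) as intensity
    lines of uniform linear density (counts per pixel of arc length)."""
    g = scene.geometry
    ds_px = 0.3  # sub-pixel step along the arc
    entries = [(side, sh) for side, sh in scene.shells.flat]
    if include_pm:
        entries += [(0, Shell(0.0, 1.0))]
    for side, sh in entries:
        off_um = sh.offset_nm / 1000.0
        L = g.length - 2 * off_um
        W = g.width - 2 * off_um
        per_um = 2 * (L - W) + math.pi * W
        per_px = per_um / px_um
        if side == 0:  # full plasma-membrane ring
            span = 1.0
            mid = 0.0
        else:
            span = sh.arc_extent * 0.5  # fraction of the full outline drawn
            mid = 0.0 if side == 1 else 0.5
        npts = max(int(math.ceil(span * per_px / ds_px)), 8)
        t = (mid - span / 2.0 + span * (np.arange(npts) + 0.5) / npts) % 1.0
        pts = outline_points(g, t, off_um)
        row, col = _um_to_idx(pts, origin, px_um)
        w = np.full(npts, line_density * span * per_px / npts)
        _splat_points(img, row, col, w)


def _apply_noise(img, optics: OpticsNoiseParams, rng: np.random.Generator):
    img = img + optics.background
    if optics.poisson_gain > 0:
        img = rng.poisson(np.maximum(img, 0.0) / optics.poisson_gain) * optics.poisson_gain
        img = img.astype(float)
    if optics.read_sigma > 0:
        img = img + rng.normal(0.0, optics.read_sigma, size=img.shape)
    return img


def render_fluorescence(
    scene: SceneSpec,
    *,
    shape: tuple[int, int] | None = None,
    origin_um: tuple[float, float] | None = None,
    chl_line_density: float = 800.0,
) -> FluorescenceImage:
    """Render the two-channel fluorescence raster.

    GFP channel: protein point amplitudes splatted and PSF-blurred.  Chl
    channel: thylakoid shell arcs at uniform line intensity, blurred the same
    way.  Noise order: blur, background, Poisson, Gaussian read noise.
    """
    optics = scene.optics
    px_um = optics.pixel_size_nm / 1000.0
    if shape is None or origin_um is None:
        shape, origin_um = _grid_for(scene, optics)
    _check_grid(scene, optics, shape, origin_um)

    gfp = np.zeros(shape)
    pos = scene.protein_positions_um()
    if len(pos):
        row, col = _um_to_idx(pos, origin_um, px_um)
        _splat_points(gfp, row, col, scene.proteins[:, 2])
        protein_px = np.column_stack([row, col])
    else:
        protein_px = np.empty((0, 2))

    chl = np.zeros(shape)
    _splat_shell_arcs(chl, scene, origin_um, px_um, chl_line_density, include_pm=False)

    sigma_px = optics.psf_sigma_nm / optics.pixel_size_nm
    if sigma_px > 0:
        # constant padding: blur redistributes intensity and light leaving
        # the grid is lost, never reflected back
        gfp = gaussian_filter(gfp, sigma_px, mode="constant")
        chl = gaussian_filter(chl, sigma_px, mode="constant")

    rng = np.random.default_rng([scene.seed, 7])
    gfp = _apply_noise(gfp, optics, rng)
    chl = _apply_noise(chl, optics, rng)

    footprint = rasterize_footprint(
        scene.geometry, shape, optics.pixel_size_nm, origin_um
    )
    return FluorescenceImage(
        gfp=gfp,
        chl=chl,
        footprint=footprint,
        pixel_size_nm=optics.pixel_size_nm,
        origin_um=origin_um,
        protein_px=protein_px,
    )


def render_tem(
    scene: SceneSpec,
    *,
    optics: OpticsNoiseParams | None = None,
    exterior: float = 210.0,
    cytoplasm: float = 160.0,
    membrane_density: float = 500.0,
    membrane_sigma_nm: float = 8.0,
    shape: tuple[int, int] | None = None,
    origin_um: tuple[float, float] | None = None,
) -> TemImage:
    """Render a thin-section-like raster: dark membrane lines (plasma
    membrane always included) on a cytoplasm darker than the embedding
    background, blurred by the combined membrane/PSF width, then noise."""
    optics = optics or TEM_OPTICS
    px_um = optics.pixel_size_nm / 1000.0
    if shape is None or origin_um is None:
        shape, origin_um = _grid_for(scene, optics)
    _check_grid(scene, optics, shape, origin_um)

    footprint = rasterize_footprint(
        scene.geometry, shape, optics.pixel_size_nm, origin_um
    )
    raw = np.where(footprint, cytoplasm, exterior).astype(float)

    lines = np.zeros(shape)
    _splat_shell_arcs(lines, scene, origin_um, px_um, membrane_density, include_pm=True)
    raw = raw - lines

    sigma_px = (
        math.hypot(optics.psf_sigma_nm, membrane_sigma_nm) / optics.pixel_size_nm
    )
    img = gaussian_filter(raw, sigma_px, mode="nearest") if sigma_px > 0 else raw

    rng = np.random.default_rng([scene.seed, 11])
    img = _apply_noise(img, optics, rng)
    img = np.maximum(img, 0.0)

    # ground truth: signed membrane offsets crossed by the mid-cell transect
    half_nm = scene.geometry.radius * 1000.0
    pos = [-half_nm, half_nm]
    for side, sh in scene.shells.flat:
        sign = -1.0 if side == 1 else 1.0
        pos.append(sign * (half_nm - sh.offset_nm))
    return TemImage(
        image=img,
        footprint=footprint,
        pixel_size_nm=optics.pixel_size_nm,
        origin_um=origin_um,
        transect_positions_nm=np.sort(np.asarray(pos)),
    )
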