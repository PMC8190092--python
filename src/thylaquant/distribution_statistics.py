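"""Summary statistics of protein distribution along the cell periphery.

* patchiness — population SD of the periphery profile normalized by its
  total; low for evenly distributed fluorescence, high for patchy signal.
  The statistic scales as 1/N with the sampling density, so profiles must be
  compared at a fixed number of samples (360 by default elsewhere).
* side asymmetry — ratio of the maximum fluorescence on the two longitudinal
  sides, reported brighter/dimmer so the anchoring convention cannot change
  the value.
* Pearson colocalization of two channels over in-cell pixels (with optional
  Manders split coefficients).
* pooled two-sided two-sample t-test for group comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cell_segmentation import CellMask
from .periphery_profiles import PeripheryProfile

__all__ = [
    "PatchinessValue",
    "AsymmetryValue",
    "TestResult",
    "patchiness",
    "side_asymmetry",
    "pearson_colocalization",
    "manders_coefficients",
    "compare_groups",
]


@dataclass(frozen=True)
class PatchinessValue:
    value: float
    n_samples: int
    channel: str
    normalizer: str = "sum"


@dataclass(frozen=True)
class AsymmetryValue:
    value: float  # >= 1 by construction (brighter / dimmer)
    brighter_side: str  # "L1" or "L2"


@dataclass(frozen=True)
class TestResult:
    t: float
    df: float
    p: float


def patchiness(profile: PeripheryProfile, *, normalizer: str = "sum") -> PatchinessValue:
    """Population SD of the profile divided by its total (or mean).

    The default divides by the sum of the N profile samples ("normalized by
    the total fluorescence"); ``normalizer="mean"`` divides by the mean
    instead (a plain coefficient of variation).  Scale-invariant either way;
    undefined (error) for an all-zero profile.
    """
    v = np.asarray(profile.values, dtype=float)
    total = v.sum()
    if total <= 0:
        raise ValueError("profile total is not positive; patchiness undefined")
    sd = v.std(ddof=0)
    if normalizer == "sum":
        val = sd / total
    elif normalizer == "mean":
        val = sd / v.mean()
    else:
        raise ValueError(f"unknown normalizer {normalizer!r}")
    return PatchinessValue(float(val), len(v), profile.channel, normalizer)


def side_asymmetry(profile: PeripheryProfile) -> AsymmetryValue:
    """Ratio of the longitudinal-side profile maxima, brighter over dimmer."""
    m1 = profile.side_values("L1")
    m2 = profile.side_values("L2")
    if m1.size == 0 or m2.size == 0:
        raise ValueError("both longitudinal sides need profile samples")
    max1 = float(m1.max())
    max2 = float(m2.max())
    if min(max1, max2) <= 0:
        raise ValueError("a side maximum is not positive; ratio undefined")
    if max1 >= max2:
        return AsymmetryValue(max1 / max2, "L1")
    return AsymmetryValue(max2 / max1, "L2")


def pearson_colocalization(
    ch1: np.ndarray, ch2: np.ndarray, mask: CellMask | np.ndarray
) -> float:
    """Pearson correlation of the two channels over in-mask pixels."""
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    a = np.asarray(ch1, dtype=float)[m]
    b = np.asarray(ch2, dtype=float)[m]
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if a.size == 0:
        raise ValueError("empty mask")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance within the mask; correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def manders_coefficients(
    ch1: np.ndarray, ch2: np.ndarray, mask: CellMask | np.ndarray
) -> tuple[float, float]:
    """Manders split coefficients M1, M2 with thresholds at zero."""
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    a = np.asarray(ch1, dtype=float)[m]
    b = np.asarray(ch2, dtype=float)[m]
    ta = a.sum()
    tb = b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("channel totals must be positive")
    return float(a[b > 0].sum() / ta), float(b[a > 0].sum() / tb)


def compare_groups(x, y, *, welch: bool = False) -> TestResult:
    """Two-sided two-sample t-test (pooled variance by default).

    Pooled: t = (mx - my) / (sp sqrt(1/nx + 1/ny)) with
    sp^2 = ((nx-1) sx^2 + (ny-1) sy^2) / (nx + ny - 2) and df = nx + ny - 2.
    Degenerate zero-variance groups: equal means give t = 0, p = 1; unequal
    means are an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nx, ny = x.size, y.size
    if nx < 2 or ny < 2:
        raise ValueError("each group needs at least two observations")
    mx, my = x.mean(), y.mean()
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)

    if welch:
        se2 = sx2 / nx + sy2 / ny
        if se2 == 0:
            if mx == my:
                return TestResult(0.0, float(nx + ny - 2), 1.0)
            raise ValueError("zero variance with unequal means; t undefined")
        t = (mx - my) / math.sqrt(se2)
        df = se2**2 / ((sx2 / nx) ** 2 / (nx - 1) + (sy2 / ny) ** 2 / (ny - 1))
    else:
        df = float(nx + ny - 2)
        sp2 = ((nx - 1) * sx2 + (ny - 1) * sy2) / df
        if sp2 == 0:
            if mx == my:
                return TestResult(0.0, df, 1.0)
            raise ValueError("zero pooled variance with unequal means; t undefined")
        t = (mx - my) / math.sqrt(sp2 * (1.0 / nx + 1.0 / ny))

    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(min(p, 1.0)))
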