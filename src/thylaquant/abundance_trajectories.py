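"""Protein-abundance trajectories across the light-regime time course.

Label-free MS abundances are tabulated long-form (protein, condition,
replicate, abundance) over the seven conditions GL, HL, LL1..LL5.  Values are
normalized per protein to the replicate mean of a reference condition
(GL by default), condition means are fitted with a fourth-degree polynomial
over the integer condition coding 0..6, and goodness of fit is reported as
R-squared and adjusted R-squared,
``adj R2 = 1 - (1 - R2) (n - 1) / (n - p - 1)`` with p = polynomial degree
(parameters excluding the intercept).

Band-intensity tables from native-gel westerns are summarized as
oligomer/monomer ratios (PSI monomer/trimer, PSII monomer/dimer) per
condition, replicate-wise, with mean and SD; conditions where the oligomer
band is absent yield a flagged undefined entry rather than a number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CONDITIONS",
    "TrajectoryFit",
    "NormalizationResult",
    "normalize_to_reference",
    "fit_trajectory",
    "fit_all_trajectories",
    "oligomer_ratios",
    "simulate_abundance_table",
]

logger = logging.getLogger(__name__)

#: Fixed condition order and default integer x-coding 0..6.
CONDITIONS = ("GL", "HL", "LL1", "LL2", "LL3", "LL4", "LL5")

REQUIRED_COLUMNS = ("protein", "condition", "replicate", "abundance")


@dataclass(frozen=True)
class TrajectoryFit:
    degree: int
    coefficients: np.ndarray  # lowest order first
    r2: float
    adj_r2: float
    n: int


@dataclass
class NormalizationResult:
    table: pd.DataFrame
    dropped: list[str]  # proteins excluded for a zero reference mean


def _check_table(table: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"abundance table is missing columns {missing}")


def normalize_to_reference(
    table: pd.DataFrame, reference: str = "GL"
) -> NormalizationResult:
    """Divide every abundance by that protein's reference-condition replicate
    mean; proteins whose reference mean is zero are dropped and reported."""
    _check_table(table)
    if reference not in set(table["condition"]):
        raise ValueError(f"reference condition {reference!r} absent from table")
    ref_means = (
        table[table["condition"] == reference]
        .groupby("protein")["abundance"]
        .mean()
    )
    dropped = sorted(ref_means.index[ref_means <= 0].tolist())
    missing_ref = sorted(set(table["protein"]) - set(ref_means.index))
    dropped += missing_ref
    if dropped:
        logger.info("dropped %d proteins with zero/absent reference mean: %s",
                    len(dropped), dropped)
    out = table[~table["protein"].isin(dropped)].copy()
    out["abundance"] = out["abundance"] / out["protein"].map(ref_means)
    return NormalizationResult(table=out, dropped=dropped)


def fit_trajectory(x, y, degree: int = 4) -> TrajectoryFit:
    """Least-squares polynomial fit with R-squared and adjusted R-squared.

    Requires at least ``degree + 2`` distinct x values so the adjusted
    R-squared is defined (an exact interpolation has no residual degrees of
    freedom).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = x.size
    if len(np.unique(x)) < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} distinct x values, "
            f"got {len(np.unique(x))}"
        )
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    yhat = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - degree - 1)
    return TrajectoryFit(degree, coeffs, r2, adj, n)


def fit_all_trajectories(
    table: pd.DataFrame,
    *,
    degree: int = 4,
    on: str = "mean",
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Fit one trajectory per protein over the condition time course.

    ``on="mean"`` fits the replicate means per condition (the default used
    for the reported curves); ``on="replicates"`` fits all replicate points.
    Returns a frame with columns protein, c0..c<degree>, r2, adj_r2, n.
    """
    _check_table(table)
    xmap = {c: i for i, c in enumerate(conditions)}
    rows = []
    for protein, sub in table.groupby("protein"):
        sub = sub[sub["condition"].isin(xmap)]
        if on == "mean":
            agg = sub.groupby("condition")["abundance"].mean()
            x = np.array([xmap[c] for c in agg.index])
            y = agg.to_numpy()
        elif on == "replicates":
            x = sub["condition"].map(xmap).to_numpy(dtype=float)
            y = sub["abundance"].to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown fit target {on!r}")
        fit = fit_trajectory(x, y, degree)
        row = {"protein": protein, "r2": fit.r2, "adj_r2": fit.adj_r2, "n": fit.n}
        row.update({f"c{i}": c for i, c in enumerate(fit.coefficients)})
        rows.append(row)
    return pd.DataFrame(rows).set_index("protein").sort_index()


#: Oligomer/monomer pairs summarized from native-gel band tables.
RATIO_PAIRS = {
    "PSI monomer/trimer": ("PSI monomer", "PSI trimer"),
    "PSII monomer/dimer": ("PSII monomer", "PSII dimer"),
}


def oligomer_ratios(
    bands: pd.DataFrame, pairs: dict[str, tuple[str, str]] = RATIO_PAIRS
) -> pd.DataFrame:
    """Replicate-wise monomer/oligomer band ratios per condition.

    ``bands`` is long-form (assembly, condition, replicate, intensity).
    Each ratio is computed per replicate then summarized as mean +- SD; a
    zero or missing oligomer band makes the entry undefined
    (``defined=False``, NaN mean) instead of a number.
    """
    for col in ("assembly", "condition", "replicate", "intensity"):
        if col not in bands.columns:
            raise ValueError(f"band table is missing column {col!r}")
    rows = []
    for name, (num, den) in pairs.items():
        for cond, sub in bands.groupby("condition"):
            a = sub[sub["assembly"] == num].set_index("replicate")["intensity"]
            b = sub[sub["assembly"] == den].set_index("replicate")["intensity"]
            common = a.index.intersection(b.index)
            if len(a) != len(b) or len(common) != len(a):
                raise ValueError(
                    f"mismatched replicates for {num!r} vs {den!r} in {cond!r}"
                )
            if len(common) == 0 or (b.loc[common] <= 0).any():
                rows.append(
                    {"ratio": name, "condition": cond, "mean": np.nan,
                     "sd": np.nan, "n": len(common), "defined": False}
                )
                continue
            r = (a.loc[common] / b.loc[common]).to_numpy()
            rows.append(
                {"ratio": name, "condition": cond, "mean": float(r.mean()),
                 "sd": float(r.std(ddof=1)) if r.size > 1 else np.nan,
                 "n": int(r.size), "defined": True}
            )
    return pd.DataFrame(rows)


def simulate_abundance_table(
    *,
    proteins: dict[str, np.ndarray] | None = None,
    n_replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """Synthetic stand-in for the label-free MS output.

    Each protein follows a smooth ground-truth trajectory over the seven
    conditions (quartic in the condition index by default, mimicking the
    deplete-and-recover time course) with multiplicative Gaussian replicate
    noise.  ``proteins`` maps names to length-7 relative trajectories; a
    small default set emulating photosystem depletion/recovery and an
    HL-induced subunit is provided.
    """
    rng = np.random.default_rng(seed)
    x = np.arange(len(conditions))
    if proteins is None:
        xx = x / (len(conditions) - 1)
        proteins = {
            # depleted under HL, recovering through LL (photosystem-like)
            "PS_like_1": 1.0 - 2.8 * xx + 1.0 * xx**2 + 4.0 * xx**3 - 2.2 * xx**4,
            "PS_like_2": 1.0 - 3.2 * xx + 2.0 * xx**2 + 3.5 * xx**3 - 2.1 * xx**4,
            # induced under HL, declining through LL (NDH-1_3-like)
            "HL_induced": 1.0 + 14.0 * xx - 20.0 * xx**2 + 2.0 * xx**3 + 4.0 * xx**4,
        }
    rows = []
    base = rng.uniform(5e5, 5e6, size=len(proteins))  # arbitrary abundance units
    for (name, traj), b in zip(proteins.items(), base):
        traj = np.asarray(traj, dtype=float)
        if traj.shape != x.shape:
            raise ValueError(f"trajectory for {name!r} must have {x.size} values")
        for i, cond in enumerate(conditions):
            for rep in range(1, n_replicates + 1):
                val = b * max(traj[i], 0.0) * rng.lognormal(0.0, noise_sd)
                rows.append(
                    {"protein": name, "condition": cond,
                     "replicate": rep, "abundance": val}
                )
    return pd.DataFrame(rows)
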