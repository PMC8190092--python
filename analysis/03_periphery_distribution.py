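#!/usr/bin/env python
"""Periphery distribution statistics of labelled complexes.

Simulates fluorescence cohorts and quantifies, per cell, the patchiness of
the GFP periphery profile, the longitudinal-side asymmetry ratio, and the
GFP/Chl Pearson colocalization:

* clustering sweep (kappa = 0, 2, 8 at 500 points/cell) — the contrast
  between evenly distributed complexes (ATP-synthase-like) and clustered
  ones (PSI-like);
* side-asymmetry sweep (true ratio 1 and 2) — the early-biogenesis state in
  which new thylakoid membrane and its complexes appear on one longitudinal
  side first.

Writes per-cell tables and the cross-cell mean profiles under results/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from thylaquant.periphery_profiles import average_profiles
from thylaquant.pipelines import profile_cohort
from thylaquant.synthetic_scenes import ProteinDistributionParams

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(parents=True, exist_ok=True)

N_CELLS = 30
SEED = 515


def main() -> None:
    rows = []
    mean_profiles = {}

    for kappa in (0.0, 2.0, 8.0):
        ms = profile_cohort(
            N_CELLS,
            distribution=ProteinDistributionParams(n_points=500, kappa=kappa),
            seed=SEED + int(kappa),
        )
        for i, m in enumerate(ms):
            rows.append({"sweep": "clustering", "level": kappa, "cell": i,
                         "patchiness": m.patchiness, "asymmetry": m.asymmetry,
                         "pearson_gfp_chl": m.colocalization})

    for a in (1.0, 2.0):
        ms = profile_cohort(
            N_CELLS,
            distribution=ProteinDistributionParams(side_asymmetry=a),
            seed=SEED + 100 + int(a),
        )
        mean_profiles[a] = average_profiles([m.profile for m in ms])
        for i, m in enumerate(ms):
            rows.append({"sweep": "asymmetry", "level": a, "cell": i,
                         "patchiness": m.patchiness, "asymmetry": m.asymmetry,
                         "pearson_gfp_chl": m.colocalization})

    df = pd.DataFrame(rows)
    df.to_csv(OUT / "periphery_per_cell.csv", index=False)
    summary = (
        df.groupby(["sweep", "level"])[["patchiness", "asymmetry", "pearson_gfp_chl"]]
        .agg(["mean", "std"])
        .round(5)
    )
    summary.to_csv(OUT / "periphery_summary.csv")
    print(summary.to_string())

    fig, ax = plt.subplots(figsize=(7, 3.2))
    for a, mp in mean_profiles.items():
        ax.plot(mp.positions, mp.mean, label=f"true side ratio {a:g}")
        pd.DataFrame({"position": mp.positions, "mean": mp.mean}).to_csv(
            OUT / f"mean_profile_asym_{a:g}.csv", index=False
        )
    ax.set_xlabel("normalized arc length from L1 midpoint")
    ax.set_ylabel(f"mean GFP intensity ({N_CELLS} cells)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "mean_profiles.png", dpi=120)

    clus = df[df.sweep == "clustering"].groupby("level")["patchiness"].mean()
    asym = df[df.sweep == "asymmetry"].groupby("level")["asymmetry"].mean()
    print(
        f"\nFinding: mean patchiness rises monotonically with clustering "
        f"({clus[0.0]:.5f} -> {clus[2.0]:.5f} -> {clus[8.0]:.5f}); the "
        f"side-maximum ratio recovers the built-in asymmetry "
        f"(true 1 -> {asym[1.0]:.2f}, true 2 -> {asym[2.0]:.2f})."
    )


if __name__ == "__main__":
    main()
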