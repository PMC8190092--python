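#!/usr/bin/env python
"""Render one example cell per light-condition preset.

Writes two-channel fluorescence TIFFs, TEM-like TIFFs and a gallery figure
under results/scenes/.  The presets encode the thylakoid arrangements of the
light regimes: 3 concentric layers at 78.4 nm spacing under growth light,
one continuous layer plus a near-membrane fragment at 109.2 nm under high
light, and a staged return to the growth-light phenotype over five low-light
days.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import tifffile

from thylaquant.synthetic_scenes import PRESETS, make_scene, render_fluorescence, render_tem

OUT = Path(__file__).resolve().parent.parent / "results" / "scenes"
OUT.mkdir(parents=True, exist_ok=True)


def to_u16(img):
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


def main() -> None:
    fig, axes = plt.subplots(3, len(PRESETS), figsize=(3 * len(PRESETS), 9))
    for j, preset in enumerate(PRESETS):
        scene = make_scene(preset, seed=100 + j)
        fl = render_fluorescence(scene)
        tem = render_tem(scene)
        tifffile.imwrite(OUT / f"{preset}_fluor.tif",
                         np.stack([to_u16(fl.gfp), to_u16(fl.chl)]))
        tifffile.imwrite(OUT / f"{preset}_tem.tif", to_u16(tem.image))
        for i, (img, cmap, title) in enumerate(
            [(fl.gfp, "viridis", "GFP"), (fl.chl, "magma", "Chl"),
             (tem.image, "gray", "TEM-like")]
        ):
            ax = axes[i, j]
            ax.imshow(img, cmap=cmap)
            ax.set_axis_off()
            if i == 0:
                ax.set_title(preset)
            if j == 0:
                ax.text(-0.15, 0.5, title, transform=ax.transAxes,
                        rotation=90, va="center")
        n1 = len(scene.shells.side1)
        n2 = len(scene.shells.side2)
        print(f"{preset}: {n1}+{n2} shells, "
              f"L={scene.geometry.length:.2f} um, W={scene.geometry.width:.2f} um")
    fig.tight_layout()
    fig.savefig(OUT / "gallery.png", dpi=120)
    print(f"wrote per-preset TIFFs and gallery.png to {OUT}")


if __name__ == "__main__":
    main()
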