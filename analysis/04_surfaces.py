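#!/usr/bin/env python
"""Response surfaces for the annual models, masked to the observed climate hull.

Re-fits the annual Psd and CVp models and writes hull-masked prediction grids
over (MAT, AP) plus marginal-effect slices of MAT at three AP levels
(results/surfaces/). Grid coordinates are in centered-and-scaled units: 0 is
the species' range-median climate.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mastgrad import climate as cl
from mastgrad import marginality_model as mm
from mastgrad.surfaces import marginal_effect, predict_surface

ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "surfaces"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    metrics = pd.read_csv(ROOT / "metrics.csv")
    climate = pd.read_csv(ROOT / "study" / "climate.csv")
    ranges = cl.range_medians(pd.read_csv(ROOT / "study" / "range_cells.csv"))
    centered = cl.center_design(metrics, climate, ranges)

    for response in ("psd", "cvp"):
        fit = mm.fit_model(mm.ModelSpec(response=response), centered)
        pts = centered.table[["mat", "ap"]]
        grid = predict_surface(fit, "mat", "ap", pts)
        grid.to_frame().to_csv(OUT / f"{response}_annual_mat_ap.csv", index=False)

        inside = grid.predictions[grid.inside_hull]
        print(f"{response}: surface range {inside.min():+.3f} to {inside.max():+.3f} "
              f"({grid.inside_hull.mean():.0%} of grid inside hull)")

        slices = []
        xs = np.linspace(pts["mat"].min(), pts["mat"].max(), 41)
        for ap_level in (-1.0, 0.0, 1.0):
            sl = marginal_effect(fit, "mat", xs, at={"ap": ap_level})
            sl["ap_level"] = ap_level
            slices.append(sl)
        pd.concat(slices).to_csv(OUT / f"{response}_annual_mat_slices.csv", index=False)

    print(f"surfaces written to {OUT}")


if __name__ == "__main__":
    main()
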