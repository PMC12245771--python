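#!/usr/bin/env python
"""Voxel-wise segmented IVIM fitting of the phantom DWI stack.

D comes from the log-linear decay above b = 200 s/mm^2; f and D* from a
bounded nonlinear fit of the full curve with D held fixed.  The script
reports per-habitat recovery of the true parameters and writes the fitted
maps as NIfTI under results/analysis/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ivim_habitat.dwi import DwiStack, VoiMask
from ivim_habitat.ivim import fit_volume

OUTDIR = Path("results/analysis")


def main() -> None:
    dwi = DwiStack.load(OUTDIR / "phantom_dwi.nii.gz", OUTDIR / "phantom.bval")
    mask = VoiMask.load(OUTDIR / "phantom_mask.nii.gz")
    truth = pd.read_csv(OUTDIR / "phantom_truth.csv")

    maps = fit_volume(dwi, mask)
    maps.save(OUTDIR, prefix="ivim")
    print(f"fitted {mask.n_voxels} voxels, "
          f"convergence {100 * maps.convergence_fraction:.1f}%")

    d_fit = maps.d[mask.data]
    f_fit = maps.f[mask.data]
    rows = []
    for part, grp in truth.groupby("label"):
        sel = truth["label"].to_numpy() == part
        rows.append({
            "part": part,
            "true_D": grp["D"].iloc[0], "median_D_hat": np.median(d_fit[sel]),
            "true_f": grp["f"].iloc[0], "median_f_hat": np.median(f_fit[sel]),
        })
    report = pd.DataFrame(rows)
    report["D_err_pct"] = 100 * (report["median_D_hat"] / report["true_D"] - 1)
    report.to_csv(OUTDIR / "ivim_recovery.csv", index=False)
    print(report.to_string(index=False, float_format=lambda v: f"{v:.4g}"))
    worst = report["D_err_pct"].abs().max()
    print(f"worst per-habitat median D error: {worst:.2f}% (SNR 50)")


if __name__ == "__main__":
    main()
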