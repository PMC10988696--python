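#!/usr/bin/env python
"""Fit lifetimes: per-cell ROI decays and the 2x2-binned lifetime image.

Each cell ROI's summed decay gets a biexponential tail fit (start 200 ps
after the peak); the binned frame is fitted per pixel and rendered on the
1.70 ns (blue) to 2.60 ns (red) scale.  Writes results/cell_lifetimes.csv
and image exports under scratch/.
"""

import importlib.util
from pathlib import Path

import numpy as np
import tifffile

from flimfret import (
    FitConfig,
    aggregate_roi_decay,
    bin_pixels,
    fit_lifetime_image,
    read_stack,
    render_lifetime_map,
    tail_fit,
)
from flimfret.io import fit_results_frame

ROOT = Path(__file__).parent.parent
STACK = ROOT / "scratch" / "example_stack.h5"


def _ensure_stack():
    if not STACK.exists():
        spec = importlib.util.spec_from_file_location(
            "simulate_experiment", Path(__file__).parent / "01_simulate_experiment.py"
        )
        mod = importlib.util.module_from_spec(spec)
        spec.loader.exec_module(mod)
        mod.simulate()
    return read_stack(STACK)


def main():
    stack = _ensure_stack()
    config = FitConfig()

    fits = {}
    for label, mask in stack.masks.items():
        fits[label] = tail_fit(aggregate_roi_decay(stack, mask.astype(bool)), config)
    table = fit_results_frame(fits)
    table["group"] = [stack.truth["phantoms"][l]["group"] for l in table["id"]]
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    table.to_csv(out / "cell_lifetimes.csv", index=False)
    print("per-cell ROI fits (amplitude-weighted mean lifetimes):")
    print(table[["id", "group", "tau_mean", "chi2_reduced", "n_photons"]]
          .round(3).to_string(index=False))

    binned = bin_pixels(stack, 2)
    img = fit_lifetime_image(binned, config)
    tifffile.imwrite(ROOT / "scratch" / "lifetime_tau.tif",
                     img.tau_mean.astype(np.float32))
    tifffile.imwrite(ROOT / "scratch" / "lifetime_rgb.tif",
                     render_lifetime_map(img))
    print(f"\nlifetime image: {int(img.valid.sum())} valid binned pixels, "
          f"mean tau_m = {np.nanmean(img.tau_mean):.3f} ns "
          "(exports in scratch/)")


if __name__ == "__main__":
    main()
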