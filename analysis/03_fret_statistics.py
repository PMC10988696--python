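#!/usr/bin/env python
"""FRET statistics for the validation experiment.

Summarises the per-cell amplitude-weighted lifetimes from
results/cell_lifetimes.csv into donor-only and fusion groups, computes
E = 1 - tau_DA/tau_D from the group means, applies the per-cell 3-SD rule
and the Welch t-test, and writes results/fret_report.txt and
results/groups.csv.
"""

import importlib.util
import subprocess
import sys
from pathlib import Path

import pandas as pd

from flimfret import CellMeasurement, group_fret, summarize_group
from flimfret.pipeline import render_report

ROOT = Path(__file__).parent.parent
CELLS_CSV = ROOT / "results" / "cell_lifetimes.csv"


def main():
    if not CELLS_CSV.exists():
        subprocess.run(
            [sys.executable, str(Path(__file__).parent / "02_fit_lifetimes.py")],
            check=True,
        )
    df = pd.read_csv(CELLS_CSV)
    groups = {}
    for group, sub in df.groupby("group"):
        groups[group] = [
            CellMeasurement(cell_id=r["id"], group_label=group,
                            tau_mean=r["tau_mean"], chi2=r["chi2_reduced"],
                            n_photons=int(r["n_photons"]))
            for _, r in sub.iterrows()
            if r["converged"]
        ]
    donor = groups["EGFP"]
    sample = groups["mCherry-EGFP"]
    decision = group_fret(sample, donor)

    out = ROOT / "results"
    pd.DataFrame([vars(summarize_group(donor)), vars(summarize_group(sample))]) \
        .to_csv(out / "groups.csv", index=False)
    report = render_report(decision)
    (out / "fret_report.txt").write_text(report)
    print(report)


if __name__ == "__main__":
    main()
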