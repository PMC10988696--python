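"""Stack container I/O and tabular serialisation.

A simulated or recorded FLIM frame is stored as a single HDF5 file:

    /counts            uint32 [rows, cols, channels]
    /meta              group; attrs: channel_width_ns, repetition_period_ns,
                       n_channels, rows, cols, seed
    /truth             JSON string (optional ground-truth record)
    /masks/<label>     uint8 [rows, cols] per phantom ROI

Round-trips are lossless: counts bit-exact, metadata and ground truth
unchanged.  Malformed containers raise errors naming the missing or
inconsistent field rather than silently repairing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datatypes import AcquisitionConfig, FitResult, PixelHistogramStack

__all__ = ["write_stack", "read_stack", "fit_results_frame", "FIT_CSV_COLUMNS"]

_META_ATTRS = ("channel_width_ns", "repetition_period_ns", "n_channels", "rows", "cols", "seed")

FIT_CSV_COLUMNS = [
    "id",
    "a_fast",
    "tau_fast",
    "a_slow",
    "tau_slow",
    "tau_mean",
    "chi2_reduced",
    "n_photons",
    "converged",
]


def write_stack(stack: PixelHistogramStack, path: str | Path) -> None:
    """Write a stack to the single-file HDF5 container."""
    acq = stack.acquisition
    rows, cols = stack.shape
    with h5py.File(path, "w") as f:
        f.create_dataset("counts", data=stack.counts.astype(np.uint32),
                         compression="gzip", compression_opts=1)
        meta = f.create_group("meta")
        meta.attrs["channel_width_ns"] = acq.channel_width
        meta.attrs["repetition_period_ns"] = acq.repetition_period
        meta.attrs["n_channels"] = acq.n_channels
        meta.attrs["rows"] = rows
        meta.attrs["cols"] = cols
        meta.attrs["seed"] = acq.seed
        if stack.truth is not None:
            f.create_dataset("truth", data=json.dumps(stack.truth))
        if stack.masks:
            mg = f.create_group("masks")
            for label, m in stack.masks.items():
                mg.create_dataset(label, data=np.asarray(m, dtype=np.uint8))


def read_stack(path: str | Path) -> PixelHistogramStack:
    """Read a stack container; raise naming any missing/inconsistent field."""
    with h5py.File(path, "r") as f:
        if "counts" not in f:
            raise ValueError(f"{path}: container is missing /counts")
        if "meta" not in f:
            raise ValueError(f"{path}: container is missing /meta")
        meta = f["meta"].attrs
        for key in _META_ATTRS:
            if key not in meta:
                raise ValueError(f"{path}: /meta is missing attribute {key!r}")
        counts = np.asarray(f["counts"])
        expected = (int(meta["rows"]), int(meta["cols"]), int(meta["n_channels"]))
        if counts.shape != expected:
            raise ValueError(
                f"{path}: /counts shape {counts.shape} does not match "
                f"/meta (rows, cols, n_channels) = {expected}; "
                "container is truncated or corrupt"
            )
        acq = AcquisitionConfig(
            n_channels=int(meta["n_channels"]),
            channel_width=float(meta["channel_width_ns"]),
            repetition_period=float(meta["repetition_period_ns"]),
            image_shape=(int(meta["rows"]), int(meta["cols"])),
            seed=int(meta["seed"]),
        )
        truth = json.loads(f["truth"][()]) if "truth" in f else None
        masks = {}
        if "masks" in f:
            for label in f["masks"]:
                masks[label] = np.asarray(f["masks"][label], dtype=np.uint8)
    return PixelHistogramStack(counts=counts, acquisition=acq, truth=truth, masks=masks)


def fit_results_frame(results: dict[str, FitResult]) -> pd.DataFrame:
    """Serialise fit results as a stable-schema table, one row per decay."""
    rows = [
        {
            "id": key,
            "a_fast": r.a_fast,
            "tau_fast": r.tau_fast,
            "a_slow": r.a_slow,
            "tau_slow": r.tau_slow,
            "tau_mean": r.tau_mean,
            "chi2_reduced": r.chi2_reduced,
            "n_photons": r.n_photons_used,
            "converged": r.converged,
        }
        for key, r in results.items()
    ]
    return pd.DataFrame(rows, columns=FIT_CSV_COLUMNS)
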