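"""FRET efficiency and group statistics from donor lifetimes.

FRET shortens the donor excited-state lifetime; the transfer efficiency
follows from the quenched (τ_DA) and unquenched (τ_D) donor lifetimes:

    E = 1 − τ_DA / τ_D

Per-group statistics follow the conventions of lifetime-based FRET
studies: the unit of replication is the cell (one ROI-aggregated
amplitude-weighted lifetime each), groups are reported as mean ± SEM, a
cell counts as showing FRET when its lifetime undercuts the donor-only
mean by more than three donor-only SDs, and groups are compared with a
two-sided Welch t-test.  A group-level FRET call additionally requires
the efficiency to clear a molecular-crowding floor (default 3%), the
level reachable by co-expressed but non-interacting fluorophores.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CellMeasurement, FretDecision, GroupSummary

__all__ = [
    "fret_efficiency",
    "classify_fret_cell",
    "summarize_group",
    "group_fret",
    "timecourse_compare",
    "CROWDING_FLOOR",
]

CROWDING_FLOOR = 0.03  # efficiencies below this can arise from crowding alone


def fret_efficiency(tau_da: float, tau_d: float) -> float:
    """E = 1 − τ_DA/τ_D.  May be negative; callers flag, never clip."""
    if tau_d <= 0:
        raise ValueError("donor-only lifetime tau_d must be > 0")
    if tau_da <= 0:
        raise ValueError("quenched lifetime tau_da must be > 0")
    return 1.0 - tau_da / tau_d


def summarize_group(cells: Sequence[CellMeasurement]) -> GroupSummary:
    """Mean, sample SD (n−1) and SEM of the cells' lifetimes.

    With a single cell the SD/SEM are undefined and reported as NaN.
    """
    if len(cells) == 0:
        raise ValueError("cannot summarise an empty group")
    taus = np.array([c.tau_mean for c in cells], dtype=float)
    labels = {c.group_label for c in cells}
    label = labels.pop() if len(labels) == 1 else "+".join(sorted(labels))
    n = taus.size
    sd = float(np.std(taus, ddof=1)) if n > 1 else float("nan")
    return GroupSummary(
        group_label=label,
        n_cells=int(n),
        mean_tau=float(taus.mean()),
        sd_tau=sd,
        sem_tau=sd / math.sqrt(n) if n > 1 else float("nan"),
    )


def classify_fret_cell(tau_cell: float, donor_ref: GroupSummary) -> bool:
    """True iff the cell's lifetime is > 3 donor-only SDs below the mean.

    Strict inequality: a cell sitting exactly at mean − 3·SD is not called.
    """
    if donor_ref.n_cells < 2 or not math.isfinite(donor_ref.sd_tau):
        raise ValueError(
            "donor reference needs >= 2 cells for a defined SD "
            f"(got n={donor_ref.n_cells})"
        )
    return tau_cell < donor_ref.mean_tau - 3.0 * donor_ref.sd_tau


def group_fret(
    sample: Sequence[CellMeasurement],
    donor_only: Sequence[CellMeasurement],
    crowding_floor: float = CROWDING_FLOOR,
    alpha: float = 0.05,
) -> FretDecision:
    """Group-level FRET decision for a sample vs a donor-only reference.

    The efficiency is computed from the two group *means* (one E per
    experiment panel), not averaged over per-cell ratios.  The group is
    called FRET-positive when E exceeds the crowding floor AND the Welch
    two-sided t-test between the groups is significant at ``alpha``.
    """
    if len(sample) == 0 or len(donor_only) == 0:
        raise ValueError("both groups must be non-empty")
    donor_summary = summarize_group(donor_only)
    sample_summary = summarize_group(sample)
    efficiency = fret_efficiency(sample_summary.mean_tau, donor_summary.mean_tau)
    flags = tuple(
        classify_fret_cell(c.tau_mean, donor_summary) for c in sample
    )
    sample_taus = [c.tau_mean for c in sample]
    donor_taus = [c.tau_mean for c in donor_only]
    t_stat, p_value = stats.ttest_ind(sample_taus, donor_taus, equal_var=False)
    is_fret = bool(efficiency > crowding_floor and p_value < alpha)
    return FretDecision(
        efficiency=float(efficiency),
        per_cell_flags=flags,
        group_is_fret=is_fret,
        t_statistic=float(t_stat),
        p_value=float(p_value),
        donor_reference=donor_summary,
        sample_summary=sample_summary,
    )


def timecourse_compare(
    groups_by_timepoint: Mapping[str, Sequence[CellMeasurement]],
    donor_ref_by_timepoint: Mapping[str, Sequence[CellMeasurement]],
    crowding_floor: float = CROWDING_FLOOR,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One FRET decision per timepoint against its own donor reference.

    Each timepoint needs an explicit donor-only reference (references are
    never silently shared across conditions).  Returns the efficiency
    trajectory as a table, one row per timepoint in mapping order.
    """
    if len(groups_by_timepoint) < 2:
        raise ValueError("a time course needs at least two timepoints")
    rows = []
    for tp, cells in groups_by_timepoint.items():
        if tp not in donor_ref_by_timepoint:
            raise ValueError(f"missing donor reference for timepoint {tp!r}")
        d = group_fret(cells, donor_ref_by_timepoint[tp],
                       crowding_floor=crowding_floor, alpha=alpha)
        rows.append(
            {
                "timepoint": tp,
                "n_sample": d.sample_summary.n_cells,
                "n_donor": d.donor_reference.n_cells,
                "mean_tau_sample": d.sample_summary.mean_tau,
                "mean_tau_donor": d.donor_reference.mean_tau,
                "efficiency": d.efficiency,
                "t_statistic": d.t_statistic,
                "p_value": d.p_value,
                "group_is_fret": d.group_is_fret,
            }
        )
    return pd.DataFrame(rows)
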