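# flimfret

Simulation and quantification of FLIM-FRET experiments: per-pixel TCSPC
decay simulation, biexponential lifetime fitting, amplitude-weighted mean
lifetimes, FRET-efficiency calculation, and per-cell group statistics.

## The problem

Förster resonance energy transfer (FRET) reports molecular proximity on
the 1–10 nm scale: when an acceptor fluorophore sits close enough to an
excited donor, non-radiative energy transfer shortens the donor's
excited-state lifetime. Fluorescence lifetime imaging (FLIM) with
time-correlated single photon counting (TCSPC) measures that lifetime per
pixel, so protein–protein interactions — e.g. between EGFP-tagged annexins
and mCherry-tagged S100 proteins in living cells — can be quantified
without intensity calibration. This package implements the full analysis
chain for such experiments and, because raw per-cell decay data from
microscopes are rarely shared, a synthetic-data generator that emulates
the acquisition with known ground truth, so every stage is testable.

## The model

A donor population with lifetime components τ_i (photon fractions f_i) is
excited by a pulsed laser (repetition period T = 50 ns, i.e. 20 MHz). The
expected content of TCSPC channel k is

    E[c_k] = N · [ (1−b) · p_k + b/C ]

where p_k integrates the periodic fold of Σ f_i (1/τ_i) e^(−t/τ_i)
convolved with a Gaussian instrument response (IRF) over channel k, b is a
uniform background fraction (< 0.5%), and counts are independently
Poisson. The analysis chain mirrors standard practice:

- **Tail fit**: a biexponential c(t) = N(A_f e^(−t/τ_f) + A_s e^(−t/τ_s))
  is fitted from 200 ps after the decay peak onward (the IRF region is
  distrusted), with normalised amplitudes A_f + A_s = 1 and goodness of
  fit judged by the reduced χ²ν (a quality flag at 1.1). An iterative
  reconvolution fit (IRF ⊛ model over the full window) is available as an
  alternative pathway.
- **Amplitude-weighted mean lifetime**: τ_m = A_f τ_f + A_s τ_s, the
  per-cell summary statistic.
- **Lifetime images**: decay data of 2×2 pixels are binned, fitted per
  pixel, and rendered on a fixed blue (1.70 ns) → red (2.60 ns) scale;
  per-cell decays are obtained by summing all pixels inside an ROI.
- **FRET efficiency**: E = 1 − τ_DA/τ_D from the quenched (τ_DA) and
  donor-only (τ_D) group mean lifetimes.
- **Decision rule**: a cell shows FRET when its τ_m lies more than three
  donor-only standard deviations below the donor-only mean; a group is
  called FRET-positive when E exceeds a 3% molecular-crowding floor and a
  two-sided Welch t-test between the groups has p < 0.05.

## Worked example

The numbered scripts under `analysis/` run a complete validation
experiment: four simulated cells expressing the donor alone (τ = 2.44 ns)
against four expressing a fully bound donor–acceptor fusion with a true
FRET efficiency of 0.25:

```sh
python analysis/01_simulate_experiment.py   # FLIM frame -> scratch/
python analysis/02_fit_lifetimes.py         # ROI + per-pixel fits -> results/
python analysis/03_fret_statistics.py       # group stats + FRET call
python analysis/04_negative_control.py      # null-calibration replicates
```

The third script prints:

```
FLIM-FRET group report
======================
donor-only : tau_m = 2.461 ± 0.005 ns (SEM), n = 4
sample     : tau_m = 1.845 ± 0.001 ns (SEM), n = 4
FRET efficiency E = 1 - tau_DA/tau_D = 25.0%
cells beyond 3 SD of donor-only: 4/4
Welch t-test: t = -113.175, p = 9.81e-07
group FRET call: FRET
```

The donor-only group recovers its 2.44 ns truth to within 1%, the fusion
group recovers the quenched 1.83 ns lifetime, and the efficiency computed
from the two group means lands on the expected 25%. For comparison, an
unquenched donor of 2.44 ns against a quenched lifetime of 1.84 ns gives
E = 1 − 1.84/2.44 ≈ 0.246, i.e. also "approximately 25%".

The same machinery is scriptable through a CLI
(`flimfret simulate | fit-image | roi-fit | fret | report | selftest`);
experiment configs are flat TOML files (see `examples/experiment.toml`)
and FLIM frames are stored in a single-file HDF5 container
(`/counts` uint32 [rows, cols, channels]; `/meta` attrs with channel
width, repetition period and seed; `/truth` JSON; `/masks/<label>` uint8).

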