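# Methods

This note records the models, defaults and numerical choices behind
`flimfret`, and what the synthetic-data tests do and do not demonstrate
about real acquisitions.

## Forward model of a TCSPC acquisition

A pulsed excitation with repetition period T drives a donor population
whose emission density is a mixture of exponentials, Σ f_i (1/τ_i)
e^(−t/τ_i), with photon fractions f_i ≥ 0 summing to one. Photon
*fractions* and pre-exponential *amplitudes* are different weightings of
the same mixture (f_i ∝ A_i τ_i); the package stores ground truth as
photon fractions and reports fits as normalised amplitudes, converting
where needed.

The recorded arrival-time distribution is this mixture convolved with a
Gaussian IRF and folded modulo T. Each component is therefore an
exponentially modified Gaussian; per-channel probabilities are computed
as exact differences of its CDF (`scipy.stats.exponnorm`) summed over
preceding excitation pulses until the geometric tail is below 1e-12 (the
n = −1 term catches IRF mass leaking before t = 0). Incomplete-decay
wrap-around is thus part of the model; for the lifetimes of interest
(≈1.8–2.5 ns against T = 50 ns) its size is small but nonzero, and a
warning is raised when a lifetime reaches T/2, where the fold becomes
substantial. A fraction b of detected photons is uniform background over
the window. Channel counts are drawn independently Poisson, so the frame
total is Poisson around the nominal photon number.

### Defaults and why

| parameter | default | rationale |
|---|---|---|
| repetition period | 50 ns | 20 MHz pulsed excitation |
| channels × width | 1024 × 48.8 ps | tiles the 50 ns window |
| IRF | Gaussian, fwhm 0.1 ns, centre 2 ns | narrow enough that a 200 ps tail offset clears it |
| background fraction | 0.005 | autofluorescence measured below 0.5% of signal in the donor channel |
| photons per cell | 1e5 (ROI-aggregated) | typical of summed-ROI decays; per-pixel counts after 2×2 binning are ~10³–10⁴ |
| cell-to-cell lifetime jitter | 0.03 ns (group simulations) | realistic biological heterogeneity; matches the per-cell spread assumed in the group statistics examples |

Published acquisition protocols state total scan time, not photons per
pixel, so the photon defaults are plausible values chosen once, not
measurements.

## Decay fitting

`tail_fit` fits c(t) = N(a e^(−t/τ_f) + (1−a) e^(−t/τ_s)) (+ optional
constant offset) to the channels starting ceil(200 ps / channel width)
after the maximum-count channel — never earlier than the requested
offset — through the end of the histogram. Design choices:

- **Objective.** The optimiser minimises the Poisson deviance of the
  counts (signed square-root deviance residuals inside a bounded
  trust-region least-squares solver). Per-channel χ² weights of the
  1/max(obs, 1) kind were evaluated and rejected: once tail counts drop
  to a few per channel, each channel's weight anti-correlates with its
  own fluctuation and the amplitude-weighted lifetime comes out several
  percent low (≈−8% at 4×10³ photons in our replicate studies). The
  deviance objective is unbiased there (≤0.2%) and roughly halves the
  replicate-to-replicate spread. The *reported* goodness of fit remains
  the conventional Neyman reduced χ²ν = Σ(obs−model)²/max(obs,1)/(n−k),
  judged against the 1.1 quality threshold; it flags fits, it never
  silently rejects cells.
- **Parameterisation and bounds.** Total intensity N > 0; the amplitude
  split is a logistic fraction, so A_f + A_s = 1 holds by construction;
  0.05 ns ≤ τ ≤ window length. Components are relabelled after the fit so
  τ_f ≤ τ_s always.
- **Initialisation.** Biexponential objectives are ill-conditioned, so
  the solver starts from three lifetime pairs — (0.5 τ̂, 1.5 τ̂),
  (0.3 τ̂, τ̂), (τ̂, 3 τ̂) — seeded by a count-weighted log-linear
  regression estimate τ̂ of the tail slope; the lowest-objective solution
  wins.
- **Degenerate inputs.** Histograms with fewer tail photons than
  `min_photons` (default 400 — amplitude-weighted biexponential estimates
  are unstable below a few hundred counts) or failed optimisations return
  a flagged non-converged result with NaN parameters instead of raising,
  so image fitting can mask pixels instead of aborting. A monoexponential
  model (`model_order=1`) reports a_f = 1, τ_m = τ by convention.

`reconvolution_fit` shares the contract but models the full window as the
same folded-EMG forward model used by the simulator, with the photon
fraction as the mixture parameter (converted to amplitude fractions for
τ_m). Two extra choices: the lifetime lower bound is raised to the IRF
fwhm, because a sub-IRF component is unresolvable yet can absorb peak
noise with almost no χ² cost while dragging the amplitude-weighted mean
down by percents; and the repetition period, which a bare histogram does
not carry, defaults to the histogram span (they coincide on the default
channel grid). Tail fitting is the default pathway throughout; the two
pathways agree within tolerance for a δ-like IRF.

### Known fitting limitations

With *zero* background and low counts the deep tail is all zeros and the
likelihood acquires a nearly flat direction in which a small spurious
fast component can sit; replicate means then skew ≈1–2% low at 4×10³
photons. Real acquisitions (and the generator default) include a small
uniform background, which pins the slow component and removes the skew.
With background present but the offset term disabled (the default, since
background is below 0.5%), the slow component absorbs the background and
biases τ_m up by ≈+0.7% at 10⁵ photons — inside the 1% recovery target
and removable by `include_offset=True` when conditions warrant.

## Imaging

2×2 binning sums channel counts over blocks (edge blocks may be smaller);
photon conservation is exact integer equality, asserted in tests. ROI
decays are channel-wise sums over arbitrary binary masks. Masks travel
with the stack and are downsampled by block-OR when the stack is binned.
Lifetime maps clamp τ_m linearly onto a blue→cyan→green→yellow→red
colormap between 1.70 and 2.60 ns; invalid pixels render black; rendering
is a pure function of the image.

## Group statistics and the FRET decision

The unit of replication is the cell (one ROI-aggregated τ_m each); groups
report mean ± SEM with the sample (n−1) SD. The group FRET efficiency is
computed from the two group *means*, E = 1 − mean(τ_DA)/mean(τ_D) — not
as a mean of per-cell ratios — which reproduces the canonical
2.44/1.84 → ≈25% arithmetic. Negative efficiencies are reported and
flagged, never clipped, since they diagnose a miscalibrated donor
reference. Per-cell calls use the three-SD rule with strict inequality at
the boundary (a cell exactly at mean − 3·SD is not called). The group
call requires both E > 0.03 — the level that molecular crowding alone can
produce between co-expressed but non-interacting fluorophores — and a
two-sided Welch (unequal-variance) t-test at α = 0.05; Welch is the
defensible reading of an "unpaired two-sided t-test" between cell groups
of unequal spread. No multiple-testing correction is applied, matching
the single-comparison design. Time courses evaluate one decision per
timepoint against an explicitly supplied donor reference for that
timepoint; references are never silently shared across conditions.

With a single cell the sample SD is undefined; `summarize_group` reports
NaN and the 3-SD classifier refuses references with n < 2.

## What the synthetic data does and does not show

The generator reproduces the statistical structure of a TCSPC
acquisition — Poisson counting noise, IRF broadening, periodic fold,
uniform background, cell-to-cell lifetime variation — with exactly known
ground truth, so passing tests demonstrate that the estimator chain is
calibrated under those statistics (donor recovery within 1% at 10⁵
photons; E recovery within ±0.02 of a true 0.25; false FRET calls ≤5% on
null samples). It deliberately omits optical effects: detector afterpulsing
and dead time, IRF asymmetry and drift, spectral bleed-through, acceptor
photophysics, autofluorescence with its own decay structure, and motion
within a frame. Agreement on synthetic data therefore validates the
computation, not the microscope; systematic instrument effects must be
controlled experimentally (e.g. the 200 ps tail offset exists precisely
to dodge early-time IRF artefacts).

## Problem sizes

Test and acceptance runs use desk-scale sizes chosen for tight
statistical bands at interactive runtimes: 20 cells per group at 10⁵
photons for recovery checks, 100 scaled-down replicates (5 cells/group)
for the negative-control rate, 40–100 replicates for precision-scaling
checks, and 256-channel histograms where only structure (not timing
resolution) matters.
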