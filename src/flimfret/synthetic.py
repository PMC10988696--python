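"""Synthetic TCSPC/FLIM acquisitions with known ground truth.

Stands in for the microscope: every downstream stage (binning, ROI
aggregation, decay fitting, FRET statistics) can be exercised against
decays whose true lifetimes, bound fractions and FRET efficiencies are
known exactly.

The forward model per channel is the pulsed-excitation expectation

    E[c_k] = N * [ (1 - b) * p_k + b / C ]

where p_k integrates, over channel k, the periodic fold of
Σ f_i (1/τ_i) exp(-t/τ_i) convolved with a Gaussian IRF (an
exponentially-modified Gaussian per component, summed over preceding
excitation pulses), b is the uniform background fraction and C the number
of channels.  Counts are drawn independently Poisson per channel, so the
total is Poisson around N.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from .datatypes import (
    AcquisitionConfig,
    CellPhantom,
    DecayGroundTruth,
    DecayHistogram,
    IrfModel,
    PixelHistogramStack,
)

__all__ = [
    "WraparoundWarning",
    "expected_decay",
    "component_channel_probabilities",
    "simulate_decay_histogram",
    "simulate_flim_image",
    "make_two_population_truth",
]

# Below this IRF width (ns) the Gaussian is numerically a delta and the
# exponnorm parameterisation K = tau/sigma overflows; fall back to the
# plain exponential CDF.
_DELTA_SIGMA = 1e-6


class WraparoundWarning(UserWarning):
    """A lifetime is long enough that inter-pulse fold-over is substantial."""


def _folded_component_cdf(
    edges: np.ndarray, tau: float, irf: IrfModel, period: float
) -> np.ndarray:
    """CDF of arrival time mod the repetition period, evaluated at edges.

    Sums the exponentially-modified-Gaussian CDF over preceding pulses
    (n = -1 covers IRF mass leaking before t = 0, which physically appears
    at the end of the previous period's window).
    """
    sigma = irf.sigma
    if sigma < _DELTA_SIGMA:
        dist = stats.expon(loc=irf.center, scale=tau)
    else:
        dist = stats.exponnorm(K=tau / sigma, loc=irf.center, scale=sigma)
    # enough pulses that the residual geometric tail is < 1e-12
    n_wrap = int(np.ceil(28.0 * tau / period)) + 1
    total = np.zeros_like(edges, dtype=float)
    for n in range(-1, n_wrap + 1):
        total += dist.cdf(edges + n * period)
    return total


def component_channel_probabilities(
    tau: float, irf: IrfModel, config: AcquisitionConfig
) -> np.ndarray:
    """Per-channel detection probability for a single lifetime component.

    Normalised over the acquisition window (photons falling outside the
    recorded window are not counted).
    """
    edges = config.channel_edges()
    cdf = _folded_component_cdf(edges, tau, irf, config.repetition_period)
    p = np.diff(cdf)
    p = np.clip(p, 0.0, None)
    s = p.sum()
    if s <= 0:
        raise ValueError("component has no probability mass inside the window")
    return p / s


def expected_decay(
    truth: DecayGroundTruth,
    irf: IrfModel,
    n_photons: float,
    config: AcquisitionConfig,
) -> np.ndarray:
    """Noise-free expected counts per channel (floats summing to n_photons)."""
    if not n_photons > 0:
        raise ValueError("n_photons must be > 0")
    signal = np.zeros(config.n_channels)
    for frac, tau in truth.components:
        if frac == 0.0:
            continue
        signal += frac * component_channel_probabilities(tau, irf, config)
    s = signal.sum()
    if s > 0:
        signal /= s
    b = truth.background_fraction
    return n_photons * ((1.0 - b) * signal + b / config.n_channels)


def _warn_on_wraparound(truth: DecayGroundTruth, config: AcquisitionConfig) -> None:
    for _, tau in truth.components:
        if tau >= config.repetition_period / 2.0:
            warnings.warn(
                f"lifetime {tau} ns >= half the repetition period "
                f"({config.repetition_period} ns): substantial inter-pulse "
                "wrap-around is being simulated",
                WraparoundWarning,
                stacklevel=3,
            )


def simulate_decay_histogram(
    truth: DecayGroundTruth,
    irf: IrfModel,
    n_photons: float,
    config: AcquisitionConfig,
    seed: int | np.random.Generator | None = None,
) -> DecayHistogram:
    """Simulate one TCSPC histogram by Poisson sampling the expected decay.

    ``seed`` may be an integer, a Generator (consumed in place) or None
    (then ``config.seed`` is used). Fixing the seed fixes the output
    bit-for-bit.
    """
    _warn_on_wraparound(truth, config)
    expected = expected_decay(truth, irf, n_photons, config)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(config.seed if seed is None else seed)
    )
    counts = rng.poisson(expected).astype(np.uint32)
    return DecayHistogram(counts=counts, channel_width=config.channel_width)


def simulate_flim_image(
    phantoms: list[CellPhantom],
    irf: IrfModel,
    config: AcquisitionConfig,
    background_photons_per_pixel: float = 0.0,
) -> PixelHistogramStack:
    """Simulate a FLIM frame from cell phantoms.

    Each masked pixel gets an independent Poisson histogram drawn from its
    phantom's decay model; unmasked pixels carry only uniform background
    counts (``background_photons_per_pixel`` expected photons each, 0 by
    default).  Overlapping phantom masks are rejected: the ground truth of
    a shared pixel would be ambiguous.  The stack records each phantom's
    ground truth and mask for later scoring.
    """
    rows, cols = config.image_shape
    occupancy = np.zeros((rows, cols), dtype=np.int64)
    for ph in phantoms:
        if ph.mask.shape != (rows, cols):
            raise ValueError(
                f"phantom {ph.label!r} mask shape {ph.mask.shape} does not "
                f"match image_shape {(rows, cols)}"
            )
        occupancy += ph.mask
    if np.any(occupancy > 1):
        raise ValueError("phantom masks overlap: ground truth would be ambiguous")

    rng = np.random.default_rng(config.seed)
    counts = np.zeros((rows, cols, config.n_channels), dtype=np.uint32)

    if background_photons_per_pixel > 0:
        lam = background_photons_per_pixel / config.n_channels
        counts += rng.poisson(lam, size=counts.shape).astype(np.uint32)

    truth_record: dict = {"phantoms": {}}
    masks: dict[str, np.ndarray] = {}
    for ph in phantoms:
        _warn_on_wraparound(ph.truth, config)
        expected = expected_decay(ph.truth, irf, ph.photons_per_pixel, config)
        idx = np.argwhere(ph.mask)
        drawn = rng.poisson(expected, size=(len(idx), config.n_channels))
        counts[idx[:, 0], idx[:, 1], :] += drawn.astype(np.uint32)
        masks[ph.label] = ph.mask.astype(np.uint8)
        truth_record["phantoms"][ph.label] = {
            "group": ph.group,
            "photons_per_pixel": ph.photons_per_pixel,
            "truth": ph.truth.to_dict(),
        }
    truth_record["background_photons_per_pixel"] = background_photons_per_pixel

    return PixelHistogramStack(
        counts=counts, acquisition=config, truth=truth_record, masks=masks
    )


def make_two_population_truth(
    tau_donor: float, e_true: float, bound_fraction: float
) -> DecayGroundTruth:
    """Decay model for a partially bound donor population.

    A bound donor is quenched by FRET to τ_D·(1−E); an unbound donor keeps
    τ_D.  ``bound_fraction`` of the photons come from the quenched
    component.  Zero-fraction components are dropped.
    """
    if not 0.0 <= e_true < 1.0:
        raise ValueError(f"e_true must be in [0, 1), got {e_true}")
    if not 0.0 <= bound_fraction <= 1.0:
        raise ValueError(f"bound_fraction must be in [0, 1], got {bound_fraction}")
    if not tau_donor > 0:
        raise ValueError("tau_donor must be > 0")
    components = []
    if bound_fraction > 0:
        components.append((bound_fraction, tau_donor * (1.0 - e_true)))
    if bound_fraction < 1:
        components.append((1.0 - bound_fraction, tau_donor))
    return DecayGroundTruth(components=tuple(components))
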