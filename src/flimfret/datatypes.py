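"""Core containers shared across the FLIM-FRET pipeline.

The atomic measurement is a :class:`DecayHistogram` — photon counts per
TCSPC time channel.  An image of such histograms plus acquisition metadata
is a :class:`PixelHistogramStack`.  Fitting a decay yields a
:class:`FitResult`; ROI aggregation and fitting per cell yields
:class:`CellMeasurement` rows, which the statistics layer summarises into
:class:`GroupSummary` and :class:`FretDecision`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "IrfModel",
    "DecayGroundTruth",
    "CellPhantom",
    "AcquisitionConfig",
    "DecayHistogram",
    "PixelHistogramStack",
    "FitConfig",
    "FitResult",
    "LifetimeImage",
    "CellMeasurement",
    "GroupSummary",
    "FretDecision",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class IrfModel:
    """Gaussian instrument response function.

    Parameters
    ----------
    center : float
        Time offset of the excitation flash within the TCSPC window (ns).
    fwhm : float
        Full width at half maximum of the Gaussian kernel (ns).
    """

    center: float = 2.0
    fwhm: float = 0.1

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError(f"IRF fwhm must be > 0, got {self.fwhm}")
        if self.center < 0:
            raise ValueError(f"IRF center must be >= 0, got {self.center}")

    @property
    def sigma(self) -> float:
        """Gaussian standard deviation (ns)."""
        return self.fwhm * _FWHM_TO_SIGMA


@dataclass(frozen=True)
class DecayGroundTruth:
    """True emission model behind a simulated decay.

    ``components`` is a tuple of ``(fraction, lifetime_ns)`` pairs where the
    fractions are *photon* fractions: each component contributes
    ``fraction * (1/tau) * exp(-t/tau)`` to the emission density, so the
    fractions weight normalised exponential pdfs and must sum to one.
    ``background_fraction`` is the fraction of detected photons that is
    uniform over the excitation window (autofluorescence / dark counts).
    """

    components: tuple[tuple[float, float], ...]
    background_fraction: float = 0.0

    def __post_init__(self) -> None:
        comps = tuple((float(f), float(t)) for f, t in self.components)
        object.__setattr__(self, "components", comps)
        if not comps:
            raise ValueError("at least one decay component is required")
        fracs = [f for f, _ in comps]
        taus = [t for _, t in comps]
        if any(f < 0 for f in fracs):
            raise ValueError(f"component fractions must be >= 0, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"component fractions must sum to 1, got {sum(fracs)}")
        if any(t <= 0 for t in taus):
            raise ValueError(f"lifetimes must be > 0, got {taus}")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError(
                f"background_fraction must be in [0, 1), got {self.background_fraction}"
            )

    @property
    def lifetimes(self) -> tuple[float, ...]:
        return tuple(t for _, t in self.components)

    def mean_photon_lifetime(self) -> float:
        """Intensity-weighted mean lifetime Σ f_i τ_i (ns)."""
        return sum(f * t for f, t in self.components)

    def amplitude_weighted_lifetime(self) -> float:
        """Amplitude-weighted mean lifetime Σ a_i τ_i with a_i ∝ f_i/τ_i (ns).

        Photon fractions f_i relate to pre-exponential amplitudes a_i by
        f_i ∝ a_i τ_i; this converts back and applies the amplitude weighting
        used throughout the analysis.
        """
        alphas = [f / t for f, t in self.components]
        total = sum(alphas)
        return sum(al / total * t for al, (_, t) in zip(alphas, self.components))

    def to_dict(self) -> dict:
        return {
            "components": [list(c) for c in self.components],
            "background_fraction": self.background_fraction,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DecayGroundTruth":
        return cls(
            components=tuple(tuple(c) for c in d["components"]),
            background_fraction=d.get("background_fraction", 0.0),
        )


@dataclass(frozen=True)
class CellPhantom:
    """A simulated cell: a labelled pixel region with a known decay model."""

    label: str
    mask: np.ndarray
    photons_per_pixel: float
    truth: DecayGroundTruth
    group: str = ""

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 2:
            raise ValueError("phantom mask must be a 2-D binary raster")
        if not mask.any():
            raise ValueError(f"phantom {self.label!r} has an empty mask")
        if not self.photons_per_pixel > 0:
            raise ValueError("photons_per_pixel must be > 0")


@dataclass(frozen=True)
class AcquisitionConfig:
    """TCSPC acquisition geometry and timing.

    Defaults describe a 20 MHz pulsed excitation (50 ns repetition period)
    with 1024 channels tiling the window (≈48.8 ps per channel).
    """

    n_channels: int = 1024
    channel_width: float = 50.0 / 1024.0
    repetition_period: float = 50.0
    image_shape: tuple[int, int] = (64, 64)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels <= 0:
            raise ValueError("n_channels must be > 0")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be > 0")
        if self.repetition_period <= 0:
            raise ValueError("repetition_period must be > 0")
        if any(s <= 0 for s in self.image_shape):
            raise ValueError("image_shape entries must be > 0")
        window = self.n_channels * self.channel_width
        if window > self.repetition_period + self.channel_width:
            raise ValueError(
                "TCSPC window exceeds the repetition period: "
                f"{self.n_channels} x {self.channel_width} ns > "
                f"{self.repetition_period} ns"
            )

    @property
    def window(self) -> float:
        """Total histogram span (ns)."""
        return self.n_channels * self.channel_width

    def channel_edges(self) -> np.ndarray:
        return np.arange(self.n_channels + 1) * self.channel_width

    def replace(self, **kw) -> "AcquisitionConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class DecayHistogram:
    """Photon counts per TCSPC time channel for one pixel or one ROI."""

    counts: np.ndarray
    channel_width: float
    t0_channel: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size < 16:
            raise ValueError("counts must be 1-D with at least 16 channels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        if self.channel_width <= 0:
            raise ValueError("channel_width must be > 0")

    @property
    def n_channels(self) -> int:
        return int(self.counts.size)

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def times(self) -> np.ndarray:
        """Channel-center times relative to histogram start (ns)."""
        return (np.arange(self.n_channels) + 0.5 + self.t0_channel) * self.channel_width


@dataclass
class PixelHistogramStack:
    """Image of decay histograms: counts[rows, cols, channels] plus metadata.

    ``truth`` optionally records the simulation ground truth (per-phantom
    decay models) and ``masks`` the per-phantom binary ROIs, so downstream
    stages can be scored against what was simulated.
    """

    counts: np.ndarray
    acquisition: AcquisitionConfig
    truth: Optional[dict] = None
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 3:
            raise ValueError("stack counts must be [rows, cols, channels]")
        if np.any(counts < 0):
            raise ValueError("stack counts must be non-negative")
        if counts.shape[2] != self.acquisition.n_channels:
            raise ValueError(
                f"stack has {counts.shape[2]} channels but acquisition "
                f"declares {self.acquisition.n_channels}"
            )
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    def pixel_histogram(self, row: int, col: int) -> DecayHistogram:
        return DecayHistogram(
            counts=self.counts[row, col], channel_width=self.acquisition.channel_width
        )


@dataclass(frozen=True)
class FitConfig:
    """Decay-fitting configuration.

    The tail fit starts ``tail_start_offset`` (default 200 ps) after the
    histogram peak; ``chi2_threshold`` (default 1.1) flags questionable fits
    but never rejects them; ``model_order`` selects mono- (1) or
    bi-exponential (2) models.
    """

    tail_start_offset: float = 0.200
    chi2_threshold: float = 1.1
    model_order: int = 2
    min_photons: int = 400
    include_offset: bool = False
    use_reconvolution: bool = False

    def __post_init__(self) -> None:
        if self.tail_start_offset < 0:
            raise ValueError("tail_start_offset must be >= 0")
        if self.chi2_threshold <= 0:
            raise ValueError("chi2_threshold must be > 0")
        if self.model_order not in (1, 2):
            raise ValueError("model_order must be 1 or 2")
        if self.min_photons < 0:
            raise ValueError("min_photons must be >= 0")

    def replace(self, **kw) -> "FitConfig":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class FitResult:
    """Biexponential fit of one decay.

    Amplitudes are normalised (``a_fast + a_slow == 1``) and components
    ordered so ``tau_fast <= tau_slow``.  ``tau_mean`` is the
    amplitude-weighted mean lifetime a_f·τ_f + a_s·τ_s.  For a
    monoexponential fit the slow component is absent by convention
    (``a_fast=1, a_slow=0, tau_mean=tau_fast``).
    """

    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    offset: float
    chi2_reduced: float
    tau_mean: float
    n_photons_used: int
    converged: bool

    def quality_ok(self, chi2_threshold: float = 1.1) -> bool:
        """Quality flag: converged with χ²ν below the threshold."""
        return bool(self.converged and self.chi2_reduced < chi2_threshold)


@dataclass
class LifetimeImage:
    """Per-(binned-)pixel amplitude-weighted lifetimes with a validity mask."""

    tau_mean: np.ndarray
    chi2: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.tau_mean.shape == self.chi2.shape == self.valid.shape):
            raise ValueError("tau_mean, chi2 and valid must share one shape")


@dataclass(frozen=True)
class CellMeasurement:
    """One cell's ROI-aggregated lifetime — the unit of replication."""

    cell_id: str
    group_label: str
    tau_mean: float
    chi2: float = float("nan")
    n_photons: int = 0

    def __post_init__(self) -> None:
        if not self.tau_mean > 0:
            raise ValueError(f"tau_mean must be > 0, got {self.tau_mean}")


@dataclass(frozen=True)
class GroupSummary:
    """Mean ± SEM of amplitude-weighted lifetimes over the cells of a group."""

    group_label: str
    n_cells: int
    mean_tau: float
    sd_tau: float
    sem_tau: float


@dataclass(frozen=True)
class FretDecision:
    """Group-level FRET call: efficiency, per-cell 3-SD flags, Welch test."""

    efficiency: float
    per_cell_flags: tuple[bool, ...]
    group_is_fret: bool
    t_statistic: float
    p_value: float
    donor_reference: GroupSummary
    sample_summary: GroupSummary
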