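"""Shared configuration types and the assay's named default constants.

Every threshold the assay depends on lives here as a named constant:
the photon-count SNR cutoff, the spatial-binning kernel sizes, the
Voronoi region-size guard, the PI death threshold, the tri-state NMS
band edges, the KDE grid step, and the cross-validation fold count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Tuple

# --- assay defaults -------------------------------------------------------

#: Strict lower photon-count bound for a pixel to enter the analysis (n > 20).
MIN_PHOTONS = 20
#: Circular spatial-binning kernel size for the NAD(P)H channel.
KERNEL_SIZE_NADH = 5
#: Circular spatial-binning kernel size for the FAD channel.
KERNEL_SIZE_FAD = 6
#: Voronoi regions with strictly more pixels than this are excluded.
MAX_REGION_PX = 1000
#: A cell is marked PI-dead when its summed PI counts strictly exceed this.
PI_DEAD_COUNTS = 1000
#: Left (necroptotic) NMS band edge.
NMS_LEFT_THRESHOLD = -0.28
#: Right (apoptotic/necrotic) NMS band edge.
NMS_RIGHT_THRESHOLD = 0.33
#: KDE evaluation-grid step.
KDE_STEP = 5e-3
#: Default KDE grid bounds for LMR and NMS distributions.
LMR_GRID = (-0.5, 3.0)
NMS_GRID = (-0.5, 1.0)
#: Folds for cross-validated AUROC / optimal-threshold estimation.
CV_FOLDS = 10
#: Minimum pixels pooled for an IRF calibration phasor.
MIN_CALIBRATION_PIXELS = 500

#: Pure-species reference lifetimes (ns).  For NAD(P)H the short-lifetime
#: species is the free (unbound) form; for FAD the short species is the
#: protein-bound form.
NADH_TAU_SHORT_NS = 0.4
NADH_TAU_LONG_NS = 3.5
FAD_TAU_SHORT_NS = 0.3
FAD_TAU_LONG_NS = 2.8


@dataclass(frozen=True)
class AcquisitionConfig:
    """TCSPC acquisition geometry shared by the simulator and the transform.

    Parameters
    ----------
    n_time_bins:
        Number of histogram time bins G per pixel.
    period_ns:
        Decay record period D in ns.  The default 12.5 ns corresponds to an
        80 MHz pulse train; the first-harmonic phasor frequency is 1/D.
    image_size:
        Pixels per side of the (square) frame.
    irf_center_ns, irf_fwhm_ns:
        Peak position and full width at half maximum of the Gaussian
        instrument response function.
    seed:
        Seed for every stochastic draw made with this configuration.
    """

    n_time_bins: int = 256
    period_ns: float = 12.5
    image_size: int = 512
    irf_center_ns: float = 2.0
    irf_fwhm_ns: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_time_bins < 2:
            raise ValueError("n_time_bins must be >= 2")
        if self.period_ns <= 0:
            raise ValueError("period_ns must be positive")
        if self.irf_fwhm_ns < 0:
            raise ValueError("irf_fwhm_ns must be nonnegative")
        if self.irf_fwhm_ns > self.period_ns:
            raise ValueError("IRF wider than the decay period")
        if self.image_size < 1:
            raise ValueError("image_size must be >= 1")

    @property
    def frequency_ghz(self) -> float:
        """First-harmonic phasor frequency 1/D (GHz when D is in ns)."""
        return 1.0 / self.period_ns

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_time_bins

    @property
    def bin_centers_ns(self):
        import numpy as np

        return (np.arange(self.n_time_bins) + 0.5) * self.bin_width_ns


@dataclass(frozen=True)
class PreprocessConfig:
    """Photon threshold and binning-kernel settings."""

    min_photons: int = MIN_PHOTONS
    kernel_size_nadh: int = KERNEL_SIZE_NADH
    kernel_size_fad: int = KERNEL_SIZE_FAD

    def __post_init__(self) -> None:
        if self.min_photons < 0:
            raise ValueError("min_photons must be >= 0")
        if self.kernel_size_nadh < 1 or self.kernel_size_fad < 1:
            raise ValueError("kernel sizes must be >= 1")


@dataclass(frozen=True)
class SegmentationConfig:
    """Voronoi-region filtering and PI death-call settings."""

    max_region_px: int = MAX_REGION_PX
    pi_dead_counts: int = PI_DEAD_COUNTS

    def __post_init__(self) -> None:
        if self.max_region_px <= 0 or self.pi_dead_counts <= 0:
            raise ValueError("segmentation thresholds must be positive")


@dataclass(frozen=True)
class ThresholdBands:
    """Tri-state NMS classification bands.

    NMS below ``t_left`` is called necroptotic, NMS in the closed interval
    [t_left, t_right] viable, and NMS above ``t_right`` apoptotic/necrotic.
    """

    t_left: float = NMS_LEFT_THRESHOLD
    t_right: float = NMS_RIGHT_THRESHOLD
    provenance: str = "CT26 viability screen + shikonin AUROC defaults"

    def __post_init__(self) -> None:
        if not self.t_left < self.t_right:
            raise ValueError("t_left must be < t_right")


@dataclass
class RunConfig:
    """Top-level run settings tying the pipeline stages together."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    bands: ThresholdBands = field(default_factory=ThresholdBands)
    pooling: str = "population"  # or "fragment"
    seed: int = 0
    lmr_grid: Tuple[float, float] = LMR_GRID
    nms_grid: Tuple[float, float] = NMS_GRID
    kde_step: float = KDE_STEP

    def to_dict(self) -> dict:
        return asdict(self)
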