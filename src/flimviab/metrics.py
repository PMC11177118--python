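"""Lifetime Metabolic Ratio (LMR) and Normalized Metabolic Shift (NMS).

The LMR combines the two channels' phasor ratios into a single metabolic
index,

.. math:: \\mathrm{LMR} = \\frac{1 - r_\\mathrm{NAD(P)H}}{r_\\mathrm{FAD}},

where :math:`r_\\mathrm{NAD(P)H}` is the free-NAD(P)H (short-species)
intensity fraction and :math:`r_\\mathrm{FAD}` the bound-FAD
(short-species) fraction, so numerator and denominator are both bound
fractions.  Treatment response is quantified as a shift against baseline,

.. math:: \\mathrm{NMS} = \\mathrm{LMR}(t_n) - \\mathrm{mode}\\,\\mathrm{LMR}(t_0),

with the baseline mode taken either from the same fragment before
treatment or from the pooled single-cell LMR population (viability
screen).  Modes are located on a kernel-density estimate evaluated on a
fixed grid (step 5e-3) and normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .config import KDE_STEP, LMR_GRID, NMS_GRID

__all__ = ["MetricImage", "KdeGrid", "lmr", "kde", "distribution_mode", "nms"]

#: Pixels with |r_FAD| below this are flagged invalid in the LMR.
LMR_DENOMINATOR_TOL = 1e-3


@dataclass
class MetricImage:
    """Per-masked-pixel real metric map (LMR or NMS)."""

    values: np.ndarray
    mask: np.ndarray
    metric: str = ""
    timepoint: str = ""
    baseline_mode: Optional[float] = None

    def finite_values(self) -> np.ndarray:
        v = self.values[self.mask]
        return v[np.isfinite(v)]


@dataclass
class KdeGrid:
    """Fixed evaluation grid with (optionally) the estimated densities.

    Densities are normalized so that they sum to one over the grid points.
    """

    lo: float
    hi: float
    step: float = KDE_STEP
    density: Optional[np.ndarray] = None

    @property
    def points(self) -> np.ndarray:
        n = int(round((self.hi - self.lo) / self.step)) + 1
        return self.lo + self.step * np.arange(n)


def lmr(r_nadh: MetricImage, r_fad: MetricImage,
        denominator_tol: float = LMR_DENOMINATOR_TOL) -> MetricImage:
    """Per-pixel LMR = (1 - r_NADH) / r_FAD on the shared mask.

    Pixels where |r_FAD| falls below ``denominator_tol`` are flagged
    invalid (NaN) and removed from the output mask.
    """
    if r_nadh.values.shape != r_fad.values.shape:
        raise ValueError("channel ratio images must share a shape")
    mask = r_nadh.mask & r_fad.mask
    ok = mask & (np.abs(r_fad.values) >= denominator_tol)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = (1.0 - r_nadh.values) / r_fad.values
    values = np.where(ok, values, np.nan)
    return MetricImage(values=values, mask=ok, metric="lmr",
                       timepoint=r_nadh.timepoint)


def kde(values: np.ndarray, grid: KdeGrid,
        bandwidth: Optional[float] = None) -> KdeGrid:
    """Gaussian KDE on the fixed grid, renormalized to sum to one.

    Bandwidth defaults to Silverman's rule on the input sample.  A
    zero-variance sample degenerates to a point mass at the grid point
    nearest the common value.
    """
    values = np.asarray(values, dtype=float).ravel()
    values = values[np.isfinite(values)]
    if values.size == 0:
        raise ValueError("KDE requires at least one finite value")
    pts = grid.points
    if values.size == 1 or np.ptp(values) == 0:
        density = np.zeros(pts.size)
        density[int(np.argmin(np.abs(pts - values[0])))] = 1.0
    else:
        bw = bandwidth if bandwidth is not None else "silverman"
        k = stats.gaussian_kde(values, bw_method=bw)
        density = k(pts)
        total = density.sum()
        if total <= 0:
            raise ValueError("all density mass falls outside the grid")
        density = density / total
    return KdeGrid(lo=grid.lo, hi=grid.hi, step=grid.step, density=density)


def distribution_mode(values: np.ndarray, grid: KdeGrid,
                      bandwidth: Optional[float] = None) -> float:
    """Grid point maximizing the KDE; ties break toward the lower value."""
    est = kde(values, grid, bandwidth)
    return float(est.points[int(np.argmax(est.density))])


def default_lmr_grid() -> KdeGrid:
    return KdeGrid(lo=LMR_GRID[0], hi=LMR_GRID[1], step=KDE_STEP)


def default_nms_grid() -> KdeGrid:
    return KdeGrid(lo=NMS_GRID[0], hi=NMS_GRID[1], step=KDE_STEP)


def nms(lmr_tn: MetricImage, baseline, pooling: str = "per_fragment_baseline",
        grid: Optional[KdeGrid] = None) -> MetricImage:
    """NMS = LMR(t_n) minus the baseline LMR mode.

    ``baseline`` is either a :class:`MetricImage` of baseline LMR (the mode
    is computed on its pixel values for ``per_fragment_baseline`` pooling,
    or on whatever sample it carries for ``population_mode`` — typically
    per-cell mean LMR pooled over a screen), or an already-computed scalar
    mode.
    """
    if pooling not in ("per_fragment_baseline", "population_mode"):
        raise ValueError("pooling must be per_fragment_baseline or population_mode")
    if baseline is None:
        raise ValueError("missing baseline")
    if isinstance(baseline, MetricImage):
        sample = baseline.finite_values()
        mode = distribution_mode(sample, grid or default_lmr_grid())
    elif np.ndim(baseline) > 0:
        mode = distribution_mode(np.asarray(baseline), grid or default_lmr_grid())
    else:
        mode = float(baseline)
    if not np.isfinite(mode):
        raise ValueError("baseline mode is not finite")
    return MetricImage(values=lmr_tn.values - mode, mask=lmr_tn.mask,
                       metric="nms", timepoint=lmr_tn.timepoint,
                       baseline_mode=mode)
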