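"""First-harmonic phasor analysis of TCSPC decay histograms.

The phasor of a per-pixel decay histogram :math:`G_p` is

.. math:: z = \\frac{\\sum_{p=1}^{G} G_p\\, e^{i 2\\pi f t_p}}{\\sum_{p=1}^{G} G_p},

with ``f`` the first-harmonic frequency (the inverse of the decay record
period) and ``t_p`` the bin-center times.  Noiseless mono-exponential decays
fall on the universal semicircle ``g = 1/(1+(\\omega\\tau)^2)``,
``s = \\omega\\tau/(1+(\\omega\\tau)^2)``; a measured instrument response with
effective lifetime 0 ns provides the calibration phasor ``z_IT`` and raw
phasors are calibrated by complex division ``z / z_IT``.

The intensity fraction of the short-lifetime species in a two-species
mixture is recovered by orthogonal projection of the calibrated phasor onto
the chord joining the two pure-species reference phasors (the phasor ratio).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import MIN_CALIBRATION_PIXELS

__all__ = [
    "Phasor",
    "PhasorImage",
    "CalibrationPhasor",
    "ReferencePair",
    "phasor_transform",
    "calibration_from_irf",
    "calibrate",
    "phasor_of_lifetime",
    "lifetime_from_phasor",
    "phasor_ratio",
    "references_from_lifetimes",
    "references_from_cloud",
]


@dataclass(frozen=True)
class Phasor:
    """A single first-harmonic phasor (g, s)."""

    g: float
    s: float

    @property
    def z(self) -> complex:
        return complex(self.g, self.s)

    @staticmethod
    def from_complex(z: complex) -> "Phasor":
        return Phasor(float(np.real(z)), float(np.imag(z)))


@dataclass
class PhasorImage:
    """Per-pixel phasors defined on a mask.

    ``g`` and ``s`` are float arrays; pixels outside ``mask`` (or with an
    undefined phasor, e.g. zero counts) hold NaN.
    """

    g: np.ndarray
    s: np.ndarray
    mask: np.ndarray
    frequency_ghz: float
    channel: str = ""

    @property
    def z(self) -> np.ndarray:
        return self.g + 1j * self.s


@dataclass(frozen=True)
class CalibrationPhasor:
    """Pooled IRF phasor used to calibrate a channel/excitation.

    The phasor is computed on the photon-weighted pooled histogram of at
    least ``MIN_CALIBRATION_PIXELS`` selected pixels, and corresponds to an
    effective lifetime of 0 ns.
    """

    z_it: complex
    n_pixels_used: int
    channel: str = ""

    def __post_init__(self) -> None:
        if self.n_pixels_used <= MIN_CALIBRATION_PIXELS:
            raise ValueError(
                f"calibration needs > {MIN_CALIBRATION_PIXELS} pixels, "
                f"got {self.n_pixels_used}"
            )
        if abs(self.z_it) == 0:
            raise ValueError("calibration phasor has zero modulus")


@dataclass(frozen=True)
class ReferencePair:
    """Pure-species reference phasors bounding the mixture chord.

    ``z_short`` is the short-lifetime species (free NAD(P)H, bound FAD) and
    ``z_long`` the long-lifetime one; the phasor ratio r is the intensity
    fraction of the short species, so r=1 at ``z_short`` and r=0 at
    ``z_long``.
    """

    z_short: Phasor
    z_long: Phasor
    tau_short_ns: float = float("nan")
    tau_long_ns: float = float("nan")

    @property
    def d(self) -> float:
        """Chord length between the two references."""
        return float(np.hypot(self.z_short.g - self.z_long.g,
                              self.z_short.s - self.z_long.s))

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("coincident reference phasors")


def phasor_transform(counts: np.ndarray, period_ns: float,
                     mask: Optional[np.ndarray] = None,
                     times_ns: Optional[np.ndarray] = None) -> PhasorImage:
    """First-harmonic phasor of a decay cube.

    Parameters
    ----------
    counts:
        Histogram array, time axis first: ``(G,)``, ``(G, H, W)`` or any
        ``(G, ...)`` shape.
    period_ns:
        Decay record period D; the harmonic frequency is 1/D.
    mask:
        Optional boolean spatial mask; phasors are NaN outside it.  Pixels
        inside the mask with zero total counts are flagged (NaN, removed
        from the returned mask) with a warning.
    times_ns:
        Bin timestamps; defaults to bin centers ``(p + 1/2) D / G``.
    """
    counts = np.asarray(counts, dtype=float)
    n_bins = counts.shape[0]
    if times_ns is None:
        times_ns = (np.arange(n_bins) + 0.5) * (period_ns / n_bins)
    times_ns = np.asarray(times_ns, dtype=float)
    if times_ns.shape != (n_bins,):
        raise ValueError("times_ns must match the time axis length")
    freq = 1.0 / period_ns

    phase = np.exp(2j * np.pi * freq * times_ns)
    total = counts.sum(axis=0)
    num = np.tensordot(phase, counts, axes=(0, 0))

    spatial_shape = counts.shape[1:]
    if mask is None:
        mask = np.ones(spatial_shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    valid = mask & (total > 0)
    n_zero = int(np.count_nonzero(mask & (total == 0)))
    if n_zero:
        warnings.warn(f"{n_zero} in-mask pixels have zero counts; "
                      "their phasors are undefined and dropped")
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(valid, num, np.nan) / np.where(valid, total, 1.0)
    z = np.where(valid, z, np.nan + 0j)
    return PhasorImage(g=np.real(z), s=np.imag(z), mask=valid,
                       frequency_ghz=freq)


def calibration_from_irf(irf_counts: np.ndarray, period_ns: float,
                         pixel_mask: Optional[np.ndarray] = None,
                         channel: str = "") -> CalibrationPhasor:
    """Calibration phasor from an IRF measurement.

    Pools the histograms of the selected pixels (photon-weighted: the pooled
    histogram is the per-bin sum over pixels) and applies the phasor
    transform.  At least 500 pixels must be selected.
    """
    irf_counts = np.asarray(irf_counts, dtype=float)
    if irf_counts.ndim == 1:
        irf_counts = irf_counts[:, None]
    flat = irf_counts.reshape(irf_counts.shape[0], -1)
    if pixel_mask is not None:
        sel = np.asarray(pixel_mask, dtype=bool).reshape(-1)
        flat = flat[:, sel]
    n_pixels = flat.shape[1]
    pooled = flat.sum(axis=1)
    img = phasor_transform(pooled, period_ns)
    z_it = complex(img.g.item(), img.s.item())
    return CalibrationPhasor(z_it=z_it, n_pixels_used=n_pixels, channel=channel)


def calibrate(phasors: PhasorImage, cal: CalibrationPhasor) -> PhasorImage:
    """Calibrate raw phasors by complex division with the IRF phasor.

    Maps a measured 0 ns sample to (1, 0); noiseless mono-exponentials land
    on the universal semicircle afterwards.
    """
    if abs(cal.z_it) < 1e-12:
        raise ValueError("calibration phasor modulus below tolerance")
    z = (phasors.g + 1j * phasors.s) / cal.z_it
    return PhasorImage(g=np.real(z), s=np.imag(z), mask=phasors.mask,
                       frequency_ghz=phasors.frequency_ghz,
                       channel=phasors.channel)


def phasor_of_lifetime(tau_ns: float, frequency_ghz: float) -> Phasor:
    """Universal-semicircle phasor of a mono-exponential lifetime."""
    if tau_ns < 0:
        raise ValueError("lifetime must be nonnegative")
    omega_tau = 2.0 * np.pi * frequency_ghz * tau_ns
    denom = 1.0 + omega_tau ** 2
    return Phasor(g=1.0 / denom, s=omega_tau / denom)


def lifetime_from_phasor(p, frequency_ghz: float):
    """Phase lifetime ``tau = s / (g * 2 pi f)``; exact on the semicircle.

    Accepts a :class:`Phasor` or (g, s) arrays; non-positive g yields NaN
    with a warning.
    """
    if isinstance(p, Phasor):
        g, s = np.asarray(p.g, dtype=float), np.asarray(p.s, dtype=float)
        scalar = True
    else:
        g, s = np.asarray(p[0], dtype=float), np.asarray(p[1], dtype=float)
        scalar = np.ndim(g) == 0
    omega = 2.0 * np.pi * frequency_ghz
    bad = g <= 0
    if np.any(bad):
        warnings.warn("non-positive g: phase lifetime undefined (NaN)")
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = np.where(bad, np.nan, s / (np.where(bad, 1.0, g) * omega))
    return float(tau) if scalar else tau


def references_from_lifetimes(tau_short_ns: float, tau_long_ns: float,
                              frequency_ghz: float) -> ReferencePair:
    """Analytic reference pair from configured pure-species lifetimes."""
    if not 0 < tau_short_ns < tau_long_ns:
        raise ValueError("require 0 < tau_short < tau_long")
    return ReferencePair(
        z_short=phasor_of_lifetime(tau_short_ns, frequency_ghz),
        z_long=phasor_of_lifetime(tau_long_ns, frequency_ghz),
        tau_short_ns=tau_short_ns, tau_long_ns=tau_long_ns)


def phasor_ratio(phasors, refs: ReferencePair):
    """Phasor ratio r: short-lifetime-species intensity fraction.

    Normalized scalar projection of ``z - z_long`` onto the chord
    ``z_short - z_long``:

    .. math::
        r = \\frac{(g-g_2)(g_1-g_2) + (s-s_2)(s_1-s_2)}{d^2},

    with subscript 1 the short- and 2 the long-lifetime reference.  r = 1 at
    the short reference, 0 at the long one; under shot noise r may fall
    slightly outside [0, 1] and is not clamped.
    """
    d2 = refs.d ** 2
    if isinstance(phasors, PhasorImage):
        g, s = phasors.g, phasors.s
    elif isinstance(phasors, Phasor):
        g, s = phasors.g, phasors.s
    else:
        g, s = phasors
    g1, s1 = refs.z_short.g, refs.z_short.s
    g2, s2 = refs.z_long.g, refs.z_long.s
    r = ((np.asarray(g) - g2) * (g1 - g2) + (np.asarray(s) - s2) * (s1 - s2)) / d2
    return r


def plot_phasor_density(phasors: PhasorImage, path, bins: int = 200,
                        refs: Optional[ReferencePair] = None) -> None:
    """Diagnostic 2-D phasor-density plot with the universal semicircle."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = phasors.g[phasors.mask]
    s = phasors.s[phasors.mask]
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.hist2d(g, s, bins=bins, range=[[-0.05, 1.05], [-0.05, 0.65]],
              cmin=1, cmap="viridis")
    theta = np.linspace(0, np.pi, 200)
    ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k--", lw=0.8)
    if refs is not None:
        ax.plot([refs.z_short.g, refs.z_long.g],
                [refs.z_short.s, refs.z_long.s], "r.-", ms=8, lw=0.8)
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.set_title(phasors.channel or "phasor density")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def references_from_cloud(phasors: PhasorImage) -> ReferencePair:
    """Infer references from the linear arrangement of a phasor cloud.

    Fits a total-least-squares line through the in-mask phasors (principal
    axis of the (g, s) scatter) and intersects it with the universal
    semicircle ``(g - 1/2)^2 + s^2 = 1/4``; the intersection closer to
    (1, 0) becomes the short-lifetime reference.  Provided as an alternative
    to analytic references; requires the cloud to actually straddle a chord.
    """
    g = phasors.g[phasors.mask]
    s = phasors.s[phasors.mask]
    pts = np.column_stack([g, s])
    pts = pts[np.isfinite(pts).all(axis=1)]
    if len(pts) < 2:
        raise ValueError("need at least 2 phasors to fit a chord")
    center = pts.mean(axis=0)
    u, sv, vt = np.linalg.svd(pts - center, full_matrices=False)
    direction = vt[0]
    # line: p = center + t * direction; intersect with semicircle
    c = center - np.array([0.5, 0.0])
    b = 2.0 * float(c @ direction)
    cc = float(c @ c) - 0.25
    disc = b * b - 4.0 * cc
    if disc <= 0:
        raise ValueError("fitted phasor line does not cross the semicircle")
    t1 = (-b - np.sqrt(disc)) / 2.0
    t2 = (-b + np.sqrt(disc)) / 2.0
    p1 = center + t1 * direction
    p2 = center + t2 * direction
    for p in (p1, p2):
        p[1] = abs(p[1])  # references live on the upper semicircle
    short, long_ = (p1, p2) if p1[0] > p2[0] else (p2, p1)
    freq = phasors.frequency_ghz
    return ReferencePair(
        z_short=Phasor(*short), z_long=Phasor(*long_),
        tau_short_ns=lifetime_from_phasor((short[0], short[1]), freq),
        tau_long_ns=lifetime_from_phasor((long_[0], long_[1]), freq))
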