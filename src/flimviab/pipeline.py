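"""End-to-end quantification and screen-level analysis.

``quantify_fragment`` chains the per-fragment stages: NAD(P)H photon
threshold -> circular binning (both channels, NAD(P)H mask gating both) ->
phasor transform -> IRF calibration -> chord projection against the
analytic pure-species references -> LMR.  ``run_screen`` simulates a
multi-fragment viability screen, normalizes per-cell LMR to NMS with the
population-pooled mode, and runs the cross-validated AUROC, confusion and
regression analyses against the simulated PI ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from . import classify as cls
from . import metrics as met
from . import preprocess as pre
from . import segmentation as seg
from .config import (AcquisitionConfig, PreprocessConfig, RunConfig,
                     SegmentationConfig, ThresholdBands)
from .phasor import (PhasorImage, calibrate, calibration_from_irf,
                     phasor_ratio, phasor_transform,
                     references_from_lifetimes)
from .simulate import (DecayImage, EffectParams, FragmentLayout, GroundTruth,
                       FAD_SPECIES, NADH_SPECIES, make_fragment, make_irf)

__all__ = ["FragmentData", "QuantifyResult", "ScreenResult",
           "quantify_fragment", "simulate_fragment_dataset", "run_screen",
           "vehicle_time_series"]


@dataclass
class FragmentData:
    """One fragment's raw inputs as consumed by the quantification chain."""

    decay_nadh: DecayImage
    decay_fad: DecayImage
    pi_image: np.ndarray
    irf: DecayImage
    centroids: np.ndarray
    layout: Optional[FragmentLayout] = None
    truth: Optional[GroundTruth] = None
    fragment_id: str = "f0"
    timepoint: str = "t0"


@dataclass
class QuantifyResult:
    """Per-fragment quantification products."""

    lmr: met.MetricImage
    nms: Optional[met.MetricImage]
    cell_table: pd.DataFrame
    mask: np.ndarray
    labels: np.ndarray
    ratio_nadh: met.MetricImage
    ratio_fad: met.MetricImage
    phasor_nadh: Optional[PhasorImage] = None
    phasor_fad: Optional[PhasorImage] = None


@dataclass
class ScreenResult:
    """Screen-level analysis products."""

    cell_table: pd.DataFrame
    cv: cls.CvResult
    confusion: dict
    regression: dict
    summaries: List[cls.FragmentSummary]
    lmr_mode: float


def quantify_fragment(data: FragmentData,
                      run: Optional[RunConfig] = None,
                      baseline_mode: Optional[float] = None,
                      compute_cells: bool = True) -> QuantifyResult:
    """Quantify one fragment from decay cubes to LMR (and NMS if a
    baseline mode is supplied) and the per-cell table.

    The NAD(P)H intensity threshold (strict n > min_photons) defines the
    analysis mask for both channels; binning, phasors and ratios follow.
    When ``baseline_mode`` is None the NMS image is omitted (screen-style
    runs subtract a population mode from per-cell LMR later).
    """
    run = run or RunConfig()
    pcfg = run.preprocess
    period = data.decay_nadh.period_ns
    freq = 1.0 / period

    intensity = pre.total_intensity(data.decay_nadh)
    mask = pre.snr_mask(intensity, pcfg.min_photons)
    binned_nadh = pre.circular_bin(data.decay_nadh, pcfg.kernel_size_nadh, mask)
    binned_fad = pre.circular_bin(data.decay_fad, pcfg.kernel_size_fad, mask)

    cal = calibration_from_irf(data.irf.counts, period)
    ph_nadh = calibrate(phasor_transform(binned_nadh.counts, period, mask), cal)
    ph_fad = calibrate(phasor_transform(binned_fad.counts, period, mask), cal)
    ph_nadh.channel, ph_fad.channel = "nadh", "fad"

    refs_nadh = references_from_lifetimes(NADH_SPECIES.tau_short_ns,
                                          NADH_SPECIES.tau_long_ns, freq)
    refs_fad = references_from_lifetimes(FAD_SPECIES.tau_short_ns,
                                         FAD_SPECIES.tau_long_ns, freq)
    r_nadh = met.MetricImage(values=phasor_ratio(ph_nadh, refs_nadh),
                             mask=ph_nadh.mask, metric="r_nadh",
                             timepoint=data.timepoint)
    r_fad = met.MetricImage(values=phasor_ratio(ph_fad, refs_fad),
                            mask=ph_fad.mask, metric="r_fad",
                            timepoint=data.timepoint)
    lmr_img = met.lmr(r_nadh, r_fad)

    nms_img = None
    metric_img = lmr_img
    if baseline_mode is not None:
        nms_img = met.nms(lmr_img, baseline_mode, pooling="population_mode")
        metric_img = nms_img

    if compute_cells:
        labels = seg.voronoi_labels(data.centroids, lmr_img.mask | mask)
        table = seg.cell_stats(labels, metric_img, data.pi_image,
                               run.segmentation, centroids=data.centroids,
                               fragment_id=data.fragment_id,
                               timepoint=data.timepoint)
    else:
        labels = np.zeros(mask.shape, dtype=np.int32)
        table = pd.DataFrame(columns=seg.CELL_TABLE_COLUMNS)
    return QuantifyResult(lmr=lmr_img, nms=nms_img, cell_table=table,
                          mask=mask, labels=labels, ratio_nadh=r_nadh,
                          ratio_fad=r_fad, phasor_nadh=ph_nadh,
                          phasor_fad=ph_fad)


def simulate_fragment_dataset(scenario: str, n_cells: int,
                              config: AcquisitionConfig,
                              rng: np.random.Generator,
                              fragment_id: str = "f0", timepoint: str = "t0",
                              **kwargs) -> FragmentData:
    """Simulate one fragment plus its IRF measurement as pipeline input."""
    nadh, fad, pi, layout, truth = make_fragment(
        scenario, n_cells, config=config, rng=rng, **kwargs)
    irf = make_irf(config, total_photons=1e4, frame_shape=(24, 24),
                   noisy=True, rng=rng)
    return FragmentData(decay_nadh=nadh, decay_fad=fad, pi_image=pi, irf=irf,
                        centroids=layout.centroids, layout=layout, truth=truth,
                        fragment_id=fragment_id, timepoint=timepoint)


def run_screen(n_fragments: int = 30, cells_per_fragment: int = 150,
               dead_frac_range: Tuple[float, float] = (0.0, 0.6),
               config: Optional[AcquisitionConfig] = None,
               run: Optional[RunConfig] = None,
               seed: int = 0, k_folds: int = 10) -> ScreenResult:
    """Synthetic multi-fragment viability screen, analyzed end to end.

    Each fragment is a ``mixed_viability`` draw with its dead-cell
    probability sampled uniformly from ``dead_frac_range``.  Per-cell mean
    LMR is normalized by the mode of the pooled single-cell LMR
    distribution (population pooling, as in a baseline viability screen);
    the resulting per-cell NMS is scored against the simulated-PI death
    call by stratified k-fold AUROC, tri-state confusion metrics, and the
    per-fragment percent-dead regression.
    """
    config = config or AcquisitionConfig(n_time_bins=64, image_size=256)
    run = run or RunConfig()
    master = np.random.SeedSequence(seed)
    frag_seeds = master.spawn(n_fragments)
    rng_screen = np.random.default_rng(master.spawn(1)[0])

    tables = []
    for i in range(n_fragments):
        rng = np.random.default_rng(frag_seeds[i])
        dead_prob = rng_screen.uniform(*dead_frac_range)
        data = simulate_fragment_dataset("mixed_viability", cells_per_fragment,
                                         config, rng, fragment_id=f"f{i:02d}",
                                         dead_prob=dead_prob)
        result = quantify_fragment(data, run)
        table = result.cell_table.copy()
        # screen pooling works on per-cell mean LMR; store it before NMS
        table = table.rename(columns={"mean_nms": "mean_lmr"})
        truth_dead = data.truth.pi_positive
        table["true_dead"] = truth_dead[table["cell_id"].to_numpy() - 1]
        tables.append(table)
    cells = pd.concat(tables, ignore_index=True)

    lmr_mode = met.distribution_mode(cells["mean_lmr"].to_numpy(),
                                     met.default_lmr_grid())
    cells["mean_nms"] = cells["mean_lmr"] - lmr_mode
    calls = cls.tri_state(cells["mean_nms"].to_numpy(), run.bands)
    cells["nms_class"] = calls
    pred_dead = np.asarray(calls) != "viable"

    cv = cls.cv_auroc(cells["mean_nms"].to_numpy(),
                      cells["pi_dead"].to_numpy(), k=k_folds, seed=seed)
    confusion = cls.confusion_metrics(pred_dead, cells["pi_dead"].to_numpy())
    summaries = [cls.fragment_viability(sub, run.bands, fragment_id=fid)
                 for fid, sub in cells.groupby("fragment_id")]
    regression = cls.fragment_regression(summaries)
    return ScreenResult(cell_table=cells, cv=cv, confusion=confusion,
                        regression=regression, summaries=summaries,
                        lmr_mode=lmr_mode)


def vehicle_time_series(n_timepoints: int = 3, n_cells: int = 120,
                        config: Optional[AcquisitionConfig] = None,
                        run: Optional[RunConfig] = None,
                        seed: int = 0) -> List[met.MetricImage]:
    """Untreated fragment imaged repeatedly; NMS against its own baseline.

    The same generator parameters are drawn at every timepoint (fresh shot
    noise only), emulating a metabolically stable fragment; the baseline
    mode comes from the t0 LMR pixel distribution, so the returned NMS
    images form a no-shift null.
    """
    from .simulate import simulate_decay

    config = config or AcquisitionConfig(n_time_bins=64, image_size=192)
    run = run or RunConfig()
    seeds = np.random.SeedSequence(seed).spawn(n_timepoints + 1)

    # one geometry + species-fraction field, shared across all timepoints
    geom_rng = np.random.default_rng(seeds[0])
    data = simulate_fragment_dataset("vehicle", n_cells, config, geom_rng,
                                     fragment_id="veh", timepoint="t0")
    f_nadh = data.truth.free_fraction_nadh  # short species for NAD(P)H
    f_fad = 1.0 - data.truth.free_fraction_fad  # short species for FAD
    irf_hist = data.irf.counts.sum(axis=(1, 2))
    mask = data.layout.mask

    results = []
    baseline_mode = None
    photons = 1000.0
    for t in range(n_timepoints):
        rng = np.random.default_rng(seeds[t + 1])
        nadh = simulate_decay(f_nadh, NADH_SPECIES, irf_hist, photons, config,
                              rng=rng, channel="nadh", mask=mask)
        fad = simulate_decay(f_fad, FAD_SPECIES, irf_hist, photons, config,
                             rng=rng, channel="fad", mask=mask)
        shot = FragmentData(decay_nadh=nadh, decay_fad=fad,
                            pi_image=data.pi_image, irf=data.irf,
                            centroids=data.centroids, layout=data.layout,
                            truth=data.truth, fragment_id="veh",
                            timepoint=f"t{t}")
        q = quantify_fragment(shot, run, compute_cells=False)
        if t == 0:
            baseline_mode = met.distribution_mode(q.lmr.finite_values(),
                                                  met.default_lmr_grid())
        results.append(met.nms(q.lmr, baseline_mode,
                               pooling="per_fragment_baseline"))
    return results
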