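# flimviab

Label-free viability assessment of live tumor fragments from NAD(P)H/FAD
fluorescence lifetime imaging (FLIM), using phasor analysis and a
normalized metabolic shift metric.

## The problem and the method

Freshly excised tumor fragments are only useful for drug testing while
their cells are alive, but the standard death stains (propidium iodide,
caspase reporters) are themselves perturbative and unreliable in dense
tissue. Autofluorescence FLIM offers a label-free alternative: the
metabolic co-factors NAD(P)H and FAD have distinct excited-state
lifetimes in their free and protein-bound forms, and the free/bound
balance shifts when cells die.

The pipeline implemented here goes from raw time-correlated
single-photon-counting (TCSPC) histograms to a per-cell viability call:

1. **Preprocessing** — pixels with insufficient NAD(P)H photon counts
   (n > 20) are discarded; histograms are summed over a circular spatial
   kernel (5×5 for NAD(P)H, 6×6 for FAD) to boost counts.
2. **Phasor transform** — per pixel, the first-harmonic Fourier
   coordinates of the decay histogram,
   `z = Σ_p G_p exp(i2πf t_p) / Σ_p G_p`, with `f = 1/D ≈ 80 MHz` the
   repetition rate. Mono-exponential decays fall on the universal
   semicircle `g = 1/(1+(ωτ)²)`, `s = ωτ/(1+(ωτ)²)`.
3. **Calibration** — complex division by the phasor of a measured
   instrument response (effective lifetime 0 ns), pooled over >500
   pixels.
4. **Phasor ratio** — orthogonal projection of each calibrated phasor
   onto the chord joining the two pure-species reference phasors
   (free/bound NAD(P)H at 0.4/3.5 ns), giving the short-lifetime-species
   intensity fraction `r`.
5. **Metabolic metrics** — the lifetime metabolic ratio
   `LMR = (1 − r_NAD(P)H) / r_FAD` (a ratio of bound fractions) and the
   normalized metabolic shift `NMS = LMR(t_n) − mode LMR(t_0)`, where
   the baseline mode is located on a kernel-density estimate (grid step
   5·10⁻³).
6. **Single cells** — Voronoi partition of the fragment from nucleus
   centroids (regions >1000 px excluded), per-cell mean NMS and summed
   label-channel intensity (>1000 counts ⇒ PI-dead).
7. **Classification** — tri-state call per cell: NMS < −0.28 ⇒
   necroptotic, NMS in [−0.28, 0.33] ⇒ viable, NMS > 0.33 ⇒
   apoptotic/necrotic; plus stratified 10-fold cross-validated AUROC,
   Youden-optimal thresholds, confusion metrics and per-fragment
   percent-dead regression against the PI ground truth.

Because no public FLIM dataset of this kind exists, the package ships a
first-class synthetic generator (`flimviab.simulate`) that emulates the
measurement chain — bi-exponential free/bound decays wrapped on the
12.5 ns period, Gaussian IRF convolution, Poisson shot noise, a dense
fragment of Voronoi-packed cells, spatial death patterns (uniform
apoptosis/necrosis, a peripheral necroptotic ring), and a PI-like label
channel — with full per-pixel/per-cell ground truth.

## Worked example

```python
import numpy as np
from flimviab import (AcquisitionConfig, ThresholdBands, quantify_fragment,
                      tri_state)
from flimviab.metrics import default_lmr_grid, distribution_mode
from flimviab.pipeline import simulate_fragment_dataset

cfg = AcquisitionConfig(n_time_bins=64, image_size=256, seed=0)
data = simulate_fragment_dataset("necroptotic_ring", 120, cfg,
                                 np.random.default_rng(0), rim_px=14)
q = quantify_fragment(data)
mode = distribution_mode(q.lmr.finite_values(), default_lmr_grid())
table = q.cell_table.assign(mean_nms=lambda t: t.mean_nms - mode)
table["nms_class"] = tri_state(table.mean_nms.to_numpy(), ThresholdBands())
print("baseline LMR mode:", round(mode, 3))
print(table.nms_class.value_counts().to_dict())
```

prints

```
baseline LMR mode: 1.0
{'viable': 92, 'necroptotic': 28}
```

The baseline LMR mode of 1.0 reflects the untreated metabolic state
(free NAD(P)H and bound FAD fractions both ≈0.5). The 28 cells called
necroptotic are exactly the cells the generator placed in the fragment's
peripheral rim — their free-NAD(P)H fraction rises to ≈0.75, dropping
the LMR to ≈0.5 and the NMS below the −0.28 band edge; a head of the
table shows per-cell values such as `mean_nms ≈ −0.47,
total_pi_counts ≈ 4900, pi_dead=True` for ring cells versus
`mean_nms ≈ −0.01, total_pi_counts ≈ 100, pi_dead=False` for interior
ones. On this fragment the tri-state call agrees with the simulator's
ground-truth death state for 100% of cells.

The same flow is available from the shell:

```bash
flimviab simulate --scenario mixed_viability --n-cells 150 --seed 1 --out ds/
flimviab quantify --dataset ds/ --seed 1 --out quant/
flimviab classify --cells quant/cell_table.csv --seed 1 --out cls/
flimviab all --n-fragments 30 --seed 1 --out screen/
```

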