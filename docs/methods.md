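# Methods

This note documents the models, conventions and numerical choices behind
`flimviab`: what each stage assumes, which knobs matter, what the
synthetic generator does and does not emulate, and the design decisions
taken where more than one reasonable option existed.

## Decay model and band-limited synthesis

A TCSPC measurement at an 80 MHz pulse train records, per pixel, a
histogram of photon arrival times over the period D = 12.5 ns in G bins.
The fluorescence of each spectral channel is modeled as a two-species
mixture: intensity fraction `f` of a short-lifetime species and `1 − f`
of a long one, each a mono-exponential wrapped on the period, convolved
(circularly) with the instrument response and corrupted by Poisson shot
noise. `f` is an *intensity* fraction: each species' decay is normalized
to unit area before mixing, which is what makes the phasor of a mixture
a linear combination of the pure-species phasors.

Expected histograms are synthesized in the Fourier domain. The wrapped
exponential of lifetime τ has exact Fourier coefficients
`c_k = 1/(1 − i k ω τ)` with `ω = 2π/D`, and a wrapped Gaussian IRF
centered at `t₀` with standard deviation σ has
`c_k = exp(i k ω t₀ − (k ω σ)²/2)`; circular convolution multiplies
coefficient-wise. The expected histogram is the truncated Fourier series
sampled at the bin centers, and simulation against a *measured* IRF
histogram applies the decay's analytic transfer function to the IRF's
discrete spectrum (`simulate._apply_transfer`), with the sign convention
matched to the bin-center phasor transform.

This construction was chosen over bin-integrating the continuous model
because it makes the discretization commute exactly with the
first-harmonic phasor: the binned histogram's phasor equals the
continuous closed form, so IRF calibration removes the instrument
response *exactly*, noiseless mono-exponentials land on the universal
semicircle to machine precision at any G, and mixture phasors are
exactly affine in `f`. A bin-integrated kernel, by contrast, leaves a
residual discretization bias (≈2·10⁻³ off-semicircle at G = 256 for
τ = 0.4 ns) that calibration cannot remove. The cost is that the
truncated series can ring slightly negative when the IRF is much
narrower than one time bin; expected counts are clipped at zero before
Poisson sampling, a negligible correction at the default IRF width
(0.3 ns FWHM ≈ 2.6 bins at G = 256). A zero-width IRF is special-cased
as a discrete delta in the bin containing the requested center.

## Phasor analysis conventions

* Bin timestamps are bin centers `(p + ½)D/G`, which minimizes
  discretization bias in the transform and is the convention the
  synthesis above is matched to.
* Calibration is a single complex division per channel/excitation by a
  pooled IRF phasor (photon-weighted sum of ≥500 pixel histograms),
  correcting modulation and phase jointly — the standard treatment for
  a τ = 0 reference. Per-pixel calibration is not implemented.
* The phasor ratio is the normalized scalar projection of `z − z_long`
  onto the chord `z_short − z_long`. The self-referential angle
  definitions sometimes printed for this quantity do not describe an
  orthogonal projection; the chord projection reproduces the intended
  contract (`r` = short-species intensity fraction, exact on mixtures)
  and is what is implemented. `r` is deliberately not clamped to [0, 1]:
  shot noise moves it slightly outside, and clamping would bias means.
* Reference phasors default to the analytic semicircle points of the
  configured lifetimes — NAD(P)H 0.4/3.5 ns (free/bound); FAD 0.3/2.8 ns
  (bound/free), literature-typical values exposed as configuration since
  all downstream math depends only on the configured references. A
  fit-based alternative (`references_from_cloud`: total-least-squares
  line through the phasor cloud intersected with the semicircle) is
  provided but is not the default, as cloud geometry makes it fragile on
  narrow mixtures.

## Preprocessing

The SNR threshold is strict (`counts > 20` on the NAD(P)H total
intensity) and the NAD(P)H-derived mask gates both channels;
thresholding happens before binning. The "circular kernel" is the k×k
square with the three corner-most pixels trimmed at each corner
(threshold `r² ≤ max(c², (k/2)² − 2)` around the square center
`c = (k−1)/2`), giving a 13-pixel footprint at 5×5 and a symmetric
24-pixel footprint at 6×6; for even k the footprint center sits between
pixels and the summation window is anchored half a pixel up-left of the
output pixel. Binning *sums* histograms rather than averaging — the
purpose is photon count, and phasors are invariant to count scaling —
and only in-mask neighbors contribute, so masked-out pixels never leak
photons.

## Metrics

`LMR = (1 − r_NADH)/r_FAD` with `r_NADH` the free-NAD(P)H fraction and
`r_FAD` the bound-FAD fraction, i.e. a ratio of bound fractions; with
both baselines at 0.5 the vehicle LMR is 1. Pixels with `|r_FAD|` below
10⁻³ are flagged invalid rather than producing huge ratios. KDEs use
scipy's Gaussian KDE with Silverman bandwidth (the grid is prescribed;
the bandwidth is not, and Silverman is the common default), evaluated on
a fixed grid of step 5·10⁻³ (LMR grid [−0.5, 3], NMS grid [−0.5, 1],
both configurable) and renormalized to sum to one; zero-variance samples
degenerate to a point mass at the nearest grid point. The mode is the
argmax grid point with ties broken toward the lower value. NMS
subtracts the baseline mode, which is computed on pixel values for
image-level NMS (per-fragment baseline) and on per-cell mean LMR for the
population-pooled viability screen.

## Segmentation and classification

Voronoi regions are nearest-centroid assignments on the pixel grid
restricted to the fragment mask (plain Euclidean, not geodesic; a
frame-bounded option exists). Ties break to the lowest centroid index;
KD-tree candidates are re-compared with exact integer squared distances
so the tie-break is bit-reproducible. Regions >1000 px are excluded
(strict), per-cell PI totals are raw summed counts without background
subtraction, and the 1000-count death threshold is strict — both are
configuration fields, as the intensity threshold is acquisition-
dependent in practice.

Cross-validated AUROC uses stratified, seeded 10-fold splits (stratified
to avoid degenerate single-class folds); AUC is evaluated on held-out
cells while the optimal threshold maximizes Youden's J on the training
cells, both reported as mean ± SD over folds. Youden's J was adopted
because a single operating point was needed and no criterion was
prescribed. The necroptotic (left) threshold can be studied with the
same machinery by negating scores. Dead-vs-alive for confusion metrics,
percent-dead summaries and the fragment regression takes the union of
the two dead classes of the tri-state bands (−0.28 and 0.33, both
endpoints viable).

## The synthetic generator as study conditions

Defaults encode the regime the assay operates in: vehicle free fractions
0.5 for both channels; apoptosis/necrosis lowers the free-NAD(P)H
fraction to 0.3 and the bound-FAD fraction to 0.35 (cell-mean NMS ≈ +1,
well past the +0.33 band); necroptosis raises free NAD(P)H to 0.75
(the reported post-treatment level; NMS ≈ −0.5, past −0.28); per-pixel
fraction jitter SD 0.02; 1000 Poisson photons per raw pixel (≈10⁴ per
binned pixel); PI budgets 5000 photons for dead cells (Gaussian nuclear
blob, σ = 3 px) vs 100 flat background for viable ones, placing the two
classes far on either side of the 1000-count call. Fragments are gently
wobbled disks (≈6% boundary modulation) with dart-thrown centroids at a
density-derived minimum separation; the necroptotic rim is measured by
the Euclidean distance transform of the mask.

The generator emulates shot noise, IRF convolution, spatial death
patterns and label bleed-through *budget*, but not optical PSF or
scattering, depth sectioning, photobleaching, detector afterpulsing,
inter-cell lifetime heterogeneity beyond the fraction jitter, or the
off-semicircle "long-lifetime species" trajectory rotation seen under
some oxidative treatments. Passing tests therefore demonstrate the
correctness and statistical behavior of the analysis chain under the
assay's stated noise model — not robustness to every real-tissue
artifact; in particular the near-perfect synthetic screen separation
(AUC ≈ 1) reflects the generator's clean class structure, and real
tissue will sit closer to the published operating regime.

## Problem sizes and determinism

The shipped screens use 30 fragments × ~150 cells on 256×256 frames with
G = 64 time bins — sizes chosen so a full screen runs in about a minute
on one CPU while keeping ≥10⁴ photons per binned pixel; closed-form
phasor checks use G = 256. All randomness flows through
`numpy.random.Generator` objects derived from a single seed via
`SeedSequence.spawn`, so every dataset, screen and CLI run is
bit-reproducible given its seed; run manifests record config, seed,
package version and input checksums.

## Known limitations

* The population-pooled LMR mode assumes most cells are viable; screens
  where dead cells dominate would shift the baseline.
* Voronoi cells are a proxy for true cell boundaries; the 1000-px guard
  removes gross failures but not subtle bleed between adjacent cells.
* The phase-lifetime inversion `τ = s/(gω)` is exact only for
  mono-exponential (on-semicircle) decays and is provided for
  verification, not for mixture analysis.
* Fraction jitter is clipped to [0, 1], slightly shrinking the effective
  variance at extreme target fractions.
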