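"""Synthetic fragment generator: decay synthesis, scenarios, label channel."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from flimviab import (
    AcquisitionConfig,
    calibrate,
    calibration_from_irf,
    phasor_of_lifetime,
    phasor_ratio,
    phasor_transform,
    references_from_lifetimes,
)
from flimviab.simulate import (
    FAD_SPECIES,
    NADH_SPECIES,
    SpeciesModel,
    make_fragment,
    make_irf,
    simulate_decay,
    simulate_label_channel,
)


def _calibrated_phasor(decay, acq, irf_frame):
    cal = calibration_from_irf(irf_frame.counts, acq.period_ns)
    return calibrate(phasor_transform(decay.counts, acq.period_ns), cal)


class TestMakeIrf:
    def test_zero_width_is_delta_at_center_bin(self, acq):
        cfg = AcquisitionConfig(n_time_bins=64, irf_center_ns=3.0,
                                irf_fwhm_ns=0.0)
        irf = make_irf(cfg, 1e4)
        h = irf.counts[:, 0, 0]
        k = int(3.0 / cfg.bin_width_ns)
        assert h[k] == 1e4 and h.sum() == 1e4

    def test_noiseless_conserves_photons(self, acq):
        h = make_irf(acq, 1e4).counts[:, 0, 0]
        assert h.sum() == pytest.approx(1e4, abs=1e-9)

    def test_self_calibration_identity(self, acq):
        irf = make_irf(acq, 1e5, frame_shape=(30, 30))
        out = _calibrated_phasor(irf, acq, irf)
        assert out.g.flat[0] == pytest.approx(1.0, abs=1e-12)
        assert out.s.flat[0] == pytest.approx(0.0, abs=1e-12)

    def test_wide_irf_rejected(self):
        with pytest.raises(ValueError, match="wider"):
            AcquisitionConfig(irf_fwhm_ns=20.0)

    def test_noisy_variant_reproducible(self, acq, rng):
        a = make_irf(acq, 1e3, frame_shape=(4, 4), noisy=True,
                     rng=np.random.default_rng(7))
        b = make_irf(acq, 1e3, frame_shape=(4, 4), noisy=True,
                     rng=np.random.default_rng(7))
        assert np.array_equal(a.counts, b.counts)


class TestSimulateDecay:
    def test_mono_exponential_closed_form_with_delta_irf(self, acq_fine):
        cfg = AcquisitionConfig(n_time_bins=256, irf_fwhm_ns=0.0,
                                irf_center_ns=0.0)
        irf = make_irf(cfg, 1e5, frame_shape=(30, 30))
        sp = SpeciesModel(0.4, 3.5)
        dec = simulate_decay(1.0, sp, irf.counts[:, 0, 0], 1e4, cfg,
                             noiseless=True)
        out = _calibrated_phasor(dec, cfg, irf)
        z = phasor_of_lifetime(0.4, cfg.frequency_ghz)
        assert out.g.item() == pytest.approx(z.g, abs=1e-12)
        assert out.s.item() == pytest.approx(z.s, abs=1e-12)

    def test_mixture_phasor_matches_linear_combination_oracle(
            self, acq_fine, irf_hist_fine):
        # oracle: f * z(tau_short) + (1-f) * z(tau_long), closed form
        f, freq = 0.75, acq_fine.frequency_ghz
        z = (f * phasor_of_lifetime(0.4, freq).z
             + (1 - f) * phasor_of_lifetime(3.5, freq).z)
        assert z.real == pytest.approx(0.7819, abs=5e-5)  # frozen oracle value
        assert z.imag == pytest.approx(0.2523, abs=5e-5)
        irf = make_irf(acq_fine, 1e5, frame_shape=(30, 30))
        dec = simulate_decay(f, NADH_SPECIES, irf_hist_fine, 1e4, acq_fine,
                             noiseless=True)
        out = _calibrated_phasor(dec, acq_fine, irf)
        assert out.g.item() == pytest.approx(z.real, abs=1e-9)
        assert out.s.item() == pytest.approx(z.imag, abs=1e-9)

    def test_same_seed_bit_identical(self, acq, irf_hist):
        kw = dict(species=NADH_SPECIES, irf=irf_hist, photons_per_pixel=500,
                  config=acq)
        a = simulate_decay(np.full((4, 4), 0.5), rng=np.random.default_rng(3), **kw)
        b = simulate_decay(np.full((4, 4), 0.5), rng=np.random.default_rng(3), **kw)
        assert np.array_equal(a.counts, b.counts)

    def test_noiseless_conserves_photon_budget(self, acq, irf_hist):
        dec = simulate_decay(np.full((3, 3), 0.3), NADH_SPECIES, irf_hist,
                             1234.0, acq, noiseless=True)
        assert dec.counts.sum(axis=0) == pytest.approx(1234.0, abs=1e-8)

    def test_poisson_totals_have_requested_mean(self, acq, irf_hist, rng):
        # >= 100 replicate pixels; mean within 3 sigma of the budget
        n, budget = 400, 800.0
        dec = simulate_decay(np.full((n, 1), 0.5), NADH_SPECIES, irf_hist,
                             budget, acq, rng=rng)
        totals = dec.counts.sum(axis=0).ravel()
        se = np.sqrt(budget / n)
        assert abs(totals.mean() - budget) < 3 * se

    def test_invalid_fractions_rejected(self, acq, irf_hist):
        with pytest.raises(ValueError, match="fractions"):
            simulate_decay(1.5, NADH_SPECIES, irf_hist, 100, acq)

    @given(f=st.floats(min_value=0.0, max_value=1.0))
    def test_phasor_linearity_through_gaussian_irf(self, f):
        cfg = AcquisitionConfig(n_time_bins=64)
        irf = make_irf(cfg, 1e5, frame_shape=(30, 30))
        dec = simulate_decay(f, NADH_SPECIES, irf.counts[:, 0, 0], 1e4, cfg,
                             noiseless=True)
        out = _calibrated_phasor(dec, cfg, irf)
        freq = cfg.frequency_ghz
        z = (f * phasor_of_lifetime(0.4, freq).z
             + (1 - f) * phasor_of_lifetime(3.5, freq).z)
        # delta-IRF tolerance is 1e-9; the Gaussian-IRF contract is 1e-3
        assert abs(complex(out.g.item(), out.s.item()) - z) < 1e-9

    def test_projection_recovers_fractions(self, acq, irf_hist):
        # |bias| < 0.01 and SD < 0.03 over 100 pixels at 1e4 photons
        refs = references_from_lifetimes(0.4, 3.5, acq.frequency_ghz)
        irf = make_irf(acq, 1e5, frame_shape=(30, 30))
        rng = np.random.default_rng(42)
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            dec = simulate_decay(np.full((10, 10), f), NADH_SPECIES, irf_hist,
                                 1e4, acq, rng=rng)
            out = _calibrated_phasor(dec, acq, irf)
            r = phasor_ratio(out, refs)
            assert abs(r.mean() - f) < 0.01
            assert r.std() < 0.03


class TestMakeFragment:
    @pytest.fixture()
    def cfg(self):
        return AcquisitionConfig(n_time_bins=32, image_size=96, seed=0)

    def test_vehicle_all_viable(self, cfg, rng):
        *_, layout, truth = make_fragment("vehicle", 20, config=cfg, rng=rng,
                                          photons_per_pixel=50)
        assert (truth.cell_state == "viable").all()
        assert not truth.pi_positive.any()

    def test_zero_rim_ring_is_vehicle(self, cfg):
        *_, _, t1 = make_fragment("necroptotic_ring", 20, config=cfg,
                                  rng=np.random.default_rng(5), rim_px=0,
                                  photons_per_pixel=50)
        *_, _, t2 = make_fragment("vehicle", 20, config=cfg,
                                  rng=np.random.default_rng(5),
                                  photons_per_pixel=50)
        assert (t1.cell_state == t2.cell_state).all()

    def test_huge_rim_makes_all_necroptotic_with_warning(self, cfg, rng):
        with pytest.warns(UserWarning, match="rim"):
            *_, truth = make_fragment("necroptotic_ring", 15, config=cfg,
                                      rng=rng, rim_px=1000,
                                      photons_per_pixel=50)
        assert (truth.cell_state == "necroptotic").all()

    def test_mixed_dead_count_in_binomial_interval(self, cfg):
        n, p = 200, 0.3
        *_, truth = make_fragment(
            "mixed_viability", n, config=AcquisitionConfig(
                n_time_bins=32, image_size=192, seed=0),
            rng=np.random.default_rng(11), dead_prob=p, photons_per_pixel=50)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, p)
        assert lo <= truth.pi_positive.sum() <= hi

    def test_fraction_maps_respect_states(self, cfg, rng):
        nadh, fad, pi, layout, truth = make_fragment(
            "apoptotic", 15, config=cfg, rng=rng, photons_per_pixel=50)
        inside = layout.mask
        # free NAD(P)H decreased from 0.5 baseline toward 0.3
        assert truth.free_fraction_nadh[inside].mean() < 0.4
        assert (truth.free_fraction_nadh >= 0).all()
        assert (truth.free_fraction_fad <= 1).all()

    def test_unknown_scenario_rejected(self, cfg, rng):
        with pytest.raises(ValueError, match="scenario"):
            make_fragment("zombie", 5, config=cfg, rng=rng)


class TestLabelChannel:
    @pytest.fixture()
    def fragment(self):
        cfg = AcquisitionConfig(n_time_bins=32, image_size=128, seed=2)
        return make_fragment("mixed_viability", 40, config=cfg,
                             rng=np.random.default_rng(2), dead_prob=0.4,
                             photons_per_pixel=50)

    def _cell_totals(self, layout, pi):
        from flimviab import voronoi_labels

        labels = voronoi_labels(layout.centroids, layout.mask)
        return np.array([pi[labels == i + 1].sum()
                         for i in range(len(layout.centroids))])

    def test_dead_cells_cross_1000_viable_stay_below(self, fragment):
        *_, pi, layout, truth = fragment
        totals = self._cell_totals(layout, pi)
        assert (totals[truth.pi_positive] > 1000).all()
        alive_budget = 100.0
        bound = alive_budget + 5 * np.sqrt(alive_budget)
        assert (totals[~truth.pi_positive] <= bound).all()

    def test_zero_alive_budget_gives_zero_counts(self, fragment, rng):
        *_, _, layout, truth = fragment
        pi = simulate_label_channel(layout, truth, photons_dead=5000.0,
                                    photons_alive=0.0, rng=rng)
        totals = self._cell_totals(layout, pi)
        assert (totals[~truth.pi_positive] == 0).all()

    def test_budget_ordering_enforced(self, fragment, rng):
        *_, _, layout, truth = fragment
        with pytest.raises(ValueError, match="photons_dead"):
            simulate_label_channel(layout, truth, photons_dead=50.0,
                                   photons_alive=100.0, rng=rng)
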