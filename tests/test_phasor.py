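"""Phasor transform, calibration, semicircle utilities and chord projection."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flimviab import (
    AcquisitionConfig,
    Phasor,
    PhasorImage,
    ReferencePair,
    calibrate,
    calibration_from_irf,
    lifetime_from_phasor,
    phasor_of_lifetime,
    phasor_ratio,
    phasor_transform,
    references_from_cloud,
    references_from_lifetimes,
)
from flimviab.simulate import SpeciesModel, make_irf, simulate_decay

F80 = 0.08  # GHz, the 12.5 ns period's first harmonic


class TestPhasorTransform:
    def test_all_counts_at_time_zero_give_unit_phasor(self):
        counts = np.array([5.0, 0.0, 0.0, 0.0])
        img = phasor_transform(counts, period_ns=12.5,
                               times_ns=np.array([0.0, 1.0, 2.0, 3.0]))
        assert img.g.item() == pytest.approx(1.0, abs=1e-12)
        assert img.s.item() == pytest.approx(0.0, abs=1e-12)

    def test_uniform_histogram_has_zero_first_harmonic(self):
        counts = np.ones(64)
        img = phasor_transform(counts, period_ns=12.5)
        assert abs(img.g.item()) < 1e-12 and abs(img.s.item()) < 1e-12

    def test_two_bin_toy_histogram(self):
        # one photon at t=0, one at t=D/4: z = (1 + i)/2
        counts = np.array([1.0, 1.0])
        img = phasor_transform(counts, period_ns=12.5,
                               times_ns=np.array([0.0, 12.5 / 4]))
        assert img.g.item() == pytest.approx(0.5, abs=1e-12)
        assert img.s.item() == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force_complex_sum(self, rng):
        counts = rng.integers(0, 50, size=(32, 4, 5)).astype(float)
        counts[:, 0, 0] += 1  # avoid an all-zero pixel
        period = 10.0
        img = phasor_transform(counts, period)
        t = (np.arange(32) + 0.5) * period / 32
        for i in range(4):
            for j in range(5):
                z = (counts[:, i, j] * np.exp(2j * np.pi * t / period)).sum()
                z /= counts[:, i, j].sum()
                assert img.g[i, j] == pytest.approx(z.real, abs=1e-12)
                assert img.s[i, j] == pytest.approx(z.imag, abs=1e-12)

    def test_zero_count_pixel_inside_mask_is_flagged(self):
        counts = np.zeros((8, 2, 2))
        counts[0, 0, 0] = 3.0
        with pytest.warns(UserWarning, match="zero counts"):
            img = phasor_transform(counts, 12.5, mask=np.ones((2, 2), bool))
        assert img.mask[0, 0] and not img.mask[1, 1]
        assert np.isnan(img.g[1, 1])


class TestCalibration:
    def test_delta_irf_at_zero_gives_unit_calibration(self):
        counts = np.zeros((16, 30, 30))
        counts[0] = 7.0
        cal = calibration_from_irf(counts, period_ns=12.5)
        t0 = 0.5 * 12.5 / 16  # bin-center convention
        expect = np.exp(2j * np.pi * 0.08 * t0)
        assert cal.z_it == pytest.approx(expect, abs=1e-12)

    def test_pooling_is_photon_weighted(self):
        h = np.exp(-np.arange(16) / 3.0)
        one = h[:, None, None] * np.ones((1, 26, 26))
        two = h[:, None, None] * np.ones((1, 40, 40))
        cal1 = calibration_from_irf(one, 12.5)
        cal2 = calibration_from_irf(two, 12.5)
        assert cal1.z_it == pytest.approx(cal2.z_it, abs=1e-12)

    def test_too_few_pixels_rejected(self):
        counts = np.ones((8, 10, 10))
        with pytest.raises(ValueError, match="500"):
            calibration_from_irf(counts, 12.5)

    def test_identity_calibration_and_self_calibration(self, acq):
        irf = make_irf(acq, 1e5, frame_shape=(30, 30))
        cal = calibration_from_irf(irf.counts, acq.period_ns)
        raw = phasor_transform(irf.counts[:, :1, :1], acq.period_ns)
        out = calibrate(raw, cal)
        assert out.g.item() == pytest.approx(1.0, abs=1e-12)
        assert out.s.item() == pytest.approx(0.0, abs=1e-12)

    def test_calibrated_mono_exponential_on_semicircle(self, acq_fine,
                                                       irf_hist_fine):
        sp = SpeciesModel(0.4, 4.0)
        dec = simulate_decay(1.0, sp, irf_hist_fine, 1e4, acq_fine,
                             noiseless=True)
        irf = make_irf(acq_fine, 1e5, frame_shape=(30, 30))
        cal = calibration_from_irf(irf.counts, acq_fine.period_ns)
        out = calibrate(phasor_transform(dec.counts, acq_fine.period_ns), cal)
        radius = abs(complex(out.g.item() - 0.5, out.s.item()))
        assert radius == pytest.approx(0.5, abs=1e-6)
        z = phasor_of_lifetime(0.4, acq_fine.frequency_ghz)
        assert out.g.item() == pytest.approx(z.g, abs=1e-6)
        assert out.s.item() == pytest.approx(z.s, abs=1e-6)


class TestSemicircle:
    def test_limits(self):
        z0 = phasor_of_lifetime(0.0, F80)
        assert (z0.g, z0.s) == (1.0, 0.0)
        zinf = phasor_of_lifetime(1e9, F80)
        assert abs(zinf.g) < 1e-12 and abs(zinf.s) < 1e-6

    def test_known_point_at_04ns(self):
        z = phasor_of_lifetime(0.4, F80)
        assert z.g == pytest.approx(0.9611, abs=1e-4)
        assert z.s == pytest.approx(0.1933, abs=1e-4)

    def test_phase_lifetime_inversions(self):
        assert lifetime_from_phasor(Phasor(1.0, 0.0), F80) == 0.0
        z = phasor_of_lifetime(3.5, F80)
        assert lifetime_from_phasor(z, F80) == pytest.approx(3.5, rel=1e-12)
        tau = lifetime_from_phasor(Phasor(0.5, 0.5), F80)
        assert tau == pytest.approx(1.989, abs=1e-3)

    def test_nonpositive_g_flagged(self):
        with pytest.warns(UserWarning, match="non-positive"):
            tau = lifetime_from_phasor(Phasor(0.0, 0.5), F80)
        assert np.isnan(tau)


class TestPhasorRatio:
    @pytest.fixture()
    def refs(self):
        return references_from_lifetimes(0.4, 3.5, F80)

    def test_endpoints(self, refs):
        assert phasor_ratio(refs.z_short, refs) == pytest.approx(1.0, abs=1e-12)
        assert phasor_ratio(refs.z_long, refs) == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_displacement_from_midpoint(self, refs):
        mid = 0.5 * (refs.z_short.z + refs.z_long.z)
        chord = refs.z_short.z - refs.z_long.z
        perp = 1j * chord / abs(chord)
        p = Phasor.from_complex(mid + 0.1 * perp)
        assert phasor_ratio(p, refs) == pytest.approx(0.5, abs=1e-12)

    @given(f=st.floats(min_value=-1.0, max_value=2.0))
    def test_projection_is_affine_exact(self, f):
        refs = references_from_lifetimes(0.4, 3.5, F80)
        p = Phasor.from_complex(f * refs.z_short.z + (1 - f) * refs.z_long.z)
        assert phasor_ratio(p, refs) == pytest.approx(f, abs=1e-9)

    def test_monotone_along_chord(self, refs):
        fs = np.linspace(0, 1, 11)
        rs = [phasor_ratio(Phasor.from_complex(
            f * refs.z_short.z + (1 - f) * refs.z_long.z), refs) for f in fs]
        assert np.all(np.diff(rs) > 0)

    def test_coincident_references_rejected(self):
        z = phasor_of_lifetime(1.0, F80)
        with pytest.raises(ValueError, match="coincident"):
            ReferencePair(z_short=z, z_long=z)


def test_references_from_cloud_recovers_chord():
    refs = references_from_lifetimes(0.4, 3.5, F80)
    fs = np.linspace(0.2, 0.8, 200)
    z = fs * refs.z_short.z + (1 - fs) * refs.z_long.z
    img = PhasorImage(g=z.real[None], s=z.imag[None],
                      mask=np.ones((1, 200), bool), frequency_ghz=F80)
    fitted = references_from_cloud(img)
    assert fitted.z_short.g == pytest.approx(refs.z_short.g, abs=1e-6)
    assert fitted.z_long.s == pytest.approx(refs.z_long.s, abs=1e-6)
    assert fitted.tau_short_ns == pytest.approx(0.4, abs=1e-6)
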