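"""Peak finding, shift classification, synchronous spectra, EEM taxonomy."""

import numpy as np
import pytest

import quenchbind as qb
from quenchbind import simulate as sim
from quenchbind.errors import InputDomainError, InsufficientDataError


def gaussian_spectrum(center, width=25.0, amp=1000.0, lo=300.0, hi=500.0, step=1.0):
    wl = np.arange(lo, hi + step, step)
    return qb.EmissionSpectrum(280.0, wl, amp * np.exp(-0.5 * ((wl - center) / width) ** 2))


class TestFindPeak:
    def test_gaussian_center_recovered(self):
        peak = qb.find_peak(gaussian_spectrum(340.0))
        assert peak.found
        assert peak.wavelength == pytest.approx(340.0, abs=0.1)

    def test_off_grid_center_refined_below_grid_resolution(self):
        peak = qb.find_peak(gaussian_spectrum(341.4))
        assert peak.wavelength == pytest.approx(341.4, abs=0.1)

    def test_tie_goes_to_lowest_wavelength(self):
        wl = np.arange(300.0, 306.0)
        y = np.array([1.0, 5.0, 2.0, 2.0, 5.0, 1.0])
        peak = qb.find_peak(qb.EmissionSpectrum(280.0, wl, y), refine=False)
        assert peak.wavelength == 301.0

    def test_monotone_spectrum_flagged_boundary(self):
        wl = np.arange(300.0, 310.0)
        peak = qb.find_peak(qb.EmissionSpectrum(280.0, wl, wl * 2.0))
        assert not peak.found
        assert peak.flag == "boundary"

    def test_flat_spectrum_flagged(self):
        wl = np.arange(300.0, 310.0)
        peak = qb.find_peak(qb.EmissionSpectrum(280.0, wl, np.full(wl.size, 3.0)))
        assert not peak.found
        assert peak.flag == "flat"

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            qb.find_peak(qb.EmissionSpectrum(280.0, [300.0, 301.0], [1.0, 2.0]))


class TestPeakShift:
    def test_redshift_with_intensity_loss(self):
        free, bound = sim.generate_emission_pair(shift_nm=8.0, damping=0.81)
        shift = qb.peak_shift(free, bound)
        assert shift.shift == pytest.approx(8.0, abs=0.1)
        assert shift.direction == "redshift"
        assert shift.intensity_change_pct == pytest.approx(-19.0, abs=0.5)

    def test_identical_spectra_no_shift(self):
        spec = gaussian_spectrum(340.0)
        shift = qb.peak_shift(spec, spec)
        assert shift.shift == 0.0
        assert shift.direction == "none"
        assert shift.intensity_change_pct == 0.0

    def test_one_nanometer_blueshift_resolved(self):
        """Sub-grid refinement resolves a 1-nm shift on a 1-nm grid."""
        free, bound = sim.generate_emission_pair(shift_nm=-1.0, damping=1.0)
        shift = qb.peak_shift(free, bound)
        assert shift.shift == pytest.approx(-1.0, abs=0.1)
        assert shift.direction == "blueshift"

    def test_antisymmetric_under_swap(self):
        a = gaussian_spectrum(340.0)
        b = gaussian_spectrum(347.3)
        assert qb.peak_shift(a, b).shift == pytest.approx(-qb.peak_shift(b, a).shift)

    def test_disjoint_ranges_rejected(self):
        a = gaussian_spectrum(320.0, lo=300.0, hi=350.0)
        b = gaussian_spectrum(420.0, lo=400.0, hi=450.0)
        with pytest.raises(InputDomainError):
            qb.peak_shift(a, b)


class TestSynchronousSpectrum:
    def make_separable_eem(self):
        ex = np.arange(250.0, 310.0, 5.0)
        em = np.arange(250.0, 450.0, 5.0)
        f_em = np.exp(-0.5 * ((em - 350.0) / 30.0) ** 2)   # intensity = f(lambda_em)
        z = np.tile(f_em, (ex.size, 1))
        return qb.EEM(ex, em, z), ex, em

    def test_separable_field_sampled_at_offset(self):
        eem, ex, em = self.make_separable_eem()
        out = qb.synchronous_spectrum(eem, 15.0)
        expected = np.exp(-0.5 * ((out.wavelengths + 15.0 - 350.0) / 30.0) ** 2)
        np.testing.assert_allclose(out.intensities, expected, rtol=1e-9)

    def test_zero_offset_is_rayleigh_ridge(self):
        eem, ex, em = self.make_separable_eem()
        out = qb.synchronous_spectrum(eem, 0.0)
        expected = np.exp(-0.5 * ((out.wavelengths - 350.0) / 30.0) ** 2)
        np.testing.assert_allclose(out.intensities, expected, rtol=1e-9)

    def test_trp_like_gaussian_peaks_at_excitation_center(self):
        eem = sim.generate_eem(
            peaks=((280.0, 340.0, 1000.0),), ridge_amplitude=0.0
        )
        out = qb.synchronous_spectrum(eem, 60.0)
        peak = qb.find_peak(out)
        assert peak.wavelength == pytest.approx(280.0, abs=2.5)

    def test_commutes_with_intensity_scaling(self):
        eem, _, _ = self.make_separable_eem()
        scaled = qb.EEM(eem.excitation_grid, eem.emission_grid, eem.intensity_matrix * 7.5)
        a = qb.synchronous_spectrum(eem, 15.0)
        b = qb.synchronous_spectrum(scaled, 15.0)
        np.testing.assert_allclose(b.intensities, a.intensities * 7.5, rtol=1e-12)

    def test_empty_diagonal_rejected(self):
        eem, _, _ = self.make_separable_eem()
        with pytest.raises(InputDomainError):
            qb.synchronous_spectrum(eem, 500.0)


class TestEEMPeaks:
    def test_two_gaussian_peaks_located_and_classified(self):
        eem = sim.generate_eem()  # peaks at (280, 340) and (230, 330)
        found = qb.eem_peaks(eem)
        assert found.peak1 is not None and found.peak2 is not None
        assert found.peak1[:2] == (280.0, 340.0)
        assert found.peak2[:2] == (230.0, 330.0)

    def test_ridge_cells_match_definition_exactly(self):
        eem = sim.generate_eem()
        tol = 7.0
        found = qb.eem_peaks(eem, tolerance=tol)
        expected_rayleigh = {
            (float(x), float(m))
            for x in eem.excitation_grid
            for m in eem.emission_grid
            if abs(m - x) <= tol
        }
        assert set(found.rayleigh_ridge) == expected_rayleigh
        expected_second = {
            (float(x), float(m))
            for x in eem.excitation_grid
            for m in eem.emission_grid
            if abs(m - 2 * x) <= tol
        }
        assert set(found.second_order_ridge) == expected_second

    def test_ridge_only_eem_has_no_peaks(self):
        eem = sim.generate_eem(peaks=(), ridge_amplitude=300.0)
        found = qb.eem_peaks(eem)
        assert found.peak1 is None and found.peak2 is None
        assert found.flag == "no off-ridge maxima"
        assert len(found.rayleigh_ridge) > 0

    def test_bound_free_pair_shows_declining_peaks(self):
        free, bound = sim.generate_eem_pair(damping=0.7)
        deltas = qb.eem_peak_deltas(bound, free)
        assert deltas["peak1"] is not None and deltas["peak1"] < 0
        assert deltas["peak2"] is not None and deltas["peak2"] < 0
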