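"""Physics-layer tests: spectra, materials, efficiency, signal statistics,
and dose bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mvkvct import physics as ph

from conftest import monoenergetic


class TestSpectrumModels:
    def test_kv_spectrum_endpoint_and_positivity(self):
        kv = ph.build_kv_spectrum(80.0)
        assert np.all(kv.fluence[kv.energies > 80.0] == 0)
        assert np.all(kv.fluence >= 0)

    def test_kv_mean_energy_in_diagnostic_band(self, kv_spectrum):
        # regression value frozen from numeric integration of the model
        mean = kv_spectrum.mean_energy()
        assert 40.0 <= mean <= 60.0
        assert mean == pytest.approx(40.382, abs=0.1)

    @pytest.mark.parametrize("kvp", [30.0, 180.0])
    def test_kvp_out_of_range_rejected(self, kvp):
        with pytest.raises(ph.ParameterError):
            ph.build_kv_spectrum(kvp)

    def test_mv_spectrum_mode_near_1mev(self, mv_spectrum):
        mode = mv_spectrum.energies[np.argmax(mv_spectrum.fluence)]
        assert 800.0 <= mode <= 1200.0

    def test_mv_spectrum_mean_below_3mev(self, mv_spectrum):
        assert mv_spectrum.mean_energy() < 3000.0

    def test_mv_spectrum_truncated_at_6mev(self, mv_spectrum):
        assert np.all(mv_spectrum.fluence[mv_spectrum.energies > 6000.0] == 0)
        assert mv_spectrum.energies.max() <= 6000.0

    def test_spectrum_file_round_trip(self, tmp_path, kv_spectrum):
        path = tmp_path / "spec.txt"
        np.savetxt(path, np.column_stack([kv_spectrum.energies,
                                          kv_spectrum.fluence]),
                   header="energy_keV fluence")
        loaded = ph.load_spectrum(path)
        np.testing.assert_allclose(loaded.fluence, kv_spectrum.fluence,
                                   rtol=1e-6)

    def test_spectrum_validation(self):
        with pytest.raises(ph.GridError):
            ph.Spectrum(np.array([50.0, 40.0]), np.array([1.0, 1.0]))
        with pytest.raises(ph.ParameterError):
            ph.Spectrum(np.array([40.0, 50.0]), np.array([1.0, -1.0]))


class TestDetectiveEfficiency:
    def test_anchor_values(self):
        assert ph.detective_efficiency(6000.0) == pytest.approx(0.20)
        assert ph.detective_efficiency(60.0) >= 0.95

    def test_non_increasing_and_bounded(self):
        grid = np.linspace(10.0, 6000.0, 500)
        eta = ph.detective_efficiency(grid)
        assert np.all(np.diff(eta) <= 1e-12)
        assert np.all((eta >= 0.2) & (eta <= 1.0))

    @pytest.mark.parametrize("energy", [5.0, 7000.0])
    def test_out_of_range(self, energy):
        with pytest.raises(ph.EnergyRangeError):
            ph.detective_efficiency(energy)


class TestMaterials:
    @pytest.mark.parametrize("name", sorted(ph.BUNDLED_MATERIALS))
    def test_curves_positive_over_range(self, name):
        mat = ph.load_material(name)
        grid = np.geomspace(10.0, 6000.0, 300)
        assert np.all(mat.mu_over_rho(grid) > 0)
        assert np.all(mat.muen_over_rho(grid) > 0)

    def test_unknown_material_rejected(self):
        with pytest.raises(ph.ParameterError):
            ph.load_material("unobtainium")

    def test_interpolation_hits_table_points(self):
        water = ph.load_material("water")
        assert water.mu_over_rho(60.0) == pytest.approx(0.2059, rel=1e-6)
        assert water.muen_over_rho(1000.0) == pytest.approx(0.03103, rel=1e-6)

    def test_energy_out_of_table_raises(self):
        with pytest.raises(ph.EnergyRangeError):
            ph.load_material("water").mu_over_rho(7.0)


class TestStoppingFraction:
    def test_detector_slab_attenuation(self):
        si = ph.load_material("silicon")
        cdte = ph.load_material("cdte")
        assert ph.stopping_fraction(si, 3.0, 3000.0) == pytest.approx(0.20, abs=0.05)
        assert ph.stopping_fraction(cdte, 3.0, 3000.0) == pytest.approx(0.50, abs=0.05)

    def test_zero_thickness(self):
        assert ph.stopping_fraction(ph.load_material("water"), 0.0, 100.0) == 0.0

    def test_negative_thickness_rejected(self):
        with pytest.raises(ph.ParameterError):
            ph.stopping_fraction(ph.load_material("water"), -1.0, 100.0)

    @given(t1=st.floats(0.0, 10.0), t2=st.floats(0.0, 10.0),
           e=st.floats(20.0, 5000.0))
    def test_exponential_composition(self, t1, t2, e):
        water = ph.load_material("water")
        f1 = ph.stopping_fraction(water, t1, e)
        f2 = ph.stopping_fraction(water, t2, e)
        f12 = ph.stopping_fraction(water, t1 + t2, e)
        assert f12 == pytest.approx(1.0 - (1.0 - f1) * (1.0 - f2),
                                    rel=1e-10, abs=1e-12)


class TestDose:
    def test_empty_spectrum_zero_dose(self):
        empty = ph.Spectrum(np.array([]), np.array([]))
        assert ph.dose_per_ray(empty) == 0.0

    @given(c=st.floats(1e-3, 1e3))
    def test_linearity(self, c, kv_spectrum):
        d1 = ph.dose_per_ray(kv_spectrum)
        assert ph.dose_per_ray(kv_spectrum.scaled(c)) == pytest.approx(
            c * d1, rel=1e-12)

    def test_normalized_ray_scan_dose(self, spectra):
        # a 1-uGy ray repeated over 1000 views delivers 1 mGy
        for spec in spectra:
            assert 1000.0 * ph.dose_per_ray(spec) == pytest.approx(
                1000.0, rel=1e-9)  # uGy -> 1 mGy


class TestAllocateDose:
    def test_complement_rule(self, spectra):
        mv, kv = ph.allocate_dose(*spectra, r=0.99, total_ugy=1.0)
        assert ph.dose_per_ray(kv) == pytest.approx(0.01, rel=1e-9)

    @given(r=st.floats(0.01, 0.99))
    def test_total_dose_conserved(self, r, spectra):
        mv, kv = ph.allocate_dose(*spectra, r=r, total_ugy=2.5)
        total = ph.dose_per_ray(mv) + ph.dose_per_ray(kv)
        assert total == pytest.approx(2.5, rel=1e-10)

    def test_scan_budget_split(self, spectra):
        # 85% of 10 mGy over 1200 views -> 8.5/1200 mGy per view to the MV beam
        per_view_ugy = 10.0 * 1000.0 / 1200.0
        mv, _ = ph.allocate_dose(*spectra, r=0.85, total_ugy=per_view_ugy)
        assert ph.dose_per_ray(mv) * 1e-3 == pytest.approx(8.5 / 1200.0,
                                                           rel=1e-9)

    @pytest.mark.parametrize("r", [0.0, 0.995, 1.5])
    def test_r_out_of_range(self, r, spectra):
        with pytest.raises(ph.ParameterError):
            ph.allocate_dose(*spectra, r=r, total_ugy=1.0)


class TestSignalStatistics:
    def test_monoenergetic_no_attenuation(self, basis):
        spec = monoenergetic(100.0, 5000.0)
        comp = ph.RayComposition.tissue_bone(0.0, 0.0)
        # eta(100 keV) = 1 for the shared efficiency model
        assert ph.expected_signal(spec, comp, basis, ph.DetectorModel.pcd()) \
            == pytest.approx(5000.0)
        assert ph.expected_signal(spec, comp, basis, ph.DetectorModel.eid()) \
            == pytest.approx(5000.0 * 100.0)

    def test_full_attenuation_limit(self, basis, kv_spectrum, pcd):
        comp = ph.RayComposition.tissue_bone(500.0, 100.0)
        assert ph.expected_signal(kv_spectrum, comp, basis, pcd) \
            == pytest.approx(0.0, abs=1e-12)

    def test_two_bin_hand_computed_sum(self, basis, pcd, eid):
        # brute-force oracle: two bins, attenuation factors taken straight
        # from the material tables
        e = np.array([60.0, 100.0])
        n = np.array([1000.0, 2000.0])
        spec = ph.Spectrum(e, n)
        comp = ph.RayComposition.tissue_bone(10.0, 1.0)
        tissue, bone = basis
        a = comp.mass_thicknesses
        tau = np.exp(-(tissue.mu_over_rho(e) * a[0] + bone.mu_over_rho(e) * a[1]))
        expected_pcd = (n * tau).sum()  # eta = 1 below 150 keV
        expected_eid = (n * tau * e).sum()
        assert ph.expected_signal(spec, comp, basis, pcd) == pytest.approx(
            expected_pcd, rel=1e-12)
        assert ph.expected_signal(spec, comp, basis, eid) == pytest.approx(
            expected_eid, rel=1e-12)

    @given(t=st.floats(0.1, 30.0))
    def test_signal_strictly_decreasing_in_thickness(self, t, basis,
                                                     kv_spectrum, pcd):
        c1 = ph.RayComposition.tissue_bone(t, 0.5)
        c2 = ph.RayComposition.tissue_bone(t + 0.5, 0.5)
        s1 = ph.expected_signal(kv_spectrum, c1, basis, pcd)
        s2 = ph.expected_signal(kv_spectrum, c2, basis, pcd)
        assert s2 < s1
        assert ph.signal_variance(kv_spectrum, c2, basis, pcd) < \
            ph.signal_variance(kv_spectrum, c1, basis, pcd)

    def test_pcd_variance_is_poisson(self, basis, kv_spectrum, pcd):
        comp = ph.RayComposition.tissue_bone(20.0, 2.0)
        assert ph.signal_variance(kv_spectrum, comp, basis, pcd) == \
            ph.expected_signal(kv_spectrum, comp, basis, pcd)

    def test_eid_monoenergetic_variance(self, basis):
        spec = monoenergetic(80.0, 1e4)
        comp = ph.RayComposition.tissue_bone(15.0, 0.0)
        tissue = basis[0]
        tau = np.exp(-tissue.mu_over_rho(80.0) * comp.mass_thicknesses[0])
        # sigma_e = 0: single-energy compound Poisson, var = E * mean
        det0 = ph.DetectorModel("eid", 0.0)
        mean = ph.expected_signal(spec, comp, basis, det0)
        assert ph.signal_variance(spec, comp, basis, det0) == pytest.approx(
            80.0 * mean, rel=1e-12)
        # sigma_e = 10: direct evaluation of the stated formula
        det10 = ph.DetectorModel.eid(10.0)
        assert ph.signal_variance(spec, comp, basis, det10) == pytest.approx(
            1e4 * tau * 80.0 ** 2 + (10.0 * 80.0) ** 2, rel=1e-12)

    def test_eid_pcd_snr_equal_for_monoenergetic_noise_free_beam(self, basis):
        # the energy weight cancels in mean/sqrt(var) when sigma_e = 0
        spec = monoenergetic(500.0, 1e5)
        comp = ph.RayComposition.tissue_bone(25.0, 3.0)
        snrs = []
        for det in (ph.DetectorModel.pcd(), ph.DetectorModel("eid", 0.0)):
            m = ph.expected_signal(spec, comp, basis, det)
            v = ph.signal_variance(spec, comp, basis, det)
            snrs.append(m / np.sqrt(v))
        assert snrs[0] == pytest.approx(snrs[1], rel=1e-12)


class TestDetectorModel:
    def test_pcd_must_be_noise_free(self):
        with pytest.raises(ph.ParameterError):
            ph.DetectorModel("pcd", 5.0)

    def test_response_weighting_ratio(self):
        eid = ph.DetectorModel.eid()
        r = eid.response(np.array([3000.0, 30.0]))
        assert r[0] / r[1] == 100.0
        pcd = ph.DetectorModel.pcd()
        assert np.all(pcd.response(np.array([30.0, 3000.0])) == 1.0)
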