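import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isojump.errors import (ConfigurationError, NumericalContractError,
                            RangeError)
from isojump.exciton import (SiteDipoleParams, SiteEnergyModel, Spectrum,
                             band_maxima, broaden, build_hamiltonian,
                             calibrate, difference_spectrum, site_energies,
                             sticks, tdc_coupling, variant_spectrum)
from isojump.fixtures import fixture_spectrum
from isojump.geometry import AmideUnit, LabelScheme, PeptideStructure


def make_unit(index, origin, dipole, strand=1, orientation="inward"):
    origin = np.asarray(origin, dtype=float)
    return AmideUnit(
        residue_index=index, residue_name="ALA", strand_id=strand,
        c_pos=origin, o_pos=origin + np.array([0.0, 1.23, 0.0]),
        n_next_pos=origin + np.array([1.2, 0.0, 0.0]),
        dipole_dir=np.asarray(dipole, dtype=float),
        orientation=orientation,
    )


def dimer(v_coupling, site=1620.0, separation=5.0):
    """Two identical labeled sites with an imposed coupling."""
    u1 = make_unit(1, [0, 0, 0], [0, 0, 1])
    u2 = make_unit(2, [separation, 0, 0], [0, 0, 1], strand=2)
    s = PeptideStructure("AA", [u1, u2])
    h = build_hamiltonian(
        s, LabelScheme("dimer", frozenset({1, 2})),
        SiteEnergyModel(nu0=site + 40.0),
        SiteDipoleParams(origin_frac=0.0),
        nn_override={(1, 2): v_coupling})
    return h


class TestSiteEnergies:
    def test_unlabeled_inward_site_is_nu0(self, structure):
        model = SiteEnergyModel(nu0=1655.0, delta_out=7.0, delta_central=15.0)
        e = site_energies(structure, LabelScheme("1W"), model)
        inward_edge = [i for i, u in enumerate(structure.units)
                       if u.orientation == "inward" and u.strand_id in (1, 3)]
        assert all(e[i] == 1655.0 for i in inward_edge)

    def test_isotope_shift_is_exactly_delta_iso(self, structure):
        model = SiteEnergyModel(nu0=1660.0)
        e0 = site_energies(structure, LabelScheme("1W"), model)
        e1 = site_energies(structure, LabelScheme("1W-4", frozenset({4})),
                           model)
        idx = [u.residue_index for u in structure.units].index(4)
        assert e0[idx] - e1[idx] == pytest.approx(40.0, abs=1e-12)
        assert np.all(np.delete(e0, idx) == np.delete(e1, idx))

    def test_corrections_are_additive(self, structure):
        model = SiteEnergyModel(nu0=1650.0, delta_out=6.0, delta_central=20.0,
                                delta_turn=25.0,
                                per_residue_overrides={5: 2.5})
        e = site_energies(structure, LabelScheme("1W"), model)
        units = structure.units
        by_res = {u.residue_index: e[i] for i, u in enumerate(units)}
        assert by_res[13] == 1670.0          # central strand
        assert by_res[8] == 1675.0           # turn
        assert by_res[5] == pytest.approx(
            1650.0 + (6.0 if units[4].orientation == "outward" else 0) + 2.5)

    def test_override_for_unknown_residue_raises(self, structure):
        model = SiteEnergyModel(per_residue_overrides={99: 1.0})
        with pytest.raises(ConfigurationError):
            site_energies(structure, LabelScheme("1W"), model)


class TestTdcCoupling:
    def test_worked_orientation_factor(self):
        # parallel dipoles, both perpendicular to the separation, R = 5 A,
        # prefactor * mu^2 = 1000 cm^-1 A^3 -> V = 1000 / 5^3 = 8 cm^-1
        p = SiteDipoleParams(mu_mag=1.0, coupling_prefactor=1000.0,
                             refractive_screening=1.0, origin_frac=0.0)
        u1 = make_unit(1, [0, 0, 0], [0, 0, 1])
        u2 = make_unit(2, [5, 0, 0], [0, 0, 1])
        assert tdc_coupling(u1, u2, p) == pytest.approx(8.0, abs=1e-12)

    def test_symmetric_in_argument_order(self):
        p = SiteDipoleParams()
        u1 = make_unit(1, [0, 0, 0], [0.3, 0.4, math.sqrt(0.75)])
        u2 = make_unit(2, [3, 2, 1], [0, 1, 0])
        assert tdc_coupling(u1, u2, p) == tdc_coupling(u2, u1, p)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(r=st.floats(2.0, 12.0),
           theta=st.floats(0.0, math.pi),
           phi=st.floats(0.0, 2 * math.pi))
    def test_r_cubed_scaling(self, r, theta, phi):
        d = [math.sin(theta) * math.cos(phi), math.sin(theta) * math.sin(phi),
             math.cos(theta)]
        p = SiteDipoleParams(origin_frac=0.0)
        u1 = make_unit(1, [0, 0, 0], d)
        base = tdc_coupling(u1, make_unit(2, [r, 0.5, 0], d), p)
        doubled = tdc_coupling(u1, make_unit(2, [2 * r, 1.0, 0], d), p)
        quadrupled = tdc_coupling(u1, make_unit(2, [4 * r, 2.0, 0], d), p)
        if abs(base) > 1e-9:
            assert doubled / base == pytest.approx(1 / 8, rel=1e-9)
            assert quadrupled / base == pytest.approx(1 / 64, rel=1e-9)


class TestHamiltonian:
    def test_one_residue_system(self):
        u = make_unit(1, [0, 0, 0], [0, 1, 0])
        s = PeptideStructure("A", [u])
        h = build_hamiltonian(s, LabelScheme("x"), SiteEnergyModel(nu0=1650.0))
        assert h.matrix.shape == (1, 1)
        assert h.matrix[0, 0] == 1650.0

    @pytest.mark.parametrize("scheme", [
        LabelScheme("1W"), LabelScheme("1W-4-13", frozenset({4, 13})),
        LabelScheme("1W-4-13-20", frozenset({4, 13, 20}))])
    def test_trace_equals_sum_of_site_energies(self, structure,
                                               calibrated_model,
                                               nn_coupling, scheme):
        h = build_hamiltonian(structure, scheme, calibrated_model,
                              nn_override=nn_coupling)
        e = site_energies(structure, scheme, calibrated_model)
        assert np.trace(h.matrix) == pytest.approx(e.sum(), rel=1e-12)

    def test_degenerate_dimer_splits_symmetrically(self):
        h = dimer(v_coupling=6.0)
        freqs = [f for f, _ in sticks(h)]
        assert freqs == pytest.approx([1614.0, 1626.0], abs=1e-9)

    def test_nn_override_map_applies_to_covalent_pair(self):
        h = dimer(v_coupling=-4.25)
        assert h.matrix[0, 1] == -4.25

    def test_non_symmetric_matrix_rejected(self):
        u = make_unit(1, [0, 0, 0], [0, 1, 0])
        m = np.array([[1600.0, 1.0], [2.0, 1600.0]])
        from isojump.exciton import ExcitonHamiltonian
        with pytest.raises(NumericalContractError):
            ExcitonHamiltonian([u, u], m, np.zeros((2, 3)))


class TestSticks:
    def test_bright_dark_splitting_of_parallel_dimer(self):
        # the symmetric combination (at site + V for V > 0) carries all the
        # intensity, 2 mu^2; the antisymmetric one is dark
        h = dimer(v_coupling=5.0)
        modes = sticks(h)
        mu2 = SiteDipoleParams().mu_mag ** 2
        assert modes[1][1] == pytest.approx(2 * mu2, rel=1e-9)
        assert modes[0][1] == pytest.approx(0.0, abs=1e-12)

    def test_intensity_sum_conserved_for_orthogonal_dipoles(self):
        u1 = make_unit(1, [0, 0, 0], [1, 0, 0])
        u2 = make_unit(2, [4, 0, 0], [0, 1, 0], strand=2)
        u3 = make_unit(3, [8, 0, 0], [0, 0, 1], strand=3)
        s = PeptideStructure("AAA", [u1, u2, u3])
        h = build_hamiltonian(s, LabelScheme("x"), SiteEnergyModel())
        total = sum(i for _, i in sticks(h))
        assert total == pytest.approx(3 * SiteDipoleParams().mu_mag ** 2,
                                      rel=1e-9)

    def test_zero_coupling_returns_site_energies(self, structure):
        model = SiteEnergyModel(nu0=1640.0, delta_out=5.0, delta_central=12.0,
                                delta_turn=20.0)
        h = build_hamiltonian(structure, LabelScheme("1W"), model,
                              nn_override=0.0)
        h.matrix[~np.eye(len(h.basis), dtype=bool)] = 0.0
        freqs = np.array([f for f, _ in sticks(h)])
        expected = np.sort(site_energies(structure, LabelScheme("1W"), model))
        assert np.allclose(freqs, expected, atol=1e-10)

    def test_matches_closed_form_two_by_two(self):
        # eigenvalues of [[a, v], [v, b]]
        a, b, v = 1600.0, 1618.0, 7.5
        u1 = make_unit(1, [0, 0, 0], [0, 0, 1])
        u2 = make_unit(2, [5, 0, 0], [0, 0, 1], strand=2)
        s = PeptideStructure("AA", [u1, u2])
        h = build_hamiltonian(s, LabelScheme("x"),
                              SiteEnergyModel(nu0=a,
                                              per_residue_overrides={2: b - a}),
                              nn_override={(1, 2): v})
        mean, half = (a + b) / 2, math.hypot((a - b) / 2, v)
        assert [f for f, _ in sticks(h)] == pytest.approx(
            [mean - half, mean + half], abs=1e-8)

    def test_matches_closed_form_symmetric_trimer(self):
        # chain site energies (e, e, e), neighbor coupling v, no 1-3 term:
        # eigenvalues e - v sqrt 2, e, e + v sqrt 2
        e, v = 1610.0, 4.0
        units = [make_unit(i + 1, [6 * i, 0, 0], [0, 0, 1], strand=i + 1)
                 for i in range(3)]
        s = PeptideStructure("AAA", units)
        h = build_hamiltonian(s, LabelScheme("x"), SiteEnergyModel(nu0=e),
                              nn_override={(1, 2): v, (2, 3): v})
        h.matrix[0, 2] = h.matrix[2, 0] = 0.0
        freqs = [f for f, _ in sticks(h)]
        assert freqs == pytest.approx(
            [e - v * math.sqrt(2), e, e + v * math.sqrt(2)], abs=1e-8)


class TestBroadenAndMaxima:
    def test_single_stick_peaks_at_stick_frequency(self):
        s = broaden([(1634.0, 1.0)], "lorentzian", 12.0)
        assert band_maxima(s, (1600, 1660))[0] == pytest.approx(1634.0, abs=1.0)

    @pytest.mark.parametrize("lineshape", ["lorentzian", "gaussian"])
    def test_area_normalization(self, lineshape):
        grid = np.arange(1100.0, 2200.0, 0.5)
        s = broaden([(1634.0, 2.5)], lineshape, 12.0, grid)
        area = np.trapezoid(s.absorbance, s.wavenumbers)
        assert area == pytest.approx(2.5, rel=0.01)

    def test_two_sticks_three_fwhm_apart_resolve(self):
        s = broaden([(1600.0, 1.0), (1636.0, 1.0)], "lorentzian", 12.0)
        assert len(band_maxima(s, (1580, 1660))) == 2

    def test_monotonic_segment_has_no_maxima(self):
        s = broaden([(1700.0, 1.0)], "lorentzian", 12.0)
        assert band_maxima(s, (1560, 1620)) == []

    def test_tie_breaks_toward_lower_wavenumber(self):
        grid = np.arange(0.0, 11.0)
        a = np.array([0, 1, 2, 1, 0, 0, 0, 1, 2, 1, 0.0])
        s = Spectrum(grid, a)
        assert band_maxima(s, (0, 10)) == [2.0, 8.0]

    def test_window_outside_grid_raises(self):
        s = broaden([(1634.0, 1.0)])
        with pytest.raises(RangeError):
            band_maxima(s, (1300, 1400))


class TestDifferenceSpectrum:
    def test_self_difference_is_zero(self):
        s = fixture_spectrum("1W")
        d = difference_spectrum(s, s)
        assert np.allclose(d.absorbance, 0.0, atol=1e-15)

    def test_invariant_to_positive_scaling_of_sample(self):
        s, r = fixture_spectrum("1W-4"), fixture_spectrum("1W")
        scaled = Spectrum(s.wavenumbers, 17.0 * s.absorbance, s.metadata)
        d1 = difference_spectrum(s, r)
        d2 = difference_spectrum(scaled, r)
        assert np.allclose(d1.absorbance, d2.absorbance, atol=1e-12)

    @pytest.mark.parametrize("variant", ["1W-4", "1W-13", "1W-20"])
    def test_labeled_minus_unlabeled_lobe_pattern(self, variant):
        # intensity moves out of the main 12C band into the 13C region
        d = difference_spectrum(fixture_spectrum(variant),
                                fixture_spectrum("1W"))
        wn = d.wavenumbers
        label_region = (wn >= 1580) & (wn <= 1615)
        main_region = (wn >= 1625) & (wn <= 1645)
        assert d.absorbance[label_region].max() > 0
        assert d.absorbance[main_region].min() < 0

    def test_disjoint_grids_raise(self):
        a = broaden([(1634.0, 1.0)], grid=np.arange(1550.0, 1720.0))
        b = Spectrum(np.arange(900.0, 1100.0),
                     np.exp(-((np.arange(900.0, 1100.0) - 1000) / 30) ** 2))
        with pytest.raises(RangeError):
            difference_spectrum(a, b)


class TestCalibration:
    def test_recovers_known_model(self, structure, nn_coupling):
        truth = SiteEnergyModel(nu0=1631.0, delta_out=5.0, delta_central=19.0,
                                delta_turn=25.0)
        schemes = [LabelScheme(f"1W-{r}", frozenset({r})) for r in (4, 13, 20)]
        targets = {}
        for scheme in schemes:
            s = variant_spectrum(structure, scheme, truth,
                                 nn_override=nn_coupling)
            targets[scheme] = band_maxima(s, (1570, 1620), refine=True)[0]
        start = SiteEnergyModel(nu0=1660.0, delta_turn=25.0)
        model, resid = calibrate(start, targets, structure,
                                 nn_override=nn_coupling)
        assert model.nu0 == pytest.approx(truth.nu0, abs=0.1)
        assert model.delta_out == pytest.approx(truth.delta_out, abs=0.1)
        assert model.delta_central == pytest.approx(truth.delta_central,
                                                    abs=0.1)

    def test_no_free_parameters_returns_model_unchanged(self, structure,
                                                        nn_coupling):
        base = SiteEnergyModel(nu0=1629.0, delta_out=6.0, delta_central=20.0)
        schemes = {LabelScheme(f"1W-{r}", frozenset({r})): 1590.0
                   for r in (4, 13, 20)}
        model, resid = calibrate(base, schemes, structure, free=(),
                                 nn_override=nn_coupling)
        assert model == base

    def test_requires_three_single_label_targets(self, structure):
        from isojump.errors import CalibrationError
        with pytest.raises(CalibrationError):
            calibrate(SiteEnergyModel(),
                      {LabelScheme("1W-4", frozenset({4})): 1594.0},
                      structure)
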