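"""Materials: contrast mixtures, attenuation coefficients, Ir-192 spectrum."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mammodose import materials as M

from _oracles import brute_force_mu_over_rho


class TestContrastMixtures:
    def test_compound_composition(self):
        c = M.compound_mass_fractions()
        # published contrast-solution composition; 0.03 pp slack covers
        # printed rounding and the source's slightly different atomic weights
        expected = {"I": 48.13, "C": 27.31, "H": 3.06, "N": 5.31, "O": 16.18}
        for el, pct in expected.items():
            assert c.mass_fractions[el] * 100 == pytest.approx(pct, abs=0.03)
        assert c.density == 1.409
        assert sum(c.mass_fractions.values()) == pytest.approx(1.0, abs=1e-4)

    @pytest.mark.parametrize(
        "pct, expected, density",
        [
            (50, {"I": 24.06, "C": 13.66, "H": 7.12, "N": 2.66, "O": 52.49}, 1.20),
            # the 15% carbon cell is a documented misprint (affine rule gives
            # 4.10); it is deliberately not asserted here
            (15, {"I": 7.22, "H": 9.97, "N": 0.80, "O": 77.92}, 1.06),
        ],
    )
    def test_mixture_rows(self, pct, expected, density):
        m = M.contrast_mixture(pct)
        for el, val in expected.items():
            assert m.mass_fractions[el] * 100 == pytest.approx(val, abs=0.03)
        assert m.density == pytest.approx(density, abs=0.005)

    def test_zero_concentration_is_water(self):
        m = M.contrast_mixture(0)
        assert m.mass_fractions["H"] * 100 == pytest.approx(11.19, abs=0.01)
        assert m.mass_fractions["O"] * 100 == pytest.approx(88.81, abs=0.01)
        assert m.density == 1.0

    @given(st.floats(min_value=0, max_value=100))
    @settings(max_examples=30, deadline=None)
    def test_mixture_affine_in_concentration(self, pct):
        m = M.contrast_mixture(pct)
        c = pct / 100.0
        comp, w = M.compound_mass_fractions(), M.water()
        for el, frac in m.mass_fractions.items():
            ref = c * comp.mass_fractions.get(el, 0) + (1 - c) * w.mass_fractions.get(el, 0)
            assert frac == pytest.approx(ref, abs=1e-12)
        assert sum(m.mass_fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_density_monotone_in_concentration(self):
        d = [M.contrast_mixture(p).density for p in np.linspace(0, 100, 21)]
        assert np.all(np.diff(d) > 0)
        assert d[0] == 1.0 and d[-1] == 1.409

    def test_out_of_range_concentration(self):
        with pytest.raises(ValueError):
            M.contrast_mixture(-1)
        with pytest.raises(ValueError):
            M.contrast_mixture(101)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            M.Material("bad", {"H": 0.6, "O": 0.6}, 1.0)
        with pytest.raises(ValueError):
            M.Material("bad", {"H": 1.0}, -1.0)


class TestAttenuation:
    def test_water_against_standard_values(self, water):
        # standard published water mu/rho (cm^2/g); tables are an analytic
        # reconstruction so allow 2%
        for e, ref in [(0.06, 0.2059), (0.1, 0.1707), (0.3, 0.1186),
                       (0.5, 0.0969), (1.0, 0.0707)]:
            assert M.mu_over_rho(water, e) == pytest.approx(ref, rel=0.02)

    def test_mixture_rule_matches_elemental_sum(self, rng):
        mats = [M.water(), M.contrast_mixture(100), M.contrast_mixture(37.5),
                M.saline(), M.wax()]
        for _ in range(100):
            m = mats[rng.integers(len(mats))]
            e = float(rng.uniform(0.06, 0.885))
            assert M.mu_over_rho(m, e) == pytest.approx(
                brute_force_mu_over_rho(m, e), rel=1e-12
            )

    def test_single_element_material_matches_table(self):
        iodine = M.Material("iodine", {"I": 1.0}, 4.93)
        data = M.load_element("I")
        for j in (0, 10, 25, 47):
            e = data.energies[j]
            assert M.mu_over_rho(iodine, e) == pytest.approx(data.total[j], rel=1e-9)

    def test_contrast_attenuates_more_than_water_everywhere(self, water):
        # linear attenuation: the contrast's density and iodine photoelectric
        # dominate at every spectrum energy.  (Per unit MASS water wins above
        # ~0.7 MeV thanks to its higher Z/A, so the comparison must be linear.)
        e = np.linspace(0.06, 0.885, 50)
        assert np.all(M.linear_mu(M.contrast_mixture(100), e) > M.linear_mu(water, e))
        # iodine photoelectric makes the gap widen toward low energy
        gap = M.linear_mu(M.contrast_mixture(100), e) - M.linear_mu(water, e)
        assert gap[0] > 10 * gap[-1]

    def test_linear_mu(self, water):
        assert M.linear_mu(water, 0.3) == pytest.approx(M.mu_over_rho(water, 0.3))
        c = M.contrast_mixture(100)
        assert M.linear_mu(c, 0.3) == pytest.approx(1.409 * M.mu_over_rho(c, 0.3))
        vacuum = M.Material("vacuum", {}, 0.0)
        assert M.linear_mu(vacuum, 0.3) == 0.0

    def test_energy_out_of_range(self, water):
        with pytest.raises(ValueError):
            M.mu_over_rho(water, 0.01)
        with pytest.raises(ValueError):
            M.mu_over_rho(water, 2.0)

    def test_element_tables_positive_increasing_grid(self):
        for sym in M.ATOMIC_WEIGHTS:
            d = M.load_element(sym)
            assert np.all(np.diff(d.energies) > 0)
            assert d.energies[0] <= 0.06 and d.energies[-1] >= 0.885
            assert np.all(d.total > 0)

    def test_mu_tr_below_mu(self, water):
        e = np.linspace(0.06, 0.885, 20)
        assert np.all(M.mu_tr_over_rho(water, e) < M.mu_over_rho(water, e))


class TestSpectrum:
    def test_spectrum_shape(self, spectrum):
        assert spectrum.energies.size == 34
        assert spectrum.energies.min() >= 0.060
        assert spectrum.energies.max() <= 0.885
        assert np.all(spectrum.relative_intensities >= 0)
        assert spectrum.probabilities.sum() == pytest.approx(1.0)

    def test_mean_energy(self, spectrum):
        assert 0.3 <= spectrum.mean_energy <= 0.4

    def test_invalid_spectrum(self):
        with pytest.raises(ValueError):
            M.PhotonSpectrum(np.array([0.3, 0.2]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            M.PhotonSpectrum(np.array([0.2, 0.3]), np.array([0.0, 0.0]))


class TestSerialization:
    def test_material_round_trip(self):
        m = M.contrast_mixture(37.5)
        back = M.material_from_text(M.material_to_text(m))
        assert back.name == m.name and back.density == m.density
        for el, f in m.mass_fractions.items():
            assert back.mass_fractions[el] == f

    def test_spectrum_round_trip(self, spectrum):
        back = M.spectrum_from_text(M.spectrum_to_text(spectrum))
        assert np.array_equal(back.energies, spectrum.energies)
        assert np.array_equal(back.relative_intensities, spectrum.relative_intensities)
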