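"""Forward-model unit and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from allokin import model
from allokin.scheme import ModulatorScheme

from conftest import oracle_efficiency, oracle_kcat, oracle_km, oracle_sum


class TestBindingPolynomial:
    @pytest.mark.parametrize(
        "K, c, sites, expected",
        [
            (0.5, 0.0, 3, 1.0),  # zero concentration
            (1.0, 2.0, 3, 27.0),  # (1+2)^3
            (0.02, 5.0, 2, 1.21),  # (1.1)^2
        ],
    )
    def test_known_values(self, K, c, sites, expected):
        assert model.binding_polynomial(K, c, sites) == pytest.approx(expected)

    @given(
        K=st.floats(0, 100),
        c=st.floats(0, 50),
        sites=st.integers(0, 6),
    )
    @settings(deadline=None, max_examples=100)
    def test_equals_binomial_expansion(self, K, c, sites):
        closed = model.binding_polynomial(K, c, sites)
        assert closed == pytest.approx(oracle_sum(K, c, sites), rel=1e-12)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, -1, 1), (1, 1, -1)])
    def test_negative_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            model.binding_polynomial(*bad)


class TestStatePopulations:
    def test_symmetric_allosteric_constant_is_half_half(self, h20s):
        scheme = h20s.replace(L_L=1.0)
        f_A, f_B = model.state_populations(scheme, 0.0, "substrate_bound")
        assert (f_A, f_B) == (0.5, 0.5)

    def test_inaccessible_B_state(self, h20s):
        # L_U -> 0 limit: conformation B never populated in the unbound form
        scheme = h20s.replace(L_U=1e-300, m=0)
        for L in (0.0, 1.0, 100.0):
            f_A, f_B = model.state_populations(scheme, L, "unbound")
            assert f_A == pytest.approx(1.0, abs=1e-250)

    def test_conservation(self, all_schemes):
        L = np.geomspace(1e-3, 1e3, 50)
        for scheme in all_schemes.values():
            for form in ("unbound", "substrate_bound"):
                f_A, f_B = model.state_populations(scheme, L, form)
                np.testing.assert_allclose(f_A + f_B, 1.0, rtol=1e-14)

    def test_matches_enumeration_oracle(self, h20s):
        from conftest import oracle_weights

        w_A, w_B = oracle_weights(h20s, 1.0, "substrate_bound")
        f_A, f_B = model.state_populations(h20s, 1.0, "substrate_bound")
        assert f_A == pytest.approx(w_A / (w_A + w_B), rel=1e-12)

    def test_cooperativity_cap(self, all_schemes):
        # the log-log slope of f_B/f_A never exceeds the number of sites
        L = np.geomspace(1e-3, 1e3, 400)
        for scheme in all_schemes.values():
            f_A, f_B = model.state_populations(scheme, L, "unbound")
            slope = np.gradient(np.log(f_B / f_A), np.log(L))
            assert slope.max() <= scheme.n + scheme.m + 1e-6


class TestObservedParameters:
    def test_identical_states_give_flat_kcat(self, h20s):
        scheme = h20s.replace(kcat_B=h20s.kcat_A)
        L = np.array([0.0, 0.5, 5.0, 50.0])
        np.testing.assert_allclose(
            model.observed_kcat(scheme, L), h20s.kcat_A, rtol=1e-14
        )

    def test_kcat_modulator_free_limit(self, h20s):
        scheme = h20s.replace(kcat_A=1.0, kcat_B=0.5, L_L=4.02e-5)
        expected = (1.0 + 4.02e-5 * 0.5) / (1.0 + 4.02e-5)
        assert model.observed_kcat(scheme, 0.0) == pytest.approx(expected, rel=1e-12)
        assert round(model.observed_kcat(scheme, 0.0), 5) == 0.99998

    def test_km_modulator_free_limit(self, h20s):
        # km_0 (1 + L_U) / (1 + L_L) with the anchored allosteric constants
        assert model.observed_km(h20s, 0.0) == pytest.approx(59.9978, abs=1e-4)

    def test_km_flat_when_weights_cancel(self, h20s):
        scheme = h20s.replace(K_AU=0.3, K_BU=0.3, K_AL=0.3, K_BL=0.3, m=0)
        L = np.array([0.0, 1.0, 10.0, 100.0])
        expected = scheme.km_0 * (1 + scheme.L_U) / (1 + scheme.L_L)
        np.testing.assert_allclose(model.observed_km(scheme, L), expected, rtol=1e-12)

    def test_kcat_bounded_by_state_turnovers(self, all_schemes):
        L = np.geomspace(1e-4, 1e4, 200)
        for scheme in all_schemes.values():
            kcat = model.observed_kcat(scheme, L)
            lo = min(scheme.kcat_A, scheme.kcat_B) - 1e-12
            hi = max(scheme.kcat_A, scheme.kcat_B) + 1e-12
            assert np.all((kcat >= lo) & (kcat <= hi))

    def test_efficiency_equal_states(self, h20s):
        scheme = h20s.replace(kcat_A=1.0, km_A=10.0, kcat_B=2.0, km_B=20.0)
        expected = 1.0 / 10.0
        for L in (0.0, 1.0, 50.0):
            assert model.observed_efficiency(scheme, L) == pytest.approx(expected)

    def test_efficiency_saturating_limit(self, h20s):
        # at saturating modulator a residual A fraction 1/(1 + L_U·gamma^n)
        # survives (both weights grow as L^n), so the exact asymptote mixes
        # the two specificity constants with that weight
        eff_A = h20s.kcat_A / h20s.km_A
        eff_B = h20s.kcat_B / h20s.km_B
        w = h20s.L_U * (h20s.K_BU / h20s.K_AU) ** h20s.n
        asymptote = (eff_A + w * eff_B) / (1 + w)
        assert model.observed_efficiency(h20s, 1e8) == pytest.approx(
            asymptote, rel=1e-9
        )
        assert model.observed_efficiency(h20s, 1e8) == pytest.approx(eff_B, rel=1e-5)

    @pytest.mark.parametrize("name", ["H20S_LIKE", "Y20S_LIKE", "A3DN_LIKE"])
    @pytest.mark.parametrize("L", [0.0, 0.1, 1.0, 10.0])
    def test_oracle_equivalence(self, all_schemes, name, L):
        scheme = all_schemes[name]
        assert model.observed_kcat(scheme, L) == pytest.approx(
            oracle_kcat(scheme, L), rel=1e-10
        )
        assert model.observed_km(scheme, L) == pytest.approx(
            oracle_km(scheme, L), rel=1e-10
        )
        assert model.observed_efficiency(scheme, L) == pytest.approx(
            oracle_efficiency(scheme, L), rel=1e-10
        )

    def test_competitive_signature(self, y20s, h20s):
        # m >= 1: observed Km eventually increases without bound; m = 0: finite limit
        L = np.geomspace(10, 1e6, 60)
        km_y = model.observed_km(y20s, L)
        assert np.all(np.diff(km_y) > 0)
        assert km_y[-1] > 1e3 * km_y[0]
        km_h_far = model.observed_km(h20s, 1e8)
        limit = h20s.km_0 * (h20s.L_U * h20s.K_BU**h20s.n) / (
            h20s.L_L * h20s.K_BL**h20s.n
        )
        assert km_h_far == pytest.approx(limit, rel=1e-5)


class TestEfficiencyConsistency:
    def test_degenerate_symmetric_scheme_collapses(self, h20s):
        scheme = h20s.replace(
            K_AU=h20s.K_AL, K_BU=h20s.K_BL, L_U=h20s.L_L,
            km_A=h20s.km_0, km_B=h20s.km_0, m=0,
        )
        assert model.efficiency_consistency(scheme, [0.1, 1, 10]) < 1e-12

    def test_single_state_scheme_collapses(self, h20s):
        # only conformation A, with coinciding substrate-free/bound constants
        scheme = h20s.replace(
            L_U=1e-300, L_L=1e-300, K_AU=h20s.K_AL, km_A=h20s.km_0, m=0
        )
        assert model.efficiency_consistency(scheme, [0.1, 1, 10]) < 1e-12

    def test_strictly_positive_on_asymmetric_scheme(self, h20s):
        grid = np.geomspace(0.1, 10, 20)
        assert model.efficiency_consistency(h20s, grid) > 0.01


class TestVelocity:
    def test_half_saturation(self, all_schemes):
        for scheme in all_schemes.values():
            for L in (0.0, 1.0):
                km = model.observed_km(scheme, L)
                v = model.velocity(scheme, 2.0, km, L)
                assert v == pytest.approx(
                    0.5 * 2.0 * model.observed_kcat(scheme, L), rel=1e-12
                )

    def test_saturation(self, h20s):
        km = model.observed_km(h20s, 0.5)
        v = model.velocity(h20s, 2.0, 1e9 * km, 0.5)
        assert v == pytest.approx(2.0 * model.observed_kcat(h20s, 0.5), rel=1e-8)

    def test_composes_observed_parameters(self, h20s):
        kcat = model.observed_kcat(h20s, 0.0)
        km = model.observed_km(h20s, 0.0)
        assert model.velocity(h20s, 2.0, 10.0, 0.0) == pytest.approx(
            2.0 * kcat * 10.0 / (km + 10.0), rel=1e-14
        )

    def test_zero_substrate(self, h20s):
        assert model.velocity(h20s, 2.0, 0.0, 1.0) == 0.0


class TestIC50:
    def test_closed_form_competitive_limit(self):
        # all-B scheme, pure competitive inhibition, S << Km: IC50 = 1/K_BI
        scheme = ModulatorScheme(
            kcat_A=1.0, kcat_B=1.0, km_0=10.0, km_A=10.0, km_B=10.0,
            K_AU=0.0, K_BU=0.0, K_AL=0.0, K_BL=0.0, K_BI=2.0,
            L_U=1e12, L_L=1e12, n=1, m=1,
        )
        result = model.ic50(scheme, 2.0, 0.001 * scheme.km_B, L_max=100.0)
        assert result == pytest.approx(0.5, abs=1e-3)

    def test_pure_activator_has_no_ic50(self, h20s):
        assert model.ic50(h20s, 2.0, 10.0, L_max=100.0) is None

    def test_matches_grid_oracle(self, y20s):
        found = model.ic50(y20s, 2.0, 25.0, L_max=1000.0)
        assert found is not None
        # dense brute-force scan at 1e-3 µM resolution
        v0 = model.velocity(y20s, 2.0, 25.0, 0.0)
        grid = np.arange(1e-3, 1000.0, 1e-3)
        ratio = np.asarray(model.velocity(y20s, 2.0, 25.0, grid)) / v0 - 0.5
        first = grid[np.nonzero(np.sign(ratio[:-1]) * np.sign(ratio[1:]) < 0)[0][0]]
        assert found == pytest.approx(first, abs=2e-3)
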