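"""Rate laws, ODE right-hand side, and stoichiometry of the yeast network."""

import numpy as np
import pytest

import irontraffic as it
from irontraffic.network import UnknownReactionError
from conftest import random_profiles


class TestCompartmentLayout:
    def test_default_fractions_and_interregional_factor(self):
        lay = it.CompartmentLayout()
        assert lay.f_cyt == 0.8
        assert lay.f_cyt / lay.f_vac == pytest.approx(8.0)

    @pytest.mark.parametrize("bad", [
        dict(f_cyt=0.9, f_mit=0.1, f_vac=0.1),   # sums to 1.1
        dict(f_cyt=1.0, f_mit=0.0, f_vac=0.0),   # zero fractions
        dict(f_cyt=-0.8, f_mit=0.9, f_vac=0.9),
    ])
    def test_invalid_layouts_rejected(self, bad):
        with pytest.raises(ValueError):
            it.CompartmentLayout(**bad)


class TestConcentrationProfile:
    def test_whole_cell_iron_of_healthy_state(self, W):
        # f_cyt(CIA+FC) + f_vac(F2+F3) + f_mit(FM+FS+MP)
        assert W.profile.fe_cell() == pytest.approx(505.0, abs=1e-9)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            it.ConcentrationProfile.from_array([-1, 0, 0, 0, 0, 0, 0, 0])


class TestReactionRate:
    def test_saturating_iron_import(self, W):
        # k=2.629947, K=10, [IRON]=40 -> k*40/50
        got = it.reaction_rate("cyt", W.profile, W.params)
        assert got == pytest.approx(W.params.k["cyt"] * 40 / 50, rel=1e-12)
        assert got == pytest.approx(2.103960, rel=1e-5)
        # the printed constant reproduces the printed rate the same way
        assert 2.629947 * 40 / 50 == pytest.approx(2.103960, rel=1e-5)

    def test_zero_substrate_gives_zero_rate(self, W):
        prof = it.ConcentrationProfile.from_dict({**W.profile.as_dict(), "FM": 0.0})
        assert it.reaction_rate("mp", prof, W.params) == 0.0

    def test_o2_inhibited_isc_assembly(self, W):
        # k=6.666, K=100, [FM]=100, sp=[O2]=1 -> 6.666*0.5*0.5
        assert it.reaction_rate("isu", W.profile, W.params) == \
            pytest.approx(1.6665, rel=1e-9)

    def test_vacuolar_oxidation_times_external_oxygen(self, W):
        got = it.reaction_rate("23", W.profile, W.params)
        assert got == pytest.approx(W.params.k["23"] * 0.5 * 100, rel=1e-12)
        assert got == pytest.approx(11.3322, rel=1e-5)
        assert 0.226643 * 0.5 * 100 == pytest.approx(11.3322, rel=1e-4)

    def test_o2_exchange_may_be_negative(self, W):
        prof = it.ConcentrationProfile.from_dict({**W.profile.as_dict(), "O2": 150.0})
        assert it.reaction_rate("O2", prof, W.params) < 0

    def test_unknown_reaction_id(self, W):
        with pytest.raises(UnknownReactionError):
            it.reaction_rate("nope", W.profile, W.params)


class TestOdeRhs:
    def test_trained_state_is_stationary(self, bundle):
        for lab in ("W", "Y", "D"):
            st = bundle.state(lab)
            rates = [it.reaction_rate(r, st.profile, st.params)
                     for r in it.REACTION_IDS]
            resid = np.max(np.abs(it.ode_rhs(st.profile, st.params)))
            assert resid < 1e-3 * max(rates)

    def test_empty_cell_only_oxygen_flows(self, W):
        import dataclasses
        params = dataclasses.replace(W.params, iron=0.0)
        zero = it.ConcentrationProfile.from_array(np.zeros(8))
        dydt = it.ode_rhs(zero, params)
        expect = np.zeros(8)
        expect[it.COMPONENTS.index("O2")] = params.k["O2"] * params.oxygen
        np.testing.assert_allclose(dydt, expect, atol=1e-12)

    def test_vacuolar_fe2_balance_hand_evaluated(self, W):
        # d[F2]/dt = 8 R_vac − R_23 − α[F2] with the published W rates
        dydt = it.ode_rhs(W.profile, W.params)
        assert dydt[it.COMPONENTS.index("F2")] == \
            pytest.approx(8 * 1.49985 - 11.3322 - 0.6666, abs=1e-3)

    def test_rhs_consistent_with_stoichiometric_assembly(self, W):
        """ode_rhs must equal S·R for arbitrary nonnegative profiles."""
        S = it.stoichiometric_matrix()
        net = it.yeast_network()
        for arr in random_profiles(100, seed=42):
            prof = it.ConcentrationProfile.from_array(arr)
            rates = np.array([it.reaction_rate(r, prof, W.params)
                              for r in it.REACTION_IDS]
                             + [W.params.alpha * c for c in arr])
            direct = it.ode_rhs(prof, W.params)
            assembled = S @ rates
            np.testing.assert_allclose(direct, assembled, rtol=1e-10, atol=1e-12)

    def test_rates_nonnegative_except_o2_exchange(self, W):
        for arr in random_profiles(50, seed=7):
            prof = it.ConcentrationProfile.from_array(arr)
            for rid in it.REACTION_IDS:
                if rid == "O2":
                    continue
                assert it.reaction_rate(rid, prof, W.params) >= 0


class TestStoichiometricMatrix:
    def test_cytosolic_iron_row(self):
        S = it.stoichiometric_matrix()
        row = S[it.COMPONENTS.index("FC")]
        names = list(it.REACTION_IDS) + [f"D_{c}" for c in it.COMPONENTS]
        expect = {"cyt": 1, "mit": -1, "vac": -1, "cia": -1, "D_FC": -1}
        for j, n in enumerate(names):
            assert row[j] == expect.get(n, 0)

    def test_dilution_column_touches_one_component(self):
        S = it.stoichiometric_matrix()
        col = S[:, 9 + it.COMPONENTS.index("MP")]
        assert col[it.COMPONENTS.index("MP")] == -1
        assert np.count_nonzero(col) == 1

    def test_interregional_factor_eight(self):
        S = it.stoichiometric_matrix()
        assert S[it.COMPONENTS.index("F2"), it.REACTION_IDS.index("vac")] == 8
        assert S[it.COMPONENTS.index("FM"), it.REACTION_IDS.index("mit")] == 8

    def test_published_rate_vector_lies_in_null_space(self, bundle):
        S = it.stoichiometric_matrix()
        ref = bundle.reference_table["W"]
        R = np.array([ref[f"R_{r}"] for r in it.REACTION_IDS]
                     + [ref[f"D_{c}"] for c in it.COMPONENTS])
        resid = S @ R
        # rows balance to the published values' printing precision (the O2
        # row carries rates of magnitude ~9e3 printed to 6 digits)
        row_scale = np.abs(S) @ np.abs(R)
        assert np.max(np.abs(resid) / np.maximum(row_scale, 1.0)) < 1e-4


def test_iron_conservation_without_import_or_growth(W):
    """With no import and no dilution, whole-cell iron is invariant."""
    import dataclasses
    params = dataclasses.replace(W.params.with_k(cyt=0.0), alpha=0.0)
    tr = it.integrate(params, W.profile, 5000.0,
                      t_eval=np.linspace(0, 5000, 21))
    fe = [it.ConcentrationProfile.from_array(np.maximum(y, 0)).fe_cell()
          for y in tr.conc]
    np.testing.assert_allclose(fe, fe[0], rtol=1e-7)
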