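"""Integration, steady states, transitions, and perturbation recovery."""

import numpy as np
import pytest

import irontraffic as it
from irontraffic.dynamics import T_STEADY


class TestIntegrate:
    def test_healthy_state_holds_its_steady_state(self, W):
        tr = it.integrate(W.params, W.profile, T_STEADY)
        np.testing.assert_allclose(tr.conc[-1], W.profile.as_array(), rtol=0.01)

    def test_zero_horizon_returns_initial(self, W):
        tr = it.integrate(W.params, W.profile, 0.0)
        np.testing.assert_array_equal(tr.conc[0], W.profile.as_array())

    def test_endpoint_agrees_with_algebraic_root(self, Y):
        ss = it.steady_state(Y.params, Y.profile.as_array())
        root = it.root_steady_state(Y.params, ss)
        np.testing.assert_allclose(ss, root, rtol=1e-3)

    def test_effective_constants_recorded_along_trace(self, W, case1):
        tr = it.integrate(W.params, W.profile, 100.0, crm=case1,
                          t_eval=np.linspace(0, 100, 5))
        assert tr.kobs.shape == (5, 9)
        j = it.REACTION_IDS.index("23")
        assert tr.kobs[0, j] == pytest.approx(0.226643, rel=0.01)


class TestAlphaOfKisu:
    def test_anchor_points(self):
        assert it.alpha_of_kisu(6.666) == pytest.approx(0.003333)
        assert it.alpha_of_kisu(0.6666) == pytest.approx(0.002)

    def test_midpoint_of_line(self):
        mid = (6.666 + 0.6666) / 2
        assert it.alpha_of_kisu(mid) == pytest.approx((0.003333 + 0.002) / 2)

    def test_extrapolation_warns(self):
        with pytest.warns(UserWarning, match="extrapolating"):
            it.alpha_of_kisu(10.0)


class TestTimeTransition:
    def test_disease_transition_reaches_target(self, bundle, W, Y, case1):
        """Abrupt frataxin loss under case-1 autoregulation lands within 1%
        of the diseased state, with nanoparticles accumulating."""
        spec = it.TransitionSpec.w_to_y(Y.params.k["isu"])
        t_eval = np.linspace(0.0, T_STEADY, 201)
        tr = it.time_transition(W.params, spec, crm=case1,
                                init=W.profile, t_eval=t_eval)
        np.testing.assert_allclose(tr.conc[-1], Y.profile.as_array(), rtol=0.015)
        mp = tr.component("MP")
        assert mp[-1] > 100 * mp[0]   # 50 -> ~8500 μM

    def test_null_trigger_gives_flat_trace(self, W):
        spec = it.TransitionSpec(kind="custom", targets={})
        tr = it.time_transition(W.params, spec, init=W.profile,
                                t_eval=np.linspace(0, 1000, 11))
        assert np.max(np.abs(tr.conc - tr.conc[0]) /
                      np.maximum(tr.conc[0], 1e-12)) < 1e-5

    def test_severe_hypoxia_from_diseased_state(self, bundle, Y, case1):
        """Lowering external oxygen to 1 μM from the diseased state empties
        nanoparticles into vacuolar Fe(II) (the hypoxia prediction)."""
        start = it.steady_state(Y.params, Y.profile.as_array(), crm=case1)
        tr = it.time_transition(Y.params, it.TransitionSpec.hypoxia(1.0),
                                crm=case1, init=start)
        end = dict(zip(it.COMPONENTS, tr.conc[-1]))
        reported = bundle.predictions["H_Y"]["reported"]
        assert end["F2"] == pytest.approx(reported["F2"], rel=0.05)
        assert end["FS"] / Y.profile.FS > 1.5   # partial FS recovery

    def test_reverse_transition_is_not_time_mirror(self, W, Y, case1):
        t_eval = np.linspace(0.0, 5000.0, 101)
        fwd = it.time_transition(
            W.params, it.TransitionSpec.w_to_y(Y.params.k["isu"]),
            crm=case1, init=it.steady_state(W.params, W.profile.as_array(),
                                            crm=case1), t_eval=t_eval)
        y_params = W.params.with_k(isu=Y.params.k["isu"])
        import dataclasses
        y_params = dataclasses.replace(y_params, alpha=Y.params.alpha)
        rev = it.time_transition(
            y_params, it.TransitionSpec(kind="Y->W",
                                        targets={"k_isu": W.params.k["isu"],
                                                 "alpha": W.params.alpha}),
            crm=case1, init=it.steady_state(y_params, Y.profile.as_array(),
                                            crm=case1), t_eval=t_eval)
        # compare forward trace with time-reversed reverse trace (normalized)
        f = fwd.conc / np.maximum(fwd.conc[0], 1e-12)
        r = rev.conc[::-1] / np.maximum(rev.conc[-1], 1e-12)
        assert np.max(np.abs(f - r)) > 0.05


class TestSteadyStateTransition:
    def test_two_increments_are_just_the_endpoints(self, W, D, case1):
        spec = it.TransitionSpec(kind="W->D", targets={"iron": 1.0},
                                 n_increments=2)
        tr = it.steady_state_transition(W.params, spec, crm=case1,
                                        init=W.profile)
        assert len(tr.abscissa) == 2
        assert tr.abscissa[0] == pytest.approx(40.0)
        assert tr.abscissa[-1] == pytest.approx(1.0)
        # published valve parameters carry 3 significant figures
        np.testing.assert_allclose(tr.conc[-1], D.profile.as_array(), rtol=0.03)

    def test_iron_starvation_hits_deficient_state(self, W, D, case1):
        spec = it.TransitionSpec.w_to_d(1.0)
        spec = it.TransitionSpec(kind=spec.kind, targets=spec.targets,
                                 n_increments=25)
        tr = it.steady_state_transition(W.params, spec, crm=case1,
                                        init=W.profile)
        assert tr.converged.all()
        np.testing.assert_allclose(tr.conc[-1], D.profile.as_array(), rtol=0.03)

    def test_isc_pool_declines_monotonically_toward_disease(self, W, Y, case1):
        spec = it.TransitionSpec(kind="W->Y",
                                 targets={"k_isu": Y.params.k["isu"],
                                          "alpha": Y.params.alpha},
                                 couple_alpha=True, n_increments=25)
        w_ss = it.steady_state(W.params, W.profile.as_array(), crm=case1)
        tr = it.steady_state_transition(W.params, spec, crm=case1, init=w_ss)
        fs = tr.component("FS")
        # smoothly and gradually downward: no increment rises by more than
        # 0.1% of the starting level, and the pool ends far lower
        assert np.all(np.diff(fs) < 1e-3 * fs[0])
        assert fs[-1] < 0.35 * fs[0]

    def test_growth_rate_follows_linear_map_along_schedule(self, W, Y, case1):
        spec = it.TransitionSpec(kind="W->Y",
                                 targets={"k_isu": Y.params.k["isu"],
                                          "alpha": Y.params.alpha},
                                 couple_alpha=True, n_increments=5)
        tr = it.steady_state_transition(W.params, spec, crm=case1,
                                        init=W.profile)
        for kisu in tr.abscissa:
            assert it.alpha_of_kisu(kisu) == pytest.approx(
                np.interp(kisu, [0.6666, 6.666], [0.002, 0.003333]))


class TestPerturbRecover:
    def test_unregulated_isc_doubling_leaves_upstream_unaffected(self, W):
        tr, t_rec = it.perturb_recover(W.params, "FS", 2.0, t_perturb=400.0,
                                       t_end=8000.0, init=W.profile)
        assert t_rec is not None
        ss = W.profile.as_array()
        for comp in ("FC", "F2", "CIA", "F3"):
            i = it.COMPONENTS.index(comp)
            np.testing.assert_allclose(tr.conc[:, i], ss[i], rtol=1e-4)

    def test_regulated_isc_doubling_impacts_every_component(self, W, case1):
        ss = it.steady_state(W.params, W.profile.as_array(), crm=case1)
        tr, t_rec = it.perturb_recover(W.params, "FS", 2.0, t_perturb=400.0,
                                       t_end=10_000.0, crm=case1, init=ss)
        assert t_rec is not None
        post = tr.conc[tr.abscissa > 400.0]
        rel_dev = np.max(np.abs(post - ss) / np.maximum(ss, 1e-12), axis=0)
        assert np.all(rel_dev > 1e-3)

    def test_unit_factor_gives_flat_trace(self, W):
        tr, t_rec = it.perturb_recover(W.params, "FS", 1.0, t_perturb=100.0,
                                       t_end=2000.0, init=W.profile)
        assert np.max(np.abs(tr.conc - tr.conc[0]) /
                      np.maximum(tr.conc[0], 1e-12)) < 1e-5
        assert t_rec == pytest.approx(100.0, abs=20)

    def test_small_perturbations_recover_each_component(self, W):
        """±10% single-component kicks die out, as the all-negative
        eigenvalues require."""
        for comp in ("FC", "MP"):
            for factor in (0.9, 1.1):
                _, t_rec = it.perturb_recover(W.params, comp, factor,
                                              t_perturb=10.0, t_end=10_000.0,
                                              init=W.profile)
                assert t_rec is not None
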