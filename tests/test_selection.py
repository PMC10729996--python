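"""The six-filter CRM selection machinery (unit level)."""

import numpy as np
import pandas as pd
import pytest

import irontraffic as it
import irontraffic.selection as sel
from irontraffic.dynamics import TransitionTrace


class TestEnumerateAndUniqueness:
    @pytest.mark.parametrize("n_rxn,n_sen,expect", [
        (9, 8, 134_217_728),
        (7, 8, 2_097_152),
        (1, 1, 1),
    ])
    def test_candidate_counts(self, n_rxn, n_sen, expect):
        assert it.enumerate_count(n_rxn, n_sen) == expect

    def test_bundled_regulatable_set(self, bundle):
        reg = it.filter_uniqueness(bundle.states)
        assert set(reg) == {"cia", "23", "mp", "vac", "mit", "cyt", "O2"}

    def test_identical_states_nothing_regulatable(self, W):
        assert it.filter_uniqueness({"W": W, "Y": W, "D": W}) == ()

    def test_near_equal_constants_not_regulatable(self, W, Y, D):
        import dataclasses
        # make the diseased-state value a 1e-12 perturbation of healthy
        y2 = dataclasses.replace(
            Y, params=Y.params.with_k(cia=W.params.k["cia"] * (1 + 1e-12)))
        reg = it.filter_uniqueness({"W": W, "Y": y2, "D": D})
        assert "cia" not in reg

    def test_primary_mutation_lock_excludes_isu(self, bundle):
        # k_isu differs between W and Y yet stays locked
        ks = [bundle.state(lab).params.k["isu"] for lab in "WY"]
        assert ks[0] != ks[1]
        assert "isu" not in it.filter_uniqueness(bundle.states)


class TestTrending:
    def test_bundled_count(self, k_table, conc_table):
        valid = it.filter_trending(k_table, conc_table)
        assert sel.trending_count(valid) == 576

    def test_mitochondrial_import_only_isc_feedback(self, k_table, conc_table):
        valid = it.filter_trending(k_table, conc_table)
        assert valid["mit"] == [("FS", "feedback")]

    def test_tied_sensor_concentrations_disqualify(self, k_table):
        conc = {c: (1.0, 1.0, 2.0) for c in it.COMPONENTS}
        valid = it.filter_trending(k_table, conc)
        assert sel.trending_count(valid) == 0

    def test_product_equals_brute_force_enumeration(self, k_table, conc_table):
        valid = it.filter_trending(k_table, conc_table)
        assert it.trending_bruteforce(valid) == sel.trending_count(valid)

    def test_product_equals_brute_force_on_random_tables(self):
        rng = np.random.RandomState(0)
        for _ in range(5):
            k_table = {f"r{i}": tuple(rng.rand(3)) for i in range(4)}
            conc = {c: tuple(rng.choice(10, 3, replace=False).astype(float))
                    for c in it.COMPONENTS}
            valid = it.filter_trending(k_table, conc)
            assert it.trending_bruteforce(valid) == sel.trending_count(valid)


def _trace(abscissa, conc, converged=True):
    conc = np.asarray(conc, float)
    n = len(abscissa)
    return TransitionTrace(abscissa=np.asarray(abscissa, float), conc=conc,
                           kobs=np.zeros((n, 9)),
                           converged=np.full(n, converged))


class TestWanderScores:
    def test_linear_transition_wanders_nothing(self):
        p = np.linspace(0, 10, 100)
        conc = np.outer(np.linspace(0, 1, 100), np.arange(1.0, 9.0))
        tr_ss = _trace(p, conc)
        tr_t = _trace(np.linspace(0, 5000, 100), conc)
        _, _, (we_t, we_s) = it.wander_scores(tr_t, tr_ss)
        assert we_s == pytest.approx(0.0, abs=1e-9)
        assert we_t == pytest.approx(0.0, abs=1e-9)

    def test_constructed_detour_doubling_arc_length(self):
        # a symmetric triangular detour with known polyline length:
        # choose the apex so the path is exactly twice the straight line
        p = np.array([0.0, 0.5, 1.0])
        straight = 1.0  # flat component: endpoints identical, distance = Δp
        apex = np.sqrt(1.0 - 0.25)  # each leg = sqrt(0.25 + apex²) = 1
        conc = np.zeros((3, 8))
        conc[1, :] = apex
        tr_ss = _trace(p, conc)
        _, al_ss, (_, we_s) = it.wander_scores(_trace([0, 2500, 5000], conc), tr_ss)
        assert we_s == pytest.approx(100.0, rel=1e-9)

    def test_nonconverged_increment_invalidates_scores(self):
        tr = _trace([0, 1], np.zeros((2, 8)), converged=False)
        with pytest.raises(ValueError, match="non-convergent"):
            it.wander_scores(_trace([0, 5000], np.zeros((2, 8))), tr)


class TestSmoothness:
    def test_constant_trace_is_perfectly_smooth(self):
        tr = _trace(np.arange(100), np.ones((100, 8)))
        assert it.smoothness_score([tr]) == 0.0

    def test_single_spike_contribution(self):
        conc = np.ones((100, 8))
        conc[50, 0] = 1.1  # one 10% spike in one component
        tr = _trace(np.arange(100), conc)
        expect = 100 * (0.1 / 1.0 + 0.1 / 1.1)
        assert it.smoothness_score([tr]) == pytest.approx(expect, rel=1e-9)

    def test_sums_over_both_transitions(self):
        conc = np.ones((100, 8))
        conc[10, 3] = 2.0
        tr = _trace(np.arange(100), conc)
        assert it.smoothness_score([tr, tr]) == \
            pytest.approx(2 * it.smoothness_score([tr]), rel=1e-12)


class TestNSpScores:
    def test_unit_sensitivity_scores_zero(self, conc_table):
        crm = it.CRM(regulators={"23": it.HeavisideRegulator("FC", 1.0, 11.67, 1.0)})
        n_err, _ = it.n_sp_scores(crm, conc_table)
        assert n_err == 0.0

    def test_shallow_sensitivity_penalized_reciprocally(self, conc_table):
        crm = it.CRM(regulators={"mit": it.HeavisideRegulator("FS", -0.022, 0.992, 169.0)})
        n_err, _ = it.n_sp_scores(crm, conc_table)
        assert n_err == pytest.approx(1 / 0.022 - 1, rel=1e-9)

    def test_setpoint_at_sensor_mean_scores_zero(self, conc_table):
        mean_fc = np.mean(conc_table["FC"])
        crm = it.CRM(regulators={"23": it.HeavisideRegulator("FC", 1.0, mean_fc, 1.0)})
        _, sp_err = it.n_sp_scores(crm, conc_table)
        assert sp_err == pytest.approx(0.0, abs=1e-12)

    def test_zero_sensitivity_flagged_infinite(self, conc_table):
        crm = it.CRM(regulators={"23": it.HeavisideRegulator("FC", 0.0, 10.0, 1.0)})
        n_err, _ = it.n_sp_scores(crm, conc_table)
        assert n_err == np.inf


class TestFitPool:
    def test_vacuolar_oxidation_pairs_all_fit(self, k_table, conc_table):
        valid = {"23": it.filter_trending(k_table, conc_table)["23"]}
        pool, frame = sel.build_fit_pool(k_table, conc_table, valid, seed=0)
        assert len(pool) == 4
        assert (frame["max_rel_error"] < 1e-3).all()

    def test_candidate_construction_respects_pool(self, k_table, conc_table):
        valid = {"mit": [("FS", "feedback")], "23": [("FC", "feedforward"),
                                                     ("CIA", "feedforward")]}
        pool, _ = sel.build_fit_pool(k_table, conc_table, valid, seed=0)
        pool.pop(("23", "CIA"))
        crms = sel._candidate_crms(valid, pool)
        assert len(crms) == 1
        assert crms[0].sensors() == {"mit": "FS", "23": "FC"}


def test_degenerate_model_collapses_cascade(W):
    """With identical states nothing is regulatable and the cascade empties
    without raising."""
    rep = it.evolve({"W": W, "Y": W, "D": W})
    assert rep.counts["uniqueness"] == 0
    assert rep.survivors == []
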