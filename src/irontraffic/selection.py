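"""Evolutionary selection of cellular regulatory mechanisms (CRMs).

A CRM assigns one sensor component (and a fitted logistic valve) to every
regulatable reaction.  Candidates are screened through six sequential
fitness filters:

  i   uniqueness  — only reactions whose rate constants differ between the
                    three trained states are regulatable,
  ii  trending    — a sensor's concentrations must order strictly with
                    (feedforward) or against (feedback) the rate constants,
  iii targeting   — simulated transitions must land within 1% of the target
                    state's concentrations for every component,
  iv  wandering   — transition paths should not stray from a straight line
                    (arc-length excess), lowest-error halves intersected,
  v   smoothness  — steady-state transition plots must not contain spikes,
                    the top (smoothest) mean-shift cluster is kept,
  vi  n/SP-reasonableness — sensitivity near 1 and setpoints near the sensor
                    range are preferred (scored, reported).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import COMPONENTS, ConcentrationProfile
from .parameterize import DerivedState
from .regulation import CRM, FitFailure, HeavisideRegulator, fit_regulator
from .dynamics import (
    TransitionSpec,
    TransitionTrace,
    IntegrationError,
    integrate,
    steady_state,
    steady_state_transition,
)

__all__ = [
    "FilterReport", "enumerate_count", "filter_uniqueness", "filter_trending",
    "trending_bruteforce", "build_fit_pool", "filter_targeting",
    "wander_scores", "smoothness_score", "n_sp_scores", "evolve",
]

#: reactions never autoregulated in the bundled model: the iron-sulfur
#: assembly constant is the primary mutation defining the diseased state
#: (manually locked), and the respiration constant is state-independent.
PRIMARY_MUTATION_LOCK = ("isu",)

_SM_FLOOR = 1e-12  # μM floor for smoothness terms at zero concentration


@dataclass
class FilterReport:
    """Cascade counts, per-candidate scores, and surviving CRMs."""

    counts: dict[str, int] = field(default_factory=dict)
    regulatable: tuple[str, ...] = ()
    valid_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    pool: pd.DataFrame | None = None
    targeting: pd.DataFrame | None = None
    wandering: pd.DataFrame | None = None
    smoothness: pd.DataFrame | None = None
    n_sp: pd.DataFrame | None = None
    survivors: list[CRM] = field(default_factory=list)

    def cascade(self) -> list[tuple[str, int]]:
        order = ["enumeration", "uniqueness", "trending", "targeting",
                 "wandering", "smoothness"]
        return [(s, self.counts[s]) for s in order if s in self.counts]


def enumerate_count(n_reactions: int, n_sensors: int) -> int:
    """Number of unrestricted sensor assignments: n_sensors ** n_reactions."""
    if n_reactions < 1 or n_sensors < 1:
        raise ValueError("need positive counts")
    return n_sensors ** n_reactions


def filter_uniqueness(states: dict[str, DerivedState],
                      locked: tuple[str, ...] = PRIMARY_MUTATION_LOCK,
                      rel_tol: float = 1e-9) -> tuple[str, ...]:
    """Reactions whose rate constants are pairwise distinct across states.

    ``locked`` reactions are excluded even when distinct (primary-mutation
    lock).  Distinctness uses a relative tolerance so that re-derived
    near-equal constants are treated as equal.
    """
    labels = list(states)
    rids = list(next(iter(states.values())).params.k)
    out = []
    for rid in rids:
        if rid in locked:
            continue
        vals = [states[lab].params.k[rid] for lab in labels]
        distinct = all(abs(a - b) > rel_tol * max(abs(a), abs(b), 1e-300)
                       for a, b in itertools.combinations(vals, 2))
        if distinct:
            out.append(rid)
    return tuple(out)


def _strict_order(vals) -> tuple[int, ...] | None:
    """Descending order of three values, or None if any two are equal."""
    if len({*vals}) < len(vals):
        return None
    return tuple(int(i) for i in np.argsort(vals)[::-1])


def filter_trending(k_table: dict[str, tuple[float, ...]],
                    conc_table: dict[str, tuple[float, ...]]
                    ) -> dict[str, list[tuple[str, str]]]:
    """Valid (sensor, mode) pairs per regulatable reaction.

    ``k_table`` maps reaction id -> per-state rate constants and
    ``conc_table`` maps component -> per-state concentrations, in the same
    state order.  A sensor is valid in feedforward mode when its
    concentrations order strictly the same way as the constants, and in
    feedback mode when they order strictly opposite.  Any tie disqualifies
    the sensor for that reaction.
    """
    valid: dict[str, list[tuple[str, str]]] = {}
    for rid, ks in k_table.items():
        k_ord = _strict_order(ks)
        pairs = []
        if k_ord is not None:
            for sen, cs in conc_table.items():
                c_ord = _strict_order(cs)
                if c_ord is None:
                    continue
                if c_ord == k_ord:
                    pairs.append((sen, "feedforward"))
                elif c_ord == k_ord[::-1]:
                    pairs.append((sen, "feedback"))
        valid[rid] = pairs
    return valid


def trending_count(valid: dict[str, list]) -> int:
    """Surviving CRM count: the product of per-reaction valid-sensor counts."""
    n = 1
    for pairs in valid.values():
        n *= len(pairs)
    return n


def trending_bruteforce(valid: dict[str, list], sensors=COMPONENTS) -> int:
    """Count survivors by enumerating every sensor assignment explicitly.

    Builds the full n_sensors**n_reactions validity grid (one boolean per
    assignment) and sums it — an independent check of the product formula.
    """
    masks = []
    for rid, pairs in valid.items():
        ok = np.array([any(s == sen for sen, _ in pairs) for s in sensors], dtype=np.int64)
        masks.append(ok)
    grid = masks[0]
    for m in masks[1:]:
        grid = np.multiply.outer(grid, m)
    return int(grid.sum())


def build_fit_pool(k_table: dict[str, tuple[float, ...]],
                   conc_table: dict[str, tuple[float, ...]],
                   valid: dict[str, list[tuple[str, str]]],
                   seed: int = 0,
                   max_rel_error: float = 1e-3
                   ) -> tuple[dict[tuple[str, str], HeavisideRegulator], pd.DataFrame]:
    """Fit one logistic valve per trending-valid (reaction, sensor) pair.

    Each valve is fitted to the three (sensor concentration, rate constant)
    points by deterministic multi-start least squares.  Pairs whose best fit
    misses any point by more than ``max_rel_error`` (relative) are excluded
    from the pool, with the reason recorded.
    """
    pool: dict[tuple[str, str], HeavisideRegulator] = {}
    rows = []
    for rid, pairs in valid.items():
        ks = np.array(k_table[rid], dtype=float)
        for sen, mode in pairs:
            xs = np.array(conc_table[sen], dtype=float)
            try:
                reg = fit_regulator(list(zip(xs, ks)), sensor=sen, seed=seed)
            except FitFailure as e:
                rows.append((rid, sen, mode, np.nan, np.nan, np.nan, np.nan,
                             np.nan, f"fit_failure: {e}"))
                continue
            pred = np.array([reg(x) for x in xs])
            err = float(np.max(np.abs(pred - ks) / np.abs(ks)))
            reason = "" if err <= max_rel_error else "fit_error"
            if not reason:
                pool[(rid, sen)] = reg
            rows.append((rid, sen, mode, reg.n, reg.setpoint, reg.k_reg,
                         reg.k_unreg, err, reason))
    frame = pd.DataFrame(rows, columns=["reaction", "sensor", "mode", "n",
                                        "setpoint", "k_reg", "k_unreg",
                                        "max_rel_error", "excluded"])
    return pool, frame


def _candidate_crms(valid: dict[str, list[tuple[str, str]]],
                    pool: dict[tuple[str, str], HeavisideRegulator]
                    ) -> list[CRM]:
    rids = list(valid)
    per_rxn = [[(sen, mode) for sen, mode in valid[rid]] for rid in rids]
    crms = []
    for combo in itertools.product(*per_rxn):
        if any((rid, sen) not in pool for rid, (sen, _) in zip(rids, combo)):
            continue  # uses an excluded valve: cannot be constructed
        regs = {rid: pool[(rid, sen)] for rid, (sen, _) in zip(rids, combo)}
        modes = {rid: mode for rid, (_, mode) in zip(rids, combo)}
        label = "+".join(f"{rid}:{sen}" for rid, (sen, _) in zip(rids, combo))
        crms.append(CRM(regulators=regs, modes=modes, label=label))
    return crms


def filter_targeting(candidates: list[CRM], w_state: DerivedState,
                     transitions: dict[str, tuple[TransitionSpec, np.ndarray]],
                     tol: float = 0.01, t_end: float = 50_000.0,
                     rtol: float = 1e-8, atol: float = 1e-8
                     ) -> tuple[list[CRM], pd.DataFrame]:
    """Keep CRMs whose simulated transitions hit every target concentration.

    ``transitions`` maps a name to (spec, target profile).  Each candidate
    starts from its own self-consistent healthy steady state, the trigger
    parameters switch abruptly, and the endpoint at ``t_end`` must be within
    ``tol`` relative of the target for all 8 components in every transition.
    """
    rows = []
    survivors = []
    w0 = w_state.profile.as_array()
    for crm in candidates:
        errs = {}
        reason = ""
        try:
            w_ss = steady_state(w_state.params, w0, crm=crm, rtol=rtol, atol=atol)
            for name, (spec, target) in transitions.items():
                tr = integrate(_retarget(w_state, spec), w_ss, t_end, crm=crm,
                               rtol=rtol, atol=atol)
                end = tr.conc[-1]
                errs[name] = float(np.max(np.abs(end - target) / np.abs(target)))
        except IntegrationError as e:
            reason = f"integration_failure: {e}"
        ok = not reason and all(e <= tol for e in errs.values())
        rows.append((crm.label, *[errs.get(n, np.nan) for n in transitions],
                     ok, reason))
        if ok:
            survivors.append(crm)
    frame = pd.DataFrame(rows, columns=["crm", *[f"err_{n}" for n in transitions],
                                        "pass", "reason"])
    return survivors, frame


def _retarget(state: DerivedState, spec: TransitionSpec):
    from .dynamics import _apply_targets
    return _apply_targets(state.params, spec.targets)


def _time_arc_lengths(trace: TransitionTrace) -> np.ndarray:
    """Per-component polyline arc length of C_i(t) in (t, C) coordinates."""
    dt = np.diff(trace.abscissa)
    dc = np.diff(trace.conc, axis=0)
    return np.sqrt(dt[:, None] ** 2 + dc ** 2).sum(axis=0)


def _time_wander_err(trace: TransitionTrace) -> float:
    al = _time_arc_lengths(trace)
    span = trace.abscissa[-1] - trace.abscissa[0]
    dc = trace.conc[-1] - trace.conc[0]
    al_min = np.sqrt(span ** 2 + dc ** 2)
    return float(np.mean((al - al_min) / al_min * 100.0))


def _ss_wander_err(trace: TransitionTrace) -> float:
    dp = np.diff(trace.abscissa)
    dc = np.diff(trace.conc, axis=0)
    al = np.sqrt(dp[:, None] ** 2 + dc ** 2).sum(axis=0)
    al_min = np.sqrt((trace.abscissa[-1] - trace.abscissa[0]) ** 2
                     + (trace.conc[-1] - trace.conc[0]) ** 2)
    return float(np.mean((al - al_min) / al_min * 100.0))


def wander_scores(trace_time: TransitionTrace, trace_ss: TransitionTrace
                  ) -> tuple[float, float, tuple[float, float]]:
    """Arc lengths and wandering errors for one transition.

    Returns (mean AL_time, mean AL_ss, (Wander_Err_time, Wander_Err_ss)):
    arc length is the polyline length of each component's path — in (t, C)
    coordinates over the time window for the time mode, in (trigger
    parameter, C) coordinates over the increments for the steady-state mode
    — and the error is the percent excess over the straight endpoint-to-
    endpoint distance, averaged over the 8 components.
    """
    if trace_ss.converged is not None and not bool(trace_ss.converged.all()):
        raise ValueError("steady-state trace has non-convergent increments")
    al_t = float(np.mean(_time_arc_lengths(trace_time)))
    dp = np.diff(trace_ss.abscissa)
    dc = np.diff(trace_ss.conc, axis=0)
    al_ss = float(np.mean(np.sqrt(dp[:, None] ** 2 + dc ** 2).sum(axis=0)))
    return al_t, al_ss, (_time_wander_err(trace_time), _ss_wander_err(trace_ss))


def smoothness_score(ss_traces: list[TransitionTrace]) -> float:
    """Spike score of steady-state transitions (summed over transitions).

    For each component, 100·Σ_j |C(j) − C(j+1)|/C(j) over consecutive
    increments; zero concentrations are floored at a tiny epsilon so a spike
    out of zero is heavily (finitely) penalized.
    """
    total = 0.0
    for tr in ss_traces:
        c = tr.conc
        denom = np.maximum(c[:-1], _SM_FLOOR)
        total += float((100.0 * np.abs(np.diff(c, axis=0)) / denom).sum())
    return total


def n_sp_scores(crm: CRM, conc_table: dict[str, tuple[float, ...]]
                ) -> tuple[float, float]:
    """Sensitivity- and setpoint-reasonableness errors of a fitted CRM.

    n_Err sums |n|−1 for |n| > 1 and |1/n|−1 for |n| < 1 over the regulated
    reactions (a zero sensitivity scores infinite); SP_Err sums the relative
    deviation of each setpoint from the mean of its sensor's per-state
    concentrations.
    """
    n_err = 0.0
    sp_err = 0.0
    for rid, reg in crm.regulators.items():
        a = abs(reg.n)
        if a == 0:
            n_err = math.inf
        elif a > 1:
            n_err += a - 1
        elif a < 1:
            n_err += 1 / a - 1
        mean_sen = float(np.mean(conc_table[reg.sensor]))
        sp_err += abs(reg.setpoint - mean_sen) / mean_sen
    return n_err, sp_err


def _select_top_cluster(scores: np.ndarray) -> np.ndarray:
    """Indices of the mean-shift cluster containing the smallest score."""
    from sklearn.cluster import MeanShift, estimate_bandwidth
    X = scores.reshape(-1, 1)
    if len(scores) < 2 or np.ptp(scores) == 0:
        return np.arange(len(scores))
    bw = estimate_bandwidth(X, quantile=0.3)
    if not np.isfinite(bw) or bw <= 0:
        bw = np.ptp(scores) / 4
    labels = MeanShift(bandwidth=bw).fit(X).labels_
    best = labels[int(np.argmin(scores))]
    return np.nonzero(labels == best)[0]


def evolve(states: dict[str, DerivedState],
           state_order: tuple[str, str, str] = ("W", "Y", "D"),
           seed: int = 0, n_increments: int = 100,
           time_window: float = 5000.0, t_end: float = 50_000.0,
           targeting_tol: float = 0.01,
           rtol: float = 1e-8, atol: float = 1e-8,
           t_ss: float = 50_000.0) -> FilterReport:
    """Run the full six-filter cascade on a parameterized three-state model.

    The first state in ``state_order`` is the healthy start state; the second
    is reached by switching the locked (primary-mutation) constants and
    growth rate, the third by switching the external iron level.  Returns a
    :class:`FilterReport` with per-stage counts, all scores, and the
    surviving CRMs.  Deterministic for a fixed ``seed``.
    """
    w_lab, y_lab, d_lab = state_order
    w, y, d = states[w_lab], states[y_lab], states[d_lab]
    report = FilterReport()
    n_sensors = len(COMPONENTS)
    n_reactions = len(w.params.k)
    report.counts["enumeration"] = enumerate_count(n_reactions, n_sensors)

    regulatable = filter_uniqueness(states)
    report.regulatable = regulatable
    report.counts["uniqueness"] = enumerate_count(len(regulatable), n_sensors) \
        if regulatable else 0
    if not regulatable:
        return report

    k_table = {rid: tuple(states[lab].params.k[rid] for lab in state_order)
               for rid in regulatable}
    conc_table = {c: tuple(states[lab].profile[c] for lab in state_order)
                  for c in COMPONENTS}
    valid = filter_trending(k_table, conc_table)
    report.valid_pairs = valid
    report.counts["trending"] = trending_count(valid)
    if report.counts["trending"] == 0:
        return report

    pool, pool_frame = build_fit_pool(k_table, conc_table, valid, seed=seed)
    report.pool = pool_frame

    candidates = _candidate_crms(valid, pool)
    spec_y = TransitionSpec(kind=f"{w_lab}->{y_lab}",
                            targets={"k_isu": y.params.k["isu"],
                                     "alpha": y.params.alpha},
                            couple_alpha=True, n_increments=n_increments)
    spec_d = TransitionSpec(kind=f"{w_lab}->{d_lab}",
                            targets={"iron": d.params.iron},
                            n_increments=n_increments)
    transitions = {y_lab: (spec_y, y.profile.as_array()),
                   d_lab: (spec_d, d.profile.as_array())}
    survivors, targ_frame = filter_targeting(
        candidates, w, transitions, tol=targeting_tol, t_end=t_end,
        rtol=rtol, atol=atol)
    report.targeting = targ_frame
    report.counts["targeting"] = len(survivors)
    if not survivors:
        return report

    # ---- wandering -------------------------------------------------------
    t_grid = np.concatenate([[0.0], np.geomspace(1e-3, time_window, 400)])
    rows = []
    traces_ss: dict[str, list[TransitionTrace]] = {}
    for crm in survivors:
        w_ss = steady_state(w.params, w.profile.as_array(), crm=crm,
                            rtol=rtol, atol=atol)
        errs_t, errs_s = [], []
        ok = True
        ss_pair = []
        for name, (spec, _) in transitions.items():
            try:
                tr_t = integrate(_retarget(w, spec), w_ss, time_window,
                                 crm=crm, t_eval=t_grid, rtol=rtol, atol=atol)
                tr_s = steady_state_transition(w.params, spec, crm=crm,
                                               init=w_ss, t_ss=t_ss,
                                               rtol=rtol, atol=atol)
                _, _, (we_t, we_s) = wander_scores(tr_t, tr_s)
            except (IntegrationError, ValueError):
                ok = False
                break
            errs_t.append(we_t)
            errs_s.append(we_s)
            ss_pair.append(tr_s)
        if not ok:
            rows.append((crm.label, np.nan, np.nan, False))
            continue
        traces_ss[crm.label] = ss_pair
        rows.append((crm.label, float(np.mean(errs_t)), float(np.mean(errs_s)), True))
    wander_frame = pd.DataFrame(rows, columns=["crm", "wander_time",
                                               "wander_ss", "valid"])
    ok_frame = wander_frame[wander_frame["valid"]]
    keep = (len(ok_frame) + 1) // 2
    best_t = set(ok_frame.nsmallest(keep, "wander_time")["crm"])
    best_s = set(ok_frame.nsmallest(keep, "wander_ss")["crm"])
    inter = best_t & best_s
    report.wandering = wander_frame
    report.counts["wandering"] = len(inter)
    wander_survivors = [c for c in survivors if c.label in inter]
    if not wander_survivors:
        return report

    # ---- smoothness ------------------------------------------------------
    sm = np.array([smoothness_score(traces_ss[c.label]) for c in wander_survivors])
    top = _select_top_cluster(sm)
    report.smoothness = pd.DataFrame({
        "crm": [c.label for c in wander_survivors], "sm_err": sm,
        "selected": [i in set(top) for i in range(len(wander_survivors))]})
    final = [wander_survivors[i] for i in top]
    report.counts["smoothness"] = len(final)

    # ---- n/SP reasonableness (scored and reported) -----------------------
    nsp = [(c.label, *n_sp_scores(c, conc_table)) for c in final]
    report.n_sp = pd.DataFrame(nsp, columns=["crm", "n_err", "sp_err"])
    order = np.argsort([r[1] + r[2] for r in nsp], kind="stable")
    report.survivors = [final[i] for i in order]
    return report
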