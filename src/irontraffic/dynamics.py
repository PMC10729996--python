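"""Time integration, steady-state location, state transitions and
perturbation-recovery.

Steady states are defined operationally as the concentrations attained after
50,000 min of integration (roughly 240 doublings at the wild-type growth
rate); an algebraic root of the right-hand side serves as an independent
cross-check, not as the primary definition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import odeint
from scipy.optimize import root

from .network import (
    COMPONENTS,
    REACTION_IDS,
    CellStateParams,
    ConcentrationProfile,
    ReactionNetwork,
    ode_rhs,
    yeast_network,
)
from .regulation import CRM

__all__ = [
    "OdeSystem", "TransitionSpec", "TransitionTrace", "IntegrationError",
    "integrate", "steady_state", "root_steady_state", "alpha_of_kisu",
    "time_transition", "steady_state_transition", "perturb_recover",
    "ALPHA_KISU_ANCHORS",
]

_CIDX = {c: i for i, c in enumerate(COMPONENTS)}
_RIDX = {r: i for i, r in enumerate(REACTION_IDS)}

#: (k_isu, alpha_cell) anchors of the healthy and frataxin-deficient states
ALPHA_KISU_ANCHORS = ((6.666, 0.003333), (0.6666, 0.002))

#: operational steady-state horizon (min)
T_STEADY = 50_000.0

_REG_CLIP = 700.0  # overflow guard for logistic exponents


class IntegrationError(RuntimeError):
    def __init__(self, message: str, last_time: float | None = None):
        super().__init__(message)
        self.last_time = last_time


@dataclass
class TransitionTrace:
    """Concentrations (and effective rate constants) along a transition.

    ``abscissa`` is time in min for time-dependent runs, or the trigger
    parameter value per increment for steady-state runs.
    """

    abscissa: np.ndarray
    conc: np.ndarray                  # (n_points, 8) local μM
    kobs: np.ndarray                  # (n_points, 9) effective rate constants
    abscissa_name: str = "time_min"
    label: str = ""
    converged: np.ndarray | None = None   # per-increment flag (steady-state mode)
    reference: np.ndarray | None = None   # normalization profile (e.g. W steady state)

    def final_profile(self) -> ConcentrationProfile:
        return ConcentrationProfile.from_array(np.maximum(self.conc[-1], 0.0))

    def component(self, name: str) -> np.ndarray:
        return self.conc[:, _CIDX[name]]


@dataclass(frozen=True)
class TransitionSpec:
    """Declarative description of a cell-state transition.

    ``targets`` holds the post-trigger values, e.g. {"k_isu": 0.6666,
    "alpha": 0.002} for the disease transition or {"iron": 1.0} for iron
    starvation; {"oxygen": 25.0} gives a hypoxic shift.  When ``couple_alpha``
    is set, steady-state schedules recompute alpha from k_isu at every
    increment through the linear growth-rate map.
    """

    kind: str = "custom"
    targets: dict = field(default_factory=dict)
    n_increments: int = 100
    t_end: float = T_STEADY
    couple_alpha: bool = False

    def __post_init__(self) -> None:
        if self.n_increments < 2:
            raise ValueError("need at least 2 increments")
        if self.t_end <= 0:
            raise ValueError("t_end must be > 0")

    @classmethod
    def w_to_y(cls, k_isu_target: float = 0.6666) -> "TransitionSpec":
        return cls(kind="W->Y", targets={"k_isu": k_isu_target,
                                         "alpha": alpha_of_kisu(k_isu_target)},
                   couple_alpha=True)

    @classmethod
    def w_to_d(cls, iron_target: float = 1.0) -> "TransitionSpec":
        return cls(kind="W->D", targets={"iron": iron_target})

    @classmethod
    def hypoxia(cls, oxygen_target: float) -> "TransitionSpec":
        return cls(kind="hypoxia", targets={"oxygen": oxygen_target})


def _apply_targets(params: CellStateParams, targets: dict) -> CellStateParams:
    p = params
    k_updates = {key[2:]: v for key, v in targets.items() if key.startswith("k_")}
    if k_updates:
        p = p.with_k(**k_updates)
    plain = {key: v for key, v in targets.items() if not key.startswith("k_")}
    if plain:
        p = replace(p, **plain)
    return p


class OdeSystem:
    """Compiled right-hand side and analytic Jacobian for one parameter set.

    The bundled yeast network gets a hand-specialized fast path; other
    networks fall back to the generic rate-law dispatcher.
    """

    def __init__(self, params: CellStateParams, crm: CRM | None = None,
                 network: ReactionNetwork | None = None):
        self.params = params
        self.crm = crm
        self.network = network or yeast_network()
        self._is_yeast = network is None
        regs = []
        if crm is not None:
            for rid, reg in crm.regulators.items():
                regs.append((_RIDX[rid], reg, _CIDX[reg.sensor]))
        self._regs = regs
        k = params.k
        self._k0 = np.array([k[r] for r in REACTION_IDS])
        km = params.km
        self._km = (km["cyt"], km["mit"], km["vac"], km["cia"],
                    km["23"], km["isu"], km["res"])
        S9 = self.network.reaction_stoich()
        for j, rxn in enumerate(self.network.reactions):
            if rxn.kind == "exchange":
                S9[_CIDX[rxn.substrates[0]], j] = 1.0
        self._S9 = S9
        if self._is_yeast:
            self.rhs = self._compile_yeast_rhs()

    # ------------------------------------------------------------------
    def _phi_vec(self, y: np.ndarray) -> np.ndarray:
        if self._is_yeast:
            Kcyt, Kmit, Kvac, Kcia, K23, Kisu, Kres = self._km
            p = self.params
            FC = max(y[0], 0.0); F2 = max(y[2], 0.0); FM = max(y[4], 0.0)
            FS = max(y[5], 0.0); O2 = max(y[7], 0.0)
            sp = p.o2_setpoint
            return np.array([
                p.iron / (Kcyt + p.iron),
                FC / (Kmit + FC),
                FC / (Kvac + FC),
                FC / (Kcia + FC),
                FM / (Kisu + FM) * sp / (sp + O2),
                FM * O2,
                p.oxygen - O2,
                F2 / (K23 + F2) * p.oxygen,
                FS * O2 / (Kres + O2),
            ])
        return np.array([self.network.phi(r, y, self.params)
                         for r in self.network.reactions])

    def effective_k(self, y: np.ndarray) -> np.ndarray:
        k = self._k0.copy()
        for j, reg, sidx in self._regs:
            k[j] = reg(max(y[sidx], 0.0))
        return k

    def rates(self, y: np.ndarray) -> np.ndarray:
        return self.effective_k(y) * self._phi_vec(y)

    def rhs(self, t: float, y: np.ndarray) -> np.ndarray:
        return self._S9 @ self.rates(y) - self.params.alpha * y

    def _compile_yeast_rhs(self):
        """Scalar closure for the bundled network (hot path: the screening
        pipeline evaluates this millions of times)."""
        import math
        kcyt, kmit, kvac, kcia, kisu, kmp, ko2, k23, kres = self._k0
        Kcyt, Kmit, Kvac, Kcia, K23, Kisu, Kres = self._km
        p = self.params
        sp, alpha, ox = p.o2_setpoint, p.alpha, p.oxygen
        phi_cyt = p.iron / (Kcyt + p.iron)
        regs = tuple((j, sidx, r.n, r.setpoint, r.k_reg, r.k_unreg)
                     for j, r, sidx in self._regs)

        def rhs(t, y):
            k = [kcyt, kmit, kvac, kcia, kisu, kmp, ko2, k23, kres]
            for j, sidx, n, spnt, kreg, kunreg in regs:
                s = y[sidx]
                x = n * (spnt - (s if s > 0.0 else 0.0))
                if x > _REG_CLIP:
                    k[j] = kunreg
                elif x < -_REG_CLIP:
                    k[j] = kunreg + kreg
                else:
                    k[j] = kreg / (1.0 + math.exp(x)) + kunreg
            FC = y[0] if y[0] > 0.0 else 0.0
            F2 = y[2] if y[2] > 0.0 else 0.0
            FM = y[4] if y[4] > 0.0 else 0.0
            FS = y[5] if y[5] > 0.0 else 0.0
            O2 = y[7] if y[7] > 0.0 else 0.0
            Rcyt = k[0] * phi_cyt
            Rmit = k[1] * FC / (Kmit + FC)
            Rvac = k[2] * FC / (Kvac + FC)
            Rcia = k[3] * FC / (Kcia + FC)
            Risu = k[4] * FM / (Kisu + FM) * sp / (sp + O2)
            Rmp = k[5] * FM * O2
            Ro2 = k[6] * (ox - O2)
            R23 = k[7] * F2 / (K23 + F2) * ox
            Rres = k[8] * FS * O2 / (Kres + O2)
            return (Rcyt - Rvac - Rmit - Rcia - alpha * y[0],
                    Rcia - alpha * y[1],
                    8.0 * Rvac - R23 - alpha * y[2],
                    R23 - alpha * y[3],
                    8.0 * Rmit - Risu - Rmp - alpha * y[4],
                    Risu - alpha * y[5],
                    Rmp - alpha * y[6],
                    Ro2 - Rmp - Rres - alpha * y[7])

        return rhs

    def jac(self, t: float, y: np.ndarray) -> np.ndarray:
        k = self.effective_k(y)
        G = np.zeros((len(self.network.reactions), 8))
        if self._is_yeast:
            Kcyt, Kmit, Kvac, Kcia, K23, Kisu, Kres = self._km
            p = self.params
            FC = max(y[0], 0.0); F2 = max(y[2], 0.0); FM = max(y[4], 0.0)
            FS = max(y[5], 0.0); O2 = max(y[7], 0.0)
            sp = p.o2_setpoint
            blk = sp / (sp + O2)
            satFM = FM / (Kisu + FM)
            G[1, 0] = k[1] * Kmit / (Kmit + FC) ** 2
            G[2, 0] = k[2] * Kvac / (Kvac + FC) ** 2
            G[3, 0] = k[3] * Kcia / (Kcia + FC) ** 2
            G[4, 4] = k[4] * Kisu / (Kisu + FM) ** 2 * blk
            G[4, 7] = -k[4] * satFM * sp / (sp + O2) ** 2
            G[5, 4] = k[5] * O2
            G[5, 7] = k[5] * FM
            G[6, 7] = -k[6]
            G[7, 2] = k[7] * K23 / (K23 + F2) ** 2 * p.oxygen
            G[8, 5] = k[8] * O2 / (Kres + O2)
            G[8, 7] = k[8] * FS * Kres / (Kres + O2) ** 2
        else:
            for j, rxn in enumerate(self.network.reactions):
                for idx, g in self.network.phi_grad(rxn, y, self.params):
                    G[j, idx] = k[j] * g
        if self._regs:
            phi = self._phi_vec(y)
            for j, reg, sidx in self._regs:
                G[j, sidx] += phi[j] * reg.derivative(max(y[sidx], 0.0))
        return self._S9 @ G - self.params.alpha * np.eye(8)


def integrate(params: CellStateParams, init: ConcentrationProfile | np.ndarray,
              t_end: float, crm: CRM | None = None,
              t_eval: np.ndarray | None = None,
              network: ReactionNetwork | None = None,
              rtol: float = 1e-8, atol: float = 1e-8,
              label: str = "") -> TransitionTrace:
    """Stiff-capable integration of the dilution-augmented ODE system.

    Uses LSODA with the analytic Jacobian.  ``t_end == 0`` returns the
    initial profile unchanged.
    """
    if t_end < 0:
        raise ValueError("t_end must be >= 0")
    y0 = init.as_array() if isinstance(init, ConcentrationProfile) else np.asarray(init, float)
    sysm = OdeSystem(params, crm, network)
    if t_end == 0:
        t = np.array([0.0])
        conc = y0[None, :]
    else:
        if t_eval is not None:
            t = np.asarray(t_eval, float)
        else:
            # a handful of intermediate outputs keeps lsoda's step-size
            # heuristics healthy over very long horizons
            t = np.concatenate([[0.0], np.geomspace(max(t_end * 1e-6, 1e-9),
                                                    t_end, 17)])
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                conc, info = odeint(sysm.rhs, y0, t, Dfun=sysm.jac, tfirst=True,
                                    rtol=rtol, atol=atol, mxstep=100_000,
                                    full_output=True, printmessg=False)
            except Warning as w:
                raise IntegrationError(f"integrator failure: {w}") from None
        if not np.all(np.isfinite(conc)):
            bad = np.argmax(~np.isfinite(conc).all(axis=1))
            raise IntegrationError("non-finite state encountered",
                                   last_time=float(t[max(bad - 1, 0)]))
    kobs = np.array([sysm.effective_k(y) for y in conc])
    return TransitionTrace(abscissa=t, conc=conc, kobs=kobs, label=label)


def steady_state(params: CellStateParams, init: ConcentrationProfile | np.ndarray,
                 crm: CRM | None = None, t_ss: float = T_STEADY,
                 network: ReactionNetwork | None = None,
                 rtol: float = 1e-8, atol: float = 1e-8) -> np.ndarray:
    """Operational steady state: the t = ``t_ss`` endpoint of an integration."""
    tr = integrate(params, init, t_ss, crm=crm, network=network,
                   rtol=rtol, atol=atol)
    return tr.conc[-1]


def root_steady_state(params: CellStateParams, init: np.ndarray,
                      crm: CRM | None = None,
                      network: ReactionNetwork | None = None) -> np.ndarray:
    """Algebraic steady state: a root of the right-hand side (oracle)."""
    sysm = OdeSystem(params, crm, network)
    sol = root(lambda y: np.asarray(sysm.rhs(0.0, y)), np.asarray(init, float),
               jac=lambda y: sysm.jac(0.0, y), method="hybr", tol=1e-12)
    if not sol.success:
        raise IntegrationError(f"root finder failed: {sol.message}")
    return sol.x


def alpha_of_kisu(k_isu: float,
                  anchors: tuple[tuple[float, float], ...] = ALPHA_KISU_ANCHORS
                  ) -> float:
    """Growth rate coupled linearly to the iron-sulfur assembly constant.

    Linear interpolation through the healthy (6.666, 0.003333) and
    frataxin-deficient (0.6666, 0.002) anchor points; extrapolation outside
    the anchor interval is permitted but warned about.
    """
    (k1, a1), (k2, a2) = anchors
    lo, hi = min(k1, k2), max(k1, k2)
    if not (lo <= k_isu <= hi):
        warnings.warn(f"k_isu={k_isu} outside the anchor interval [{lo}, {hi}]; "
                      "extrapolating the growth-rate map", stacklevel=2)
    return a1 + (a2 - a1) * (k_isu - k1) / (k2 - k1)


def time_transition(start_params: CellStateParams, spec: TransitionSpec,
                    crm: CRM | None = None,
                    init: ConcentrationProfile | np.ndarray | None = None,
                    t_eval: np.ndarray | None = None,
                    network: ReactionNetwork | None = None,
                    rtol: float = 1e-8, atol: float = 1e-8) -> TransitionTrace:
    """Abrupt parameter switch at t = 0, then free evolution.

    The start state should be at its steady state; if ``init`` is omitted it
    is computed from the start parameters (with the CRM applied).
    """
    if init is None:
        guess = np.full(8, 100.0)
        init = steady_state(start_params, guess, crm=crm, network=network,
                            rtol=rtol, atol=atol)
    target_params = _apply_targets(start_params, spec.targets)
    tr = integrate(target_params, init, spec.t_end, crm=crm, t_eval=t_eval,
                   network=network, rtol=rtol, atol=atol, label=spec.kind)
    y0 = init.as_array() if isinstance(init, ConcentrationProfile) else np.asarray(init, float)
    tr.reference = y0
    return tr


def steady_state_transition(start_params: CellStateParams, spec: TransitionSpec,
                            crm: CRM | None = None,
                            init: ConcentrationProfile | np.ndarray | None = None,
                            warm_start: bool = True,
                            network: ReactionNetwork | None = None,
                            t_ss: float = T_STEADY,
                            rtol: float = 1e-8, atol: float = 1e-8,
                            ss_tol: float = 1e-4) -> TransitionTrace:
    """Sequence of steady states along a linear parameter schedule.

    The trigger parameters move linearly from their start values to the
    ``spec.targets`` over ``spec.n_increments`` points (endpoints included);
    when ``spec.couple_alpha`` is set the growth rate is recomputed from
    k_isu at every increment.  Warm-starting each increment from the previous
    endpoint is an efficiency choice; ``warm_start=False`` reproduces the
    literal cold-start protocol.

    A per-increment convergence flag compares the residual derivative with
    the dilution flux; downstream filters treat a non-convergent increment as
    a disqualifier.
    """
    n = spec.n_increments
    start_vals = {}
    for key in spec.targets:
        if key == "alpha" and spec.couple_alpha:
            continue
        start_vals[key] = (start_params.k[key[2:]] if key.startswith("k_")
                           else getattr(start_params, key))
    if init is None:
        init = steady_state(start_params, np.full(8, 100.0), crm=crm,
                            network=network, rtol=rtol, atol=atol)
    y = init.as_array() if isinstance(init, ConcentrationProfile) else np.asarray(init, float)
    y0 = y.copy()

    prim_key = next(k for k in spec.targets if not (k == "alpha" and spec.couple_alpha))
    abscissa = np.empty(n)
    conc = np.empty((n, 8))
    kobs = np.empty((n, len(REACTION_IDS)))
    converged = np.empty(n, dtype=bool)
    for i in range(n):
        frac = i / (n - 1)
        targets_i = {}
        for key, tv in spec.targets.items():
            if key == "alpha" and spec.couple_alpha:
                continue
            targets_i[key] = start_vals[key] + frac * (tv - start_vals[key])
        if spec.couple_alpha:
            targets_i["alpha"] = alpha_of_kisu(targets_i["k_isu"])
        params_i = _apply_targets(start_params, targets_i)
        start_y = y if warm_start else y0
        yi = steady_state(params_i, start_y, crm=crm, t_ss=t_ss,
                          network=network, rtol=rtol, atol=atol)
        sysm = OdeSystem(params_i, crm, network)
        resid = np.abs(sysm.rhs(0.0, yi))
        flux = params_i.alpha * np.maximum(np.abs(yi), 1.0)
        converged[i] = bool(np.all(resid <= ss_tol * flux + 10 * atol))
        abscissa[i] = targets_i[prim_key]
        conc[i] = yi
        kobs[i] = sysm.effective_k(yi)
        y = yi
    return TransitionTrace(abscissa=abscissa, conc=conc, kobs=kobs,
                           abscissa_name=prim_key, label=spec.kind,
                           converged=converged, reference=y0)


def perturb_recover(params: CellStateParams, component: str, factor: float,
                    t_perturb: float = 400.0, t_end: float = 10_000.0,
                    crm: CRM | None = None,
                    init: ConcentrationProfile | np.ndarray | None = None,
                    recovery_tol: float = 0.01, n_points: int = 801,
                    network: ReactionNetwork | None = None,
                    rtol: float = 1e-8, atol: float = 1e-8
                    ) -> tuple[TransitionTrace, float | None]:
    """Multiply one concentration at ``t_perturb`` and follow the recovery.

    Returns the trace and the recovery time: the first post-perturbation time
    at which every component is back within ``recovery_tol`` (relative) of
    the steady state, or None if it never recovers within the window.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    if init is None:
        init = steady_state(params, np.full(8, 100.0), crm=crm, network=network,
                            rtol=rtol, atol=atol)
    ss = init.as_array() if isinstance(init, ConcentrationProfile) else np.asarray(init, float)
    t_pre = np.linspace(0.0, t_perturb, max(2, int(n_points * t_perturb / t_end)))
    pre = integrate(params, ss, t_perturb, crm=crm, t_eval=t_pre,
                    network=network, rtol=rtol, atol=atol)
    y = pre.conc[-1].copy()
    y[_CIDX[component]] *= factor
    t_post = np.linspace(0.0, t_end - t_perturb, n_points)
    post = integrate(params, y, t_end - t_perturb, crm=crm, t_eval=t_post,
                     network=network, rtol=rtol, atol=atol)
    abscissa = np.concatenate([pre.abscissa, post.abscissa + t_perturb])
    conc = np.vstack([pre.conc, post.conc])
    kobs = np.vstack([pre.kobs, post.kobs])
    scale = np.maximum(np.abs(ss), 1e-12)
    rel = np.max(np.abs(post.conc - ss) / scale, axis=1)
    rec_idx = np.nonzero(rel <= recovery_tol)[0]
    recovery_time = float(post.abscissa[rec_idx[0]] + t_perturb) if rec_idx.size else None
    trace = TransitionTrace(abscissa=abscissa, conc=conc, kobs=kobs,
                            label=f"perturb {component} x{factor}", reference=ss)
    return trace, recovery_time
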