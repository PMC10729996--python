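"""Jacobian stability classification and local sensitivity analysis.

A steady state is stable to limited perturbations iff every eigenvalue of the
8x8 Jacobian has negative real part; the eigenvalues act as apparent
first-order recovery constants (min^-1).  Sensitivity of a rate constant is
the mean absolute slope, at unit scale, of the percent change of each
steady-state concentration as that constant is multiplied by a scale factor
h, estimated with a five-point central-difference stencil.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import COMPONENTS, CellStateParams, ConcentrationProfile, ReactionNetwork
from .dynamics import OdeSystem, steady_state, T_STEADY
from .regulation import CRM

__all__ = ["StabilityReport", "SensitivityReport", "jacobian",
           "finite_difference_jacobian", "eigenvalues", "sensitivity_of_k"]


@dataclass(frozen=True)
class StabilityReport:
    """Eigen-decomposition of a Jacobian with a stability verdict."""

    jacobian: np.ndarray
    eigvals: np.ndarray               # sorted by descending magnitude
    stable: bool
    dominant_components: tuple[str, ...]   # per eigenvalue, largest |entry| of its eigenvector

    @property
    def max_real_part(self) -> float:
        return float(np.max(self.eigvals.real))


@dataclass(frozen=True)
class SensitivityReport:
    """Per rate-constant sensitivity scores for one cellular state."""

    state: str
    scores: dict[str, float]          # reaction id -> mean |dG/dh| at h=1 (percent units)
    step: float
    h_range: tuple[float, float]

    def ranked(self) -> list[tuple[str, float]]:
        return sorted(self.scores.items(), key=lambda kv: kv[1], reverse=True)


def jacobian(params: CellStateParams, conc: ConcentrationProfile | np.ndarray,
             crm: CRM | None = None,
             network: ReactionNetwork | None = None,
             fm_row_o2_factor: bool = True) -> np.ndarray:
    """Analytic 8x8 Jacobian of the ODE right-hand side at a state.

    When a CRM is supplied, the chain-rule terms through the logistic valves
    (rate constants depending on sensor concentrations) are included.

    ``fm_row_o2_factor=False`` drops the O2-inhibition factor from the
    iron-sulfur assembly term of the FM row only, mimicking a published
    Jacobian-function table whose FM row omits it; the default keeps the
    Jacobian consistent with the actual dynamics (the published eigenvalue
    table matches the consistent form).
    """
    y = conc.as_array() if isinstance(conc, ConcentrationProfile) else np.asarray(conc, float)
    J = OdeSystem(params, crm, network).jac(0.0, y)
    if not fm_row_o2_factor:
        FM, O2 = max(y[4], 0.0), max(y[7], 0.0)
        K = params.km["isu"]
        sp = params.o2_setpoint
        k_isu = params.k["isu"]
        blk = sp / (sp + O2)
        J = J.copy()
        J[4, 4] -= k_isu * K / (K + FM) ** 2 * (1.0 - blk)
        J[4, 7] -= k_isu * (FM / (K + FM)) * sp / (sp + O2) ** 2
    return J


def finite_difference_jacobian(params: CellStateParams, conc: np.ndarray,
                               crm: CRM | None = None,
                               network: ReactionNetwork | None = None,
                               eps: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian (independent numerical oracle)."""
    sysm = OdeSystem(params, crm, network)
    y = np.asarray(conc, float)
    J = np.zeros((8, 8))
    for j in range(8):
        h = eps * max(abs(y[j]), 1.0)
        yp, ym = y.copy(), y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (np.asarray(sysm.rhs(0.0, yp))
                   - np.asarray(sysm.rhs(0.0, ym))) / (2 * h)
    return J


def eigenvalues(J: np.ndarray) -> StabilityReport:
    """Full spectrum of a (square) Jacobian, sorted by descending magnitude."""
    J = np.asarray(J, float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("Jacobian must be square")
    vals, vecs = np.linalg.eig(J)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    names = COMPONENTS[: J.shape[0]] if J.shape[0] <= len(COMPONENTS) else tuple(
        f"x{i}" for i in range(J.shape[0]))
    dominant = tuple(names[int(np.argmax(np.abs(vecs[:, i])))] for i in range(J.shape[0]))
    return StabilityReport(jacobian=J, eigvals=vals,
                           stable=bool(np.max(vals.real) < 0),
                           dominant_components=dominant)


def five_point_slope(g_m2, g_m1, g_p1, g_p2, j: float, strict: bool = False):
    """First derivative at the center of a five-point stencil with step j.

    Standard form: (g(-2j) − 8g(−j) + 8g(+j) − g(+2j)) / 12j.  ``strict``
    flips the sign of the last term to the as-printed variant (kept for
    comparison; it is not a consistent first-derivative stencil).
    """
    last = +1.0 if strict else -1.0
    return (g_m2 - 8.0 * g_m1 + 8.0 * g_p1 + last * g_p2) / (12.0 * j)


def _scaled_system(params: CellStateParams, crm: CRM | None, k_name: str,
                   h: float) -> tuple[CellStateParams, CRM | None]:
    """Scale one observed rate constant, including its regulated term, by h."""
    rid = k_name[2:] if k_name.startswith("k_") else k_name
    if crm is not None and rid in crm.regulators:
        from dataclasses import replace as _rep
        reg = crm.regulators[rid]
        scaled = _rep(reg, k_reg=reg.k_reg * h, k_unreg=reg.k_unreg * h)
        regs = dict(crm.regulators)
        regs[rid] = scaled
        return params, CRM(regulators=regs, modes=dict(crm.modes), label=crm.label)
    return params.with_k(**{rid: params.k[rid] * h}), crm


def sensitivity_of_k(params: CellStateParams, k_name: str,
                     crm: CRM | None = None,
                     base_profile: ConcentrationProfile | np.ndarray | None = None,
                     j: float = 0.01, h_range: tuple[float, float] = (0.5, 2.0),
                     t_ss: float = T_STEADY,
                     network: ReactionNetwork | None = None,
                     strict_stencil: bool = False,
                     strict_weighting: bool = False,
                     rtol: float = 1e-8, atol: float = 1e-8) -> float:
    """Sensitivity score of one rate constant at a steady state.

    G_i(h) is the percent change of steady-state [C_i] when the constant
    (its regulated and unregulated parts alike) is multiplied by h; the score
    is the mean over components of |dG_i/dh| at h = 1, by the five-point
    stencil with step ``j``.  ``strict_stencil`` flips the sign of the
    G(h+2j) term to the as-printed (nonstandard) form and
    ``strict_weighting`` multiplies each term by the steady-state
    concentration, both provided for comparison only.  Returns ``inf`` when
    a scaled system loses its steady state.
    """
    if base_profile is None:
        base_profile = steady_state(params, np.full(8, 100.0), crm=crm,
                                    network=network, rtol=rtol, atol=atol)
    y0 = (base_profile.as_array() if isinstance(base_profile, ConcentrationProfile)
          else np.asarray(base_profile, float))

    def G(h: float) -> np.ndarray:
        p, c = _scaled_system(params, crm, k_name, h)
        try:
            y = steady_state(p, y0, crm=c, t_ss=t_ss, network=network,
                             rtol=rtol, atol=atol)
        except Exception:
            return np.full(8, np.nan)
        return 100.0 * (y - y0) / np.maximum(np.abs(y0), 1e-300)

    g_m2, g_m1, g_p1, g_p2 = G(1 - 2 * j), G(1 - j), G(1 + j), G(1 + 2 * j)
    last_sign = +1.0 if strict_stencil else -1.0
    deriv = (g_m2 - 8 * g_m1 + 8 * g_p1 + last_sign * g_p2) / (12 * j)
    if strict_weighting:
        deriv = deriv * y0
    if not np.all(np.isfinite(deriv)):
        return float("inf")
    return float(np.mean(np.abs(deriv)))
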