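"""Soft-Heaviside (logistic) regulation of rate constants.

Each regulated rate constant is split into a constitutive part k_unreg and an
inducible part k_reg gated by a logistic valve driven by the concentration of
a sensor component:

    k_obs([Sen]) = k_reg / (1 + exp(n([SP] − [Sen]))) + k_unreg

[SP] is the setpoint (the sensor concentration at which the inducible part is
half open) and n the signed sensitivity: n > 0 opens the valve as the sensor
rises (feedforward trend), n < 0 closes it (feedback trend).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .network import COMPONENTS, CellStateParams

__all__ = ["HeavisideRegulator", "CRM", "regulated_k", "fit_regulator",
           "apply_crm", "FitFailure"]

_SP_MAX = 10000.0
_EXP_CLIP = 700.0


class FitFailure(RuntimeError):
    """No converged fit was found for a candidate regulator."""


class DegenerateFitError(FitFailure):
    """The three rate constants are identical; the reaction is unregulatable."""


@dataclass(frozen=True)
class HeavisideRegulator:
    """One logistic regulatory valve."""

    sensor: str
    n: float
    setpoint: float
    k_reg: float
    k_unreg: float = 0.0
    residual: float = 0.0   # RMS relative misfit of the defining points

    def __post_init__(self) -> None:
        if self.sensor not in COMPONENTS:
            raise ValueError(f"sensor must be a model component, got {self.sensor!r}")
        if not (0.0 < self.setpoint <= _SP_MAX):
            raise ValueError(f"setpoint must lie in (0, {_SP_MAX}]")
        if self.k_reg < 0 or self.k_unreg < 0:
            raise ValueError("k_reg and k_unreg must be >= 0")

    def __call__(self, sen_conc: float) -> float:
        return regulated_k(self, sen_conc)

    def derivative(self, sen_conc: float) -> float:
        """d k_obs / d [Sen], overflow-safe (saturates to 0)."""
        x = self.n * (self.setpoint - sen_conc)
        if abs(x) > _EXP_CLIP:
            return 0.0
        L = 1.0 / (1.0 + math.exp(x))
        return self.k_reg * self.n * L * (1.0 - L)


def regulated_k(reg: HeavisideRegulator, sen_conc: float) -> float:
    """Evaluate the logistic valve at a sensor concentration.

    Saturates (to k_unreg or k_unreg + k_reg) when the exponent magnitude
    exceeds the overflow guard instead of raising.
    """
    if sen_conc < 0:
        sen_conc = 0.0
    x = reg.n * (reg.setpoint - sen_conc)
    if x > _EXP_CLIP:
        return reg.k_unreg
    if x < -_EXP_CLIP:
        return reg.k_unreg + reg.k_reg
    return reg.k_reg / (1.0 + math.exp(x)) + reg.k_unreg


@dataclass(frozen=True)
class CRM:
    """A cellular regulatory mechanism: one valve per regulated reaction.

    ``regulators`` maps reaction ids (e.g. "cyt", "23") to their valves;
    ``modes`` records the feedback/feedforward label assigned by the trending
    rule (not re-inferred from the sign of n).
    """

    regulators: dict[str, HeavisideRegulator]
    modes: dict[str, str] = field(default_factory=dict)
    label: str = ""

    def __post_init__(self) -> None:
        for rid, reg in self.regulators.items():
            if reg.sensor not in COMPONENTS:
                raise ValueError(f"reaction {rid}: sensor {reg.sensor} not in model")

    def sensors(self) -> dict[str, str]:
        return {rid: reg.sensor for rid, reg in self.regulators.items()}

    def effective_k(self, conc: np.ndarray) -> dict[str, float]:
        cidx = {c: i for i, c in enumerate(COMPONENTS)}
        return {rid: regulated_k(reg, conc[cidx[reg.sensor]])
                for rid, reg in self.regulators.items()}

    def effective_params(self, base: CellStateParams, conc: np.ndarray) -> CellStateParams:
        return apply_crm(self, base, conc)


def apply_crm(crm: CRM, base: CellStateParams,
              conc: np.ndarray | "ConcentrationProfile") -> CellStateParams:
    """Replace regulated rate constants with their valve outputs at the
    current sensor concentrations; unregulated reactions are untouched."""
    arr = conc if isinstance(conc, np.ndarray) else conc.as_array()
    if not crm.regulators:
        return base
    return base.with_k(**crm.effective_k(arr))


def _linear_sub_solve(x: np.ndarray, y: np.ndarray, n: float, sp: float
                      ) -> tuple[float, float]:
    """Given (n, SP), solve the inner linear least squares for (k_reg, k_unreg)."""
    z = np.clip(n * (sp - x), -_EXP_CLIP, _EXP_CLIP)
    L = 1.0 / (1.0 + np.exp(z))
    A = np.column_stack([L, np.ones_like(L)])
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return max(sol[0], 0.0), max(sol[1], 0.0)


def fit_regulator(points: list[tuple[float, float]], sensor: str = "FC",
                  seed: int = 0, n_random_starts: int = 4,
                  rel_tol: float = 1e-6) -> HeavisideRegulator:
    """Fit a logistic valve to ([Sen], k_obs) pairs by multi-start least squares.

    With four parameters and three data points the fit is generically exact
    but non-unique; the selection is deterministic: the converged start with
    the smallest residual wins, ties broken by smallest |n| and then by
    setpoint closest to the mean sensor concentration.  The setpoint is
    constrained to (0, 10000] and the constants to be nonnegative.

    Raises ``DegenerateFitError`` when all k values coincide (nothing to
    regulate) and ``FitFailure`` when no start converges.
    """
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if len(points) < 3 or len(set(x.tolist())) < len(x):
        raise ValueError("need at least three distinct sensor concentrations")
    if np.allclose(y, y[0], rtol=1e-12, atol=0.0):
        raise DegenerateFitError("identical rate constants: reaction is unregulatable")

    scale = max(np.abs(y).max(), 1e-300)
    span = x.max() - x.min()
    mean_sen = float(x.mean())

    def residual(theta: np.ndarray) -> np.ndarray:
        n, sp, kreg, kunreg = theta
        z = np.clip(n * (sp - x), -_EXP_CLIP, _EXP_CLIP)
        return (kreg / (1.0 + np.exp(z)) + kunreg - y) / scale

    n_grid = [s * m / span for s in (+1, -1) for m in (0.5, 2.0, 10.0, 50.0)]
    sp_grid = [x.min(), mean_sen, x.max(),
               max(x.min() / 2, 1e-3), min(x.max() * 2, _SP_MAX)]
    starts = list(itertools.product(n_grid, sp_grid))
    rng = np.random.RandomState(seed)
    for _ in range(n_random_starts):
        starts.append((float(rng.uniform(-1, 1)) * 50.0 / span,
                       float(rng.uniform(x.min() / 2, min(x.max() * 2, _SP_MAX)))))

    lb = [-np.inf, 1e-9, 0.0, 0.0]
    ub = [np.inf, _SP_MAX, np.inf, np.inf]
    candidates = []
    for n0, sp0 in starts:
        kreg0, kunreg0 = _linear_sub_solve(x, y, n0, sp0)
        if kreg0 <= 0:
            kreg0 = max(y.max() - y.min(), scale * 1e-3)
        try:
            sol = least_squares(residual, [n0, sp0, kreg0, kunreg0],
                                bounds=(lb, ub), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400)
        except Exception:
            continue
        if not np.all(np.isfinite(sol.x)):
            continue
        res = float(np.sqrt(2.0 * sol.cost))
        candidates.append((res, abs(sol.x[0]), abs(sol.x[1] - mean_sen), sol.x))
    if not candidates:
        raise FitFailure("no converged fit among the start grid")
    best_res = min(c[0] for c in candidates)
    tol = max(best_res * (1.0 + 1e-9), rel_tol * 1e-3)
    tied = [c for c in candidates if c[0] <= tol]
    tied.sort(key=lambda c: (c[1], c[2]))
    res, _, _, theta = tied[0]
    n, sp, kreg, kunreg = (float(v) for v in theta)
    return HeavisideRegulator(sensor=sensor, n=n, setpoint=sp, k_reg=kreg,
                              k_unreg=kunreg, residual=res)
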