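"""Derive a full kinetic parameterization of a cellular state from its
steady-state concentrations.

At steady state the stoichiometric matrix S (8 x 17, over the 9 reaction
rates and 8 dilution pseudo-rates) satisfies S·R = 0.  Exact rational
reduction to reduced row-echelon form splits the rate vector into 8 pivot
(dependent) and 9 free (independent) rates; for the bundled network the
independent rates are the respiration rate R_res and the 8 dilution rates
D_i = α_cell·[C_i].  Once the independent rates are fixed by measured
concentrations and the growth rate, every dependent rate follows from the
null-space relations, and inverting each rate law at the measured
concentrations yields the rate constants.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
import sympy

from .network import (
    COMPONENTS,
    REACTION_IDS,
    CellStateParams,
    ConcentrationProfile,
    ReactionNetwork,
    stoichiometric_matrix,
    yeast_network,
)

__all__ = [
    "StoichiometricSystem",
    "RateVector",
    "rref_decompose",
    "dilution_rates",
    "dependent_rates",
    "invert_rate_laws",
    "build_cell_state",
    "DerivedState",
]

#: default Michaelis constants (μM): the W-state substrate concentration,
#: except K_cyt(IRON) which was adjusted from 40 to 10 to avoid instability.
DEFAULT_KM = {"cyt": 10.0, "mit": 20.0, "vac": 20.0, "cia": 20.0,
              "23": 200.0, "isu": 100.0, "res": 1.0}

RATE_NAMES = tuple(f"R_{r}" for r in REACTION_IDS) + tuple(f"D_{c}" for c in COMPONENTS)


class RankDeficiencyError(ValueError):
    """The stoichiometric matrix does not have full row rank."""


class RateInversionError(ValueError):
    """A rate law cannot be inverted (zero shape factor with nonzero rate)."""


@dataclass(frozen=True)
class StoichiometricSystem:
    """Exact RREF decomposition of a stoichiometric matrix.

    ``relations`` maps each dependent (pivot) rate column to the rational
    coefficients of the independent (free) rate columns such that
    R_dep = Σ coeff · R_free on the null space.
    """

    S: np.ndarray
    rref: np.ndarray
    pivot_cols: tuple[int, ...]
    free_cols: tuple[int, ...]
    relations: dict[int, dict[int, Fraction]]
    names: tuple[str, ...] = RATE_NAMES

    @property
    def null_space_dim(self) -> int:
        return len(self.free_cols)

    def dependent_names(self) -> tuple[str, ...]:
        return tuple(self.names[j] for j in self.pivot_cols)

    def independent_names(self) -> tuple[str, ...]:
        return tuple(self.names[j] for j in self.free_cols)


@dataclass(frozen=True)
class RateVector:
    """The 9 reaction rates plus 8 dilution rates (μM/min, local convention)."""

    values: dict[str, float]

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_array(self, names: tuple[str, ...] = RATE_NAMES) -> np.ndarray:
        return np.array([self.values[n] for n in names])

    def as_series(self) -> pd.Series:
        return pd.Series(self.values)


def rref_decompose(S: np.ndarray | None = None,
                   names: tuple[str, ...] = RATE_NAMES) -> StoichiometricSystem:
    """Exact rational RREF of a stoichiometric matrix.

    Uses exact rational arithmetic so that pivot classification cannot be
    corrupted by floating-point noise.  Raises ``RankDeficiencyError`` if the
    matrix has dependent rows (rank < number of components).
    """
    arr = stoichiometric_matrix() if S is None else np.asarray(S, dtype=float)
    M = sympy.Matrix([[sympy.nsimplify(x, rational=True) for x in row] for row in arr])
    rref, pivots = M.rref()
    if len(pivots) < arr.shape[0]:
        dep_rows = [i for i in range(arr.shape[0]) if i >= len(pivots)]
        raise RankDeficiencyError(
            f"matrix has rank {len(pivots)} < {arr.shape[0]} rows; "
            f"redundant rows near indices {dep_rows}")
    free = tuple(j for j in range(arr.shape[1]) if j not in pivots)
    relations: dict[int, dict[int, Fraction]] = {}
    for row, p in enumerate(pivots):
        coeffs = {}
        for j in free:
            c = rref[row, j]
            if c != 0:
                coeffs[j] = Fraction(int(sympy.fraction(c)[0]), int(sympy.fraction(c)[1])) * -1
        relations[p] = coeffs
    return StoichiometricSystem(
        S=arr, rref=np.array(rref.tolist(), dtype=float),
        pivot_cols=tuple(int(p) for p in pivots), free_cols=free,
        relations=relations, names=tuple(names[: arr.shape[1]]) if len(names) >= arr.shape[1]
        else tuple(f"col{j}" for j in range(arr.shape[1])))


def dilution_rates(conc: ConcentrationProfile, alpha: float) -> dict[str, float]:
    """D_i = α_cell·[C_i] for every component (μM/min)."""
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    return {f"D_{c}": alpha * conc[c] for c in COMPONENTS}


def dependent_rates(independent: dict[str, float],
                    system: StoichiometricSystem | None = None) -> RateVector:
    """Fill the dependent rates from the null-space relations.

    ``independent`` maps independent rate names (R_res and the D_i for the
    bundled model) to values; returns the complete rate vector.
    """
    sys_ = system or rref_decompose()
    name_to_col = {n: j for j, n in enumerate(sys_.names)}
    values = dict(independent)
    free_vals = {}
    for n in sys_.independent_names():
        if n not in independent:
            raise KeyError(f"missing independent rate {n}")
        free_vals[name_to_col[n]] = independent[n]
    for p, coeffs in sys_.relations.items():
        values[sys_.names[p]] = float(sum(float(c) * free_vals[j] for j, c in coeffs.items()))
    return RateVector(values=values)


def invert_rate_laws(rates: RateVector, conc: ConcentrationProfile,
                     params_template: CellStateParams,
                     network: ReactionNetwork | None = None) -> dict[str, float]:
    """Solve each rate-law expression for its rate constant.

    Every rate law is linear in its rate constant, rate = k·phi([C]), so
    k = rate/phi.  A zero rate gives a zero constant; a zero shape factor
    with a nonzero rate is not invertible.
    """
    net = network or yeast_network()
    arr = conc.as_array()
    k = {}
    for rxn in net.reactions:
        rate = rates[f"R_{rxn.rid}"]
        phi = net.phi(rxn, arr, params_template)
        if rate == 0.0:
            k[rxn.rid] = 0.0
        elif phi == 0.0:
            raise RateInversionError(
                f"reaction {rxn.rid}: zero substrate with nonzero rate {rate}")
        else:
            k[rxn.rid] = rate / phi
    return k


@dataclass(frozen=True)
class DerivedState:
    """Result of parameterizing one cellular state."""

    params: CellStateParams
    profile: ConcentrationProfile   # possibly with back-solved [O2]
    rates: RateVector

    def to_frame(self) -> pd.DataFrame:
        """Flat table of rates, rate constants and K_m values."""
        rows = {}
        for rid in REACTION_IDS:
            rows[f"R_{rid}"] = self.rates[f"R_{rid}"]
        for c in COMPONENTS:
            rows[f"D_{c}"] = self.rates[f"D_{c}"]
        for rid in REACTION_IDS:
            rows[f"k_{rid}"] = self.params.k[rid]
        for rid, v in self.params.km.items():
            rows[f"K_{rid}"] = v
        rows["O2_sp"] = self.params.o2_setpoint
        rows["alpha_cell"] = self.params.alpha
        return pd.DataFrame({"value": rows})


def build_cell_state(conc: ConcentrationProfile, alpha: float, iron: float,
                     oxygen: float, r_res: float,
                     km: dict[str, float] | None = None,
                     o2_setpoint: float = 1.0,
                     label: str = "custom",
                     tie_k_res: float | None = None,
                     system: StoichiometricSystem | None = None,
                     network: ReactionNetwork | None = None) -> DerivedState:
    """Compose dilution -> null-space -> rate-law inversion into a full state.

    ``r_res`` is the one independent rate not fixed by concentrations (the
    respiration rate, μM/min).  If ``tie_k_res`` is given (the respiration
    rate constant of a reference state), the mitochondrial [O2] of this state
    is back-solved from r_res = k_res·[FS][O2]/(K_res+[O2]) instead of taken
    from the profile; this enforces a state-independent respiration constant,
    matching how non-reference states are parameterized.
    """
    if r_res <= 0:
        raise ValueError("r_res must be > 0")
    km = dict(km or DEFAULT_KM)
    if tie_k_res is not None:
        denom = tie_k_res * conc.FS - r_res
        if denom <= 0:
            raise RateInversionError(
                "cannot back-solve [O2]: k_res·[FS] must exceed R_res")
        o2 = r_res * km["res"] / denom
        conc = ConcentrationProfile.from_dict({**conc.as_dict(), "O2": o2})
    D = dilution_rates(conc, alpha)
    rates = dependent_rates({**D, "R_res": r_res}, system=system)
    template = CellStateParams(
        k={r: 1.0 for r in REACTION_IDS}, km=km, o2_setpoint=o2_setpoint,
        alpha=alpha, iron=iron, oxygen=oxygen, label=label)
    k = invert_rate_laws(rates, conc, template, network=network)
    params = CellStateParams(k=k, km=km, o2_setpoint=o2_setpoint,
                             alpha=alpha, iron=iron, oxygen=oxygen, label=label)
    return DerivedState(params=params, profile=conc, rates=rates)
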