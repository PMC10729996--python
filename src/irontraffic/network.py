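"""Reaction network, rate laws, and the dilution-augmented ODE right-hand side.

The bundled model describes iron trafficking in an exponentially growing yeast
cell: nutrient IRON enters the cytosol as a labile Fe(II) pool (FC) which is
distributed into mitochondria (FM), vacuoles (F2/F3) and cytosolic/nuclear
iron proteins (CIA).  Mitochondrial iron is either assembled into iron-sulfur
clusters and hemes (FS) or, in the presence of O2, precipitates as ferric
phosphate nanoparticles (MP).  Every component is diluted at the exponential
growth rate of the cell.

Concentrations are *local* to their compartment (μM); interregional reactions
carry a fractional-volume factor so that mass is conserved when material moves
between compartments of different size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "COMPONENTS",
    "REACTION_IDS",
    "CompartmentLayout",
    "ConcentrationProfile",
    "CellStateParams",
    "Reaction",
    "ReactionNetwork",
    "yeast_network",
    "reaction_rate",
    "ode_rhs",
    "stoichiometric_matrix",
]

#: ordering of the 8 model components (rows of the stoichiometric matrix)
COMPONENTS = ("FC", "CIA", "F2", "F3", "FM", "FS", "MP", "O2")

#: ordering of the 9 reactions (first 9 columns of the stoichiometric matrix)
REACTION_IDS = ("cyt", "mit", "vac", "cia", "isu", "mp", "O2", "23", "res")

_CIDX = {c: i for i, c in enumerate(COMPONENTS)}
_RIDX = {r: i for i, r in enumerate(REACTION_IDS)}


class UnknownReactionError(KeyError):
    """Raised when a reaction id is not part of the network."""


@dataclass(frozen=True)
class CompartmentLayout:
    """Fractional volumes of the three cellular regions.

    Fractions are dimensionless parts of the total cell volume and must sum
    to one.  The defaults are the yeast values: cytosol 0.8, mitochondria 0.1,
    vacuole 0.1, giving interregional factors f_cyt/f_mit = f_cyt/f_vac = 8.
    """

    f_cyt: float = 0.8
    f_mit: float = 0.1
    f_vac: float = 0.1

    def __post_init__(self) -> None:
        for name in ("f_cyt", "f_mit", "f_vac"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if abs(self.f_cyt + self.f_mit + self.f_vac - 1.0) > 1e-12:
            raise ValueError("fractional volumes must sum to 1 within 1e-12")

    def fraction(self, region: str) -> float:
        return {"C": self.f_cyt, "M": self.f_mit, "V": self.f_vac, "E": 1.0}[region]


@dataclass(frozen=True)
class ConcentrationProfile:
    """Local concentrations (μM) of the 8 components."""

    FC: float
    CIA: float
    F2: float
    F3: float
    FM: float
    FS: float
    MP: float
    O2: float

    def __post_init__(self) -> None:
        for c in COMPONENTS:
            v = getattr(self, c)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"concentration of {c} must be finite and >= 0")

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "ConcentrationProfile":
        return cls(**dict(zip(COMPONENTS, (float(x) for x in arr))))

    @classmethod
    def from_dict(cls, d: Mapping[str, float]) -> "ConcentrationProfile":
        return cls(**{c: float(d[c]) for c in COMPONENTS})

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, c) for c in COMPONENTS], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in COMPONENTS}

    def __getitem__(self, comp: str) -> float:
        return getattr(self, comp)

    def fe_cell(self, layout: CompartmentLayout | None = None) -> float:
        """Whole-cell iron concentration (μM of cell volume).

        [Fe_cell] = f_cyt([CIA]+[FC]) + f_vac([F2]+[F3]) + f_mit([FM]+[FS]+[MP]).
        O2 is not iron and does not contribute.
        """
        lay = layout or CompartmentLayout()
        return (
            lay.f_cyt * (self.CIA + self.FC)
            + lay.f_vac * (self.F2 + self.F3)
            + lay.f_mit * (self.FM + self.FS + self.MP)
        )


@dataclass(frozen=True)
class CellStateParams:
    """Full kinetic parameterization of one cellular state.

    ``k`` maps reaction id -> rate constant (units set by the rate law),
    ``km`` maps reaction id -> Michaelis constant in μM (only for saturating
    rate laws).  ``o2_setpoint`` is the O2 inhibition setpoint of the
    iron-sulfur assembly reaction, ``alpha`` the exponential growth rate in
    min^-1, and ``iron``/``oxygen`` the external nutrient levels in μM.
    """

    k: Mapping[str, float]
    km: Mapping[str, float]
    o2_setpoint: float = 1.0
    alpha: float = 0.003333
    iron: float = 40.0
    oxygen: float = 100.0
    label: str = "custom"

    def __post_init__(self) -> None:
        object.__setattr__(self, "k", dict(self.k))
        object.__setattr__(self, "km", dict(self.km))
        for rid, v in self.k.items():
            if v < 0:
                raise ValueError(f"rate constant k_{rid} must be >= 0")
        for rid, v in self.km.items():
            if v < 0:
                raise ValueError(f"K_m of reaction {rid} must be >= 0")
        if self.o2_setpoint <= 0:
            raise ValueError("[O2]_sp must be > 0")
        for name in ("alpha", "iron", "oxygen"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def with_k(self, **updates: float) -> "CellStateParams":
        """Copy with some rate constants replaced (keys are reaction ids)."""
        k = dict(self.k)
        k.update(updates)
        return replace(self, k=k)

    def external(self, name: str) -> float:
        return {"IRON": self.iron, "OXYGEN": self.oxygen}[name]


@dataclass(frozen=True)
class Reaction:
    """One reaction with its rate-law kind.

    kinds:
      sat_external   k·X/(K+X)           X = external nutrient
      sat            k·[S]/(K+[S])
      sat_o2_block   k·[S]/(K+[S])·sp/(sp+[O2])
      mass_action_2  k·[S1][S2]
      exchange       k·(X − [S])         signed; X = external nutrient
      sat_catalyzed  k·[CAT][S]/(K+[S])
      sat_x_external k·[S]/(K+[S])·X
    """

    rid: str
    kind: str
    substrates: tuple[str, ...] = ()   # model components consumed (coeff −1)
    products: tuple[str, ...] = ()     # model components produced
    catalyst: str | None = None
    external: str | None = None
    region_from: str = "C"
    region_to: str = "C"

    def __post_init__(self) -> None:
        for c in self.substrates + self.products + ((self.catalyst,) if self.catalyst else ()):
            if c not in _CIDX:
                raise ValueError(f"reaction {self.rid}: unknown component {c}")


@dataclass(frozen=True)
class ReactionNetwork:
    """An ordered reaction list plus the compartment layout."""

    reactions: tuple[Reaction, ...]
    layout: CompartmentLayout = field(default_factory=CompartmentLayout)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.rid for r in self.reactions)

    def reaction(self, rid: str) -> Reaction:
        for r in self.reactions:
            if r.rid == rid:
                return r
        raise UnknownReactionError(f"unknown reaction id: {rid!r}")

    # -- rate laws -----------------------------------------------------
    def phi(self, rxn: Reaction, conc: np.ndarray, params: CellStateParams) -> float:
        """Rate-law shape factor: rate = k_obs · phi.

        Concentrations are clipped at zero so that transient tiny negatives
        produced by the integrator cannot generate negative rates.
        """
        def C(name: str) -> float:
            return max(conc[_CIDX[name]], 0.0)

        kind = rxn.kind
        if kind == "sat_external":
            x = params.external(rxn.external)
            return x / (params.km[rxn.rid] + x)
        if kind == "sat":
            s = C(rxn.substrates[0])
            return s / (params.km[rxn.rid] + s)
        if kind == "sat_o2_block":
            s = C(rxn.substrates[0])
            sp = params.o2_setpoint
            return s / (params.km[rxn.rid] + s) * sp / (sp + C("O2"))
        if kind == "mass_action_2":
            s1, s2 = rxn.substrates
            return C(s1) * C(s2)
        if kind == "exchange":
            # signed: net flux may be out of the cell
            return params.external(rxn.external) - max(conc[_CIDX[rxn.substrates[0]]], 0.0)
        if kind == "sat_catalyzed":
            s = C(rxn.substrates[0])
            return C(rxn.catalyst) * s / (params.km[rxn.rid] + s)
        if kind == "sat_x_external":
            s = C(rxn.substrates[0])
            return s / (params.km[rxn.rid] + s) * params.external(rxn.external)
        raise ValueError(f"unknown rate-law kind {kind!r}")

    def phi_grad(self, rxn: Reaction, conc: np.ndarray, params: CellStateParams
                 ) -> list[tuple[int, float]]:
        """Sparse gradient of phi w.r.t. the component vector."""
        def C(name: str) -> float:
            return max(conc[_CIDX[name]], 0.0)

        kind = rxn.kind
        if kind == "sat_external":
            return []
        if kind == "sat":
            s = C(rxn.substrates[0])
            K = params.km[rxn.rid]
            return [(_CIDX[rxn.substrates[0]], K / (K + s) ** 2)]
        if kind == "sat_o2_block":
            s = C(rxn.substrates[0])
            K = params.km[rxn.rid]
            sp = params.o2_setpoint
            o2 = C("O2")
            blk = sp / (sp + o2)
            return [
                (_CIDX[rxn.substrates[0]], K / (K + s) ** 2 * blk),
                (_CIDX["O2"], -s / (K + s) * sp / (sp + o2) ** 2),
            ]
        if kind == "mass_action_2":
            s1, s2 = rxn.substrates
            return [(_CIDX[s1], C(s2)), (_CIDX[s2], C(s1))]
        if kind == "exchange":
            return [(_CIDX[rxn.substrates[0]], -1.0)]
        if kind == "sat_catalyzed":
            s = C(rxn.substrates[0])
            K = params.km[rxn.rid]
            cat = C(rxn.catalyst)
            return [
                (_CIDX[rxn.catalyst], s / (K + s)),
                (_CIDX[rxn.substrates[0]], cat * K / (K + s) ** 2),
            ]
        if kind == "sat_x_external":
            s = C(rxn.substrates[0])
            K = params.km[rxn.rid]
            return [(_CIDX[rxn.substrates[0]],
                     K / (K + s) ** 2 * params.external(rxn.external))]
        raise ValueError(f"unknown rate-law kind {kind!r}")

    # -- stoichiometry -------------------------------------------------
    def reaction_stoich(self) -> np.ndarray:
        """8 x n_reactions stoichiometric block (no dilution columns).

        Products moving into a smaller compartment carry the interregional
        factor f_from/f_to (= 8 for cytosol -> mitochondria/vacuole).
        """
        S = np.zeros((len(COMPONENTS), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for s in rxn.substrates:
                S[_CIDX[s], j] -= 1.0
            factor = self.layout.fraction(rxn.region_from) / self.layout.fraction(rxn.region_to)
            if rxn.region_from == "E":
                factor = 1.0
            for p in rxn.products:
                S[_CIDX[p], j] += factor
        return S


def yeast_network() -> ReactionNetwork:
    """The bundled 9-reaction, 8-component yeast iron-trafficking network."""
    return ReactionNetwork(reactions=(
        Reaction("cyt", "sat_external", external="IRON", products=("FC",),
                 region_from="E", region_to="C"),
        Reaction("mit", "sat", substrates=("FC",), products=("FM",),
                 region_from="C", region_to="M"),
        Reaction("vac", "sat", substrates=("FC",), products=("F2",),
                 region_from="C", region_to="V"),
        Reaction("cia", "sat", substrates=("FC",), products=("CIA",),
                 region_from="C", region_to="C"),
        Reaction("isu", "sat_o2_block", substrates=("FM",), products=("FS",),
                 region_from="M", region_to="M"),
        Reaction("mp", "mass_action_2", substrates=("FM", "O2"), products=("MP",),
                 region_from="M", region_to="M"),
        Reaction("O2", "exchange", substrates=("O2",), products=("O2",),
                 external="OXYGEN", region_from="E", region_to="M"),
        Reaction("23", "sat_x_external", substrates=("F2",), products=("F3",),
                 external="OXYGEN", region_from="V", region_to="V"),
        Reaction("res", "sat_catalyzed", substrates=("O2",), catalyst="FS",
                 region_from="M", region_to="M"),
    ))


def _o2_exchange_stoich(S: np.ndarray, network: ReactionNetwork) -> np.ndarray:
    # the exchange reaction already nets substrate and product on one row
    for j, rxn in enumerate(network.reactions):
        if rxn.kind == "exchange":
            S[_CIDX[rxn.substrates[0]], j] = 1.0  # d[O2]/dt gets +R_O2 (signed rate)
    return S


def stoichiometric_matrix(network: ReactionNetwork | None = None) -> np.ndarray:
    """The 8 x 17 stoichiometric matrix over [R_cyt..R_res, D_FC..D_O2].

    Reaction columns follow the network's reaction order; the trailing 8
    columns are the dilution pseudo-rates, −1 on the diagonal.
    """
    net = network or yeast_network()
    S = _o2_exchange_stoich(net.reaction_stoich(), net)
    D = -np.eye(len(COMPONENTS))
    return np.hstack([S, D])


def reaction_rate(reaction_id: str, conc: ConcentrationProfile,
                  params: CellStateParams,
                  network: ReactionNetwork | None = None) -> float:
    """Evaluate one rate-law expression (μM/min, local to the source region).

    All rates are nonnegative except the O2 exchange rate, which is signed
    (net efflux when mitochondrial [O2] exceeds the external level).
    """
    net = network or yeast_network()
    rxn = net.reaction(reaction_id)
    arr = conc.as_array()  # profile construction enforces nonnegativity
    return params.k[reaction_id] * net.phi(rxn, arr, params)


def ode_rhs(conc: ConcentrationProfile | np.ndarray, params: CellStateParams,
            regulators=None, network: ReactionNetwork | None = None) -> np.ndarray:
    """d[C_i]/dt (μM/min) including the −α_cell[C_i] dilution on every component.

    If ``regulators`` (a CRM) is supplied, the effective rate constants are
    recomputed from the current sensor concentrations before rate evaluation.
    """
    net = network or yeast_network()
    arr = conc.as_array() if isinstance(conc, ConcentrationProfile) else np.asarray(conc, float)
    p = params if regulators is None else regulators.effective_params(params, arr)
    S = _o2_exchange_stoich(net.reaction_stoich(), net)
    rates = np.array([p.k[r.rid] * net.phi(r, arr, p) for r in net.reactions])
    return S @ rates - p.alpha * arr
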