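"""Bundled model fixtures, structured-text model files, and trace writers."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .network import (
    COMPONENTS,
    REACTION_IDS,
    CompartmentLayout,
    ConcentrationProfile,
    Reaction,
    ReactionNetwork,
    yeast_network,
)
from .parameterize import DerivedState, build_cell_state
from .regulation import CRM, HeavisideRegulator
from .dynamics import TransitionTrace

__all__ = ["ModelBundle", "BundleValidationError", "load_bundle", "save_bundle",
           "write_trace", "read_trace"]

_DEFAULT_RESOURCE = "yeast.yaml"


class BundleValidationError(ValueError):
    """A model file violates the schema or a bundle invariant."""

    def __init__(self, path: str, message: str):
        super().__init__(f"{path}: {message}")
        self.field_path = path


@dataclass
class ModelBundle:
    """A reaction network plus named cellular states and regulatory cases."""

    network: ReactionNetwork
    states: dict[str, DerivedState]
    crms: dict[str, CRM]
    predictions: dict[str, dict]
    reference_table: pd.DataFrame | None
    config: dict
    checksum: str
    reference_state: str = "W"

    def state(self, label: str) -> DerivedState:
        try:
            return self.states[label]
        except KeyError:
            raise KeyError(f"unknown state {label!r}; have {sorted(self.states)}") from None

    def crm(self, label: str) -> CRM:
        try:
            return self.crms[label]
        except KeyError:
            raise KeyError(f"unknown CRM {label!r}; have {sorted(self.crms)}") from None

    def validate(self, rel_tol: float = 1e-4, print_quantum: float = 5.1e-7
                 ) -> pd.DataFrame:
        """Re-derive every published rate and rate constant and compare.

        Returns a tidy frame of (state, quantity, derived, reference,
        rel_error, ok); raises ``BundleValidationError`` if any entry is off
        by more than ``rel_tol`` relative.  Reference values are printed to
        six decimals, so agreement to within half a printing quantum is also
        accepted (matters only for the smallest entries).
        """
        if self.reference_table is None:
            raise BundleValidationError("reference_table", "no reference values bundled")
        rows = []
        for label in self.reference_table.columns:
            derived = self.states[label].to_frame()["value"]
            for name, ref in self.reference_table[label].dropna().items():
                key = name.replace("k_", "k_")
                got = _lookup_quantity(derived, name)
                rel = abs(got - ref) / max(abs(ref), 1e-300)
                ok = rel <= rel_tol or abs(got - ref) <= print_quantum
                rows.append((label, name, got, float(ref), rel, ok))
        frame = pd.DataFrame(rows, columns=["state", "quantity", "derived",
                                            "reference", "rel_error", "ok"])
        bad = frame[~frame["ok"]]
        if len(bad):
            worst = bad.iloc[bad["rel_error"].argmax()]
            raise BundleValidationError(
                f"states.{worst.state}", f"derived {worst.quantity}={worst.derived:.6f} "
                f"differs from reference {worst.reference:.6f} "
                f"(rel {worst.rel_error:.2e} > {rel_tol})")
        return frame


def _lookup_quantity(derived: pd.Series, name: str) -> float:
    if name in derived.index:
        return float(derived[name])
    raise BundleValidationError("reference_table", f"unknown quantity {name}")


_RATE_LAW_KINDS = {"sat_external", "sat", "sat_o2_block", "mass_action_2",
                   "exchange", "sat_catalyzed", "sat_x_external"}


def _network_from_config(cfg: dict) -> ReactionNetwork:
    comp = cfg.get("compartments", {})
    try:
        layout = CompartmentLayout(**{k: float(v) for k, v in comp.items()}) \
            if comp else CompartmentLayout()
    except ValueError as e:
        raise BundleValidationError("compartments", str(e)) from None
    if "reactions" not in cfg:
        return ReactionNetwork(reactions=yeast_network().reactions, layout=layout)
    reactions = []
    for i, r in enumerate(cfg["reactions"]):
        if r.get("kind") not in _RATE_LAW_KINDS:
            raise BundleValidationError(f"reactions[{i}].kind",
                                        f"unknown rate-law kind {r.get('kind')!r}")
        reactions.append(Reaction(
            rid=str(r["id"]), kind=r["kind"],
            substrates=tuple(r.get("substrates", ())),
            products=tuple(r.get("products", ())),
            catalyst=r.get("catalyst"), external=r.get("external"),
            region_from=r.get("region_from", "C"), region_to=r.get("region_to", "C")))
    return ReactionNetwork(reactions=tuple(reactions), layout=layout)


def _crm_from_config(name: str, cfg: dict) -> CRM:
    regs, modes = {}, {}
    for rid, rc in cfg.items():
        try:
            regs[str(rid)] = HeavisideRegulator(
                sensor=rc["sensor"], n=float(rc["n"]), setpoint=float(rc["setpoint"]),
                k_reg=float(rc["k_reg"]), k_unreg=float(rc.get("k_unreg", 0.0)))
        except (KeyError, ValueError) as e:
            raise BundleValidationError(f"crms.{name}.{rid}", str(e)) from None
        modes[str(rid)] = rc.get("mode", "")
    return CRM(regulators=regs, modes=modes, label=name)


def load_bundle(path: str | Path | None = None) -> ModelBundle:
    """Load a model bundle from a structured-text model file.

    With no path, loads the packaged yeast fixture.  States are fully
    parameterized on load (null-space derivation + rate-law inversion), the
    respiration constant being tied across states to the reference state's
    value, with [O2] back-solved for states flagged ``derive_o2``.
    """
    if path is None:
        raw = resources.files("irontraffic").joinpath(
            "data", _DEFAULT_RESOURCE).read_bytes()
        src = f"builtin:{_DEFAULT_RESOURCE}"
    else:
        raw = Path(path).read_bytes()
        src = str(path)
    checksum = hashlib.sha256(raw).hexdigest()
    try:
        cfg = yaml.safe_load(raw)
    except yaml.YAMLError as e:
        raise BundleValidationError(src, f"not parseable YAML: {e}") from None
    if not isinstance(cfg, dict) or "states" not in cfg:
        raise BundleValidationError("states", "model file must define a states mapping")

    network = _network_from_config(cfg)
    km = {str(k): float(v) for k, v in cfg.get("km", {}).items()}
    o2_sp = float(cfg.get("o2_setpoint", 1.0))
    ref_label = cfg.get("reference_state")

    states: dict[str, DerivedState] = {}
    order = list(cfg["states"])
    if ref_label in order:
        order.remove(ref_label)
        order.insert(0, ref_label)
    k_res_ref = None
    for label in order:
        sc = cfg["states"][label]
        try:
            conc = ConcentrationProfile.from_dict(sc["concentrations"])
        except (KeyError, ValueError, TypeError) as e:
            raise BundleValidationError(f"states.{label}.concentrations", str(e)) from None
        tie = k_res_ref if sc.get("derive_o2") else None
        states[label] = build_cell_state(
            conc, alpha=float(sc["alpha"]), iron=float(sc["iron"]),
            oxygen=float(sc["oxygen"]), r_res=float(sc["r_res"]),
            km=km or None, o2_setpoint=o2_sp, label=str(label),
            tie_k_res=tie, network=network)
        if label == ref_label or k_res_ref is None:
            k_res_ref = states[label].params.k.get("res", k_res_ref)

    crms = {str(n): _crm_from_config(str(n), c) for n, c in cfg.get("crms", {}).items()}
    ref_tab = None
    if "reference_table" in cfg:
        ref_tab = pd.DataFrame({lab: pd.Series({k: float(v) for k, v in col.items()})
                                for lab, col in cfg["reference_table"].items()})
    return ModelBundle(network=network, states=states, crms=crms,
                       predictions=dict(cfg.get("predictions", {})),
                       reference_table=ref_tab, config=cfg, checksum=checksum,
                       reference_state=ref_label or order[0])


def save_bundle(bundle: ModelBundle, path: str | Path) -> Path:
    """Write a bundle's model file back out (round-trips through load)."""
    path = Path(path)
    path.write_text(yaml.safe_dump(bundle.config, sort_keys=False))
    return path


def write_trace(trace: TransitionTrace, path: str | Path,
                manifest: dict | None = None) -> Path:
    """Write a trace as CSV plus a JSON sidecar manifest.

    Columns: abscissa, the 8 local concentrations, the 9 effective rate
    constants.  The sidecar (<path>.manifest.json) records the run metadata
    passed in ``manifest`` plus the trace label; output is bit-stable for
    identical inputs.
    """
    path = Path(path)
    cols = {trace.abscissa_name: trace.abscissa}
    for i, c in enumerate(COMPONENTS):
        cols[c] = trace.conc[:, i]
    for i, r in enumerate(REACTION_IDS):
        cols[f"k_{r}"] = trace.kobs[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    meta = {"label": trace.label, "abscissa": trace.abscissa_name,
            "n_points": int(len(trace.abscissa)),
            "components": list(COMPONENTS), "reactions": list(REACTION_IDS)}
    if trace.converged is not None:
        meta["all_increments_converged"] = bool(trace.converged.all())
    if manifest:
        meta.update(manifest)
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True, default=str))
    return path


def read_trace(path: str | Path) -> TransitionTrace:
    """Reload a CSV trace written by :func:`write_trace`."""
    df = pd.read_csv(path)
    abscissa_name = df.columns[0]
    return TransitionTrace(
        abscissa=df[abscissa_name].to_numpy(),
        conc=df[list(COMPONENTS)].to_numpy(),
        kobs=df[[f"k_{r}" for r in REACTION_IDS]].to_numpy(),
        abscissa_name=abscissa_name)


def default_manifest(params=None, seed: int | None = None, **extra) -> dict:
    """Standard manifest fields: parameters, seed, tolerances, timestamp."""
    m: dict = {"rtol": 1e-8, "atol": 1e-8}
    if params is not None:
        m["params"] = {"label": params.label, "alpha_cell": params.alpha,
                       "iron": params.iron, "oxygen": params.oxygen,
                       "k": dict(params.k), "km": dict(params.km),
                       "o2_setpoint": params.o2_setpoint}
    if seed is not None:
        m["seed"] = int(seed)
    m.update(extra)
    return m
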