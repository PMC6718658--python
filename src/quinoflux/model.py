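"""Metabolic network data structures and structural edits.

The in-memory containers mirror the usual constraint-based layout: a
:class:`MetabolicModel` holds metabolites, reactions (stoichiometry,
flux bounds in mmol/gDW/hr, GPR), a gene list, and the id of the biomass
reaction that serves as the growth objective.  Reversibility is encoded
purely through bounds; exchange reactions are single-metabolite
reactions on external-compartment species, with uptake as negative flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np
from scipy import sparse

from .gpr import GprExpression, parse_gpr

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicModel",
    "ConditionSpec",
    "ModelValidationError",
    "DEFAULT_BOUND",
    "build_stoichiometric_matrix",
    "add_sink_reaction",
    "remove_reaction",
    "apply_condition",
    "carbon_balance_report",
]

#: conventional "effectively unbounded" flux box, mmol/gDW/hr
DEFAULT_BOUND = 1000.0

EXTERNAL_COMPARTMENTS = ("e", "external", "extracellular")


class ModelValidationError(ValueError):
    """A structural invariant of the model is violated."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("metabolite id must be non-empty")
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id}: empty compartment")

    @property
    def is_external(self) -> bool:
        return self.compartment in EXTERNAL_COMPARTMENTS

    def carbon_count(self) -> Optional[int]:
        """Number of carbon atoms parsed from ``formula``; None if unknown."""
        if not self.formula:
            return None
        import re

        m = re.search(r"C(\d*)(?![a-z])", self.formula)
        if m is None:
            return 0
        return int(m.group(1)) if m.group(1) else 1


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    lower_bound: float = 0.0
    upper_bound: float = DEFAULT_BOUND
    gpr: GprExpression = field(default_factory=GprExpression)
    name: str = ""
    subsystem: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ModelValidationError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id}: empty stoichiometry")
        for met, coef in self.stoichiometry.items():
            if not math.isfinite(coef) or coef == 0:
                raise ModelValidationError(
                    f"reaction {self.id}: coefficient for {met} must be finite and nonzero"
                )
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0

    def with_bounds(self, lb: float, ub: float) -> "Reaction":
        return replace(self, lower_bound=lb, upper_bound=ub)


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model.

    Invariants (checked by :meth:`validate`): unique ids; every
    stoichiometry key names a declared metabolite; the biomass reaction
    exists; the gene list equals the union of GPR leaves.
    """

    metabolites: list
    reactions: list
    biomass_reaction_id: str
    genes: list = field(default_factory=list)
    id: str = "model"

    def __post_init__(self):
        self.validate()

    # -- lookups ---------------------------------------------------------
    @property
    def metabolite_ids(self) -> list:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except (AttributeError, KeyError):
            self._met_index = {m.id: m for m in self.metabolites}
            return self._met_index[met_id]

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}")

    def has_reaction(self, rxn_id: str) -> bool:
        return any(r.id == rxn_id for r in self.reactions)

    def is_exchange(self, rxn_id: str) -> bool:
        """A reaction is an exchange when it touches exactly one metabolite
        and that metabolite is external (``metabolite_e <-> ∅``)."""
        rxn = self.reaction(rxn_id)
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return self.metabolite(met_id).is_external

    def is_sink(self, rxn_id: str) -> bool:
        """A sink drains a single internal metabolite (``metabolite -> ∅``)."""
        rxn = self.reaction(rxn_id)
        if len(rxn.stoichiometry) != 1:
            return False
        (met_id,) = rxn.stoichiometry
        return not self.metabolite(met_id).is_external

    @property
    def exchange_reaction_ids(self) -> list:
        return [r.id for r in self.reactions if self.is_exchange(r.id)]

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dup = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dup}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dup = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dup}")
        met_set = set(met_ids)
        for r in self.reactions:
            for met_id in r.stoichiometry:
                if met_id not in met_set:
                    raise ModelValidationError(
                        f"reaction {r.id} references undeclared metabolite {met_id!r}"
                    )
        if self.biomass_reaction_id not in set(rxn_ids):
            raise ModelValidationError(
                f"biomass reaction {self.biomass_reaction_id!r} not in model"
            )
        gpr_genes = set()
        for r in self.reactions:
            gpr_genes |= r.gpr.genes()
        if set(self.genes) != gpr_genes:
            missing = gpr_genes - set(self.genes)
            extra = set(self.genes) - gpr_genes
            raise ModelValidationError(
                f"gene list out of sync with GPR leaves "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )
        self._met_index = {m.id: m for m in self.metabolites}

    # -- copies / edits --------------------------------------------------
    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            metabolites=list(self.metabolites),
            reactions=list(self.reactions),
            biomass_reaction_id=self.biomass_reaction_id,
            genes=list(self.genes),
            id=self.id,
        )

    def with_reaction_bounds(self, rxn_id: str, lb: float, ub: float) -> "MetabolicModel":
        new = self.copy()
        new.reactions = [
            r.with_bounds(lb, ub) if r.id == rxn_id else r for r in new.reactions
        ]
        # bounds edits cannot break structural invariants; skip revalidation
        return new


@dataclass(frozen=True)
class ConditionSpec:
    """Environmental condition: exchange-bound overrides plus O2/light flags.

    ``uptake_caps`` maps exchange reaction ids to positive uptake
    magnitudes (translated to a negative lower bound internally);
    ``overrides`` gives raw (lb, ub) pairs for full control.
    """

    name: str
    uptake_caps: Mapping[str, float] = field(default_factory=dict)
    overrides: Mapping[str, Tuple[float, float]] = field(default_factory=dict)
    aerobic: bool = False
    light: bool = True
    o2_exchange: str = "EX_o2"
    photon_exchange: str = "EX_photon"


def build_stoichiometric_matrix(model: MetabolicModel) -> sparse.csr_matrix:
    """S with one row per metabolite and one column per reaction.

    Entry (i, j) is reaction j's signed coefficient for metabolite i
    (reactants negative).  Row/column order follows the model's
    metabolite and reaction lists.
    """
    met_pos = {m.id: i for i, m in enumerate(model.metabolites)}
    rows, cols, data = [], [], []
    for j, rxn in enumerate(model.reactions):
        for met_id, coef in rxn.stoichiometry.items():
            rows.append(met_pos[met_id])
            cols.append(j)
            data.append(float(coef))
    return sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


def add_sink_reaction(
    model: MetabolicModel,
    metabolite_id: str,
    rate: float,
    mode: str = "fixed",
) -> MetabolicModel:
    """Add a sink reaction ``metabolite -> ∅`` with id ``SK_<metabolite_id>``.

    ``mode="fixed"`` pins the flux to ``rate`` (lb = ub = rate), treating
    the sink as a known rate; ``mode="max"`` sets bounds (0, rate),
    treating it as the capacity of an uncharacterised consuming process.

    Raises on negative rate, unknown metabolite, or a duplicate sink id.
    """
    if rate < 0:
        raise ValueError(f"sink rate must be non-negative, got {rate}")
    if mode not in ("fixed", "max"):
        raise ValueError(f"sink mode must be 'fixed' or 'max', got {mode!r}")
    model.metabolite(metabolite_id)  # KeyError if absent
    sink_id = f"SK_{metabolite_id}"
    if model.has_reaction(sink_id):
        raise ValueError(f"model already contains sink {sink_id}")
    lb, ub = (rate, rate) if mode == "fixed" else (0.0, rate)
    sink = Reaction(
        id=sink_id,
        name=f"{metabolite_id} sink",
        stoichiometry={metabolite_id: -1.0},
        lower_bound=lb,
        upper_bound=ub,
    )
    new = model.copy()
    new.reactions = new.reactions + [sink]
    new.validate()
    return new


def remove_reaction(model: MetabolicModel, rxn_id: str) -> MetabolicModel:
    """Return a model without ``rxn_id`` (e.g. to retract a sink)."""
    if not model.has_reaction(rxn_id):
        raise KeyError(f"no reaction {rxn_id!r} to remove")
    new = model.copy()
    new.reactions = [r for r in new.reactions if r.id != rxn_id]
    new.validate()
    return new


def apply_condition(model: MetabolicModel, spec: ConditionSpec) -> MetabolicModel:
    """Apply an environmental condition to the exchange bounds.

    Uptake caps are positive magnitudes: a cap of 100 on EX_ac yields
    bounds (-100, DEFAULT_BOUND).  The aerobic flag opens/closes the O2
    exchange, the light flag the photon exchange.  Overrides on
    non-exchange reactions are rejected.
    """
    new = model.copy()
    for rxn_id in list(spec.uptake_caps) + list(spec.overrides):
        if not new.has_reaction(rxn_id):
            raise ModelValidationError(f"condition {spec.name!r}: no reaction {rxn_id!r}")
        if not new.is_exchange(rxn_id):
            raise ModelValidationError(
                f"condition {spec.name!r}: {rxn_id} is not an exchange reaction"
            )

    def set_bounds(rxn_id: str, lb: float, ub: float) -> None:
        new.reactions = [
            r.with_bounds(lb, ub) if r.id == rxn_id else r for r in new.reactions
        ]

    # close all carbon-source style uptakes first?  No: only touch what the
    # spec names, so conditions compose predictably with model defaults.
    for rxn_id, cap in spec.uptake_caps.items():
        if cap < 0:
            raise ValueError(f"uptake cap for {rxn_id} must be a positive magnitude")
        ub = new.reaction(rxn_id).upper_bound
        set_bounds(rxn_id, -cap, ub)
    for rxn_id, (lb, ub) in spec.overrides.items():
        set_bounds(rxn_id, lb, ub)
    if new.has_reaction(spec.o2_exchange) and spec.o2_exchange not in spec.overrides:
        set_bounds(
            spec.o2_exchange,
            -DEFAULT_BOUND if spec.aerobic else 0.0,
            DEFAULT_BOUND,
        )
    if new.has_reaction(spec.photon_exchange) and spec.photon_exchange not in spec.overrides:
        set_bounds(
            spec.photon_exchange,
            -DEFAULT_BOUND if spec.light else 0.0,
            0.0,
        )
    return new


def carbon_balance_report(model: MetabolicModel) -> Dict[str, float]:
    """Net carbon created per internal reaction, where formulas allow.

    Exchanges and sinks are skipped (they move carbon across the system
    boundary by design).  Reactions involving any metabolite without a
    formula are skipped.  A nonzero entry flags a carbon-conservation
    violation; the report is informational, not fatal.
    """
    report: Dict[str, float] = {}
    for rxn in model.reactions:
        if (
            model.is_exchange(rxn.id)
            or model.is_sink(rxn.id)
            or rxn.id == model.biomass_reaction_id
        ):
            continue
        total = 0.0
        known = True
        for met_id, coef in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            if met.formula is None:
                known = False
                break
            total += coef * (met.carbon_count() or 0)
        if known and abs(total) > 1e-9:
            report[rxn.id] = total
    return report


def reaction_from_equation(
    rxn_id: str,
    equation: str,
    lb: float = None,
    ub: float = None,
    gpr: str = "",
    name: str = "",
    subsystem: Optional[str] = None,
) -> Reaction:
    """Build a Reaction from text like ``"2 A + B -> C"`` or ``"A <-> B"``.

    ``->`` marks an irreversible reaction (default bounds [0, 1000]),
    ``<->`` a reversible one (default bounds [-1000, 1000]).  Explicit
    lb/ub win over the arrow default.  Either side may be empty for
    boundary reactions (``"A ->"``).
    """
    if "<->" in equation:
        left, right = equation.split("<->")
        default_lb = -DEFAULT_BOUND
    elif "->" in equation:
        left, right = equation.split("->")
        default_lb = 0.0
    else:
        raise ValueError(f"equation for {rxn_id} lacks '->' or '<->': {equation!r}")
    stoich: Dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if not parts:
                raise ValueError(f"empty term in equation for {rxn_id}: {equation!r}")
            if len(parts) == 1:
                coef, met = 1.0, parts[0]
            elif len(parts) == 2:
                coef, met = float(parts[0]), parts[1]
            else:
                raise ValueError(f"cannot parse term {term!r} in {rxn_id}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    return Reaction(
        id=rxn_id,
        name=name or rxn_id,
        stoichiometry=stoich,
        lower_bound=default_lb if lb is None else lb,
        upper_bound=DEFAULT_BOUND if ub is None else ub,
        gpr=parse_gpr(gpr),
        subsystem=subsystem,
    )


def equation_to_string(model: MetabolicModel, rxn: Reaction) -> str:
    """Inverse of :func:`reaction_from_equation` (used by the TSV writer)."""
    def side(items):
        terms = []
        for met, coef in items:
            coef = abs(coef)
            terms.append(met if coef == 1 else f"{coef:.12g} {met}")
        return " + ".join(terms)

    lhs = [(m, c) for m, c in rxn.stoichiometry.items() if c < 0]
    rhs = [(m, c) for m, c in rxn.stoichiometry.items() if c > 0]
    arrow = "<->" if rxn.reversible else "->"
    return f"{side(lhs)} {arrow} {side(rhs)}".strip()
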