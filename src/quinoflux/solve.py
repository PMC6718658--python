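"""FBA, parsimonious FBA via objective tilting, and flux variability.

The growth problem is the standard LP

    maximize  v_biomass
    s.t.      S v = 0,  LB <= v <= UB

Parsimonious FBA folds the flux-minimising secondary objective into a
single tilted objective,

    maximize  v_biomass - w * sum_{j != biomass} |v_j|,   w = 1e-4,

which is linearised by splitting every reversible reaction into two
irreversible halves, so the penalty is the total absolute (L1) flux.
The tiny tilt weight trades at most w * (total flux) of growth for
parsimony; both the recovered growth and the tilted optimum are
reported so that degradation is visible.

Reactions are ordered lexicographically by id before the LP is built,
so ties between degenerate optima resolve reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MetabolicModel, build_stoichiometric_matrix

__all__ = ["SolverConfig", "FluxSolution", "solve_fba", "solve_pfba", "flux_variability"]


@dataclass(frozen=True)
class SolverConfig:
    """Numerical settings for the LP layer.

    tilt_weight is the coefficient on the summed absolute flux in the
    parsimonious objective (dimensionless); lp_tolerance is both the
    solver tolerance and the mass-balance acceptance threshold.
    """

    tilt_weight: float = 1e-4
    lp_tolerance: float = 1e-9
    backend: str = "highs"

    def __post_init__(self):
        if self.tilt_weight <= 0:
            raise ValueError("tilt_weight must be positive")
        if self.lp_tolerance <= 0:
            raise ValueError("lp_tolerance must be positive")


@dataclass
class FluxSolution:
    """Result of one LP solve.

    ``objective_value`` is the biomass flux (growth, in the model's own
    biomass units); ``tilted_objective_value`` is the parsimonious
    objective when applicable.  ``fluxes`` is empty unless optimal.
    """

    status: str  # optimal | infeasible | unbounded
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)
    tilted_objective_value: Optional[float] = None

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def total_flux(self, exclude: Tuple[str, ...] = ()) -> float:
        return sum(abs(v) for k, v in self.fluxes.items() if k not in exclude)


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _ordered(model: MetabolicModel):
    order = sorted(range(len(model.reactions)), key=lambda j: model.reactions[j].id)
    rxns = [model.reactions[j] for j in order]
    S = build_stoichiometric_matrix(model)[:, order]
    return rxns, S.tocsc()


def _run_lp(c, S, b, bounds, config: SolverConfig):
    res = linprog(
        c,
        A_eq=S,
        b_eq=b,
        bounds=bounds,
        method=config.backend,
        options={"presolve": True},
    )
    return res


def solve_fba(model: MetabolicModel, config: SolverConfig = SolverConfig()) -> FluxSolution:
    """Maximise biomass flux subject to mass balance and bounds.

    The optimum value is unique; the returned flux vector is one of the
    possibly-many optimal vertices (use pFBA for a parsimonious one).
    """
    rxns, S = _ordered(model)
    n = len(rxns)
    c = np.zeros(n)
    bio = [j for j, r in enumerate(rxns) if r.id == model.biomass_reaction_id][0]
    c[bio] = -1.0  # linprog minimises
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    res = _run_lp(c, S, np.zeros(S.shape[0]), bounds, config)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=0.0)
    fluxes = {r.id: float(v) for r, v in zip(rxns, res.x)}
    return FluxSolution(status="optimal", objective_value=float(res.x[bio]), fluxes=fluxes)


def solve_pfba(model: MetabolicModel, config: SolverConfig = SolverConfig()) -> FluxSolution:
    """Parsimonious FBA with a single tilted objective.

    Every reversible reaction is split into forward and backward
    irreversible halves so the tilt penalises total absolute flux; the
    biomass reaction is excluded from the penalty.  Reported fluxes are
    recombined (forward minus backward).
    """
    rxns, S = _ordered(model)
    n = len(rxns)
    bio = [j for j, r in enumerate(rxns) if r.id == model.biomass_reaction_id][0]

    cols = []
    bounds = []
    c = []
    col_map = []  # (reaction index, sign)
    for j, r in enumerate(rxns):
        lb, ub = r.lower_bound, r.upper_bound
        w = 0.0 if j == bio else config.tilt_weight
        if lb >= 0:
            cols.append(S[:, j])
            bounds.append((lb, ub))
            c.append(-1.0 + w if j == bio else w)
            col_map.append((j, +1.0))
        elif ub <= 0:
            # purely backward reaction: substitute v = -u, u >= 0
            cols.append(-S[:, j])
            bounds.append((-ub, -lb))
            c.append(w)
            col_map.append((j, -1.0))
        else:
            cols.append(S[:, j])
            bounds.append((0.0, ub))
            c.append(-1.0 + w if j == bio else w)
            col_map.append((j, +1.0))
            cols.append(-S[:, j])
            bounds.append((0.0, -lb))
            c.append(w)
            col_map.append((j, -1.0))
    A = sparse.hstack(cols, format="csc")
    c = np.array(c)
    # biomass penalty exclusion: biomass column got weight 0 via w, but the
    # "-1.0 + w" expression above must not re-add it
    res = _run_lp(c, A, np.zeros(A.shape[0]), bounds, config)
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FluxSolution(status=status, objective_value=0.0)
    v = np.zeros(n)
    for x, (j, sign) in zip(res.x, col_map):
        v[j] += sign * x
    fluxes = {r.id: float(val) for r, val in zip(rxns, v)}
    tilted = -float(res.fun)
    return FluxSolution(
        status="optimal",
        objective_value=float(v[bio]),
        fluxes=fluxes,
        tilted_objective_value=tilted,
    )


def flux_variability(
    model: MetabolicModel,
    fraction_of_optimum: float = 1.0,
    config: SolverConfig = SolverConfig(),
    reactions: Optional[list] = None,
) -> Dict[str, Tuple[float, float]]:
    """Per-reaction flux ranges at a growth fraction of the FBA optimum."""
    if not (0 < fraction_of_optimum <= 1):
        raise ValueError("fraction_of_optimum must be in (0, 1]")
    base = solve_fba(model, config)
    if not base.ok:
        raise RuntimeError(f"FVA base problem is {base.status}")
    rxns, S = _ordered(model)
    n = len(rxns)
    bio = [j for j, r in enumerate(rxns) if r.id == model.biomass_reaction_id][0]
    bounds = [(r.lower_bound, r.upper_bound) for r in rxns]
    # pin growth at >= fraction * optimum via the biomass lower bound
    floor = fraction_of_optimum * base.objective_value
    lb, ub = bounds[bio]
    bounds[bio] = (max(lb, floor), ub)
    wanted = set(reactions) if reactions is not None else None
    out: Dict[str, Tuple[float, float]] = {}
    for j, r in enumerate(rxns):
        if wanted is not None and r.id not in wanted:
            continue
        c = np.zeros(n)
        c[j] = 1.0
        lo = _run_lp(c, S, np.zeros(S.shape[0]), bounds, config)
        c[j] = -1.0
        hi = _run_lp(c, S, np.zeros(S.shape[0]), bounds, config)
        if lo.status != 0 or hi.status != 0:
            raise RuntimeError(f"FVA subproblem for {r.id} failed")
        out[r.id] = (float(lo.fun), float(-hi.fun))
    return out


def check_mass_balance(
    model: MetabolicModel, solution: FluxSolution, config: SolverConfig = SolverConfig()
) -> float:
    """Max |S v| over metabolites for a solved flux vector (diagnostic)."""
    S = build_stoichiometric_matrix(model)
    v = np.array([solution.fluxes[r.id] for r in model.reactions])
    return float(np.max(np.abs(S @ v))) if len(v) else 0.0
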