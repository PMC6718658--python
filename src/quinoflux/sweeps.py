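"""Parameter sweeps over quinol oxidation and light uptake, plus the
CO2 accounting that summarises each condition.

Two sweep experiments probe how the quinone redox state couples light
harvesting, growth and CO2 fixation:

* :func:`quinol_sink_sweep` varies the quinol sink.  ``mode="fixed"``
  forces the sink flux to each rate (the sink as a known oxidation
  rate); ``mode="max"`` caps it (the sink as the capacity of an
  uncharacterised quinol oxidase, which parsimonious FBA leaves unused
  when quinol oxidation brings no benefit — the relevant reading for
  an oxidised substrate such as fumarate).
* :func:`light_uptake_sweep` varies the photon uptake bound at a fixed
  quinol oxidation rate, exposing the low-light energy-limited and
  high-light carbon-limited growth regions.

"Light uptake rate" is operationalised as the photon exchange flux and
the electron transport rate (ETR) as the flux through the photochemical
reaction centre; the condition tables report ETR divided by 10
(dmol/gDW/hr) to match the conventional table layout, flagged in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import pandas as pd

from .model import (
    ConditionSpec,
    MetabolicModel,
    add_sink_reaction,
    apply_condition,
)
from .solve import FluxSolution, SolverConfig, solve_pfba

__all__ = [
    "SweepRecord",
    "SweepResult",
    "Co2Report",
    "quinol_sink_sweep",
    "light_uptake_sweep",
    "co2_accounting",
    "condition_report",
]


@dataclass(frozen=True)
class SweepRecord:
    parameter_value: float
    status: str
    growth: float = float("nan")
    photon_uptake: float = float("nan")
    etr: float = float("nan")
    carbon_uptake: float = float("nan")
    co2_fixation: float = float("nan")
    co2_net_exchange: float = float("nan")


@dataclass
class SweepResult:
    parameter: str  # swept parameter name
    units: str
    condition: str
    records: List[SweepRecord] = field(default_factory=list)
    solutions: Dict[float, FluxSolution] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.records])

    @property
    def feasible(self) -> List[SweepRecord]:
        return [r for r in self.records if r.status == "optimal"]


@dataclass
class Co2Report:
    """Gross CO2 bookkeeping for one optimal solution.

    ``total_produced`` sums positive stoichiometric CO2 production over
    all metabolic reactions (gross, per actual flux direction);
    transport and exchange of CO2 across the boundary are excluded.
    ``percent_fixed`` = fixation / total produced, undefined (flag
    False) when CO2 is taken up from the medium.  Net exchange is
    positive for excretion.
    """

    fixation: float
    total_produced: float
    net_exchange: float
    percent_fixed: Optional[float]
    defined: bool


def _extract_record(
    model: MetabolicModel,
    sol: FluxSolution,
    value: float,
    carbon_exchange: str,
    photon_exchange: str = "EX_photon",
    rc_reaction: str = "RC",
    carboxylase: str = "CBB",
    co2_exchange: str = "EX_co2",
) -> SweepRecord:
    if not sol.ok:
        return SweepRecord(parameter_value=value, status=sol.status)
    fx = sol.fluxes
    report = co2_accounting(model, sol, carboxylase=carboxylase, co2_exchange=co2_exchange)
    return SweepRecord(
        parameter_value=value,
        status="optimal",
        growth=sol.objective_value,
        photon_uptake=-fx.get(photon_exchange, 0.0),
        etr=fx.get(rc_reaction, 0.0),
        carbon_uptake=-fx.get(carbon_exchange, 0.0),
        co2_fixation=report.fixation,
        co2_net_exchange=report.net_exchange,
    )


def quinol_sink_sweep(
    model: MetabolicModel,
    condition: ConditionSpec,
    rates: Sequence[float],
    config: SolverConfig = SolverConfig(),
    mode: str = "fixed",
    sink_metabolite: str = "qh2",
    keep_solutions: bool = False,
) -> SweepResult:
    """pFBA across a grid of quinol sink rates (see module docstring)."""
    rates = list(rates)
    if any(r < 0 for r in rates):
        raise ValueError("sink rates must be non-negative")
    if sorted(rates) != rates:
        raise ValueError("sink rates must be sorted ascending")
    conditioned = apply_condition(model, condition)
    carbon_exchange = next(iter(condition.uptake_caps))
    result = SweepResult(
        parameter=f"quinol sink rate ({mode})",
        units="mmol/gDW/hr",
        condition=condition.name,
    )
    for rate in rates:
        with_sink = add_sink_reaction(conditioned, sink_metabolite, rate, mode=mode)
        sol = solve_pfba(with_sink, config)
        result.records.append(_extract_record(with_sink, sol, rate, carbon_exchange))
        if keep_solutions and sol.ok:
            result.solutions[rate] = sol
    return result


def light_uptake_sweep(
    model: MetabolicModel,
    condition: ConditionSpec,
    photon_rates: Sequence[float],
    sink_rate: float,
    config: SolverConfig = SolverConfig(),
    sink_metabolite: str = "qh2",
    photon_exchange: str = "EX_photon",
    keep_solutions: bool = False,
) -> SweepResult:
    """pFBA across photon uptake bounds at a fixed quinol sink rate."""
    photon_rates = list(photon_rates)
    if any(r < 0 for r in photon_rates):
        raise ValueError("photon rates must be non-negative")
    if sorted(photon_rates) != photon_rates:
        raise ValueError("photon rates must be sorted ascending")
    conditioned = apply_condition(model, condition)
    conditioned = add_sink_reaction(conditioned, sink_metabolite, sink_rate, mode="fixed")
    carbon_exchange = next(iter(condition.uptake_caps))
    result = SweepResult(
        parameter="photon uptake bound",
        units="mmol/gDW/hr",
        condition=condition.name,
    )
    for rate in photon_rates:
        capped = conditioned.with_reaction_bounds(photon_exchange, -rate, 0.0)
        sol = solve_pfba(capped, config)
        result.records.append(_extract_record(capped, sol, rate, carbon_exchange))
        if keep_solutions and sol.ok:
            result.solutions[rate] = sol
    return result


def co2_accounting(
    model: MetabolicModel,
    solution: FluxSolution,
    co2_metabolites: Sequence[str] = ("co2",),
    co2_exchange: str = "EX_co2",
    carboxylase: str = "CBB",
    tol: float = 1e-9,
) -> Co2Report:
    """CO2 fixation vs gross production for an optimal solution."""
    if not solution.ok:
        raise ValueError("CO2 accounting requires an optimal solution")
    co2_set = set(co2_metabolites)
    produced = 0.0
    for rxn in model.reactions:
        touches_boundary = any(
            model.metabolite(m).is_external for m in rxn.stoichiometry
        )
        if touches_boundary:
            continue  # transport/exchange moves CO2, it does not make it
        v = solution.fluxes.get(rxn.id, 0.0)
        for met, coef in rxn.stoichiometry.items():
            if met in co2_set and coef * v > tol:
                produced += coef * v
    fixation = 0.0
    if model.has_reaction(carboxylase):
        rxn = model.reaction(carboxylase)
        v = solution.fluxes.get(carboxylase, 0.0)
        for met, coef in rxn.stoichiometry.items():
            if met in co2_set and coef * v < -tol:
                fixation += -coef * v
    net_exchange = solution.fluxes.get(co2_exchange, 0.0)
    if net_exchange < -tol:
        # CO2 supplied from the medium: the ratio no longer measures
        # recapture of metabolic CO2, so it is left undefined
        percent, defined = None, False
    elif produced <= tol:
        percent, defined = 0.0, True
    else:
        percent, defined = 100.0 * fixation / produced, True
    return Co2Report(
        fixation=fixation,
        total_produced=produced,
        net_exchange=net_exchange,
        percent_fixed=percent,
        defined=defined,
    )


def condition_report(
    model: MetabolicModel,
    conditions: Sequence[ConditionSpec],
    fitted_sink_rates: Mapping[str, float],
    config: SolverConfig = SolverConfig(),
    sink_metabolite: str = "qh2",
    sqo_reaction: str = "SDH",
    rc_reaction: str = "RC",
    carboxylase: str = "CBB",
    co2_exchange: str = "EX_co2",
) -> pd.DataFrame:
    """Per-condition summary table at the fitted quinol sink rates.

    Columns mirror the conventional layout: quinol oxidation (sink)
    rate, quinone reduction through the TCA cycle (the
    succinate:quinone oxidoreductase flux), electron transport rate
    (reaction-centre flux / 10, in dmol/gDW/hr), CO2 fixation rate,
    percent CO2 fixed (blank when CO2 was supplied), and net CO2
    excretion (negative = net uptake).
    """
    rows = []
    for cond in conditions:
        if cond.name not in fitted_sink_rates:
            raise KeyError(f"no fitted sink rate for condition {cond.name!r}")
        rate = fitted_sink_rates[cond.name]
        prepared = add_sink_reaction(
            apply_condition(model, cond), sink_metabolite, rate, mode="fixed"
        )
        sol = solve_pfba(prepared, config)
        if not sol.ok:
            raise RuntimeError(f"condition {cond.name!r} infeasible at sink rate {rate}")
        report = co2_accounting(
            prepared, sol, carboxylase=carboxylase, co2_exchange=co2_exchange
        )
        rows.append(
            {
                "condition": cond.name,
                "qh2_oxidation_rate": rate,
                "q_reduction_tca": sol.fluxes.get(sqo_reaction, 0.0),
                "etr_dmol": sol.fluxes.get(rc_reaction, 0.0) / 10.0,
                "co2_fixation": report.fixation,
                "percent_co2_fixed": report.percent_fixed,
                "net_co2_excretion": report.net_exchange,
                "growth": sol.objective_value,
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["units"] = {
        "qh2_oxidation_rate": "mmol/gDW/hr",
        "q_reduction_tca": "mmol/gDW/hr",
        "etr_dmol": "dmol/gDW/hr (reaction-centre flux / 10)",
        "co2_fixation": "mmol/gDW/hr",
        "percent_co2_fixed": "% of gross CO2 produced; None when CO2 supplied",
        "net_co2_excretion": "mmol/gDW/hr, positive = excreted",
        "growth": "1/hr (model biomass units)",
    }
    return df
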