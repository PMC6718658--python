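"""Single-knockout essentiality scans and validation against gene lists.

A knockout is essential when the re-solved FBA optimum falls below a
fraction (default 10%) of the wild-type growth rate under the same
condition.  Knockout growth uses plain FBA: only the optimum matters
for classification and the LP optimum is unique, so the cheaper solve
suffices.  Gene-level scans evaluate each reaction's GPR under the
deletion and disable every reaction whose GPR turns False.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

from .gpr import GprExpression
from .model import MetabolicModel
from .solve import SolverConfig, solve_fba

__all__ = [
    "EssentialityConfig",
    "EssentialityResult",
    "ConfusionReport",
    "reaction_knockout_scan",
    "gene_knockout_scan",
    "evaluate_gpr",
    "essential_genes_by_projection",
    "confusion_report",
]


@dataclass(frozen=True)
class EssentialityConfig:
    growth_fraction_threshold: float = 0.1
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self):
        if not (0 < self.growth_fraction_threshold < 1):
            raise ValueError("growth_fraction_threshold must lie in (0, 1)")


@dataclass
class EssentialityResult:
    condition: str
    wild_type_growth: float
    knockout_growth: Dict[str, float]
    essential: List[str]
    level: str  # "reaction" | "gene"


@dataclass
class ConfusionReport:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.universe_size if self.universe_size else float("nan")

    @property
    def false_negative_rate(self) -> float:
        return self.fn / (self.fn + self.tp) if (self.fn + self.tp) else float("nan")

    def as_dict(self) -> dict:
        return {
            "TP": self.tp,
            "FP": self.fp,
            "FN": self.fn,
            "TN": self.tn,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "false_negative_rate": self.false_negative_rate,
        }


def evaluate_gpr(gpr: GprExpression, deleted_genes: Iterable[str]) -> bool:
    """True when the reaction remains catalysable after the deletions."""
    return gpr.evaluate(deleted_genes)


def _wild_type_growth(model: MetabolicModel, config: EssentialityConfig) -> float:
    wt = solve_fba(model, config.solver)
    if not wt.ok or wt.objective_value <= config.solver.lp_tolerance:
        raise RuntimeError(
            "wild-type growth is zero under this condition; "
            "the essentiality threshold is undefined"
        )
    return wt.objective_value


def reaction_knockout_scan(
    model: MetabolicModel,
    condition_name: str = "",
    config: EssentialityConfig = EssentialityConfig(),
) -> EssentialityResult:
    """Knock out each reaction in turn (bounds -> 0) and classify.

    The input model is never mutated; every knockout works on a copy,
    so the model after the scan is identical to the input.
    """
    wt = _wild_type_growth(model, config)
    cutoff = config.growth_fraction_threshold * wt
    growth: Dict[str, float] = {}
    essential: List[str] = []
    for rxn in model.reactions:
        ko = model.with_reaction_bounds(rxn.id, 0.0, 0.0)
        sol = solve_fba(ko, config.solver)
        g = sol.objective_value if sol.ok else 0.0
        growth[rxn.id] = max(g, 0.0)
        if growth[rxn.id] < cutoff:
            essential.append(rxn.id)
    return EssentialityResult(
        condition=condition_name,
        wild_type_growth=wt,
        knockout_growth=growth,
        essential=essential,
        level="reaction",
    )


def gene_knockout_scan(
    model: MetabolicModel,
    condition_name: str = "",
    config: EssentialityConfig = EssentialityConfig(),
) -> EssentialityResult:
    """In-silico single-gene deletions via GPR evaluation."""
    wt = _wild_type_growth(model, config)
    cutoff = config.growth_fraction_threshold * wt
    growth: Dict[str, float] = {}
    essential: List[str] = []
    for gene in sorted(model.genes):
        deleted = {gene}
        ko = model.copy()
        disabled = [
            r.id for r in ko.reactions if not evaluate_gpr(r.gpr, deleted)
        ]
        for rid in disabled:
            ko = ko.with_reaction_bounds(rid, 0.0, 0.0)
        if disabled:
            sol = solve_fba(ko, config.solver)
            g = sol.objective_value if sol.ok else 0.0
        else:
            g = wt
        growth[gene] = max(g, 0.0)
        if growth[gene] < cutoff:
            essential.append(gene)
    return EssentialityResult(
        condition=condition_name,
        wild_type_growth=wt,
        knockout_growth=growth,
        essential=essential,
        level="gene",
    )


def essential_genes_by_projection(
    model: MetabolicModel,
    reaction_result: EssentialityResult,
) -> List[str]:
    """Map essential reactions to genes through their GPRs.

    A gene is projected essential when its single deletion disables at
    least one essential reaction.  This mirrors the coarser
    reaction-to-gene mapping sometimes used with trans-mutagenesis
    screens; :func:`gene_knockout_scan` is the stricter default.
    """
    out: Set[str] = set()
    essential_rxns = set(reaction_result.essential)
    for rxn in model.reactions:
        if rxn.id not in essential_rxns or rxn.gpr.is_empty:
            continue
        for gene in rxn.gpr.genes():
            if not evaluate_gpr(rxn.gpr, {gene}):
                out.add(gene)
    return sorted(out)


def confusion_report(
    predicted_essential: Iterable[str],
    observed_essential: Iterable[str],
    gene_universe: Iterable[str],
) -> ConfusionReport:
    """Confusion counts over a gene universe containing both input sets."""
    universe = set(gene_universe)
    pred = set(predicted_essential)
    obs = set(observed_essential)
    if not pred <= universe or not obs <= universe:
        raise ValueError("predicted and observed gene sets must lie in the universe")
    tp = len(pred & obs)
    fp = len(pred - obs)
    fn = len(obs - pred)
    tn = len(universe - pred - obs)
    return ConfusionReport(tp=tp, fp=fp, fn=fn, tn=tn)
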