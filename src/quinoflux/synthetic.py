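"""Synthetic stand-ins for the study's data: a reduced photoheterotroph
core network, noisy MFA-like flux tables, and essentiality label lists.

The core network is a ~30-reaction single-compartment model of
anaerobic photoheterotrophic growth on four carboxylic acids (acetate,
fumarate, succinate, butyrate).  It closes the quinone cycle the way a
purple non-sulfur bacterium does:

* the oxidative TCA arm reduces quinone at succinate dehydrogenase;
* the glyoxylate shunt provides net C4 synthesis;
* the photochemical reaction centre moves electrons from cytochrome c2
  onto quinone and the bc1 complex moves them back while pumping
  protons, so RC and bc1 fluxes are stoichiometrically coupled and the
  cyclic chain cannot consume *net* quinol;
* net quinol oxidation is only possible through reverse electron flow
  at NADH dehydrogenase (capacity-limited) or an explicit quinol sink
  hook added with :func:`quinoflux.model.add_sink_reaction`;
* a lumped CBB reaction fixes CO2 at the cost of ATP and NADPH and is
  the only electron sink that does not touch the quinone pool.

Degrees of reduction are bookkept exactly (acetate 4.0 e-/C, butyrate
5.0, succinate 3.5, fumarate 3.0, biomass ~4.3), which reproduces the
qualitative phenotypes: growth on acetate/butyrate/succinate needs
quinol oxidation, fumarate does not, and butyrate needs external CO2.

Carrier and currency metabolites (ATP, NADPH, Q/QH2, cytochromes,
pumped protons) carry the carbon-free placeholder formula ``"X"`` so
elemental carbon closure can still be checked on every reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .essentiality import EssentialityConfig, gene_knockout_scan
from .mfa import MfaDataset
from .model import (
    ConditionSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
    add_sink_reaction,
    apply_condition,
    reaction_from_equation,
)
from .solve import SolverConfig, solve_pfba

__all__ = [
    "CoreModelParams",
    "NoiseSpec",
    "CoreModelError",
    "build_core_model",
    "biomass_from_composition",
    "make_condition",
    "synthetic_mfa",
    "synthetic_essentiality_labels",
    "SUBSTRATES",
    "DEFAULT_SINK_RATES",
    "DEFAULT_UPTAKE_CAPS",
    "BUTYRATE_CO2_CAP",
]

SUBSTRATES = ("acetate", "fumarate", "succinate", "butyrate")

#: paper-style uptake caps, mmol/gDW/hr: 100 for the C2 acid, 50 for the C4
#: acids, so every condition is offered the same 200 mmol C/gDW/hr.
DEFAULT_UPTAKE_CAPS = {
    "acetate": 100.0,
    "fumarate": 50.0,
    "succinate": 50.0,
    "butyrate": 50.0,
}

#: CO2 uptake allowance during growth on butyrate, mmol/gDW/hr
BUTYRATE_CO2_CAP = 32.1

#: ground-truth quinol sink rates used by the synthetic MFA generator,
#: mmol/gDW/hr.  Fumarate is the oxidised substrate that needs none.
DEFAULT_SINK_RATES = {
    "acetate": 40.0,
    "butyrate": 45.0,
    "succinate": 35.0,
    "fumarate": 0.0,
}

_EXCHANGES = {
    "acetate": "EX_ac",
    "fumarate": "EX_fum",
    "succinate": "EX_succ",
    "butyrate": "EX_but",
}

#: macromolecular composition, g/gDW (synthetic placeholder values in the
#: range reported for heterotrophic alphaproteobacteria; the real organism's
#: measured composition can be substituted without touching the topology)
DEFAULT_MASS_FRACTIONS = {
    "protein": 0.55,
    "carbohydrate": 0.20,
    "lipid": 0.15,
    "nucleic_acid": 0.07,
    "ash": 0.03,
}

#: mean monomer masses, g/mmol
DEFAULT_MONOMER_MASSES = {
    "protein": 0.110,
    "carbohydrate": 0.162,
    "lipid": 0.550,
    "nucleic_acid": 0.330,
}

#: precursor demand per mmol of monomer polymerised
#: (accoa/pyr/oaa in mmol, atp and nadph in mmol)
#: the mix fixes the biomass degree of reduction at ~3.7 e-/C, between
#: succinate (3.5) and acetate (4.0), which is what separates the four
#: substrate phenotypes (net electron excess on acetate/butyrate, mild
#: deficit on succinate, strong deficit on fumarate)
DEFAULT_MONOMER_RECIPES = {
    "protein": {"accoa": 0.1, "pyr": 0.3, "oaa": 0.6, "atp": 4.0, "nadph": 1.75},
    "carbohydrate": {"pyr": 2.0, "atp": 3.0},
    "lipid": {"accoa": 8.0, "atp": 7.0, "nadph": 2.0},
    "nucleic_acid": {"pyr": 2.0, "oaa": 1.0, "atp": 6.0, "nadph": 0.5},
}


class CoreModelError(RuntimeError):
    """The requested parameterisation cannot produce biomass."""


@dataclass(frozen=True)
class CoreModelParams:
    """Stoichiometric knobs of the synthetic core network.

    Defaults were fixed by a small calibration search over integer-ish
    values so that the qualitative phenotype suite holds, and are frozen
    here; they are toy coefficients, not measurements.
    """

    cbb_atp_per_co2: float = 3.0        # ATP cost of the CBB cycle per CO2 fixed
    cbb_nadph_per_co2: float = 2.0      # NADPH cost per CO2 fixed
    bc1_h_per_qh2: float = 4.0          # protons pumped per quinol oxidised at bc1
    atps_h_per_atp: float = 3.0         # protons per ATP at the synthase
    ndh_h_per_nadph: float = 0.0        # protons pumped by forward NADH:Q oxidoreductase
                                        # (0 = non-electrogenic NDH-2, the PNSB default)
    rev_ci_h_per_nadph: float = 4.0     # proton cost of reverse electron flow
    rev_ci_capacity: float = 1.0        # mmol/gDW/hr; "low activity" bound
    gam_atp: float = 25.0               # growth-associated maintenance, mmol ATP/gDW
    uptake_caps: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_UPTAKE_CAPS)
    )
    butyrate_co2_cap: float = BUTYRATE_CO2_CAP
    mass_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MASS_FRACTIONS)
    )
    monomer_masses: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MONOMER_MASSES)
    )
    monomer_recipes: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MONOMER_RECIPES.items()}
    )

    def __post_init__(self):
        for name in (
            "cbb_atp_per_co2",
            "cbb_nadph_per_co2",
            "bc1_h_per_qh2",
            "atps_h_per_atp",
            "rev_ci_h_per_nadph",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.rev_ci_capacity < 0 or self.gam_atp < 0:
            raise ValueError("capacities and maintenance must be non-negative")


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative lognormal measurement noise for synthetic MFA."""

    cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("coefficient of variation must be >= 0")


def biomass_from_composition(
    mass_fractions: Mapping[str, float],
    monomer_masses: Mapping[str, float],
) -> Dict[str, float]:
    """Monomer drains (mmol/gDW) from macromolecular mass fractions.

    coefficient = fraction (g/gDW) / monomer mass (g/mmol), so one unit
    of biomass flux drains exactly 1 gDW of polymerised material.
    Classes without a monomer mass (ash and similar) contribute nothing.
    Fractions must sum to 1 within +-0.01; there is no silent
    renormalisation.
    """
    total = sum(mass_fractions.values())
    if not (0.99 <= total <= 1.01):
        raise ValueError(
            f"mass fractions sum to {total:.4f}, outside [0.99, 1.01]; "
            "fix the composition instead of relying on renormalisation"
        )
    if any(f < 0 for f in mass_fractions.values()):
        raise ValueError("mass fractions must be non-negative")
    out: Dict[str, float] = {}
    for cls, fraction in mass_fractions.items():
        if cls not in monomer_masses:
            continue
        mass = monomer_masses[cls]
        if mass <= 0:
            raise ValueError(f"monomer mass for {cls!r} must be positive")
        out[cls] = fraction / mass
    return out


def _biomass_stoichiometry(params: CoreModelParams) -> Dict[str, float]:
    monomers = biomass_from_composition(params.mass_fractions, params.monomer_masses)
    drains: Dict[str, float] = {}
    for cls, mmol in monomers.items():
        recipe = params.monomer_recipes.get(cls, {})
        for precursor, per_monomer in recipe.items():
            drains[precursor] = drains.get(precursor, 0.0) + mmol * per_monomer
    drains["atp"] = drains.get("atp", 0.0) + params.gam_atp
    return {k: -v for k, v in drains.items() if v > 0}


def build_core_model(params: CoreModelParams = CoreModelParams(), validate: bool = True) -> MetabolicModel:
    """Assemble the synthetic photoheterotroph core network.

    With ``validate=True`` (default) the generated model is checked to
    produce biomass on at least one substrate when quinol oxidation is
    available; an unusable parameterisation raises
    :class:`CoreModelError` with a diagnosis.
    """
    p = params
    X = "X"  # carbon-free placeholder formula for carriers and currency
    mets = [
        Metabolite("ac_e", "acetate", "e", "C2H3O2"),
        Metabolite("but_e", "butyrate", "e", "C4H7O2"),
        Metabolite("fum_e", "fumarate", "e", "C4H2O4"),
        Metabolite("succ_e", "succinate", "e", "C4H4O4"),
        Metabolite("co2_e", "carbon dioxide (external)", "e", "CO2"),
        Metabolite("photon_e", "photon", "e", X),
        Metabolite("o2_e", "oxygen (external)", "e", "O2"),
        Metabolite("accoa", "acetyl-CoA (C2 acyl unit)", "c", "C2H3O"),
        Metabolite("pyr", "pyruvate", "c", "C3H3O3"),
        Metabolite("oaa", "oxaloacetate", "c", "C4H2O5"),
        Metabolite("succ", "succinate", "c", "C4H4O4"),
        Metabolite("fum", "fumarate", "c", "C4H2O4"),
        Metabolite("co2", "carbon dioxide", "c", "CO2"),
        Metabolite("atp", "ATP equivalent", "c", X),
        Metabolite("nadph", "NAD(P)H equivalent", "c", X),
        Metabolite("q", "ubiquinone (oxidised)", "c", X),
        Metabolite("qh2", "ubiquinol", "c", X),
        Metabolite("cytc_ox", "cytochrome c2 (oxidised)", "c", X),
        Metabolite("cytc_red", "cytochrome c2 (reduced)", "c", X),
        Metabolite("hp", "pumped proton (periplasmic)", "c", X),
        Metabolite("o2", "oxygen", "c", "O2"),
    ]

    def rxn(rid, equation, lb=None, ub=None, gpr="", name="", subsystem=None):
        return reaction_from_equation(
            rid, equation, lb=lb, ub=ub, gpr=gpr, name=name, subsystem=subsystem
        )

    g = f"{p.bc1_h_per_qh2:g}"
    reactions = [
        # exchanges: positive flux = excretion, negative = uptake; carbon
        # sources closed by default, opened per condition
        rxn("EX_ac", "ac_e ->", lb=0, ub=1000, name="acetate exchange"),
        rxn("EX_but", "but_e ->", lb=0, ub=1000, name="butyrate exchange"),
        rxn("EX_fum", "fum_e ->", lb=0, ub=1000, name="fumarate exchange"),
        rxn("EX_succ", "succ_e ->", lb=0, ub=1000, name="succinate exchange"),
        rxn("EX_co2", "co2_e ->", lb=0, ub=1000, name="CO2 exchange"),
        rxn("EX_photon", "photon_e ->", lb=-1000, ub=0, name="photon exchange"),
        rxn("EX_o2", "o2_e ->", lb=0, ub=0, name="O2 exchange"),
        # transport and activation
        rxn("ACS", "ac_e + atp -> accoa", gpr="acsA",
            name="acetyl-CoA synthetase", subsystem="substrate assimilation"),
        rxn("BUTCOA", "but_e + atp + q -> 2 accoa + qh2 + nadph", gpr="fadD and fadE",
            name="butyrate activation and beta-oxidation (FAD and NAD steps)",
            subsystem="substrate assimilation"),
        rxn("FUMT", "fum_e -> fum", gpr="dctA", name="dicarboxylate uptake (fumarate)",
            subsystem="substrate assimilation"),
        rxn("SUCCT", "succ_e -> succ", gpr="dctA",
            name="dicarboxylate uptake (succinate)", subsystem="substrate assimilation"),
        rxn("CO2T", "co2_e <-> co2", name="CO2 diffusion"),
        rxn("O2T", "o2_e -> o2", name="O2 diffusion"),
        # central carbon metabolism
        rxn("TCA_OX", "accoa + oaa -> succ + 2 co2 + 2 nadph + atp",
            gpr="gltA and icd and sucA",
            name="oxidative TCA arm (citrate -> succinate, lumped)",
            subsystem="TCA cycle"),
        rxn("SDH", "succ + q -> fum + qh2", gpr="sdhA and sdhB",
            name="succinate:quinone oxidoreductase", subsystem="TCA cycle"),
        rxn("FUM_MDH", "fum -> oaa + nadph", gpr="fumC and mdh",
            name="fumarase + malate dehydrogenase (lumped)", subsystem="TCA cycle"),
        rxn("GLX", "2 accoa -> succ + nadph", gpr="aceA and aceB",
            name="glyoxylate shunt (net C4 synthesis, lumped)",
            subsystem="glyoxylate shunt"),
        rxn("PCK", "oaa + atp -> pyr + co2", gpr="pckA",
            name="PEP carboxykinase + pyruvate kinase (lumped)",
            subsystem="gluconeogenesis"),
        rxn("PDH", "pyr -> accoa + co2 + nadph", gpr="pdhA and pdhB",
            name="pyruvate dehydrogenase", subsystem="central carbon"),
        rxn(
            "CBB",
            f"2 co2 + {2 * p.cbb_atp_per_co2:g} atp + {2 * p.cbb_nadph_per_co2:g} nadph -> accoa",
            gpr="cbbL and cbbS and prkB",
            name="CBB cycle to acetyl-CoA (lumped RuBisCO carboxylation)",
            subsystem="CBB cycle",
        ),
        # photosynthetic cyclic electron transport
        rxn("RC", "photon_e + q + 2 cytc_red -> qh2 + 2 cytc_ox",
            gpr="pufL and pufM", name="photochemical reaction centre",
            subsystem="electron transport"),
        rxn("CYTBC1", f"qh2 + 2 cytc_ox -> q + 2 cytc_red + {g} hp",
            gpr="petA and petB and petC", name="cytochrome bc1 complex",
            subsystem="electron transport"),
        rxn("ATPS", f"{p.atps_h_per_atp:g} hp -> atp", gpr="atpA and atpD",
            name="ATP synthase", subsystem="electron transport"),
        rxn(
            "NDH2",
            "nadph + q -> qh2"
            + (f" + {p.ndh_h_per_nadph:g} hp" if p.ndh_h_per_nadph else ""),
            gpr="ndh",
            name="type II NADH:quinone oxidoreductase (non-electrogenic)",
            subsystem="electron transport",
        ),
        rxn("NDH1R", f"qh2 + {p.rev_ci_h_per_nadph:g} hp -> q + nadph",
            ub=p.rev_ci_capacity, gpr="nuoA and nuoB",
            name="reverse electron flow through complex I",
            subsystem="electron transport"),
        rxn("CCO", "qh2 + 0.5 o2 -> q + 4 hp", gpr="ccoN and ccoO",
            name="cbb3-type quinol/cytochrome oxidase (lumped)",
            subsystem="electron transport"),
        rxn("QSYN", " -> q", gpr="ubiG", name="ubiquinone biosynthesis (carrier supply)",
            subsystem="electron transport"),
    ]
    biomass_stoich = _biomass_stoichiometry(p)
    reactions.append(
        Reaction(
            id="BIOMASS",
            name="biomass (1 gDW per flux unit)",
            stoichiometry=biomass_stoich,
            lower_bound=0.0,
            upper_bound=1000.0,
            subsystem="biomass",
        )
    )
    genes = sorted(set().union(*[r.gpr.genes() for r in reactions]))
    model = MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction_id="BIOMASS",
        genes=genes,
        id="core_pnsb",
    )
    if validate:
        _check_producible(model, p)
    return model


def _check_producible(model: MetabolicModel, params: CoreModelParams) -> None:
    failures = []
    for substrate in SUBSTRATES:
        cond = make_condition(substrate, params)
        rate = max(DEFAULT_SINK_RATES[substrate], 1.0)
        with_sink = add_sink_reaction(
            apply_condition(model, cond), "qh2", rate, mode="max"
        )
        sol = solve_pfba(with_sink)
        if not sol.ok or sol.objective_value <= 1e-6:
            failures.append(substrate)
    if len(failures) == len(SUBSTRATES):
        raise CoreModelError(
            "biomass is unproducible on every substrate with quinol oxidation "
            f"available; check ATP/NADPH costs and uptake caps (failures: {failures})"
        )


def make_condition(
    substrate: str,
    params: CoreModelParams = CoreModelParams(),
    light: bool = True,
    aerobic: bool = False,
) -> ConditionSpec:
    """Photoheterotrophic growth condition for one carbon source.

    Applies the per-substrate uptake cap; butyrate additionally opens
    CO2 uptake (its catabolism is more reduced than biomass and needs
    the external electron acceptor).
    """
    if substrate not in SUBSTRATES:
        raise ValueError(f"unknown substrate {substrate!r}; pick one of {SUBSTRATES}")
    caps = {_EXCHANGES[substrate]: params.uptake_caps[substrate]}
    if substrate == "butyrate":
        caps["EX_co2"] = params.butyrate_co2_cap
    return ConditionSpec(
        name=substrate if not aerobic else f"aerobic_{substrate}",
        uptake_caps=caps,
        aerobic=aerobic,
        light=light,
    )


def synthetic_mfa(
    model: MetabolicModel,
    condition: ConditionSpec,
    sink_rate: float,
    noise: NoiseSpec = NoiseSpec(),
    config: SolverConfig = SolverConfig(),
    sink_metabolite: str = "qh2",
) -> MfaDataset:
    """MFA-like flux table drawn from the ground-truth pFBA solution.

    The model is solved with the quinol sink fixed at ``sink_rate``
    under ``condition``; every reaction carrying flux is 'measured' with
    multiplicative lognormal noise of the given coefficient of
    variation (mean-one factors, so cv=0 returns the exact fluxes).
    """
    conditioned = apply_condition(model, condition)
    with_sink = add_sink_reaction(conditioned, sink_metabolite, sink_rate, mode="fixed")
    sol = solve_pfba(with_sink, config)
    if not sol.ok:
        raise RuntimeError(
            f"ground-truth pFBA infeasible at sink rate {sink_rate} "
            f"under condition {condition.name!r}"
        )
    carbon_rxn = next(iter(condition.uptake_caps))
    rng = np.random.default_rng(noise.seed)
    fluxes: Dict[str, float] = {}
    for rid, v in sol.fluxes.items():
        if abs(v) < 1e-9:
            continue
        if noise.cv > 0:
            sigma = float(np.sqrt(np.log1p(noise.cv**2)))
            factor = rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma)
        else:
            factor = 1.0
        fluxes[rid] = v * factor
    return MfaDataset(
        condition=condition.name,
        fluxes=fluxes,
        carbon_uptake_reaction=carbon_rxn,
        scale_note=f"synthetic, sink={sink_rate:g}, cv={noise.cv:g}, seed={noise.seed}",
    )


def synthetic_essentiality_labels(
    model: MetabolicModel,
    condition: ConditionSpec,
    flip_rate: float,
    seed: int,
    sink_rate: Optional[float] = None,
    config: EssentialityConfig = EssentialityConfig(),
    sink_metabolite: str = "qh2",
) -> List[str]:
    """Noisy 'experimental' essential-gene list for the core model.

    Runs the in-silico gene knockout scan under ``condition`` (with the
    quinol sink fixed at ``sink_rate``, default the condition's
    ground-truth rate) and then flips each gene's essential/dispensable
    label independently with probability ``flip_rate``.  A flip rate of
    0.16 emulates a screen that agrees with the model on 84% of genes.
    """
    if not (0 <= flip_rate < 0.5):
        raise ValueError("flip_rate must lie in [0, 0.5)")
    if sink_rate is None:
        sink_rate = DEFAULT_SINK_RATES.get(condition.name, 0.0)
    conditioned = apply_condition(model, condition)
    with_sink = add_sink_reaction(conditioned, sink_metabolite, sink_rate, mode="fixed")
    scan = gene_knockout_scan(with_sink, condition.name, config)
    essential = set(scan.essential)
    rng = np.random.default_rng(seed)
    labels: List[str] = []
    for gene in sorted(model.genes):
        is_essential = gene in essential
        if rng.random() < flip_rate:
            is_essential = not is_essential
        if is_essential:
            labels.append(gene)
    return labels
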