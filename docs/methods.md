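# Methods

## The optimisation model

Growth is modeled as the standard constraint-based LP: steady-state
mass balance `S·v = 0` over metabolites, flux bounds
`LB_j ≤ v_j ≤ UB_j` (mmol/gDW/hr), and maximisation of the biomass
reaction flux. Parsimonious FBA folds the secondary flux-minimising
objective into one *tilted* objective,

```
maximize  v_biomass − w · Σ_{j ≠ biomass} |v_j|,    w = 1e-4,
```

rather than solving lexicographically. The summed-flux term is only
meaningful as a magnitude, so every reversible reaction is split into
two irreversible halves before the LP is built and recombined
(forward − backward) afterwards; the reported solution carries both the
recovered biomass flux and the tilted optimum so the (at most
`w × total flux`) growth degradation is visible. The tilt suppresses
thermodynamically infeasible cycles and collapses most alternate optima
without removing network content. Reactions are sorted lexicographically
by id before LP construction so that degenerate ties resolve identically
across runs and platforms. LPs are solved with HiGHS via
`scipy.optimize.linprog`; `lp_tolerance` (default 1e-9) is the
mass-balance acceptance threshold for solutions.

Knockout classification deliberately uses plain FBA, not pFBA: only the
optimum value enters the essential/dispensable decision, the LP optimum
is unique, and FBA is roughly half the solve. A knockout is essential
when its optimum falls below `growth_fraction_threshold` (default 0.1)
times the wild-type FBA optimum under the same condition. Gene deletions
disable every reaction whose GPR evaluates false with the deleted gene
set to false; an empty GPR (orphan reaction) never evaluates false. Both
the true gene-deletion scan and the coarser projection of essential
reactions through their GPRs are provided; the scan is the default
because the projection misses synthetic-lethal gene sharing.

## Sink semantics: rate versus capacity

A quinol sink `qh2 → ∅` is attached with deterministic id `SK_qh2`.
Two readings of its parameter are supported and both are used:

* **fixed** (`lb = ub = rate`): the sink is a known oxidation *rate*.
  This is the reading used for MFA fitting (the fitted value is the
  flux the data demand) and for the sink sweeps on reduced substrates,
  where it produces the observed two-region behaviour — forcing
  oxidation beyond the growth optimum wastes electrons and carbon, so
  light uptake and CO₂ fixation fall again.
* **max** (`lb = 0, ub = rate`): the sink is the *capacity* of an
  uncharacterised quinol oxidase. Parsimonious FBA leaves unused
  capacity at zero, which is the only reading under which "the sink
  does not affect the flux distribution" can hold exactly: on a
  mass-conserving network a forced sink must be fed, so the
  sink-indifference of an oxidised substrate such as fumarate is a
  statement about capacity, not forced rate.

Because removing quinol also removes its carrier, the core network
includes a carrier-supply pseudo-reaction (`∅ → q`, ubiquinone
biosynthesis lumped to a carbon-free token); without it any nonzero
sink would be structurally infeasible.

## CO₂ accounting

Gross CO₂ production sums, over non-boundary reactions, the positive
stoichiometric production of the CO₂ species at the actual flux
direction; transport and exchange are excluded. Fixation is the CO₂
consumption of the designated carboxylase (the lumped CBB reaction).
Percent fixed = 100 · fixation / gross production; when CO₂ is taken up
from the medium the ratio no longer measures recapture and is reported
as undefined. Net exchange is positive for excretion. When no CO₂ is
supplied, mass balance forces gross production = fixation + net
excretion, which the tests verify both on the pipeline's own reports
and on the published per-condition rates at printed precision. The
condition table reports the electron transport rate as the
reaction-centre flux divided by 10 (dmol/gDW/hr) purely in the report
layer, flagged in the table metadata; all internal units stay
mmol/gDW/hr.

## MFA comparison and sink fitting

Model accuracy against a flux dataset is the sum over shared reactions
of `|v_pred − v_mfa| / |v_mfa| × 100`. Reactions measured at exactly
zero are excluded (the metric is undefined there) and reported with
absolute deviations instead; reactions are equally weighted. Datasets
are rescaled multiplicatively so conditions share a carbon uptake
(100 mmol/gDW/hr for the C2 substrate, 50 for C4 substrates — equal
carbon offered). An explicit id-mapping table can translate lumped MFA
reactions to model reactions; synthetic data uses the identity map. The
sink rate is fitted by grid search (default step 2.5 over 0–80 in the
shipped analyses), with ties broken toward the smaller rate; the LP
response is piecewise linear in the rate, so a grid is robust and the
recovered minimum is stable to refinement.

## The synthetic core network

`build_core_model` emits a 28-reaction, single-compartment
photoheterotroph: exchanges for four carboxylic acids, CO₂, photons and
O₂; substrate activation (acetyl-CoA synthetase, β-oxidation of
butyrate with its FAD→quinol and NAD(P)H steps, dicarboxylate uptake);
an oxidative TCA arm producing NADPH and succinate; succinate:quinone
oxidoreductase (the quinone-reducing step); a lumped
fumarase/malate-dehydrogenase step; the glyoxylate shunt as the sole
net C4 source on C2 substrates; PEP-carboxykinase/pyruvate-kinase and
pyruvate dehydrogenase lumps; a lumped CBB reaction
(2 CO₂ + 6 ATP + 4 NADPH → acetyl-CoA, i.e. 3 ATP and 2 NADPH per CO₂);
the cyclic chain (reaction centre, bc1 pumping 4 H⁺ per quinol, ATP
synthase at 3 H⁺/ATP) closed through a cytochrome c2 pool so that
reaction-centre and bc1 fluxes are stoichiometrically equal; a
non-electrogenic type-II NADH dehydrogenase; reverse electron flow
through complex I with a low capacity bound (1 mmol/gDW/hr); an
aerobic quinol oxidase gated by the O₂ exchange; and a biomass reaction
derived from macromolecular composition.

Currency and carrier species (ATP, NADPH, quinone/quinol, cytochromes,
pumped protons) are tokens with a carbon-free placeholder formula so
elemental carbon closure is checkable on every reaction; redox
stoichiometry is bookkept exactly in electron pairs (degrees of
reduction: acetate 4.0 e⁻/C, succinate 3.5, fumarate 3.0,
butyrate 5.0).

The biomass equation comes from `biomass_from_composition`: monomer
drains are mass fraction (g/gDW) divided by mean monomer mass (g/mmol),
so one biomass flux unit drains 1 gDW; fractions must sum to 1 ± 0.01
with no silent renormalisation. The shipped fractions
(protein 0.55, carbohydrate 0.20, lipid 0.15, nucleic acid 0.07,
ash 0.03) are synthetic placeholders in the range typical of
heterotrophic alphaproteobacteria, and each monomer has a precursor
recipe over acetyl-CoA, pyruvate, oxaloacetate, ATP and NADPH plus
25 mmol ATP/gDW growth-associated maintenance. The recipes were fixed
by a small calibration search and then frozen; the one deliberately
tuned property is the biomass degree of reduction, ≈3.7 e⁻/C, *between*
succinate and acetate. That single number is what makes the four
substrates behave distinctly:

* acetate and butyrate are more reduced than biomass — growth requires
  net electron disposal, so it scales with the quinol sink (two-region
  sweeps, single-peaked ETR) and butyrate additionally needs medium CO₂
  as electron acceptor (strictly infeasible without it when no sink is
  attached);
* succinate is slightly less reduced than biomass but all of its carbon
  must pass succinate dehydrogenase, so growth needs quinol oxidation
  through either the sink or capacity-limited reverse electron flow;
* fumarate is strongly oxidised — no net quinol arises and sink
  capacity is never used.

Uptake caps follow the study conditions: 100 mmol/gDW/hr acetate,
50 for the C4 acids (equal carbon), CO₂ at 32.1 mmol/gDW/hr for
butyrate only. Ground-truth sink rates for the data generators are
{acetate 40, butyrate 45, succinate 35, fumarate 0} mmol/gDW/hr —
toy-scaled analogues of the fitted genome-scale values, with fumarate
pinned at zero by its oxidation state.

Synthetic MFA tables perturb the ground-truth pFBA fluxes with
mean-one multiplicative lognormal noise of a given coefficient of
variation (cv 0 returns exact fluxes; the seed is recorded in the file
metadata). Synthetic essentiality labels flip each gene's in-silico
label independently with probability `flip_rate`; 0.16 emulates a
screen agreeing with the model on 84% of genes.

### What the generator does and does not emulate

It reproduces the *mechanisms* — cyclic-chain electron coupling, the
quinone-pool bottleneck, glyoxylate-shunt anaplerosis, redox-driven CBB
usage — at roughly 1/50 of genome-scale size. It does not reproduce
genome-scale numbers: absolute growth rates, the fitted sink rates, the
per-condition fixation percentages and essential-gene counts are
toy-scale. Passing tests therefore demonstrate that the pipeline's
logic (LP formulation, knockout bookkeeping, error minimisation, sweep
extraction) is correct and that the qualitative biology is attainable,
not that the full reconstruction's values are reproduced; the loaders
accept a genome-scale SBML/JSON/TSV model directly when one is
available. Real MFA data would also need the id-mapping table, since
measured lumped reactions rarely match model granularity.

## Numerical choices and degenerate inputs

* Default bounds ±1000 (reversible) and [0, 1000] (irreversible)
  mmol/gDW/hr; reversibility is encoded purely in bounds.
* Uptake is negative flux on an exchange `met_e → ∅`; condition caps
  are given as positive magnitudes and translated.
* Infeasible sweep/fit points are retained and flagged, never fatal;
  a fit errors out only if every grid point is infeasible.
* A biomass precursor with no producing route yields an optimal
  zero-growth solution, not an infeasibility; knockout scans raise
  when the wild type itself cannot grow (the threshold is undefined).
* Carbon-closure violations are reported per reaction, not fatal, and
  skip reactions touching species without formulas.
* The fitting grid tie-break (smaller rate) and the lexicographic
  reaction ordering make every reported number deterministic for a
  given seed.

## Known limitations

Single compartment with an external pseudo-compartment; no
proton-motive-force thermodynamics beyond fixed pumping ratios; no
kinetic ceiling on RuBisCO, so fixation grows linearly with light
where a real cell saturates; loopless-FVA and MILP cycle removal are
out of scope (the flux penalty stands in for them); confidence
intervals on fitted sink rates are not computed.
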