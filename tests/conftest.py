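"""Shared fixtures: tiny hand-built networks plus the synthetic core model."""

import pytest

from quinoflux import (
    MetabolicModel,
    Metabolite,
    build_core_model,
    reaction_from_equation,
)


def model_from_equations(equations, biomass_id, external=(), model_id="fixture"):
    """Build a model from (id, equation[, lb, ub, gpr]) tuples.

    Metabolites are inferred; ids listed in ``external`` (or suffixed
    ``_e``) go to the external compartment.
    """
    reactions = []
    for spec in equations:
        rid, equation = spec[0], spec[1]
        lb = spec[2] if len(spec) > 2 else None
        ub = spec[3] if len(spec) > 3 else None
        gpr = spec[4] if len(spec) > 4 else ""
        reactions.append(reaction_from_equation(rid, equation, lb=lb, ub=ub, gpr=gpr))
    met_ids = sorted({m for r in reactions for m in r.stoichiometry})
    mets = [
        Metabolite(
            id=m,
            name=m,
            compartment="e" if (m in external or m.endswith("_e")) else "c",
        )
        for m in met_ids
    ]
    genes = sorted(set().union(*[r.gpr.genes() for r in reactions]))
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction_id=biomass_id,
        genes=genes,
        id=model_id,
    )


@pytest.fixture
def chain_model():
    """Linear pathway: uptake (capacity 10) -> conversion -> biomass."""
    return model_from_equations(
        [
            ("R_up", " -> a", 0, 10),
            ("R_conv", "a -> b"),
            ("BIO", "b ->"),
        ],
        biomass_id="BIO",
    )


@pytest.fixture
def diamond_model():
    """Two redundant routes from a to b; one direct, one via c."""
    return model_from_equations(
        [
            ("R_up", " -> a", 0, 10),
            ("R_direct", "a -> b"),
            ("R_via1", "a -> c"),
            ("R_via2", "c -> b"),
            ("BIO", "b ->"),
        ],
        biomass_id="BIO",
    )


@pytest.fixture
def loop_model():
    """Chain plus a 2-reaction antiparallel loop that can circulate freely."""
    return model_from_equations(
        [
            ("R_up", " -> a", 0, 10),
            ("R_conv", "a -> b"),
            ("L_fwd", "a -> c", 0, 1000),
            ("L_bwd", "c -> a", 0, 1000),
            ("BIO", "b ->"),
        ],
        biomass_id="BIO",
    )


@pytest.fixture(scope="session")
def core_model():
    return build_core_model()
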