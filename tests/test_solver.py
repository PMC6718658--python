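"""LP layer: FBA against a vertex-enumeration oracle, pFBA parsimony,
FVA ranges, and scaling/tilt properties."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quinoflux import (
    MetabolicModel,
    Metabolite,
    Reaction,
    SolverConfig,
    build_stoichiometric_matrix,
    flux_variability,
    solve_fba,
    solve_pfba,
)
from quinoflux.solve import check_mass_balance

from conftest import model_from_equations


def brute_force_fba_optimum(model, tol=1e-9):
    """Independent oracle: enumerate candidate vertices of {S v = 0,
    lb <= v <= ub} by fixing n - rank(S) variables at a bound and
    solving for the rest; return the best biomass flux found.

    Exponential; only usable on fixtures with <= ~8 reactions.  All
    bounds must be finite so the polytope is bounded and the optimum is
    attained at a vertex.
    """
    S = build_stoichiometric_matrix(model).toarray()
    m, n = S.shape
    assert n <= 8, "oracle is exponential; keep fixtures tiny"
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    assert np.all(np.isfinite(lb)) and np.all(np.isfinite(ub))
    bio = model.reaction_ids.index(model.biomass_reaction_id)
    r = np.linalg.matrix_rank(S)
    best = None
    for free in itertools.combinations(range(n), n - r):
        fixed = [j for j in range(n) if j not in free]
        for choice in itertools.product(*[(lb[j], ub[j]) for j in free]):
            v = np.zeros(n)
            for j, val in zip(free, choice):
                v[j] = val
            rhs = -S[:, list(free)] @ np.array(choice)
            A = S[:, fixed]
            sol, residual, rank_, _ = np.linalg.lstsq(A, rhs, rcond=None)
            v[fixed] = sol
            if np.max(np.abs(S @ v)) > 1e-7:
                continue
            if np.any(v < lb - 1e-7) or np.any(v > ub + 1e-7):
                continue
            if best is None or v[bio] > best:
                best = v[bio]
    return best


def random_bounded_network(seed):
    """Random small network with finite bounds (always feasible at v=0)."""
    rng = np.random.default_rng(seed)
    n_mets = rng.integers(2, 5)
    n_rxns = rng.integers(3, 8)
    mets = [Metabolite(f"m{i}") for i in range(n_mets)]
    reactions = []
    for j in range(n_rxns):
        k = rng.integers(1, min(3, n_mets) + 1)
        chosen = rng.choice(n_mets, size=k, replace=False)
        coefs = rng.choice([-2, -1, 1, 2], size=k)
        stoich = {f"m{i}": float(c) for i, c in zip(chosen, coefs)}
        reversible = rng.random() < 0.4
        reactions.append(
            Reaction(
                id=f"r{j}",
                stoichiometry=stoich,
                lower_bound=-10.0 if reversible else 0.0,
                upper_bound=float(rng.integers(1, 11)),
            )
        )
    return MetabolicModel(
        metabolites=mets,
        reactions=reactions,
        biomass_reaction_id="r0",
        id=f"random{seed}",
    )


class TestFbaAgainstOracle:
    def test_chain_bound_limited(self, chain_model):
        sol = solve_fba(chain_model)
        assert sol.ok
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)

    def test_diamond_objective_independent_of_routing(self, diamond_model):
        sol = solve_fba(diamond_model)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-9)
        assert sol.objective_value == pytest.approx(
            brute_force_fba_optimum(diamond_model), abs=1e-6
        )

    def test_unproducible_precursor_means_zero_growth(self):
        model = model_from_equations(
            [("R_up", " -> a", 0, 10), ("BIO", "a + ghost ->")],
            biomass_id="BIO",
        )
        sol = solve_fba(model)
        assert sol.ok and sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_forced_flux_through_missing_precursor_is_infeasible(self):
        model = model_from_equations(
            [("R_up", " -> a", 0, 10), ("BIO", "a + ghost ->", 1, 10)],
            biomass_id="BIO",
        )
        sol = solve_fba(model)
        assert sol.status == "infeasible"
        assert sol.fluxes == {}

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_on_random_networks(self, seed):
        model = random_bounded_network(seed)
        lp = solve_fba(model)
        oracle = brute_force_fba_optimum(model)
        assert lp.ok and oracle is not None
        assert lp.objective_value == pytest.approx(oracle, abs=1e-6)

    def test_oracle_equivalence_on_fixtures(
        self, chain_model, diamond_model, loop_model
    ):
        for model in (chain_model, diamond_model, loop_model):
            assert solve_fba(model).objective_value == pytest.approx(
                brute_force_fba_optimum(model), abs=1e-6
            )


class TestPfba:
    def test_chain_tilted_objective_arithmetic(self, chain_model):
        sol = solve_pfba(chain_model)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        # forced non-biomass flux is 10 (uptake) + 10 (conversion)
        assert sol.tilted_objective_value == pytest.approx(
            10.0 - 1e-4 * 20.0, abs=1e-6
        )

    def test_diamond_takes_the_short_route(self, diamond_model):
        sol = solve_pfba(diamond_model)
        assert sol.fluxes["R_direct"] == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["R_via1"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["R_via2"] == pytest.approx(0.0, abs=1e-9)

    def test_loop_carries_no_flux_under_pfba(self, loop_model):
        sol = solve_pfba(loop_model)
        assert sol.objective_value == pytest.approx(10.0, abs=1e-6)
        assert sol.fluxes["L_fwd"] == pytest.approx(0.0, abs=1e-9)
        assert sol.fluxes["L_bwd"] == pytest.approx(0.0, abs=1e-9)

    def test_tilt_consistency(self, core_model):
        from quinoflux import add_sink_reaction, apply_condition, make_condition

        model = add_sink_reaction(
            apply_condition(core_model, make_condition("acetate")), "qh2", 40.0
        )
        config = SolverConfig()
        fba = solve_fba(model, config)
        pfba = solve_pfba(model, config)
        total = pfba.total_flux(exclude=(model.biomass_reaction_id,))
        assert pfba.objective_value >= fba.objective_value - config.tilt_weight * total
        fba_total = fba.total_flux(exclude=(model.biomass_reaction_id,))
        assert total <= fba_total + 1e-6

    def test_mass_balance_within_tolerance(self, core_model):
        from quinoflux import add_sink_reaction, apply_condition, make_condition

        model = add_sink_reaction(
            apply_condition(core_model, make_condition("acetate")), "qh2", 40.0
        )
        config = SolverConfig()
        sol = solve_pfba(model, config)
        assert check_mass_balance(model, sol) <= 10 * config.lp_tolerance

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(k=st.floats(min_value=0.1, max_value=50.0))
    def test_scaling_homogeneity(self, k):
        """Scaling the uptake capacity scales every pFBA flux linearly."""
        model = model_from_equations(
            [
                ("R_up", " -> a", 0, 10 * k),
                ("R_direct", "a -> b"),
                ("R_via1", "a -> c"),
                ("R_via2", "c -> b"),
                ("BIO", "b ->"),
            ],
            biomass_id="BIO",
        )
        base = model_from_equations(
            [
                ("R_up", " -> a", 0, 10),
                ("R_direct", "a -> b"),
                ("R_via1", "a -> c"),
                ("R_via2", "c -> b"),
                ("BIO", "b ->"),
            ],
            biomass_id="BIO",
        )
        scaled = solve_pfba(model)
        ref = solve_pfba(base)
        for rid, v in ref.fluxes.items():
            assert scaled.fluxes[rid] == pytest.approx(k * v, rel=1e-6, abs=1e-6)

    def test_reaction_order_determinism(self, diamond_model):
        a = solve_pfba(diamond_model)
        b = solve_pfba(diamond_model)
        assert a.fluxes == b.fluxes


class TestFva:
    def test_chain_fully_determined(self, chain_model):
        ranges = flux_variability(chain_model, 1.0)
        for rid, (lo, hi) in ranges.items():
            assert lo == pytest.approx(10.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_diamond_routes_span_zero_to_ten(self, diamond_model):
        ranges = flux_variability(diamond_model, 1.0)
        for rid in ("R_direct", "R_via1"):
            lo, hi = ranges[rid]
            assert lo == pytest.approx(0.0, abs=1e-6)
            assert hi == pytest.approx(10.0, abs=1e-6)

    def test_fraction_validation(self, chain_model):
        with pytest.raises(ValueError):
            flux_variability(chain_model, 0.0)

    def test_pfba_vector_lies_within_fva_ranges(self, core_model):
        from quinoflux import add_sink_reaction, apply_condition, make_condition

        model = add_sink_reaction(
            apply_condition(core_model, make_condition("fumarate")), "qh2", 0.0
        )
        fba = solve_fba(model)
        pfba = solve_pfba(model)
        fraction = min(1.0, pfba.objective_value / fba.objective_value)
        ranges = flux_variability(model, fraction)
        for rid, (lo, hi) in ranges.items():
            assert lo - 1e-6 <= pfba.fluxes[rid] <= hi + 1e-6


def test_agrees_with_cobrapy_on_core_model(core_model):
    """Independent reference implementation: cobrapy's FBA and pFBA on
    the prepared core network must agree with ours on the optimum and
    on the total absolute flux (the pFBA-unique quantities)."""
    cobra = pytest.importorskip("cobra")
    from quinoflux import add_sink_reaction, apply_condition, make_condition

    model = add_sink_reaction(
        apply_condition(core_model, make_condition("acetate")), "qh2", 40.0
    )
    cm = cobra.Model("cross_check")
    cm.add_metabolites(
        [cobra.Metabolite(m.id, compartment=m.compartment) for m in model.metabolites]
    )
    cm.add_reactions(
        [
            cobra.Reaction(r.id, lower_bound=r.lower_bound, upper_bound=r.upper_bound)
            for r in model.reactions
        ]
    )
    for r in model.reactions:
        cm.reactions.get_by_id(r.id).add_metabolites(
            {cm.metabolites.get_by_id(k): v for k, v in r.stoichiometry.items()}
        )
    cm.objective = model.biomass_reaction_id

    ours_fba = solve_fba(model)
    theirs_fba = cm.optimize().objective_value
    assert ours_fba.objective_value == pytest.approx(theirs_fba, abs=1e-6)

    ours = solve_pfba(model)
    theirs = cobra.flux_analysis.pfba(cm)
    assert ours.objective_value == pytest.approx(
        theirs.fluxes[model.biomass_reaction_id], abs=1e-6
    )
    ours_total = ours.total_flux(exclude=(model.biomass_reaction_id,))
    theirs_total = sum(
        abs(v) for k, v in theirs.fluxes.items() if k != model.biomass_reaction_id
    )
    assert ours_total == pytest.approx(theirs_total, rel=1e-6)


def test_config_validation():
    with pytest.raises(ValueError):
        SolverConfig(tilt_weight=0.0)
    with pytest.raises(ValueError):
        SolverConfig(lp_tolerance=-1)
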