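"""The synthetic core network's contract: structure, composition-derived
biomass, the qualitative phenotype suite, and the noisy data generators."""

import numpy as np
import pytest

from quinoflux import (
    CoreModelError,
    CoreModelParams,
    NoiseSpec,
    add_sink_reaction,
    apply_condition,
    biomass_from_composition,
    build_core_model,
    carbon_balance_report,
    confusion_report,
    gene_knockout_scan,
    light_uptake_sweep,
    make_condition,
    quinol_sink_sweep,
    solve_pfba,
    synthetic_essentiality_labels,
    synthetic_mfa,
)

from test_sweeps import assert_single_interior_peak


class TestStructure:
    def test_size_and_content(self, core_model):
        assert len(core_model.reactions) <= 40
        for rid in ("SDH", "GLX", "CBB", "RC", "CYTBC1", "ATPS", "NDH1R", "BIOMASS"):
            assert core_model.has_reaction(rid)
        assert core_model.biomass_reaction_id == "BIOMASS"

    def test_invariants_and_carbon_closure(self, core_model):
        core_model.validate()
        assert carbon_balance_report(core_model) == {}

    def test_cyclic_chain_couples_rc_and_bc1(self, core_model):
        """Cytochrome c2 closure forces equal reaction-centre and bc1
        fluxes, so the cyclic chain cannot consume net quinol."""
        model = add_sink_reaction(
            apply_condition(core_model, make_condition("acetate")), "qh2", 40.0
        )
        sol = solve_pfba(model)
        assert sol.fluxes["RC"] == pytest.approx(sol.fluxes["CYTBC1"], abs=1e-7)

    def test_unusable_parameterisation_raises(self):
        params = CoreModelParams(
            uptake_caps={"acetate": 0.0, "fumarate": 0.0, "succinate": 0.0, "butyrate": 0.0}
        )
        with pytest.raises(CoreModelError, match="unproducible"):
            build_core_model(params)


class TestBiomassComposition:
    def test_protein_coefficient_arithmetic(self):
        out = biomass_from_composition(
            {"protein": 0.55, "rest": 0.45}, {"protein": 0.110, "rest": 0.45}
        )
        assert out["protein"] == pytest.approx(5.0)

    def test_zero_fraction_gives_zero_coefficient(self):
        out = biomass_from_composition(
            {"protein": 0.0, "rest": 1.0}, {"protein": 0.110, "rest": 0.5}
        )
        assert out["protein"] == 0.0

    def test_bad_sum_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            biomass_from_composition({"a": 0.6, "b": 0.5}, {"a": 0.1, "b": 0.1})

    def test_homogeneity_of_degree_one(self):
        base = biomass_from_composition({"a": 0.5, "b": 0.5}, {"a": 0.2, "b": 0.4})
        k = 0.99
        scaled = biomass_from_composition(
            {"a": 0.5 * k, "b": 0.5 * k}, {"a": 0.2, "b": 0.4}
        )
        for cls in base:
            assert scaled[cls] == pytest.approx(k * base[cls])

    def test_classes_without_monomer_mass_are_structural(self):
        out = biomass_from_composition(
            {"protein": 0.97, "ash": 0.03}, {"protein": 0.110}
        )
        assert "ash" not in out


class TestPhenotypeSuite:
    """The generator's behavioural contract on the four substrates."""

    def test_acetate_growth_needs_quinol_oxidation(self, core_model):
        base = apply_condition(core_model, make_condition("acetate"))
        no_disposal = base.with_reaction_bounds("NDH1R", 0.0, 0.0)
        hindered = solve_pfba(no_disposal)
        assert hindered.ok and hindered.objective_value == pytest.approx(0.0, abs=1e-8)
        with_sink = add_sink_reaction(no_disposal, "qh2", 40.0, mode="max")
        assert solve_pfba(with_sink).objective_value > 1.0

    @pytest.mark.parametrize(
        "substrate,grid_max",
        [("acetate", 80.0), ("butyrate", 140.0)],
    )
    def test_single_peaked_etr_on_reduced_substrates(
        self, core_model, substrate, grid_max
    ):
        grid = list(np.arange(0.0, grid_max + 1e-9, 5.0))
        sweep = quinol_sink_sweep(
            core_model, make_condition(substrate), grid, mode="fixed"
        )
        photon = [r.photon_uptake for r in sweep.records if r.status == "optimal"]
        assert_single_interior_peak(photon)

    def test_fumarate_flux_vector_sink_invariant(self, core_model):
        conditioned = apply_condition(core_model, make_condition("fumarate"))
        sols = {}
        for cap in (0.0, 20.0):
            model = add_sink_reaction(conditioned, "qh2", cap, mode="max")
            sols[cap] = solve_pfba(model)
        for rid, v in sols[0.0].fluxes.items():
            assert sols[20.0].fluxes[rid] == pytest.approx(v, abs=1e-6)

    def test_succinate_needs_sink_or_reverse_complex_one(self, core_model):
        conditioned = apply_condition(core_model, make_condition("succinate"))
        neither = conditioned.with_reaction_bounds("NDH1R", 0.0, 0.0)
        assert solve_pfba(neither).objective_value == pytest.approx(0.0, abs=1e-8)
        rev_only = solve_pfba(conditioned)
        assert rev_only.objective_value > 1e-3
        with_sink = add_sink_reaction(neither, "qh2", 20.0, mode="max")
        assert solve_pfba(with_sink).objective_value > rev_only.objective_value

    def test_succinate_cannot_avoid_sdh(self, core_model):
        model = add_sink_reaction(
            apply_condition(core_model, make_condition("succinate")), "qh2", 20.0,
            mode="max",
        )
        sol = solve_pfba(model)
        assert sol.objective_value > 0
        assert sol.fluxes["SDH"] > 1e-3

    def test_light_sweep_shows_energy_then_carbon_limited_regions(self, core_model):
        sweep = light_uptake_sweep(
            core_model,
            make_condition("acetate"),
            list(np.arange(0.0, 401.0, 50.0)),
            sink_rate=50.0,
        )
        growth = np.array([r.growth for r in sweep.records])
        fixation = np.array([r.co2_fixation for r in sweep.records])
        uptake = np.array([r.carbon_uptake for r in sweep.records])
        assert growth[0] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(growth) > -1e-9)  # more light never hurts
        # energy-limited region: several low-light points with zero
        # fixation while growth still climbs (all ATP goes to biomass)
        dark_region = fixation < 1e-6
        assert dark_region[:4].all()
        assert np.all(np.diff(growth[dark_region]) > 1e-6)
        # carbon-limited region: fixation switches on, rises with light,
        # and the substrate ends pinned at its uptake cap
        assert fixation[-1] > 1e-3
        assert np.all(np.diff(fixation) > -1e-6)
        assert uptake[-1] == pytest.approx(100.0, abs=1e-6)

    def test_butyrate_requires_co2_supplementation(self, core_model):
        cond = make_condition("butyrate")
        with_co2 = apply_condition(core_model, cond)
        no_co2 = with_co2.with_reaction_bounds("EX_co2", 0.0, 1000.0)
        assert solve_pfba(no_co2).objective_value == pytest.approx(0.0, abs=1e-8)
        assert solve_pfba(with_co2).objective_value > 1e-3


class TestSyntheticMfa:
    def test_zero_noise_returns_exact_fluxes(self, core_model):
        cond = make_condition("acetate")
        ds = synthetic_mfa(core_model, cond, 40.0, NoiseSpec(0.0, 5))
        model = add_sink_reaction(apply_condition(core_model, cond), "qh2", 40.0)
        truth = solve_pfba(model)
        for rid, v in ds.fluxes.items():
            assert v == pytest.approx(truth.fluxes[rid], abs=1e-9)

    def test_seed_determinism(self, core_model):
        cond = make_condition("acetate")
        a = synthetic_mfa(core_model, cond, 40.0, NoiseSpec(0.05, 11))
        b = synthetic_mfa(core_model, cond, 40.0, NoiseSpec(0.05, 11))
        assert a.fluxes == b.fluxes

    def test_noise_magnitude_tracks_cv(self, core_model):
        cond = make_condition("acetate")
        exact = synthetic_mfa(core_model, cond, 40.0, NoiseSpec(0.0, 0))
        noisy = synthetic_mfa(core_model, cond, 40.0, NoiseSpec(0.05, 3))
        rel = [
            abs(noisy.fluxes[r] / exact.fluxes[r] - 1.0)
            for r in exact.fluxes
        ]
        assert 0.005 < np.median(rel) < 0.2


class TestSyntheticEssentialityLabels:
    def test_zero_flip_rate_matches_scan_exactly(self, core_model):
        cond = make_condition("acetate")
        labels = synthetic_essentiality_labels(core_model, cond, 0.0, seed=1)
        model = add_sink_reaction(apply_condition(core_model, cond), "qh2", 40.0)
        scan = gene_knockout_scan(model, "acetate")
        rep = confusion_report(set(scan.essential), set(labels), set(core_model.genes))
        assert rep.accuracy == 1.0

    def test_seed_determinism(self, core_model):
        cond = make_condition("acetate")
        a = synthetic_essentiality_labels(core_model, cond, 0.16, seed=9)
        b = synthetic_essentiality_labels(core_model, cond, 0.16, seed=9)
        assert a == b

    def test_flip_rate_sets_expected_accuracy(self, core_model):
        """Flipping 16% of labels should land accuracy near 0.84."""
        cond = make_condition("acetate")
        model = add_sink_reaction(apply_condition(core_model, cond), "qh2", 40.0)
        scan = gene_knockout_scan(model, "acetate")
        universe = set(core_model.genes)
        accs = []
        for seed in range(12):
            labels = synthetic_essentiality_labels(core_model, cond, 0.16, seed=seed)
            rep = confusion_report(set(scan.essential), set(labels), universe)
            accs.append(rep.accuracy)
        assert np.mean(accs) == pytest.approx(0.84, abs=0.05)

    def test_flip_rate_validation(self, core_model):
        with pytest.raises(ValueError):
            synthetic_essentiality_labels(
                core_model, make_condition("acetate"), 0.7, seed=0
            )
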