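"""Tests for FBA/pFBA/FVA/sampling against independent oracles.

The primary oracle is brute-force vertex enumeration (tests/_oracles.py);
the calibrated community fixture is additionally cross-checked against an
independent LP stack (cobrapy/GLPK).
"""

import numpy as np
import pytest

from syntrophyflux.fba import (
    apply_proteome_atp_constraints,
    community_yield,
    fba,
    flux_sample,
    fva,
    pfba,
    scenario_drop_guild,
)
from syntrophyflux.fixture import PROTEOME_SHARES

from _oracles import fva_by_enumeration, lp_by_enumeration, model_arrays


def _objective(model):
    if any(r.startswith("ATPM_") for r in model.reactions):
        return model.default_objective()
    return {"EX_b": 1.0}


class TestToysAgainstEnumeration:
    @pytest.mark.parametrize("name", ["chain", "diamond", "blocked"])
    def test_fba_matches_vertex_enumeration(self, toys, name):
        model = toys[name]
        obj = _objective(model)
        sol = fba(model, obj)
        best, _ = lp_by_enumeration(*model_arrays(model, obj)[:4])
        assert sol.ok
        assert sol.objective_value == pytest.approx(best, abs=1e-9)

    @pytest.mark.parametrize("name", ["chain", "diamond", "blocked"])
    def test_fva_matches_vertex_enumeration(self, toys, name):
        model = toys[name]
        obj = _objective(model)
        S, lbs, ubs, c, rxn_ids = model_arrays(model, obj)
        _, lo, hi = fva_by_enumeration(S, lbs, ubs, c)
        ranges = fva(model, obj)
        assert np.allclose(ranges["min"].to_numpy(), lo, atol=1e-7)
        assert np.allclose(ranges["max"].to_numpy(), hi, atol=1e-7)

    def test_chain_is_uptake_limited(self, toys):
        sol = fba(toys["chain"], {"EX_b": 1.0})
        assert sol.objective_value == pytest.approx(5.0)

    def test_blocked_chain_yields_zero(self, toys):
        sol = fba(toys["blocked"], {"EX_b": 1.0})
        assert sol.objective_value == pytest.approx(0.0)


class TestPfba:
    def test_diamond_selects_short_route(self, toys):
        """Two equal-yield routes: pFBA drops the longer one entirely."""
        sol = pfba(toys["diamond"], {"EX_b": 1.0})
        assert sol.objective_value == pytest.approx(5.0)
        assert sol.fluxes["R_short"] == pytest.approx(5.0, abs=1e-7)
        assert sol.fluxes["R_long1"] == pytest.approx(0.0, abs=1e-7)
        # enumeration of both routes: short route total |v| is strictly less
        assert sol.fluxes.abs().sum() < 5.0 * 5 + 1e-6

    def test_unique_optimum_equals_fba(self, toys):
        f = fba(toys["chain"], {"EX_b": 1.0})
        p = pfba(toys["chain"], {"EX_b": 1.0})
        assert np.allclose(f.fluxes, p.fluxes, atol=1e-7)

    def test_pfba_objective_locked_to_fba_optimum(self, constrained_model):
        f = fba(constrained_model)
        p = pfba(constrained_model)
        assert p.objective_value == pytest.approx(f.objective_value, abs=1e-9)

    def test_pfba_total_flux_not_larger_than_sampled(self, toys):
        model = toys["diamond"]
        sol = pfba(model, {"EX_b": 1.0})
        samples = flux_sample(model, 20, seed=4)
        # compare at the same objective value: scale samples to EX_b = optimum
        at_opt = samples[np.isclose(samples["EX_b"], sol.objective_value, atol=0.5)]
        for _, row in at_opt.iterrows():
            assert sol.fluxes.abs().sum() <= row.abs().sum() * (
                sol.objective_value / row["EX_b"]
            ) + 1e-6


class TestCommunityFixture:
    def test_steady_state_and_bounds(self, constrained_model, community_solution):
        S, _, rxn_ids = constrained_model.stoichiometric_matrix()
        v = community_solution.fluxes[rxn_ids].to_numpy()
        assert np.abs(S @ v).max() < 1e-8
        for rid in rxn_ids:
            rxn = constrained_model.reactions[rid]
            assert rxn.lower_bound - 1e-9 <= community_solution.fluxes[rid] <= rxn.upper_bound + 1e-9

    def test_atp_shares_match_constraint(self, community_solution):
        total = sum(community_solution.atp_per_guild.values())
        norm = {g: s / sum(PROTEOME_SHARES.values()) for g, s in PROTEOME_SHARES.items()}
        for g, atp in community_solution.atp_per_guild.items():
            assert atp / total == pytest.approx(norm[g], abs=1e-6)

    def test_share_normalization_values(self, constrained_model):
        shares = constrained_model.proteome_shares
        assert shares["m1"] == pytest.approx(50 / 91)
        assert shares["saob"] == pytest.approx(23 / 91)
        assert shares["m2"] == pytest.approx(18 / 91)

    def test_carbon_balance(self, community_yield_summary):
        """2 carbons per acetate leave as CH4 + CO2 + formate."""
        nets = community_yield_summary["net_stoichiometry"]
        carbon = {"ac": 2, "for": 1, "co2": 1, "ch4": 1}
        total = sum(
            coeff * carbon.get(sp, 0)
            for net in nets.values()
            for sp, coeff in net.items()
        )
        assert total == pytest.approx(0.0, abs=1e-8)

    def test_saob_electron_balance(self, community_yield_summary):
        """SAOB products carry 8 electron-equivalents per acetate."""
        net = community_yield_summary["net_stoichiometry"]["saob"]
        electrons = 2 * net.get("h2", 0) + 2 * net.get("for", 0) + 8 * net.get("ch4", 0)
        assert electrons == pytest.approx(8.0 * -net["ac"], abs=1e-8)

    def test_fva_envelope_contains_pfba(self, constrained_model, community_solution):
        ranges = fva(constrained_model)
        for rid in ranges.index:
            v = community_solution.fluxes[rid]
            assert ranges.loc[rid, "min"] - 1e-6 <= v <= ranges.loc[rid, "max"] + 1e-6

    def test_formate_export_routes_degenerate_but_net_pinned(
        self, constrained_model, community_solution
    ):
        """Cytoplasmic export and membrane-Fdh synthesis are alternate
        optima individually, yet the summed export is invariant."""
        ranges = fva(constrained_model, reactions=["FORt_saob", "FDH_CYTB"])
        for rid in ("FORt_saob", "FDH_CYTB"):
            assert ranges.loc[rid, "min"] == pytest.approx(0.0, abs=1e-6)
            assert ranges.loc[rid, "max"] == pytest.approx(0.221, abs=1e-3)
        net = community_solution.guild_net_stoichiometry["saob"]["for"]
        assert net == pytest.approx(0.221, abs=1e-6)


class TestScenarios:
    def test_drop_m2_shifts_all_transfer_to_h2(self, constrained_model):
        sol = pfba(scenario_drop_guild(constrained_model, "m2"))
        assert sol.ok
        net = sol.guild_net_stoichiometry["saob"]
        assert net.get("for", 0.0) == pytest.approx(0.0, abs=1e-8)
        assert net["h2"] == pytest.approx(4.0, abs=1e-6)
        assert sol.guild_net_stoichiometry["m1"]["ch4"] == pytest.approx(1.0, abs=1e-6)

    def test_drop_saob_reported_infeasible_not_raised(self, constrained_model):
        sol = fba(scenario_drop_guild(constrained_model, "saob"))
        assert sol.status in ("infeasible", "optimal")
        if sol.status == "optimal":
            assert sol.objective_value == pytest.approx(0.0, abs=1e-9)

    def test_drop_m1_status_surfaced(self, constrained_model):
        """Without the H2-only methanogen the SAOB cannot balance its
        electron export against the formate-coupled partner alone."""
        sol = fba(scenario_drop_guild(constrained_model, "m1"))
        assert sol.status == "infeasible"


class TestFluxSampling:
    def test_samples_inside_fva_envelope(self, toys):
        model = toys["diamond"]
        samples = flux_sample(model, 15, seed=1)
        S, _, rxn_ids = model.stoichiometric_matrix()
        assert np.abs(samples.to_numpy() @ S.T).max() < 1e-6
        for rid in rxn_ids:
            rxn = model.reactions[rid]
            assert (samples[rid] >= rxn.lower_bound - 1e-6).all()
            assert (samples[rid] <= rxn.upper_bound + 1e-6).all()

    def test_same_seed_reproduces_samples(self, toys):
        a = flux_sample(toys["chain"], 5, seed=42)
        b = flux_sample(toys["chain"], 5, seed=42)
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_1d_segment_mean_near_midpoint(self):
        """A single uptake-limited chain is a 1-D segment: the uniform mean
        is its midpoint within 3 standard errors."""
        from syntrophyflux.network import CommunityModel, Metabolite, Reaction

        m = CommunityModel("segment")
        m.add_metabolite(Metabolite("a[e]", "e", "X", 0))
        m.add_metabolite(Metabolite("a[saob]", "saob", "X", 0))
        m.add_reaction(Reaction("EX_a", "exchange", {"a[e]": -1.0}, -10.0, 0.0))
        m.add_reaction(Reaction("T", "saob", {"a[e]": -1.0, "a[saob]": 1.0}, 0.0, 10.0))
        m.add_reaction(Reaction("SINK", "saob", {"a[saob]": -1.0}, 0.0, 10.0))
        n = 200
        samples = flux_sample(m, n, seed=9, thin=20)
        # flux on the segment is uniform on [0, 10]: mean 5, var 100/12
        se = np.sqrt(100.0 / 12.0 / n)
        assert abs(samples["SINK"].mean() - 5.0) < 3 * se * 3  # conservative

    def test_unbounded_region_raises(self, toys):
        model = toys["chain"].copy()
        model.reactions["EX_b"].upper_bound = float("inf")
        with pytest.raises((ValueError, RuntimeError)):
            flux_sample(model, 3, seed=0)


class TestProteomeConstraintEdgeCases:
    def test_missing_guild_share_rejected(self, community_model):
        with pytest.raises(KeyError):
            apply_proteome_atp_constraints(community_model, {"saob": 1.0})

    def test_nonpositive_share_rejected(self, community_model):
        with pytest.raises(ValueError):
            apply_proteome_atp_constraints(
                community_model, {"saob": 0.5, "m1": 0.5, "m2": 0.0}
            )


class TestCobraCrossCheck:
    def test_constrained_optimum_matches_independent_solver(self, constrained_model):
        """Rebuild the fixture in cobrapy and solve with GLPK."""
        cobra = pytest.importorskip("cobra")

        cm = cobra.Model("community")
        mets = {
            mid: cobra.Metabolite(mid.replace("[", "_").replace("]", ""))
            for mid in constrained_model.metabolites
        }
        rxns = []
        for rid, rxn in constrained_model.reactions.items():
            cr = cobra.Reaction(rid)
            cr.lower_bound, cr.upper_bound = rxn.lower_bound, rxn.upper_bound
            cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
            rxns.append(cr)
        cm.add_reactions(rxns)
        sinks = {g: cm.reactions.get_by_id(f"ATPM_{g}") for g in ("saob", "m1", "m2")}
        total = sum(r.flux_expression for r in sinks.values())
        for g, share in constrained_model.proteome_shares.items():
            cm.add_cons_vars(
                cm.problem.Constraint(
                    sinks[g].flux_expression - share * total, lb=0, ub=0
                )
            )
        cm.objective = total
        value = cm.slim_optimize()
        assert value == pytest.approx(0.706, rel=1e-4)
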