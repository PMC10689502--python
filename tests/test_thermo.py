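"""Tests for Gibbs-energy calculations and the H2 feasibility analysis."""

import math

import numpy as np
import pytest

from syntrophyflux.fba import community_yield, pfba, scenario_drop_guild
from syntrophyflux.thermo import (
    ATP_PHOSPHORYLATION_POTENTIAL,
    Conditions,
    R_KJ,
    delta_g_insitu,
    delta_g_standard,
    dg_per_atp,
    feasibility_interval,
    feasibility_window,
    guild_energetics,
    h2_sweep,
    load_thermo_table,
    syntrophy_window,
)

COMMUNITY_RXN = {"acetate": -1.0, "h": -1.0, "ch4": 1.0, "co2": 1.0}
UNIT = {"acetate": 1.0, "formate": 1.0, "ch4": 1.0, "co2": 1.0, "h2": 1.0}


@pytest.fixture(scope="module")
def table():
    return load_thermo_table()


@pytest.fixture(scope="module")
def sweeps(constrained_model, community_yield_summary, table):
    cond = Conditions()
    sol_b = pfba(scenario_drop_guild(constrained_model, "m2"))
    yield_b = community_yield(sol_b)
    return (
        h2_sweep(community_yield_summary, table, cond, scenario="A"),
        h2_sweep(yield_b, table, cond, scenario="B"),
    )


class TestStandardDeltaG:
    def test_empty_reaction_is_zero(self, table):
        assert delta_g_standard({}, table) == 0.0

    def test_hydrogenotrophic_methanogenesis_at_298(self, table):
        """4 H2 + CO2 -> CH4 + 2 H2O: about -131 kJ from the table sums."""
        rxn = {"h2": -4.0, "co2": -1.0, "ch4": 1.0, "h2o": 2.0}
        # hand summation oracle: -50.75 + 2*(-237.18) - (-394.36)
        assert delta_g_standard(rxn, table) == pytest.approx(-130.75, abs=0.01)

    def test_community_reaction_transformed_standard(self, table):
        """Acetate- + H+ -> CH4 + CO2 is about -35.7 kJ at pH 7, 298.15 K."""
        cond = Conditions(temperature=298.15, ph=7.0, concentrations=UNIT)
        assert delta_g_insitu(COMMUNITY_RXN, table, cond) == pytest.approx(-35.8, abs=1.0)

    def test_gibbs_helmholtz_shifts_with_temperature(self, table):
        """Gas-producing conversion becomes more exergonic when heated
        (chemical convention); the pH-7 transformed value moves to ~-41 kJ
        at 328.15 K."""
        assert delta_g_standard(COMMUNITY_RXN, table, 298.15) == pytest.approx(-75.7, abs=0.1)
        assert delta_g_standard(COMMUNITY_RXN, table, 328.15) == pytest.approx(-85.1, abs=0.2)
        cond = Conditions(temperature=328.15, ph=7.0, concentrations=UNIT)
        assert delta_g_insitu(COMMUNITY_RXN, table, cond) == pytest.approx(-41.1, abs=0.2)

    def test_missing_species_named(self, table):
        with pytest.raises(KeyError, match="mystery"):
            delta_g_standard({"mystery": 1.0}, table)


class TestInSituDeltaG:
    def test_unit_activities_reduce_to_standard(self, table):
        cond = Conditions(temperature=328.15, ph=0.0, concentrations=UNIT)
        # pH 0 => proton activity 1: in-situ equals the chemical standard
        assert delta_g_insitu(COMMUNITY_RXN, table, cond) == pytest.approx(
            delta_g_standard(COMMUNITY_RXN, table, 328.15), abs=1e-9
        )

    def test_halving_h2_pressure_closed_form(self, table):
        rxn = {"h2": -4.0, "co2": -1.0, "ch4": 1.0, "h2o": 2.0}
        cond = Conditions(concentrations=dict(UNIT))
        half = cond.with_h2(0.5)
        shift = delta_g_insitu(rxn, table, half) - delta_g_insitu(rxn, table, cond)
        assert shift == pytest.approx(4 * R_KJ * cond.temperature * math.log(2), abs=1e-9)

    def test_nonpositive_activity_rejected(self, table):
        cond = Conditions(concentrations={"h2": 0.0, **{k: 1.0 for k in ("co2", "ch4")}})
        with pytest.raises(ValueError):
            delta_g_insitu({"h2": -1.0, "co2": 1.0}, table, cond)


class TestPerAtp:
    def test_quotient_and_zero_dg(self):
        assert dg_per_atp(-35.74, 0.706) == pytest.approx(-50.7, abs=0.2)
        assert dg_per_atp(0.0, 0.5) == 0.0

    def test_zero_atp_rejected(self):
        with pytest.raises(ValueError):
            dg_per_atp(-10.0, 0.0)

    def test_community_value_is_atp_weighted_mean_of_guilds(
        self, community_yield_summary, table
    ):
        cond = Conditions()
        ge = guild_energetics(community_yield_summary, table, cond)
        total_atp = sum(g.atp for g in ge.values())
        weighted = sum(g.dg_per_atp * g.atp for g in ge.values()) / total_atp
        community_dg = sum(g.dg for g in ge.values())
        assert weighted == pytest.approx(community_dg / total_atp, abs=1e-9)


class TestAdditivity:
    def test_guild_energies_sum_to_community_conversion(
        self, community_yield_summary, table
    ):
        """Interspecies H2/formate terms cancel exactly."""
        cond = Conditions()
        ge = guild_energetics(community_yield_summary, table, cond)
        total = sum(g.dg for g in ge.values())
        assert total == pytest.approx(
            delta_g_insitu(COMMUNITY_RXN, table, cond), abs=1e-6
        )


class TestSweep:
    def test_curves_affine_in_log_p_with_stoichiometric_slope(
        self, sweeps, community_yield_summary
    ):
        sweep_a, _ = sweeps
        cond = Conditions()
        for guild, net in community_yield_summary["net_stoichiometry"].items():
            sub = sweep_a[sweep_a["guild"] == guild].sort_values("p_h2_atm")
            logp = np.log(sub["p_h2_atm"].to_numpy())
            dg = sub["dg_kj"].to_numpy()
            slopes = np.diff(dg) / np.diff(logp)
            expected = net.get("h2", 0.0) * R_KJ * cond.temperature
            assert np.allclose(slopes, expected, atol=1e-9)

    def test_producer_rises_and_consumers_fall(self, sweeps):
        sweep_a, _ = sweeps
        for guild, sign in (("saob", 1), ("m1", -1), ("m2", -1)):
            sub = sweep_a[sweep_a["guild"] == guild].sort_values("p_h2_atm")
            diffs = np.diff(sub["dg_per_atp_kj"].to_numpy())
            assert (sign * diffs > 0).all()

    def test_empty_grid_rejected(self, community_yield_summary, table):
        with pytest.raises(ValueError):
            h2_sweep(community_yield_summary, table, Conditions(), np.array([]))


class TestFeasibilityWindows:
    def test_threshold_below_all_curves_gives_empty_window(self, sweeps):
        sweep_a, _ = sweeps
        assert feasibility_window(sweep_a, threshold=-1e4) is None

    def test_window_is_interval_intersection(self, sweeps):
        sweep_a, _ = sweeps
        from syntrophyflux.thermo import _curve_from_sweep

        w = feasibility_window(sweep_a, guilds=["saob", "m1"])
        iv_s = feasibility_interval(_curve_from_sweep(sweep_a, "saob"))
        iv_m = feasibility_interval(_curve_from_sweep(sweep_a, "m1"))
        assert w[0] == pytest.approx(max(iv_s[0], iv_m[0]), rel=1e-9)
        assert w[1] == pytest.approx(min(iv_s[1], iv_m[1]), rel=1e-9)

    def test_formate_partner_broadens_the_syntrophic_window(self, sweeps):
        """The three-member window strictly contains the two-member one."""
        sweep_a, sweep_b = sweeps
        win_a = syntrophy_window(sweep_a, consumers=("m1", "m2"))
        win_b = syntrophy_window(sweep_b, consumers=("m1",))
        assert win_a is not None and win_b is not None
        assert win_a[0] < win_b[0]
        assert win_a[1] > win_b[1]

    def test_window_endpoints_bracket_threshold(self, sweeps):
        sweep_a, _ = sweeps
        from syntrophyflux.thermo import _curve_from_sweep

        curve = _curve_from_sweep(sweep_a, "saob")
        iv = feasibility_interval(curve, rtol=0.001)
        assert curve(iv[1]) == pytest.approx(ATP_PHOSPHORYLATION_POTENTIAL, abs=0.5)
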