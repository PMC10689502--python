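"""Proteome-constrained flux balance analysis of the three-guild consortium.

Loads the calibrated community model (acetate oxidizer + H2-only methanogen
+ formate/H2 methanogen), pins each guild's ATP yield to its proteome share
(50/23/18%), and solves by parsimonious FBA on a 1-mol-acetate basis.  Then
removes the formate-consuming methanogen and re-solves.
"""

from syntrophyflux import (
    PROTEOME_SHARES,
    apply_proteome_atp_constraints,
    community_yield,
    load_model,
    pfba,
    scenario_drop_guild,
)

model = apply_proteome_atp_constraints(load_model("community"), PROTEOME_SHARES)
solution = pfba(model)
summary = community_yield(solution)

print(f"community ATP yield: {summary['atp_total']:.3f} mol ATP / mol acetate")
for guild, net in summary["net_stoichiometry"].items():
    terms = ", ".join(f"{sp} {v:+.3f}" for sp, v in sorted(net.items()))
    print(f"  {guild:5s} net exchange: {terms}")
print("  CH4 split:",
      ", ".join(f"{g} {s*100:.0f}%" for g, s in summary["ch4_share"].items()))

dropped = scenario_drop_guild(model, "m2")
alt = community_yield(pfba(dropped))
print(f"\nwithout the formate methanogen: ATP {alt['atp_total']:.3f} mol/mol "
      f"(+{(alt['atp_total']/summary['atp_total']-1)*100:.0f}%), "
      "with all interspecies transfer carried by H2.")
print("The formate partner costs the community some net ATP but, as the "
      "thermodynamic sweep shows, widens the conditions where everyone "
      "conserves energy.")
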