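"""Absolute protein quantification and per-MAG 13C-protein flux.

Builds a small synthetic SIP metaproteomics experiment (three genomes at
50/23/18% proteome share plus minor members), runs the total-protein
quantification chain, and derives the community biomass yield from the
labeled protein accumulated by the end of the incubation.
"""

from syntrophyflux import CommunityDesign, biomass_yield, quantify_all_samples
from syntrophyflux.synth import simulate_proteomics

tables = simulate_proteomics(CommunityDesign(seed=1))
per_protein, per_mag = quantify_all_samples(
    tables["proteins"], tables["lfq"], tables["labels"], tables["samples"]
)

final = per_mag[per_mag["time_h"] == per_mag["time_h"].max()]
c13 = final.groupby("mag_id")["c13_protein_mg_per_l"].mean()
share = final.groupby("mag_id")["metaproteome_fraction"].mean()

print("Per-MAG results at 408 h (mean over triplicates):")
for mag in c13.index:
    print(f"  {mag:28s} 13C-protein {c13[mag]:6.2f} mg/L   "
          f"metaproteome share {share[mag]*100:5.1f}%")

y_vss, y_cod = biomass_yield(float(c13.sum()), acetate_dose_mg_per_l=3000.0)
print(f"\nCommunity biomass yield: {y_vss:.4f} g-VSS/g-acetate "
      f"({y_cod:.4f} g-COD/g-COD)")
print("The 13C-protein column is the newly synthesized biomass each genome "
      "built from the labeled acetate; dividing the community total by the "
      "protein content of biomass and the acetate dose gives the growth yield.")
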