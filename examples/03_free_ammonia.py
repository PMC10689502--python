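"""Free-ammonia speciation under thermophilic digester conditions.

Free (unionized) NH3 inhibits acetoclastic methanogens; above roughly
200-500 mg NH3-N/L at thermophilic temperatures, acetate conversion shifts
to syntrophic oxidation.
"""

from syntrophyflux import AmmoniaConditions, free_ammonia

for label, tan, ph in (("inoculum", 1.7, 7.5), ("steady-state reactor", 1.6, 8.0)):
    cond = AmmoniaConditions(tan=tan, ph=ph, temperature=328.15)
    nh3 = free_ammonia(cond)
    print(f"{label:22s} TAN {tan} g N/L, pH {ph}, 55 degC "
          f"-> {nh3*1000:6.1f} mg NH3-N/L")

print("\nBoth conditions sit at or above the reported inhibition thresholds "
      "for acetoclastic methanogenesis, selecting for the SAO pathway.")
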