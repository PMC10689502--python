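# syntrophyflux

Quantitative analysis of **syntrophic acetate oxidation (SAO)** in
methanogenic communities: per-genome ¹³C-protein fluxes from
stable-isotope-probing (SIP) metaproteomics, isotope partitioning of
methanogenic pathways, a proteome-constrained three-guild community
flux-balance model, and the thermodynamics of interspecies H₂/formate
transfer.

In ammonia-stressed or thermophilic anaerobic digesters, acetate is often
converted to methane not by acetoclastic methanogens but by a cross-feeding
partnership: an SAO bacterium oxidizes acetate to CO₂ plus H₂/formate,
which hydrogenotrophic methanogens reduce to CH₄. The package is written
for microbial ecologists and environmental engineers who want to quantify
that partnership — who grows on the acetate carbon, which pathway carries
the flux, and over what range of H₂ partial pressures every member still
conserves energy.

## What it computes

**SIP protein quantification** (`syntrophyflux.quant`) — the total-protein
approach: per-protein relative abundance
`w_i = I_i / Σ_j I_j`, absolute mass `w_i·C_sample` (g/L), molar
concentration `/MW_i` (nmol/L), and per-MAG labeled protein

&nbsp;&nbsp;&nbsp;&nbsp;[¹³C protein]₍MAG₎ = (Σ_i∈MAG TotalProteinᵢ) × mean(RIA) × mean(LR),

plus the community biomass yield from the labeled protein and the acetate
dose.

**Isotope partitioning** (`syntrophyflux.isotopes`) — the fraction of
methane formed via SAO + CO₂ reduction versus acetoclastic cleavage, from
headspace ¹³C atom fractions under methyl-labeled acetate:
`f_SAO = (a_methyl − a_CH4)/(a_methyl − a_CO2)` after background
correction.

**Free ammonia** (`syntrophyflux.ammonia`) —
NH₃-N = TAN/(1 + 10^(pKa(T)−pH)), pKa(T) = 0.09018 + 2729.92/T.

**Community FBA** (`syntrophyflux.network`, `.fba`, `.fixture`) — a
mass- and charge-balanced stoichiometric model over four compartments
(SAO bacterium, H₂-only methanogen, formate+H₂ methanogen, extracellular
space) solved by FBA/pFBA/FVA/hit-and-run sampling with each guild's ATP
yield pinned to its proteome share (ratio constraints linearized exactly).

**Thermodynamics** (`syntrophyflux.thermo`) — ΔG of each guild's net
catabolism from packaged formation energies (Gibbs–Helmholtz temperature
adjustment, `RT ln Q` in-situ correction), ΔG per mol ATP as a function of
H₂ partial pressure, and the feasibility window against the ATP
phosphorylation potential (−32.1 kJ/mol ATP).

**Synthetic data** (`syntrophyflux.synth`) — seeded, ground-truthed
generators for every input so the whole chain is testable offline.

## Worked example

```python
from syntrophyflux import (
    PROTEOME_SHARES, apply_proteome_atp_constraints, community_yield,
    load_model, pfba, scenario_drop_guild,
)

model = apply_proteome_atp_constraints(load_model("community"), PROTEOME_SHARES)
summary = community_yield(pfba(model))
print(summary["atp_total"], summary["net_stoichiometry"]["saob"])
```

Running `python examples/04_community_fba.py` prints:

```
community ATP yield: 0.706 mol ATP / mol acetate
  saob  net exchange: ac -1.000, co2 +1.779, for +0.221, h -0.779, h2 +3.779, h2o -2.000
  m1    net exchange: ch4 +0.779, co2 -0.779, h2 -3.116, h2o +1.558
  m2    net exchange: ch4 +0.221, for -0.221, h -0.221, h2 -0.663, h2o +0.442
  CH4 split: m1 78%, m2 22%

without the formate methanogen: ATP 0.765 mol/mol (+8%), ...
```

Reading: per mol acetate the oxidizer exports 0.221 mol formate and 3.779
mol H₂ (8 electron-equivalents in total); the formate-consuming methanogen
takes the formate plus 0.663 mol H₂ for 22% of the methane, the H₂-only
methanogen the rest. Removing the formate consumer raises community ATP to
0.765 mol/mol — yet `examples/05_thermodynamic_window.py` shows the
three-member H₂ feasibility window (84–341 μatm) strictly contains the
two-member one (90–275 μatm): electron shunting through formate is
thermodynamically mutualistic at the price of net ATP.

The other examples cover protein quantification and biomass yield
(`01`, prints ≈0.011 g-VSS/g-acetate for the default synthetic community),
isotope partitioning (`02`, recovers f_SAO = 0.98 as 0.979 ± 0.012),
free ammonia (`03`: 186.5 mg NH₃-N/L for the inoculum, 448.6 mg at steady
state), and the full orchestrated pipeline (`06`).

A thin CLI wraps the same functions:

```bash
syntrophyflux ammonia --tan 1.6 --ph 8.0 --temp-c 55
syntrophyflux fba --out-dir results/ --fva
syntrophyflux run --config config.yaml
```

## Layout

```
src/syntrophyflux/   quant, isotopes, ammonia, network, fba, fixture,
                     thermo, synth, orchestrate, cli + packaged data
examples/            one narrative script per capability
tests/               pytest suite incl. brute-force LP oracles
docs/methods.md      models, assumptions, calibration, limitations
```
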