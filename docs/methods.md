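# Methods

This note documents the models and procedures implemented in
`syntrophyflux`, the assumptions behind them, the parameters that matter,
and what the synthetic-data tests do and do not demonstrate.

## 1. SIP metaproteomics quantification (`quant`)

The "total protein approach" chain converts label-free quantification (LFQ)
intensities into absolute concentrations:

1. **Relative abundance** of protein *i* in a sample:
   `w_i = I_i / Σ_j I_j` over all proteins quantified in that sample (g/g).
   A sample with zero total intensity has no defined composition and is
   rejected.
2. **Mass concentration**: `c_i = w_i × C_sample` where `C_sample` is the
   bulk protein concentration (g/L) measured independently.
3. **Molar concentration**: `n_i = c_i / MW_i × 10⁹` (nmol/L), with `MW_i`
   from the amino-acid sequence.
4. **Per-MAG ¹³C protein**: for each genome bin (MAG),
   `c13 = (Σ_i∈MAG c_i [mg/L]) × mean(RIA) × mean(LR)`,
   where RIA is the ¹³C atom fraction of labeled peptides and LR the labeled
   fraction of the peptide signal, both averaged *unweighted* over the MAG's
   labeled proteins in the sample.

Conventions and edge rules:

* RIA and LR are stored as fractions in [0, 1]; readers convert
  percent-scaled columns (isotope-probing tools commonly emit RIA as a
  percentage). With fractional units the bound `c13 ≤ total protein` holds
  identically.
* LR is interpreted as labeled/(labeled+unlabeled) signal. An alternative
  reading as a labeled:unlabeled *ratio* would exceed 1 for heavily labeled
  peptides and break the bound above, so it is rejected.
* Proteins with LFQ signal but no label row count toward a MAG's total
  protein but not toward its mean RIA/LR; a MAG with no labeled proteins
  gets `c13 = 0`.
* Proteins assigned to more than one MAG are excluded at read time (the
  per-MAG sums require unique assignment); the count of exclusions is
  logged.

**Biomass yield.** With the community's summed ¹³C protein `P` (mg/L) at the
end of labeling, a protein-to-biomass ratio of 0.5 g protein/g VSS and an
acetate dose `D` (mg/L), the growth yield is `Y = (P / 0.5) / D`
(g-VSS/g-acetate). The COD-basis yield multiplies by 1.42 g-COD/g-VSS and
divides by the acetate COD factor (default 64/59 g-COD per g acetate ion,
configurable). Note these two bases are not interchangeable at a fixed
rounding: 15 mg/L of labeled protein and a 3000 mg/L dose give 0.010
g-VSS/g-acetate but ≈0.013 g-COD/g-COD with the default COD factor.

## 2. Isotope partitioning (`isotopes`)

Under methyl-labeled (2-¹³C) acetate, methane formed acetoclastically
carries the methyl label `a_methyl` (tracer purity, default 0.98), while
methane formed via SAO + CO₂ reduction carries the CO₂-pool label `a_co2`.
The estimator is the closed-form two-source mixing model

    f_sao = (a_methyl − a_ch4) / (a_methyl − a_co2)

applied after correcting each measured atom fraction for the unlabeled
dissolved-inorganic-carbon background, `(raw − bg) / (1 − bg)` with bg
defaulting to natural abundance (0.0111). A dynamic pool model that tracks
the CO₂ labeling kinetics explicitly would use the same two end-members;
the closed-form estimator evaluated along the time series and averaged is a
deliberate simplification (the time-resolved pool information enters through
the measured `a_co2(t)`).

Properties: f_sao is 1 when `a_ch4 = a_co2`, 0 when `a_ch4 = a_methyl`, and
strictly decreasing in `a_ch4`. Measurement noise can push individual
estimates outside [0, 1]; they are clamped and flagged. Observations where
the CO₂ pool reaches the tracer label are unidentifiable (the two sources
coincide) and are skipped with a reported count. The estimator is
ill-conditioned as `a_co2 → a_methyl`, so precision is best early in an
incubation or in well-buffered (large-DIC) systems.

## 3. Free ammonia (`ammonia`)

NH₃-N = TAN / (1 + 10^(pKa(T) − pH)) with the Emerson-type relation
pKa(T) = 0.09018 + 2729.92/T. This reproduces both reactor chemistry
checkpoints (185 mg NH₃-N/L at TAN 1.7 g/L, pH 7.5; 0.45 g NH₃-N/L at TAN
1.6 g/L, pH 8.0; both 55 °C) within 1%, so no ionic-strength correction is
applied.

## 4. Community flux balance analysis (`network`, `fba`, `fixture`)

### Model structure

One stoichiometric matrix spans four compartments: the cytoplasm of the
acetate oxidizer (`saob`), the two methanogens (`m1`, `m2`), and the shared
extracellular space (`e`). Interspecies transfer happens only through
explicit transporters into `e`; community-level exchange of H₂ and formate
is closed, so cross-feeding is obligate. The flux basis is 1 mol acetate
(the acetate exchange is fixed at −1).

Every non-exchange reaction is checked for element and charge balance at
load time. Carrier cofactors (ferredoxin, F420, THF, H4MPT, NAD,
menaquinone) are written with conserved moiety tokens and explicit
electron/proton bookkeeping; ion-motive force is a massless pseudo-species
`imf[guild]` in ATP-equivalent units (the ATP synthase consumes 1 imf per
ATP, so pumping stoichiometries are directly ATP-equivalents).

Each guild has an ATP sink (`ATPM_<guild>`: ATP + H₂O → ADP + Pi + H⁺)
whose flux is its net catabolic ATP yield, an ion leak (`LEAK_<guild>`)
permitting sub-maximal coupling, and the default community objective is the
summed sink flux.

### Proteome-share constraint

The guilds' relative ATP yields are pinned to their relative proteome
contributions (defaults 50/23/18% for m1/saob/m2, renormalized to
0.549/0.253/0.198). The ratio constraint is linearized exactly as
`y_g − s_g Σ_h y_h = 0` rows appended to the equality system. "Relative ATP
yield" is implemented as ATP-production share; a growth-rate interpretation
was rejected because the model deliberately contains no biomass reactions.

### Solvers

FBA/pFBA/FVA are linear programs solved with HiGHS
(`scipy.optimize.linprog`). pFBA fixes the FBA optimum as an exact equality
and minimizes Σ|v| via forward/backward flux splitting. FVA constrains the
objective to ≥ fraction × optimum (with a 1e-9 numerical slack). Flux
sampling is hit-and-run on the null-space of the equality system, started
from the centroid of the FVA vertex solutions, 100-step thinning, fully
seeded. Results are asserted only on quantities invariant across alternate
optima (objective value, net guild exchange stoichiometries); e.g. the two
formate-export routes of the SAOB are individually degenerate while their
sum is pinned.

### The calibrated three-guild fixture

Pathway content: the SAOB activates acetate by Ack/Pta and runs the reverse
Wood–Ljungdahl pathway (CODH/Acs, MetFV against the menaquinone pool,
MTHFD, Fhs recovering the activation ATP as the methyl carbon leaves as
formate); intracellular formate is exported or re-oxidized by the
electron-confurcating FdhA–NuoEF; membrane Fdh–CytB can synthesize
extracellular formate from CO₂ at menaquinol expense; electrons leave as H₂
via Ech (ion-pumping), the NADH-dependent Group 3b hydrogenase, bifurcating
HydABC, or periplasmic Hys–CytB (ion-consuming reverse electron transport).
`m1` is a strict hydrogenotroph (Mvh–Hdr bifurcation, Frh, Fwd–Mer trunk,
Na⁺-pumping Mtr, Mcr). `m2` oxidizes formate via FdhA to supply the
ferredoxin for CO₂ activation and reduces heterodisulfide with F420H₂, so
each of its CH₄ requires exactly 1 formate + 3 H₂ — the structural encoding
of the two methanogens' donor niche partitioning (m2 cannot run on H₂
alone).

Ion-translocation stoichiometries are not observable from annotation. The
four energy-coupling parameters (Ech imf yield per H₂; Hys and membrane-Fdh
imf costs; Mtr imf per CH₄ for each methanogen) are fixed in closed form so
that the proteome-constrained optimum reproduces the consortium's benchmark
net conversion: with the ATP synthase at 1 imf/ATP, the SAOB's maximal ATP
yield is affine in its formate export `f`,
`A(f) = 1.5·ech − hys − (ech/2)·f`, the methanogens' yields are their Mtr
coefficients, and requiring (i) the three-member optimum at ATP = 0.706
mol/mol acetate with f = 0.221 and (ii) the two-member (no m2) optimum at
0.765 uniquely determines all four parameters (both export routes are set
to the same marginal cost, which is why they are degenerate alternate
optima). No individual ion stoichiometry is claimed as a measurement; the
calibration is reproducible from `fixture._coupling_parameters`.

Fixture consequences worth knowing:

* at the constrained optimum, m1 runs slightly below its maximal coupling
  (its ion leak carries ~5% of its pumped imf) — the proteome constraint,
  not m1's capacity, sets its ATP;
* dropping `m2` forces all transfer through H₂ (SAOB net 2 CO₂ + 4 H₂) and
  raises community ATP to 0.765;
* dropping `saob` leaves the fixed acetate feed without a consumer:
  infeasible, surfaced as a status;
* dropping `m1` is also infeasible: with the 1:3 formate:H₂ coupling in m2
  as sole acceptor, the SAOB would have to export all electrons as formate,
  where its net ATP is negative. This is a property of the calibration, not
  an assertion about real communities.

### Conservation guarantees

Every returned solution satisfies ‖S·v‖∞ < 1e-8; acetate carbon leaves
exactly as CH₄ + CO₂ + formate (2 C per acetate) and the SAOB's products
carry 8 electron-equivalents per acetate. On toy networks (≤7 reactions)
FBA and FVA agree with brute-force vertex enumeration to 1e-9; the
community optimum is additionally cross-checked against an independent LP
stack (cobrapy/GLPK) in the test suite.

## 5. Thermodynamics (`thermo`)

Formation energies are packaged in the chemical (untransformed) convention
at 298.15 K from the standard anaerobic-microbiology compilation (Thauer et
al. 1977; enthalpies from NBS tables). Temperature adjustment is
Gibbs–Helmholtz species-wise: `dGf(T) = dHf − T (dHf − dGf,298)/298.15`.
In-situ values add `RT ln Q` with molar activities for aqueous species, atm
for gases, water at 1, and the proton at `10^−pH` — evaluating with unit
activities and pH 7 yields the pH-7 transformed standard value.

**Temperature convention for the headline number.** The transformed
standard free energy of the overall conversion
CH₃COO⁻ + H⁺ → CH₄(g) + CO₂(g) is −35.7 kJ/mol at 298.15 K and pH 7. This
is the package's reported "standard conditions" figure. The same quantity
Gibbs–Helmholtz-adjusted to 328.15 K is −41.1 kJ/mol (the conversion is
entropy-driven and more exergonic hot, but the pH-7 proton term also grows
with T); at the reactor pH of 8 and 328.15 K it is −34.8 kJ/mol. Only the
298.15 K transformed state reproduces the conventional literature value, so
that is the documented reference; both shifted values are exposed through
`delta_g_standard`/`delta_g_insitu` and asserted in the tests. Dividing by
the constrained community ATP yield gives −35.7/0.706 ≈ −50.6 kJ/mol ATP.

**H₂ sweep and feasibility windows.** Guild net stoichiometries come from
the pFBA solution on the 1-mol-acetate basis, so per-guild ΔG values add
exactly to the community ΔG (interspecies terms cancel). Each ΔG/ATP curve
is affine in ln P_H₂ with slope sign equal to the guild's net H₂
stoichiometry. Default sweep: 200 log-spaced points over 10⁻⁶–1 atm at 50
mM acetate, 7.5 μM formate, 0.5 atm CH₄ and CO₂, 55 °C, pH 7. The
feasibility threshold is the ATP phosphorylation potential, −32.1 kJ/mol
ATP (configurable; ΔG < 0 selectable). Window endpoints are found by
bisection in log space to 1% relative precision.

Two window semantics are provided: `feasibility_window` (intersection over
a listed guild set) and `syntrophy_window` (producer ∩ union of consumers —
the electron acceptors are interchangeable partners for sustaining the
oxidation). Under the defaults the three-member `syntrophy_window`
(84–341 μatm) strictly contains the two-member one (90–275 μatm): the
formate partner extends the habitable H₂ range on both ends at the price of
~8% community ATP.

## 6. Synthetic data (`synth`)

The generators emulate the *shape* of the study system, with exact
bookkeeping as ground truth:

* **Proteomics**: 3 dominant MAGs at 50/23/18% proteome share plus a 9%
  minor tail; 300 proteins per dominant MAG; molecular weights uniform on
  10–150 kg/mol; lognormal within-MAG abundance spread (σ = 1) and
  multiplicative per-sample noise (CV 0.1 default); triplicates at 24, 144,
  408 h; 0.1 g/L bulk protein; 3000 mg/L acetate dose. RIA and LR follow
  `0.98 (1 − e^(−k t))` with LR delayed (0.8 k); the default rates
  (0.0010–0.0016 h⁻¹) put per-MAG ¹³C protein on the few-mg/L scale of the
  emulated experiment. Truth records per-(sample, MAG) totals and the exact
  Σ mass·RIA·LR.
* **Headspace**: the CO₂-pool label relaxes from natural abundance toward
  the tracer purity with a 600-h time constant (a large, bicarbonate-
  buffered DIC pool; this also keeps the mixing end-members distinct, the
  regime in which the estimator — and the experiment — is informative);
  CH₄ mixes the two sources at the design `f_sao`; Gaussian relative noise.
* **Toy networks**: chain, diamond (degenerate FBA / unique pFBA), blocked
  chain, plus the calibrated community fixture.

What passing the recovery tests shows: the estimators are consistent with
their own forward models at realistic noise (per-MAG ¹³C protein within 10%
at 200 proteins/MAG and CV 0.1; proteome shares within 2 points at 500
proteins/MAG; f_sao within 0.05 at 5% noise and 20 observations). What it
does not show: robustness to peptide misassignment, shared peptides,
MS-level intensity biases, isotope-peak detection errors, or pool kinetics
beyond first order — those upstream effects are outside the package's
scope, which starts at tabular search/quantification output.

## 7. Numerical choices

* LP feasibility/optimality tolerances 1e-9 (HiGHS defaults are tighter
  than the asserted 1e-8 steady-state bound); pFBA holds the objective to
  1e-9 relative; FVA uses a 1e-9 slack on the optimum.
* Solver ties are left to the solver; only optimum-invariant quantities are
  reported as results.
* Bisection for window endpoints: 1% relative in P_H₂.
* All RNG is `numpy.random.default_rng` seeded explicitly; the orchestrator
  fans one top-level seed out to the stages.
* Degenerate inputs: all-zero LFQ samples, zero-ATP guilds in `dg_per_atp`,
  empty sweeps, non-monotone curves, unbounded sampling regions, and
  percent/fraction confusion in label tables all raise explicit errors
  rather than propagating NaNs.

## 8. Known limitations

* The fixture is a reconstruction calibrated to a benchmark conversion; its
  internal route fluxes (e.g. the split between the two formate-export
  routes) are degenerate and should not be over-interpreted.
* The isotope estimator ignores isotopic fractionation and CO₂/CH₄
  dissolution kinetics.
* Thermodynamics uses unit activity coefficients; no ionic-strength or
  component-contribution corrections.
* The ammonia module covers NH₄⁺/NH₃ only, not full carbonate speciation.
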