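# cyanoflux

Constraint-based analysis of cyanobacterial product synthesis: maximal
stoichiometric yields, growth-versus-production trade-offs, and *in silico*
transition experiments that classify how every reaction's flux must change
when a phototrophic cell shifts from growing to making a product.

## The problem

Cyanobacteria such as *Synechocystis* sp. PCC 6803 can be engineered to
secrete fuels and bulk chemicals — ethanol, ethylene, lactate, propane,
1-butanol, isoprene, fatty alcohols and alkanes, butane-2,3-diol,
isobutyraldehyde, isobutanol — directly from CO₂ and light.  Which product is
stoichiometrically attractive, and which host reactions become bottlenecks
when product flux dominates metabolism, are questions that network
stoichiometry alone can answer.  cyanoflux answers them with flux-balance
analysis (FBA): maximize a linear objective `cᵀv` over steady-state flux
vectors (`S·v = 0`, `lb ≤ v ≤ ub`), and flux-variability analysis (FVA):
the per-reaction min/max flux with the objective pinned at its optimum.

Three stages, usable as a library or from the `cyanoflux` command line:

1. **Yield accounting** — for each product, the maximal synthesis flux at
   fixed photon influx and the per-molecule demands: photons, ATP (flux
   through the ATP synthase), NADPH (FNR flux minus NDH-1 flux), O₂,
   Rubisco carboxylations, net CO₂, and the energetic yield via the lower
   heating value (LHV).
2. **Trade-off scans** — the frontier of maximal product flux as the
   required growth rate is stepped from 100% to 0% of its maximum under
   constant light.
3. **Transition experiments** — per-step FVA along that frontier, with every
   reaction classified as *sign change*, *flux increase* (from flux / from
   zero), *flux decrease* (to flux / to zero) or *no change* between the
   growth-only and production-only phenotypes.  Reactions that increase but
   are not part of the synthesis pathway (by-product reintegration, ATP
   wasting cycles) are the interesting engineering targets.

A synthetic **core phototrophic network** is generated programmatically
(light reactions with 1 photon per electron per photosystem, Q-cycle,
14/3 H⁺ per ATP, the Calvin–Benson–Bassham cycle, lower glycolysis,
phosphoketolase, cyanobacterial TCA reactions, cost-free Na⁺-dependent
bicarbonate uptake, NAD(P)H interconversion, a toy biomass objective), so
everything runs with no downloads.  Under linear electron flow the core
delivers exactly 9/7 ≈ 1.29 ATP per NADPH.  A genome-scale SBML
reconstruction can be dropped in for full-scale analyses.  See
`docs/methods.md` for the model, conventions and known limitations.

## Worked example

```
$ cyanoflux yield-table --products ethanol,lactate --out-dir out/
product  n_react  photons  nadph  atp  atp_nadph  o2  rubisco  co2  flux  yield_J note
ethanol       33     24.0    6.0  7.0       1.17 3.0      3.0  2.0 0.649    0.889
lactate       36     24.0    6.0  7.0       1.17 3.0      3.0  3.0 0.649    0.884
```

Read: one ethanol molecule costs 24 photons, 6 NADPH and 7 ATP; 3 CO₂ are
fixed by Rubisco of which one is lost again at the decarboxylase, so net CO₂
uptake is 2; 3 O₂ are evolved.  At a photon influx of 15.57 µmol gDW⁻¹h⁻¹
the maximal flux is 15.57/24 = 0.649 µmol gDW⁻¹h⁻¹, worth
0.649 × 1.37 J µmol⁻¹ = 0.889 J gDW⁻¹h⁻¹ of fuel.  The `note` column flags
products whose core-network values deviate from the genome-scale reference
(propane, the long-chain alkanes, ethylene) instead of adjusting them.

```
$ cyanoflux transition --product ethanol --steps 11 --out-dir out/
 sign_change  increase_from_flux  increase_from_zero  decrease_to_flux  decrease_to_zero  no_change
           1                  27                  12                 4                17         11
```

In the ethanol transition on the core network the heterologous pyruvate
decarboxylase and alcohol dehydrogenase increase from zero, Rubisco
increases, and the maintenance ATP hydrolysis rises — ethanol's ATP/NADPH
demand (7/6 ≈ 1.17) sits below the 9/7 supply of linear electron flow, so a
production-only phenotype must waste ATP.  The long table
`out/transition_ethanol.tsv` holds every reaction's flux interval at every
growth fraction.

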