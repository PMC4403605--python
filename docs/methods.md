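# Methods

## Scope and model class

cyanoflux analyses *stoichiometric* properties of product synthesis in a
photoautotrophic host (the cyanobacterium *Synechocystis* sp. PCC 6803 is the
motivating organism).  All computations are constraint-based: a flux vector
`v` over the reactions of a metabolic network `S` is feasible when it
satisfies steady state (`S·v = 0`) and the flux bounds, and quantities of
interest are optima of linear programs over this polytope.  Kinetics, enzyme
capacities, product toxicity and the photosynthetic sink effect are outside
the model class: a computed optimum is a stoichiometric ceiling, not a
prediction of an expression experiment.

## The core phototrophic network

The packaged synthetic network (`cyanoflux.corenet`) exists so that every
pipeline stage runs and is testable without any external model file.  It is a
curated ~75-reaction core (≈110 with all extension packs) whose *energetic*
skeleton is exact rather than approximate:

| parameter | default | consequence |
|---|---|---|
| photons per electron, per photosystem | 1 | 2 photons per linear-flow electron |
| lumen H⁺ per electron, water oxidation | 1 | |
| lumen H⁺ per electron, b6f with Q-cycle | 2 | 3 H⁺ per electron in linear flow |
| lumen H⁺ per ATP, ATP synthase | 14/3 | linear-flow ATP/NADPH = 6/(14/3) = **9/7 ≈ 1.29** |
| lumen H⁺ per electron pumped, NDH-1 | 2 | configurable; unused at yield optima |
| photon energy at 680 nm | 175.9 kJ mol⁻¹ | 15.57 µmol photons ≈ 2.7 J |

Coefficients are stored as exact rationals (e.g. 14/3) and reach floating
point only at LP assembly.

The b6f complex is represented by two modes: with the Q-cycle (2 H⁺/e⁻
translocated) and with the Q-cycle bypassed (the two plastoquinol protons
only).  The bypass is the chain's native way of lowering its ATP/NADPH
output below 9/7 — the same degree of freedom that appears in the transition
analyses as "less Q-cycle utilization" — and it is what makes the ATP
accounting (below) read the true demand instead of the proton-budget ceiling.
A passive lumen proton leak is also present as a last-resort dissipation
route.

Dark/electron metabolism comprises the CBB cycle (Rubisco carboxylase and
oxygenase as separate reactions), lower glycolysis with PEP synthase and
pyruvate kinase, phosphoketolase + phosphotransacetylase, pyruvate
dehydrogenase, the 2-oxoglutarate-dehydrogenase-free cyanobacterial TCA
reactions, carbonic anhydrase with cost-free Na⁺-dependent and ATP-dependent
bicarbonate uptake, GS-GOGAT nitrogen assimilation from nitrate (default) or
ammonium, a cost-free NAD(P)H transhydrogenase, maintenance ATP hydrolysis,
and respiration / Mehler-like / ROS sinks used only by the wild-type
constraint preset.  Lumen and cytoplasmic protons are distinct species; every
non-pseudo reaction is elementally balanced for C, H, N, O, P and S (electron
carriers are elementally null pools with hydrogens tracked through explicit
protons).

Extension packs supply host precursor metabolism per product family:
`fermentative` (LDH substrate, acetolactate→ketoisovalerate, acetoacetyl-CoA
trunk, CoA-acylating acetaldehyde route), `isoprenoid_mep`, `fatty_acid`
(lumped two-carbon elongation cycles to C16/C18 acyl-ACP), `arginine_tca`
(arginine biosynthesis with ornithine-acetyl recycling, P5C→glutamate) and
`photorespiration` (bacterial glycerate pathway; without it glycolate is
excreted).

Two deliberate lumpings:

* **MEP pathway.**  The cytidylyl-carrier segment (CDP-ME synthase, CDP-ME
  kinase, MEcPP synthase) is lumped into a single ATP-consuming step with the
  CMP/CTP pool treated as catalytic.  A fully explicit representation with
  CMP → CDP → CTP regeneration prices the segment at 3 ATP-equivalents, which
  exceeds what 56 photons of linear flow can deliver for isoprene and is not
  how the genome-scale reference treats the nucleotide pool; the lumped cost
  (1 ATP) reproduces the reference demand of 17 ATP per isoprene.
* **Fatty-acid elongation.**  Each KS/KR/DH/ER round is one reaction
  (malonyl-ACP + 2 NADPH per C2 unit).

### Toy biomass

The toy biomass drain (0.6 GAP + 0.3 acetyl-CoA + 0.25 glutamate + 5 ATP of
growth-associated maintenance per unit) is an artifact of this package, not a
measured composition.  It is chosen so growth is ATP-limited: its implied
ATP/NADPH demand ratio (~2.1, computed by the tests, not assumed) exceeds the
9/7 supply of linear electron flow, qualitatively matching real biomass
synthesis.  No numeric biomass claims are gated on it.  Nucleotide material
is not drained (the core has no purine synthesis); phosphorus enters via a
phosphate transporter for the phosphorylated precursors.

## Yield accounting

For a product-augmented model under the *yield-mode* preset (photon influx
15.57 µmol gDW⁻¹h⁻¹; maintenance, respiration, Mehler and ROS reactions off;
Rubisco oxygenase decoupled) the product export flux is maximized, then total
absolute flux is minimized with the optimum pinned (parsimonious FBA).  The
parsimonious step matters twice: it selects the cheapest of degenerate routes
(e.g. acetyl-CoA via phosphoketolase rather than pyruvate dehydrogenase for
1-butanol, which is what makes its carboxylation count 4), and it removes
futile ATP cycles so that the conventions below read demands, not ceilings.
The active-reaction count is the number of |v| > 10⁻⁹ in this parsimonious
solution.

Conventions, all per unit product flux:

* **ATP** = flux through the thylakoid ATP synthase;
* **NADPH** = FNR flux − NDH-1 flux;
* **photons** = photon uptake; **O₂** = net export; **Rubisco** = carboxylase
  flux; **CO₂** = net inorganic-carbon uptake;
* **electron pairs** = PSII turnover (per 2 e⁻), reported alongside NADPH
  because ferredoxin-consuming steps (aldehyde deformylating oxygenase, the
  MEP reductases, nitrite reductase) draw electrons without passing FNR.

Energetic yield is `flux [µmol gDW⁻¹h⁻¹] × LHV [kJ mol⁻¹] × 10⁻³`
(J gDW⁻¹h⁻¹); fluxes are µmol-scaled throughout the yield outputs so that,
e.g., ethanol's 0.649 × 1.37 = 0.889 J gDW⁻¹h⁻¹.

A useful cross-check implemented as a test invariant: photon demand is
bounded below by twice the product's degree of reduction (4C + H − 2O
available electrons), with equality exactly when the ATP demand per electron
pair stays within 9/7 and no pathway step consumes O₂ or emits reduced
by-products.

### Known deviations from the genome-scale reference

On the core network the ferredoxin-heavy rows differ from the published
genome-scale values: propane computes as 48 photons / 10 FNR-NADPH
(reference 50/13), pentadecane 192/46 (194/49), heptadecane 216/52 (218/53),
ethylene 62.5 photons (61), isoprene NADPH 12 (13).  These follow from strict
electron bookkeeping with direct ferredoxin draws and from route availability
in a core-sized network; `yield_table` reports the computed values and
annotates the deviation in a `note` column rather than adjusting anything.
Similarly, an ethylene variant flux of 0.354 µmol gDW⁻¹h⁻¹ times the 1.41
J µmol⁻¹ heating value is 0.499 J gDW⁻¹h⁻¹; the pipeline always reports the
computed product of its own flux and the LHV.

## Scenario presets

*Yield mode* is described above.  *Transition mode* reflects an initial
wild-type state: photon influx 18.0; basal maintenance ATP demand 0.6312
mmol gDW⁻¹h⁻¹ as a **lower bound** (the optimizer may hydrolyze more —
ATP-wasting is precisely what the production phenotype does); Rubisco
oxygenase carrying 3% of total Rubisco flux (`0.97·v_oxy − 0.03·v_carb = 0`;
the alternative reading, 3% of the carboxylase, is a one-line change);
respiration and the Mehler-like reaction each consuming 10% of PSII O₂
evolution; ROS formation diverting 0.5% of the electrons converted at each
photosystem.  The percentage rules are installed as linear coupling rows tied
dynamically to the PSII flux (default); a `fixed` coupling mode instead
freezes the side fluxes at their 100%-growth values, covering the other
reading of "10% of the *initial* oxygen evolution".  Both modes are exposed;
category counts on the core network are insensitive to the choice for the
products examined.

## Trade-off scans and transition experiments

The maximal growth rate `µ_max` is computed first; then for each fraction
`f` on a grid from 1.0 to 0.0 (101 points by default; the analyses in the
test suite and acceptance script use 3–11 points, which is sufficient
because classification is endpoint-determined) growth enters as the
inequality `v_biomass ≥ f·µ_max` and product export is maximized.  LP
value-function concavity guarantees the frontier is concave in `f`; this is
asserted, not assumed.

For transition experiments, flux variability of every reaction is computed at
each step with the product flux fixed at the step optimum minus an absolute
slack of 10⁻⁹ (the reference analysis states no fraction-of-optimum; exact
fixing is numerically brittle).  Classification compares interval midpoints
at the endpoints — for an interval the median and the mean of the flux range
coincide at the midpoint:

* focus filter: |midpoint| > 10⁻⁶ at 100% growth or > 10⁻⁴ at 100% product
  synthesis (flux units);
* *sign change* when the two endpoint minima, or the two maxima, have
  opposite signs (tested before the magnitude rules);
* *no change* when |b − a| / max(|a|, |b|) < 5% — the denominator is this
  package's choice (symmetric, never divides by zero at one live endpoint);
* otherwise *increase* (from zero iff |a| ≤ 10⁻⁶) or *decrease* (to zero iff
  |b| ≤ 10⁻⁴), on magnitudes so the labels are invariant under a reversible
  reaction's sign convention.

Category tallies exclude below-focus reactions.  Because only the endpoint
intervals enter the rules, grid density cannot move reactions between
categories; a test asserts this on the core network.

## Numerical choices

HiGHS (via scipy) with primal/dual feasibility tolerances 10⁻⁹,
single-threaded, fixed constraint ordering; every reported optimum passes a
strong-duality check at 10⁻⁷ relative.  Steady-state residuals are verified
against `max|S·v| ≤ 10⁻⁹·max|v|` at optima.  Active-flux threshold 10⁻⁹
(below the smallest classification threshold of 10⁻⁴).  Parsimonious FBA uses
the standard split-variable LP (`t ≥ |v|`, minimize Σt).  Infeasible or
unbounded programs raise; nothing is silently zeroed.  The pipeline contains
no randomness: identical inputs give byte-identical outputs.

## What the synthetic network does and does not show

Passing the desk-scale checks demonstrates that the pipeline's accounting,
optimization and classification machinery is correct on a network whose
light-reaction energetics match the reference assumptions exactly.  It does
not demonstrate genome-scale route fidelity: the core has one route where the
genome-scale reconstruction may have several (so active-reaction counts are
smaller, ~33–63 versus ~55–94), no gene associations, no compartmental charge
balancing, and a toy biomass.  Full-network quantities (814 reactions / 601
species, the 698 isoreaction-collapsed classification set, the 371
decrease-to-zero count for ethanol, ethylene-reintegration photon demand 44)
are therefore exercised only when the deposited genome-scale SBML file is
supplied at `data/external/Metabolic_Network_Supplementary_File1.xml`; the
isoreaction grouping for external models is read from a sidecar mapping or
falls back to grouping reactions identical up to scaling, which may not
reproduce a hand-curated grouping exactly.

## Problem sizes used by the shipped analyses

Yield summaries: core network with the product's extension pack, 74–90
reactions, two LPs plus one parsimonious LP per product.  Trade-off scans:
5–11 grid points.  Transition experiments: 3–11 grid points × 2 LPs per
reaction per point (a 3-point ethanol transition is ~500 LP solves and runs
in a few seconds).  The 101-point default grid is the intended setting for
standalone use.
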