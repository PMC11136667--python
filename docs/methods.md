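# Methods

## The biological system

Synthetic methylotrophic *Escherichia coli* assimilates methanol through
three heterologous activities — an NAD-dependent methanol dehydrogenase
(Mdh), hexulose-6-phosphate synthase (Hps) and phosphohexuloisomerase
(Phi) — feeding formaldehyde into the ribulose-monophosphate (RuMP) cycle.
The evolved production strain runs the Entner–Doudoroff/transaldolase
(ED/TA) regeneration variant of the cycle, enforced by a *tpiA*
(triosephosphate isomerase) deletion. A dissimilatory branch oxidizes
formaldehyde via formate to CO₂ (FrmA-type formaldehyde dehydrogenase,
formate dehydrogenase), generating NADH at the cost of carbon. The package
models this metabolism on the 72-metabolite / 95-reaction *E. coli* core
network and layers four bioproduct pathways on top: L-lactate (from
pyruvate), a polyhydroxybutyrate (PHB) monomer (from acetyl-CoA),
itaconate (from *cis*-aconitate) and *p*-aminobenzoate (PABA, from
chorismate precursors E4P and PEP).

## Model construction

The core network ships with the package as BIGG-style JSON. Pathway
additions are expressed as named `PathwayExtension` bundles (YAML under
`src/methyloflux/data/extensions/`), applied functionally — a knockout
forces both flux bounds to zero, and the base model is never mutated.
Reconstruction choices, where the primary description leaves details open:

* **ED reactions added.** The core network contains no Entner–Doudoroff
  pair, although wild-type *E. coli* has one; `rump_base` therefore adds
  EDD and EDA with standard BIGG stoichiometry. The `ed_ta` variant then
  removes TPI (so regeneration must route through ED + transaldolase,
  as in the evolved strain); `fba_ta` instead removes EDD/EDA, leaving the
  fructose-bisphosphate-aldolase route.
* **Sedoheptulose-1,7-bisphosphate branch.** An FBA-type aldolase
  (DHAP + E4P ⇌ S17BP) and an irreversible phosphatase (S17BP → S7P + Pi)
  provide the SBP regeneration bypass.
* **Formaldehyde dissimilation is lumped.** The core network carries no
  glutathione species, so the FrmA step is written glutathione-free
  (fald + NAD⁺ + H₂O → formate + NADH + 2 H⁺); the lump preserves carbon
  and redox.
* **Methanol transport is passive** (diffusion plus exchange; no ATP or
  PMF cost), reflecting free membrane permeation of methanol.
* **Malic enzymes (ME1, ME2) are knocked out** in all methylotroph
  models: neither carries meaningful carboxylating flux under
  physiological CO₂, and the decarboxylating direction is not part of the
  system being modelled.
* **Elemental closure.** Every added reaction balances C, O, N, P and S
  exactly; free cytosolic protons close hydrogen, following core-model
  convention. `validate_mass_balance` audits this and is enforced in the
  test suite for all shipped extensions (exchange/demand and biomass
  reactions exempt).
* **Product lumps.** LDH (pyr + NADH → lactate), a phaCAB lump
  (2 AcCoA + NADPH → C4H6O2 monomer + 2 CoA, drained by a demand
  reaction — the polymer has no single molar mass, so accounting is per
  monomer), cis-aconitate decarboxylase (acon → itaconate + CO₂; the core
  network carries aconitate explicitly), and a chorismate-pathway net
  reaction (E4P + 2 PEP + ATP + NADPH + Gln → PABA + pyruvate + Glu +
  ADP + NADP + 4 Pi + H⁺), the exact sum of the nine-step DAHP-synthase →
  ADC-lyase route.

## FBA and parsimonious FBA

FBA solves max cᵀv s.t. S·v = 0, lb ≤ v ≤ ub. pFBA fixes the objective
flux at its optimum (configurable `optimality_fraction`, default 1.0) and
minimizes Σ|v| with the non-negative splitting v = v⁺ − v⁻. The LPs are
assembled in `methyloflux.lp` and solved through a minimal backend
contract; the default backend is HiGHS dual simplex via
`scipy.optimize.linprog` with a primal feasibility tolerance of 1e-10, so
that returned solutions satisfy |S·v| ≤ 1e-9 (asserted on every solve in
the tests). Optimality agreement between the pFBA stage-two objective and
the FBA optimum is held to 1e-6; zero-flux claims use a 1e-6 threshold.

Because alternate optima are ubiquitous in FBA, zero-flux statements
(e.g. pyruvate kinase silence) are additionally certified by
`flux_range_at_pfba`: with the objective flux and the minimal total
absolute flux both pinned (total-flux slack 1e-8, relative), the target
flux is minimized and maximized. A (0, 0) interval is solver-vertex
independent. Knockouts that leave no feasible steady state are scored as
zero growth (the biological reading of lethality) and flagged.

The flux scan (`flux_scan`) fixes a reaction on a strictly increasing
grid, re-optimizes growth at every point, records infeasible points as
NaN, and fits a least-squares line over the feasible points; r² of that
fit is the linearity measure used for the 6-phosphogluconate
dehydrogenase sensitivity analysis (11 points over the feasible range).

## Growth simulations versus yield ceilings: the C1 branch

Two conventions govern the formaldehyde-dissimilation branch, and they
are deliberately different:

* **Growth analyses** treat both oxidation steps as irreversible. Both
  reactions are strongly exergonic in vivo; allowing the reverse
  (CO₂ → formate → formaldehyde at the cost of 2 NADH) lets the LP
  exploit a thermodynamically implausible refixation loop on a substrate
  as electron-rich as methanol, which distorts the predicted flux
  pattern. With the oxidative convention the model reproduces the
  expected physiology of the evolved strain: growth enters the TCA cycle
  via PEP carboxylation (PPC > 0) with PEP synthetase active and pyruvate
  kinase silent, the dissimilatory branch drains ~3% of
  6-phosphogluconate, a *gnd* knockout retains ~99.9% of the growth
  optimum (NADPH supply shifts to the transhydrogenase), and forcing
  flux through *gnd* decreases growth linearly (r² ≈ 0.99).
* **Theoretical-yield analyses** open the C1 branch in both directions
  (the `c1_salvage` extension). A yield ceiling is a stoichiometric upper
  bound, not a kinetic prediction; allowing formate/CO₂ carbon to
  re-enter the formaldehyde pool makes the ceiling a pure
  carbon-conservation bound. Under this convention all four products
  reach exactly 100% carbon yield from methanol, in both RuMP variants —
  the ED/TA cycle does not depress any product ceiling. Without salvage
  the ceilings would instead be redox-shaped (PHB 66.7%, itaconate
  83.3%, PABA 95.5% from methanol).

Yield computations fix growth to zero, keep the ATP maintenance demand at
the core default (8.39 mmol gDW⁻¹ h⁻¹; a `atpm="zero"` switch is
provided), and close the uptake of every carbon-containing exchange other
than the designated substrate, so the substrate is the sole carbon
source. This guarantees the ≤100% cap and makes the reported yield
well-defined. Yields are invariant to the uptake magnitude (LP
homogeneity; verified); the default bases are methanol at 60 and glucose
at 10 mmol gDW⁻¹ h⁻¹ — an equal-carbon basis.

## PABA from glucose: reconstruction sensitivity

The PABA ceiling from glucose on the wild-type network is the one yield
that depends on fine accounting inside the chorismate lump. Charging the
glutamine amide-recharge ATP (glutamine synthetase) to the product
pathway — the chemically faithful reading, and the shipped default —
gives 72.8% at default maintenance; sourcing the amine from ammonium
without that ATP gives 75.3%. Dropping maintenance raises either by
~3 pp. `yields.paba_glucose_yield_report` emits this sensitivity table;
the attainable ceiling should be read as ~73–75%, and comparisons against
any single printed value should carry that bracket. All other
glucose-side ceilings in this reconstruction are structural rather than
accounting-sensitive: lactate 100%, PHB 66.7% (acetyl-CoA synthesis from
pyruvate loses CO₂ and no carboxylation to C2 exists in *E. coli*), and
itaconate 83.3% (one net CO₂ loss per molecule after PEP carboxylase
refixes one of the two decarboxylations).

## Mutation parallelism

`parallel` consumes population-mode variant tables (TSV; columns
sample_id, position, ref, alt, class, locus, frequency; frequencies may
be fractions or percentages). Filtering keeps mutations with frequency
strictly above 0.60, class in {nonsynonymous, nonsense, intergenic}
(nonsense is counted within the nonsynonymous category; the class set is
configurable because the treatment of indels/structural events inside
coding regions is a judgement call), and variant identity
(position, ref, alt) absent from the ancestor at any frequency — a new
mutation in an already-mutated gene still counts. Survivors are grouped
at the gene / intergenic-region level (intergenic loci named
`i_<left>/<right>`; an alias map can apply preferred labels), and locus
sets are intersected across lines with a full Venn decomposition. Counts
are reported per line with mean ± sd (sample sd, n−1). Structural
variants are treated as single records at their left breakpoint.
Coordinates are 1-based, following the variant-caller convention.

## Synthetic data

The mutation generator emulates the study structure: four replicate
lines from one starter population, 40 ancestral background variants
present in the ancestor table and all lines, 8 planted parallel loci
present in every line at frequency above 0.60 + 0.05 (so they always
survive the filter) and in a kept class, and Poisson(300) line-private
noise mutations with uniform frequencies on (0.05, 1) and a realistic
class mix. Positions are drawn without replacement from 1..4,631,000
(approximate host genome length) so planted and noise loci never
collide; private loci are globally unique, so recovered all-line sets can
be scored exactly against the truth record. One seeded generator stream
per dataset makes everything reproducible. What the generator does *not*
emulate: linkage and clonal interference, realistic mutational spectra,
shared noise loci arising by chance, and frequency estimation error —
so exact planted-locus recovery in tests validates the pipeline's set
logic, not its behaviour on real sequencing noise. Observed per-line
counts of real lines (hundreds of mutations) are matched only in order
of magnitude.

Toy stoichiometric networks (linear chain, alternate-route branch,
futile 2-cycle, carbon-losing split) come with analytic optima attached
and stay small enough (≤ 6 reactions) for an exhaustive
polytope-vertex-enumeration oracle, against which the LP solvers are
checked independently.

## Kinetics

Forward Michaelis–Menten evaluation only: v = k_cat·E·S/(K_M + S), plus
the percent activity difference of two parameter sets at equal enzyme
concentration (S→∞ limit available, where it reduces to the k_cat
ratio). For the two Mdh variants (k_cat 0.021 vs 0.022 s⁻¹, K_M 164 vs
112 mM) the point-estimate gain at 300 mM methanol is +18.0%. Replicate-
level assay ratios would scatter around this; parameter estimation from
raw traces is out of scope.

## Numerical choices and problem sizes

Feasibility 1e-9, optimality 1e-6, zero-flux 1e-6 (all configurable);
HiGHS primal/dual tolerances 1e-10/1e-9; pFBA objective-fixing slack
1e-9 (relative); FVA total-flux slack 1e-8 (relative). Reported
precision follows bench convention: percent yields to one decimal, mass
yields to three, millimolar titres and fold changes to one. Analyses run
on the 95-reaction core network (~110 reactions extended), 11-point
scans, and 20–50 seeded mutation datasets — every stage completes in
seconds on one CPU.

## Known limitations

Core-network scope only (no genome-scale model, no gene–protein-reaction
logic, no thermodynamic constraints); supplementary reaction tables of
the source study were not available, so the pathway extensions are
reconstructions and small quantitative differences against published
model outputs (notably the PABA-from-glucose ceiling) are expected and
documented above; experimental quantities (growth rates, titres,
proteomics, per-line mutation counts of the real evolution lines) are
inputs or non-targets, not predictions of this package.
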