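# Methods

## Model structure

`mitoflux` models a human cell as two compartments: *cytosolic* (cytosol,
outer membrane, intermembrane space and the cytosolic face of the inner
membrane) and *mitochondrial* (matrix plus the matrix face of the inner
membrane). Metabolite ids carry `_c`/`_m` suffixes; boundary species are
elided, so exchange reactions are one-sided. Fluxes are in µmol/min/gDW
throughout, with conventional ±1000 large-M bounds (irreversible: [0, 1000])
and the COBRA sign convention for exchanges (negative flux = uptake).

Reactions carry a category (`metabolic`, `mito_transport`,
`boundary_exchange`, `pseudo`), gene mappings as (symbol, stable-id) pairs —
protein complexes are single reactions, so any subunit gene silences the
whole step in a knockout — and provenance annotation fields
(directionality/localisation evidence, heart expression).

## The proton motive force

The PMF across the inner membrane is a bookkeeping pseudo-metabolite (one
species per compartment, exempt from balance checks). The membrane potential
contributes 0.82 and the pH gradient 0.18 of the total PMF; a transport step
moving net charge *q* and *p* protons into the matrix per cycle therefore
co-transports `0.82·|q| + 0.18·p` PMF cytosol → matrix (`pmf_coefficient`).
The respiratory complexes move PMF matrix → cytosol: 4 (complex I), 2
(complex III, per ubiquinol) and 4 (complex IV, per electron pair; the
reaction is written per O₂ and moves 8). Only the totals — 10 per NADH and 6
per ubiquinol — affect ATP yields; the per-complex split is a configuration
choice (`PMFParameters.complex_split`, alternative 4/4/2 available). The ATP
synthase consumes 2.7 PMF (and one scalar matrix proton, for the chemistry)
per ATP.

**Scalar versus vectorial protons.** All energetic consequences of proton
movement live on the PMF species; `h_c`/`h_m` appear only as chemistry
(e.g. `mal + nad → oaa + nadh + h`) and as the carried proton of symporters
(the phosphate carrier moves `h_c → h_m` plus 0.18 PMF). Because the
vectorial circuit is not represented by explicit `h` translocation, the
scalar proton ledgers of the two compartments would otherwise be
overdetermined — the malate–aspartate shuttle, substrate-level
phosphorylation and the ROS branch each leave a small proton residue with no
outlet. A PMF-free equilibration step (`HtmA_MitoCore`, `h_c ↔ h_m`)
therefore vents scalar protons. It cannot create energy: no reaction
converts an `h` gradient into PMF, ATP or redox equivalents, which the
closed-system QC test verifies. The UCP2 leak (`HtmB_MitoCore`) is distinct:
it moves a proton *and* one PMF cytosol → matrix, so forcing its lower bound
dissipates the gradient, which is how the leak scan is driven.

**Split carriers.** Proton-coupled or electrogenic carriers that must not
pump in reverse are written as irreversible pairs; the reverse leg (ATP/ADP
carrier, phosphate carrier) carries neither proton nor PMF, so a
forward+reverse cycle is purely dissipative. This is what allows both
carriers to reverse under extreme proton leak without ever acting as pumps.

**ROS.** Complex I diverts fraction 1e-5 (0.001 %) of its flux to
superoxide, with proportionally reduced pumping; superoxide dismutase and a
lumped NADPH-dependent peroxide clearance convert it to water. Matrix NADPH
comes from NADP-dependent isocitrate dehydrogenase; NADH and NADPH pools are
otherwise strictly separate (both isocitrate dehydrogenases are
irreversible, and no transhydrogenase exists).

**Prosthetic cofactors.** No free FAD/FADH species exists. Succinate
dehydrogenase reduces ubiquinone in one reaction, and the ETF/ETF:QO
electrons of β-oxidation reduce ubiquinone inside the single lumped
palmitoyl-CoA oxidation reaction (7 cycles: 7 QH₂ + 7 NADH + 8 acetyl-CoA).

## Transport categories

Inner-membrane steps belong to one of four mechanistic classes: CARRIER
(characterised transporters, counter-exchange and proton coupling modelled
per mechanism — e.g. ATP⁴⁻/ADP³⁻ exchange 0.82 PMF, phosphate/H⁺ symport
0.18, aspartate/glutamate carrier 1.0), UNIPORT_UNKNOWN (unidentified
transporter; charged cargo moving inward is charged 0.82·|q|),
DIFFUSION (O₂, CO₂, H₂O, NH₃: reversible, PMF-free) and FLIPPASE
(ATP-hydrolysis-coupled lipid insertion; constructor enforces the ATP
coupling). The oxoglutarate/malate and dicarboxylate carriers are
electroneutral 2−:2− exchanges (0 PMF); this choice prices a cytosolic NADH
at 9 PMF through the malate–aspartate shuttle (10 minus the 1.0 PMF
aspartate/glutamate carrier cycle) and is what places the glucose and
lactate yields where they land.

## Bundled network and default bounds

`build_reduced_model()` assembles 87 reactions / 80 metabolites:
glycolysis, lactate oxidation, pyruvate carboxylase and PEPCK (the
4-carbon entry/exit routes, with NAD-malic enzyme), the TCA cycle, the
malate–aspartate shuttle, fatty-acid activation + carnitine shuttle + lumped
β-oxidation, ketolysis, transaminase/glutamate-dehydrogenase amino-acid
routes with ammonia efflux (no urea cycle), the respiratory chain, the four
pseudo objectives and boundary exchanges. The pentose phosphate pathway and
glycerol oxidation are outside this reduced scope. Amino-acid nitrogen
leaves as ammonia; the lipid pseudo reaction drains 0.5 Pi per palmitoyl-CoA
(phospholipid headgroups), which also gives the phosphate exchange a
structural flux route.

Default cardiomyocyte uptakes (`data/cardiomyocyte_uptakes.json`) are
approximate values chosen so that a mixed fuel supply (fatty acid, glucose,
lactate, ketone bodies, amino acids) slightly exceeds what the oxygen bound
(19.5 µmol/min/gDW) can oxidise, as in well-perfused heart: baseline maximal
ATP ≈ 99 µmol/min/gDW with ≈52 % of acetyl-CoA from fatty acids. The file is
marked editable; exact published uptake values can be transcribed into it
without code changes.

## Solvers

FBA solves `max c·v` s.t. `S v = 0`, `l ≤ v ≤ u` through scipy's HiGHS
interface with 1e-9 primal/dual feasibility tolerances; results carry the
steady-state residual `max|S v|`. FVA minimises and maximises each flux
subject to `c·v ≥ fraction·opt` (protocols use 1.0 and 0.98). Geometric FBA
computes the FVA box at the optimum, moves to the point minimising the
maximum deviation from the box midpoints, shrinks the box and repeats until
every width falls below `epsilon` (default 1e-6; `flex_rel` relaxes the
optimum constraint, `max_iter` caps iterations and non-convergence raises an
error carrying the last iterate). Working-box bounds are padded by 1e-7
because stacking ~100 independently solved FVA bounds unpadded can make the
box jointly infeasible at solver precision. Iterations only re-examine
not-yet-pinned fluxes, which keeps a full geometric solve on the bundled
model under half a second. There is no randomness anywhere, so runs are
deterministic and geometric FBA is idempotent. Reported yield values are
printed to one decimal.

Alternate optima exist in the bundled model only as futile exchange loops
(e.g. fumarate/malate/phosphate counter-exchange cycling) and isoenzyme-like
parallel routes; geometric FBA centres them, and reported single numbers
(objective values) are identical between plain and geometric FBA.

## Quality control

`run_qc` implements the curation tests: (1) flux capability — with all
boundary exchanges opened to ±1000, every reaction is maximised and
minimised; blocked means both optima are zero; (2) dead ends — metabolites
only ever produced or only ever consumed, with reversible reactions counting
on both sides and exchanges treated as bidirectional; (3) energy-generating
cycles — with every exchange closed to zero, the maximal flux through the
ATP-hydrolysis objective and through PMF/NADH/NADPH sinks must be exactly
zero; (4) charge balance on every non-exempt reaction plus elemental balance
where all formulas are known (PMF species, pseudo reactions and one-sided
exchanges are exempt; cytochrome c has no formula, so its reactions are
charge-checked only). The bundled model passes all checks, and the test
suite carries three deliberately broken variants (an energy cycle built from
PMF-stripped carriers plus a reversible leak, a dead-end metabolite, and an
orphan blocked reaction) that each fail their targeted check — the energy
cycle at exactly 1000/2.7 ATP, reproducible by hand from the flux caps.

## Simulation protocols

*ATP yield*: close all degradable-fuel uptakes, open O₂ to 50 µmol/min/gDW
(asserted non-binding at the optimum), supply the fuel at 1 µmol/min/gDW,
maximise ATP hydrolysis with geometric FBA; at unit uptake the objective is
mol ATP per mol fuel. *Fumarase deficiency*: knock out the FH gene (both
compartmental isoforms), keep default uptakes, compare maximal ATP and
record fumarate efflux. *Proton leak*: raise the leak step's lower bound
over a series up to the feasibility edge (`default_leak_values` finds the
edge by maximising leak flux); report maximal ATP and the synthase, ATP/ADP
carrier and phosphate-carrier net fluxes, truncating at the first infeasible
point. *Acetyl-CoA attribution*: partition matrix acetyl-CoA production by
producing reaction (β-oxidation, ketolysis, pyruvate dehydrogenase), tracing
the pyruvate and PEP pools pro rata over their producing fluxes — FBA
carries no tracer information, so proportional pool mixing is a convention,
and PEPCK-derived PEP is attributed to the amino-acid route.

## What the bundled network does and does not show

The network is a reduced, hand-balanced reconstruction: yields, knockout
phenotypes and leak behaviour emerge from the PMF stoichiometry and are not
fitted. It omits the pentose phosphate pathway, glycerol, most amino-acid
routes, heme/folate chemistry and any urea cycle, so absolute baseline
fluxes with the approximate default bounds are indicative rather than
transcribed; qualitative disease phenotypes (fumarate efflux, >50 % ATP
loss, carrier reversal under uncoupling) are robust to those bounds. Passing
tests demonstrate internal consistency of the bioenergetic bookkeeping, not
agreement with any particular tissue measurement.

## Serialisation

The TSV dialect is a curation table: one reaction per row (id, equation
string with decimal coefficients and compartment suffixes, bounds,
`symbol|accession` gene lists, subsystem, category, three provenance
columns, residual annotation as JSON), with metabolite attributes and the
objective in `#!` header lines so the file round-trips losslessly. SBML
output defaults to Level 3 + fbc (bounds, objective, charges, formulas,
gene products); a legacy Level 2 Version 1 dialect stores bounds and
objective coefficients in kinetic-law parameters for compatibility with
older curated-model distributions. The reader accepts both dialects and
externally produced files (categories are then inferred from the
compartments touched). Coefficients are serialised at full precision.
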