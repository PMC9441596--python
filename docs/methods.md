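# Methods

## Model and constraints

`acidfba` operates on GECKO-style enzyme-constrained metabolic models.  The
underlying linear program is standard FBA — maximize c·v subject to
steady-state mass balances S·v = 0 and flux bounds — augmented with enzyme
capacity and a proteome budget:

* each catalyzed reaction consumes its enzyme pseudo-metabolite at
  1/k<sub>cat</sub> per unit flux (v ≤ k<sub>cat</sub>·[E]);
* enzymes are supplied from a pool pseudo-metabolite whose exchange flux
  (g gDW⁻¹) is bounded by σ·f·P<sub>total</sub>, with σ the average in-vivo
  saturation, f the modeled proteome mass fraction, and P<sub>total</sub> the
  total cellular protein fraction (defaults to 0.5 g gDW⁻¹ for exponentially
  growing yeast when a pool configuration is supplied; otherwise the parent
  model's bound is preserved verbatim).

The acidFBA rebuild replaces each enzyme draw reaction
(MW<sub>k</sub>/1000 · E<sub>pool</sub> → E<sub>k</sub>) by a source drawing
from 20 amino-acid pseudo-metabolites (Σ<sub>l</sub> ξ<sub>kl</sub>
A<sub>l</sub> → E<sub>k</sub>), each supplied by an irreversible 1:1-mass
drain E<sub>pool</sub> → A<sub>l</sub>.  Summing the amino-acid balances
Σ<sub>k</sub> ξ<sub>kl</sub> e<sub>k</sub> = a<sub>l</sub> over l recovers
the pool balance, which yields two structural guarantees that the test suite
asserts continuously:

* **growth equivalence** — the rebuilt model's optimum equals the parent's
  (each row of ξ sums to MW<sub>k</sub>/1000, so per-enzyme pool cost is
  unchanged);
* **mass closure** — Σ<sub>l</sub> a<sub>l</sub> equals the pool exchange
  flux in every feasible solution (assertions use 10⁻⁹ g gDW⁻¹).

## Residue masses and the composition matrix

ξ entries are residue counts × average residue mass / 1000 (g mmol⁻¹).
Residue masses use the polymeric (water-free) formulas with average atomic
masses pinned in one table (C 12.011, H 1.008, N 14.007, O 15.999, S 32.06),
rounded to three decimals — e.g. Gly 57.052, Ala 71.079.  Protein molecular
weights follow the same residue-mass convention (no terminal water): this
keeps the amino-acid-resolved pool inequality algebraically identical to the
aggregate pool bound.  A `terminal_water` flag exists for free-chain masses
but is deliberately excluded from ξ and pool accounting; the discrepancy is
at most 18.015 g mol⁻¹ per protein.

Non-canonical symbols (B, J, X, Z, U, O) are rejected by default; a lenient
mode drops them with a logged warning and excludes their mass, because a
silently guessed residue mass would corrupt the pool budget.  All vectors and
matrices use one canonical ordering: alphabetical by one-letter code.
Multimeric enzymes are treated with subunit copy number 1 per polypeptide by
default; an optional per-protein copy-number table multiplies ξ rows when
complex stoichiometry is known.  If a parent draw reaction's MW coefficient
disagrees with the ξ row sum by more than 0.5%, ξ wins and the deviation is
logged — internal consistency of the amino-acid balances takes precedence
over annotation drift.  Enzymes without sequences are an error under the
strict policy; the optional `mean` policy imputes the mean relative
composition of the present proteins scaled to the draw reaction's MW.

## Simulation procedures

**Batch profiles.**  Growth is maximized, the biomass flux pinned at a
fraction of the optimum (equality with relative tolerance 10⁻⁹), and the
total flux sum minimized (parsimonious-FBA style, reversible fluxes split
into non-negative forward/reverse parts).  Enzyme, drain and pool
pseudo-fluxes are included in the sum by default; a toggle excludes them.
The amino-acid profile is read off the 20 drain fluxes.

**Minimal pool at fixed growth.**  The biomass flux is pinned exactly, the
pool exchange flux minimized, then — to select a unique profile among
alternate minimal-pool optima — the pool is capped at its exact minimum (no
upward slack, which would let the flux-sum step trade pool between routes)
and the flux sum minimized as a lexicographic tie-break.

**Drain FVA.**  With growth constrained to ≥ the optimality fraction
(default 0.99; an equality toggle exists), each drain flux is minimized and
maximized.  The relative variability is the range normalized by the midpoint
(max+min)/2 — symmetric and available without an extra solve.  A drain that
is structurally zero (amino acid absent from every enzyme) reports NaN
rather than an infinite variability, and NaNs are excluded from medians.

**Chemostat sweeps.**  P<sub>total</sub>(μ) is supplied as a callable or a
two-column table interpolated monotone piecewise-linearly — the package does
not re-fit any regression to culture data; the fitted curve is configuration
input.  Per grid point the pool bound is σ·f·P<sub>total</sub>(μ), condition
constraints are applied, and the minimal-pool problem solved.  The critical
growth rate is the first μ whose pool slack is ≤ 10⁻⁸ g gDW⁻¹.  Infeasible
points are flagged and skipped, not fatal.

**Fermentative vs respiratory comparison.**  Two condition setups (bound
overrides, blocked reactions, optionally a pinned growth rate for the
protein-non-limiting respiratory reference) are each simulated as above;
per-amino-acid deviations |p<sup>a</sup> − p<sup>b</sup>|/p<sup>b</sup> use a
NaN sentinel for zero references.  Anaerobic re-parameterization (biomass
swap, maintenance adjustments) is expressed through generic condition files;
`examples/anaerobic_condition.yaml` shows the shape against ecYeastGEM-style
identifiers.

**Nutrient sampling.**  Exchanges are classified by the elements of their
metabolite's formula.  A source is viable if, with all other members of its
class closed and itself opened, maximal growth reaches 10⁻⁴ h⁻¹
(configurable; the threshold is a package choice).  Conditions draw one
source per class uniformly with replacement from one seeded generator —
sampling a subset of the combinatorial space rather than enumerating it.
"Unlimited" uptake is implemented as a large finite bound (1000 mmol gDW⁻¹
h⁻¹) to keep the LPs bounded; all non-selected class members are closed,
including other carbon-containing exchanges of the class table.  Relative
deviations are computed column-wise against the arithmetic across-sample
mean (and are therefore mean-centered by construction).

**Species profiles.**  Distributions load from 20-row TSVs; a value column
named with `mmol`/`coeff` marks biomass coefficients, converted to mass
fractions by residue-mass weighting; sums off unity beyond 10⁻⁶ are
renormalized with a warning.  Hard constraints couple each drain
proportionally to the distribution through an auxiliary total, a<sub>l</sub>
= p<sub>l</sub>·T with T = Σ a<sub>m</sub> free — the literal proportional
reading; note that under proportional coupling the zero-proteome point is
always feasible, so an "infeasible" distribution manifests as a maximal
growth of 0 rather than LP infeasibility (growth at any positive pinned rate
is then infeasible).  The soft fit minimizes Σ<sub>l</sub> (a<sub>l</sub> −
p<sub>l</sub>T)² at a pinned growth — a convex quadratic program over the
stoichiometric polytope, solved with OSQP (polishing enabled, ε = 10⁻⁸, the
reported distance is the objective's square root).  The linearization via
the auxiliary total keeps the problem convex while measuring distance in
relative-profile space scaled by total drain mass.  Growth-fraction scans
default to steps of 0.05 from 0.1 up to the ratio of the unconstrained
optimum to the reference growth; the reference growth is the hard-coupled
optimum under the reference distribution, computed once.

## Synthetic fixtures and what they do (not) show

Toy models are linear chains S<sub>ext</sub> → S → P → biomass with K
parallel enzyme-catalyzed routes, GECKO-conform pseudo-metabolites, and
biomass flux used directly as growth rate (no maintenance terms, keeping the
optima in closed form).  An optional variant adds C/N/P/S exchange classes
with trace biomass requirements for the nutrient-sampling machinery.  Random
models draw k<sub>cat</sub> log-uniformly from 10–10⁴ h⁻¹, sequences of
length 50–500 uniformly over the 20 residues (so every drain is exercised
with high probability at K ≥ 3), yields log-uniformly within roughly
0.2–2, and pool bounds log-uniformly from 10⁻³–10⁻¹ g gDW⁻¹.

The independent oracle enumerates all vertices of the reduced route LP
(intersections of the uptake, pool, equality and non-negativity constraints;
feasible for ≤ 8 enzymes), flagging degenerate optima instead of silently
picking one.  Acceptance-grade checks run at these sizes: 1000 random models
for growth equivalence, 100 for oracle/LP agreement, grids of a handful of
growth fractions for the species-fit cross-validation — sizes chosen so the
whole suite solves a few thousand tiny LPs in well under a minute.

What passing these tests shows: the construction, the optimization
procedures and their invariants are correct on networks where ground truth
is computable exactly.  What they do not show: behavior that only emerges at
genome scale — realistic k<sub>cat</sub> distributions, isozyme/complex
structure, compartmentalization, maintenance energetics, or the specific
yeast numbers; those require an external ecGEM and proteome FASTA, which the
CLI consumes but the repository does not ship.

## Numerical choices

GLPK solves all LPs (deterministic, no seed dependence); OSQP solves the
QPs.  Key tolerances: 10⁻⁶ relative for growth equivalence, 10⁻⁹ g gDW⁻¹
for mass closure, 10⁻⁸ relative for oracle agreement, 10⁻⁶ for the mutual
equality of uniform-control variabilities, binding detection at 10⁻⁸
g gDW⁻¹ pool slack, and a 10⁻⁶ feasibility threshold on the QP distance when
cross-validating against hard coupling.  Degenerate FVA midpoints (0/0)
propagate as NaN sentinels.  Identifier schemes (`aa_<code>`,
`draw_aa_<code>`, sources keeping the parent draw ids) are fixed strings,
bit-stable across runs.

## Known limitations

Post-translational modifications, signal peptides and selenocysteine/
pyrrolysine are out of scope (non-canonical symbols are rejected or
dropped).  The hard species coupling is proportional, not per-drain equality
bounds; other readings would tighten it.  The chemostat sweep trusts the
supplied P<sub>total</sub>(μ) curve.  Dual-value sensitivity beyond binding
detection, thermodynamic constraints, and dynamic FBA are not implemented.
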