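# Methods

This note documents the models and algorithms gemkit implements, the
parameters that matter, the numerical choices, and what the bundled
synthetic models do and do not establish.

## Model representation

A model is an ordered collection of reaction entries (id, equation,
optional GPR, subsystem, EC number, open annotation mapping) and
compound entries (id with compartment label, name, formula, charge,
open mapping), plus the simulation context: a biomass designation,
growth-medium entries, explicit flux limits, an optional model subset
(when the reaction list doubles as a broader database), and a default
flux limit. Stoichiometric coefficients are exact rationals
(`fractions.Fraction`) throughout the model layer; conversion to floats
happens only at the solver boundary. This keeps the mass checks exact:
a residual of 2 is the integer 2 up to LP tolerance, not an accumulation
of float noise.

Flux bounds follow the convention [-x, x] for reversible and [0, x]
for irreversible reactions, with x the model's `default_flux_limit`
(1000 when unset). Explicit limits override per side; a limit that
opens flow against the equation's stated direction is honoured (imported
COBRA bounds win) but recorded as a reversibility-conflict warning.
Exchange reactions are recognized structurally: an equation with one
empty side. Media entries configure — or, when no such reaction exists,
synthesize — exchange columns; negative flux is uptake.

A compound may appear on both sides of one equation. The parser accepts
this (importers must be able to load broken models in order to report
them) and model validation flags it.

## Equation grammar

Terms are separated by `+` flanked by whitespace, because compound
names themselves may contain `+`, digits and spaces (`H+`,
`D-Glucose 1-phosphate`). Coefficients are parenthesized (`(2)`,
`(1/2)`, `(0.5)`); a bare leading number followed by a space is also
accepted. Arrows: `-->`, `<--`, `<==>` (canonical on output) and `=>`,
`<=>` (accepted on input). A leading `[c]:` applies a compartment to
every compound without its own suffix; rendering factors a common
compartment back out, which reproduces the conventional printed form.
Rendering then re-parsing is an exact identity, property-tested over
randomized equations.

## Stoichiometric consistency

*Compound-based*: maximize Σ zᵢ subject to Sᵀm = 0 (columns restricted
to non-excluded reactions), mᵢ ≥ zᵢ, zᵢ ∈ [0,1], m ≥ 0. Because any
feasible mass vector can be scaled, every compound that can carry
positive mass at all reaches mass 1 at some optimum; compounds with
optimal mᵢ < 1 − 10⁻⁶ are flagged. The objective value approximates the
number of consistently balanceable compounds.

*Reaction-based*: minimize Σ zⱼ subject to Sᵀm = r, mᵢ ≥ 1,
rⱼ ∈ [−zⱼ, zⱼ], zⱼ ≥ 0. The direction of the printed optimization for
this system is ambiguous in the literature this follows (a maximization
of the residual bounds is unbounded under these constraints); gemkit
minimizes, which reproduces the published worked-example residuals
exactly. Reactions in the `checked` set have rⱼ fixed at 0; excluded
reactions (by default the biomass and exchange reactions, which are
unbalanced by design) are dropped from the constraint set entirely
rather than forced balanced. Compounds named in `zero_mass_ok`
(photons, electrons) get mᵢ ≥ 0 instead of ≥ 1 and are never flagged.
Residuals are reported in both orientations: net production (Sᵀm) and
left-minus-right (its negation), which matches the sign convention of
counting atoms on each side of a printed equation.

Degenerate optima (the same Σz achievable with residuals on different
reactions) are resolved by a deterministic second solve: Σz is pinned
at its optimum and re-minimized with weights 1 + j·10⁻⁶ by reaction
position, preferring residuals on earlier reactions. The documented
`--checked` workflow remains the scientific way to disambiguate.

A genuine limitation: in a linear (tree-like) network a single
unbalanced reaction may be *absorbable* — free compound masses can hide
the imbalance — so the mass check is a consistency check, not an atom
count. The per-reaction formula check is the complementary tool when
formulas are annotated; the test suite demonstrates both behaviours.

## Flux consistency

A reaction is flux inconsistent (blocked) when no solution of Sv = 0
within bounds gives it non-zero flux. The FVA sweep builds one
steady-state LP and re-solves with the objective swapped per reaction:
maximize vⱼ, and if the lower bound allows, minimize; consistent iff
max > 10⁻⁶ or min < −10⁻⁶. With `unrestricted_exchanges`, exchange
bounds are widened to ±default first, giving the
environment-independent (lower) estimate of the blocked fraction.

The FASTCC-style algorithm certifies many reactions per LP: a joint LP
maximizes Σ zⱼ with zⱼ ≤ vⱼ (or ≤ −vⱼ for flipped reversibles),
zⱼ ∈ [0, ε], ε = 10⁻⁴; every reaction carrying flux in the solution is
consistent. Activation is done purely by bound toggling (each link
constraint carries a slack variable that is closed only while its block
member is active), so one problem instance serves the whole run. One
deliberate deviation from the original block-elimination scheme: a
reaction is only ever *declared blocked* by its own rescue LP (maximize
its flux; for reversibles also the flipped direction), never by
absence from a joint-LP support. The original shortcut relies on a
superposition argument that finite flux bounds can in principle defeat;
the certified variant costs a few extra LPs and guarantees the
partition equals the FVA sweep, which the suite asserts on 100
randomized models.

## Constraint-based simulation

FBA maximizes the objective flux over Sv = 0 and bounds. FVA first
maximizes the objective, then constrains it to ≥ fraction × optimum and
min/maximizes each flux, mutating a single problem. Robustness computes
the varied reaction's feasible range by min/max, then fixes its flux at
`steps` evenly spaced values and re-optimizes; infeasible points are
recorded as such (the curve always has exactly `steps` entries), and a
blocked varied reaction degenerates to a single-point curve with a
warning.

Loop removal (tfba) augments the problem per internal reaction j with a
binary direction indicator yⱼ (big-M coupling: vⱼ ≤ uⱼyⱼ,
vⱼ ≥ lⱼ(1−yⱼ)) and a potential difference gⱼ = Sᵀⱼμ over free
per-compound potentials μ, constrained to gⱼ ≤ −1 when yⱼ=1 and
gⱼ ≥ 1 when yⱼ=0 (big-M 1000). Since any flux around an internal cycle
would need potential drops of consistent sign summing to zero, no
internal cycle can carry flux; exchange reactions are exempt. The
loop-law MILP is an implementation choice — the method name is standard
but no published constraint system is being reproduced — so the tests
assert its *properties*: objective equal to plain FBA on loop-free
networks, never larger otherwise, and zero circulation as judged by an
independent sign-pattern enumeration oracle.

`randomsparse` deletes elements (genes through GPR evaluation, or
reactions) in a seeded random order, keeping a deletion only if the
re-optimized objective stays at or above fraction × wild-type. Because
constraints only tighten as deletions accumulate, every element that
survives its own test remains essential in the final network; the suite
verifies minimality exhaustively by single re-deletions. The shuffle
order is the only stochastic element and is fully determined by the
integer seed.

## Gap analysis

Both gap programs use the relaxed balance Sv ≥ 0 — production may
accumulate — as in the formulation they follow; under strict Sv = 0 an
imported compound would always need a consumer and single-exchange
fixes would be artificially infeasible. A compound is *produced* when
some reaction term contributes at least ε of it (direction-aware for
reversibles), with ε = 10⁻³ × default flux limit. ε must stay well
above big-M times the solver's MIP feasibility tolerance
(1000 × 10⁻⁶ = 10⁻³), otherwise indicator constraints can be satisfied
by integrality slack alone; the default has two orders of magnitude of
headroom. gapfind maximizes the number of produced compounds with one
binary per compound and one per candidate producing term; compounds
unproduced at the optimum are blocked, and those with no producing term
at all are root gaps.

gapfill chooses a minimum-penalty subset of candidate additions so that
every target (default: the blocked set) is producible: database
reactions outside the model subset (penalty 1), reversals of
irreversible model reactions (5, optional), and artificial exchanges
for targets and dead-end compounds (10). The ordering prefers
biochemical candidates over directionality changes over topology
hacks; all three weights are configurable. Infeasibility is reported
per target. Proposals are verified two ways in the suite: re-running
gapfind after applying a proposal removes all targeted compounds
(closure), and for small candidate sets the proposal size matches
exhaustive subset enumeration.

## SBML handling

Import uses a built-in parser over the standard-library XML tools,
levels 1–3, reading COBRA kinetic-law parameters (LOWER_BOUND,
UPPER_BOUND, OBJECTIVE_COEFFICIENT) into limits and the objective.
Strict mode rejects the four known dialect deviations; lax mode repairs
each with a warning: decimal stoichiometry at level 1, boundary-suffix
(`_b`) species without `boundaryCondition`, references to undefined
species, and irreversible reactions with negative LOWER_BOUND (the
COBRA bounds are kept). Species flagged `boundaryCondition="true"` are
external by definition and their terms are removed, which is what turns
reactions touching them into exchanges. The repair set is empty exactly
when strict mode succeeds, a property the suite asserts.

Identifier decoding strips the conventional `M_`/`R_` prefixes and a
trailing compartment token matching the compartment attribute, keeping
the original id in the entry's annotation mapping for traceability.
When every species carries a unique `name` attribute, names are used as
compound identifiers (names are what printed equations and curation
notes use); otherwise decoded ids are used. The biomass reaction is the
unique reaction with a non-zero objective coefficient, falling back to
a case-insensitive id search for "biomass"; ties pick the first in
model order with a warning.

Export targets level 2 with COBRA kinetic-law bounds (the dialect the
bulk of published models use). Exchange (one-sided) equations gain a
counterpart species with `boundaryCondition="true"` so the file is
well-formed SBML and a strict re-import reproduces the one-sided form.
Ids are sanitized to the SBML character set with collision suffixes;
original names ride in the `name` attribute. Exported files are
validated against libsbml in the test suite, and cobrapy re-optimizes
an exported model to the same objective value as the native FBA.

## Synthetic models

The fixture generator provides the study conditions for every
algorithm. The toy networks (chain, blocked, loop, branched) are
minimal by design: uptake limit 10 on the nutrient exchange, default
bounds elsewhere, shared hexose formula so the internal conversions are
elementally balanced. Randomized models are balanced by construction:
compound compositions are drawn over 3–6 conserved pseudo-elements and
every reaction rearranges pseudo-element pools, so total pseudo-atom
counts certify mass consistency — a known positive certificate that
makes checker soundness testable. Fault injection mirrors documented
failure modes of published models: stray protons on one side, a
mislabeled compartment, a compound duplicated on both sides, a closed
exchange. Same spec and seed give byte-identical models.

What passing these tests does *not* show: real reconstructions have
thousands of reactions, multiple compartments, annotation noise, and
inconsistencies in combination rather than singly. The generator
establishes algorithmic correctness at desk scale (the suite's random
models have ~6 compounds and ~8 reactions; the agreement and
property tests run on 10–100 of them), not performance or robustness on
genome-scale inputs — though all solver interaction is through the
reused-problem path that makes the sweeps cheap at scale.

## Numerical choices

- LP feasibility tolerance 10⁻⁹; MILP residue/integrality
  classification 10⁻⁶.
- Residual and flux classification threshold 10⁻⁶; FASTCC ε = 10⁻⁴;
  gap production ε = 10⁻³ × default flux limit. None of these are given
  by the source method descriptions; they are chosen to sit far from
  both solver tolerance and the unit-scale quantities they classify.
- big-M values: flux coupling uses the default flux limit; the loop-law
  potential range is 1000; gap indicator constraints use the default
  limit times the largest stoichiometric coefficient.
- Ties and degeneracies: masscheck's lexicographic second solve (above);
  FVA/robustness iterate reactions in model order; flagged reactions are
  reported by descending |residual| with position as tiebreak.
- Degenerate inputs: an empty model is an error in the checks; a blocked
  robustness target yields a one-point curve with a warning; a zero
  wild-type optimum aborts `randomsparse`; contradictory `checked` sets
  make the residual LP infeasible and are diagnosed as such.

## Known limitations

- The fast gap-filling variant (FASTCORE-based) is not implemented; the
  CLI name is reserved and says so.
- Excel workbooks are not read or written; tabular I/O is delimited
  text. Model-specific spreadsheet parsers for individual published
  models are out of scope.
- No exact rational LP backend is bundled; the registry accepts one as
  a plugin, and such a backend should declare itself LP-only so MILP
  analyses refuse it.
- Loop removal solves one MILP per objective; FVA under loop removal is
  correspondingly expensive.
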