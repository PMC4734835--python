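# gemkit

A portable toolkit for curating and simulating genome-scale metabolic
models (GEMs). It represents models in a modular, line-oriented YAML
format that plays well with version control, imports SBML (levels 1–3,
standard or COBRA dialect, with optional automatic repair of common
inconsistencies) and tab-delimited annotation tables, checks models for
stoichiometric and flux inconsistencies, and runs the standard
constraint-based analyses — all from one-line commands or a small Python
API.

## Who it is for

Model curators who need to find out *why* a published reconstruction
misbehaves (unbalanced equations, mislabeled compartments, blocked
pathways, missing boundary conditions) and modellers who want FBA-family
simulations without a MATLAB dependency.

## What it computes

Let S be the compound-by-reaction stoichiometric matrix, v the flux
vector with bounds l ≤ v ≤ u.

- **Stoichiometric (mass) consistency** (`masscheck`). A network is
  consistent when strictly positive compound masses m exist with
  Sᵀm = 0 over internal reactions. The compound variant solves
  max Σᵢ zᵢ s.t. Sᵀm = 0, mᵢ ≥ zᵢ, zᵢ ∈ [0,1]: compounds whose mass
  stays below 1 are the sources of inconsistency. The reaction variant
  gives every reaction a residual r bounded by |rⱼ| ≤ zⱼ, requires
  mᵢ ≥ 1, and minimizes Σⱼ zⱼ: non-zero residuals localize the broken
  equations, and a `--checked` set pins residuals of known-balanced
  reactions at zero so the residual converges on the true faults.
- **Flux consistency** (`fluxcheck`). A reaction is blocked when no
  solution of Sv = 0 gives it non-zero flux; computed either by an FVA
  sweep (one reused LP, objective swapped per reaction) or by a
  FASTCC-style block elimination.
- **Formula and charge balance** (`formulacheck`, `chargecheck`)
  wherever compound annotations permit.
- **Simulation**: FBA, loopless FBA (`--loop-removal tfba`, a
  MILP loop-law forbidding internal cycles), FVA, robustness sweeps and
  random minimal networks (`randomsparse`, successive random deletions
  leaving every surviving gene or reaction essential).
- **Gap analysis** (`gapfill`): MILPs that identify unproducible
  compounds and propose a minimum-penalty set of database reactions,
  reaction reversals or artificial exchanges that restore production.

## Worked example

The reaction-based mass check on a two-reaction model in which
glucose-phosphate isomerization appears both with and without two stray
protons (a real failure mode in a published model):

```sh
$ gemkit-fixtures make glucose_pair --dest pair
$ gemkit-model --model pair masscheck --type=reaction \
      --no-default-exclude --checked RR08939
RR00610	-2	2	[c]: D-Glucose 1-phosphate + (2) H+ <==> D-Glucose 6-phosphate
```

Columns: reaction, net-production residual, left-minus-right residual,
equation. The left-minus-right value +2 says the left side of RR00610
carries two hydrogen atoms too many — exactly the two spurious protons —
while the checked reaction RR08939 stays residual-free. The same
workflow on a full model reduces hundreds of suspect reactions to a
short list for manual inspection.

From Python:

```python
>>> from gemkit import make_fixture, masscheck_reactions
>>> model = make_fixture("glucose_pair")
>>> result = masscheck_reactions(model, exclude=set(), checked={"RR08939"})
>>> result.flagged
[('RR00610', -2.0)]
>>> result.left_minus_right("RR00610")
2.0
```

The `examples/` directory holds short narrative scripts, one per
capability (consistency checking, growth simulation, loop removal and
minimal networks, gap filling, import/export).

## Command-line surface

`gemkit-model` (run against a model directory): `fba`, `fva`,
`robustness`, `randomsparse`, `masscheck`, `fluxcheck`, `formulacheck`,
`chargecheck`, `gapfill`, `search`, `sbmlexport`, `tabexport`; global
`--model DIR`, `--solver NAME`, `-v`. `gemkit-import`: `sbml`,
`sbml-strict`, `table`. `gemkit-fixtures make KIND` writes the bundled
toy models. Reports are TSV on stdout, diagnostics on stderr; exit codes
are 0 (success), 1 (analysis error), 2 (usage error).

## Format notes

The native format is a `model.yaml` with sections `name`, `biomass`,
`default_flux_limit`, `compounds`, `reactions`, `model` (subset of a
broader reaction database), `media` and `limits`; any section can pull
records from further YAML or tab-separated files via
`- include: path`. Unknown record keys survive read/write round trips
verbatim, and serialization is deterministic with one scalar per line so
that edits diff cleanly. See `docs/methods.md` for the model and
algorithm details and the design decisions behind them.
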