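"""Gap analysis: unproducible compounds and minimal gap-filling proposals.

``gapfind`` poses a MILP with a binary production indicator per compound:
a compound counts as produced when some reaction term contributes at
least ``epsilon`` net production of it at steady state (direction-aware
for reversible reactions).  Maximizing the number of produced compounds
and reading off the zeros yields the blocked set; root gaps are the
subset with no producing reaction term at all.

``gapfill`` proposes a minimum-penalty set of additions that make a set
of target compounds producible: database reactions outside the model
subset, reversals of irreversible model reactions (optional), and
artificial exchange reactions.  Penalties default to preferring
biochemical candidates (database 1) over directionality changes
(reversal 5) over topology hacks (artificial exchange 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

from .equation import Compound, Direction, Equation
from .lp import Problem
from .model import Model, ReactionEntry, matrix_view

# Production threshold relative to the default flux limit.  It must stay
# well above big-M times the solver's MIP feasibility tolerance, or the
# indicator constraints can be satisfied with integrality slack alone.
PRODUCTION_EPSILON_SCALE = 1e-3


class GapError(Exception):
    pass


@dataclass
class GapReport:
    blocked_compounds: set[Compound]
    root_gaps: set[Compound]


@dataclass
class GapProposal:
    added_reactions: list[tuple[str, str]]  # (reaction id, origin)
    producible: set[Compound]
    penalty: float

    def added_ids(self) -> set[str]:
        return {rid for rid, _ in self.added_reactions}


def _epsilon(model: Model) -> float:
    return PRODUCTION_EPSILON_SCALE * model.default_flux_limit


def _relaxed_balance(problem: Problem, matrix) -> None:
    # Production may accumulate (S v >= 0): a compound needs a producer
    # but not necessarily a consumer, as in the cited gap formulations.
    for rid in matrix.reactions:
        problem.add_variable(f"v_{rid}", *matrix.bounds[rid])
    for compound in matrix.compounds:
        coeffs = {
            f"v_{rid}": float(matrix.value(compound, rid))
            for rid in matrix.reactions
            if matrix.value(compound, rid) != 0}
        if coeffs:
            problem.add_constraint(coeffs, ">=", 0.0)


def _producing_terms(matrix, bounds) -> dict[Compound, list[tuple[str, float]]]:
    """compound -> [(reaction, stoichiometry)] for terms able to net-produce it."""
    producers: dict[Compound, list[tuple[str, float]]] = {}
    for (compound, rid), value in matrix.entries.items():
        lower, upper = bounds[rid]
        value = float(value)
        if (value > 0 and upper > 0) or (value < 0 and lower < 0):
            producers.setdefault(compound, []).append((rid, value))
    return producers


def gapfind(
    model: Model,
    epsilon: float | None = None,
    solver: str | None = None,
) -> GapReport:
    """Identify compounds with no feasible steady-state production."""
    matrix = matrix_view(model)
    if epsilon is None:
        epsilon = _epsilon(model)
    big_m = model.default_flux_limit * max(
        (abs(float(v)) for v in matrix.entries.values()), default=1.0)

    problem = Problem()
    _relaxed_balance(problem, matrix)
    producers = _producing_terms(matrix, matrix.bounds)
    root_gaps = {c for c in matrix.compounds if not producers.get(c)}

    objective = {}
    for compound in matrix.compounds:
        problem.add_variable(f"x_{compound}", binary=True)
        objective[f"x_{compound}"] = 1.0
        terms = producers.get(compound, [])
        if not terms:
            problem.set_bounds(f"x_{compound}", 0.0, 0.0)
            continue
        indicator_sum: dict[str, float] = {}
        for rid, coef in terms:
            w = f"w_{compound}_{rid}"
            problem.add_variable(w, binary=True)
            # w=1 -> this term net-produces at least epsilon.
            problem.add_constraint(
                {f"v_{rid}": coef, w: -(epsilon + big_m)}, ">=", -big_m)
            indicator_sum[w] = 1.0
        indicator_sum[f"x_{compound}"] = -1.0
        problem.add_constraint(indicator_sum, ">=", 0.0)

    problem.set_objective(objective, "max")
    result = problem.solve(solver)
    if not result.optimal:
        raise GapError(f"gapfind MILP unexpectedly {result.status}")
    blocked = {
        c for c in matrix.compounds if result.value(f"x_{c}") < 0.5}
    return GapReport(blocked, root_gaps)


DEFAULT_PENALTIES = {
    "database": 1.0,
    "reversal": 5.0,
    "artificial-exchange": 10.0,
}


def _union_model(model: Model, database: Model) -> Model:
    """Model context (media, limits, defaults) plus database-only reactions."""
    union = model.copy()
    union.model_subset = None
    for rid, entry in database.reactions.items():
        if rid not in union.reactions:
            union.add_reaction(
                ReactionEntry(rid, entry.equation, entry.genes,
                              entry.subsystem, entry.ec, dict(entry.extra)))
    return union


def gapfill(
    model: Model,
    database: Model | None = None,
    targets: set[Compound] | None = None,
    penalties: dict[str, float] | None = None,
    allow_reversals: bool = True,
    epsilon: float | None = None,
    solver: str | None = None,
) -> GapProposal:
    """Propose a minimum-penalty set of additions making targets producible.

    ``database`` defaults to the model itself, in which case the candidate
    reactions are those outside ``model_subset`` (the broader-database
    pattern); ``targets`` defaults to the gapfind blocked set.  Raises
    :class:`GapError` naming the unfixable targets when no candidate set
    suffices.
    """
    if database is None:
        database = model
    if targets is None:
        targets = gapfind(
            model, epsilon=epsilon, solver=solver).blocked_compounds
    targets = set(targets)
    if not targets:
        return GapProposal([], set(), 0.0)
    pen = dict(DEFAULT_PENALTIES)
    if penalties:
        pen.update(penalties)
    if epsilon is None:
        epsilon = _epsilon(model)

    model_ids = set(model.subset_ids())
    union = _union_model(model, database)
    matrix = matrix_view(union)
    unknown = targets - set(matrix.compounds)
    if unknown:
        raise GapError(
            "target compounds absent from the network: "
            + ", ".join(str(c) for c in sorted(unknown, key=str)))
    x = union.default_flux_limit
    big_m = x * max(
        (abs(float(v)) for v in matrix.entries.values()), default=1.0)

    # Candidate sets, decided before the constraint system is built.
    db_candidates = [rid for rid in matrix.reactions if rid not in model_ids]
    reversal_candidates = []
    if allow_reversals:
        for rid in matrix.reactions:
            if rid in model_ids:
                lower, upper = matrix.bounds[rid]
                if lower >= 0 and upper > 0:
                    reversal_candidates.append(rid)

    # Widest-case bounds decide which terms can ever produce a compound
    # and which compounds are dead ends needing an artificial exchange.
    wide_bounds = dict(matrix.bounds)
    for rid in reversal_candidates:
        wide_bounds[rid] = (-x, wide_bounds[rid][1])
    producers = _producing_terms(matrix, wide_bounds)
    dead_ends = {c for c in matrix.compounds if not producers.get(c)}
    artificial = sorted(targets | dead_ends, key=str)

    problem = Problem()
    for rid in matrix.reactions:
        lower, upper = matrix.bounds[rid]
        if rid in reversal_candidates:
            lower = -x
        problem.add_variable(f"v_{rid}", lower, upper)
    for compound in artificial:
        problem.add_variable(f"v_xex_{compound}", -x, x)
    for compound in matrix.compounds:
        coeffs = {
            f"v_{rid}": float(matrix.value(compound, rid))
            for rid in matrix.reactions
            if matrix.value(compound, rid) != 0}
        if compound in set(artificial):
            # compound <=> (outside); negative flux imports (produces) it.
            coeffs[f"v_xex_{compound}"] = -1.0
        if coeffs:
            # Accumulation allowed, matching the gapfind relaxation.
            problem.add_constraint(coeffs, ">=", 0.0)

    objective: dict[str, float] = {}
    origin: dict[str, str] = {}

    def gate(name: str, kind: str) -> str:
        y = f"y_{name}"
        problem.add_variable(y, binary=True)
        objective[y] = pen[kind]
        origin[name] = kind
        return y

    for rid in db_candidates:
        y = gate(rid, "database")
        lower, upper = matrix.bounds[rid]
        problem.add_constraint({f"v_{rid}": 1.0, y: -upper}, "<=", 0.0)
        problem.add_constraint({f"v_{rid}": 1.0, y: -lower}, ">=", 0.0)
    for rid in reversal_candidates:
        y = gate(f"rev_{rid}", "reversal")
        # y=0 keeps the original non-negative lower bound.
        problem.add_constraint({f"v_{rid}": 1.0, y: x}, ">=", 0.0)
    for compound in artificial:
        y = gate(f"xex_{compound}", "artificial-exchange")
        problem.add_constraint(
            {f"v_xex_{compound}": 1.0, y: -x}, "<=", 0.0)
        problem.add_constraint(
            {f"v_xex_{compound}": 1.0, y: x}, ">=", 0.0)

    # Production requirement per target.
    candidate_producers = _producing_terms(matrix, wide_bounds)
    for compound in sorted(targets, key=str):
        terms: list[tuple[str, float]] = [
            (f"v_{rid}", coef)
            for rid, coef in candidate_producers.get(compound, [])]
        if compound in set(artificial):
            terms.append((f"v_xex_{compound}", -1.0))
        indicator_sum: dict[str, float] = {}
        for var, coef in terms:
            w = f"w_{compound}_{var}"
            problem.add_variable(w, binary=True)
            problem.add_constraint(
                {var: coef, w: -(epsilon + big_m)}, ">=", -big_m)
            indicator_sum[w] = 1.0
        if not indicator_sum:
            raise GapError(f"target {compound} has no candidate producer")
        problem.add_constraint(indicator_sum, ">=", 1.0)

    problem.set_objective(objective, "min")
    result = problem.solve(solver)
    if result.status == "infeasible":
        unfixable = _probe_unfixable(
            model, database, targets, allow_reversals, epsilon, solver)
        raise GapError(
            "no candidate set makes these targets producible: "
            + ", ".join(str(c) for c in sorted(unfixable, key=str)))
    if not result.optimal:
        raise GapError(f"gapfill MILP unexpectedly {result.status}")

    added = [
        (name, kind) for name, kind in origin.items()
        if result.value(f"y_{name}") > 0.5]
    return GapProposal(added, set(targets), result.objective_value)


def _probe_unfixable(model, database, targets, allow_reversals, epsilon, solver):
    unfixable = []
    for compound in targets:
        try:
            gapfill(
                model, database, {compound},
                allow_reversals=allow_reversals, epsilon=epsilon,
                solver=solver)
        except GapError:
            unfixable.append(compound)
    return unfixable or list(targets)


def apply_proposal(model: Model, database: Model, proposal: GapProposal) -> Model:
    """Return a copy of the model with the proposed additions applied."""
    result = model.copy()
    x = result.default_flux_limit
    for name, kind in proposal.added_reactions:
        if kind == "database":
            entry = database.reactions[name]
            if name in result.reactions:
                if result.model_subset is not None:
                    result.model_subset.add(name)
            else:
                result.add_reaction(
                    ReactionEntry(name, entry.equation, entry.genes,
                                  entry.subsystem, entry.ec,
                                  dict(entry.extra)))
                if result.model_subset is not None:
                    result.model_subset.add(name)
        elif kind == "reversal":
            rid = name[len("rev_"):]
            entry = result.reactions[rid]
            entry.equation = Equation(
                entry.equation.left, entry.equation.right, Direction.BOTH)
            limits = result.limits_map()
            if rid in limits:
                limits[rid].lower = -x
        elif kind == "artificial-exchange":
            compound = Compound.parse(name[len("xex_"):])
            rid = f"EX_gap_{len(result.reactions)}"
            result.add_reaction(ReactionEntry(
                rid,
                Equation([(compound, Fraction(1))], [], Direction.BOTH)))
            if result.model_subset is not None:
                result.model_subset.add(rid)
        else:
            raise GapError(f"unknown proposal origin {kind!r}")
    return result
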