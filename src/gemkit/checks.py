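"""Model-quality checks.

Stoichiometric (mass) consistency
---------------------------------
A network is stoichiometrically consistent when strictly positive compound
masses ``m`` exist with ``S^T m = 0`` over the internal reactions: every
internal reaction then conserves mass.  Two LP variants localize failures:

*Compound-based*: maximize the number of compounds that can attain mass at
least 1 (``max sum(z)`` s.t. ``S^T m = 0``, ``m_i >= z_i``, ``z in
[0,1]``).  Compounds whose mass stays below 1 at the optimum are the
sources of inconsistency.

*Reaction-based*: give every reaction a mass residual ``r_j`` bounded by
``|r_j| <= z_j``, require all masses at least 1, and minimize ``sum(z)``.
Reactions carrying a non-zero residual are candidates of inconsistency;
the ``checked`` set fixes residuals of reactions known to be balanced at
zero so the residual converges onto the remaining faults.  Residuals are
reported in both orientations: net production (``S^T m``) and
left-minus-right (its negation), the convention used when counting atoms
on each side of a printed equation.

By default both variants exclude the biomass and exchange reactions, which
are unbalanced by design, and a ``zero_mass_ok`` set lifts the positive
mass requirement for pseudo-compounds such as photons or electrons.

Flux consistency
----------------
A reaction is blocked (flux inconsistent) when no steady-state flux
distribution gives it a non-zero flux.  Two implementations: an FVA sweep
(maximize, and for reversible reactions also minimize, each flux in turn
on one reused LP) and a FASTCC-style block elimination that certifies many
reactions per LP.

Formula and charge balance apply per reaction whenever compound formulas
or charges are annotated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .equation import Compound
from .formula import Formula
from .lp import Problem, Solution
from .model import Model, StoichiometricMatrix, matrix_view

RESIDUAL_TOL = 1e-6
FLUX_TOL = 1e-6
FASTCC_EPSILON = 1e-4


class ConsistencyError(Exception):
    pass


def _default_exclude(model: Model) -> set[str]:
    exclude = set(model.exchange_ids())
    if model.biomass is not None:
        exclude.add(model.biomass)
    return exclude


@dataclass
class MassAssignment:
    """Result of the compound-based stoichiometric check."""

    masses: dict[Compound, float]
    indicators: dict[Compound, float]
    flagged: set[Compound]
    objective: float
    checked_reactions: list[str]


@dataclass
class ResidualAssignment:
    """Result of the reaction-based stoichiometric check.

    ``residuals`` maps every checked reaction to its net-production
    residual ``r_j = (S^T m)_j``; ``left_minus_right`` is the negation.
    ``flagged`` lists reactions with ``|r| > tol``, largest first.
    """

    masses: dict[Compound, float]
    residuals: dict[str, float]
    bounds: dict[str, float]
    flagged: list[tuple[str, float]]
    objective: float

    def left_minus_right(self, reaction_id: str) -> float:
        return -self.residuals[reaction_id]


def masscheck_compounds(
    model: Model,
    exclude: set[str] | None = None,
    zero_mass_ok: set[Compound] | None = None,
    tol: float = RESIDUAL_TOL,
    solver: str | None = None,
) -> MassAssignment:
    """Find compounds that cannot attain a positive mass."""
    matrix = matrix_view(model)
    if not matrix.reactions:
        raise ConsistencyError("model has no reactions to check")
    if exclude is None:
        exclude = _default_exclude(model)
    zero_mass_ok = zero_mass_ok or set()
    checked = [r for r in matrix.reactions if r not in exclude]

    problem = Problem()
    for compound in matrix.compounds:
        problem.add_variable(f"m_{compound}", 0.0)
        if compound not in zero_mass_ok:
            problem.add_variable(f"z_{compound}", 0.0, 1.0)
            problem.add_constraint(
                {f"m_{compound}": 1.0, f"z_{compound}": -1.0}, ">=", 0.0)
    for rid in checked:
        coeffs = {
            f"m_{c}": float(v)
            for c, v in matrix.column(rid).items()}
        if coeffs:
            problem.add_constraint(coeffs, "==", 0.0)
    objective = {
        f"z_{c}": 1.0 for c in matrix.compounds if c not in zero_mass_ok}
    problem.set_objective(objective, "max")
    result = problem.solve(solver)
    if not result.optimal:
        raise ConsistencyError(
            f"compound mass check LP unexpectedly {result.status}")

    masses = {c: result.value(f"m_{c}") for c in matrix.compounds}
    indicators = {
        c: result.value(f"z_{c}")
        for c in matrix.compounds if c not in zero_mass_ok}
    flagged = {
        c for c in matrix.compounds
        if c not in zero_mass_ok and masses[c] < 1.0 - tol}
    return MassAssignment(
        masses, indicators, flagged, result.objective_value, checked)


def masscheck_reactions(
    model: Model,
    exclude: set[str] | None = None,
    checked: set[str] | None = None,
    zero_mass_ok: set[Compound] | None = None,
    tol: float = RESIDUAL_TOL,
    solver: str | None = None,
) -> ResidualAssignment:
    """Localize mass inconsistency onto individual reactions.

    ``exclude`` drops reactions from the check entirely (their balance is
    not required); ``checked`` keeps them in the system with their residual
    fixed at zero.  A second solve with reaction-indexed weights breaks
    ties among degenerate optima deterministically.
    """
    matrix = matrix_view(model)
    if not matrix.reactions:
        raise ConsistencyError("model has no reactions to check")
    if exclude is None:
        exclude = _default_exclude(model)
    checked = checked or set()
    zero_mass_ok = zero_mass_ok or set()
    included = [r for r in matrix.reactions if r not in exclude]

    problem = Problem()
    for compound in matrix.compounds:
        lower = 0.0 if compound in zero_mass_ok else 1.0
        problem.add_variable(f"m_{compound}", lower)
    for rid in included:
        if rid in checked:
            problem.add_variable(f"r_{rid}", 0.0, 0.0)
        else:
            problem.add_variable(f"r_{rid}")
        problem.add_variable(f"z_{rid}", 0.0)
        # |r| <= z
        problem.add_constraint({f"r_{rid}": 1.0, f"z_{rid}": -1.0}, "<=", 0.0)
        problem.add_constraint({f"r_{rid}": -1.0, f"z_{rid}": -1.0}, "<=", 0.0)
        coeffs = {
            f"m_{c}": float(v) for c, v in matrix.column(rid).items()}
        coeffs[f"r_{rid}"] = -1.0
        problem.add_constraint(coeffs, "==", 0.0)

    problem.set_objective({f"z_{rid}": 1.0 for rid in included}, "min")
    result = problem.solve(solver)
    if result.status == "infeasible":
        raise ConsistencyError(
            "reaction mass check is infeasible; the checked/fixed residual "
            f"constraints contradict the positive-mass requirement "
            f"(checked reactions: {sorted(checked)})")
    if not result.optimal:
        raise ConsistencyError(
            f"reaction mass check LP unexpectedly {result.status}")
    total = result.objective_value

    # Tie-break pass: among optima of sum(z), prefer pushing residual onto
    # the earliest reactions so that the reported set is deterministic.
    problem.add_constraint(
        {f"z_{rid}": 1.0 for rid in included}, "<=", total + tol)
    weights = {
        f"z_{rid}": 1.0 + 1e-6 * j for j, rid in enumerate(included)}
    problem.set_objective(weights, "min")
    second = problem.solve(solver)
    if second.optimal:
        result = second

    masses = {c: result.value(f"m_{c}") for c in matrix.compounds}
    residuals = {rid: result.value(f"r_{rid}") for rid in included}
    bounds = {rid: result.value(f"z_{rid}") for rid in included}
    flagged = sorted(
        ((rid, r) for rid, r in residuals.items() if abs(r) > tol),
        key=lambda item: (-abs(item[1]), included.index(item[0])))
    return ResidualAssignment(masses, residuals, bounds, flagged, total)


@dataclass
class BalanceResult:
    """Per-reaction balance report for formula or charge checks."""

    flagged: list[tuple[str, object, object]]  # (reaction, left, right)
    checked: list[str]
    skipped: list[str]


def formulacheck(
    model: Model, exclude: set[str] | None = None
) -> BalanceResult:
    """Check elemental balance reaction by reaction.

    Reactions involving a compound without a parsed formula are skipped
    (and counted); biomass and exchange reactions are excluded by default.
    """
    if exclude is None:
        exclude = _default_exclude(model)
    flagged, checked, skipped = [], [], []
    for rid in model.subset_ids():
        if rid in exclude:
            continue
        entry = model.reactions[rid]
        sides = []
        missing = False
        for terms in (entry.equation.left, entry.equation.right):
            total = Formula()
            for compound, value in terms:
                centry = model.compounds.get(compound)
                if centry is None or centry.formula is None:
                    missing = True
                    break
                total = total + centry.formula * value
            if missing:
                break
            sides.append(total)
        if missing:
            skipped.append(rid)
            continue
        checked.append(rid)
        left, right = sides
        if left != right:
            flagged.append((rid, left, right))
    return BalanceResult(flagged, checked, skipped)


def chargecheck(
    model: Model, exclude: set[str] | None = None
) -> BalanceResult:
    """Check net charge balance reaction by reaction."""
    if exclude is None:
        exclude = _default_exclude(model)
    flagged, checked, skipped = [], [], []
    for rid in model.subset_ids():
        if rid in exclude:
            continue
        entry = model.reactions[rid]
        sides = []
        missing = False
        for terms in (entry.equation.left, entry.equation.right):
            total = Fraction(0)
            for compound, value in terms:
                centry = model.compounds.get(compound)
                if centry is None or centry.charge is None:
                    missing = True
                    break
                total += value * centry.charge
            if missing:
                break
            sides.append(total)
        if missing:
            skipped.append(rid)
            continue
        checked.append(rid)
        left, right = sides
        if left != right:
            flagged.append((rid, left, right))
    return BalanceResult(flagged, checked, skipped)


@dataclass
class FluxConsistencyResult:
    consistent: set[str]
    inconsistent: set[str]
    method: str

    @property
    def blocked(self) -> set[str]:
        return self.inconsistent


def _steady_state_problem(
    matrix: StoichiometricMatrix,
    unrestricted_exchanges: bool,
    model: Model,
) -> Problem:
    problem = Problem()
    exchanges = model.exchange_ids()
    x = model.default_flux_limit
    for rid in matrix.reactions:
        lower, upper = matrix.bounds[rid]
        if unrestricted_exchanges and rid in exchanges:
            lower, upper = -x, x
        problem.add_variable(f"v_{rid}", lower, upper)
    for compound in matrix.compounds:
        coeffs = {
            f"v_{rid}": float(matrix.value(compound, rid))
            for rid in matrix.reactions
            if matrix.value(compound, rid) != 0}
        if coeffs:
            problem.add_constraint(coeffs, "==", 0.0)
    return problem


def fluxcheck_fva(
    model: Model,
    unrestricted_exchanges: bool = False,
    tol: float = FLUX_TOL,
    solver: str | None = None,
) -> FluxConsistencyResult:
    """Classify every reaction as flux consistent or blocked by FVA sweep.

    One steady-state LP is built and reused; only the objective changes
    per reaction.  A reaction is consistent when its maximum flux exceeds
    ``tol`` or, if reversible, its minimum flux is below ``-tol``.
    """
    matrix = matrix_view(model)
    problem = _steady_state_problem(matrix, unrestricted_exchanges, model)
    consistent, blocked = set(), set()
    for rid in matrix.reactions:
        problem.set_objective({f"v_{rid}": 1.0}, "max")
        res = problem.solve(solver)
        if res.optimal and res.objective_value > tol:
            consistent.add(rid)
            continue
        lower = problem.bounds(f"v_{rid}")[0]
        if lower < 0:
            problem.set_objective({f"v_{rid}": 1.0}, "min")
            res = problem.solve(solver)
            if res.optimal and res.objective_value < -tol:
                consistent.add(rid)
                continue
        blocked.add(rid)
    return FluxConsistencyResult(consistent, blocked, "fva")


def fluxcheck_fastcc(
    model: Model,
    epsilon: float = FASTCC_EPSILON,
    unrestricted_exchanges: bool = False,
    tol: float = FLUX_TOL,
    solver: str | None = None,
) -> FluxConsistencyResult:
    """FASTCC-style flux consistency check.

    A joint LP pushes many not-yet-certified reactions towards a flux of
    at least ``epsilon`` at once; any reaction carrying flux in the
    solution is certified consistent.  Reactions the block steps fail to
    certify fall back to individual rescue LPs (maximize the flux, and for
    reversible reactions also the flipped direction); only these
    per-reaction LPs ever declare a reaction blocked, so the partition
    matches the FVA sweep by construction.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    matrix = matrix_view(model)
    problem = _steady_state_problem(matrix, unrestricted_exchanges, model)
    reactions = list(matrix.reactions)
    reversible = {
        rid for rid in reactions if problem.bounds(f"v_{rid}")[0] < 0}

    # Auxiliary block variables: zf_j <= v_j (forward orientation) and
    # zr_j <= -v_j (flipped); activated per block by opening z to [0, eps]
    # and closing the slack that otherwise disables the link constraint.
    wide = 2.0 * model.default_flux_limit
    for rid in reactions:
        problem.add_variable(f"zf_{rid}", 0.0, 0.0)
        problem.add_variable(f"sf_{rid}", 0.0, wide)
        problem.add_constraint(
            {f"zf_{rid}": 1.0, f"v_{rid}": -1.0, f"sf_{rid}": -1.0},
            "<=", 0.0)
        if rid in reversible:
            problem.add_variable(f"zr_{rid}", 0.0, 0.0)
            problem.add_variable(f"sr_{rid}", 0.0, wide)
            problem.add_constraint(
                {f"zr_{rid}": 1.0, f"v_{rid}": 1.0, f"sr_{rid}": -1.0},
                "<=", 0.0)

    consistent: set[str] = set()
    blocked: set[str] = set()

    def support(solution: Solution) -> set[str]:
        return {
            rid for rid in reactions
            if abs(solution.value(f"v_{rid}")) > tol}

    def block_lp(members: list[str], orientation: dict[str, int]) -> Solution:
        active = []
        for rid in members:
            tag = "f" if orientation.get(rid, 1) > 0 else "r"
            problem.set_bounds(f"z{tag}_{rid}", 0.0, epsilon)
            problem.set_bounds(f"s{tag}_{rid}", 0.0, 0.0)
            active.append((f"z{tag}_{rid}", f"s{tag}_{rid}"))
        problem.set_objective({z: 1.0 for z, _ in active}, "max")
        solution = problem.solve(solver)
        for z, s in active:
            problem.set_bounds(z, 0.0, 0.0)
            problem.set_bounds(s, 0.0, wide)
        if not solution.optimal:
            raise ConsistencyError(
                f"FASTCC block LP unexpectedly {solution.status}")
        return solution

    def rescue(rid: str) -> bool:
        problem.set_objective({f"v_{rid}": 1.0}, "max")
        res = problem.solve(solver)
        if res.optimal and res.objective_value > tol:
            consistent.update(support(res))
            return True
        if rid in reversible:
            problem.set_objective({f"v_{rid}": 1.0}, "min")
            res = problem.solve(solver)
            if res.optimal and res.objective_value < -tol:
                consistent.update(support(res))
                return True
        return False

    irreversible = [r for r in reactions if r not in reversible]
    if irreversible:
        consistent.update(support(block_lp(irreversible, {})))

    remaining = [r for r in reactions if r not in consistent]
    orientation = {rid: 1 for rid in remaining}
    flipped = False
    singleton = False
    while remaining:
        if singleton:
            rid = remaining[0]
            if rescue(rid):
                pass
            else:
                blocked.add(rid)
            remaining = [r for r in remaining if r not in consistent
                         and r not in blocked]
            continue
        before = len(consistent)
        consistent.update(support(block_lp(remaining, orientation)))
        if len(consistent) > before:
            remaining = [r for r in remaining if r not in consistent]
            flipped = False
            continue
        flippable = [r for r in remaining if r in reversible]
        if flipped or not flippable:
            singleton = True
            flipped = False
        else:
            for rid in flippable:
                orientation[rid] = -orientation[rid]
            flipped = True

    return FluxConsistencyResult(consistent, blocked, "fastcc")


def blocked_fraction_by_subsystem(
    model: Model,
    pathway_map: dict[str, str] | None = None,
    method: str = "fva",
    unrestricted_exchanges: bool = True,
    solver: str | None = None,
) -> dict[str, tuple[int, int, float]]:
    """Fraction of blocked internal reactions per metabolic pathway.

    Subsystem annotations are mapped to pathways through ``pathway_map``;
    unmapped or missing subsystems fall into ``"other"``.  Returns
    ``pathway -> (n_reactions, n_blocked, fraction)``.
    """
    pathway_map = pathway_map or {}
    if method == "fva":
        result = fluxcheck_fva(
            model, unrestricted_exchanges=unrestricted_exchanges,
            solver=solver)
    elif method == "fastcc":
        result = fluxcheck_fastcc(
            model, unrestricted_exchanges=unrestricted_exchanges,
            solver=solver)
    else:
        raise ValueError(f"unknown flux check method {method!r}")

    exchanges = model.exchange_ids()
    counts: dict[str, list[int]] = {}
    for rid in model.subset_ids():
        if rid in exchanges:
            continue
        subsystem = model.reactions[rid].subsystem
        pathway = pathway_map.get(subsystem, "other") \
            if subsystem is not None else "other"
        row = counts.setdefault(pathway, [0, 0])
        row[0] += 1
        if rid in result.inconsistent:
            row[1] += 1
    return {
        pathway: (n, b, b / n if n else 0.0)
        for pathway, (n, b) in sorted(counts.items())}
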