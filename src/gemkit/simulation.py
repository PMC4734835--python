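"""Constraint-based simulation.

All analyses share one steady-state problem (``S v = 0`` with resolved
flux bounds) and mutate it in place — swapping the objective for each FVA
reaction, pinning one flux per robustness step, zeroing bounds for each
tentative deletion in the random minimal network — instead of rebuilding
it per solve.

Loop removal (``loop_removal="tfba"``) augments the problem with
thermodynamic loop-law constraints: every internal reaction gets a binary
direction indicator coupled to its flux by big-M constraints, and a
potential-difference variable tied to per-compound potentials whose sign
must oppose the chosen direction.  Because potential differences around
any internal cycle sum to zero, no internal cycle can carry flux that is
not driven through an exchange reaction.  Exchange reactions are exempt.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .genes import evaluate_genes, iter_genes
from .lp import Problem
from .model import Model, matrix_view

FLUX_TOL = 1e-6


class SimulationError(Exception):
    pass


class InfeasibleError(SimulationError):
    pass


class UnboundedError(SimulationError):
    pass


@dataclass
class FluxSolution:
    objective_reaction: str
    objective_value: float
    fluxes: dict[str, float]
    loop_removal: str = "none"

    def flux(self, reaction_id: str) -> float:
        return self.fluxes[reaction_id]


@dataclass
class RobustnessCurve:
    varied_reaction: str
    points: list[tuple[float, float | None]]  # (fixed flux, objective|None)
    warnings: list[str] = field(default_factory=list)


@dataclass
class MinimalNetwork:
    mode: str  # 'genes' | 'reactions'
    retained: set[str]
    deleted: list[str]
    seed: int
    objective_value: float


def _objective_reaction(model: Model, objective: str | None) -> str:
    if objective is None:
        objective = model.biomass
    if objective is None:
        raise SimulationError(
            "no objective reaction given and no biomass designated")
    return objective


def _flux_problem(
    model: Model, loop_removal: str = "none"
) -> tuple[Problem, list[str]]:
    matrix = matrix_view(model)
    problem = Problem()
    for rid in matrix.reactions:
        problem.add_variable(f"v_{rid}", *matrix.bounds[rid])
    for compound in matrix.compounds:
        coeffs = {
            f"v_{rid}": float(matrix.value(compound, rid))
            for rid in matrix.reactions
            if matrix.value(compound, rid) != 0}
        if coeffs:
            problem.add_constraint(coeffs, "==", 0.0)

    if loop_removal == "tfba":
        _add_loop_law(problem, model, matrix)
    elif loop_removal != "none":
        raise SimulationError(f"unknown loop removal mode {loop_removal!r}")
    return problem, list(matrix.reactions)


def _add_loop_law(problem: Problem, model: Model, matrix) -> None:
    big_m = model.default_flux_limit
    pot_m = 1000.0
    exchanges = model.exchange_ids()
    internal = [r for r in matrix.reactions if r not in exchanges]
    for compound in matrix.compounds:
        problem.add_variable(f"mu_{compound}")
    for rid in internal:
        problem.add_variable(f"y_{rid}", binary=True)
        problem.add_variable(f"g_{rid}")
        lower, upper = matrix.bounds[rid]
        # y=1 allows forward flux only; y=0 reverse only.
        problem.add_constraint(
            {f"v_{rid}": 1.0, f"y_{rid}": -max(upper, 0.0)}, "<=", 0.0)
        problem.add_constraint(
            {f"v_{rid}": 1.0, f"y_{rid}": min(lower, 0.0)}, ">=",
            min(lower, 0.0))
        # g = S^T mu for this reaction's column.
        coeffs = {
            f"mu_{c}": float(v) for c, v in matrix.column(rid).items()}
        coeffs[f"g_{rid}"] = -1.0
        problem.add_constraint(coeffs, "==", 0.0)
        # Potential difference opposes the direction: y=1 -> g <= -1,
        # y=0 -> g >= 1.
        problem.add_constraint(
            {f"g_{rid}": 1.0, f"y_{rid}": pot_m + 1}, "<=", pot_m)
        problem.add_constraint(
            {f"g_{rid}": 1.0, f"y_{rid}": pot_m + 1}, ">=", 1.0)


def _solve_max(problem: Problem, rid: str, solver: str | None):
    problem.set_objective({f"v_{rid}": 1.0}, "max")
    result = problem.solve(solver)
    if result.status == "infeasible":
        raise InfeasibleError("flux problem is infeasible")
    if result.status == "unbounded":
        raise UnboundedError(
            f"objective flux of {rid!r} is unbounded; check flux limits")
    return result


def fba(
    model: Model,
    objective: str | None = None,
    loop_removal: str = "none",
    solver: str | None = None,
) -> FluxSolution:
    """Flux balance analysis: maximize the objective reaction's flux."""
    objective = _objective_reaction(model, objective)
    problem, reactions = _flux_problem(model, loop_removal)
    if not problem.has_variable(f"v_{objective}"):
        raise SimulationError(
            f"objective reaction {objective!r} not in the model")
    result = _solve_max(problem, objective, solver)
    fluxes = {rid: result.value(f"v_{rid}") for rid in reactions}
    return FluxSolution(
        objective, result.value(f"v_{objective}"), fluxes, loop_removal)


def fva(
    model: Model,
    objective: str | None = None,
    optimum_fraction: float = 1.0,
    loop_removal: str = "none",
    solver: str | None = None,
) -> dict[str, tuple[float, float]]:
    """Flux variability analysis.

    The objective is first maximized, then constrained to at least
    ``optimum_fraction`` of its optimum; each reaction's flux is then
    minimized and maximized over the constrained polytope on the same
    problem instance.
    """
    if not 0 < optimum_fraction <= 1:
        raise SimulationError("optimum_fraction must be in (0, 1]")
    objective = _objective_reaction(model, objective)
    problem, reactions = _flux_problem(model, loop_removal)
    if not problem.has_variable(f"v_{objective}"):
        raise SimulationError(
            f"objective reaction {objective!r} not in the model")
    optimum = _solve_max(problem, objective, solver).objective_value
    problem.add_constraint(
        {f"v_{objective}": 1.0}, ">=", optimum_fraction * optimum - 1e-9)

    intervals: dict[str, tuple[float, float]] = {}
    for rid in reactions:
        problem.set_objective({f"v_{rid}": 1.0}, "min")
        low = problem.solve(solver)
        problem.set_objective({f"v_{rid}": 1.0}, "max")
        high = problem.solve(solver)
        if not (low.optimal and high.optimal):
            raise SimulationError(
                f"FVA subproblem for {rid!r} was "
                f"{low.status}/{high.status}")
        intervals[rid] = (low.objective_value, high.objective_value)
    return intervals


def robustness(
    model: Model,
    varied: str,
    objective: str | None = None,
    steps: int = 10,
    loop_removal: str = "none",
    solver: str | None = None,
) -> RobustnessCurve:
    """Sweep the varied reaction's feasible range, re-optimizing each step.

    The feasible range [lo, hi] comes from minimizing and maximizing the
    varied flux; the curve fixes the flux at ``steps`` evenly spaced
    values and records the optimal objective (or None when infeasible).
    """
    if steps < 2:
        raise SimulationError("steps must be at least 2")
    objective = _objective_reaction(model, objective)
    problem, _ = _flux_problem(model, loop_removal)
    for rid in (varied, objective):
        if not problem.has_variable(f"v_{rid}"):
            raise SimulationError(f"reaction {rid!r} not in the model")

    problem.set_objective({f"v_{varied}": 1.0}, "min")
    low = problem.solve(solver)
    problem.set_objective({f"v_{varied}": 1.0}, "max")
    high = problem.solve(solver)
    if not (low.optimal and high.optimal):
        raise InfeasibleError("flux problem is infeasible")
    lo, hi = low.objective_value, high.objective_value

    warnings = []
    if hi - lo < FLUX_TOL:
        warnings.append(
            f"reaction {varied!r} has a degenerate feasible range "
            f"[{lo:g}, {hi:g}]; single-point curve")
        values = [lo]
    else:
        values = [
            lo + k * (hi - lo) / (steps - 1) for k in range(steps)]

    original = problem.bounds(f"v_{varied}")
    points: list[tuple[float, float | None]] = []
    for value in values:
        problem.set_bounds(f"v_{varied}", value, value)
        problem.set_objective({f"v_{objective}": 1.0}, "max")
        result = problem.solve(solver)
        points.append(
            (value, result.objective_value if result.optimal else None))
    problem.set_bounds(f"v_{varied}", *original)
    return RobustnessCurve(varied, points, warnings)


def randomsparse(
    model: Model,
    objective: str | None = None,
    threshold_fraction: float = 1.0,
    mode: str = "reactions",
    seed: int = 0,
    solver: str | None = None,
) -> MinimalNetwork:
    """Random minimal network by successive deletions.

    Elements (genes or reactions) are visited in a seeded random order;
    each is tentatively deleted and the deletion is kept only when the
    optimized objective stays at or above ``threshold_fraction`` times the
    wild-type optimum.  Because constraints only tighten as deletions
    accumulate, every retained element is essential in the final network.
    """
    if mode not in ("genes", "reactions"):
        raise SimulationError(f"unknown randomsparse mode {mode!r}")
    if not 0 < threshold_fraction <= 1:
        raise SimulationError("threshold_fraction must be in (0, 1]")
    objective = _objective_reaction(model, objective)
    problem, reactions = _flux_problem(model)
    wild_type = _solve_max(problem, objective, solver).objective_value
    if wild_type <= FLUX_TOL:
        raise SimulationError(
            f"wild-type objective is zero; nothing to minimize")
    threshold = threshold_fraction * wild_type - 1e-6 * max(1.0, wild_type)

    rng = random.Random(seed)
    if mode == "genes":
        elements = sorted(model.genes())
    else:
        elements = list(reactions)
    rng.shuffle(elements)

    original = {rid: problem.bounds(f"v_{rid}") for rid in reactions}

    def disabled_for(deleted_genes: set[str]) -> set[str]:
        out = set()
        for rid in reactions:
            entry = model.reactions.get(rid)
            if entry is not None and entry.genes is not None \
                    and not evaluate_genes(entry.genes, deleted_genes):
                out.add(rid)
        return out

    deleted: list[str] = []
    if mode == "genes":
        deleted_genes: set[str] = set()
        disabled: set[str] = set()
        for gene in elements:
            tentative = deleted_genes | {gene}
            new_disabled = disabled_for(tentative)
            for rid in new_disabled - disabled:
                problem.set_bounds(f"v_{rid}", 0.0, 0.0)
            problem.set_objective({f"v_{objective}": 1.0}, "max")
            result = problem.solve(solver)
            if result.optimal and result.objective_value >= threshold:
                deleted_genes = tentative
                disabled = new_disabled
                deleted.append(gene)
            else:
                for rid in new_disabled - disabled:
                    problem.set_bounds(f"v_{rid}", *original[rid])
        retained = set(elements) - set(deleted)
    else:
        for rid in elements:
            saved = problem.bounds(f"v_{rid}")
            problem.set_bounds(f"v_{rid}", 0.0, 0.0)
            problem.set_objective({f"v_{objective}": 1.0}, "max")
            result = problem.solve(solver)
            if result.optimal and result.objective_value >= threshold:
                deleted.append(rid)
            else:
                problem.set_bounds(f"v_{rid}", *saved)
        retained = set(elements) - set(deleted)

    problem.set_objective({f"v_{objective}": 1.0}, "max")
    final = problem.solve(solver)
    value = final.objective_value if final.optimal else 0.0
    return MinimalNetwork(mode, retained, deleted, seed, value)
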