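"""Solver-agnostic linear and mixed-integer programming layer.

A :class:`Problem` is a mutable handle: variables, linear constraints and
the objective can be changed in place between solves.  Analyses that sweep
over many closely related problems (flux variability, robustness, the
consistency checks) build the constraint system once and then only swap
the objective or a bound per iteration; backends cache the constraint
matrix against a structure version counter so repeated solves avoid
rebuilding it.

Backends are registered by name and selected per solve (``--solver`` on
the command line).  Bundled backends:

``highs``
    scipy's HiGHS interface; LP and MILP.  The default.
``glpk``
    GNU Linear Programming Kit via swiglpk; LP and MILP.  Registered only
    when swiglpk is importable.

Commercial or exact-rational solvers can be plugged in by registering an
object with the same ``solve(problem)`` interface; an exact LP-only
backend should set ``supports_milp = False`` so that mixed-integer
analyses refuse it explicitly.

Numerical tolerances: feasibility 1e-9 (LP); integrality 1e-6 (MILP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

FEASIBILITY_TOL = 1e-9
INTEGRALITY_TOL = 1e-6

_INF = math.inf


class LPError(Exception):
    pass


class SolverError(LPError):
    """The backend failed; never reported as a fake solution status."""


class UnknownVariableError(LPError):
    pass


@dataclass
class _Variable:
    name: str
    lower: float
    upper: float
    binary: bool = False


@dataclass
class _Constraint:
    coeffs: dict[str, float]
    sense: str  # 'E', 'L' (<=), 'G' (>=)
    rhs: float


@dataclass
class Solution:
    status: str  # 'optimal' | 'infeasible' | 'unbounded'
    objective_value: float | None = None
    assignment: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def value(self, name: str) -> float:
        return self.assignment[name]


_SENSES = {"==": "E", "=": "E", "E": "E", "<=": "L", "L": "L", ">=": "G", "G": "G"}


class Problem:
    """Mutable LP/MILP problem definition."""

    def __init__(self) -> None:
        self._variables: dict[str, _Variable] = {}
        self._order: list[str] = []
        self._constraints: list[_Constraint] = []
        self._objective: dict[str, float] = {}
        self._maximize = True
        self._structure_version = 0
        self._cache: dict[str, object] = {}

    # -- construction / mutation -------------------------------------

    def add_variable(
        self,
        name: str,
        lower: float = -_INF,
        upper: float = _INF,
        binary: bool = False,
    ) -> None:
        if name in self._variables:
            raise LPError(f"duplicate variable {name!r}")
        if binary:
            lower, upper = 0.0, 1.0
        if lower > upper:
            raise LPError(f"variable {name!r}: lower bound exceeds upper")
        self._variables[name] = _Variable(name, float(lower), float(upper), binary)
        self._order.append(name)
        self._structure_version += 1

    def has_variable(self, name: str) -> bool:
        return name in self._variables

    def add_constraint(
        self, coeffs: Mapping[str, float], sense: str, rhs: float
    ) -> int:
        sense = _SENSES[sense]
        clean: dict[str, float] = {}
        for name, coef in coeffs.items():
            if name not in self._variables:
                raise UnknownVariableError(
                    f"constraint references unknown variable {name!r}")
            coef = float(coef)
            if coef != 0.0:
                clean[name] = coef
        self._constraints.append(_Constraint(clean, sense, float(rhs)))
        self._structure_version += 1
        return len(self._constraints) - 1

    def set_objective(self, coeffs: Mapping[str, float], direction: str = "max") -> None:
        for name in coeffs:
            if name not in self._variables:
                raise UnknownVariableError(
                    f"objective references unknown variable {name!r}")
        if direction not in ("max", "min"):
            raise LPError(f"unknown objective direction {direction!r}")
        self._objective = {n: float(c) for n, c in coeffs.items() if c != 0}
        self._maximize = direction == "max"

    def set_bounds(self, name: str, lower: float, upper: float) -> None:
        if name not in self._variables:
            raise UnknownVariableError(f"unknown variable {name!r}")
        if lower > upper:
            raise LPError(f"variable {name!r}: lower bound exceeds upper")
        var = self._variables[name]
        var.lower, var.upper = float(lower), float(upper)

    def bounds(self, name: str) -> tuple[float, float]:
        var = self._variables[name]
        return var.lower, var.upper

    # -- introspection -----------------------------------------------

    @property
    def variables(self) -> list[str]:
        return list(self._order)

    @property
    def is_integer(self) -> bool:
        return any(v.binary for v in self._variables.values())

    # -- solving -----------------------------------------------------

    def solve(self, solver: str | None = None) -> Solution:
        backend = get_backend(solver)
        if self.is_integer and not getattr(backend, "supports_milp", True):
            raise SolverError(
                f"solver {backend.name!r} supports LP problems only; "
                f"this problem has binary variables")
        return backend.solve(self)


def build(variables, constraints, objective=None, direction="max") -> Problem:
    """Convenience constructor.

    ``variables``: iterable of (name, lower, upper) or (name, lower,
    upper, binary); ``constraints``: iterable of (coeffs, sense, rhs);
    ``objective``: mapping variable -> coefficient.
    """
    problem = Problem()
    for spec in variables:
        problem.add_variable(*spec)
    for coeffs, sense, rhs in constraints:
        problem.add_constraint(coeffs, sense, rhs)
    if objective is not None:
        problem.set_objective(objective, direction)
    return problem


class HighsBackend:
    name = "highs"
    supports_milp = True
    exact = False

    def _matrices(self, problem: Problem):
        key = ("highs", problem._structure_version)
        cached = problem._cache.get("highs")
        if cached is not None and cached[0] == problem._structure_version:
            return cached[1]
        index = {name: i for i, name in enumerate(problem._order)}
        n = len(index)
        eq_rows, eq_rhs = [], []
        ub_rows, ub_rhs = [], []
        data_eq: list[tuple[int, int, float]] = []
        data_ub: list[tuple[int, int, float]] = []
        for con in problem._constraints:
            if con.sense == "E":
                row = len(eq_rhs)
                eq_rhs.append(con.rhs)
                for name, coef in con.coeffs.items():
                    data_eq.append((row, index[name], coef))
            else:
                sign = 1.0 if con.sense == "L" else -1.0
                row = len(ub_rhs)
                ub_rhs.append(sign * con.rhs)
                for name, coef in con.coeffs.items():
                    data_ub.append((row, index[name], sign * coef))

        def to_csr(data, nrows):
            if not nrows:
                return None
            if data:
                rows, cols, vals = zip(*data)
            else:
                rows, cols, vals = (), (), ()
            return sparse.csr_matrix(
                (vals, (rows, cols)), shape=(nrows, n))

        mats = (
            index,
            to_csr(data_eq, len(eq_rhs)), np.asarray(eq_rhs, dtype=float),
            to_csr(data_ub, len(ub_rhs)), np.asarray(ub_rhs, dtype=float),
        )
        problem._cache["highs"] = (problem._structure_version, mats)
        return mats

    def solve(self, problem: Problem) -> Solution:
        index, a_eq, b_eq, a_ub, b_ub = self._matrices(problem)
        n = len(index)
        c = np.zeros(n)
        for name, coef in problem._objective.items():
            c[index[name]] = coef
        sign = -1.0 if problem._maximize else 1.0
        lowers = np.array([problem._variables[v].lower for v in problem._order])
        uppers = np.array([problem._variables[v].upper for v in problem._order])

        if problem.is_integer:
            constraints = []
            if a_eq is not None:
                constraints.append(LinearConstraint(a_eq, b_eq, b_eq))
            if a_ub is not None:
                constraints.append(
                    LinearConstraint(a_ub, np.full(len(b_ub), -np.inf), b_ub))
            integrality = np.array(
                [1 if problem._variables[v].binary else 0
                 for v in problem._order])
            res = milp(
                sign * c,
                constraints=constraints,
                integrality=integrality,
                bounds=Bounds(lowers, uppers),
            )
        else:
            res = linprog(
                sign * c,
                A_ub=a_ub, b_ub=b_ub if a_ub is not None else None,
                A_eq=a_eq, b_eq=b_eq if a_eq is not None else None,
                bounds=np.column_stack([lowers, uppers]),
                method="highs",
            )

        if res.status == 0:
            assignment = {
                name: float(res.x[i]) for name, i in index.items()}
            objective = float(sign * res.fun)
            return Solution("optimal", objective, assignment)
        if res.status == 2:
            return Solution("infeasible")
        if res.status == 3:
            return Solution("unbounded")
        raise SolverError(
            f"HiGHS failed (status {res.status}): {res.message}")


class GlpkBackend:
    name = "glpk"
    supports_milp = True
    exact = False

    def solve(self, problem: Problem) -> Solution:
        import swiglpk as glp

        lp = glp.glp_create_prob()
        try:
            n = len(problem._order)
            index = {name: i + 1 for i, name in enumerate(problem._order)}
            glp.glp_add_cols(lp, n)
            for name, j in index.items():
                var = problem._variables[name]
                _set_glpk_bounds(glp, lp, j, var.lower, var.upper, col=True)
                if var.binary:
                    glp.glp_set_col_kind(lp, j, glp.GLP_IV)
            m = len(problem._constraints)
            if m:
                glp.glp_add_rows(lp, m)
            for i, con in enumerate(problem._constraints, start=1):
                if con.sense == "E":
                    glp.glp_set_row_bnds(lp, i, glp.GLP_FX, con.rhs, con.rhs)
                elif con.sense == "L":
                    glp.glp_set_row_bnds(lp, i, glp.GLP_UP, 0.0, con.rhs)
                else:
                    glp.glp_set_row_bnds(lp, i, glp.GLP_LO, con.rhs, 0.0)
                k = len(con.coeffs)
                ind = glp.intArray(k + 1)
                val = glp.doubleArray(k + 1)
                for pos, (name, coef) in enumerate(con.coeffs.items(), 1):
                    ind[pos] = index[name]
                    val[pos] = coef
                glp.glp_set_mat_row(lp, i, k, ind, val)
            glp.glp_set_obj_dir(
                lp, glp.GLP_MAX if problem._maximize else glp.GLP_MIN)
            for name, coef in problem._objective.items():
                glp.glp_set_obj_coef(lp, index[name], coef)

            parm = glp.glp_smcp()
            glp.glp_init_smcp(parm)
            parm.msg_lev = glp.GLP_MSG_OFF
            ret = glp.glp_simplex(lp, parm)
            if ret != 0:
                raise SolverError(f"GLPK simplex failed with code {ret}")
            status = glp.glp_get_status(lp)
            if status in (glp.GLP_INFEAS, glp.GLP_NOFEAS):
                return Solution("infeasible")
            if status == glp.GLP_UNBND:
                return Solution("unbounded")
            if status != glp.GLP_OPT:
                raise SolverError(f"GLPK returned status {status}")

            if problem.is_integer:
                iparm = glp.glp_iocp()
                glp.glp_init_iocp(iparm)
                iparm.msg_lev = glp.GLP_MSG_OFF
                ret = glp.glp_intopt(lp, iparm)
                if ret != 0:
                    raise SolverError(f"GLPK intopt failed with code {ret}")
                mip_status = glp.glp_mip_status(lp)
                if mip_status == glp.GLP_NOFEAS:
                    return Solution("infeasible")
                if mip_status not in (glp.GLP_OPT, glp.GLP_FEAS):
                    raise SolverError(f"GLPK MIP status {mip_status}")
                assignment = {
                    name: glp.glp_mip_col_val(lp, j)
                    for name, j in index.items()}
                return Solution(
                    "optimal", glp.glp_mip_obj_val(lp), assignment)

            assignment = {
                name: glp.glp_get_col_prim(lp, j)
                for name, j in index.items()}
            return Solution("optimal", glp.glp_get_obj_val(lp), assignment)
        finally:
            glp.glp_delete_prob(lp)


def _set_glpk_bounds(glp, lp, j, lower, upper, col=True):
    set_bnds = glp.glp_set_col_bnds
    if lower == -_INF and upper == _INF:
        set_bnds(lp, j, glp.GLP_FR, 0.0, 0.0)
    elif lower == -_INF:
        set_bnds(lp, j, glp.GLP_UP, 0.0, upper)
    elif upper == _INF:
        set_bnds(lp, j, glp.GLP_LO, lower, 0.0)
    elif lower == upper:
        set_bnds(lp, j, glp.GLP_FX, lower, upper)
    else:
        set_bnds(lp, j, glp.GLP_DB, lower, upper)


_REGISTRY: dict[str, object] = {"highs": HighsBackend()}
DEFAULT_SOLVER = "highs"

try:  # pragma: no cover - presence depends on the installation
    import swiglpk  # noqa: F401

    _REGISTRY["glpk"] = GlpkBackend()
except ImportError:  # pragma: no cover
    pass


def register_backend(name: str, backend: object) -> None:
    _REGISTRY[name] = backend


def available_backends() -> list[str]:
    return sorted(_REGISTRY)


def get_backend(name: str | None = None):
    if name is None:
        name = DEFAULT_SOLVER
    try:
        return _REGISTRY[name]
    except KeyError:
        raise SolverError(
            f"unknown solver {name!r}; available: {available_backends()}")
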