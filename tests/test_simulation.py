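"""Constraint-based simulation: FBA, loop removal, FVA, robustness,
random minimal networks.

Solutions are re-verified independently of the solver: steady state and
bounds by direct substitution into the stoichiometric matrix, loop
freeness by enumerating circulation sign patterns, minimal networks by
exhaustive single-deletion re-optimization.
"""

import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from gemkit import (
    fba, fva, make_fixture, matrix_view, randomsparse, robustness)
from gemkit.simulation import InfeasibleError, SimulationError
from tests.conftest import random_models

TOL = 1e-6


def assert_valid_solution(model, fluxes):
    """Sv = 0 and bounds, checked by direct substitution."""
    matrix = matrix_view(model)
    for compound in matrix.compounds:
        net = sum(
            float(matrix.value(compound, rid)) * fluxes[rid]
            for rid in matrix.reactions)
        assert abs(net) <= TOL, f"imbalance at {compound}: {net}"
    for rid in matrix.reactions:
        lower, upper = matrix.bounds[rid]
        assert lower - TOL <= fluxes[rid] <= upper + TOL, rid


class TestFba:
    def test_chain_throughput_is_uptake_limit(self, chain):
        solution = fba(chain)
        assert solution.objective_value == pytest.approx(10.0)
        assert solution.objective_reaction == "BIO"
        assert_valid_solution(chain, solution.fluxes)

    def test_closed_model_grows_nothing(self, chain):
        chain.media = []
        chain.limits.append(
            __import__("gemkit").LimitEntry("EX_A", 0.0, 0.0))
        assert fba(chain).objective_value == pytest.approx(0.0)

    def test_unknown_objective_rejected(self, chain):
        with pytest.raises(SimulationError):
            fba(chain, objective="ghost")

    def test_objective_defaults_to_biomass(self, chain):
        chain.biomass = None
        with pytest.raises(SimulationError, match="biomass"):
            fba(chain)


class TestLoopRemoval:
    def test_tfba_objective_equals_fba_on_loop_free(self, chain):
        plain = fba(chain)
        loopless = fba(chain, loop_removal="tfba")
        assert loopless.objective_value == pytest.approx(
            plain.objective_value)

    def test_tfba_never_exceeds_fba(self, loop):
        assert fba(loop, loop_removal="tfba").objective_value <= \
            fba(loop).objective_value + TOL

    def test_tfba_zeroes_futile_cycle(self, loop):
        solution = fba(loop, loop_removal="tfba")
        assert solution.objective_value == pytest.approx(10.0)
        assert_valid_solution(loop, solution.fluxes)
        assert self._circulations_in(loop, solution.fluxes) == []

    def test_plain_fba_admits_the_cycle(self, loop):
        # Force circulation through the cycle, then show tfba forbids it.
        from gemkit import LimitEntry

        loop.limits.append(LimitEntry("R_BA", lower=1.0))
        plain = fba(loop)
        assert plain.fluxes["R_BA"] >= 1.0 - TOL
        assert self._circulations_in(loop, plain.fluxes)
        with_loop_removal = [
            sign for sign in self._feasible_circulations(loop)]
        assert with_loop_removal  # the oracle does see the cycle

    @staticmethod
    def _feasible_circulations(model):
        """Sign-pattern enumeration oracle for internal circulations.

        Enumerates every orientation pattern over the internal reactions
        (at most six) and keeps those admitting a non-zero internal flux
        with S v = 0 and matching signs.
        """
        matrix = matrix_view(model)
        internal = [
            rid for rid in matrix.reactions if not model.is_exchange(rid)]
        assert len(internal) <= 6
        compounds = matrix.compounds
        S = np.array([
            [float(matrix.value(c, rid)) for rid in internal]
            for c in compounds])
        patterns = []
        for signs in itertools.product((-1, 0, 1), repeat=len(internal)):
            if not any(signs):
                continue
            bounds = []
            for sign, rid in zip(signs, internal):
                if sign == 0:
                    bounds.append((0, 0))
                elif sign > 0:
                    bounds.append((1, None))
                else:
                    bounds.append((None, -1))
            res = linprog(
                np.zeros(len(internal)), A_eq=S, b_eq=np.zeros(len(S)),
                bounds=bounds, method="highs")
            if res.status == 0:
                patterns.append(dict(zip(internal, signs)))
        return patterns

    def _circulations_in(self, model, fluxes):
        found = []
        for pattern in self._feasible_circulations(model):
            if all(
                sign == 0 or np.sign(fluxes[rid]) == sign
                and abs(fluxes[rid]) > TOL
                    for rid, sign in pattern.items()):
                found.append(pattern)
        return found


class TestFva:
    def test_unique_path_gives_point_intervals(self, chain):
        intervals = fva(chain, optimum_fraction=1.0)
        for rid, (low, high) in intervals.items():
            assert high - low == pytest.approx(0.0, abs=1e-6)

    def test_intervals_widen_as_fraction_drops(self, branched):
        tight = fva(branched, optimum_fraction=1.0)
        loose = fva(branched, optimum_fraction=0.5)
        for rid in tight:
            assert loose[rid][0] <= tight[rid][0] + TOL
            assert loose[rid][1] >= tight[rid][1] - TOL

    def test_fba_flux_lies_inside_every_interval(self, branched):
        solution = fba(branched)
        intervals = fva(branched, optimum_fraction=1.0)
        for rid, (low, high) in intervals.items():
            assert low - TOL <= solution.fluxes[rid] <= high + TOL

    def test_interval_endpoints_are_feasible(self):
        for model in random_models(3, start=40):
            if model.biomass is None:
                objective = next(iter(model.reactions))
            else:
                objective = None
            intervals = fva(
                model, objective=objective
                or next(iter(model.reactions)), optimum_fraction=0.9)
            for low, high in intervals.values():
                assert low <= high + TOL

    def test_bad_fraction_rejected(self, chain):
        with pytest.raises(SimulationError):
            fva(chain, optimum_fraction=0.0)


class TestRobustness:
    def test_linear_throughput_curve(self, chain):
        curve = robustness(chain, "EX_A", steps=11)
        assert len(curve.points) == 11
        for fixed, objective in curve.points:
            assert objective == pytest.approx(abs(fixed), abs=1e-6)

    def test_two_steps_are_the_endpoints(self, chain):
        curve = robustness(chain, "EX_A", steps=2)
        fixed = [value for value, _ in curve.points]
        assert fixed == [pytest.approx(-10.0), pytest.approx(0.0)]

    def test_decoupled_reaction_gives_flat_curve(self, blocked):
        curve = robustness(blocked, "R_CD", steps=4)
        values = {round(obj, 6) for _, obj in curve.points if obj is not None}
        assert len(curve.warnings) == 1  # degenerate (blocked) range
        assert values == {10.0}

    def test_step_count_respected_with_infeasible_points(self, chain):
        curve = robustness(chain, "TP_A", steps=7)
        assert len(curve.points) == 7
        assert all(obj is not None for _, obj in curve.points)


class TestRandomsparse:
    def _verify_minimal(self, model, network, threshold):
        """Exhaustive single-deletion check of the minimality invariant."""
        from gemkit.simulation import _flux_problem

        problem, reactions = _flux_problem(model)
        objective = model.biomass

        def optimum(disabled):
            for rid in reactions:
                if rid in disabled:
                    problem.set_bounds(f"v_{rid}", 0.0, 0.0)
            problem.set_objective({f"v_{objective}": 1.0}, "max")
            result = problem.solve()
            # Reset for the next round.
            matrix = matrix_view(model)
            for rid in reactions:
                problem.set_bounds(f"v_{rid}", *matrix.bounds[rid])
            return result.objective_value if result.optimal else 0.0

        if network.mode == "reactions":
            base_disabled = set(network.deleted)
            assert optimum(base_disabled) >= threshold - 1e-5
            for rid in network.retained:
                assert optimum(base_disabled | {rid}) < threshold - 1e-6
        else:
            from gemkit.genes import evaluate_genes

            def disabled_for(genes_off):
                return {
                    rid for rid, entry in model.reactions.items()
                    if entry.genes is not None
                    and not evaluate_genes(entry.genes, genes_off)}

            deleted = set(network.deleted)
            assert optimum(disabled_for(deleted)) >= threshold - 1e-5
            for gene in network.retained:
                assert optimum(
                    disabled_for(deleted | {gene})) < threshold - 1e-6

    def test_single_path_retains_everything(self, chain):
        for seed in (0, 1, 5):
            network = randomsparse(chain, mode="reactions", seed=seed)
            assert network.retained == set(chain.reactions)
            self._verify_minimal(chain, network, 10.0)

    def test_redundant_paths_keep_exactly_one(self, branched):
        retained_sets = set()
        for seed in range(6):
            network = randomsparse(branched, mode="reactions", seed=seed)
            assert len(network.retained) == 5
            path = frozenset(
                network.retained & {"P1a", "P1b", "P2a", "P2b"})
            assert path in (
                frozenset({"P1a", "P1b"}), frozenset({"P2a", "P2b"}))
            retained_sets.add(path)
            self._verify_minimal(branched, network, 10.0)
        assert len(retained_sets) == 2  # both outcomes occur across seeds

    def test_isozyme_deletion_keeps_reaction_active(self, chain):
        # R_AB is guarded by "g1 or g2": one of the two can always go.
        for seed in range(4):
            network = randomsparse(chain, mode="genes", seed=seed)
            deleted = set(network.deleted)
            assert len(deleted & {"g1", "g2"}) == 1
            assert "gT" in network.retained
            self._verify_minimal(chain, network, 10.0)

    def test_zero_wild_type_rejected(self, chain):
        chain.limits.append(
            __import__("gemkit").LimitEntry("EX_A", 0.0, 0.0))
        chain.media = []
        with pytest.raises(SimulationError):
            randomsparse(chain, mode="reactions", seed=0)
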