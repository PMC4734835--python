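"""Stoichiometric consistency: the compound and reaction LP variants.

The printed two-reaction worked examples pin the exact residuals; the
brute-force oracle re-solves the reaction LP with an independently
constructed scipy linprog call; property tests use the fixture
generator's balanced-by-construction models and its fault injector.
"""

import numpy as np
import pytest
from scipy.optimize import linprog

from gemkit import (
    Compound, Fault, FixtureSpec, inject_fault, make_fixture,
    masscheck_compounds, masscheck_reactions, matrix_view, chargecheck,
    formulacheck)
from gemkit.checks import ConsistencyError
from tests.conftest import random_models

H = Compound("H+", "c")


class TestPrintedPairs:
    def test_glucose_pair_compound_check_flags_proton(self, glucose_pair):
        result = masscheck_compounds(glucose_pair, exclude=set())
        assert result.flagged == {H}
        assert result.objective == pytest.approx(2.0)  # 2 of 3 balanced

    def test_glucose_pair_residual(self, glucose_pair):
        result = masscheck_reactions(
            glucose_pair, exclude=set(), checked={"RR08939"})
        assert [rid for rid, _ in result.flagged] == ["RR00610"]
        assert result.left_minus_right("RR00610") == pytest.approx(2.0)
        assert result.objective == pytest.approx(2.0)
        assert result.masses[H] == pytest.approx(1.0)

    def test_uroporphyrinogen_pair_residual(self, uro_pair):
        result = masscheck_reactions(
            uro_pair, exclude=set(), checked={"IR01815"})
        assert [rid for rid, _ in result.flagged] == ["IR04287"]
        assert result.left_minus_right("IR04287") == pytest.approx(-7.0)

    def test_balanced_reaction_alone_has_zero_residual(self, glucose_pair):
        glucose_pair.reactions.pop("RR00610")
        result = masscheck_reactions(glucose_pair, exclude=set())
        assert result.flagged == []
        assert result.residuals["RR08939"] == pytest.approx(0.0)


class TestExclusions:
    def test_default_exclusion_covers_biomass_and_exchanges(self, chain):
        # The biomass drain and exchanges are unbalanced by design; the
        # default exclusion must keep them out of the check.
        compound = masscheck_compounds(chain)
        assert compound.flagged == set()
        reaction = masscheck_reactions(chain)
        assert reaction.flagged == []

    def test_empty_exclusion_flags_the_drains(self, chain):
        result = masscheck_reactions(chain, exclude=set())
        assert result.flagged != []

    def test_zero_mass_ok_lifts_requirement(self):
        # A photon-like pseudo-compound driving an otherwise balanced
        # conversion: without the waiver the reaction is flagged.
        from gemkit import Model, ReactionEntry, parse_equation

        model = Model()
        model.add_reaction(ReactionEntry(
            "rub", parse_equation("A[c] + photon[c] => B[c]")))
        model.add_reaction(ReactionEntry(
            "r2", parse_equation("A[c] <=> B[c]")))
        flagged = masscheck_reactions(model, exclude=set()).flagged
        assert flagged
        waived = masscheck_reactions(
            model, exclude=set(), zero_mass_ok={Compound("photon", "c")})
        assert waived.flagged == []

    def test_contradictory_checked_set_is_diagnosed(self, glucose_pair):
        with pytest.raises(ConsistencyError, match="checked"):
            masscheck_reactions(
                glucose_pair, exclude=set(),
                checked={"RR00610", "RR08939"})


def _bruteforce_reaction_lp(model, exclude=frozenset(), checked=frozenset()):
    """Independent scipy construction of the residual-minimization LP."""
    matrix = matrix_view(model)
    reactions = [r for r in matrix.reactions if r not in exclude]
    compounds = matrix.compounds
    nm, nr = len(compounds), len(reactions)
    # Variables: [m (nm), r (nr), z (nr)]
    n = nm + 2 * nr
    c = np.zeros(n)
    c[nm + nr:] = 1.0
    a_eq = np.zeros((nr, n))
    for j, rid in enumerate(reactions):
        for i, compound in enumerate(compounds):
            a_eq[j, i] = float(matrix.value(compound, rid))
        a_eq[j, nm + j] = -1.0
    a_ub = np.zeros((2 * nr, n))
    for j in range(nr):
        a_ub[j, nm + j] = 1.0
        a_ub[j, nm + nr + j] = -1.0
        a_ub[nr + j, nm + j] = -1.0
        a_ub[nr + j, nm + nr + j] = -1.0
    bounds = [(1, None)] * nm
    for rid in reactions:
        bounds.append((0, 0) if rid in checked else (None, None))
    bounds += [(0, None)] * nr
    res = linprog(c, A_ub=a_ub, b_ub=np.zeros(2 * nr), A_eq=a_eq,
                  b_eq=np.zeros(nr), bounds=bounds, method="highs")
    assert res.status == 0
    return res.fun


class TestProperties:
    def test_balanced_models_never_flagged(self):
        for model in random_models(15):
            assert masscheck_compounds(model).flagged == set()
            assert masscheck_reactions(model).flagged == []

    def test_single_injected_imbalance_is_localized(self):
        for model in random_models(10, start=100):
            internal = [
                r for r in model.reactions if not model.is_exchange(r)]
            target = internal[len(internal) // 2]
            broken = inject_fault(model, Fault("unbalance", target))
            others = set(broken.reactions) - {target}
            result = masscheck_reactions(
                broken, checked=others - set(
                    r for r in broken.reactions
                    if broken.is_exchange(r)))
            flagged = [rid for rid, _ in result.flagged]
            assert flagged == [target]
            # Two protons were added to the right side.
            assert result.left_minus_right(target) == pytest.approx(-2.0)

    def test_objective_matches_bruteforce_small_models(self):
        count = 0
        for model in random_models(20, start=300, n_compounds=4,
                                   n_elements=2, n_reactions=4):
            if len(matrix_view(model).compounds) > 4:
                continue
            count += 1
            ours = masscheck_reactions(model, exclude=set()).objective
            reference = _bruteforce_reaction_lp(model)
            assert ours == pytest.approx(reference, abs=1e-6)
        assert count >= 5

    def test_flags_invariant_under_reordering_and_renaming(self, glucose_pair):
        result = masscheck_reactions(
            glucose_pair, exclude=set(), checked={"RR08939"})

        reordered = glucose_pair.copy()
        reordered.reactions = dict(reversed(list(
            reordered.reactions.items())))
        r2 = masscheck_reactions(
            reordered, exclude=set(), checked={"RR08939"})
        assert [rid for rid, _ in r2.flagged] == \
            [rid for rid, _ in result.flagged]

        renamed = glucose_pair.copy()
        renamed.reactions["X1"] = renamed.reactions.pop("RR00610")
        renamed.reactions["X1"].id = "X1"
        r3 = masscheck_reactions(
            renamed, exclude=set(), checked={"RR08939"})
        assert [rid for rid, _ in r3.flagged] == ["X1"]
        assert r3.left_minus_right("X1") == pytest.approx(2.0)


class TestBalanceChecks:
    def test_formula_balance_examples(self):
        from gemkit import (
            CompoundEntry, Formula, Model, ReactionEntry, parse_equation)

        model = Model()
        for name, formula in [("A", "CH4"), ("B", "CH3"), ("C", "H")]:
            model.add_compound(CompoundEntry(
                Compound(name, "c"), formula=Formula.parse(formula)))
        model.add_reaction(ReactionEntry(
            "ok", parse_equation("A[c] => B[c] + C[c]")))
        model.add_reaction(ReactionEntry(
            "bad", parse_equation("A[c] => A[c]")))
        model.reactions["bad"].equation = parse_equation(
            "A[c] => B[c] + (2) C[c]")
        result = formulacheck(model)
        assert [rid for rid, *_ in result.flagged] == ["bad"]
        rid, left, right = result.flagged[0]
        assert (right - left) == Formula({"H": 1})

    def test_glucose_isomerase_hydrogen_excess(self, glucose_pair):
        result = formulacheck(glucose_pair, exclude=set())
        flagged = {rid: (left, right) for rid, left, right in result.flagged}
        assert set(flagged) == {"RR00610"}
        left, right = flagged["RR00610"]
        from gemkit import Formula

        assert left - right == Formula({"H": 2})

    def test_missing_formula_skips_with_count(self, chain):
        del chain.compounds[Compound("B", "c")].formula
        chain.compounds[Compound("B", "c")].formula = None
        result = formulacheck(chain)
        assert "R_AB" in result.skipped

    def test_charge_balance(self):
        from gemkit import CompoundEntry, Model, ReactionEntry, \
            parse_equation

        model = Model()
        for name, charge in [("A", 0), ("B", -1), ("C", 1)]:
            model.add_compound(
                CompoundEntry(Compound(name, "c"), charge=charge))
        model.add_reaction(ReactionEntry(
            "ok", parse_equation("A[c] => B[c] + C[c]")))
        model.add_reaction(ReactionEntry(
            "bad", parse_equation("A[c] => B[c]")))
        result = chargecheck(model)
        assert [rid for rid, *_ in result.flagged] == ["bad"]
        _, left, right = result.flagged[0]
        assert right - left == -1

    def test_exchanges_never_flagged_by_default(self, chain):
        chain.compounds[Compound("A", "e")].charge = 1
        chain.compounds[Compound("A", "c")].charge = 1
        chain.compounds[Compound("B", "c")].charge = 1
        assert chargecheck(chain).flagged == []
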