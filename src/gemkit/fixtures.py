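"""Deterministic toy and randomized models for exercising every analysis.

The toy networks:

``chain``
    A viable linear pathway: medium A is taken up (limit 10), transported
    into the cytosol, converted to B, and drained by a biomass reaction.
``blocked``
    The chain plus an orphan reaction C -> D with no inlet or outlet;
    the orphan is flux-blocked and D is unproducible.
``loop``
    The chain plus a futile internal 2-cycle (A -> B, B -> A); plain FBA
    can circulate arbitrary flux through the cycle, loop removal cannot.
``branched``
    Two symmetric redundant routes from A to B; a minimal network keeps
    exactly one, so retained-set sizes agree across seeds.
``glucose_pair`` / ``uro_pair``
    Two-reaction models built from published unbalanced/balanced reaction
    pairs (glucose-phosphate isomerization with and without two stray
    protons; uroporphyrinogen III methylation with and without six
    protons) that the reaction-based mass check localizes exactly.
``random``
    Randomized models that are elementally balanced by construction:
    compound compositions are drawn over a small pool of conserved
    pseudo-elements and every reaction is a rearrangement of those pools,
    so positive masses (total pseudo-atom counts) certify consistency.

Fault injection produces deliberately broken copies mirroring failure
modes observed in published models: an unbalanced equation (stray
protons), a mislabeled compartment, a compound duplicated on both sides,
and a closed exchange.  Same spec and seed always yield the same model.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from fractions import Fraction

from .equation import Compound, Direction, Equation, parse_equation
from .formula import Formula
from .genes import parse_genes
from .model import (
    CompoundEntry, LimitEntry, MediaEntry, Model, ReactionEntry)

FIXTURE_KINDS = (
    "chain", "blocked", "loop", "branched",
    "glucose_pair", "uro_pair", "random")


class FixtureError(ValueError):
    pass


@dataclass
class FixtureSpec:
    kind: str
    seed: int = 0
    n_reactions: int = 8
    n_compounds: int = 6
    n_elements: int = 4
    n_exchanges: int = 2
    faults: list["Fault"] = field(default_factory=list)


@dataclass
class Fault:
    kind: str  # 'unbalance' | 'shift_compartment' | 'duplicate' | 'close_exchange'
    reaction: str
    amount: int = 2


def _compound(model: Model, name: str, compartment: str,
              formula: str | None = None, charge: int | None = None) -> Compound:
    compound = Compound(name, compartment)
    model.add_compound(CompoundEntry(
        id=compound, formula=Formula.parse(formula) if formula else None,
        charge=charge))
    return compound


def _reaction(model: Model, rid: str, equation: str,
              genes: str | None = None, subsystem: str | None = None) -> None:
    model.add_reaction(ReactionEntry(
        id=rid, equation=parse_equation(equation),
        genes=parse_genes(genes) if genes else None,
        subsystem=subsystem))


def _chain(model: Model, with_genes: bool = True) -> None:
    _compound(model, "A", "e", "C6H12O6", 0)
    _compound(model, "A", "c", "C6H12O6", 0)
    _compound(model, "B", "c", "C6H12O6", 0)
    _reaction(model, "EX_A", "A[e] <=>")
    _reaction(model, "TP_A", "A[e] <=> A[c]",
              genes="gT" if with_genes else None, subsystem="Transport")
    _reaction(model, "R_AB", "A[c] => B[c]",
              genes="g1 or g2" if with_genes else None,
              subsystem="Central metabolism")
    _reaction(model, "BIO", "B[c] =>")
    model.biomass = "BIO"
    model.media.append(MediaEntry(
        compound=Compound("A", "e"), reaction="EX_A", lower=-10))


def make_fixture(spec: FixtureSpec | str, seed: int | None = None) -> Model:
    """Build a fixture model from a spec (or a bare kind name)."""
    if isinstance(spec, str):
        spec = FixtureSpec(kind=spec, seed=seed or 0)
    if spec.kind not in FIXTURE_KINDS:
        raise FixtureError(f"unknown fixture kind {spec.kind!r}")
    model = Model(name=f"fixture-{spec.kind}")

    if spec.kind == "chain":
        _chain(model)
    elif spec.kind == "blocked":
        _chain(model)
        _compound(model, "C", "c", "CH4O", 0)
        _compound(model, "D", "c", "CH4O", 0)
        _reaction(model, "R_CD", "C[c] => D[c]", subsystem="Orphan pathway")
    elif spec.kind == "loop":
        _chain(model)
        _reaction(model, "R_AB2", "A[c] => B[c]",
                  subsystem="Central metabolism")
        _reaction(model, "R_BA", "B[c] => A[c]",
                  subsystem="Central metabolism")
    elif spec.kind == "branched":
        _compound(model, "A", "e", "C6H12O6", 0)
        _compound(model, "A", "c", "C6H12O6", 0)
        _compound(model, "C1", "c", "C6H12O6", 0)
        _compound(model, "C2", "c", "C6H12O6", 0)
        _compound(model, "B", "c", "C6H12O6", 0)
        _reaction(model, "EX_A", "A[e] <=>")
        _reaction(model, "TP_A", "A[e] <=> A[c]")
        _reaction(model, "P1a", "A[c] => C1[c]", genes="ga1")
        _reaction(model, "P1b", "C1[c] => B[c]", genes="ga2")
        _reaction(model, "P2a", "A[c] => C2[c]", genes="gb1")
        _reaction(model, "P2b", "C2[c] => B[c]", genes="gb2")
        _reaction(model, "BIO", "B[c] =>")
        model.biomass = "BIO"
        model.media.append(MediaEntry(
            compound=Compound("A", "e"), reaction="EX_A", lower=-10))
    elif spec.kind == "glucose_pair":
        _compound(model, "D-Glucose 1-phosphate", "c", "C6H13O9P")
        _compound(model, "D-Glucose 6-phosphate", "c", "C6H13O9P")
        _compound(model, "H+", "c", "H", 1)
        _reaction(model, "RR00610",
                  "[c]: D-Glucose 1-phosphate + (2) H+ <==> "
                  "D-Glucose 6-phosphate")
        _reaction(model, "RR08939",
                  "[c]: D-Glucose 1-phosphate <==> D-Glucose 6-phosphate")
    elif spec.kind == "uro_pair":
        _compound(model, "Uroporphyrinogen III", "c", "C40H44N4O16")
        _compound(model, "S-Adenosyl-L-methionine", "c", "C15H23N6O5S", 1)
        _compound(model, "Precorrin 2", "c", "C42H46N4O16")
        _compound(model, "S-Adenosyl-L-homocysteine", "c", "C14H20N6O5S")
        _compound(model, "H+", "c", "H", 1)
        _reaction(model, "IR04287",
                  "[c]: Uroporphyrinogen III + "
                  "(2) S-Adenosyl-L-methionine --> Precorrin 2 + "
                  "(2) S-Adenosyl-L-homocysteine + H+")
        _reaction(model, "IR01815",
                  "[c]: Uroporphyrinogen III + (6) H+ + "
                  "(2) S-Adenosyl-L-methionine --> Precorrin 2 + "
                  "(2) S-Adenosyl-L-homocysteine")
    elif spec.kind == "random":
        _random_model(model, spec)

    for fault in spec.faults:
        model = inject_fault(model, fault)
    return model


_ELEMENT_POOL = ("X", "Y", "Z", "W", "Q", "V")


def _random_model(model: Model, spec: FixtureSpec) -> None:
    """Random model, balanced by construction over conserved pseudo-elements.

    Every compound is a positive integer combination of pseudo-element
    "monomers"; every reaction rearranges a random left side into existing
    compounds plus monomer change, so total pseudo-atom counts balance
    exactly and masses = total atom counts certify consistency.
    """
    if spec.n_elements < 1 or spec.n_elements > len(_ELEMENT_POOL):
        raise FixtureError("n_elements must be between 1 and 6")
    rng = random.Random(spec.seed)
    elements = _ELEMENT_POOL[: spec.n_elements]

    compositions: dict[Compound, dict[str, int]] = {}
    monomers = []
    for element in elements:
        compound = _compound(model, f"M{element}", "c", element)
        compositions[compound] = {element: 1}
        monomers.append(compound)
    for i in range(max(0, spec.n_compounds - spec.n_elements)):
        combo = {
            e: rng.randint(0, 3) for e in elements}
        if not any(combo.values()):
            combo[rng.choice(elements)] = 1
        formula = "".join(
            f"{e}{n}" for e, n in combo.items() if n)
        compound = _compound(model, f"C{i}", "c", formula)
        compositions[compound] = combo

    compounds = list(compositions)
    non_monomers = [c for c in compounds if c not in set(monomers)]
    left_pool = non_monomers or compounds
    for j in range(spec.n_reactions):
        k = rng.randint(1, min(3, len(left_pool)))
        left: dict[Compound, int] = {}
        total: dict[str, int] = {e: 0 for e in elements}
        for compound in rng.sample(left_pool, k):
            coef = rng.randint(1, 3)
            left[compound] = left.get(compound, 0) + coef
            for e, n in compositions[compound].items():
                total[e] += coef * n
        # Right side: one random compound that fits, plus monomer change.
        right: dict[Compound, int] = {}
        fits = [
            c for c in non_monomers
            if c not in left and all(
                compositions[c].get(e, 0) <= total[e] for e in elements)]
        if fits:
            chosen = rng.choice(fits)
            right[chosen] = 1
            for e, n in compositions[chosen].items():
                total[e] -= n
        for e, monomer in zip(elements, monomers):
            if total[e] > 0 and monomer not in left:
                right[monomer] = right.get(monomer, 0) + total[e]
                total[e] = 0
        if any(total.values()) or not right:
            continue  # skip degenerate constructions
        direction = Direction.BOTH if rng.random() < 0.4 \
            else Direction.FORWARD
        equation = Equation(
            [(c, Fraction(n)) for c, n in left.items()],
            [(c, Fraction(n)) for c, n in right.items()],
            direction)
        model.add_reaction(ReactionEntry(f"R{j}", equation,
                                         subsystem=f"S{j % 3}"))

    # A few exchanges make parts of the network runnable.
    exchanged = rng.sample(compounds, min(spec.n_exchanges, len(compounds)))
    for i, compound in enumerate(exchanged):
        model.add_reaction(ReactionEntry(
            f"EX{i}",
            Equation([(compound, Fraction(1))], [], Direction.BOTH)))


def inject_fault(model: Model, fault: Fault) -> Model:
    """Return a modified copy of the model with one deliberate defect."""
    result = model.copy()
    if fault.reaction not in result.reactions:
        raise FixtureError(f"unknown reaction {fault.reaction!r}")
    entry = result.reactions[fault.reaction]
    eq = entry.equation

    if fault.kind == "unbalance":
        # Stray protons: add `amount` extra units of a compound to the
        # right side only.
        proton = Compound("H+", "c")
        if proton not in result.compounds:
            result.add_compound(CompoundEntry(id=proton,
                                              formula=Formula.parse("H")))
        entry.equation = Equation(
            eq.left, list(eq.right) + [(proton, Fraction(fault.amount))],
            eq.direction)
    elif fault.kind == "shift_compartment":
        # Mislabel the compartment of the first left-side compound.
        if not eq.left:
            raise FixtureError("reaction has no left side to mislabel")
        compound, value = eq.left[0]
        wrong = compound.in_compartment(
            "x" if compound.compartment != "x" else "y")
        if wrong not in result.compounds:
            source = result.compounds.get(compound)
            result.add_compound(CompoundEntry(
                id=wrong,
                formula=source.formula if source else None,
                charge=source.charge if source else None))
        entry.equation = Equation(
            [(wrong, value)] + list(eq.left[1:]), eq.right, eq.direction)
    elif fault.kind == "duplicate":
        # Same compound on both sides of one equation.
        if not eq.left:
            raise FixtureError("reaction has no left side to duplicate")
        compound, _ = eq.left[0]
        entry.equation = Equation(
            eq.left, list(eq.right) + [(compound, Fraction(1))],
            eq.direction)
    elif fault.kind == "close_exchange":
        if not result.is_exchange(fault.reaction):
            raise FixtureError(
                f"reaction {fault.reaction!r} is not an exchange")
        limits = result.limits_map()
        if fault.reaction in limits:
            limits[fault.reaction].lower = 0.0
            limits[fault.reaction].upper = 0.0
        else:
            result.limits.append(LimitEntry(fault.reaction, 0.0, 0.0))
        result.media = [
            m for m in result.media if m.reaction != fault.reaction]
    else:
        raise FixtureError(f"unknown fault kind {fault.kind!r}")
    return result
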