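"""Reaction equations over compartmentalized compounds.

The interchange grammar, used in YAML files and on the command line::

    equation   := [ "[" compartment "]" ":" ] side arrow side
    side       := term ( " + " term )* | ""
    term       := [ coefficient ] compound-name [ "[" compartment "]" ]
    coefficient:= "(" number ")" | integer-or-decimal
    arrow      := "-->" | "<--" | "<==>" | "=>" | "<=>"

Compound names may contain spaces, digits, and "+" (e.g. ``D-Glucose
1-phosphate`` or ``H+``); terms are therefore separated by ``+`` flanked by
whitespace, and coefficients are normally parenthesized.  A leading global
compartment (``[c]:``) applies to every compound that lacks its own suffix.
Stoichiometric coefficients are exact rationals.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Iterator, Union

Number = Union[int, float, str, Fraction]


class EquationParseError(ValueError):
    """Malformed equation text; message names the offending token."""


class Direction(enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    BOTH = "both"

    @property
    def arrow(self) -> str:
        return {_D.FORWARD: "-->", _D.REVERSE: "<--", _D.BOTH: "<==>"}[self]


_D = Direction


@dataclass(frozen=True, order=True)
class Compound:
    """A compound identifier: base name plus optional compartment label."""

    name: str
    compartment: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("compound name must be non-empty")

    def in_compartment(self, compartment: str | None) -> "Compound":
        return Compound(self.name, compartment)

    def __str__(self) -> str:
        if self.compartment is None:
            return self.name
        return f"{self.name}[{self.compartment}]"

    @classmethod
    def parse(cls, text: str) -> "Compound":
        text = text.strip()
        m = re.match(r"^(.*?)\[(\w+)\]$", text)
        if m:
            return cls(m.group(1).strip(), m.group(2))
        return cls(text)


Term = tuple[Compound, Fraction]

_ARROWS = [
    ("<==>", _D.BOTH),
    ("<=>", _D.BOTH),
    ("-->", _D.FORWARD),
    ("<--", _D.REVERSE),
    ("=>", _D.FORWARD),
]
_ARROW_RE = re.compile(
    "(?:(?<=\\s)|^)(" + "|".join(re.escape(a) for a, _ in _ARROWS) + ")(?=\\s|$)")
_TERM_SPLIT = re.compile(r"\s\+\s")
_PAREN_COEF = re.compile(r"^\((?P<coef>-?\d+(?:\.\d+)?(?:/\d+)?)\)\s+(?P<rest>.+)$")
_BARE_COEF = re.compile(r"^(?P<coef>\d+(?:\.\d+)?(?:/\d+)?)\s+(?P<rest>.+)$")
_GLOBAL_COMPARTMENT = re.compile(r"^\[(?P<compartment>\w+)\]\s*:\s*")


class Equation:
    """Signed stoichiometry over compounds with a direction.

    ``left`` and ``right`` preserve the order in which terms were written,
    giving a deterministic canonical rendering.  A compound may appear on
    both sides (some imported models contain such equations); validation,
    not parsing, is responsible for flagging that.
    """

    __slots__ = ("left", "right", "direction")

    def __init__(
        self,
        left: Iterable[tuple[Compound, Number]],
        right: Iterable[tuple[Compound, Number]],
        direction: Direction = Direction.BOTH,
    ) -> None:
        self.left: tuple[Term, ...] = tuple(
            (c, Fraction(n)) for c, n in left)
        self.right: tuple[Term, ...] = tuple(
            (c, Fraction(n)) for c, n in right)
        self.direction = direction
        for compound, value in self.left + self.right:
            if value <= 0:
                raise ValueError(
                    f"non-positive stoichiometry {value} for {compound}")

    def compounds(self) -> Iterator[Compound]:
        seen = set()
        for compound, _ in self.left + self.right:
            if compound not in seen:
                seen.add(compound)
                yield compound

    def net(self) -> dict[Compound, Fraction]:
        """Net stoichiometry: negative for consumed, positive for produced."""
        totals: dict[Compound, Fraction] = {}
        for compound, value in self.left:
            totals[compound] = totals.get(compound, Fraction(0)) - value
        for compound, value in self.right:
            totals[compound] = totals.get(compound, Fraction(0)) + value
        return totals

    def duplicate_compounds(self) -> set[Compound]:
        """Compounds that appear on both sides of the equation."""
        return {c for c, _ in self.left} & {c for c, _ in self.right}

    def reversed(self) -> "Equation":
        direction = {
            _D.FORWARD: _D.REVERSE,
            _D.REVERSE: _D.FORWARD,
            _D.BOTH: _D.BOTH,
        }[self.direction]
        return Equation(self.right, self.left, direction)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Equation):
            return NotImplemented
        return (self.left == other.left and self.right == other.right
                and self.direction == other.direction)

    def __hash__(self) -> int:
        return hash((self.left, self.right, self.direction))

    def __repr__(self) -> str:
        return f"Equation.parse({str(self)!r})"

    def __str__(self) -> str:
        return self.render()

    def render(self, compact: bool = True) -> str:
        """Render to interchange text.

        With ``compact``, a compartment shared by every compound is factored
        into a ``[c]:`` prefix, matching the conventional printed form.
        """
        prefix = ""
        strip: str | None = None
        if compact:
            compartments = {c.compartment for c, _ in self.left + self.right}
            if len(compartments) == 1:
                only = next(iter(compartments))
                if only is not None:
                    prefix = f"[{only}]: "
                    strip = only

        def side(terms: tuple[Term, ...]) -> str:
            parts = []
            for compound, value in terms:
                name = compound.name if compound.compartment == strip \
                    else str(compound)
                if value == 1:
                    parts.append(name)
                else:
                    coef = str(value.numerator) if value.denominator == 1 \
                        else f"{value.numerator}/{value.denominator}"
                    parts.append(f"({coef}) {name}")
            return " + ".join(parts)

        left, right = side(self.left), side(self.right)
        return f"{prefix}{left} {self.direction.arrow} {right}".strip()

    @classmethod
    def parse(cls, text: str) -> "Equation":
        return parse_equation(text)


def _parse_term(text: str, compartment: str | None, position: int) -> Term:
    text = text.strip()
    if not text:
        raise EquationParseError(f"empty term at position {position}")
    coef = Fraction(1)
    m = _PAREN_COEF.match(text) or _BARE_COEF.match(text)
    if m:
        coef = Fraction(m.group("coef"))
        text = m.group("rest")
    compound = Compound.parse(text)
    if compound.compartment is None and compartment is not None:
        compound = compound.in_compartment(compartment)
    if coef <= 0:
        raise EquationParseError(
            f"non-positive coefficient {coef} for {compound} "
            f"at position {position}")
    return compound, coef


def parse_equation(text: str) -> Equation:
    """Parse equation text in the interchange grammar."""
    original = text
    compartment = None
    m = _GLOBAL_COMPARTMENT.match(text)
    offset = 0
    if m:
        compartment = m.group("compartment")
        offset = m.end()
        text = text[m.end():]

    arrows = list(_ARROW_RE.finditer(text))
    if not arrows:
        raise EquationParseError(f"no arrow found in equation {original!r}")
    if len(arrows) > 1:
        pos = offset + arrows[1].start()
        raise EquationParseError(
            f"multiple arrows in equation {original!r} (second at position {pos})")
    arrow = arrows[0]
    direction = dict(_ARROWS)[arrow.group(1)]

    def parse_side(segment: str, base: int) -> list[Term]:
        if not segment.strip():
            return []
        terms = []
        pos = base
        for part in _TERM_SPLIT.split(segment):
            terms.append(_parse_term(part, compartment, pos))
            pos += len(part) + 3
        return terms

    left = parse_side(text[: arrow.start()], offset)
    right = parse_side(text[arrow.end():], offset + arrow.end())
    if not left and not right:
        raise EquationParseError(f"equation {original!r} has no compounds")
    return Equation(left, right, direction)
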