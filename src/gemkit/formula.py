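"""Chemical formula handling.

A formula is an elemental composition: a mapping from element symbols to
non-negative rational atom counts.  Compositions add and scale elementwise,
which is all that is needed to check whether a reaction equation conserves
every element.
"""

from __future__ import annotations

import re
from fractions import Fraction
from typing import Iterator, Mapping, Union

Number = Union[int, Fraction]


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed."""


_TOKEN = re.compile(r"([A-Z][a-z]*)(\d+(?:\.\d+)?)?|(\()|(\))(\d+)?|(\s+)|(.)")


class Formula:
    """Elemental composition with exact rational counts.

    Zero-count entries are never stored, so two compositions are equal
    exactly when they contain the same elements with the same counts.
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, Number] | None = None) -> None:
        self._counts: dict[str, Fraction] = {}
        if counts:
            for element, count in counts.items():
                count = Fraction(count)
                if count < 0:
                    raise ValueError(f"negative count for element {element!r}")
                if count != 0:
                    self._counts[element] = count

    @classmethod
    def parse(cls, text: str) -> "Formula":
        counts, pos = _parse_group(text, 0, depth=0)
        if pos != len(text):
            raise FormulaError(
                f"unexpected {text[pos]!r} at position {pos} in formula {text!r}")
        return cls(counts)

    def get(self, element: str) -> Fraction:
        return self._counts.get(element, Fraction(0))

    def items(self) -> Iterator[tuple[str, Fraction]]:
        return iter(sorted(self._counts.items()))

    def elements(self) -> set[str]:
        return set(self._counts)

    def __add__(self, other: "Formula") -> "Formula":
        counts = dict(self._counts)
        for element, count in other._counts.items():
            counts[element] = counts.get(element, Fraction(0)) + count
        return Formula(counts)

    def __sub__(self, other: "Formula") -> "Formula":
        # Difference may go negative; used only through ``difference`` below.
        counts: dict[str, Fraction] = dict(self._counts)
        for element, count in other._counts.items():
            counts[element] = counts.get(element, Fraction(0)) - count
        result = Formula.__new__(Formula)
        result._counts = {e: c for e, c in counts.items() if c != 0}
        return result

    def __mul__(self, factor: Number) -> "Formula":
        factor = Fraction(factor)
        return Formula({e: c * factor for e, c in self._counts.items()})

    __rmul__ = __mul__

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self._counts == other._counts

    def __hash__(self) -> int:
        return hash(frozenset(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __repr__(self) -> str:
        return f"Formula({self._counts!r})"

    def __str__(self) -> str:
        parts = []
        for element in sorted(self._counts, key=_hill_key):
            count = self._counts[element]
            if count == 1:
                parts.append(element)
            elif count.denominator == 1:
                parts.append(f"{element}{count.numerator}")
            else:
                parts.append(f"{element}{float(count):g}")
        return "".join(parts)


def _hill_key(element: str) -> tuple[int, str]:
    # Hill order: carbon, then hydrogen, then alphabetic.
    return {"C": (0, ""), "H": (1, "")}.get(element, (2, element))


def _parse_group(text: str, pos: int, depth: int) -> tuple[dict[str, Fraction], int]:
    counts: dict[str, Fraction] = {}
    while pos < len(text):
        ch = text[pos]
        if ch == "(":
            inner, pos = _parse_group(text, pos + 1, depth + 1)
            if pos >= len(text) or text[pos] != ")":
                raise FormulaError(f"unclosed parenthesis in formula {text!r}")
            pos += 1
            m = re.match(r"\d+", text[pos:])
            mult = Fraction(1)
            if m:
                mult = Fraction(m.group(0))
                pos += m.end()
            for element, count in inner.items():
                counts[element] = counts.get(element, Fraction(0)) + count * mult
        elif ch == ")":
            if depth == 0:
                raise FormulaError(
                    f"dangling ')' at position {pos} in formula {text!r}")
            return counts, pos
        else:
            m = re.match(r"([A-Z][a-z]*)(\d+(?:\.\d+)?)?", text[pos:])
            if m is None:
                raise FormulaError(
                    f"unexpected {ch!r} at position {pos} in formula {text!r}")
            element = m.group(1)
            count = Fraction(m.group(2)) if m.group(2) else Fraction(1)
            counts[element] = counts.get(element, Fraction(0)) + count
            pos += m.end()
    if depth != 0:
        raise FormulaError(f"unclosed parenthesis in formula {text!r}")
    return counts, pos


def parse_formula(text: str) -> Formula:
    """Parse a Hill-style formula such as ``C6H12O6`` or ``C2H3(CH2)2COOH``."""
    return Formula.parse(text)
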