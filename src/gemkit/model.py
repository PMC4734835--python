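"""Model container and the sparse stoichiometric view.

A :class:`Model` is a named collection of reaction and compound entries
plus the simulation context: a biomass designation, growth-medium entries
(exchange reactions and their uptake/secretion limits), explicit flux
limits, an optional ``model_subset`` (when the reaction list is a broader
database and only a subset belongs to the model proper), and a default
flux limit.

Flux bounds follow the convention: reversible reactions get [-x, x],
irreversible ones [0, x] (or [-x, 0] for reverse-only), with x the model's
``default_flux_limit`` (1000 when unset); explicit limits override per
side.

:func:`matrix_view` materializes the compound-by-reaction stoichiometric
matrix S over the reactions in the model subset, together with resolved
flux bounds; every consistency check and simulation consumes this view.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Iterator, Mapping

from .equation import Compound, Direction, Equation
from .formula import Formula
from .genes import GeneExpression

DEFAULT_FLUX_LIMIT = 1000.0


class ModelError(ValueError):
    pass


@dataclass
class CompoundEntry:
    id: Compound
    name: str | None = None
    formula: Formula | None = None
    charge: int | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class ReactionEntry:
    id: str
    equation: Equation
    genes: GeneExpression | None = None
    subsystem: str | None = None
    ec: str | None = None
    extra: dict = field(default_factory=dict)


@dataclass
class MediaEntry:
    """A growth-medium entry: an exchange compound and its flux limits.

    ``reaction`` optionally names the exchange reaction; when the model has
    no such reaction one is synthesized in the matrix view.  ``lower`` is
    the uptake limit (negative flux = uptake), ``upper`` the secretion
    limit; either may be None to fall back to the default limit.
    """

    compound: Compound
    reaction: str | None = None
    lower: float | None = None
    upper: float | None = None


@dataclass
class LimitEntry:
    reaction: str
    lower: float | None = None
    upper: float | None = None


@dataclass
class Model:
    name: str = "unnamed"
    reactions: dict[str, ReactionEntry] = field(default_factory=dict)
    compounds: dict[Compound, CompoundEntry] = field(default_factory=dict)
    biomass: str | None = None
    media: list[MediaEntry] = field(default_factory=list)
    limits: list[LimitEntry] = field(default_factory=list)
    model_subset: set[str] | None = None
    default_flux_limit: float = DEFAULT_FLUX_LIMIT
    meta: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list, compare=False)

    def add_reaction(self, entry: ReactionEntry) -> None:
        if entry.id in self.reactions:
            raise ModelError(f"duplicate reaction id {entry.id!r}")
        self.reactions[entry.id] = entry
        for compound in entry.equation.compounds():
            if compound not in self.compounds:
                self.warnings.append(
                    f"compound {compound} of reaction {entry.id} not in "
                    f"compound list; registered bare entry")
                self.compounds[compound] = CompoundEntry(id=compound)

    def add_compound(self, entry: CompoundEntry) -> None:
        self.compounds[entry.id] = entry

    def subset_ids(self) -> list[str]:
        """Reaction ids in the model proper, in insertion order."""
        if self.model_subset is None:
            return list(self.reactions)
        return [r for r in self.reactions if r in self.model_subset]

    def limits_map(self) -> dict[str, LimitEntry]:
        return {entry.reaction: entry for entry in self.limits}

    def is_exchange(self, reaction_id: str) -> bool:
        entry = self.reactions.get(reaction_id)
        if entry is None:
            # Media-synthesized exchange columns are exchanges by definition.
            return any(m.reaction == reaction_id for m in self.media)
        eq = entry.equation
        return not eq.left or not eq.right

    def exchange_ids(self) -> set[str]:
        ids = {r for r in self.subset_ids() if self.is_exchange(r)}
        ids.update(
            _media_reaction_id(m) for m in self.media)
        return ids

    def genes(self) -> set[str]:
        from .genes import iter_genes
        names: set[str] = set()
        for entry in self.reactions.values():
            if entry.genes is not None:
                names.update(iter_genes(entry.genes))
        return names

    def validate(self) -> list[str]:
        """Cross-reference checks; returns (and records) warning messages."""
        problems: list[str] = []
        if self.model_subset is not None:
            unknown = self.model_subset - set(self.reactions)
            if unknown:
                raise ModelError(
                    f"model subset names unknown reactions: {sorted(unknown)}")
        if self.biomass is not None and self.biomass not in self.reactions:
            raise ModelError(f"biomass reaction {self.biomass!r} not defined")
        for entry in self.limits:
            if entry.reaction not in self.reactions:
                raise ModelError(
                    f"limits name unknown reaction {entry.reaction!r}")
            if (entry.lower is not None and entry.upper is not None
                    and entry.lower > entry.upper):
                raise ModelError(
                    f"limits for {entry.reaction!r}: lower {entry.lower} "
                    f"exceeds upper {entry.upper}")
        for rid, entry in self.reactions.items():
            dupes = entry.equation.duplicate_compounds()
            if dupes:
                problems.append(
                    f"reaction {rid} has compounds on both sides: "
                    + ", ".join(str(c) for c in sorted(dupes)))
        self.warnings.extend(problems)
        return problems

    def copy(self) -> "Model":
        return copy.deepcopy(self)


def _media_reaction_id(entry: MediaEntry) -> str:
    if entry.reaction is not None:
        return entry.reaction
    base = "".join(
        ch if ch.isalnum() else "_" for ch in entry.compound.name)
    comp = entry.compound.compartment or ""
    return f"EX_{base}_{comp}".rstrip("_")


def resolve_bounds(
    reaction: ReactionEntry,
    explicit: LimitEntry | None,
    default_limit: float,
) -> tuple[tuple[float, float], list[str]]:
    """Resolve flux bounds for one reaction.

    Explicit limits override the direction-derived defaults per side.  A
    limit that opens flow against the equation's stated direction is kept
    (imported COBRA bounds take precedence) but recorded as a
    reversibility-conflict warning.
    """
    if default_limit <= 0:
        raise ModelError("default flux limit must be positive")
    x = float(default_limit)
    direction = reaction.equation.direction
    if direction is Direction.BOTH:
        lower, upper = -x, x
    elif direction is Direction.FORWARD:
        lower, upper = 0.0, x
    else:
        lower, upper = -x, 0.0

    warnings: list[str] = []
    if explicit is not None:
        if explicit.lower is not None:
            lower = float(explicit.lower)
        if explicit.upper is not None:
            upper = float(explicit.upper)
        if lower > upper:
            raise ModelError(
                f"reaction {reaction.id}: lower bound {lower} exceeds "
                f"upper bound {upper}")
        if direction is Direction.FORWARD and lower < 0:
            warnings.append(
                f"reaction {reaction.id} is irreversible (forward) but has "
                f"negative lower bound {lower}")
        if direction is Direction.REVERSE and upper > 0:
            warnings.append(
                f"reaction {reaction.id} is irreversible (reverse) but has "
                f"positive upper bound {upper}")
    return (lower, upper), warnings


class StoichiometricMatrix:
    """Sparse compound-by-reaction stoichiometry plus per-reaction bounds.

    Entries are exact rationals: negative for consumed (left side)
    compounds, positive for produced ones.  Column order is the model's
    reaction insertion order (media-synthesized exchanges last); row order
    is first appearance.
    """

    def __init__(self) -> None:
        self.entries: dict[tuple[Compound, str], Fraction] = {}
        self.compounds: list[Compound] = []
        self._compound_set: set[Compound] = set()
        self.reactions: list[str] = []
        self.bounds: dict[str, tuple[float, float]] = {}
        self.warnings: list[str] = []

    def add_column(
        self,
        reaction_id: str,
        net: Mapping[Compound, Fraction],
        bounds: tuple[float, float],
    ) -> None:
        if reaction_id in self.bounds:
            raise ModelError(f"duplicate matrix column {reaction_id!r}")
        self.reactions.append(reaction_id)
        self.bounds[reaction_id] = bounds
        for compound, value in net.items():
            if value == 0:
                continue
            if compound not in self._compound_set:
                self._compound_set.add(compound)
                self.compounds.append(compound)
            self.entries[(compound, reaction_id)] = value

    def column(self, reaction_id: str) -> dict[Compound, Fraction]:
        return {
            c: v for (c, r), v in self.entries.items() if r == reaction_id}

    def value(self, compound: Compound, reaction_id: str) -> Fraction:
        return self.entries.get((compound, reaction_id), Fraction(0))

    def __iter__(self) -> Iterator[tuple[tuple[Compound, str], Fraction]]:
        return iter(self.entries.items())


def matrix_view(model: Model) -> StoichiometricMatrix:
    """Build the stoichiometric matrix over the model-subset reactions.

    Media entries override (or create) exchange columns; explicit limits
    override defaults; reactions outside ``model_subset`` are excluded.
    """
    matrix = StoichiometricMatrix()
    limits = model.limits_map()
    media_by_reaction: dict[str, MediaEntry] = {}
    for entry in model.media:
        media_by_reaction[_media_reaction_id(entry)] = entry

    for rid in model.subset_ids():
        entry = model.reactions[rid]
        explicit = limits.get(rid)
        media = media_by_reaction.get(rid)
        if explicit is None and media is not None:
            explicit = LimitEntry(rid, media.lower, media.upper)
        bounds, warns = resolve_bounds(
            entry, explicit, model.default_flux_limit)
        matrix.warnings.extend(warns)
        matrix.add_column(rid, entry.equation.net(), bounds)

    # Media entries with no corresponding reaction synthesize an exchange
    # column: compound <=> (nothing), negative flux = uptake.
    for rid, media in media_by_reaction.items():
        if rid in matrix.bounds:
            continue
        x = model.default_flux_limit
        lower = -x if media.lower is None else float(media.lower)
        upper = x if media.upper is None else float(media.upper)
        if lower > upper:
            raise ModelError(
                f"media entry for {media.compound}: lower {lower} exceeds "
                f"upper {upper}")
        matrix.add_column(rid, {media.compound: Fraction(-1)}, (lower, upper))
    return matrix
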