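"""Tab-delimited reaction and compound tables.

Many published models ship annotation tables rather than structured
files.  The importer reads a delimited text file with a header row, maps
columns onto entry fields, preserves unmapped columns verbatim in
``extra``, and reports structural damage — a row whose column count does
not match the header (the classic column-shift editing accident) — by row
number.  A compound-synonym mapping hook repairs misspelled compound
identifiers in equations during import.
"""

from __future__ import annotations

import csv
from fractions import Fraction
from pathlib import Path

from ..equation import Compound, Equation, parse_equation
from ..formula import Formula, FormulaError
from ..genes import parse_genes, render_genes
from ..model import CompoundEntry, Model, ReactionEntry

REACTION_FIELDS = {"id", "equation", "genes", "subsystem", "ec", "name"}
COMPOUND_FIELDS = {"id", "name", "formula", "charge"}


class TableError(ValueError):
    pass


def _read_rows(path: Path, delimiter: str = "\t"):
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        header = None
        for number, row in enumerate(reader, start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if header is None:
                header = [cell.strip() for cell in row]
                continue
            if len(row) != len(header):
                raise TableError(
                    f"{path.name}: row {number} has {len(row)} columns, "
                    f"header has {len(header)} (column shift?)")
            yield number, dict(zip(header, (cell.strip() for cell in row)))
        if header is None:
            raise TableError(f"{path.name}: empty table")


def _apply_synonyms(equation: Equation, synonyms: dict[str, str]) -> Equation:
    def fix(terms):
        return [
            (Compound(synonyms.get(c.name, c.name), c.compartment), v)
            for c, v in terms]
    return Equation(fix(equation.left), fix(equation.right),
                    equation.direction)


def parse_reaction_row(
    row: dict[str, str],
    mapping: dict[str, str] | None = None,
    synonyms: dict[str, str] | None = None,
    location: str = "",
) -> ReactionEntry:
    """Build a reaction entry from one table row.

    ``mapping`` maps table column names onto entry fields; identity by
    default.  Unmapped columns land in ``extra``.
    """
    mapping = mapping or {}
    fields: dict[str, str] = {}
    extra: dict[str, str] = {}
    for column, value in row.items():
        target = mapping.get(column, column)
        if target in REACTION_FIELDS:
            fields[target] = value
        elif value != "":
            extra[column] = value
    if not fields.get("id"):
        raise TableError(f"{location}: missing reaction id")
    if not fields.get("equation"):
        raise TableError(
            f"{location}: reaction {fields['id']!r} has no equation")
    equation = parse_equation(fields["equation"])
    if synonyms:
        equation = _apply_synonyms(equation, synonyms)
    genes = None
    if fields.get("genes"):
        genes = parse_genes(fields["genes"])
    if fields.get("name"):
        extra.setdefault("name", fields["name"])
    return ReactionEntry(
        id=fields["id"],
        equation=equation,
        genes=genes,
        subsystem=fields.get("subsystem") or None,
        ec=fields.get("ec") or None,
        extra=extra,
    )


def parse_compound_row(
    row: dict[str, str],
    mapping: dict[str, str] | None = None,
    location: str = "",
) -> CompoundEntry:
    mapping = mapping or {}
    fields: dict[str, str] = {}
    extra: dict[str, str] = {}
    for column, value in row.items():
        target = mapping.get(column, column)
        if target in COMPOUND_FIELDS:
            fields[target] = value
        elif value != "":
            extra[column] = value
    if not fields.get("id"):
        raise TableError(f"{location}: missing compound id")
    formula = None
    if fields.get("formula"):
        try:
            formula = Formula.parse(fields["formula"])
        except FormulaError:
            extra["formula"] = fields["formula"]
    charge = None
    if fields.get("charge") not in (None, ""):
        charge = int(fields["charge"])
    return CompoundEntry(
        id=Compound.parse(fields["id"]),
        name=fields.get("name") or None,
        formula=formula,
        charge=charge,
        extra=extra,
    )


def import_table(
    reaction_file: str | Path,
    compound_file: str | Path | None = None,
    mapping: dict[str, str] | None = None,
    synonyms: dict[str, str] | None = None,
    name: str | None = None,
) -> Model:
    """Import a model from delimited reaction (and optional compound) tables."""
    reaction_file = Path(reaction_file)
    model = Model(name=name or reaction_file.stem)
    if compound_file is not None:
        compound_file = Path(compound_file)
        for number, row in _read_rows(compound_file):
            model.add_compound(parse_compound_row(
                row, mapping, location=f"{compound_file.name}:{number}"))
    for number, row in _read_rows(reaction_file):
        model.add_reaction(parse_reaction_row(
            row, mapping, synonyms,
            location=f"{reaction_file.name}:{number}"))
    return model


def export_tables(model: Model, directory: str | Path) -> list[Path]:
    """Write reactions.tsv and compounds.tsv summaries."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    reaction_path = directory / "reactions.tsv"
    compound_path = directory / "compounds.tsv"

    with open(reaction_path, "w", encoding="utf-8") as handle:
        handle.write("id\tequation\tgenes\tsubsystem\tec\n")
        for rid, entry in model.reactions.items():
            genes = render_genes(entry.genes) if entry.genes else ""
            handle.write("\t".join([
                rid, entry.equation.render(),
                genes, entry.subsystem or "", entry.ec or "",
            ]) + "\n")
    with open(compound_path, "w", encoding="utf-8") as handle:
        handle.write("id\tname\tformula\tcharge\n")
        for compound, entry in model.compounds.items():
            handle.write("\t".join([
                str(compound), entry.name or "",
                str(entry.formula) if entry.formula else "",
                "" if entry.charge is None else str(entry.charge),
            ]) + "\n")
    return [reaction_path, compound_path]
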