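"""SBML import and export with a built-in parser.

The importer reads SBML levels 1-3 (standard or COBRA dialect) using the
standard library XML tools.  Two modes:

*strict* — any deviation from the specification, and any of the known
COBRA-dialect inconsistencies below, is an error.

*lax* (default) — four common inconsistencies seen in published models
are repaired automatically, each with a warning:

(a) decimal stoichiometry is accepted at every SBML level, although
    level 1 only permits integers;
(b) species whose id ends in the boundary suffix (``_b`` by convention)
    but lack ``boundaryCondition`` are treated as boundary species, which
    turns the reactions touching them into exchange reactions;
(c) references to undefined species are dropped from equations;
(d) reactions marked irreversible but carrying a negative COBRA
    ``LOWER_BOUND`` keep the COBRA bounds, with a reversibility-conflict
    warning.

Species flagged ``boundaryCondition="true"`` are excluded from the
network and their equation terms removed (they are external by
definition).  COBRA kinetic-law parameters LOWER_BOUND / UPPER_BOUND /
OBJECTIVE_COEFFICIENT are read into flux limits and the objective;
the biomass reaction is detected from the objective coefficients, falling
back to a case-insensitive id search for "biomass".

Species ids are decoded by stripping the conventional ``M_`` prefix and a
trailing compartment token matching the compartment attribute; the
original id is kept in ``extra["sbml_id"]`` for traceability.  When every
species carries a unique ``name`` attribute the names are used as
compound identifiers instead (they are what printed equations use);
otherwise decoded ids are used.

Export targets level 2 with COBRA-dialect kinetic-law bound parameters.
One-sided (exchange) equations gain a counterpart species with
``boundaryCondition="true"``, so a strict re-import reproduces the
one-sided form.
"""

from __future__ import annotations

import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

from ..equation import Compound, Direction, Equation
from ..genes import render_genes
from ..model import (
    CompoundEntry, LimitEntry, Model, ReactionEntry, matrix_view,
    resolve_bounds)

BOUNDARY_SUFFIX = "_b"
SBML_L2_NS = "http://www.sbml.org/sbml/level2"


class SbmlError(ValueError):
    pass


@dataclass
class ImportReport:
    """Warnings and repairs recorded while importing a model."""

    warnings: list[tuple[str, str, str]] = field(default_factory=list)
    repairs: list[tuple[str, str]] = field(default_factory=list)
    objectives: dict[str, float] = field(default_factory=dict)

    def warn(self, code: str, message: str, location: str = "") -> None:
        self.warnings.append((code, message, location))

    def repair(self, code: str, location: str = "") -> None:
        self.repairs.append((code, location))


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _children(element, name: str):
    for child in element:
        if _local(child.tag) in (name, name.rstrip("s") + "s"):
            yield child


def _find(element, name: str):
    for child in element:
        if _local(child.tag) == name:
            return child
    return None


def _decode_species_id(raw: str, compartment: str | None) -> str:
    base = raw
    if base.startswith("M_"):
        base = base[2:]
    if compartment and base.endswith(f"_{compartment}"):
        base = base[: -(len(compartment) + 1)]
    return base


def _guess_compartment(raw: str) -> str | None:
    m = re.match(r"^.+_([a-z])$", raw)
    return m.group(1) if m else None


def import_sbml(
    path: str | Path, strict: bool = False
) -> tuple[Model, ImportReport]:
    """Import an SBML file; returns the model and the import report."""
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SbmlError(f"{path.name}: malformed XML: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise SbmlError(f"{path.name}: root element is not <sbml>")
    level = int(root.get("level", "2"))
    model_el = _find(root, "model")
    if model_el is None:
        raise SbmlError(f"{path.name}: no <model> element")

    report = ImportReport()
    model = Model(
        name=model_el.get("name") or model_el.get("id") or path.stem)

    # --- species ---------------------------------------------------
    species_els = []
    list_el = _find(model_el, "listOfSpecies")
    if list_el is not None:
        for el in list_el:
            if _local(el.tag) in ("species", "specie"):
                species_els.append(el)

    names = [el.get("name") for el in species_els]
    use_names = (
        species_els and all(names)
        and len(set(names)) == len(names))

    boundary: set[str] = set()
    species_map: dict[str, Compound] = {}
    for el in species_els:
        raw = el.get("id") or el.get("name")
        if raw is None:
            raise SbmlError(f"{path.name}: species without id")
        compartment = el.get("compartment") or _guess_compartment(raw)
        is_boundary = el.get("boundaryCondition") == "true"
        if not is_boundary and raw.endswith(BOUNDARY_SUFFIX):
            if strict:
                raise SbmlError(
                    f"{path.name}: species {raw!r} uses the boundary "
                    f"suffix {BOUNDARY_SUFFIX!r} instead of the "
                    f"boundaryCondition attribute")
            report.warn(
                "boundary_suffix",
                f"species {raw!r} treated as a boundary species by its "
                f"{BOUNDARY_SUFFIX!r} suffix", raw)
            report.repair("boundary_suffix", raw)
            is_boundary = True
        if is_boundary:
            boundary.add(raw)
            continue
        if use_names:
            base = el.get("name")
        else:
            base = _decode_species_id(raw, compartment)
        compound = Compound(base, compartment)
        species_map[raw] = compound
        extra = {"sbml_id": raw}
        charge = el.get("charge")
        model.add_compound(CompoundEntry(
            id=compound,
            name=el.get("name"),
            charge=int(charge) if charge is not None else None,
            extra=extra,
        ))

    # --- reactions -------------------------------------------------
    def parse_terms(reaction_el, kind: str, rid: str):
        terms = []
        list_el = _find(reaction_el, kind)
        if list_el is None:
            return terms
        for ref in list_el:
            if _local(ref.tag) not in ("speciesReference", "specieReference"):
                continue
            raw = ref.get("species") or ref.get("specie")
            text = ref.get("stoichiometry", "1")
            denominator = int(ref.get("denominator", "1"))
            try:
                value = Fraction(text)
            except ValueError as exc:
                raise SbmlError(
                    f"{path.name}: reaction {rid!r}: bad stoichiometry "
                    f"{text!r}") from exc
            value /= denominator
            if level == 1 and "." in text:
                if strict:
                    raise SbmlError(
                        f"{path.name}: reaction {rid!r}: decimal "
                        f"stoichiometry {text!r} is not permitted in "
                        f"SBML level 1")
                report.warn(
                    "decimal_stoichiometry",
                    f"reaction {rid!r}: decimal stoichiometry {text!r} "
                    f"accepted despite SBML level 1", rid)
                report.repair("decimal_stoichiometry", rid)
            if raw in boundary:
                continue
            if raw not in species_map:
                if strict:
                    raise SbmlError(
                        f"{path.name}: reaction {rid!r} references "
                        f"undefined species {raw!r}")
                report.warn(
                    "undefined_species",
                    f"reaction {rid!r}: undefined species {raw!r} "
                    f"removed from the equation", rid)
                report.repair("undefined_species", rid)
                continue
            if value != 0:
                terms.append((species_map[raw], value))
        return terms

    reactions_el = _find(model_el, "listOfReactions")
    reaction_els = list(reactions_el) if reactions_el is not None else []
    for el in reaction_els:
        if _local(el.tag) != "reaction":
            continue
        raw = el.get("id") or el.get("name")
        if raw is None:
            raise SbmlError(f"{path.name}: reaction without id")
        rid = raw[2:] if raw.startswith("R_") else raw
        reversible = el.get("reversible", "true") == "true"
        left = parse_terms(el, "listOfReactants", raw)
        right = parse_terms(el, "listOfProducts", raw)
        direction = Direction.BOTH if reversible else Direction.FORWARD
        equation = Equation(left, right, direction)

        lower = upper = None
        kinetic = _find(el, "kineticLaw")
        if kinetic is not None:
            params = _find(kinetic, "listOfParameters")
            if params is not None:
                for param in params:
                    pid = param.get("id") or param.get("name")
                    value = param.get("value")
                    if value is None:
                        continue
                    if pid == "LOWER_BOUND":
                        lower = float(value)
                    elif pid == "UPPER_BOUND":
                        upper = float(value)
                    elif pid == "OBJECTIVE_COEFFICIENT":
                        if float(value) != 0:
                            report.objectives[rid] = float(value)
        if not reversible and lower is not None and lower < 0:
            if strict:
                raise SbmlError(
                    f"{path.name}: reaction {raw!r} is irreversible but "
                    f"has negative LOWER_BOUND {lower}")
            report.warn(
                "reversibility_conflict",
                f"reaction {raw!r} is irreversible but has LOWER_BOUND "
                f"{lower}; COBRA bounds kept", raw)
            report.repair("reversibility_conflict", raw)

        entry = ReactionEntry(
            id=rid, equation=equation, extra={"sbml_id": raw})
        model.add_reaction(entry)
        if lower is not None or upper is not None:
            model.limits.append(LimitEntry(rid, lower, upper))

    model.biomass = detect_biomass(model, report.objectives)
    model.validate()
    return model, report


def detect_biomass(
    model: Model, sbml_objectives: dict[str, float] | None = None
) -> str | None:
    """Identify the biomass reaction.

    First priority: the reaction with a non-zero objective coefficient
    (unique, or first in model order with a warning).  Fallback: reaction
    ids containing "biomass" case-insensitively.  None when neither
    applies.
    """
    objectives = sbml_objectives or {}
    nonzero = [rid for rid in model.reactions if objectives.get(rid)]
    if nonzero:
        if len(nonzero) > 1:
            model.warnings.append(
                "multiple reactions with non-zero objective coefficient: "
                + ", ".join(nonzero) + f"; using {nonzero[0]!r}")
        return nonzero[0]
    candidates = [
        rid for rid in model.reactions if "biomass" in rid.lower()]
    if candidates:
        if len(candidates) > 1:
            model.warnings.append(
                "multiple reaction ids matching 'biomass': "
                + ", ".join(candidates) + f"; using {candidates[0]!r}")
        return candidates[0]
    return None


def _matches_media(media, reaction_id: str) -> bool:
    from ..model import _media_reaction_id

    return _media_reaction_id(media) == reaction_id


def _sanitize(text: str) -> str:
    out = re.sub(r"[^0-9a-zA-Z_]", "_", text)
    if out and out[0].isdigit():
        out = "_" + out
    return out


def export_sbml(model: Model, path: str | Path, level: int = 2) -> Path:
    """Write the model as a level-2 COBRA-dialect SBML file."""
    if level != 2:
        raise SbmlError("only level-2 export is supported")
    path = Path(path)
    ET.register_namespace("", SBML_L2_NS)
    root = ET.Element(
        f"{{{SBML_L2_NS}}}sbml", {"level": "2", "version": "1"})
    model_el = ET.SubElement(
        root, f"{{{SBML_L2_NS}}}model",
        {"id": _sanitize(model.name), "name": model.name})

    def sub(parent, tag, attrs):
        return ET.SubElement(parent, f"{{{SBML_L2_NS}}}{tag}", attrs)

    compartments = sorted({
        c.compartment or "cell" for c in model.compounds})
    list_el = sub(model_el, "listOfCompartments", {})
    for compartment in compartments:
        sub(list_el, "compartment", {"id": _sanitize(compartment)})

    # Stable, collision-free species ids.
    species_ids: dict[Compound, str] = {}
    used: set[str] = set()
    export_compounds: dict[Compound, CompoundEntry] = dict(model.compounds)
    for media in model.media:
        export_compounds.setdefault(
            media.compound, CompoundEntry(id=media.compound))
    for compound in export_compounds:
        comp = compound.compartment or "cell"
        sid = f"M_{_sanitize(compound.name)}_{_sanitize(comp)}"
        while sid in used:
            sid += "_x"
        used.add(sid)
        species_ids[compound] = sid

    limits = model.limits_map()
    matrix_bounds = matrix_view(model).bounds

    # Media entries without a backing reaction become explicit exchange
    # reactions on export.
    synthetic: dict[str, ReactionEntry] = {}
    for rid in matrix_bounds:
        if rid not in model.reactions:
            compound = next(
                m.compound for m in model.media if _matches_media(m, rid))
            synthetic[rid] = ReactionEntry(
                rid, Equation([(compound, Fraction(1))], [],
                              Direction.BOTH))
    all_reactions = dict(model.reactions)
    all_reactions.update(synthetic)

    boundary_species: dict[Compound, str] = {}
    for rid, entry in all_reactions.items():
        eq = entry.equation
        if eq.left and eq.right:
            continue
        for compound in eq.compounds():
            if compound not in boundary_species:
                sid = species_ids[compound] + "_bnd"
                while sid in used:
                    sid += "_x"
                used.add(sid)
                boundary_species[compound] = sid

    species_el = sub(model_el, "listOfSpecies", {})
    for compound, entry in export_compounds.items():
        attrs = {
            "id": species_ids[compound],
            "name": compound.name,
            "compartment": _sanitize(compound.compartment or "cell"),
        }
        if entry.charge is not None:
            attrs["charge"] = str(entry.charge)
        sub(species_el, "species", attrs)
    for compound, sid in boundary_species.items():
        sub(species_el, "species", {
            "id": sid,
            "name": compound.name,
            "compartment": _sanitize(compound.compartment or "cell"),
            "boundaryCondition": "true",
        })

    reactions_el = sub(model_el, "listOfReactions", {})
    for rid, entry in all_reactions.items():
        eq = entry.equation
        if rid in matrix_bounds:
            lower, upper = matrix_bounds[rid]
        else:
            (lower, upper), _ = resolve_bounds(
                entry, limits.get(rid), model.default_flux_limit)
        if eq.direction is Direction.REVERSE:
            eq = eq.reversed()
            lower, upper = -upper, -lower
        attrs = {
            "id": "R_" + _sanitize(rid),
            "reversible": "true" if eq.direction is Direction.BOTH
            else "false",
        }
        reaction_el = sub(reactions_el, "reaction", attrs)
        if entry.genes is not None:
            notes = sub(reaction_el, "notes", {})
            body = ET.SubElement(
                notes, "{http://www.w3.org/1999/xhtml}p")
            body.text = f"GENE_ASSOCIATION: {render_genes(entry.genes)}"

        def write_side(tag, terms, fill_boundary):
            holder = sub(reaction_el, tag, {})
            for compound, value in terms:
                coef = str(value) if value.denominator == 1 \
                    else str(float(value))
                sub(holder, "speciesReference", {
                    "species": species_ids[compound],
                    "stoichiometry": coef,
                })
            if not terms and fill_boundary is not None:
                for compound, value in fill_boundary:
                    sub(holder, "speciesReference", {
                        "species": boundary_species[compound],
                        "stoichiometry": str(value)
                        if value.denominator == 1 else str(float(value)),
                    })

        is_exchange = not eq.left or not eq.right
        write_side("listOfReactants", eq.left,
                   eq.right if is_exchange else None)
        write_side("listOfProducts", eq.right,
                   eq.left if is_exchange else None)

        kinetic = sub(reaction_el, "kineticLaw", {})
        params = sub(kinetic, "listOfParameters", {})
        sub(params, "parameter",
            {"id": "LOWER_BOUND", "value": f"{lower:g}"})
        sub(params, "parameter",
            {"id": "UPPER_BOUND", "value": f"{upper:g}"})
        sub(params, "parameter", {
            "id": "OBJECTIVE_COEFFICIENT",
            "value": "1" if rid == model.biomass else "0"})

    ET.indent(root)
    tree = ET.ElementTree(root)
    tree.write(path, encoding="utf-8", xml_declaration=True)
    return path
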