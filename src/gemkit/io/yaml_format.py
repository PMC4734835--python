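"""The native YAML model format.

A model lives in a directory with a central ``model.yaml`` holding the
metadata and either inline sections or references to further files via
the ``include`` mechanism::

    name: Example model
    biomass: Biomass
    default_flux_limit: 1000
    compounds:
      - include: compounds.yaml
    reactions:
      - include: glycolysis.yaml
      - include: tca-cycle.tsv
      - id: R_extra
        equation: 'A[c] => B[c]'
    model:
      - include: model_rxn.tsv
    media:
      - compound: A[e]
        lower: -10
    limits:
      - reaction: R_extra
        upper: 5

Include paths resolve relative to the including file; includes may nest,
every file is parsed exactly once, and a cyclic include is an error.
Reaction and compound sections accept both YAML record lists and
tab-delimited tables; the ``model`` section (the model-subset list for a
broader reaction database) accepts id lists or one-id-per-line files.
Section content is identical whether inlined or included.

Serialization is deterministic and line-oriented — one scalar field per
line, stable key order, records in insertion order — so that model edits
produce minimal diffs under line-based version control.  Unknown record
keys are preserved verbatim through read/write round trips.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any

import yaml

from ..equation import Compound, parse_equation
from ..formula import Formula, FormulaError
from ..genes import parse_genes, render_genes
from ..model import (
    CompoundEntry, LimitEntry, MediaEntry, Model, ReactionEntry)

REACTION_KEYS = ("id", "equation", "genes", "subsystem", "ec")
COMPOUND_KEYS = ("id", "name", "formula", "charge")


class YamlFormatError(ValueError):
    pass


class _IncludeResolver:
    def __init__(self) -> None:
        self.cache: dict[Path, Any] = {}
        self.stack: list[Path] = []

    def load(self, path: Path) -> Any:
        path = path.resolve()
        if path in self.stack:
            chain = " -> ".join(p.name for p in self.stack + [path])
            raise YamlFormatError(f"cyclic include: {chain}")
        if path in self.cache:
            return self.cache[path]
        self.stack.append(path)
        try:
            if path.suffix in (".yaml", ".yml"):
                with open(path, encoding="utf-8") as handle:
                    content = yaml.safe_load(handle)
            else:
                content = path  # tables are parsed by the caller, per kind
            self.cache[path] = content
            return content
        finally:
            self.stack.pop()


def _resolve_records(
    items: Any, base: Path, kind: str, resolver: _IncludeResolver
) -> list[Any]:
    """Flatten a section into records, following includes."""
    if items is None:
        return []
    if not isinstance(items, list):
        raise YamlFormatError(f"section {kind!r} must be a list")
    records: list[Any] = []
    for item in items:
        if isinstance(item, dict) and set(item) == {"include"}:
            target = (base / item["include"]).resolve()
            if not target.exists():
                raise YamlFormatError(f"included file not found: {target}")
            content = resolver.load(target)
            if isinstance(content, Path):
                records.extend(_table_records(content, kind))
            else:
                resolver.stack.append(target)
                try:
                    records.extend(_resolve_records(
                        content, target.parent, kind, resolver))
                finally:
                    resolver.stack.pop()
        else:
            records.append(item)
    return records


def _table_records(path: Path, kind: str) -> list[Any]:
    from .table import _read_rows

    if kind == "model":
        ids = []
        with open(path, encoding="utf-8") as handle:
            for line in handle:
                line = line.split("\t")[0].strip()
                if line and not line.startswith("#") and line.lower() != "id":
                    ids.append(line)
        return ids
    return [row for _, row in _read_rows(path)]


def _reaction_from_record(record: dict, location: str) -> ReactionEntry:
    if not isinstance(record, dict):
        raise YamlFormatError(f"{location}: reaction record must be a mapping")
    if "id" not in record or not record["id"]:
        raise YamlFormatError(f"{location}: reaction record lacks an id")
    if "equation" not in record or not record["equation"]:
        raise YamlFormatError(
            f"{location}: reaction {record['id']!r} lacks an equation")
    extra = {
        k: v for k, v in record.items()
        if k not in REACTION_KEYS and v not in (None, "")}
    genes = None
    if record.get("genes"):
        genes = parse_genes(str(record["genes"]))
    return ReactionEntry(
        id=str(record["id"]),
        equation=parse_equation(str(record["equation"])),
        genes=genes,
        subsystem=record.get("subsystem") or None,
        ec=str(record["ec"]) if record.get("ec") else None,
        extra=extra,
    )


def _compound_from_record(record: dict, location: str) -> CompoundEntry:
    if not isinstance(record, dict):
        raise YamlFormatError(f"{location}: compound record must be a mapping")
    if "id" not in record or not record["id"]:
        raise YamlFormatError(f"{location}: compound record lacks an id")
    extra = {
        k: v for k, v in record.items()
        if k not in COMPOUND_KEYS and v not in (None, "")}
    formula = None
    if record.get("formula"):
        try:
            formula = Formula.parse(str(record["formula"]))
        except FormulaError:
            extra["formula"] = record["formula"]
    charge = None
    if record.get("charge") not in (None, ""):
        charge = int(record["charge"])
    return CompoundEntry(
        id=Compound.parse(str(record["id"])),
        name=record.get("name") or None,
        formula=formula,
        charge=charge,
        extra=extra,
    )


def read_yaml(path: str | Path) -> Model:
    """Read a model from a ``model.yaml`` file (or its directory)."""
    path = Path(path)
    if path.is_dir():
        path = path / "model.yaml"
    if not path.exists():
        raise YamlFormatError(f"model file not found: {path}")
    resolver = _IncludeResolver()
    resolver.stack.append(path.resolve())
    with open(path, encoding="utf-8") as handle:
        doc = yaml.safe_load(handle)
    if not isinstance(doc, dict):
        raise YamlFormatError(f"{path}: model file must be a mapping")
    base = path.parent

    model = Model(name=str(doc.get("name", base.name or "unnamed")))
    if doc.get("default_flux_limit") is not None:
        model.default_flux_limit = float(doc["default_flux_limit"])
    known = {"name", "biomass", "default_flux_limit", "compounds",
             "reactions", "model", "media", "limits"}
    model.meta = {k: v for k, v in doc.items() if k not in known}

    for i, record in enumerate(_resolve_records(
            doc.get("compounds"), base, "compounds", resolver)):
        if isinstance(record, dict):
            record = {k: v for k, v in record.items()}
        model.add_compound(
            _compound_from_record(record, f"compounds[{i}]"))
    for i, record in enumerate(_resolve_records(
            doc.get("reactions"), base, "reactions", resolver)):
        model.add_reaction(
            _reaction_from_record(record, f"reactions[{i}]"))

    subset = _resolve_records(doc.get("model"), base, "model", resolver)
    if subset:
        model.model_subset = {str(rid) for rid in subset}

    if doc.get("biomass") is not None:
        model.biomass = str(doc["biomass"])

    for i, record in enumerate(_resolve_records(
            doc.get("media"), base, "media", resolver)):
        if not isinstance(record, dict) or "compound" not in record:
            raise YamlFormatError(
                f"media[{i}]: entry must be a mapping with a compound")
        model.media.append(MediaEntry(
            compound=Compound.parse(str(record["compound"])),
            reaction=record.get("reaction"),
            lower=_number_or_none(record.get("lower")),
            upper=_number_or_none(record.get("upper")),
        ))
    for i, record in enumerate(_resolve_records(
            doc.get("limits"), base, "limits", resolver)):
        if not isinstance(record, dict) or "reaction" not in record:
            raise YamlFormatError(
                f"limits[{i}]: entry must be a mapping with a reaction")
        model.limits.append(LimitEntry(
            reaction=str(record["reaction"]),
            lower=_number_or_none(record.get("lower")),
            upper=_number_or_none(record.get("upper")),
        ))

    model.validate()
    return model


def _number_or_none(value: Any) -> float | None:
    return None if value is None else float(value)


def _reaction_record(entry: ReactionEntry) -> dict:
    record: dict[str, Any] = {"id": entry.id,
                              "equation": entry.equation.render()}
    if entry.genes is not None:
        record["genes"] = render_genes(entry.genes)
    if entry.subsystem is not None:
        record["subsystem"] = entry.subsystem
    if entry.ec is not None:
        record["ec"] = entry.ec
    record.update(entry.extra)
    return record


def _compound_record(entry: CompoundEntry) -> dict:
    record: dict[str, Any] = {"id": str(entry.id)}
    if entry.name is not None:
        record["name"] = entry.name
    if entry.formula is not None:
        record["formula"] = str(entry.formula)
    if entry.charge is not None:
        record["charge"] = entry.charge
    record.update(entry.extra)
    return record


def write_yaml(model: Model, directory: str | Path) -> list[Path]:
    """Serialize the model to ``directory/model.yaml`` deterministically."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    doc: dict[str, Any] = {"name": model.name}
    if model.biomass is not None:
        doc["biomass"] = model.biomass
    doc["default_flux_limit"] = model.default_flux_limit
    doc.update(model.meta)
    if model.compounds:
        doc["compounds"] = [
            _compound_record(e) for e in model.compounds.values()]
    if model.reactions:
        doc["reactions"] = [
            _reaction_record(e) for e in model.reactions.values()]
    if model.model_subset is not None:
        order = {rid: i for i, rid in enumerate(model.reactions)}
        doc["model"] = sorted(
            model.model_subset, key=lambda r: order.get(r, len(order)))
    if model.media:
        doc["media"] = [
            _strip_none({
                "compound": str(m.compound), "reaction": m.reaction,
                "lower": m.lower, "upper": m.upper})
            for m in model.media]
    if model.limits:
        doc["limits"] = [
            _strip_none({
                "reaction": l.reaction, "lower": l.lower, "upper": l.upper})
            for l in model.limits]

    path = directory / "model.yaml"
    with open(path, "w", encoding="utf-8") as handle:
        yaml.safe_dump(
            doc, handle, sort_keys=False, default_flow_style=False,
            allow_unicode=True, width=10**6)
    return [path]


def _strip_none(record: dict) -> dict:
    return {k: v for k, v in record.items() if v is not None}
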