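"""Molecule readers and the JSON annotation writer.

Input formats: a raw SMILES string (possibly several whitespace-separated
entries, each optionally followed by a name token), a SMILES file (one record
per line, name = rest of line after the first whitespace) and SDF (V2000; the
record name comes from the title line, falling back to a ``name`` data field).

The output document is JSON with a fixed, stable key order; its shape is
defined by pydantic models, which double as the shipped schema
(:func:`annotation_json_schema`).  Serializing the same results twice yields
byte-identical text.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, Field
from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .matching import MoleculeRecord
from .overshadow import NO_NAME, AnnotationResult
from .patterns import PatternCollection


class MatchModel(BaseModel):
    pattern_id: str
    pattern_name: str
    category: Literal["functional_group", "cyclic", "biological"]
    atom_indices: list[int]
    bonds: list[list[int]]
    overshadowed: bool
    suppression_reason: Literal["none", "match_containment", "fewer_bonds", "hierarchy"]
    suppressed_by: list[str]


class MoleculeModel(BaseModel):
    name: str
    smiles: str
    error: Optional[str] = None
    matches: list[MatchModel] = Field(default_factory=list)


class AnnotationDocument(BaseModel):
    molecules: list[MoleculeModel]


def annotation_json_schema() -> dict:
    """JSON Schema of the annotation output document."""
    return AnnotationDocument.model_json_schema()


def _parses(smiles: str) -> bool:
    with BlockLogs():
        return Chem.MolFromSmiles(smiles) is not None


def read_smiles_string(text: str) -> list[MoleculeRecord]:
    """Parse a raw SMILES string of one or more entries.

    A whitespace-separated token that parses as SMILES starts a new record;
    a following token that does not parse is taken as that record's name.
    """
    records: list[MoleculeRecord] = []
    for line in text.splitlines():
        tokens = line.split()
        i = 0
        while i < len(tokens):
            smiles = tokens[i]
            name = None
            if i + 1 < len(tokens) and not _parses(tokens[i + 1]):
                name = tokens[i + 1]
                i += 1
            records.append(MoleculeRecord.from_smiles(smiles, name=name))
            i += 1
    return records


def read_smiles_file(path: str | Path) -> list[MoleculeRecord]:
    """One record per non-empty line: ``SMILES[<whitespace>name...]``."""
    records: list[MoleculeRecord] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        name = parts[1].strip() if len(parts) > 1 else None
        records.append(MoleculeRecord.from_smiles(smiles, name=name or None))
    return records


def read_sdf(path: str | Path) -> list[MoleculeRecord]:
    """SDF reader; unparseable records become error-carrying records."""
    records: list[MoleculeRecord] = []
    with BlockLogs():
        supplier = Chem.SDMolSupplier(str(path), sanitize=True)
        for i, mol in enumerate(supplier):
            if mol is None:
                records.append(
                    MoleculeRecord(
                        smiles="", name=None,
                        error=f"unparseable SDF record #{i + 1}",
                    )
                )
                continue
            name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
            if not name and mol.HasProp("name"):
                name = mol.GetProp("name").strip()
            records.append(MoleculeRecord.from_mol(mol, name=name or None))
    return records


def read_molecules(source: str | Path, kind: Optional[str] = None) -> list[MoleculeRecord]:
    """Dispatch on source kind: ``smiles`` (raw string), ``smi`` (SMILES file)
    or ``sdf``.  When ``kind`` is omitted the file suffix decides."""
    if kind == "smiles":
        return read_smiles_string(str(source))
    path = Path(source)
    if kind is None:
        kind = "sdf" if path.suffix.lower() in (".sdf", ".sd", ".mol") else "smi"
    if kind == "sdf":
        return read_sdf(path)
    return read_smiles_file(path)


def result_to_model(
    result: AnnotationResult,
    collection: PatternCollection,
    include_overshadowed: Optional[bool] = None,
) -> MoleculeModel:
    if include_overshadowed is None:
        include_overshadowed = result.include_overshadowed
    matches = []
    for m in result.matches:
        if m.suppression != "none" and not include_overshadowed:
            continue
        pattern = collection.get(m.pattern_id)
        matches.append(
            MatchModel(
                pattern_id=m.pattern_id,
                pattern_name=pattern.name,
                category=pattern.category,
                atom_indices=sorted(m.atom_indices),
                bonds=[list(b) for b in sorted(m.bonds)],
                overshadowed=m.suppression != "none",
                suppression_reason=m.suppression,
                suppressed_by=list(m.suppressed_by),
            )
        )
    return MoleculeModel(
        name=result.molecule_name or NO_NAME,
        smiles=result.smiles,
        error=result.error,
        matches=matches,
    )


def serialize_annotations(
    results: list[AnnotationResult],
    collection: PatternCollection,
    include_overshadowed: Optional[bool] = None,
) -> str:
    doc = AnnotationDocument(
        molecules=[
            result_to_model(r, collection, include_overshadowed) for r in results
        ]
    )
    return json.dumps(doc.model_dump(), indent=2) + "\n"


def write_annotations(
    results: list[AnnotationResult],
    collection: PatternCollection,
    path: str | Path,
    include_overshadowed: Optional[bool] = None,
) -> None:
    Path(path).write_text(
        serialize_annotations(results, collection, include_overshadowed),
        encoding="utf-8",
    )


def validate_annotation_json(text: str) -> AnnotationDocument:
    """Parse and validate an annotation document against the schema."""
    return AnnotationDocument.model_validate(json.loads(text))
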