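"""Pattern data model, serialization and prefilter signatures.

A *pattern* is a named SMARTS expression with a category: ``functional_group``
(small characteristic atom groupings), ``cyclic`` (ring systems tolerant of
substitution) or ``biological`` (nucleobases, sugars, amino acids and other
trivial names).  Collections are stored as JSON (array of objects) or as a
strict three-column TSV ``smarts<TAB>name<TAB>category`` with no quoting.

Every pattern also carries a *prefilter signature*: cheap necessary conditions
(minimum heavy atoms, forced element counts, forced ring / aromatic atom
counts) that let the matcher skip molecules that cannot possibly match.  The
signature is a sound lower bound only — a molecule passing the prefilter may
still have no match, but a molecule failing it never has one.
"""

from __future__ import annotations

import json
import re
import unicodedata
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

from rdkit import Chem

from . import smartsq

CATEGORIES = ("functional_group", "cyclic", "biological")


class PatternValidationError(ValueError):
    """Raised when one or more records of a pattern file fail validation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


def _slug(name: str) -> str:
    text = unicodedata.normalize("NFKD", name).encode("ascii", "ignore").decode()
    text = re.sub(r"[^a-z0-9]+", "-", text.lower()).strip("-")
    return text or "pattern"


@dataclass
class Pattern:
    """A named SMARTS substructure pattern."""

    id: str
    smarts: str
    name: str
    category: str
    atom_count: int
    bond_count: int

    @classmethod
    def create(cls, smarts: str, name: str, category: str, id: Optional[str] = None,
               ordinal: int = 0) -> "Pattern":
        if category not in CATEGORIES:
            raise PatternValidationError(
                [f"invalid category {category!r} for pattern {name!r} "
                 f"(expected one of {', '.join(CATEGORIES)})"]
            )
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise PatternValidationError([f"invalid SMARTS {smarts!r} for pattern {name!r}"])
        if query.GetNumAtoms() < 1:
            raise PatternValidationError([f"empty SMARTS for pattern {name!r}"])
        return cls(
            id=id if id else f"{ordinal:04d}-{_slug(name)}",
            smarts=smarts,
            name=name,
            category=category,
            atom_count=query.GetNumAtoms(),
            bond_count=query.GetNumBonds(),
        )

    def query(self) -> Chem.Mol:
        q = Chem.MolFromSmarts(self.smarts)
        if q is None:  # pragma: no cover - guarded at construction
            raise PatternValidationError([f"invalid SMARTS {self.smarts!r}"])
        return q


@dataclass(frozen=True)
class PrefilterSignature:
    """Necessary match conditions derived from a pattern's SMARTS."""

    min_heavy_atoms: int
    required_elements: dict[str, int]
    min_ring_atoms: int
    min_aromatic_atoms: int


@dataclass
class PatternCollection:
    """Ordered collection of patterns with unique ids."""

    patterns: list[Pattern] = field(default_factory=list)
    version: str = ""

    def __post_init__(self) -> None:
        self._by_id = {}
        for p in self.patterns:
            if p.id in self._by_id:
                raise PatternValidationError([f"duplicate pattern id {p.id!r}"])
            self._by_id[p.id] = p

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def get(self, pattern_id: str) -> Pattern:
        return self._by_id[pattern_id]

    def __contains__(self, pattern_id: str) -> bool:
        return pattern_id in self._by_id

    def subset(self, names_or_ids: Iterable[str]) -> "PatternCollection":
        """Sub-collection of patterns whose id or name is listed."""
        wanted = set(names_or_ids)
        return PatternCollection(
            [p for p in self.patterns if p.id in wanted or p.name in wanted],
            version=self.version,
        )


def _infer_format(path: Path, format: Optional[str]) -> str:
    if format:
        return format
    return "tsv" if path.suffix.lower() in (".tsv", ".txt", ".smarts") else "json"


def load_patterns(path: str | Path, format: Optional[str] = None,
                  permissive: bool = False) -> PatternCollection:
    """Load a pattern collection from a JSON or TSV file.

    Malformed records are collected and reported together; with
    ``permissive=True`` they are skipped with a warning instead of aborting.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    text = path.read_text(encoding="utf-8")
    records: list[tuple[int, Optional[str], str, str, str]] = []
    errors: list[str] = []

    if fmt == "json":
        try:
            data = json.loads(text)
        except json.JSONDecodeError as exc:
            raise PatternValidationError([f"{path}: not valid JSON: {exc}"]) from exc
        if not isinstance(data, list):
            raise PatternValidationError([f"{path}: expected a JSON array of objects"])
        for i, obj in enumerate(data, start=1):
            if not isinstance(obj, dict) or "smarts" not in obj or "name" not in obj:
                errors.append(f"record {i}: missing 'smarts' or 'name'")
                continue
            records.append((i, obj.get("id"), obj["smarts"], obj["name"],
                            obj.get("category", "")))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                errors.append(f"line {lineno}: expected 3 tab-separated columns, got {len(cols)}")
                continue
            records.append((lineno, None, cols[0], cols[1], cols[2]))

    patterns: list[Pattern] = []
    seen_ids: set[str] = set()
    for recno, pid, smarts, name, category in records:
        try:
            p = Pattern.create(smarts, name, category, id=pid, ordinal=len(patterns))
        except PatternValidationError as exc:
            errors.append(f"record {recno}: {exc.errors[0]}")
            continue
        if p.id in seen_ids:
            errors.append(f"record {recno}: duplicate id {p.id!r}")
            continue
        seen_ids.add(p.id)
        patterns.append(p)

    if errors:
        if not permissive:
            raise PatternValidationError([f"{path}: {e}" for e in errors])
        for e in errors:
            warnings.warn(f"{path}: skipped invalid pattern record: {e}", stacklevel=2)
    return PatternCollection(patterns, version=str(path))


def save_patterns(collection: PatternCollection, path: str | Path,
                  format: Optional[str] = None) -> None:
    """Write a collection; ``load_patterns`` of the result round-trips
    (id, smarts, name, category) in order."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "json":
        data = [
            {"id": p.id, "smarts": p.smarts, "name": p.name, "category": p.category}
            for p in collection
        ]
        path.write_text(json.dumps(data, indent=2) + "\n", encoding="utf-8")
        return
    lines = []
    for p in collection:
        fields = (p.smarts, p.name, p.category)
        for value in fields:
            # strict dialect: no quoting, so embedded tabs cannot round-trip
            if "\t" in value or "\n" in value:
                raise PatternValidationError(
                    [f"pattern {p.id!r}: field contains a tab or newline, "
                     "not representable in the TSV dialect"]
                )
        lines.append("\t".join(fields))
    path.write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def compute_prefilter_signature(pattern: Pattern) -> PrefilterSignature:
    """Derive the sound prefilter signature of a pattern.

    Only atom expressions forcing a unique element in every disjunct count
    toward ``required_elements``; disjunctive element lists (halogen lists) and
    opaque expressions (recursive environments etc.) contribute to the heavy
    atom minimum only.
    """
    query = pattern.query()
    required: Counter[str] = Counter()
    ring_atoms = 0
    aromatic_atoms = 0
    periodic = Chem.GetPeriodicTable()
    for atom in query.GetAtoms():
        expr = smartsq.atom_expression(atom)
        z = expr.forced_element()
        if z is not None:
            required[periodic.GetElementSymbol(z)] += 1
        if expr.forced_in_ring():
            ring_atoms += 1
        if expr.forced_aromatic():
            aromatic_atoms += 1
    return PrefilterSignature(
        min_heavy_atoms=pattern.atom_count,
        required_elements=dict(required),
        min_ring_atoms=ring_atoms,
        min_aromatic_atoms=aromatic_atoms,
    )
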