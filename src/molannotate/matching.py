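"""Prefiltered enumeration of pattern matches in molecules.

Matching is exhaustive: every embedding of every pattern is enumerated, mapped
to molecule atom/bond index sets, and deduplicated so that symmetric
(automorphic) embeddings collapse to one match while genuinely distinct
locations are kept.  A cheap signature prefilter can skip patterns that cannot
match; by construction it never changes the result, only the work done.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Optional

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .patterns import Pattern, PatternCollection, PrefilterSignature, compute_prefilter_signature

_MAX_EMBEDDINGS = 100_000

SUPPRESSION_REASONS = ("none", "match_containment", "fewer_bonds", "hierarchy")


@dataclass
class MoleculeRecord:
    """A parsed input molecule with stable 0-based atom indexing (parse order)."""

    smiles: str
    name: Optional[str] = None
    mol: Optional[Chem.Mol] = None
    error: Optional[str] = None

    @classmethod
    def from_smiles(cls, smiles: str, name: Optional[str] = None) -> "MoleculeRecord":
        with BlockLogs():
            mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            return cls(smiles=smiles, name=name, error=f"unparseable SMILES: {smiles!r}")
        return cls(smiles=smiles, name=name, mol=mol)

    @classmethod
    def from_mol(cls, mol: Chem.Mol, name: Optional[str] = None) -> "MoleculeRecord":
        return cls(smiles=Chem.MolToSmiles(mol), name=name, mol=mol)

    @property
    def key(self) -> str:
        return Chem.MolToSmiles(self.mol) if self.mol is not None else self.smiles


@dataclass(frozen=True)
class MoleculeSignature:
    heavy_atom_count: int
    element_histogram: dict[str, int]
    ring_atom_count: int
    aromatic_atom_count: int
    ring_count: int  # SSSR size


@dataclass
class PatternMatch:
    """One embedding of a pattern, as molecule atom/bond index sets."""

    pattern_id: str
    atom_indices: frozenset[int]
    bonds: frozenset[tuple[int, int]]
    suppression: str = "none"
    suppressed_by: list[str] = field(default_factory=list)
    molecule_key: Optional[str] = None

    def sort_key(self) -> tuple:
        return (tuple(sorted(self.atom_indices)), tuple(sorted(self.bonds)))

    def identity(self) -> tuple:
        return (self.pattern_id, self.atom_indices, self.bonds)


def molecule_signature(record: MoleculeRecord) -> MoleculeSignature:
    mol = record.mol
    if mol is None:
        raise ValueError("cannot compute a signature for an unparsed molecule")
    hist = Counter(a.GetSymbol() for a in mol.GetAtoms())
    return MoleculeSignature(
        heavy_atom_count=mol.GetNumHeavyAtoms(),
        element_histogram=dict(hist),
        ring_atom_count=sum(a.IsInRing() for a in mol.GetAtoms()),
        aromatic_atom_count=sum(a.GetIsAromatic() for a in mol.GetAtoms()),
        ring_count=mol.GetRingInfo().NumRings(),
    )


def prefilter_pass(ps: PrefilterSignature, ms: MoleculeSignature) -> bool:
    """False only when some necessary condition exceeds the molecule's counts;
    never false for a pattern with at least one match (soundness)."""
    if ms.heavy_atom_count < ps.min_heavy_atoms:
        return False
    for symbol, count in ps.required_elements.items():
        if ms.element_histogram.get(symbol, 0) < count:
            return False
    if ms.ring_atom_count < ps.min_ring_atoms:
        return False
    if ms.aromatic_atom_count < ps.min_aromatic_atoms:
        return False
    return True


class QueryCache:
    """Compiled query + signature cache for multi-molecule runs, keyed by
    pattern id.  Purely an optimization: results are identical with or
    without it."""

    def __init__(self) -> None:
        self._queries: dict[str, Chem.Mol] = {}
        self._signatures: dict[str, PrefilterSignature] = {}

    def query(self, pattern: Pattern) -> Chem.Mol:
        if pattern.id not in self._queries:
            self._queries[pattern.id] = pattern.query()
        return self._queries[pattern.id]

    def signature(self, pattern: Pattern) -> PrefilterSignature:
        if pattern.id not in self._signatures:
            self._signatures[pattern.id] = compute_prefilter_signature(pattern)
        return self._signatures[pattern.id]


def dedupe_matches(matches: list[PatternMatch]) -> list[PatternMatch]:
    """Collapse matches identical in (pattern_id, atom set, bond set)."""
    seen: set[tuple] = set()
    out: list[PatternMatch] = []
    for m in matches:
        key = m.identity()
        if key not in seen:
            seen.add(key)
            out.append(m)
    return out


def find_pattern_matches(
    record: MoleculeRecord,
    collection: PatternCollection,
    use_prefilter: bool = True,
    cache: Optional[QueryCache] = None,
) -> list[PatternMatch]:
    """All deduplicated matches of a collection in one molecule.

    Order is deterministic: collection order, then lexicographically smallest
    sorted atom-index tuple.
    """
    if record.mol is None:
        raise ValueError(f"molecule not parsed: {record.error}")
    cache = cache or QueryCache()
    mol = record.mol
    mol_sig = molecule_signature(record) if use_prefilter else None
    mol_key = record.key
    result: list[PatternMatch] = []
    for pattern in collection:
        if use_prefilter and not prefilter_pass(cache.signature(pattern), mol_sig):
            continue
        query = cache.query(pattern)
        embeddings = mol.GetSubstructMatches(
            query, uniquify=False, maxMatches=_MAX_EMBEDDINGS
        )
        matches = []
        for emb in embeddings:
            bonds = set()
            for qbond in query.GetBonds():
                i = emb[qbond.GetBeginAtomIdx()]
                j = emb[qbond.GetEndAtomIdx()]
                bonds.add((min(i, j), max(i, j)))
            matches.append(
                PatternMatch(
                    pattern_id=pattern.id,
                    atom_indices=frozenset(emb),
                    bonds=frozenset(bonds),
                    molecule_key=mol_key,
                )
            )
        matches = dedupe_matches(matches)
        matches.sort(key=PatternMatch.sort_key)
        result.extend(matches)
    return result


def copy_match(m: PatternMatch) -> PatternMatch:
    return replace(m, suppressed_by=list(m.suppressed_by))
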