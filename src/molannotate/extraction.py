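"""Mining cyclic patterns from named-SMILES tables.

The pipeline selects whole molecules that *are* pure ring systems — every atom
and bond inside a ring, except double-bonded terminal oxygen/sulfur hanging off
a ring atom (ketone-type exocyclic carbonyls/thiocarbonyls) — applies structure
and name plausibility filters, and converts each survivor into a
substitution-tolerant SMARTS pattern.

The generated SMARTS constrains atomic number, aromaticity and formal charge
per atom, and the bond order (or aromaticity) per bond.  It deliberately
imposes no hydrogen-count or degree constraints on ring atoms, so that any
substituted variant of the ring system still matches; exocyclic terminal O/S
keep a degree-1 constraint so that e.g. a cyclohexanone pattern does not match
cyclohexanol.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

from rdkit import Chem
from rdkit.Chem import BondType
from rdkit.rdBase import BlockLogs

from .patterns import Pattern, PatternCollection, _slug

FILTER_REASONS = (
    "ok",
    "not_ring_system",
    "radical",
    "isotope",
    "too_large",
    "mixture",
    "name_numbers",
    "name_yl_suffix",
    "name_cid_prefix",
    "unparseable",
)

MAX_HEAVY_ATOMS = 100
MAX_NAME_NUMBERS = 4

_BOND_TOKEN = {
    BondType.SINGLE: "-",
    BondType.DOUBLE: "=",
    BondType.TRIPLE: "#",
    BondType.AROMATIC: ":",
}


@dataclass(frozen=True)
class NamedSmilesRecord:
    """One row of a (name, SMILES) table, e.g. a chemical-database name dump."""

    name: str
    smiles: str
    source_line: int = 0


@dataclass(frozen=True)
class FilterDecision:
    passed: bool
    reason: str

    def __post_init__(self) -> None:
        assert self.reason in FILTER_REASONS
        assert self.passed == (self.reason == "ok")


_OK = FilterDecision(True, "ok")


def _fail(reason: str) -> FilterDecision:
    return FilterDecision(False, reason)


def _exocyclic_keeper_atoms(mol: Chem.Mol) -> set[int]:
    """Indices of terminal O/S double-bonded to a ring atom."""
    keep: set[int] = set()
    for atom in mol.GetAtoms():
        if atom.GetAtomicNum() not in (8, 16) or atom.IsInRing():
            continue
        if atom.GetDegree() != 1:
            continue
        bond = atom.GetBonds()[0]
        other = bond.GetOtherAtom(atom)
        if bond.GetBondType() == BondType.DOUBLE and other.IsInRing():
            keep.add(atom.GetIdx())
    return keep


def is_ring_system_molecule(mol: Chem.Mol) -> bool:
    """True iff the molecule consists solely of ring atoms/bonds plus
    exocyclic double bonds to terminal oxygen or sulfur atoms."""
    keepers = _exocyclic_keeper_atoms(mol)
    for atom in mol.GetAtoms():
        if not atom.IsInRing() and atom.GetIdx() not in keepers:
            return False
    for bond in mol.GetBonds():
        if bond.IsInRing():
            continue
        if bond.GetBeginAtomIdx() in keepers or bond.GetEndAtomIdx() in keepers:
            continue
        return False
    return bool(mol.GetNumAtoms())


def passes_structure_filters(mol: Optional[Chem.Mol],
                             max_heavy_atoms: int = MAX_HEAVY_ATOMS) -> FilterDecision:
    """Reject mixtures, radicals, isotope-labelled and oversized molecules.

    The reason reports the first failing rule in the fixed order
    mixture → radical → isotope → too_large.
    """
    if mol is None:
        return _fail("unparseable")
    if len(Chem.GetMolFrags(mol)) > 1:
        return _fail("mixture")
    if any(a.GetNumRadicalElectrons() for a in mol.GetAtoms()):
        return _fail("radical")
    if any(a.GetIsotope() for a in mol.GetAtoms()):
        return _fail("isotope")
    if mol.GetNumHeavyAtoms() > max_heavy_atoms:
        return _fail("too_large")
    return _OK


def passes_name_filters(name: str) -> FilterDecision:
    """Reject names unusable for communication.

    Checked in order: the ``CID`` database-identifier prefix, the ``yl``
    residue suffix, then more than four *numbers* where a number is one
    maximal run of consecutive digits (so "1,2,3,4-tetrahydroquinazoline"
    carries exactly four numbers and passes).
    """
    if not name or not name.strip():
        return _fail("unparseable")
    if name.startswith("CID"):
        return _fail("name_cid_prefix")
    if name.endswith("yl"):
        return _fail("name_yl_suffix")
    if len(re.findall(r"\d+", name)) > MAX_NAME_NUMBERS:
        return _fail("name_numbers")
    return _OK


def _atom_query_token(atom: Chem.Atom, force_degree1: bool = False) -> str:
    parts = [f"#{atom.GetAtomicNum()}", "a" if atom.GetIsAromatic() else "A"]
    charge = atom.GetFormalCharge()
    parts.append(f"{'+' if charge >= 0 else '-'}{abs(charge)}")
    if force_degree1:
        parts.append("D1")
    return "[" + ";".join(parts) + "]"


def build_substructure_query(mol: Chem.Mol, degree1_atoms: Iterable[int] = ()) -> Chem.Mol:
    """Query molecule constraining element/aromaticity/charge and bond order,
    with degree-1 forced only on the listed atoms."""
    degree1 = set(degree1_atoms)
    em = Chem.RWMol()
    for atom in mol.GetAtoms():
        token = _atom_query_token(atom, force_degree1=atom.GetIdx() in degree1)
        em.AddAtom(Chem.AtomFromSmarts(token))
    for bond in mol.GetBonds():
        idx = em.AddBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(),
                         bond.GetBondType()) - 1
        if bond.GetIsAromatic():
            token = _BOND_TOKEN[BondType.AROMATIC]
        else:
            token = _BOND_TOKEN[bond.GetBondType()]
        em.ReplaceBond(idx, Chem.BondFromSmarts(token))
    return em.GetMol()


def ring_pattern_from_molecule(mol: Chem.Mol) -> str:
    """SMARTS for the ring system, tolerant of substitution.

    Requires :func:`is_ring_system_molecule` to hold; the result matches the
    source molecule itself with a match covering all of its atoms.
    """
    if not is_ring_system_molecule(mol):
        raise ValueError("molecule is not a pure ring system")
    query = build_substructure_query(mol, degree1_atoms=_exocyclic_keeper_atoms(mol))
    return Chem.MolToSmarts(query)


@dataclass(frozen=True)
class ExtractionLogEntry:
    source_line: int
    name: str
    reason: str


def extract_cyclic_patterns(
    records: Iterable[NamedSmilesRecord],
    max_heavy_atoms: int = MAX_HEAVY_ATOMS,
) -> tuple[PatternCollection, list[ExtractionLogEntry]]:
    """Run the full mining pipeline over a record stream.

    Returns one ``cyclic`` pattern per distinct ring-system structure
    (deduplicated by canonical SMILES; name tie-break: shortest passing name,
    then lexicographic) plus a per-record decision log.
    """
    log: list[ExtractionLogEntry] = []
    # structure key -> (chosen name, SMARTS)
    chosen: dict[str, tuple[str, str]] = {}
    order: list[str] = []

    for rec in records:
        with BlockLogs():
            mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        decision = passes_structure_filters(mol, max_heavy_atoms=max_heavy_atoms)
        if decision.passed and not is_ring_system_molecule(mol):
            decision = _fail("not_ring_system")
        if decision.passed:
            decision = passes_name_filters(rec.name)
        log.append(ExtractionLogEntry(rec.source_line, rec.name, decision.reason))
        if not decision.passed:
            continue
        key = Chem.MolToSmiles(mol)
        smarts = ring_pattern_from_molecule(mol)
        name = rec.name.strip()
        if key not in chosen:
            chosen[key] = (name, smarts)
            order.append(key)
        else:
            current = chosen[key][0]
            if (len(name), name) < (len(current), current):
                chosen[key] = (name, chosen[key][1])

    patterns = [
        Pattern.create(
            smarts=chosen[key][1],
            name=chosen[key][0],
            category="cyclic",
            id=f"cyc{i:04d}-{_slug(chosen[key][0])}",
        )
        for i, key in enumerate(order)
    ]
    return PatternCollection(patterns, version="extracted"), log
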