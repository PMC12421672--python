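"""Normalization of SMARTS atom/bond expressions over a finite feature space.

A SMARTS atom expression built from the common primitives (element, aromaticity,
formal charge, total hydrogen count, connection count, ring membership) defines a
set of atom "feature tuples" it accepts.  Enumerating that set over a bounded,
chemically sensible space makes subset questions between two expressions
decidable by plain set inclusion, which is all the restricted subsumption engine
in :mod:`molannotate.hierarchy` needs.

Expressions using primitives outside the supported space (recursive
environments, isotopes, ring counts, ring sizes, valence, rare elements, ...)
are marked *opaque*: no feature set is computed and comparisons fall back to
exact-text equality.

The accepted set is computed empirically: for every feature tuple a tiny probe
molecule is materialized and the RDKit query atom is evaluated against it.
This keeps the semantics of every supported primitive exactly in sync with the
matcher that is used for actual substructure searches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from rdkit import Chem
from rdkit.Chem import BondType

# Elements covered by the feature space; anything else makes an atom opaque.
SUPPORTED_ELEMENTS = (1, 5, 6, 7, 8, 9, 14, 15, 16, 17, 35, 53)
CHARGES = (-2, -1, 0, 1, 2)
HCOUNTS = (0, 1, 2, 3, 4)
DEGREES = (0, 1, 2, 3, 4, 5, 6)

# feature tuple: (atomic_num, aromatic, charge, hcount, degree, in_ring)
AtomFeatures = tuple[int, bool, int, int, int, bool]
# bond feature tuple: (order, in_ring)
BondFeatures = tuple[BondType, bool]

_BOND_ORDERS = (BondType.SINGLE, BondType.DOUBLE, BondType.TRIPLE, BondType.AROMATIC)

# Query-tree node types whose semantics are fully captured by the feature
# space.  Everything else renders the expression opaque.
_ATOM_QUERY_WHITELIST = {
    "AtomAnd",
    "AtomOr",
    "AtomType",
    "AtomAtomicNum",
    "AtomHCount",
    "AtomTotalDegree",
    "AtomExplicitDegree",
    "AtomFormalCharge",
    "AtomIsAromatic",
    "AtomIsAliphatic",
    "AtomInNRings",
    "AtomNull",
}
_BOND_QUERY_WHITELIST = {
    "BondAnd",
    "BondOr",
    "BondOrder",
    "BondInRing",
    "BondNull",
    "SingleOrAromaticBond",
}


def _enumerate_atom_space() -> list[AtomFeatures]:
    space: list[AtomFeatures] = []
    for z in SUPPORTED_ELEMENTS:
        for aromatic in (False, True):
            for ring in (False, True):
                if aromatic and not ring:
                    continue  # RDKit aromatic atoms always sit in rings
                for degree in DEGREES:
                    if ring and degree < 2:
                        continue
                    for charge in CHARGES:
                        for h in HCOUNTS:
                            space.append((z, aromatic, charge, h, degree, ring))
    return space


_ATOM_SPACE: Optional[list[AtomFeatures]] = None
_ATOM_PROBES: dict[AtomFeatures, tuple[Chem.Mol, int]] = {}
_BOND_SPACE: Optional[list[BondFeatures]] = None
_BOND_PROBES: dict[BondFeatures, tuple[Chem.Mol, int]] = {}


def atom_feature_space() -> list[AtomFeatures]:
    global _ATOM_SPACE
    if _ATOM_SPACE is None:
        _ATOM_SPACE = _enumerate_atom_space()
    return _ATOM_SPACE


def bond_feature_space() -> list[BondFeatures]:
    global _BOND_SPACE
    if _BOND_SPACE is None:
        _BOND_SPACE = [
            (order, ring)
            for order in _BOND_ORDERS
            for ring in (False, True)
            if not (order == BondType.AROMATIC and not ring)
        ]
    return _BOND_SPACE


def _atom_probe(feat: AtomFeatures) -> Chem.Atom:
    """Materialize a probe atom carrying exactly the given features."""
    if feat not in _ATOM_PROBES:
        z, aromatic, charge, h, degree, ring = feat
        m = Chem.RWMol()
        a = Chem.Atom(z)
        a.SetFormalCharge(charge)
        a.SetNoImplicit(True)
        a.SetNumExplicitHs(h)
        a.SetIsAromatic(aromatic)
        idx = m.AddAtom(a)
        extra = degree
        if ring:
            j = m.AddAtom(Chem.Atom(6))
            k = m.AddAtom(Chem.Atom(6))
            m.AddBond(idx, j, BondType.SINGLE)
            m.AddBond(j, k, BondType.SINGLE)
            m.AddBond(k, idx, BondType.SINGLE)
            extra = degree - 2
        for _ in range(extra):
            j = m.AddAtom(Chem.Atom(6))
            m.AddBond(idx, j, BondType.SINGLE)
        m.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(m)
        _ATOM_PROBES[feat] = (m, idx)
    mol, idx = _ATOM_PROBES[feat]
    return mol.GetAtomWithIdx(idx)


def _bond_probe(feat: BondFeatures) -> Chem.Bond:
    if feat not in _BOND_PROBES:
        order, ring = feat
        m = Chem.RWMol()
        a = m.AddAtom(Chem.Atom(6))
        b = m.AddAtom(Chem.Atom(6))
        m.AddBond(a, b, order)
        if ring:
            c = m.AddAtom(Chem.Atom(6))
            m.AddBond(b, c, BondType.SINGLE)
            m.AddBond(c, a, BondType.SINGLE)
        if order == BondType.AROMATIC:
            m.GetAtomWithIdx(a).SetIsAromatic(True)
            m.GetAtomWithIdx(b).SetIsAromatic(True)
            m.GetBondBetweenAtoms(a, b).SetIsAromatic(True)
        m.UpdatePropertyCache(strict=False)
        Chem.FastFindRings(m)
        _BOND_PROBES[feat] = (m, m.GetBondBetweenAtoms(a, b).GetIdx())
    mol, idx = _BOND_PROBES[feat]
    return mol.GetBondWithIdx(idx)


def _query_is_supported(describe: str, whitelist: set[str], atom: bool) -> bool:
    for line in describe.splitlines():
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        node = parts[0]
        if node not in whitelist:
            return False
        if atom and node in ("AtomType", "AtomAtomicNum"):
            z = int(parts[1])
            if z > 1000:
                z -= 1000  # RDKit encodes aromatic element types as 1000+Z
            if z not in SUPPORTED_ELEMENTS:
                return False
        if atom and node == "AtomInNRings":
            # only plain ring membership ([R] / [!R], encoded as -1) is a
            # feature; explicit SSSR ring counts are beyond the space
            if int(parts[1]) != -1:
                return False
        if atom and node == "AtomFormalCharge" and not (
            CHARGES[0] <= int(parts[1]) <= CHARGES[-1]
        ):
            return False
        if atom and node == "AtomHCount" and not (
            HCOUNTS[0] <= int(parts[1]) <= HCOUNTS[-1]
        ):
            return False
        if atom and node in ("AtomTotalDegree", "AtomExplicitDegree") and not (
            DEGREES[0] <= int(parts[1]) <= DEGREES[-1]
        ):
            return False
    return True


@dataclass(frozen=True)
class AtomExpression:
    """Normalized SMARTS atom constraint.

    ``accepts`` is a frozenset of indices into :func:`atom_feature_space`, or
    ``None`` when the expression is opaque.  An expression that accepts no
    tuple at all is treated as opaque as well (it constrains features outside
    the space, e.g. a hydrogen count above the modeled range).
    """

    raw: str
    accepts: Optional[frozenset[int]]

    @property
    def opaque(self) -> bool:
        return self.accepts is None

    def forced_element(self) -> Optional[int]:
        """Atomic number forced by every accepted tuple, if unique."""
        if self.opaque:
            return None
        space = atom_feature_space()
        elems = {space[i][0] for i in self.accepts}
        return elems.pop() if len(elems) == 1 else None

    def forced_in_ring(self) -> bool:
        if self.opaque:
            return False
        space = atom_feature_space()
        return all(space[i][5] for i in self.accepts)

    def forced_aromatic(self) -> bool:
        if self.opaque:
            return False
        space = atom_feature_space()
        return all(space[i][1] for i in self.accepts)


@dataclass(frozen=True)
class BondExpression:
    raw: str
    accepts: Optional[frozenset[int]]

    @property
    def opaque(self) -> bool:
        return self.accepts is None


_atom_expr_cache: dict[str, Optional[frozenset[int]]] = {}
_bond_expr_cache: dict[str, Optional[frozenset[int]]] = {}


def atom_expression(atom: Chem.Atom) -> AtomExpression:
    """Normalize a query atom taken from a parsed SMARTS."""
    raw = atom.GetSmarts()
    if raw not in _atom_expr_cache:
        accepts: Optional[frozenset[int]] = None
        if atom.HasQuery() and _query_is_supported(
            atom.DescribeQuery(), _ATOM_QUERY_WHITELIST, atom=True
        ):
            hits = frozenset(
                i
                for i, feat in enumerate(atom_feature_space())
                if atom.Match(_atom_probe(feat))
            )
            accepts = hits if hits else None
        _atom_expr_cache[raw] = accepts
    return AtomExpression(raw=raw, accepts=_atom_expr_cache[raw])


def bond_expression(bond: Chem.Bond) -> BondExpression:
    raw = bond.GetSmarts() or "~default~"
    if raw not in _bond_expr_cache:
        accepts: Optional[frozenset[int]] = None
        if bond.HasQuery() and _query_is_supported(
            bond.DescribeQuery(), _BOND_QUERY_WHITELIST, atom=False
        ):
            hits = frozenset(
                i
                for i, feat in enumerate(bond_feature_space())
                if bond.Match(_bond_probe(feat))
            )
            accepts = hits if hits else None
        _bond_expr_cache[raw] = accepts
    return BondExpression(raw=raw, accepts=_bond_expr_cache[raw])


def atom_expr_subsumes(general: AtomExpression, specific: AtomExpression) -> str:
    """Tri-state test that ``general`` accepts every atom ``specific`` accepts.

    Returns ``"yes"``, ``"no"`` or ``"unknown"``.  Opaque expressions compare
    by raw text only; differing texts are undecidable rather than false.
    """
    if general.raw == specific.raw:
        return "yes"
    if general.opaque or specific.opaque:
        return "unknown"
    return "yes" if specific.accepts <= general.accepts else "no"


def bond_expr_subsumes(general: BondExpression, specific: BondExpression) -> str:
    if general.raw == specific.raw:
        return "yes"
    if general.opaque or specific.opaque:
        return "unknown"
    return "yes" if specific.accepts <= general.accepts else "no"
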