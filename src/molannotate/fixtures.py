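"""Seed pattern collection and programmatic toy corpus.

The seed collection is a curated, hand-written set of ~70 patterns spanning the
three categories (functional groups, cyclic systems, biologically relevant
substructures) so that every part of the annotation pipeline is testable
without downloading anything.  Cyclic and most biological patterns are derived
from reference SMILES through the same substitution-tolerant construction the
extraction pipeline uses; functional groups are hand-written SMARTS.

The toy corpus bundles fixed worked-example molecules, one exemplar molecule
per seed pattern, and a deterministic stream of randomized molecules assembled
from a small scaffold + substituent grammar.  Each corpus entry carries the
expected visible pattern names; for the randomized molecules these are the
pipeline's own (deterministic) output, recorded at corpus construction so the
suite can detect any order- or run-dependence.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from functools import lru_cache

from rdkit import Chem
from rdkit.rdBase import BlockLogs

from .extraction import (
    NamedSmilesRecord,
    _exocyclic_keeper_atoms,
    build_substructure_query,
    ring_pattern_from_molecule,
)
from .hierarchy import SubsumptionGraph, build_hierarchy
from .matching import MoleculeRecord, QueryCache
from .overshadow import annotate_molecule
from .patterns import Pattern, PatternCollection, _slug

# --------------------------------------------------------------------------
# seed patterns

_FUNCTIONAL_GROUPS = [
    # two-atom patterns: the carbon environment is demanded through recursion
    # but its atoms are not part of the match
    ("azo", "[NX2;$([NX2](=[NX2])[#6])]=[NX2;$([NX2](=[NX2])[#6])]"),
    ("aldehyde", "[CX3H1;$([CX3H1](=[OX1])[#6])]=[OX1]"),
    ("amide", "[NX3][CX3]=[OX1]"),
    ("lactam", "[NX3;R]-;@[CX3;R]=[OX1]"),
    # imide: diacyl derivative of ammonia or a primary amine
    ("imide", "[CX3](=[OX1])[NX3][CX3]=[OX1]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("trifluoromethyl", "[CX4](F)(F)F"),
    ("trihalide", "[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]"),
    ("sulfate", "[SX4](=[OX1])(=[OX1])([OX2])[OX2]"),
    ("carboxylic acid", "[CX3](=[OX1])[OX2H1]"),
    ("carboxylate", "[CX3](=[OX1])[OX1-]"),
    ("hydroxy", "[OX2H]"),
    ("carbonyl", "[#6X3]=[OX1]"),
    ("ketone", "[#6][CX3](=[OX1])[#6]"),
    ("phenol", "[OX2H][c]"),
    ("ether", "[OX2]([#6])[#6]"),
    ("primary amine", "[NX3H2][#6]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("thiol", "[SX2H]"),
    ("sulfide", "[SX2]([#6])[#6]"),
    ("sulfonamide", "[SX4](=[OX1])(=[OX1])[NX3]"),
    ("ester", "[CX3](=[OX1])[OX2][#6]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
]

# reference SMILES whose ring systems become the cyclic seed patterns
_CYCLIC_SOURCES = [
    ("benzene", "c1ccccc1"),
    ("pyridine", "c1ccncc1"),
    ("pyrimidine", "c1cncnc1"),
    ("pyrazine", "c1cnccn1"),
    ("pyridazine", "c1ccnnc1"),
    ("imidazole", "c1c[nH]cn1"),
    ("pyrazole", "c1cc[nH]n1"),
    ("oxazole", "c1ocnc1"),
    ("thiazole", "c1scnc1"),
    ("furan", "c1ccoc1"),
    ("thiophene", "c1ccsc1"),
    ("pyrrole", "c1cc[nH]c1"),
    ("purine", "c1ncc2nc[nH]c2n1"),
    ("xanthine", "C1=NC2=C(N1)C(=O)NC(=O)N2"),
    ("quinazoline", "C1=CC=C2C(=C1)C=NC=N2"),
    ("tetrahydroquinazoline", "C1Nc2ccccc2CN1"),
    ("quinoline", "C1=CC=C2C(=C1)C=CC=N2"),
    ("isoquinoline", "C1=CC=C2C=NC=CC2=C1"),
    ("indole", "c1ccc2[nH]ccc2c1"),
    ("naphthalene", "c1ccc2ccccc2c1"),
    ("benzimidazole", "c1ccc2[nH]cnc2c1"),
    ("cyclopropane", "C1CC1"),
    ("cyclobutane", "C1CCC1"),
    ("cyclopentane", "C1CCCC1"),
    ("cyclohexane", "C1CCCCC1"),
    ("cycloheptane", "C1CCCCCC1"),
    ("cyclononane", "C1CCCCCCCC1"),
    ("hydrindane", "C1CCC2CCCC2C1"),
    ("decalin", "C1CCC2CCCCC2C1"),
    ("piperidine", "C1CCNCC1"),
    ("piperazine", "C1CNCCN1"),
    ("morpholine", "C1COCCN1"),
    ("pyrrolidine", "C1CCNC1"),
    ("tetrahydrofuran", "C1CCOC1"),
    ("tetrahydropyran", "C1CCOCC1"),
    ("cyclohexanone", "O=C1CCCCC1"),
]

# biological patterns from reference SMILES, substitution-tolerant so that
# e.g. the nucleobases still match inside nucleosides
_BIOLOGICAL_SOURCES = [
    ("adenine", "Nc1ncnc2[nH]cnc12"),
    ("guanine", "Nc1nc2[nH]cnc2c(=O)[nH]1"),
    ("cytosine", "Nc1cc[nH]c(=O)n1"),
    ("thymine", "Cc1c[nH]c(=O)[nH]c1=O"),
    ("uracil", "O=c1cc[nH]c(=O)[nH]1"),
    ("glucose", "OCC1OC(O)C(O)C(O)C1O"),
    ("ribose", "OCC1OC(O)C(O)C1O"),
    ("catecholamine", "NCCc1ccc(O)c(O)c1"),
    ("glycine", "NCC(=O)O"),
    ("alanine", "CC(N)C(=O)O"),
]

# trivial names kept in the biological bucket; hand-written so the methyl
# really is a methyl
_BIOLOGICAL_SMARTS = [
    ("toluene", "[CX4H3]c1ccccc1"),
    ("cresol", "[CX4H3]c1ccc([OX2H])cc1"),
]


def loose_pattern_from_molecule(mol: Chem.Mol) -> str:
    """Substitution-tolerant SMARTS for a whole molecule: element, aromaticity
    and charge per atom, bond orders, no H/degree constraints except degree 1
    on exocyclic terminal O/S."""
    query = build_substructure_query(mol, degree1_atoms=_exocyclic_keeper_atoms(mol))
    return Chem.MolToSmarts(query)


@lru_cache(maxsize=1)
def seed_pattern_collection() -> PatternCollection:
    patterns: list[Pattern] = []
    for name, smarts in _FUNCTIONAL_GROUPS:
        patterns.append(Pattern.create(smarts, name, "functional_group",
                                       id=f"fg-{_slug(name)}"))
    for name, smiles in _CYCLIC_SOURCES:
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, f"bad cyclic source SMILES for {name}"
        patterns.append(Pattern.create(ring_pattern_from_molecule(mol), name,
                                       "cyclic", id=f"cyc-{_slug(name)}"))
    for name, smiles in _BIOLOGICAL_SOURCES:
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, f"bad biological source SMILES for {name}"
        patterns.append(Pattern.create(loose_pattern_from_molecule(mol), name,
                                       "biological", id=f"bio-{_slug(name)}"))
    for name, smarts in _BIOLOGICAL_SMARTS:
        patterns.append(Pattern.create(smarts, name, "biological",
                                       id=f"bio-{_slug(name)}"))
    return PatternCollection(patterns, version="molannotate-seed-0.1")


@lru_cache(maxsize=1)
def seed_hierarchy() -> SubsumptionGraph:
    return build_hierarchy(seed_pattern_collection())


# --------------------------------------------------------------------------
# toy corpus

# the worked examples exercising every overshadowing rule
WORKED_EXAMPLES = [
    ("caffeine", "CN1C=NC2=C1C(=O)N(C(=O)N2C)C"),
    ("purine", "c1ncc2nc[nH]c2n1"),
    ("hydrindane", "C1CCC2CCCC2C1"),
    ("trifluoromethylbenzene", "FC(F)(F)c1ccccc1"),
    ("formic acid", "OC=O"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1"),
    ("succinimide", "O=C1CCC(=O)N1"),
]

# one exemplar per functional-group pattern (cyclic/biological patterns are
# covered by their own source molecules)
_FUNCTIONAL_EXEMPLARS = [
    ("azobenzene", "c1ccc(N=Nc2ccccc2)cc1"),
    ("acetaldehyde", "CC=O"),
    ("acetamide", "CC(N)=O"),
    ("2-pyrrolidinone", "O=C1CCCN1"),
    ("guanidine", "NC(=N)N"),
    ("dimethyl sulfate", "COS(=O)(=O)OC"),
    ("acetic acid", "CC(=O)O"),
    ("acetate", "CC(=O)[O-]"),
    ("ethanol", "CCO"),
    ("acetone", "CC(=O)C"),
    ("phenol", "Oc1ccccc1"),
    ("diethyl ether", "CCOCC"),
    ("ethylamine", "CCN"),
    ("acetonitrile", "CC#N"),
    ("ethanethiol", "CCS"),
    ("dimethyl sulfide", "CSC"),
    ("methanesulfonamide", "CS(N)(=O)=O"),
    ("methyl acetate", "COC(C)=O"),
    ("urea", "NC(N)=O"),
    ("methane", "C"),
    ("toluene", "Cc1ccccc1"),
    ("p-cresol", "Cc1ccc(O)cc1"),
]

# scaffold templates with up to two substitution sites
_TEMPLATES = [
    "c1cc{A}ccc1{B}",        # benzene
    "c1cc{A}cnc1{B}",        # pyridine
    "c1ncc{A}cn1",           # pyrimidine
    "C1CC{A}CCC1{B}",        # cyclohexane
    "C1CC{A}CCN1{B}",        # piperidine
    "c1cc{A}cs1",            # thiophene
    "Cn1cc{A}nc1{B}",        # N-methylimidazole
    "c1ccc2cc{A}ccc2c1",     # naphthalene
]
_SUBSTITUENTS_BRANCH = ["", "(F)", "(Cl)", "(Br)", "(C(F)(F)F)", "(O)", "(N)",
                        "(C)", "(OC)", "(C(=O)O)", "(C#N)", "(S)", "(C(C)=O)",
                        "(C(N)=O)"]
_SUBSTITUENTS_TAIL = ["", "F", "Cl", "O", "N", "C", "OC", "C(=O)O",
                      "C(F)(F)F", "C#N"]


@dataclass(frozen=True)
class CorpusEntry:
    record: MoleculeRecord
    expected_visible: tuple[str, ...]  # sorted visible pattern names


def _fixed_molecules() -> list[tuple[str, str]]:
    seen: set[str] = set()
    out: list[tuple[str, str]] = []
    pools = (
        WORKED_EXAMPLES,
        _CYCLIC_SOURCES,
        _BIOLOGICAL_SOURCES,
        _FUNCTIONAL_EXEMPLARS,
    )
    for pool in pools:
        for name, smiles in pool:
            mol = Chem.MolFromSmiles(smiles)
            assert mol is not None, f"bad corpus SMILES for {name}"
            key = Chem.MolToSmiles(mol)
            if key in seen:
                continue
            seen.add(key)
            out.append((name, smiles))
    return out


def fixed_corpus_size() -> int:
    return len(_fixed_molecules())


def _random_molecule(rng: random.Random, ordinal: int) -> MoleculeRecord:
    while True:
        template = rng.choice(_TEMPLATES)
        smiles = template.format(
            A=rng.choice(_SUBSTITUENTS_BRANCH),
            B=rng.choice(_SUBSTITUENTS_TAIL) if "{B}" in template else "",
        )
        with BlockLogs():
            mol = Chem.MolFromSmiles(smiles)
        if mol is not None:
            return MoleculeRecord.from_smiles(smiles, name=f"synthetic-{ordinal:03d}")


def toy_corpus(seed: int, n: int) -> list[CorpusEntry]:
    """Deterministic corpus: fixed molecules plus ``n`` randomized ones.

    Each entry records the visible pattern names of a full seed-collection
    annotation at construction time, so identical inputs must reproduce them.
    """
    collection = seed_pattern_collection()
    graph = seed_hierarchy()
    cache = QueryCache()
    rng = random.Random(seed)
    records = [
        MoleculeRecord.from_smiles(smiles, name=name)
        for name, smiles in _fixed_molecules()
    ]
    records.extend(_random_molecule(rng, k) for k in range(n))
    entries = []
    for record in records:
        result = annotate_molecule(record, collection, graph, cache=cache)
        names = tuple(sorted(collection.get(m.pattern_id).name for m in result.visible))
        entries.append(CorpusEntry(record=record, expected_visible=names))
    return entries


# --------------------------------------------------------------------------
# extraction pipeline fixture (hand-checked)

# (name, smiles, expected filter reason); every filter rule is exercised
_EXTRACTION_ROWS = [
    ("benzene", "c1ccccc1", "ok"),
    ("toluene", "Cc1ccccc1", "not_ring_system"),
    ("cyclohexanone", "O=C1CCCCC1", "ok"),
    ("phenol", "Oc1ccccc1", "not_ring_system"),
    ("cyclopropane-13C", "[13CH2]1CC1", "isotope"),
    ("cyclopropane dimer", "C1CC1.C1CC1", "mixture"),
    ("cyclopropyl radical", "[CH]1CC1", "radical"),
    ("oversize macrocycle", "C1" + "C" * 100 + "1", "too_large"),
    ("largest macrocycle", "C1" + "C" * 99 + "1", "ok"),
    ("CID1234567", "c1ccncc1", "name_cid_prefix"),
    ("phenyl", "c1ccccc1", "name_yl_suffix"),
    ("1,2,3,4,5-pentamethylcyclopentadienide", "C1CCCC1", "name_numbers"),
    ("1,2,3,4-tetrahydroquinazoline", "C1Nc2ccccc2CN1", "ok"),
    ("broken smiles", "C1CC", "unparseable"),
    ("", "c1ccccc1", "unparseable"),
    ("purine", "c1ncc2nc[nH]c2n1", "ok"),
    ("7H-purine", "c1ncc2nc[nH]c2n1", "ok"),
    ("pyridinium", "c1cc[nH+]cc1", "ok"),
    ("thiocyclohexanone", "S=C1CCCCC1", "ok"),
    ("methylenecyclohexane", "C=C1CCCCC1", "not_ring_system"),
    ("cyclohexanethiol", "SC1CCCCC1", "not_ring_system"),
    ("biphenyl", "c1ccc(-c2ccccc2)cc1", "not_ring_system"),
    ("naphthalene", "c1ccc2ccccc2c1", "ok"),
    ("indanone", "O=C1CCc2ccccc21", "ok"),
    ("   ", "c1ccccc1", "unparseable"),
    ("CId-mixed-case", "C1CCCCC1", "ok"),
    ("CID99", "[CH]1CC1", "radical"),
    ("furan", "c1ccoc1", "ok"),
    ("spiro decane", "C1CCC2(CC1)CCCC2", "ok"),
    ("bad valence", "F=C", "unparseable"),
]

# the ok rows above, after structure-key dedup ("7H-purine" collapses onto
# "purine" which wins the shortest-name tie-break)
EXPECTED_SURVIVOR_NAMES = [
    "benzene",
    "cyclohexanone",
    "largest macrocycle",
    "1,2,3,4-tetrahydroquinazoline",
    "purine",
    "pyridinium",
    "thiocyclohexanone",
    "naphthalene",
    "indanone",
    "CId-mixed-case",
    "furan",
    "spiro decane",
]


def extraction_fixture_table() -> list[tuple[NamedSmilesRecord, str]]:
    """30 hand-checked rows exercising every structure and name filter."""
    return [
        (NamedSmilesRecord(name=name, smiles=smiles, source_line=i + 1), reason)
        for i, (name, smiles, reason) in enumerate(_EXTRACTION_ROWS)
    ]
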