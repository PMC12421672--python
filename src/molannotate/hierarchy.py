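"""Restricted SMARTS subsumption: which pattern is strictly more specific.

Pattern G *subsumes* pattern S when every match of S is also a match of G
(on a subset of the matched atoms).  The engine decides this with a sound
sufficient test: it searches for an injective, adjacency-preserving mapping of
G's pattern graph into S's such that every mapped atom and bond expression of
G accepts at least everything its image accepts (decided by enumeration over
the finite feature space of :mod:`molannotate.smartsq`).

The test is deliberately incomplete: expressions using unsupported primitives
(notably recursive environments) are opaque and compare by exact text only, so
``unknown`` is a possible answer.  An unknown pair simply gets no hierarchy
edge — the only consequence downstream is that an equally sized, less specific
match may stay visible, never that a match is wrongly hidden.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional

from .matching import MoleculeRecord, QueryCache, find_pattern_matches
from .patterns import Pattern, PatternCollection
from . import smartsq

logger = logging.getLogger(__name__)


@dataclass
class _PatternGraph:
    atoms: list[smartsq.AtomExpression]
    bonds: dict[tuple[int, int], smartsq.BondExpression]
    adjacency: dict[int, list[int]]


_graph_cache: dict[str, _PatternGraph] = {}


def _pattern_graph(pattern: Pattern) -> _PatternGraph:
    if pattern.smarts not in _graph_cache:
        query = pattern.query()
        atoms = [smartsq.atom_expression(a) for a in query.GetAtoms()]
        bonds: dict[tuple[int, int], smartsq.BondExpression] = {}
        adjacency: dict[int, list[int]] = {i: [] for i in range(query.GetNumAtoms())}
        for b in query.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            bonds[(min(i, j), max(i, j))] = smartsq.bond_expression(b)
            adjacency[i].append(j)
            adjacency[j].append(i)
        _graph_cache[pattern.smarts] = _PatternGraph(atoms, bonds, adjacency)
    return _graph_cache[pattern.smarts]


def atom_expr_subsumes(general: smartsq.AtomExpression,
                       specific: smartsq.AtomExpression) -> str:
    """Tri-state: does ``general`` accept every atom ``specific`` accepts?"""
    return smartsq.atom_expr_subsumes(general, specific)


def pattern_subsumes(general: Pattern, specific: Pattern) -> str:
    """Tri-state test that every match of ``specific`` embeds a match of
    ``general``.

    ``yes`` is sound: it is backed by an explicit monomorphism of the general
    pattern graph into the specific one with expression-wise subsumption on
    every mapped atom and bond.  ``no`` means no mapping survives the
    feature-space comparison; ``unknown`` means the only surviving mappings
    involve opaque expressions.
    """
    if general.smarts == specific.smarts:
        return "yes"
    g = _pattern_graph(general)
    s = _pattern_graph(specific)
    n_g, n_s = len(g.atoms), len(s.atoms)
    if n_g > n_s or len(g.bonds) > len(s.bonds):
        return "no"

    # precompute tri-state atom compatibility
    atom_cmp = [
        [smartsq.atom_expr_subsumes(g.atoms[i], s.atoms[j]) for j in range(n_s)]
        for i in range(n_g)
    ]
    # order general atoms most-constrained-first
    order = sorted(
        range(n_g), key=lambda i: sum(c != "no" for c in atom_cmp[i])
    )
    # prefer connected expansion for cheap adjacency pruning
    ordered: list[int] = []
    remaining = set(order)
    while remaining:
        anchor = next(i for i in order if i in remaining)
        stack = [anchor]
        while stack:
            cur = stack.pop()
            if cur not in remaining:
                continue
            remaining.discard(cur)
            ordered.append(cur)
            stack.extend(nb for nb in g.adjacency[cur] if nb in remaining)

    mapping: dict[int, int] = {}
    used: set[int] = set()
    saw_unknown_completion = False

    def bond_cmp(gi: int, gj: int, si: int, sj: int) -> str:
        gkey = (min(gi, gj), max(gi, gj))
        skey = (min(si, sj), max(si, sj))
        if skey not in s.bonds:
            return "no"
        return smartsq.bond_expr_subsumes(g.bonds[gkey], s.bonds[skey])

    def search(pos: int, unknown: bool) -> bool:
        nonlocal saw_unknown_completion
        if pos == len(ordered):
            if unknown:
                saw_unknown_completion = True
                return False
            return True
        gi = ordered[pos]
        for sj in range(n_s):
            if sj in used:
                continue
            a = atom_cmp[gi][sj]
            if a == "no":
                continue
            step_unknown = a == "unknown"
            ok = True
            for gn in g.adjacency[gi]:
                if gn in mapping:
                    b = bond_cmp(gi, gn, sj, mapping[gn])
                    if b == "no":
                        ok = False
                        break
                    if b == "unknown":
                        step_unknown = True
            if not ok:
                continue
            mapping[gi] = sj
            used.add(sj)
            if search(pos + 1, unknown or step_unknown):
                return True
            del mapping[gi]
            used.discard(sj)
        return False

    if search(0, False):
        return "yes"
    return "unknown" if saw_unknown_completion else "no"


@dataclass
class SubsumptionGraph:
    """Directed specificity relations: edge (general -> specific) means every
    match of the specific pattern embeds a match of the general one."""

    nodes: list[str] = field(default_factory=list)
    edges: set[tuple[str, str]] = field(default_factory=set)
    equivalences: list[frozenset[str]] = field(default_factory=list)

    def has_edge(self, general_id: str, specific_id: str) -> bool:
        return (general_id, specific_id) in self.edges

    def equivalent(self, a: str, b: str) -> bool:
        return any(a in cls_ and b in cls_ for cls_ in self.equivalences)

    def to_json(self) -> str:
        data = [{"general": g, "specific": s} for g, s in sorted(self.edges)]
        return json.dumps(data, indent=2) + "\n"

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path, nodes: Optional[list[str]] = None) -> "SubsumptionGraph":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        edges = {(d["general"], d["specific"]) for d in data}
        if nodes is None:
            nodes = sorted({n for e in edges for n in e})
        return cls(nodes=list(nodes), edges=edges)

    def is_acyclic(self) -> bool:
        import networkx as nx

        dg = nx.DiGraph()
        dg.add_nodes_from(self.nodes)
        dg.add_edges_from(self.edges)
        return nx.is_directed_acyclic_graph(dg)


def build_hierarchy(collection: PatternCollection) -> SubsumptionGraph:
    """Pairwise subsumption over a collection.

    Mutually subsuming (equivalent) pattern pairs produce no edges; they are
    merged into logged equivalence classes instead, so the result is acyclic.
    """
    ids = [p.id for p in collection]
    decided: dict[tuple[str, str], str] = {}
    for a, b in combinations(list(collection), 2):
        decided[(a.id, b.id)] = pattern_subsumes(a, b)
        decided[(b.id, a.id)] = pattern_subsumes(b, a)

    # merge mutual-yes pairs into equivalence classes (union-find)
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b), verdict in decided.items():
        if a < b and verdict == "yes" and decided[(b, a)] == "yes":
            logger.warning(
                "patterns %s and %s are mutually subsuming; merged into one "
                "equivalence class", a, b,
            )
            parent[find(a)] = find(b)

    classes: dict[str, set[str]] = {}
    for i in ids:
        classes.setdefault(find(i), set()).add(i)
    equivalences = [frozenset(c) for c in classes.values() if len(c) > 1]

    edges = {
        (a, b)
        for (a, b), verdict in decided.items()
        if verdict == "yes" and find(a) != find(b)
    }
    graph = SubsumptionGraph(nodes=ids, edges=edges, equivalences=equivalences)
    assert graph.is_acyclic(), "subsumption graph has a cycle after class merging"
    return graph


@dataclass(frozen=True)
class AuditViolation:
    general_id: str
    specific_id: str
    molecule: str
    atom_indices: tuple[int, ...]


def corpus_subsumption_audit(
    collection: PatternCollection,
    corpus: list[MoleculeRecord],
    graph: Optional[SubsumptionGraph] = None,
) -> list[AuditViolation]:
    """Empirical soundness check of a hierarchy against a molecule corpus.

    For every edge (g -> s) and every corpus molecule, every match of s must
    embed a match of g (atom and bond sets of some g-match contained in those
    of the s-match).  An empty report means the hierarchy is sound on this
    corpus.
    """
    if graph is None:
        graph = build_hierarchy(collection)
    cache = QueryCache()
    violations: list[AuditViolation] = []
    for record in corpus:
        if record.mol is None:
            continue
        matches = find_pattern_matches(record, collection, use_prefilter=True, cache=cache)
        by_pattern: dict[str, list] = {}
        for m in matches:
            by_pattern.setdefault(m.pattern_id, []).append(m)
        for general_id, specific_id in graph.edges:
            for sm in by_pattern.get(specific_id, []):
                ok = any(
                    gm.atom_indices <= sm.atom_indices and gm.bonds <= sm.bonds
                    for gm in by_pattern.get(general_id, [])
                )
                if not ok:
                    violations.append(
                        AuditViolation(
                            general_id=general_id,
                            specific_id=specific_id,
                            molecule=record.key,
                            atom_indices=tuple(sorted(sm.atom_indices)),
                        )
                    )
    return violations
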