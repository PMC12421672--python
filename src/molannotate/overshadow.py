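"""Resolution of which pattern matches are displayed by default.

A match *overshadows* another when it covers a superset of the molecule — the
larger match contains the smaller one's atoms and bonds — or when both cover
the exact same atoms and either one spans fewer bonds (a monocycle perimeter
inside a bicycle) or one pattern is strictly more specific than the other in
the subsumption hierarchy (trifluoromethyl over trihalide).  Matches covering
different atoms never overshadow each other.

Suppression is evaluated declaratively against *all* deduplicated matches, not
only visible ones: a match overshadowed solely by an itself-overshadowed match
stays suppressed.  The visible set is the unsuppressed remainder; visible and
suppressed matches always partition the deduplicated match list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

from rdkit import Chem

from .hierarchy import SubsumptionGraph
from .matching import (
    MoleculeRecord,
    PatternMatch,
    QueryCache,
    copy_match,
    find_pattern_matches,
)
from .patterns import PatternCollection

logger = logging.getLogger(__name__)

NO_NAME = "No Name"


def match_overshadows(
    a: PatternMatch, b: PatternMatch, graph: SubsumptionGraph
) -> tuple[bool, str]:
    """Does match ``a`` overshadow match ``b``?  Returns (flag, reason).

    Reasons: ``match_containment`` for strict containment of atoms and bonds,
    ``fewer_bonds`` for identical atoms with fewer bonds in ``b``, and
    ``hierarchy`` for identical atoms and bond counts where ``b``'s pattern
    subsumes ``a``'s (``a`` is strictly more specific).
    """
    if a is b or a.identity() == b.identity():
        return False, "none"
    if (
        a.molecule_key is not None
        and b.molecule_key is not None
        and a.molecule_key != b.molecule_key
    ):
        raise ValueError("cannot compare matches from different molecules")
    if b.atom_indices == a.atom_indices:
        if len(b.bonds) < len(a.bonds):
            return True, "fewer_bonds"
        if len(b.bonds) == len(a.bonds) and graph.has_edge(b.pattern_id, a.pattern_id):
            # b's pattern subsumes a's: a is strictly more specific here
            return True, "hierarchy"
        return False, "none"
    if b.atom_indices < a.atom_indices and b.bonds <= a.bonds:
        return True, "match_containment"
    return False, "none"


def resolve_overshadowing(
    matches: list[PatternMatch], graph: SubsumptionGraph
) -> list[PatternMatch]:
    """Pure function marking each match's suppression state.

    Every ordered pair is evaluated; suppressed matches carry the reason of
    their first overshadower (in deterministic match order) and the ids of all
    overshadowers.
    """
    out = [copy_match(m) for m in matches]
    for m in out:
        m.suppression = "none"
        m.suppressed_by = []
    for i, b in enumerate(out):
        for j, a in enumerate(out):
            if i == j:
                continue
            flag, reason = match_overshadows(a, b, graph)
            if flag:
                if b.suppression == "none":
                    b.suppression = reason
                b.suppressed_by.append(a.pattern_id)
            elif (
                a.atom_indices == b.atom_indices
                and a.bonds == b.bonds
                and a.pattern_id != b.pattern_id
                and graph.equivalent(a.pattern_id, b.pattern_id)
            ):
                logger.warning(
                    "equivalent patterns %s and %s match the same atoms; "
                    "neither is suppressed", a.pattern_id, b.pattern_id,
                )
    return out


@dataclass
class AnnotationResult:
    """Per-molecule annotation outcome: all matches with suppression state."""

    molecule_name: str
    smiles: str
    matches: list[PatternMatch] = field(default_factory=list)
    error: Optional[str] = None
    include_overshadowed: bool = True

    @property
    def visible(self) -> list[PatternMatch]:
        return [m for m in self.matches if m.suppression == "none"]

    @property
    def suppressed(self) -> list[PatternMatch]:
        return [m for m in self.matches if m.suppression != "none"]


def annotate_molecule(
    record: MoleculeRecord,
    collection: PatternCollection,
    graph: SubsumptionGraph,
    include_overshadowed: bool = True,
    use_prefilter: bool = True,
    cache: Optional[QueryCache] = None,
) -> AnnotationResult:
    """Full per-molecule pipeline: match, deduplicate, resolve overshadowing.

    Unparseable molecules yield an error-carrying result instead of raising,
    so batch annotation never aborts on a single bad record.
    """
    name = record.name if record.name else NO_NAME
    if record.mol is None:
        return AnnotationResult(
            molecule_name=name,
            smiles=record.smiles,
            error=record.error or "unparseable molecule",
            include_overshadowed=include_overshadowed,
        )
    matches = find_pattern_matches(
        record, collection, use_prefilter=use_prefilter, cache=cache
    )
    resolved = resolve_overshadowing(matches, graph)
    return AnnotationResult(
        molecule_name=name,
        smiles=Chem.MolToSmiles(record.mol),
        matches=resolved,
        include_overshadowed=include_overshadowed,
    )
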