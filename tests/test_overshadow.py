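"""Overshadowing rules and whole-molecule annotation."""

import networkx as nx
import pytest
from hypothesis import given, strategies as st

from molannotate.hierarchy import SubsumptionGraph
from molannotate.matching import MoleculeRecord, PatternMatch
from molannotate.overshadow import (
    annotate_molecule,
    match_overshadows,
    resolve_overshadowing,
)


def mk(pid, atoms, bonds, key="m"):
    return PatternMatch(pid, frozenset(atoms), frozenset(bonds), molecule_key=key)


EMPTY = SubsumptionGraph(nodes=[])


class TestMatchOvershadows:
    def test_strict_containment(self):
        big = mk("purine", range(9), [(i, i + 1) for i in range(8)])
        small = mk("imidazole", range(5), [(i, i + 1) for i in range(4)])
        flag, reason = match_overshadows(big, small, EMPTY)
        assert (flag, reason) == (True, "match_containment")
        assert match_overshadows(small, big, EMPTY)[0] is False

    def test_containment_requires_bond_subset(self):
        a = mk("a", {0, 1, 2}, {(0, 1), (1, 2)})
        b = mk("b", {0, 1}, {(0, 1)})
        c = mk("c", {0, 2}, {(0, 2)})  # bond not covered by a
        assert match_overshadows(a, b, EMPTY) == (True, "match_containment")
        assert match_overshadows(a, c, EMPTY)[0] is False

    def test_same_atoms_fewer_bonds(self):
        bicycle = mk("hydrindane", range(9),
                     [(i, (i + 1) % 9) for i in range(9)] + [(0, 5)])
        perimeter = mk("cyclononane", range(9),
                       [(i, (i + 1) % 9) for i in range(9)])
        assert match_overshadows(bicycle, perimeter, EMPTY) == (True, "fewer_bonds")
        assert match_overshadows(perimeter, bicycle, EMPTY)[0] is False

    def test_hierarchy_applies_only_at_equal_size(self):
        graph = SubsumptionGraph(nodes=["general", "specific"],
                                 edges={("general", "specific")})
        atoms, bonds = {0, 1, 2, 3}, {(0, 1), (0, 2), (0, 3)}
        specific = mk("specific", atoms, bonds)
        general = mk("general", atoms, bonds)
        assert match_overshadows(specific, general, graph) == (True, "hierarchy")
        assert match_overshadows(general, specific, graph)[0] is False

    def test_different_atoms_never_overshadow(self):
        a = mk("benzene", range(6), [])
        b = mk("benzene", range(6, 12), [])
        assert match_overshadows(a, b, EMPTY)[0] is False

    def test_irreflexive(self):
        a = mk("x", {0, 1}, {(0, 1)})
        assert match_overshadows(a, a, EMPTY)[0] is False

    def test_cross_molecule_comparison_rejected(self):
        a = mk("x", {0}, set(), key="mol-a")
        b = mk("y", {0}, set(), key="mol-b")
        with pytest.raises(ValueError, match="different molecules"):
            match_overshadows(a, b, EMPTY)


class TestResolve:
    def test_single_match_stays_visible(self):
        out = resolve_overshadowing([mk("x", {0, 1}, {(0, 1)})], EMPTY)
        assert out[0].suppression == "none" and out[0].suppressed_by == []

    def test_equal_unrelated_matches_both_visible(self):
        a = mk("a", {0, 1}, {(0, 1)})
        b = mk("b", {0, 1}, {(0, 1)})
        out = resolve_overshadowing([a, b], EMPTY)
        assert all(m.suppression == "none" for m in out)

    def test_suppression_by_an_overshadowed_match_persists(self):
        # chain: large ⊃ middle ⊃ small; middle is suppressed but still
        # suppresses small
        large = mk("l", {0, 1, 2, 3}, {(0, 1), (1, 2), (2, 3)})
        middle = mk("m", {0, 1, 2}, {(0, 1), (1, 2)})
        small = mk("s", {0, 1}, {(0, 1)})
        out = resolve_overshadowing([large, middle, small], EMPTY)
        by_id = {m.pattern_id: m for m in out}
        assert by_id["m"].suppression != "none"
        assert set(by_id["s"].suppressed_by) == {"l", "m"}

    def test_pure_function_leaves_input_untouched(self):
        a = mk("a", {0, 1, 2}, {(0, 1), (1, 2)})
        b = mk("b", {0, 1}, {(0, 1)})
        resolve_overshadowing([a, b], EMPTY)
        assert b.suppression == "none" and b.suppressed_by == []

    @given(st.lists(
        st.tuples(
            st.sampled_from("abcdef"),
            st.sets(st.integers(0, 7), min_size=1, max_size=6),
        ),
        min_size=0, max_size=8,
    ))
    def test_partition_and_acyclicity(self, specs):
        """Visible + suppressed is always a partition; the overshadowing
        relation never contains a cycle."""
        matches = []
        for pid, atoms in specs:
            atoms = frozenset(atoms)
            ordered = sorted(atoms)
            bonds = frozenset(zip(ordered, ordered[1:]))
            matches.append(PatternMatch(pid, atoms, bonds, molecule_key="m"))
        from molannotate.matching import dedupe_matches
        matches = dedupe_matches(matches)
        out = resolve_overshadowing(matches, EMPTY)
        assert len(out) == len(matches)
        visible = [m for m in out if m.suppression == "none"]
        suppressed = [m for m in out if m.suppression != "none"]
        assert len(visible) + len(suppressed) == len(out)
        assert all(m.suppressed_by for m in suppressed)
        assert all(not m.suppressed_by for m in visible)
        dg = nx.DiGraph()
        for i, b in enumerate(out):
            for j, a in enumerate(out):
                if i != j and match_overshadows(a, b, EMPTY)[0]:
                    dg.add_edge(j, i)
        assert nx.is_directed_acyclic_graph(dg)


class TestAnnotate:
    def test_formic_acid_shows_only_the_acid(self, seed_collection, hierarchy):
        record = MoleculeRecord.from_smiles("OC=O", name="formic acid")
        result = annotate_molecule(record, seed_collection, hierarchy)
        visible = {seed_collection.get(m.pattern_id).name for m in result.visible}
        assert visible == {"carboxylic acid"}
        suppressed = {seed_collection.get(m.pattern_id).name: m.suppression
                      for m in result.suppressed}
        assert suppressed == {"hydroxy": "match_containment",
                              "carbonyl": "match_containment"}

    def test_methane_has_zero_matches(self, seed_collection, hierarchy):
        record = MoleculeRecord.from_smiles("C", name="methane")
        result = annotate_molecule(record, seed_collection, hierarchy)
        assert result.matches == []

    def test_trifluoromethylbenzene_hides_trihalide(self, seed_collection):
        from molannotate.hierarchy import build_hierarchy
        trio = seed_collection.subset(["trifluoromethyl", "trihalide", "benzene"])
        graph = build_hierarchy(trio)
        record = MoleculeRecord.from_smiles("FC(F)(F)c1ccccc1")
        result = annotate_molecule(record, trio, graph)
        states = {trio.get(m.pattern_id).name: m.suppression for m in result.matches}
        assert states == {"trifluoromethyl": "none", "benzene": "none",
                          "trihalide": "hierarchy"}

    def test_unparseable_molecule_yields_error_result(self, seed_collection, hierarchy):
        record = MoleculeRecord.from_smiles("this-is-not-smiles")
        result = annotate_molecule(record, seed_collection, hierarchy)
        assert result.error and result.matches == []
        assert result.molecule_name == "No Name"

    def test_monotonicity_of_visibility_under_pattern_removal(
            self, seed_collection, hierarchy):
        """Dropping a pattern never suppresses a previously visible match of a
        different pattern."""
        from molannotate.hierarchy import build_hierarchy
        from molannotate.patterns import PatternCollection
        record = MoleculeRecord.from_smiles("CN1C=NC2=C1C(=O)N(C(=O)N2C)C",
                                            name="caffeine")
        base = annotate_molecule(record, seed_collection, hierarchy)
        base_visible = {(m.pattern_id, m.atom_indices, m.bonds)
                        for m in base.visible}
        involved = {m.pattern_id for m in base.matches}
        for drop in involved:
            reduced = PatternCollection(
                [p for p in seed_collection if p.id != drop])
            result = annotate_molecule(record, reduced, build_hierarchy(reduced))
            still_visible = {(m.pattern_id, m.atom_indices, m.bonds)
                             for m in result.visible}
            expected = {v for v in base_visible if v[0] != drop}
            assert expected <= still_visible
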