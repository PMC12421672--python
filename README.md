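# molannotate

Named-substructure annotation of small molecules.

Communicating about organic structures across disciplines is hard: the IUPAC
name of caffeine (1,3,7-trimethylpurine-2,6-dione) tells a non-chemist nothing
about which part of the molecule is an imidazole ring or whether a uracil
substructure is hiding inside. `molannotate` matches a collection of *named*
SMARTS patterns — functional groups, ring systems, biologically relevant
motifs — against input molecules, and then decides which of the (typically
many, heavily overlapping) matches are worth showing.

It is a library plus a small CLI, aimed at cheminformaticians who want to
annotate molecules in batch, and at tool builders who need a "what do I call
this substructure?" backend.

## The core idea: overshadowing

All matches of all patterns are enumerated (RDKit substructure search with a
cheap signature prefilter), deduplicated, and then resolved against each other.
A match **A overshadows** match **B** when:

- **containment** — atoms(B) ⊂ atoms(A) and bonds(B) ⊆ bonds(A): the purine
  ring in caffeine hides its pyrimidine and imidazole constituents;
- **fewer bonds** — atoms(B) = atoms(A) and |bonds(B)| < |bonds(A)|: the
  cyclononane perimeter of hydrindane loses against the bicycle, which spans
  the same nine atoms with ten bonds instead of nine;
- **hierarchy** — atoms(B) = atoms(A), equal bond counts, and B's pattern
  *subsumes* A's pattern (every structure matched by A's pattern is matched by
  B's): a trifluoromethyl group is formally also a trihalide, but nobody calls
  it that, so the trihalide match is hidden.

Matches covering different atoms never hide one another. Visible = not
overshadowed; overshadowed matches stay available on request.

The hierarchy rule needs a SMARTS subsumption test. `molannotate` ships a
restricted engine that normalizes atom/bond expressions over a finite feature
space (element, aromaticity, formal charge, H count, degree, ring membership)
and searches for an expression-wise monomorphism between pattern graphs. It is
sound but deliberately incomplete: expressions it cannot represent (recursive
environments, ring counts, ...) compare by exact text only, and undecided
pairs simply get no edge — a less specific match may then stay visible, but a
match is never wrongly hidden.

## Pattern mining

`molannotate` also implements the pipeline that builds cyclic-pattern
collections from a (name, SMILES) table such as a chemical-database name dump:
keep molecules that *are* pure ring systems (every atom/bond in a ring, plus
exocyclic double bonds to terminal O/S), drop radicals, isotope-labelled
entries, mixtures and molecules with more than 100 heavy atoms, drop names
with more than four numbers, `yl` suffixes or `CID` prefixes, then emit one
substitution-tolerant SMARTS per distinct ring system. The generated pattern
constrains element, aromaticity and charge but no hydrogen counts, so the
xanthine scaffold extracted from xanthine itself still matches N-methylated
caffeine.

## Worked example

```bash
molannotate export-seed --output seed.json
molannotate annotate --smiles "CN1C=NC2=C1C(=O)N(C(=O)N2C)C caffeine" --patterns seed.json
```

```json
{
  "molecules": [
    {
      "name": "caffeine",
      "smiles": "Cn1c(=O)c2c(ncn2C)n(C)c1=O",
      "error": null,
      "matches": [
        {
          "pattern_id": "cyc-xanthine",
          "pattern_name": "xanthine",
          "category": "cyclic",
          "atom_indices": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11],
          "...": "..."
        }
      ]
    }
  ]
}
```

Only the xanthine scaffold is shown: the purine, pyrimidine, imidazole and
uracil matches it contains, and the two carbonyls, are all overshadowed.
Re-running with `--include-overshadowed` lists them with their suppression
reason and the ids of the matches that hide them. On trifluoromethylbenzene
the same command reports:

```json
[
  {"pattern_name": "trifluoromethyl", "overshadowed": false, "suppression_reason": "none"},
  {"pattern_name": "trihalide",       "overshadowed": true,  "suppression_reason": "hierarchy"},
  {"pattern_name": "benzene",         "overshadowed": false, "suppression_reason": "none"}
]
```

Other commands: `build-cyclic` (mine patterns from a name/SMILES TSV),
`build-hierarchy` (precompute subsumption edges), `validate` (check a pattern
file), `export-seed` (write the bundled ~70-pattern seed collection).

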