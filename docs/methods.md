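# Methods

This note documents the models and procedures implemented in `molannotate`,
the parameters that matter, the numerical/design choices made where the design
was genuinely open, and the known limitations.

## Pattern model

A pattern is `(id, smarts, name, category)` with category one of
`functional_group`, `cyclic`, `biological`. Atom and bond counts are derived
from the parsed SMARTS graph, never stored independently. Collections are
ordered (file order) and ids are unique; names may repeat across SMARTS.
Files are JSON (array of objects) or a strict three-column TSV
(`smarts  name  category`, UTF-8, no quoting; tabs inside fields are a
validation error — bit-exact simplicity was preferred over a quoting dialect).
Ids absent from a file are auto-generated as zero-padded ordinal + name slug.

## Prefilter signatures

For each pattern a sound lower bound is computed: minimum heavy atoms (= atom
count), per-element minimum counts, minimum ring atoms, minimum aromatic
atoms. An atom expression contributes an element requirement only when every
disjunct forces the same single element; halogen lists and opaque expressions
(recursive environments) contribute to the heavy-atom minimum only. Ring/
aromatic minima come from atoms whose expression admits no non-ring /
non-aromatic assignment in the feature space (below). The molecule side counts
heavy atoms, an element histogram, ring atoms, aromatic atoms and SSSR ring
count; the pattern side deliberately never uses a ring *count* requirement, to
stay clear of SSSR ambiguity. The prefilter is an optimization with no
semantic effect, which the suite asserts by equality of prefiltered and
exhaustive runs and by verifying every skipped (pattern, molecule) pair has
zero matches.

## Matching

All embeddings of each pattern are enumerated (`uniquify=False`), converted to
molecule atom-index sets plus the induced bond set, and deduplicated on
`(pattern id, atom set, bond set)`, so automorphic embeddings collapse while
repeated occurrences at different locations are kept (a pattern matching twice
is reported twice). Match order is deterministic: collection order, then the
lexicographically smallest sorted atom tuple. Compiled queries and signatures
are cached per pattern id for multi-molecule runs. Input molecules are
sanitized with aromaticity perception; molecules failing to parse become
error-carrying records and never abort a batch. Stereochemistry is ignored
(no shipped pattern encodes it).

## Subsumption engine

The hierarchy needs to decide "every match of S is also a match of G". The
engine normalizes each SMARTS atom expression into the set of feature tuples
it accepts over a finite space: element ∈ {H,B,C,N,O,F,Si,P,S,Cl,Br,I},
aromatic ∈ {0,1}, formal charge ∈ [−2,+2], total H ∈ [0,4], heavy degree ∈
[0,6], in-ring ∈ {0,1}, with aromatic ⇒ in-ring and in-ring ⇒ degree ≥ 2.
Acceptance is evaluated *empirically*: a probe atom with exactly those
features is materialized and the RDKit query is matched against it, so the
supported primitives stay in exact sync with the production matcher. Bond
expressions are handled the same way over order × ring membership.

Expressions using anything beyond a whitelisted set of query primitives —
recursive environments, isotopes, ring counts/sizes, valence, elements outside
the supported set, or constraints outside the modeled ranges — are *opaque*
and compare by exact text only. Pattern-level subsumption searches for an
injective, adjacency-preserving mapping of the general pattern graph into the
specific one with expression subsumption on every mapped atom and bond
(backtracking with most-constrained-first ordering; patterns are small, ≤ ~25
atoms). The answer is tri-state: `yes` only with an explicit witness mapping,
`unknown` when the only surviving mappings rely on opaque comparisons, `no`
otherwise. `yes` is sound; completeness is explicitly not claimed. Unknown
pairs get no hierarchy edge, which can only leave an extra match visible,
never hide one wrongly (fail-visible). Mutually subsuming patterns are merged
into logged equivalence classes, keeping the graph acyclic; when equivalent
patterns match the same atoms neither is suppressed and a warning is logged.

Caveat: the degree feature models heavy-atom neighbours; molecules carrying
*explicit* hydrogen atoms (rare outside processed SDF) can make `D`-style
constraints behave differently than modeled. The empirical corpus audit
(`corpus_subsumption_audit`) exists precisely to catch any such drift: for
every edge and molecule, every match of the specific pattern must contain a
match of the general one.

## Overshadowing

Rules, evaluated per ordered match pair of one molecule:

1. equal atom sets, fewer bonds in B → B overshadowed (`fewer_bonds`);
2. equal atom sets, equal bond counts, B's pattern subsumes A's → B
   overshadowed (`hierarchy`);
3. atoms(B) ⊂ atoms(A) and bonds(B) ⊆ bonds(A) → B overshadowed
   (`match_containment`);
4. otherwise, in particular whenever the atom sets differ without containment,
   no overshadowing.

The equal-atom case is checked before containment so that a perimeter-vs-
bicycle situation is reported as `fewer_bonds` (its bonds happen to also be a
subset). Suppression is computed declaratively against all matches, not
re-evaluated transitively after hiding: a match overshadowed only by an
itself-overshadowed match stays suppressed. This keeps the operation a pure,
order-independent function and guarantees visible + suppressed partitions the
match list. The hierarchy rule is restricted to same-atom-set, equal-bond-count
pairs; broader readings (hiding across different locations) were rejected as
clearly unintended.

## Cyclic-pattern extraction

Pipeline per record: parse → structure filters (first failing rule in the
fixed order mixture, radical, isotope, > 100 heavy atoms) → ring-system test →
name filters (in order: `CID` prefix, `yl` suffix, more than four numbers) →
pattern construction → dedup by canonical SMILES of the source molecule.
Decisions of note, where the procedure was open:

- *Ring system* means the whole molecule qualifies (every atom/bond in a ring,
  or a terminal O/S double-bonded to a ring atom); ring systems are not
  excised from larger molecules. The selection-vs-excision question is
  genuinely ambiguous; whole-molecule selection is the simpler reading and is
  what this package implements.
- A *number* in a name is one maximal run of digits, so
  "1,2,3,4-tetrahydroquinazoline" has four numbers and is kept, while
  five-locant lists are dropped. Name checks are case-sensitive.
- Empty or whitespace-only names are rejected (`unparseable`): they cannot
  serve communication.
- Charged ring systems are retained — quaternary aromatic nitrogens occur in
  common named cations (pyridinium).
- Pattern construction constrains atomic number, aromaticity and formal charge
  per atom and order/aromaticity per bond, imposes no H-count or degree
  constraints on ring atoms (so substituted cycles match), and forces degree 1
  on the exocyclic terminal O/S (so cyclohexanone does not match
  cyclohexanol). Every emitted pattern matches its own source molecule over
  all atoms (asserted).
- Duplicate structures keep the shortest passing name, then lexicographic —
  trivial names are typically the shortest synonyms.

The pass/fail partition is independent of rule order; only reason codes depend
on it (asserted in the suite).

## Seed collection and toy corpus

The seed collection (71 patterns) is written fresh: 23 hand-written functional
groups (azo and aldehyde as two-atom patterns whose carbon environment is
demanded through recursive SMARTS but not matched), 36 cyclic patterns derived
from reference SMILES via the extraction construction, and 12 biological
patterns (nucleobases, sugars, amino acids, catecholamine, plus toluene/cresol
as trivial names with an explicit `[CX4H3]` methyl). The carboxylic-acid
pattern uses the conventional `[CX3](=[OX1])[OX2H1]` and a separate
carboxylate; hydroxy is plain `[OX2H]`, chosen so that the intended
hydroxy → carboxylic-acid subsumption actually holds.

The toy corpus is fully programmatic: 73 fixed molecules (7 worked examples
exercising every overshadowing rule, the cyclic/biological source molecules,
and one exemplar per functional group, so that every seed pattern has at least
one matching and one non-matching molecule) plus a seeded stream of randomized
molecules from a scaffold + substituent grammar (8 ring scaffolds × ~14 × ~10
substituents at up to two sites). The default study corpus is 200 molecules.
Expected visible names for each entry are recorded at corpus construction by
running the pipeline itself; for the worked examples the suite additionally
asserts hand-derived outcomes. The corpus emulates drug-like substitution
chemistry on common scaffolds; it contains no stereochemistry, no exotic
elements, no explicit-hydrogen records and no very large molecules, so passing
tests demonstrate engine correctness on this class of inputs, not coverage of
every SMARTS idiom found in the wild.

## Sizes and tolerances

All checks are exact (counts and set equalities); there are no numeric
tolerances. Problem sizes used by the suite and the acceptance script: 200
corpus molecules, 71 seed patterns (≈ 5 000 ordered pattern pairs for the
hierarchy), a 30-row extraction fixture. A full acceptance run takes a few
seconds on one CPU; the subsumption feature space holds ~5 000 atom probes and
is cached per unique atom-expression text.

## Known limitations

- Subsumption is incomplete by design; e.g. no edge is derived between the
  recursive azo/aldehyde patterns and anything else, and builder-generated
  ring atoms (which carry an explicit charge-0 constraint) are not subsumed by
  hand-written atoms without a charge constraint. Consequences are only ever
  extra visible matches.
- The trivial-name choice among synonyms of one structure is a heuristic
  (shortest name); no synonym ranking is attempted.
- No stereochemistry-aware matching; no IUPAC name construction; no attempt
  to reproduce any full-scale database-derived pattern collection.
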