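# Methods

## The representation

A molecule is modelled as a labelled graph: atoms carry element, formal
charge, isotope, and implicit-hydrogen count; bonds carry one of four
orders (single, double, triple, aromatic). Parsing (SMILES, SDF/MOL V2000,
InChI) and canonicalization are delegated to RDKit; everything the package
contributes — the identifier grammar, the fragment vocabulary, the triple
encoding, and the query semantics — sits on top of that parsed graph.

The scope is deliberately the scope of standard InChI: single covalently
bonded units. Multi-component inputs (salts, mixtures) are rejected rather
than heuristically split, because splitting silently changes which entity
an identifier names. Polymers with arbitrary repeat units and Markush
structures are out of scope for the same reason — they have no standard
InChI. Electrons and subatomic particles are not modelled.

## Canonical numbering

The standard InChI algorithm yields, besides the InChI string and key, a
canonical ordering of the heavy atoms (read from the auxiliary-info `/N:`
layer, whose entries are 1-based original indices in canonical order,
counting every input atom including explicit hydrogens). Two refinements
are needed to make identifiers *byte-stable* under input reordering:

1. **InChI-equivalent positions.** InChI's mobile-hydrogen normalization
   treats e.g. the two carboxyl oxygens as a single equivalence class (the
   `/E:` auxiliary layer) and assigns their canonical indices arbitrarily
   with respect to input order. Within each such class, atoms are
   re-assigned to the sorted positions by RDKit canonical rank (computed
   with ties unbroken), which does distinguish bond-order-distinct atoms
   such as C=O vs C–OH. For genuinely automorphic atoms the ranks tie and
   the assignment remains arbitrary — harmless, because any assignment is
   related to any other by a graph automorphism, so the *set* of minted
   identifiers is unchanged.

2. **Hydrogens.** InChI numbers heavy atoms only. Hydrogens get derived
   indices `n_heavy + k`, ranked by the canonical index of their attached
   heavy atom, with input order breaking ties among the (symmetry
   equivalent) hydrogens of one heavy atom. This places hydrogen indices
   beyond the heavy range, so a hydroxyl bond reads e.g. `-BOH39`
   (oxygen 3, hydrogen 9 in ethanol). The convention is this package's
   own; no community standard exists for hydrogen numbering.

## Hashing

Descriptor, configuration, fragment, and reaction identifiers are 40-hex
SHA-1 digests. Hash inputs are joined with the ASCII unit separator
(`0x1f`), with absent optional parts as empty strings, so part boundaries
can never be confused (`("ab","c")` ≠ `("a","bc")`). Numeric values enter
the hash exactly as their source strings — `"1.50"` is not normalized to
`"1.5"` — trading cross-source value unification for bit-level
reproducibility, which is the right trade for identifiers. Composite
descriptors hash the lexicographically sorted full local names of their
components (this transitively covers component values, units, uncertainty,
and configuration). Reactions hash role-tagged participants with their
stoichiometric coefficients, sorted within each role, so participant order
is irrelevant while stoichiometry is significant.

## Fragment vocabulary

For each heavy atom and each depth d ∈ {1, 2, 3} (configurable), the
fragment is the subgraph induced by all heavy atoms within d bonds of the
center, hydrogen-suppressed. This reading of "first, second, and third
neighbours" reproduces the canonical worked example: the oxygen of
n-propanol yields the graphs CO, CCO, CCCO. Fragments whose member sets
coincide are collapsed to one record (the representative with the smallest
(depth, center) is kept; the identifier depends only on structure, members
and molecule, so the choice of representative is cosmetic).

The fragment *class key* is the canonical SMILES of the induced subgraph,
computed on a standalone copy of that subgraph — canonicalizing a fragment
in the context of its parent (RDKit's `MolFragmentToSmiles`) turned out
not to be permutation-stable for some fragments. Bond orders are retained
in the class key, so an alcohol CCO class is distinct from an aldehyde
CC=O class; reaction matching depends on that distinction. Partial
aromatic fragments (e.g. an open `ccc` path) cannot be kekulized
standalone; sanitization falls back to keeping aromatic flags as-is, which
preserves determinism and cross-parent consistency.

## Triple encoding

Molecules are typed both as molecular entities and molecules; atoms to
element classes; bond entities to order-specific classes; fragments to a
generic organic-group class plus their structure class. Mereology uses a
single *has proper part* relation: molecule → atoms/bonds/fragments,
bond → endpoint atoms, fragment → member atoms. Bonds are encoded two
complementary ways, both on by default: as first-class entities (required
for attaching bond-level descriptors such as dissociation enthalpies) and
as direct bidirectional atom–atom predicates per order (what makes graph
pattern queries tractable). Hydrogens are suppressed by default and
encoded on request — bond-level O–H annotations need them.

The vocabulary binding every concept to an IRI is data, not code
(`data/vocabulary.tsv`): term bindings in this domain are genuinely
unsettled, and several concepts are referred to inconsistently across
sources. Terms with well-known public identifiers (SIO parthood and
reaction relations, CHEBI entity and element classes, CHEMINF descriptor
and provenance classes, UO units) carry those; terms that exist only by
name are minted in the CHESS namespace rather than given invented numeric
IDs that would collide with real ontology terms.

Serialization: Turtle for readability (round-trip tested), N-Triples
written as sorted lines for byte-identical diffable output. Loading takes
the set union of all input files; identical URIs merge, which is the
integration mechanism.

## Descriptors, configurations, provenance

Invariant descriptors (constitution-only, e.g. heavy-atom count) carry
value/uncertainty/unit. Variable descriptors additionally reference a
*chemical configuration* — the order-independent bundle of conditions
under which the value holds (data provider, temperature, geometry,
electronic state, ...). Computational provenance follows the
algorithm / parameterized-execution / software-agent pattern; experimental
provenance reuses the same structure with an observation process in place
of the execution.

One modelling decision deserves a note: bond-dissociation-enthalpy
annotations arrive with provenance (method, software, parameters) but no
explicit configuration. Since the computational context *is* the set of
conditions determining the value, `make_bde_annotation` derives the
configuration from that context. This keeps the invariant "every variable
descriptor traces to exactly one configuration" intact and makes two
identical values computed by different methods distinct entities, which is
chemically correct.

## Query semantics

Substructure matching is subgraph **monomorphism**: an injective embedding
of the pattern, enforced by pairwise inequality constraints over all atom
variables (not just the single pair the minimal two-atom example needs).
Induced-subgraph matching would wrongly reject an ethyl pattern inside
propane. The generated SPARQL is standard 1.1 text for use against any
external endpoint. In-process execution uses an order-aware backtracking
join over the same rdflib store — rdflib's own SPARQL engine statically
reorders triple patterns by bound-term count, which cross-joins all the
1-variable type patterns first and made even two-atom queries quadratic in
store size (~40 s on a 7k-triple store). The evaluator anchors on the
rarest element class, expands bond predicates breadth-first, types each
atom the moment it is bound, and prunes injectivity violations
incrementally; all eight benchmark patterns over a 50-molecule store run
in milliseconds and agree exactly with an independent VF2 oracle.

Similarity scores count *distinct shared fragment classes* (not instances)
between query and candidate, descending, ties broken by URI lexicographic
order; molecules sharing nothing score 0 and rank last. The Rule-of-Five
filter is evaluated closed-world over loaded descriptors: a molecule
passes only with a witness descriptor for each criterion, with strict
bounds on mass (< 500) and logP (−5 < x < 5) and inclusive bounds on
acceptor (≤ 10) and donor (≤ 5) counts. The BDE window screen combines
structure (a phenol-class fragment, an O–H single bond) with
method/unit-filtered descriptor values strictly inside the window; the
default window (67, 78) kcal/mol brackets biologically useful phenolic
antioxidants between ascorbate's weakest O–H and α-tocopherol's.

Reaction matching requires every class-level input group of a reaction to
be instantiated by a fragment of the candidate molecule, and every
atom-level input to be matched by an element-compatible atom inside such a
fragment; instance bindings are reported. Atom-level class typing (typing
a molecule's atoms to the class-atom nodes of their fragment's class) is
optional at encoding time and is what enables atom-history tracing through
chains of *transforms into* edges. Mapping instance atoms onto class atoms
uses an RDKit substructure match of the class graph onto the fragment
subgraph; class keys that are not standalone-parseable SMILES are skipped.

DL-safe rule output is emission-only — the rule text mirrors the
graph-pattern body (typing, parthood, bond, distinctness literals) with
the target class in the head; no reasoner is run or integrated.

## Synthetic fixtures

The fixture generator supplies the study corpus: small organic molecules
in five families (alkanes, alcohols, phenols, fatty-like chains, ring
systems), always including the four worked-example molecules (ethanol,
n-propanol, phenol, acetaldehyde), extended deterministically with longer
chains when more molecules are requested than the curated pools hold.
Everything is seeded and byte-reproducible. Annotation plans attach
synthetic descriptors: `lipinski-boundary` places values exactly at and
on either side of every Rule-of-Five threshold (including a
missing-descriptor case); `bde` assigns O–H dissociation enthalpies —
ethanol at 104.5 kcal/mol and phenols cycling through 72, 67, 78, 74.5,
70.1 so the strict window edges are exercised; `coordinates` attaches
provider-tagged synthetic 3D coordinates.

What the fixtures do *not* emulate: real descriptor values (the numbers
are constructed to probe boundary semantics, not to be chemically
accurate), stereochemistry, tautomer ensembles, charged drug-like
molecules, or database-scale corpora (the default acceptance corpus is 50
molecules; the design has no intrinsic limit, but nothing here speaks to
engine performance at millions of molecules). Passing tests therefore
demonstrate representational correctness and query semantics, not
large-scale retrieval performance or the accuracy of any property value.

## Problem sizes and numerical choices

The standard verification run uses: 100 random atom-order permutations of
each of 20 corpus molecules for identifier stability; 8 query patterns
(ethyl–pentyl chains, cyclopentene, hydroxyl, carbonyl, benzene) over a
50-molecule knowledgebase for oracle equivalence; a 14-molecule boundary
corpus for the Rule-of-Five filter; 6 annotated O–H bonds for the BDE
window. Floating-point comparison enters only at query filters, where
descriptor strings are parsed with `float()`; values are otherwise carried
as strings end to end, so no tolerance machinery is needed — equality is
string equality.

## Known limitations

- Hydrogen numbering is a package convention, not a community standard;
  graphs produced by other tools may number hydrogens differently even if
  they adopt the same heavy-atom scheme.
- InChI-key-level identity inherits InChI's normalizations: tautomers that
  standard InChI merges receive one molecule URI.
- Fragment class keys for partial aromatic subgraphs depend on RDKit's
  aromatic-SMILES writing for unkekulizable fragments; they are stable
  within this toolkit but not guaranteed to match another toolkit's
  canonical form.
- The closed-world Rule-of-Five filter can only see loaded descriptors; an
  open-world reasoner would treat missing values as unknown rather than
  failing. This is a deliberate divergence: a query-based filter needs
  witnesses.
- `reconstitute_graph` recovers the heavy-atom (or explicit-hydrogen)
  skeleton with elements, charges, isotopes and bond orders; implicit
  hydrogen counts are left to valence rules on re-parse.
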