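# chesskit

Semantic chemical entity specification: canonical, database-independent RDF
identifiers and encodings for molecules and all their parts — atoms, bonds,
functional-group fragments, descriptors, configurations, and reactions —
plus the query toolkit that runs against the emitted triple graphs.

## Who this is for

Cheminformatics and drug-discovery groups that need to *integrate* chemical
records across databases and studies. The chronic obstacle is identity:
every repository mints its own sequential IDs, so pooling a melitracene
record from one database with descriptors computed elsewhere needs manual
cross-walking. chesskit removes that step by deriving every identifier from
the chemistry itself, so independently produced RDF graphs collapse into
one knowledgebase the moment they are loaded together.

## The identifier scheme

All identifiers hang off the molecule's IUPAC InChI key and the canonical
atom numbering produced by the standard InChI algorithm (invariant to input
atom order). With base IRI `chess:` (configurable):

| entity        | local name                                  | ethanol example |
|---------------|---------------------------------------------|-----------------|
| molecule      | `INCHIKEY`                                  | `LFQSCWFLJHTTHZ-UHFFFAOYSA-N` |
| atom          | `INCHIKEY-A<element><index>`                | `...-AO3` (the oxygen, canonical index 3) |
| bond          | `INCHIKEY-B<el1><el2><i1><i2>` (ascending)  | `...-BCO23` (the C–O bond) |
| fragment      | `INCHIKEY-FG<sha1>`                         | hash of (structure, member indices, molecule) |
| descriptor    | `<ownerlocal>-D<sha1>`                      | hash of (value, uncertainty, unit[, configuration]) |
| configuration | `CC<sha1>`                                  | hash of sorted `key=value` condition annotations |
| reaction      | `RX<sha1>`                                  | hash of role-tagged participants × stoichiometry |

Hashes are 40-hex SHA-1 digests over unit-separator-joined parts; values are
hashed in their source lexical form, so identifiers reproduce byte-for-byte
on any platform. Hydrogens (outside InChI's numbering) receive derived
indices `n_heavy + k`, ordered by their heavy atom's canonical index.

Each molecule is additionally described by its **atom-centered fragment
vocabulary**: for every heavy atom, the hydrogen-suppressed subgraphs
induced by all heavy atoms within 1, 2, and 3 bonds. For n-propanol's
oxygen these are the graphs `CO`, `CCO`, `CCCO`. Fragments with isomorphic
structure share a *class*, which powers fingerprint-style similarity
ranking and generic reaction matching.

Queries provided over a loaded knowledgebase: substructure search (subgraph
monomorphism, with generated SPARQL for external endpoints and an
order-aware in-process evaluator), similarity ranking by shared fragment
classes, provenance-filtered descriptor retrieval, Lipinski Rule-of-Five
filtering (mass < 500 strict, H-bond acceptors ≤ 10 and donors ≤ 5
inclusive, logP strictly in (−5, 5)), bond-dissociation-enthalpy window
screens for phenolic antioxidants, reaction-candidate matching, and
atom-history tracing through *transforms into* mappings.

## Worked example

```python
import chesskit as ck

mol = ck.parse_molecule("CCO")
numbering = ck.canonical_numbering(mol)
print(ck.molecule_uri(numbering))
print(ck.atom_uri(numbering, 3))
print(ck.bond_uri(numbering, 2, 3))
```

prints

```
http://semanticscience.org/resource/CHESS_LFQSCWFLJHTTHZ-UHFFFAOYSA-N
http://semanticscience.org/resource/CHESS_LFQSCWFLJHTTHZ-UHFFFAOYSA-N-AO3
http://semanticscience.org/resource/CHESS_LFQSCWFLJHTTHZ-UHFFFAOYSA-N-BCO23
```

— the molecule named by its InChI key, its oxygen atom, and its C–O bond.
Any SMILES/SDF/InChI input describing ethanol yields these same three URIs.

Integration in action (`examples/lipinski_filter.py`): two graphs for
melitracene, one carrying mass + acceptor count, the other donor count +
logP, are written to disk and loaded together:

```
molecule: GWWLWDURRGNSRS-UHFFFAOYSA-N
passes from graph A alone: 0
passes from graph B alone: 0
passes after merging: 1
```

Neither source alone has witnesses for all four Rule-of-Five criteria; the
merged graph does — with zero cross-walking, because both graphs name the
molecule identically.

Each script in `examples/` demonstrates one capability end to end:
encoding/reconstitution, substructure search vs. a brute-force oracle,
similarity ranking, descriptor provenance, the Rule-of-Five filter, the
antioxidant BDE window, and reaction matching with atom tracing.

A thin CLI wraps the same library surface:

```bash
chesskit fixtures --n 10 --seed 1 --plan bde -o kb.ttl
chesskit search kb.ttl --pattern CC
chesskit bde-window kb.ttl --low 67 --high 78
chesskit validate kb.ttl
```

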