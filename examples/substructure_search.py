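"""Substructure search over an encoded knowledgebase.

A search pattern is a small element/bond-order labelled graph; matching is
subgraph monomorphism (injective embedding), executed against the triple
store and cross-checked here against an independent VF2 matcher.
"""

import chesskit as ck

fixtures = ck.generate_fixtures(ck.FixtureSpec(n_molecules=15, seed=1))
kb = ck.build_knowledgebase(fixtures)
print(f"knowledgebase: {len(fixtures.molecules)} molecules, "
      f"{len(kb)} triples")

ethyl = ck.QueryGraph.chain(2)          # two single-bonded carbons
hydroxyl = ck.QueryGraph(nodes=[("a0", "C"), ("a1", "O")],
                         edges=[("a0", "a1", "single")])

print("\ngenerated SPARQL for the ethyl pattern:\n")
print(ck.substructure_query(ethyl))

molecules = []
for smi in fixtures.molecules.smiles:
    mol = ck.parse_molecule(smi)
    num = ck.canonical_numbering(mol)
    molecules.append((ck.molecule_uri(num).iri, mol))

for name, q in (("ethyl", ethyl), ("hydroxyl", hydroxyl)):
    hits = ck.run_substructure_search(kb, q)
    oracle = ck.brute_force_substructure_search(molecules, q)
    print(f"{name}: {len(hits)} molecules match; "
          f"agrees with brute-force oracle: {hits == oracle}")
# Counts are molecules containing at least one injective embedding of the
# pattern; the store search and the graph-theoretic oracle must coincide.
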