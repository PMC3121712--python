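"""Generic reaction definition, candidate matching, and atom tracing.

The primary-alcohol -> aldehyde oxidation is defined at the class level:
input group class CCO, product group class CC=O, with the oxygen mapped
across via *transforms into*. Any molecule whose fragment vocabulary
instantiates the input classes is a candidate, and mapped atoms can be
traced through chains of reactions.
"""

import chesskit as ck

fixtures = ck.generate_fixtures(ck.FixtureSpec(n_molecules=8, seed=1))
kb = ck.build_knowledgebase(fixtures, include_reaction=True)

reaction = ck.alcohol_oxidation_reaction()
print("reaction:", reaction.uri.local)

for smiles in ("CCO", "CCCO", "C"):
    num = ck.canonical_numbering(ck.parse_molecule(smiles))
    rows = ck.reaction_candidates(kb, ck.molecule_uri(num))
    print(f"\n{smiles}: {len(rows)} candidate reaction(s)")
    for row in rows:
        for required, bound in row["bindings"].items():
            print(f"   {required.rsplit('_', 1)[-1][:16]}... "
                  f"<- {bound.rsplit('_', 1)[-1]}")

# trace ethanol's oxygen through the transformation
num = ck.canonical_numbering(ck.parse_molecule("CCO"))
chain = ck.trace_atom(kb, ck.atom_uri(num, 3))
print("\nethanol oxygen history:")
for hop in chain:
    print(f"  {hop['source'].rsplit('_', 1)[-1]} -> "
          f"{hop['target'].rsplit('_', 1)[-1]}")
# Ethanol and n-propanol both carry a CCO-class fragment, so both match (the
# fragment and its oxygen are bound); methane matches nothing. The trace
# shows the oxygen's class-level fate: alcohol oxygen -> aldehyde oxygen.
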