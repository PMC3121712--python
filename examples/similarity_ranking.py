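"""Fragment-class similarity ranking.

Each molecule is described by its atom-centered fragment classes (radius
1-3 heavy-atom subgraphs, fingerprint style). A query molecule is ranked
against the knowledgebase by the number of distinct fragment classes shared
— a size-normalizable similarity score; the query's own entry (if present)
is always tied-first.
"""

import chesskit as ck

fixtures = ck.generate_fixtures(ck.FixtureSpec(n_molecules=12, seed=1))
kb = ck.build_knowledgebase(fixtures)

query = ck.parse_molecule("CCO")  # ethanol
result = ck.similarity_rank(kb, query, limit=5)

print("top molecules by fragment classes shared with ethanol:")
for iri, score in result.ranking:
    print(f"  {score:2d}  {iri.rsplit('_', 1)[-1]}")
# The score is the count of shared fragment classes (ethanol itself has 3:
# CC, CO, CCO); other alcohols share CO/CCO, alkanes only CC, and molecules
# with no common class score 0.
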