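"""Bond-level annotation: screening phenolic antioxidants by O-H BDE.

A biologically promising phenolic antioxidant has an O-H bond dissociation
enthalpy above ascorbate's weakest O-H (67 kcal/mol, so the body can
recycle it) and below alpha-tocopherol's (78 kcal/mol, so it beats existing
defences). The query combines structure (a phenol group, an O-H single
bond) with a method- and unit-filtered descriptor window — strict at both
edges.
"""

import chesskit as ck

fixtures = ck.generate_fixtures(ck.FixtureSpec(
    n_molecules=9, seed=1, families=("phenols",), annotation_plan="bde"))
kb = ck.build_knowledgebase(fixtures)
print("annotations applied:")
for _, row in fixtures.annotations.iterrows():
    print(f"  {row.smiles:16s} O-H BDE {row.value} {row.unit} ({row.method})")

hits = ck.bde_window_search(kb, 67, 78, ck.chess_term("AM1"),
                            unit="kcal/mol")
print(f"\nphenols strictly inside (67, 78) kcal/mol: {len(hits)}")
for iri, value in hits:
    print(f"  {value:6.1f}  {iri.rsplit('_', 1)[-1]}")
# Ethanol's 104.5 is excluded twice over (no phenol group, out of window);
# phenols annotated exactly at 67 or 78 are excluded by the strict bounds.
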