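"""Descriptor annotation with configurations and provenance filtering.

Variable descriptors (coordinates, computed properties) are tied to a
*chemical configuration* — the bundle of conditions and data source under
which the value holds. Retrieval can filter on that context, so values from
different providers or conformers never mix.
"""

import chesskit as ck
from chesskit.annotations import ChemicalConfiguration

mol = ck.parse_molecule("CCO")
num = ck.canonical_numbering(mol)
g = ck.encode_molecule(mol, num)

oxygen = ck.atom_uri(num, 3)
for provider, (x, y, z) in {
        "http://pubchem.ncbi.nlm.nih.gov": ("1.55", "0.10", "-0.70"),
        "http://www.ebi.ac.uk/chembl": ("2.01", "-0.44", "0.12")}.items():
    config = ChemicalConfiguration({"provider": provider})
    coord = ck.make_coordinate_descriptor(x, y, z, ck.term("angstrom"), config)
    ck.attach_descriptor(g, oxygen, coord)

rows = ck.retrieve_descriptors(g, ck.molecule_uri(num),
                               ck.term("3D cartesian coordinate"),
                               provider="http://pubchem.ncbi.nlm.nih.gov")
print("coordinates from the PubChem-tagged configuration only:")
for row in rows:
    print(f"  atom {row['entity'].rsplit('-', 1)[-1]}: "
          f"x={row['x']} y={row['y']} z={row['z']}")
# Exactly one row, with x=1.55: the other conformer lives under a different
# configuration node and is excluded by the provider filter.
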