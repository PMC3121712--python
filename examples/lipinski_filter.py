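"""Rule-of-Five drug-likeness filtering over merged knowledge graphs.

Because identifiers are canonical, independently encoded graphs for the
same molecule collapse into one node on load — descriptors from different
databases pool automatically. The filter requires a witness descriptor for
all four criteria: mass < 500 (strict), H-bond acceptors <= 10 and donors
<= 5 (inclusive), logP strictly inside (-5, 5).
"""

import tempfile
from pathlib import Path

import chesskit as ck
from chesskit.annotations import ChemicalConfiguration

mol = ck.parse_molecule("CN(C)CCC=C1c2ccccc2C(C)(C)c2ccccc21")  # melitracene
num = ck.canonical_numbering(mol)
owner = ck.molecule_uri(num)
print("molecule:", owner.local)

# database A knows mass and acceptor count ...
g1 = ck.encode_molecule(mol, num)
ck.attach_descriptor(g1, owner, ck.make_invariant_descriptor(
    ck.term("mass descriptor"), "291.4", unit="dalton"))
ck.attach_descriptor(g1, owner, ck.make_invariant_descriptor(
    ck.term("hydrogen bond acceptor count"), "1"))
# ... database B knows donor count and logP
g2 = ck.encode_molecule(mol, num)
ck.attach_descriptor(g2, owner, ck.make_invariant_descriptor(
    ck.term("hydrogen bond donor count"), "0"))
ck.attach_descriptor(g2, owner, ck.make_variable_descriptor(
    ck.term("logP descriptor"), "4.5",
    ChemicalConfiguration({"provider": "chembl"})))

print("passes from graph A alone:", len(ck.lipinski_pass(g1)))
print("passes from graph B alone:", len(ck.lipinski_pass(g2)))

with tempfile.TemporaryDirectory() as tmp:
    ck.write_graph(g1, Path(tmp) / "a.ttl")
    ck.write_graph(g2, Path(tmp) / "b.ttl")
    merged = ck.load_knowledgebase([Path(tmp) / "a.ttl", Path(tmp) / "b.ttl"])
print("passes after merging:", len(ck.lipinski_pass(merged)))
# Neither source alone has all four witnesses (0 passes each); the merged
# graph does (1 pass) — the whole point of canonical identifiers.
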