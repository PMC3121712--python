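import hashlib
import random
import re
import subprocess
import sys

import pytest
from hypothesis import given, strategies as st

import chesskit as ck
from chesskit.annotations import ChemicalConfiguration
from chesskit.errors import DegenerateConfigurationError, NumberingError

from conftest import CORPUS, permute_graph

HEX40 = re.compile(r"^[0-9a-f]{40}$")


def test_ethanol_molecule_uri(ethanol):
    _, num = ethanol
    assert ck.molecule_uri(num).local == "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"
    assert ck.molecule_uri(num).iri.startswith(
        "http://semanticscience.org/resource/CHESS_")


def test_ethanol_atom_and_bond_uris(ethanol):
    _, num = ethanol
    assert ck.atom_uri(num, 3).local.endswith("-AO3")
    assert ck.bond_uri(num, 2, 3).local.endswith("-BCO23")
    # endpoint order never matters
    assert ck.bond_uri(num, 3, 2) == ck.bond_uri(num, 2, 3)


def test_atom_uris_pairwise_distinct(ethanol):
    _, num = ethanol
    uris = [ck.atom_uri(num, i).iri for i in sorted(num.elements)]
    assert len(set(uris)) == len(uris)


def test_atom_uri_same_under_input_reordering():
    a = ck.canonical_numbering(ck.parse_molecule("CCO"))
    b = ck.canonical_numbering(ck.parse_molecule("OCC"))
    o_a = next(i for i, e in a.elements.items() if e == "O")
    o_b = next(i for i, e in b.elements.items() if e == "O")
    assert ck.atom_uri(a, o_a) == ck.atom_uri(b, o_b)


def test_unknown_index_raises(ethanol):
    _, num = ethanol
    with pytest.raises(NumberingError):
        ck.atom_uri(num, 99)


def test_hydroxyl_bond_uri_prefix(ethanol):
    mol, _ = ethanol
    work = mol.with_explicit_hydrogens()
    num = ck.canonical_numbering(work)
    o_idx = next(ci for ci, e in num.elements.items() if e == "O")
    h_idx = max(num.hydrogen_map.values())  # hydroxyl H ranks last
    uri = ck.bond_uri(num, o_idx, h_idx)
    assert "-BOH" in uri.local


def test_fragment_uri_shape_and_permutation_stability():
    mol = ck.parse_molecule("CCO")
    num = ck.canonical_numbering(mol)
    frags = {f.members: f for f in ck.atom_centered_fragments(mol, num)}
    for frag in frags.values():
        suffix = frag.uri.local.split("-FG")[1]
        assert HEX40.match(suffix)
    shuffled, _ = permute_graph(mol, random.Random(3))
    num2 = ck.canonical_numbering(shuffled)
    frags2 = {f.members: f for f in ck.atom_centered_fragments(shuffled, num2)}
    assert {f.uri for f in frags.values()} == {f.uri for f in frags2.values()}


def test_distinct_fragments_distinct_uris(propanol):
    mol, num = propanol
    uris = [f.uri.iri for f in ck.atom_centered_fragments(mol, num)]
    assert len(set(uris)) == len(uris)


def test_configuration_uri_is_order_independent():
    a = ChemicalConfiguration({"provider": "http://pubchem.ncbi.nlm.nih.gov",
                               "temperature": "298"})
    b = ChemicalConfiguration({"temperature": "298",
                               "provider": "http://pubchem.ncbi.nlm.nih.gov"})
    assert ck.configuration_uri(a) == ck.configuration_uri(b)
    assert ck.configuration_uri(a).local.startswith("CC")
    assert HEX40.match(ck.configuration_uri(a).local[2:])


def test_configuration_uri_distinguishes_providers():
    a = ChemicalConfiguration({"provider": "http://pubchem.ncbi.nlm.nih.gov"})
    b = ChemicalConfiguration({"provider": "http://www.ebi.ac.uk/chembl"})
    assert ck.configuration_uri(a) != ck.configuration_uri(b)


def test_empty_configuration_rejected():
    with pytest.raises(DegenerateConfigurationError):
        ChemicalConfiguration({})


def test_invariant_descriptor_hash_shared_across_owners(ethanol, propanol):
    desc = ck.make_invariant_descriptor(ck.term("heavy atom count"), "3")
    owner_a = ck.molecule_uri(ethanol[1])
    owner_b = ck.molecule_uri(propanol[1])
    ua = ck.descriptor_uri(desc, owner_a)
    ub = ck.descriptor_uri(desc, owner_b)
    assert ua.local.split("-D")[-1] == ub.local.split("-D")[-1]
    assert ua != ub  # owners differ


def test_variable_descriptor_distinct_configurations(ethanol):
    owner = ck.molecule_uri(ethanol[1])
    c1 = ChemicalConfiguration({"provider": "a"})
    c2 = ChemicalConfiguration({"provider": "b"})
    d1 = ck.make_variable_descriptor(ck.term("logP descriptor"), "1.5", c1)
    d2 = ck.make_variable_descriptor(ck.term("logP descriptor"), "1.5", c2)
    assert ck.descriptor_uri(d1, owner) != ck.descriptor_uri(d2, owner)


def test_composite_descriptor_hash_matches_independent_recomputation(ethanol):
    """Oracle: re-derive the composite digest from scratch with hashlib."""
    owner = ck.atom_uri(ethanol[1], 3)
    config = ChemicalConfiguration(
        {"provider": "http://pubchem.ncbi.nlm.nih.gov"})
    comp = ck.make_coordinate_descriptor("1.55", "-0.20", "0.00",
                                         ck.term("angstrom"), config)
    got = ck.descriptor_uri(comp, owner).local.split("-D")[-1]

    component_locals = sorted(
        ck.descriptor_uri(c, owner).local for c in comp.components)
    expected = hashlib.sha1(
        "\x1f".join(component_locals).encode()).hexdigest()
    assert got == expected


def test_reaction_uri_invariances():
    rx = ck.alcohol_oxidation_reaction()
    assert rx.uri.local.startswith("RX")
    assert HEX40.match(rx.uri.local[2:])
    # reordering participants leaves the URI unchanged
    flipped = ck.ReactionSpec(inputs=list(reversed(rx.inputs)),
                              products=list(reversed(rx.products)),
                              agents=list(reversed(rx.agents)),
                              mappings=rx.mappings)
    assert flipped.uri == rx.uri
    # doubling a stoichiometric coefficient changes it
    doubled = ck.ReactionSpec(
        inputs=[ck.Participant(rx.inputs[0].ref, coefficient=2)],
        products=rx.products, agents=rx.agents)
    assert doubled.uri != rx.uri


def test_reaction_uri_stable_across_processes():
    expected = ck.alcohol_oxidation_reaction().uri.iri
    code = ("import chesskit as ck;"
            "print(ck.alcohol_oxidation_reaction().uri.iri)")
    out = subprocess.run([sys.executable, "-c", code], capture_output=True,
                         text=True, check=True)
    assert out.stdout.strip() == expected


def test_hash_parts_are_delimited():
    assert ck.sha1_hex(["ab", "c"]) != ck.sha1_hex(["a", "bc"])
    assert ck.sha1_hex(["x", None]) == ck.sha1_hex(["x", ""])


@given(st.lists(st.text(max_size=8), min_size=1, max_size=5))
def test_sha1_hex_shape(parts):
    digest = ck.sha1_hex(parts)
    assert HEX40.match(digest)
    assert digest == ck.sha1_hex(parts)


def test_no_uri_collisions_across_corpus():
    """Exhaustive pairwise injectivity over every entity of the corpus."""
    seen = {}
    for smiles in CORPUS:
        mol = ck.parse_molecule(smiles)
        num = ck.canonical_numbering(mol)
        entities = [ck.molecule_uri(num)]
        entities += [ck.atom_uri(num, i) for i in num.elements]
        entities += [ck.bond_uri(num, num.heavy_map[b.a], num.heavy_map[b.b])
                     for b in mol.bonds]
        entities += [f.uri for f in ck.atom_centered_fragments(mol, num)]
        for uri in entities:
            owner = seen.setdefault(uri.iri, smiles)
            assert owner == smiles, f"collision: {uri.iri} in {owner}/{smiles}"
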