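import networkx as nx
import pytest
from rdflib import RDF, URIRef

import chesskit as ck
from chesskit.errors import MalformedReactionError, SerializationError
from chesskit.rdfio import EncodingOptions

CHEBI = "http://purl.org/obo/owl/CHEBI#"
SIO = "http://semanticscience.org/resource/SIO_"
CHESS = "http://semanticscience.org/resource/CHESS_"


def test_ethanol_encoding_contains_worked_example_triples(ethanol):
    """Molecule/fragment/bond/atom typing and the molecule->oxygen parthood."""
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    key = "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"
    mol_node = URIRef(CHESS + key)
    o_node = URIRef(CHESS + key + "-AO3")
    bond_node = URIRef(CHESS + key + "-BCO23")
    assert (mol_node, RDF.type, URIRef(CHEBI + "CHEBI_23367")) in g.graph
    assert (o_node, RDF.type, URIRef(CHEBI + "CHEBI_25805")) in g.graph
    assert (bond_node, RDF.type, URIRef(SIO + "010498")) in g.graph
    assert (mol_node, URIRef(SIO + "000053"), o_node) in g.graph
    # one fragment typed as an organic group, local name key-FG + 40 hex
    fg_nodes = [s for s, _, o in g.graph.triples(
        (None, RDF.type, URIRef(CHEBI + "CHEBI_33247")))]
    assert fg_nodes and all(
        str(s).startswith(CHESS + key + "-FG") for s in fg_nodes)


def test_direct_bond_predicates_are_bidirectional(ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    pred = URIRef(ck.term("has single bond with").iri)
    pairs = {(str(s), str(o)) for s, _, o in g.graph.triples((None, pred, None))}
    assert all((b, a) in pairs for a, b in pairs)
    assert len(pairs) == 2 * len(mol.bonds)


def test_bond_encoding_flags():
    mol = ck.parse_molecule("CCO")
    num = ck.canonical_numbering(mol)
    entities_only = ck.encode_molecule(mol, num, EncodingOptions(
        emit_direct_bond_predicates=False, depths=frozenset()))
    pred = URIRef(ck.term("has single bond with").iri)
    assert not list(entities_only.graph.triples((None, pred, None)))
    with pytest.raises(ValueError):
        EncodingOptions(emit_bond_entities=False,
                        emit_direct_bond_predicates=False)


@pytest.mark.parametrize("k", range(2, 7))
def test_chain_triple_count_matches_enumeration(k):
    """Closed-form count for an acyclic chain, verified by an independent
    enumeration over the expected entity inventory."""
    mol = ck.parse_molecule("C" * k)
    num = ck.canonical_numbering(mol)
    g = ck.encode_molecule(mol, num, EncodingOptions(depths=frozenset({1})))

    n_bonds = k - 1
    path = nx.path_graph(k)
    balls = {frozenset(nx.ego_graph(path, v, radius=1).nodes)
             for v in path.nodes}
    n_frag = len(balls)
    frag_member_links = sum(len(b) for b in balls)
    expected = (
        2                      # molecule typed molecular entity + molecule
        + 2 * k                # atom typing + molecule->atom parthood
        + n_bonds * 7          # bond: 2 types, parthood from molecule,
                               # 2 bond->atom parts, 2 direct predicates
        + n_frag * 3           # fragment: organic group + class + parthood
        + frag_member_links)   # fragment->member parthood
    assert len(g) == expected


def test_write_and_load_round_trip(tmp_path, ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    for dialect, suffix in (("turtle", "ttl"), ("ntriples", "nt")):
        path = tmp_path / f"ethanol.{suffix}"
        ck.write_graph(g, path, dialect)
        back = ck.load_knowledgebase(path)
        assert set(back.graph) == set(g.graph)


def test_turtle_output_carries_prefixes(tmp_path, ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    path = tmp_path / "out.ttl"
    ck.write_graph(g, path, "turtle")
    text = path.read_text()
    assert "@prefix chess:" in text and "@prefix sio:" in text


def test_ntriples_output_is_sorted_and_deterministic(tmp_path, ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    p1, p2 = tmp_path / "a.nt", tmp_path / "b.nt"
    ck.write_graph(g, p1, "ntriples")
    ck.write_graph(g, p2, "ntriples")
    assert p1.read_bytes() == p2.read_bytes()
    lines = p1.read_text().splitlines()
    assert lines == sorted(lines)


def test_empty_graph_serializes(tmp_path):
    g = ck.TripleGraph()
    path = tmp_path / "empty.nt"
    ck.write_graph(g, path, "ntriples")
    assert ck.load_knowledgebase(path).graph is not None


def test_unknown_dialect_rejected(tmp_path, ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    with pytest.raises(SerializationError):
        ck.write_graph(g, tmp_path / "x.xyz", "rdfxml")


def test_merge_collapses_shared_molecule(tmp_path):
    """Two independently written graphs for one molecule merge into one node
    bearing both descriptor sets."""
    mol = ck.parse_molecule("CN(C)CCC=C1c2ccccc2C(C)(C)c2ccccc21")
    num = ck.canonical_numbering(mol)
    mol_ref = ck.molecule_uri(num)

    g1 = ck.encode_molecule(mol, num)
    ck.attach_descriptor(g1, mol_ref, ck.make_invariant_descriptor(
        ck.term("mass descriptor"), "291.4", unit="dalton"))
    g2 = ck.encode_molecule(mol, num)
    ck.attach_descriptor(g2, mol_ref, ck.make_variable_descriptor(
        ck.term("logP descriptor"), "4.5",
        ck.ChemicalConfiguration({"provider": "chembl"})))

    ck.write_graph(g1, tmp_path / "a.ttl")
    ck.write_graph(g2, tmp_path / "b.ttl")
    merged = ck.load_knowledgebase([tmp_path / "a.ttl", tmp_path / "b.ttl"])

    molecules = set(merged.graph.subjects(
        RDF.type, URIRef(ck.term("molecule").iri)))
    assert molecules == {URIRef(mol_ref.iri)}
    mass = ck.retrieve_descriptors(merged, mol_ref, ck.term("mass descriptor"))
    logp = ck.retrieve_descriptors(merged, mol_ref, ck.term("logP descriptor"))
    assert mass[0]["value"] == "291.4" and logp[0]["value"] == "4.5"
    # union equals encoding everything into one graph
    both = ck.TripleGraph()
    for t in g1.graph:
        both.graph.add(t)
    for t in g2.graph:
        both.graph.add(t)
    assert set(merged.graph) == set(both.graph)


def test_loading_same_file_twice_is_idempotent(tmp_path, ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    path = tmp_path / "ethanol.ttl"
    ck.write_graph(g, path)
    once = ck.load_knowledgebase(path)
    twice = ck.load_knowledgebase([path, path])
    assert set(once.graph) == set(twice.graph)


def test_conflicting_descriptor_values_flagged(tmp_path, ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    d_ref = ck.attach_descriptor(g, ck.molecule_uri(num),
                                 ck.make_invariant_descriptor(
                                     ck.term("mass descriptor"), "46.07",
                                     unit="dalton"))
    g.add_literal(d_ref, ck.term("has value").iri, "47.00")  # conflict
    report = ck.validate(g)
    assert any("conflicting values" in line for line in report)


def test_encode_reaction_matches_transformation_pattern():
    rx = ck.alcohol_oxidation_reaction()
    g = ck.encode_reaction(rx)
    rx_node = URIRef(rx.uri.iri)
    assert (rx_node, RDF.type, URIRef(SIO + "010345")) in g.graph
    has_input = URIRef(ck.term("has input").iri)
    transforms = URIRef(ck.term("transforms into").iri)
    inputs = set(g.graph.objects(rx_node, has_input))
    assert len(inputs) == 2  # the group and its mapped oxygen atom
    # group-level and atom-level transforms-into both present
    edges = list(g.graph.triples((None, transforms, None)))
    assert len(edges) == 2
    atom_edge = [e for e in edges if str(e[0]).endswith("AO3")]
    assert atom_edge and str(atom_edge[0][2]).endswith("AO3")
    agent = URIRef(ck.term("has agent").iri)
    assert list(g.graph.objects(rx_node, agent))


def test_reaction_without_products_rejected():
    with pytest.raises(MalformedReactionError):
        ck.ReactionSpec(inputs=[ck.Participant("http://x/FG1")], products=[])


def test_validate_flags_variable_descriptor_without_configuration(ethanol):
    mol, num = ethanol
    g = ck.encode_molecule(mol, num)
    # hand-build a logP descriptor node lacking any configuration
    d = URIRef(CHESS + "LFQSCWFLJHTTHZ-UHFFFAOYSA-N-D" + "0" * 40)
    g.graph.add((URIRef(ck.molecule_uri(num).iri),
                 URIRef(ck.term("has attribute").iri), d))
    g.graph.add((d, RDF.type, URIRef(ck.term("logP descriptor").iri)))
    g.add_literal(d, ck.term("has value").iri, "1.5")
    report = ck.validate(g)
    assert any("without configuration" in line for line in report)
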