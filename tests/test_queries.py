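import pytest

import chesskit as ck
from chesskit.annotations import ChemicalConfiguration
from chesskit.errors import PatternError
from chesskit.queries import LipinskiCriteria, bde_window_query

PUBCHEM = "http://pubchem.ncbi.nlm.nih.gov"


# --- query generation -------------------------------------------------------

def test_ethyl_query_text_shape():
    q = ck.QueryGraph.chain(2)
    text = ck.substructure_query(q)
    assert text.count("rdf:type") == 3  # two carbons + the molecule
    assert text.count("SIO_000053") == 2  # one parthood pattern per atom
    assert "FILTER(?a0 != ?a1)" in text
    assert "hasSingleBondWith" in text


def test_single_atom_query_has_no_bonds_or_filters():
    q = ck.QueryGraph(nodes=[("a0", "O")])
    text = ck.substructure_query(q)
    assert "FILTER" not in text
    assert "BondWith" not in text


def test_ring_query_contains_five_bonds_one_double():
    q = ck.QueryGraph.from_molecule(ck.parse_molecule("C1=CCCC1"))
    text = ck.substructure_query(q)
    assert text.count("hasSingleBondWith") == 4
    assert text.count("hasDoubleBondWith") == 1
    assert text.count("FILTER") == 10  # all pairs over 5 atoms


def test_disconnected_pattern_rejected():
    with pytest.raises(PatternError):
        ck.QueryGraph(nodes=[("a0", "C"), ("a1", "C")], edges=[])


# --- substructure search ----------------------------------------------------

def test_ethyl_search_over_toy_kb(toy_kb):
    kb, uris = toy_kb
    hits = ck.run_substructure_search(kb, ck.QueryGraph.chain(2))
    assert hits == {uris["CC"], uris["CCO"]}


def test_every_molecule_matches_its_own_full_graph_query(toy_kb):
    kb, uris = toy_kb
    for smi, iri in uris.items():
        q = ck.QueryGraph.from_molecule(ck.parse_molecule(smi))
        assert iri in ck.run_substructure_search(kb, q)


@pytest.mark.parametrize("pattern", ["CC", "CO", "CCC"])
def test_search_agrees_with_monomorphism_oracle(pattern):
    fset = ck.generate_fixtures(ck.FixtureSpec(n_molecules=15, seed=5))
    kb = ck.build_knowledgebase(fset)
    mols = []
    for smi in fset.molecules.smiles:
        mol = ck.parse_molecule(smi)
        num = ck.canonical_numbering(mol)
        mols.append((ck.molecule_uri(num).iri, mol))
    q = ck.QueryGraph.from_molecule(ck.parse_molecule(pattern))
    assert ck.run_substructure_search(kb, q) == \
        ck.brute_force_substructure_search(mols, q)


# --- similarity -------------------------------------------------------------

def _kb_of(smiles_list):
    g = ck.TripleGraph()
    uris = {}
    for smi in smiles_list:
        mol = ck.parse_molecule(smi)
        num = ck.canonical_numbering(mol)
        ck.encode_molecule(mol, num, graph=g)
        uris[smi] = ck.molecule_uri(num).iri
    return g, uris


def test_similarity_self_is_top_ranked():
    kb, uris = _kb_of(["CCO", "CCCO", "C", "c1ccccc1"])
    for smi in uris:
        res = ck.similarity_rank(kb, ck.parse_molecule(smi), limit=10)
        top_score = res.ranking[0][1]
        self_score = dict(res.ranking)[uris[smi]]
        assert self_score == top_score


def test_similarity_propanol_beats_methane_for_ethanol_query():
    kb, uris = _kb_of(["CCCO", "C"])
    res = ck.similarity_rank(kb, ck.parse_molecule("CCO"), limit=10)
    scores = dict(res.ranking)
    assert scores[uris["CCCO"]] > scores[uris["C"]]
    assert scores[uris["C"]] == 0


def test_similarity_scores_non_increasing_and_limited():
    fset = ck.generate_fixtures(ck.FixtureSpec(n_molecules=10, seed=3))
    kb = ck.build_knowledgebase(fset)
    res = ck.similarity_rank(kb, ck.parse_molecule("CCO"), limit=4)
    scores = [s for _, s in res.ranking]
    assert scores == sorted(scores, reverse=True)
    assert len(res.ranking) <= 4
    one = ck.similarity_rank(kb, ck.parse_molecule("CCO"), limit=1)
    assert len(one.ranking) == 1


# --- descriptor retrieval ---------------------------------------------------

@pytest.fixture(scope="module")
def coordinate_kb():
    mol = ck.parse_molecule("CCO")
    num = ck.canonical_numbering(mol)
    g = ck.encode_molecule(mol, num)
    o_ref = ck.atom_uri(num, 3)
    for provider, x in ((PUBCHEM, "1.55"), ("http://chembl", "9.99")):
        config = ChemicalConfiguration({"provider": provider})
        ck.attach_descriptor(g, o_ref, ck.make_coordinate_descriptor(
            x, "0.10", "-0.70", ck.term("angstrom"), config))
    return g, num


def test_retrieve_coordinates_filtered_by_provider(coordinate_kb):
    g, num = coordinate_kb
    rows = ck.retrieve_descriptors(g, ck.molecule_uri(num),
                                   ck.term("3D cartesian coordinate"),
                                   provider=PUBCHEM)
    assert len(rows) == 1
    assert rows[0]["x"] == "1.55"
    assert rows[0]["entity"].endswith("-AO3")


def test_retrieve_with_absent_provider_is_empty(coordinate_kb):
    g, num = coordinate_kb
    rows = ck.retrieve_descriptors(g, ck.molecule_uri(num),
                                   ck.term("3D cartesian coordinate"),
                                   provider="http://nowhere")
    assert rows == []


def test_two_conformer_configurations_never_mix(coordinate_kb):
    g, num = coordinate_kb
    rows = ck.retrieve_descriptors(g, ck.molecule_uri(num),
                                   ck.term("3D cartesian coordinate"))
    assert len(rows) == 2
    assert {r["x"] for r in rows} == {"1.55", "9.99"}
    config = ChemicalConfiguration({"provider": "http://chembl"})
    pinned = ck.retrieve_descriptors(g, ck.molecule_uri(num),
                                     ck.term("3D cartesian coordinate"),
                                     configuration=config)
    assert len(pinned) == 1 and pinned[0]["x"] == "9.99"


# --- drug-likeness filter ---------------------------------------------------

def _lipinski_kb(rows):
    """rows: smiles -> dict of descriptor values (None = omit)."""
    g = ck.TripleGraph()
    uris = {}
    config = ChemicalConfiguration({"provider": PUBCHEM})
    types = {"mass": ("mass descriptor", "invariant"),
             "hba": ("hydrogen bond acceptor count", "invariant"),
             "hbd": ("hydrogen bond donor count", "invariant"),
             "logp": ("logP descriptor", "variable")}
    for smi, values in rows.items():
        mol = ck.parse_molecule(smi)
        num = ck.canonical_numbering(mol)
        ck.encode_molecule(mol, num, graph=g)
        uris[smi] = ck.molecule_uri(num).iri
        for key, value in values.items():
            if value is None:
                continue
            name, kind = types[key]
            if kind == "variable":
                d = ck.make_variable_descriptor(ck.term(name), value, config)
            else:
                d = ck.make_invariant_descriptor(ck.term(name), value)
            ck.attach_descriptor(g, ck.molecule_uri(num), d)
    return g, uris


def test_lipinski_boundary_semantics():
    g, uris = _lipinski_kb({
        "CCO": {"mass": "499.9", "hba": "10", "hbd": "5", "logp": "4.9"},
        "CCCO": {"mass": "500.0", "hba": "10", "hbd": "5", "logp": "4.9"},
        "CC": {"mass": "499.9", "hba": "10", "hbd": "5", "logp": "5.0"},
        "C": {"mass": "100.0", "hba": "2", "hbd": "1", "logp": None},
    })
    passing = ck.lipinski_pass(g)
    assert uris["CCO"] in passing      # strict mass bound not hit
    assert uris["CCCO"] not in passing  # mass exactly 500.0 fails
    assert uris["CC"] not in passing    # logP exactly 5.0 fails
    assert uris["C"] not in passing     # no logP witness at all


def test_lipinski_monotone_in_thresholds():
    g, _ = _lipinski_kb({
        "CCO": {"mass": "499.9", "hba": "10", "hbd": "5", "logp": "4.9"},
        "CCCO": {"mass": "650.0", "hba": "12", "hbd": "7", "logp": "6.5"},
        "CC": {"mass": "200.0", "hba": "3", "hbd": "1", "logp": "0.5"},
    })
    strict = ck.lipinski_pass(g, LipinskiCriteria())
    relaxed = ck.lipinski_pass(g, LipinskiCriteria(
        mass_max=700.0, hba_max=15, hbd_max=8, logp_min=-9.0, logp_max=9.0))
    assert strict <= relaxed


# --- dissociation-enthalpy window -------------------------------------------

def test_bde_window_membership(annotated_kb):
    kb, fset = annotated_kb
    hits = dict(ck.bde_window_search(kb, 67, 78, ck.chess_term("AM1")))
    assert 72.0 in hits.values()
    assert all(67 < v < 78 for v in hits.values())
    # values exactly on the edges and ethanol's 104.5 are excluded
    wide = dict(ck.bde_window_search(kb, 0, 1000, ck.chess_term("AM1")))
    assert {67.0, 78.0} <= set(wide.values()) - set(hits.values())
    ethanol_iri = "http://semanticscience.org/resource/CHESS_" \
                  "LFQSCWFLJHTTHZ-UHFFFAOYSA-N"
    assert ethanol_iri not in wide  # no phenol group, despite its annotation


def test_bde_windows_partition(annotated_kb):
    kb, _ = annotated_kb
    method = ck.chess_term("AM1")
    ab = set(ck.bde_window_search(kb, 60, 72.5, method))
    bc = set(ck.bde_window_search(kb, 72.5, 90, method))
    ac = set(ck.bde_window_search(kb, 60, 90, method))
    assert ab.isdisjoint(bc)
    assert ab | bc <= ac


def test_bde_query_text_mentions_pattern_pieces():
    text = bde_window_query(67, 78, ck.chess_term("AM1").iri, "kcal/mol",
                            ck.chess_term("FGPhenol").iri)
    assert "FGPhenol" in text and "kcal/mol" in text
    assert "FILTER(?value > 67 && ?value < 78)" in text


# --- reaction candidates ----------------------------------------------------

def test_reaction_candidates_bindings(annotated_kb):
    kb, _ = annotated_kb
    num = ck.canonical_numbering(ck.parse_molecule("CCO"))
    rows = ck.reaction_candidates(kb, ck.molecule_uri(num))
    assert len(rows) == 1
    bindings = rows[0]["bindings"]
    assert any(v.endswith("-AO3") for v in bindings.values())
    assert any("-FG" in v for v in bindings.values())


def test_methane_matches_no_reaction(annotated_kb):
    kb, _ = annotated_kb
    num = ck.canonical_numbering(ck.parse_molecule("C"))
    assert ck.reaction_candidates(kb, ck.molecule_uri(num)) == []


def test_propanol_is_also_a_candidate(annotated_kb):
    kb, _ = annotated_kb
    num = ck.canonical_numbering(ck.parse_molecule("CCCO"))
    rows = ck.reaction_candidates(kb, ck.molecule_uri(num))
    assert len(rows) == 1


# --- rule emission ----------------------------------------------------------

def test_dl_safe_rule_for_ethyl():
    rule = ck.emit_dl_safe_rule(ck.QueryGraph.chain(2),
                                "ethyl containing molecule")
    assert "'single bond'(?a0, ?a1), 'different from'(?a0, ?a1)" in rule
    assert rule.endswith("-> 'ethyl containing molecule'(?m1)")
    assert rule.count("'carbon atom'") == 2
    assert rule.count("'is part of'") == 2


def test_dl_safe_rule_single_node():
    rule = ck.emit_dl_safe_rule(ck.QueryGraph(nodes=[("a0", "O")]), "oxide")
    assert "different from" not in rule
    assert "bond" not in rule


def test_dl_safe_rule_counts_track_pattern():
    q = ck.QueryGraph.from_molecule(ck.parse_molecule("C1=CCCC1"))
    rule = ck.emit_dl_safe_rule(q, "cyclopentene containing molecule")
    assert rule.count("bond'(") == len(q.edges)
    assert rule.count("'different from'") == len(q.distinct_pairs)
    assert rule.count("'carbon atom'") == len(q.nodes)
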