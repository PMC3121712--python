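import random

import pytest
from hypothesis import HealthCheck, settings

import chesskit as ck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

#: Small corpus covering chains, branches, rings, aromatics, heteroatoms.
CORPUS = [
    "C", "CC", "CCO", "CCCO", "CO", "CC=O", "CC(C)O", "OCCO",
    "c1ccccc1", "Oc1ccccc1", "Cc1ccc(O)cc1", "C1CCCCC1", "C1=CCCC1",
    "CCCCCC", "CC(=O)O", "c1ccncc1", "CCCCCCCC=O", "CC(C)CC",
    "COc1ccc(O)cc1", "CCCCO",
]


def permute_graph(mol: ck.MolecularGraph, rng: random.Random) -> ck.MolecularGraph:
    """Relabel atoms with a random permutation (same molecule, new order)."""
    n = len(mol.atoms)
    perm = list(range(n))
    rng.shuffle(perm)  # perm[old] = new
    atoms = [None] * n
    for old, new in enumerate(perm):
        atoms[new] = mol.atoms[old]
    bonds = [ck.Bond(perm[b.a], perm[b.b], b.order) for b in mol.bonds]
    return ck.MolecularGraph(atoms=atoms, bonds=bonds,
                             source_format=mol.source_format), perm


@pytest.fixture(scope="session")
def ethanol():
    mol = ck.parse_molecule("CCO")
    return mol, ck.canonical_numbering(mol)


@pytest.fixture(scope="session")
def propanol():
    mol = ck.parse_molecule("CCCO")
    return mol, ck.canonical_numbering(mol)


@pytest.fixture(scope="session")
def toy_kb():
    """Methane + ethane + ethanol, encoded into one knowledgebase."""
    g = ck.TripleGraph()
    uris = {}
    for smi in ("C", "CC", "CCO"):
        mol = ck.parse_molecule(smi)
        num = ck.canonical_numbering(mol)
        ck.encode_molecule(mol, num, graph=g)
        uris[smi] = ck.molecule_uri(num).iri
    return g, uris


@pytest.fixture(scope="session")
def annotated_kb():
    """Fixture corpus with O-H dissociation-enthalpy annotations and the
    generic alcohol -> aldehyde reaction loaded."""
    fset = ck.generate_fixtures(
        ck.FixtureSpec(n_molecules=9, seed=7, families=("phenols",),
                       annotation_plan="bde"))
    kb = ck.build_knowledgebase(fset, include_reaction=True)
    return kb, fset
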