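"""Chemical graphs and InChI-derived canonical atom numbering.

A molecule is held as a plain labelled graph (:class:`MolecularGraph`):
atoms carry element, formal charge, isotope, and implicit-hydrogen count;
bonds carry one of four orders (single, double, triple, aromatic). RDKit does
the parsing (SMILES, SDF/MOL, InChI) and the canonicalization behind this
surface.

Canonical numbering is the anchor of the whole identifier scheme: the
standard InChI algorithm assigns every heavy atom a 1-based canonical index
that is invariant to input atom order, so an atom, bond, or fragment can be
named identically no matter which database or file the molecule came from.
Hydrogens are outside InChI's numbering; they receive derived indices
``n_heavy + k``, ranked by the canonical index of their attached heavy atom
(ties broken by input order — hydrogens on one heavy atom are symmetry
equivalent, so the resulting URI set is still permutation invariant).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem import rdmolops

from .errors import (
    EmptyInputError,
    FormatError,
    IncompleteGraphError,
    RepresentabilityError,
)
from . import vocab

RDLogger.DisableLog("rdApp.*")  # parse errors are surfaced as exceptions

__all__ = [
    "Atom",
    "Bond",
    "MolecularGraph",
    "CanonicalNumbering",
    "parse_molecule",
    "canonical_numbering",
    "reconstitute_graph",
]

BOND_ORDERS = ("single", "double", "triple", "aromatic")

_RDKIT_TO_ORDER = {
    Chem.BondType.SINGLE: "single",
    Chem.BondType.DOUBLE: "double",
    Chem.BondType.TRIPLE: "triple",
    Chem.BondType.AROMATIC: "aromatic",
}
_ORDER_TO_RDKIT = {v: k for k, v in _RDKIT_TO_ORDER.items()}


@dataclass(frozen=True)
class Atom:
    element: str
    charge: int = 0
    isotope: int | None = None
    hcount: int = 0  # implicit hydrogens


@dataclass(frozen=True)
class Bond:
    a: int
    b: int
    order: str


@dataclass
class MolecularGraph:
    """A chemical graph: atoms as nodes, bonds as edges."""

    atoms: list[Atom]
    bonds: list[Bond]
    source_format: str = "SMILES"

    def __post_init__(self):
        if not self.atoms:
            raise ValueError("a molecular graph requires at least one atom")
        seen = set()
        for bond in self.bonds:
            if bond.order not in BOND_ORDERS:
                raise ValueError(f"unknown bond order {bond.order!r}")
            if bond.a == bond.b:
                raise ValueError(f"self-bond on atom {bond.a}")
            if not (0 <= bond.a < len(self.atoms)
                    and 0 <= bond.b < len(self.atoms)):
                raise ValueError(f"bond ({bond.a},{bond.b}) out of range")
            key = frozenset((bond.a, bond.b))
            if key in seen:
                raise ValueError(f"duplicate bond ({bond.a},{bond.b})")
            seen.add(key)

    # -- derived views -----------------------------------------------------

    def heavy_indices(self) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.element != "H"]

    @property
    def n_heavy(self) -> int:
        return len(self.heavy_indices())

    def to_networkx(self) -> nx.Graph:
        """Element/order-labelled undirected graph (used by matching oracles)."""
        g = nx.Graph()
        for i, atom in enumerate(self.atoms):
            g.add_node(i, element=atom.element, charge=atom.charge)
        for bond in self.bonds:
            g.add_edge(bond.a, bond.b, order=bond.order)
        return g

    def to_rdkit(self) -> Chem.Mol:
        rw = Chem.RWMol()
        for atom in self.atoms:
            a = Chem.Atom(atom.element)
            a.SetFormalCharge(atom.charge)
            if atom.isotope:
                a.SetIsotope(atom.isotope)
            if atom.hcount:
                a.SetNumExplicitHs(atom.hcount)
            rw.AddAtom(a)
        for bond in self.bonds:
            rw.AddBond(bond.a, bond.b, _ORDER_TO_RDKIT[bond.order])
            if bond.order == "aromatic":
                rw.GetAtomWithIdx(bond.a).SetIsAromatic(True)
                rw.GetAtomWithIdx(bond.b).SetIsAromatic(True)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol

    def with_explicit_hydrogens(self) -> "MolecularGraph":
        """Return a copy in which implicit hydrogens are real graph atoms.

        Needed before encoding hydrogen-involving entities such as an O-H
        bond that carries a dissociation-enthalpy annotation.
        """
        mol = Chem.AddHs(self.to_rdkit())
        return _from_rdkit(mol, self.source_format)


@dataclass
class CanonicalNumbering:
    """InChI canonical indices plus derived hydrogen indices for one molecule.

    ``heavy_map`` maps input atom index -> canonical index (1-based, heavy
    atoms only); ``hydrogen_map`` maps input hydrogen index -> derived index
    (all greater than the number of heavy atoms). ``elements`` is the inverse
    view: canonical/derived index -> element symbol.
    """

    heavy_map: dict[int, int]
    hydrogen_map: dict[int, int]
    inchi: str
    inchikey: str
    elements: dict[int, str] = field(default_factory=dict)
    versions: dict[str, str] = field(default_factory=dict)

    def canonical_index(self, input_index: int) -> int:
        if input_index in self.heavy_map:
            return self.heavy_map[input_index]
        return self.hydrogen_map[input_index]


INCHIKEY_PATTERN = re.compile(r"^[A-Z]{14}-[A-Z]{10}-[A-Z]$")


def parse_molecule(data: str, format: str = "smiles") -> MolecularGraph:
    """Parse a SMILES, SDF/MOL block, or InChI string into a graph.

    Hydrogens stay implicit unless the input spells them out.
    """
    fmt = format.lower()
    if data is None or not data.strip():
        raise EmptyInputError("empty structure input")
    if fmt == "smiles":
        mol = Chem.MolFromSmiles(data)
        label = "SMILES"
    elif fmt in ("sdf", "mol"):
        mol = Chem.MolFromMolBlock(data)
        label = "SDF"
    elif fmt == "inchi":
        mol = Chem.MolFromInchi(data)
        label = "InChI"
    else:
        raise FormatError(f"unknown structure format {format!r}")
    if mol is None:
        raise FormatError(f"could not parse {label} input: {data.strip()!r}")
    return _from_rdkit(mol, label)


def _from_rdkit(mol: Chem.Mol, source_format: str) -> MolecularGraph:
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(Atom(
            element=a.GetSymbol(),
            charge=a.GetFormalCharge(),
            isotope=a.GetIsotope() or None,
            hcount=a.GetTotalNumHs(includeNeighbors=False)))
    bonds = []
    for b in mol.GetBonds():
        order = _RDKIT_TO_ORDER.get(b.GetBondType())
        if order is None:
            raise FormatError(f"unsupported bond type {b.GetBondType()}")
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularGraph(atoms=atoms, bonds=bonds, source_format=source_format)


def canonical_numbering(mol: MolecularGraph) -> CanonicalNumbering:
    """Derive the canonical numbering and InChI/InChI-key for a molecule.

    Multi-component structures (salts, mixtures) and anything standard InChI
    cannot represent are rejected: identifiers are only minted for single
    covalently bonded units.
    """
    rdmol = mol.to_rdkit()
    if len(rdmolops.GetMolFrags(rdmol)) != 1:
        raise RepresentabilityError(
            "multi-component structure: identifiers cover single covalent "
            "units only")
    inchi, aux = Chem.MolToInchiAndAuxInfo(rdmol)
    if not inchi:
        raise RepresentabilityError("structure not representable in standard InChI")
    inchikey = Chem.InchiToInchiKey(inchi)
    if not inchikey or not INCHIKEY_PATTERN.match(inchikey):
        raise RepresentabilityError(f"no valid InChI key for {inchi!r}")

    heavy_map = _heavy_map_from_aux(aux, mol)
    _refine_equivalent_positions(aux, heavy_map, rdmol)
    n_heavy = len(heavy_map)

    # Hydrogens: derived indices beyond the heavy range, ranked by the
    # canonical index of the attached heavy atom; input order breaks ties
    # among the (symmetry-equivalent) hydrogens of one heavy atom.
    neighbor = {}
    for bond in mol.bonds:
        for h, x in ((bond.a, bond.b), (bond.b, bond.a)):
            if mol.atoms[h].element == "H" and mol.atoms[x].element != "H":
                neighbor[h] = x
    h_indices = [i for i, a in enumerate(mol.atoms) if a.element == "H"]
    h_indices.sort(key=lambda h: (heavy_map.get(neighbor.get(h, -1), 10**9), h))
    hydrogen_map = {h: n_heavy + k + 1 for k, h in enumerate(h_indices)}

    elements = {ci: mol.atoms[i].element for i, ci in heavy_map.items()}
    elements.update({di: "H" for di in hydrogen_map.values()})

    import rdkit
    versions = {"inchi": inchi.split("/")[0].split("=")[1],
                "toolkit": f"rdkit {rdkit.__version__}"}
    return CanonicalNumbering(
        heavy_map=heavy_map, hydrogen_map=hydrogen_map, inchi=inchi,
        inchikey=inchikey, elements=elements, versions=versions)


def _heavy_map_from_aux(aux: str, mol: MolecularGraph) -> dict[int, int]:
    """Extract input-index -> canonical-index from InChI auxiliary info.

    The ``/N:`` layer lists, in canonical order, the 1-based original indices
    of the heavy atoms (original numbering counts every input atom, explicit
    hydrogens included).
    """
    m = re.search(r"/N:([0-9,;]+)", aux or "")
    if not m:
        raise RepresentabilityError(f"no canonical numbering layer in {aux!r}")
    layer = m.group(1)
    if ";" in layer:  # one sublist per component
        raise RepresentabilityError("multi-component auxiliary numbering")
    originals = [int(tok) for tok in layer.split(",")]
    heavy_map = {orig - 1: pos + 1 for pos, orig in enumerate(originals)}
    for i in heavy_map:
        if mol.atoms[i].element == "H":
            raise RepresentabilityError(
                "canonical numbering unexpectedly covered a hydrogen")
    return heavy_map


def _refine_equivalent_positions(aux, heavy_map, rdmol):
    """Deterministic assignment within InChI-equivalent canonical positions.

    InChI's mobile-hydrogen normalization treats e.g. the two carboxyl
    oxygens as one equivalence class (the auxiliary ``/E:`` layer), so their
    canonical indices are otherwise assigned input-order-dependently. Within
    each class the atoms are reassigned to the sorted positions by RDKit
    canonical rank, which does distinguish bond-order-distinct atoms; for
    truly symmetric atoms any assignment is related by an automorphism and
    the minted identifier set is unchanged.
    """
    m = re.search(r"/E:((?:\([0-9,]+\))+)", aux or "")
    if not m:
        return
    classes = [tuple(int(x) for x in grp.split(","))
               for grp in re.findall(r"\(([0-9,]+)\)", m.group(1))]
    ranks = list(Chem.CanonicalRankAtoms(rdmol, breakTies=False))
    inverse = {ci: i for i, ci in heavy_map.items()}
    for cls in classes:
        positions = sorted(p for p in cls if p in inverse)
        if len(positions) < 2:
            continue
        atoms = sorted((inverse[p] for p in positions),
                       key=lambda i: ranks[i])
        for pos, atom in zip(positions, atoms):
            heavy_map[atom] = pos


_ATOM_SUFFIX = re.compile(r"-A([A-Z][a-z]?)(\d+)$")


def reconstitute_graph(triples, molecule) -> MolecularGraph:
    """Rebuild the chemical graph of a molecule from its triple encoding.

    Atoms come from parthood + element typing, bonds from bond entities (their
    order classes and their two member atoms). The result is isomorphic to the
    graph originally encoded, up to implicit-hydrogen bookkeeping.
    """
    from rdflib import RDF, URIRef

    g = triples.graph
    mol_ref = URIRef(getattr(molecule, "iri", str(molecule)))
    part = URIRef(vocab.term("has proper part").iri)
    charge_p = URIRef(vocab.term("has formal charge").iri)
    isotope_p = URIRef(vocab.term("has isotope").iri)

    parts = list(g.objects(mol_ref, part))
    if not parts:
        raise IncompleteGraphError(
            f"no parthood assertions for {mol_ref}", orphans=[str(mol_ref)])

    atom_nodes, bond_nodes = {}, []
    for node in parts:
        for type_iri in g.objects(node, RDF.type):
            element = vocab.element_for_iri(str(type_iri))
            if element is not None:
                atom_nodes[node] = element
                break
            if vocab.bond_order_for_iri(str(type_iri)) is not None:
                bond_nodes.append((node, vocab.bond_order_for_iri(str(type_iri))))
                break

    if not atom_nodes:
        raise IncompleteGraphError(
            f"no typed atoms for {mol_ref}", orphans=[str(mol_ref)])

    # Canonical index order makes reconstruction deterministic.
    def canonical_index(node):
        m = _ATOM_SUFFIX.search(str(node))
        return int(m.group(2)) if m else 10**9

    ordered = sorted(atom_nodes, key=lambda n: (canonical_index(n), str(n)))
    index_of = {node: i for i, node in enumerate(ordered)}
    atoms = []
    for node in ordered:
        charge = next((int(v) for v in g.objects(node, charge_p)), 0)
        isotope = next((int(v) for v in g.objects(node, isotope_p)), None)
        atoms.append(Atom(element=atom_nodes[node], charge=charge,
                          isotope=isotope))

    bonds, orphans = [], []
    for bond_node, order in bond_nodes:
        endpoints = [n for n in g.objects(bond_node, part)]
        members = [index_of[n] for n in endpoints if n in index_of]
        missing = [str(n) for n in endpoints if n not in index_of]
        if missing or len(members) != 2:
            orphans.append(str(bond_node))
            orphans.extend(missing)
            continue
        bonds.append(Bond(members[0], members[1], order))
    if orphans:
        raise IncompleteGraphError(
            "bond assertions reference atoms that are not molecule members: "
            + ", ".join(sorted(set(orphans))), orphans=sorted(set(orphans)))

    return MolecularGraph(atoms=atoms, bonds=bonds, source_format="RDF")
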