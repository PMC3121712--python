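"""Atom-centered heavy-atom fragment vocabulary.

For every heavy atom, the fragment at depth d is the subgraph induced by all
heavy atoms within d bonds of the center (hydrogens suppressed). Depths 1-3
form the fingerprint-style vocabulary used for similarity ranking and
reaction-candidate matching: for n-propanol's oxygen the depth 1/2/3
fragments are the graphs CO, CCO, and CCCO.

Fragments with identical member sets are collapsed to one record, so small
saturated molecules don't emit redundant entries. Each fragment belongs to a
*class* — the equivalence class of structurally identical fragments across
all molecules — keyed by the canonical SMILES of the induced subgraph (bond
orders retained, so an alcohol CCO class is distinct from an aldehyde CC=O
class, which reaction matching relies on).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import SimpleNamespace

from rdkit import Chem

from .chemgraph import CanonicalNumbering, MolecularGraph
from .errors import ConnectivityError
from .identifiers import EntityURI, fragment_uri, sha1_hex
from .vocab import CHESS_BASE

__all__ = [
    "Fragment",
    "FragmentClass",
    "atom_centered_fragments",
    "fragment_class",
    "register_custom_group",
]

DEFAULT_DEPTHS = frozenset({1, 2, 3})


@dataclass(frozen=True)
class Fragment:
    """An atom-centered, depth-limited heavy-atom subgraph of one molecule.

    ``center`` and ``members`` are canonical indices; ``members`` is
    ascending and induces a connected subgraph.
    """

    center: int
    depth: int
    members: tuple[int, ...]
    class_key: str
    uri: EntityURI


@dataclass(frozen=True)
class FragmentClass:
    """The structure-level class shared by all fragments with one canonical
    subgraph, usable as an RDF class for fingerprint-style typing."""

    class_key: str
    class_uri: EntityURI


def class_uri_for_key(class_key: str, base: str = CHESS_BASE) -> EntityURI:
    return EntityURI(base, "FGC" + sha1_hex([class_key]))


def fragment_class(frag: Fragment | str, base: str = CHESS_BASE) -> FragmentClass:
    """Class record for a fragment (or directly for a class key)."""
    key = frag if isinstance(frag, str) else frag.class_key
    return FragmentClass(class_key=key, class_uri=class_uri_for_key(key, base))


def _heavy_submol_smiles(rdmol: Chem.Mol, atom_ids) -> str:
    """Canonical SMILES of the induced subgraph over the given atoms.

    Built on a standalone copy of the subgraph so the canonical form depends
    only on the fragment itself, never on the parent molecule's atom order
    (fragment-in-context canonicalization is not permutation stable).
    """

    def build():
        rw = Chem.RWMol()
        idx = {}
        for pos, i in enumerate(sorted(atom_ids)):
            a = rdmol.GetAtomWithIdx(i)
            na = Chem.Atom(a.GetSymbol())
            na.SetFormalCharge(a.GetFormalCharge())
            if a.GetIsotope():
                na.SetIsotope(a.GetIsotope())
            idx[i] = pos
            rw.AddAtom(na)
        for b in rdmol.GetBonds():
            i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
            if i in idx and j in idx:
                rw.AddBond(idx[i], idx[j], b.GetBondType())
                if b.GetBondType() == Chem.BondType.AROMATIC:
                    rw.GetAtomWithIdx(idx[i]).SetIsAromatic(True)
                    rw.GetAtomWithIdx(idx[j]).SetIsAromatic(True)
        return rw.GetMol()

    sub = build()
    try:
        Chem.SanitizeMol(sub)
    except Exception:
        # partial aromatic fragments (e.g. an open "ccc" path) cannot be
        # kekulized standalone; keep aromatic flags and skip those steps
        sub = build()
        flags = (Chem.SanitizeFlags.SANITIZE_ALL
                 ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE
                 ^ Chem.SanitizeFlags.SANITIZE_SETAROMATICITY)
        try:
            Chem.SanitizeMol(sub, flags)
        except Exception:
            sub = build()
            Chem.FastFindRings(sub)
    return Chem.MolToSmiles(sub, canonical=True)


def atom_centered_fragments(
    mol: MolecularGraph,
    numbering: CanonicalNumbering,
    depths=DEFAULT_DEPTHS,
    base: str = CHESS_BASE,
) -> set[Fragment]:
    """All depth-d balls around every heavy atom, deduplicated by member set.

    When several (center, depth) pairs induce the same member set, the
    representative with the smallest (depth, center) is kept; the fragment
    URI depends only on structure + members + molecule, so the choice never
    changes an identifier.
    """
    depths = sorted(set(depths))
    if any(d < 1 for d in depths):
        raise ValueError("fragment depths must be positive integers")

    rdmol = Chem.RemoveHs(mol.to_rdkit())
    heavy_inputs = mol.heavy_indices()
    # RemoveHs preserves the relative order of heavy atoms.
    canon_of_pos = {pos: numbering.heavy_map[i]
                    for pos, i in enumerate(heavy_inputs)}
    dist = Chem.GetDistanceMatrix(rdmol)
    n = rdmol.GetNumAtoms()

    chosen: dict[tuple[int, ...], tuple] = {}
    for center in range(n):
        for depth in depths:
            ball = [j for j in range(n) if dist[center][j] <= depth]
            members = tuple(sorted(canon_of_pos[j] for j in ball))
            key = _heavy_submol_smiles(rdmol, ball)
            candidate = (depth, canon_of_pos[center], members, key)
            prev = chosen.get(members)
            if prev is None or candidate[:2] < prev[:2]:
                chosen[members] = candidate

    out = set()
    for depth, center, members, key in chosen.values():
        stub = SimpleNamespace(class_key=key, members=members)
        out.add(Fragment(center=center, depth=depth, members=members,
                         class_key=key,
                         uri=fragment_uri(numbering, stub, base)))
    return out


def register_custom_group(
    mol: MolecularGraph,
    numbering: CanonicalNumbering,
    members,
    class_uri: EntityURI | str,
    base: str = CHESS_BASE,
) -> Fragment:
    """Mint a fragment for a user-chosen connected set of heavy atoms.

    ``members`` are input atom indices; ``class_uri`` is the caller's class
    (e.g. a curated phenol-group class). The fragment URI follows the
    standard rule, so re-registering the same members is idempotent.
    """
    members = sorted(set(members))
    if not members:
        raise ConnectivityError("custom group requires at least one atom")
    g = mol.to_networkx().subgraph(members)
    import networkx as nx
    if not nx.is_connected(g):
        raise ConnectivityError(
            f"member atoms {members} do not induce a connected subgraph")

    rdmol_key = _heavy_submol_smiles(mol.to_rdkit(), members)
    canon_members = tuple(sorted(numbering.heavy_map[i] for i in members))
    center = min(canon_members)
    stub = SimpleNamespace(class_key=rdmol_key, members=canon_members)
    return Fragment(center=center, depth=0, members=canon_members,
                    class_key=rdmol_key,
                    uri=fragment_uri(numbering, stub, base))
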