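"""Deterministic, database-independent entity identifiers.

Every chemical entity — molecule, atom, bond, fragment, descriptor,
configuration, reaction — receives a URI that is a pure function of its
semantic content, anchored in the molecule's InChI key and the InChI
canonical atom numbering. Two encoders working from different source
databases therefore mint byte-identical URIs for the same entity, which is
what makes independently produced RDF graphs collapse into one knowledgebase
on load.

Local-name grammar
------------------
===========  ==============================================
molecule     ``INCHIKEY``
atom         ``INCHIKEY-A<symbol><index>``
bond         ``INCHIKEY-B<sym1><sym2><idx1><idx2>`` (ascending index)
fragment     ``INCHIKEY-FG<40 hex>``
descriptor   ``<ownerlocal>-D<40 hex>``
configuration  ``CC<40 hex>``
reaction     ``RX<40 hex>``
===========  ==============================================

Hashes are 40-character lowercase hexadecimal SHA-1 digests of the entity's
ordered semantic parts, joined with an ASCII unit separator so that part
boundaries are unambiguous (``("ab","c")`` never collides with
``("a","bc")``). Absent optional parts serialize as the empty string. Numeric
values are hashed exactly as their source strings — no float re-formatting —
so identifiers are reproducible across platforms.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from .errors import (
    DegenerateConfigurationError,
    MalformedReactionError,
    MissingConfigurationError,
    NumberingError,
)
from .vocab import CHESS_BASE

__all__ = [
    "EntityURI",
    "sha1_hex",
    "molecule_uri",
    "atom_uri",
    "bond_uri",
    "fragment_uri",
    "configuration_uri",
    "descriptor_uri",
    "reaction_uri",
]

#: ASCII unit separator: joins hash input parts unambiguously.
_US = "\x1f"


def sha1_hex(parts) -> str:
    """40-hex-character SHA-1 digest of an ordered list of strings."""
    joined = _US.join("" if p is None else str(p) for p in parts)
    return hashlib.sha1(joined.encode("utf-8")).hexdigest()


@dataclass(frozen=True, order=True)
class EntityURI:
    """An absolute IRI split into a configurable base and a local name."""

    base: str
    local: str

    @property
    def iri(self) -> str:
        return self.base + self.local

    def __str__(self) -> str:
        return self.iri


def molecule_uri(numbering, base: str = CHESS_BASE) -> EntityURI:
    """Molecule URI: the InChI key itself is the local name."""
    return EntityURI(base, numbering.inchikey)


def atom_uri(numbering, index: int, base: str = CHESS_BASE) -> EntityURI:
    """Atom URI from a canonical (or hydrogen-derived) index.

    The suffix is ``-A`` + element symbol + index; e.g. ethanol's oxygen,
    canonical index 3, is ``...-AO3``.
    """
    element = numbering.elements.get(index)
    if element is None:
        raise NumberingError(f"no atom with canonical index {index}")
    return EntityURI(base, f"{numbering.inchikey}-A{element}{index}")


def bond_uri(numbering, index_a: int, index_b: int,
             base: str = CHESS_BASE) -> EntityURI:
    """Bond URI with endpoints ordered by ascending canonical index.

    Ethanol's C-O bond (C canonical 2, O canonical 3) is ``...-BCO23``.
    """
    i, j = sorted((index_a, index_b))
    for k in (i, j):
        if k not in numbering.elements:
            raise NumberingError(f"no atom with canonical index {k}")
    e1, e2 = numbering.elements[i], numbering.elements[j]
    return EntityURI(base, f"{numbering.inchikey}-B{e1}{e2}{i}{j}")


def fragment_uri(numbering, fragment, base: str = CHESS_BASE) -> EntityURI:
    """Fragment URI: hash of (class key, ascending member indices, InChI key).

    The digest covers the fragment's chemical graph structure, the canonical
    indices of its member heavy atoms, and its molecule of origin, so the
    same substructure at a different position — or in a different molecule —
    gets a different identifier.
    """
    digest = sha1_hex(
        [fragment.class_key,
         ",".join(str(m) for m in fragment.members),
         numbering.inchikey])
    return EntityURI(base, f"{numbering.inchikey}-FG{digest}")


def configuration_uri(config, base: str = CHESS_BASE) -> EntityURI:
    """Configuration URI: ``CC`` + hash of lexicographically sorted
    ``key=value`` annotation pairs; insertion order never matters."""
    annotations = config.annotations
    if isinstance(annotations, dict):
        annotations = annotations.items()
    if not annotations:
        raise DegenerateConfigurationError(
            "chemical configuration has no annotations")
    pairs = sorted(f"{k}={v}" for k, v in annotations)
    return EntityURI(base, "CC" + sha1_hex(pairs))


def descriptor_uri(descriptor, owner: EntityURI,
                   base: str = CHESS_BASE) -> EntityURI:
    """Descriptor URI appended to the owning entity's local name.

    invariant   hash(value, uncertainty, unit)
    variable    hash(value, uncertainty, unit, configuration local name)
    composite   hash of the lexicographically sorted full local names of the
                constituent descriptors (which already encode their own
                values, units, and configuration)
    """
    kind = descriptor.kind
    if kind == "composite":
        locals_ = sorted(
            descriptor_uri(c, owner, base).local for c in descriptor.components)
        digest = sha1_hex(locals_)
    else:
        unit = descriptor.unit
        unit_str = getattr(unit, "iri", unit)
        parts = [descriptor.type_term.iri, descriptor.value,
                 descriptor.uncertainty, unit_str]
        if kind == "variable":
            if descriptor.configuration is None:
                raise MissingConfigurationError(
                    "variable descriptor requires a chemical configuration")
            parts.append(configuration_uri(descriptor.configuration, base).local)
        digest = sha1_hex(parts)
    return EntityURI(base, f"{owner.local}-D{digest}")


def reaction_uri(reaction, base: str = CHESS_BASE) -> EntityURI:
    """Reaction URI from role-tagged participants and stoichiometry.

    Participants are serialized as ``coefficient*local-name``, sorted
    lexicographically within each role, so listing order is irrelevant while
    doubling a coefficient changes the identifier.
    """
    if not reaction.inputs or not reaction.products:
        raise MalformedReactionError(
            "reaction requires at least one input and one product")
    parts = []
    for role, participants in (("input", reaction.inputs),
                               ("product", reaction.products),
                               ("agent", reaction.agents)):
        tagged = sorted(
            f"{p.coefficient}*{p.local_name()}" for p in participants)
        parts.append(role + ":" + ";".join(tagged))
    return EntityURI(base, "RX" + sha1_hex(parts))
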