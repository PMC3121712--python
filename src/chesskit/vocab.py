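"""Ontology vocabulary table.

Every ontology identifier used anywhere in the toolkit resolves through
exactly one row of a name -> IRI table. The table is data, not code: it ships
as ``data/vocabulary.tsv`` and can be replaced wholesale (``load_vocabulary``)
when a community settles on different term bindings. Terms with well-known
public identifiers (SIO parthood/reaction relations, CHEBI entity and element
classes, CHEMINF descriptor/provenance classes, UO units) carry those; terms
that exist only by name are minted in the CHESS namespace.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

__all__ = [
    "VocabularyTerm",
    "term",
    "chess_term",
    "element_term",
    "bond_order_term",
    "direct_bond_predicate",
    "load_vocabulary",
    "vocabulary",
]

#: Default base IRI for minted CHESS entities. Configurable per call site;
#: this default mirrors the semanticscience resource namespace.
CHESS_BASE = "http://semanticscience.org/resource/CHESS_"


@dataclass(frozen=True)
class VocabularyTerm:
    """A named ontology concept with its IRI."""

    name: str
    iri: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.name} <{self.iri}>"


def _read_table(path=None) -> dict[str, VocabularyTerm]:
    if path is None:
        source = resources.files("chesskit.data").joinpath("vocabulary.tsv")
        text = source.read_text(encoding="utf-8")
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    table: dict[str, VocabularyTerm] = {}
    reader = csv.DictReader(text.splitlines(), delimiter="\t")
    for row in reader:
        name = row["name"].strip()
        if name in table:
            raise ValueError(f"duplicate vocabulary row for {name!r}")
        table[name] = VocabularyTerm(name, row["iri"].strip())
    return table


_TABLE: dict[str, VocabularyTerm] = _read_table()


def vocabulary() -> dict[str, VocabularyTerm]:
    """Return the active name -> term table (a copy)."""
    return dict(_TABLE)


def load_vocabulary(path) -> None:
    """Replace the active vocabulary with the rows of a TSV file."""
    global _TABLE
    _TABLE = _read_table(path)


def term(name: str) -> VocabularyTerm:
    """Look up a term by its field name, e.g. ``term("has proper part")``."""
    try:
        return _TABLE[name]
    except KeyError:
        raise KeyError(f"no vocabulary row named {name!r}") from None


def chess_term(local: str, base: str = CHESS_BASE) -> VocabularyTerm:
    """Mint an ad-hoc individual/class term in the CHESS namespace.

    Used for nodes like a named computational method (e.g. AM1) that the
    vocabulary table has no business enumerating.
    """
    return VocabularyTerm(local, base + local)


_ELEMENT_NAMES = {
    "H": "hydrogen atom",
    "C": "carbon atom",
    "N": "nitrogen atom",
    "O": "oxygen atom",
    "S": "sulfur atom",
    "P": "phosphorus atom",
    "F": "fluorine atom",
    "Cl": "chlorine atom",
    "Br": "bromine atom",
    "I": "iodine atom",
    "Ru": "ruthenium atom",
    "Al": "aluminium atom",
}


def element_term(symbol: str) -> VocabularyTerm:
    """Atom class for an element symbol; unlisted elements get a CHESS-minted
    class so encoding never fails on exotic chemistry."""
    name = _ELEMENT_NAMES.get(symbol)
    if name is not None:
        return term(name)
    return chess_term(f"{symbol}Atom")


def element_for_iri(iri: str) -> str | None:
    """Inverse of :func:`element_term` over the active table."""
    for symbol, name in _ELEMENT_NAMES.items():
        if _TABLE[name].iri == iri:
            return symbol
    prefix = CHESS_BASE
    if iri.startswith(prefix) and iri.endswith("Atom"):
        return iri[len(prefix):-len("Atom")]
    return None


_BOND_ORDER_NAMES = {
    "single": "single bond",
    "double": "double bond",
    "triple": "triple bond",
    "aromatic": "aromatic bond",
}

_DIRECT_PREDICATE_NAMES = {
    "single": "has single bond with",
    "double": "has double bond with",
    "triple": "has triple bond with",
    "aromatic": "has aromatic bond with",
}


def bond_order_term(order: str) -> VocabularyTerm:
    """Bond-entity class for a bond order (single/double/triple/aromatic)."""
    return term(_BOND_ORDER_NAMES[order])


def bond_order_for_iri(iri: str) -> str | None:
    for order, name in _BOND_ORDER_NAMES.items():
        if _TABLE[name].iri == iri:
            return order
    return None


def direct_bond_predicate(order: str) -> VocabularyTerm:
    """Bidirectional atom-atom predicate for a bond order."""
    return term(_DIRECT_PREDICATE_NAMES[order])


def bond_order_for_predicate(iri: str) -> str | None:
    for order, name in _DIRECT_PREDICATE_NAMES.items():
        if _TABLE[name].iri == iri:
            return order
    return None
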