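"""Descriptors, chemical configurations, and provenance.

A *descriptor* is an annotated value attached to a chemical entity. Three
kinds exist:

invariant
    depends only on constitution (heavy atom count, molecular mass);
variable
    depends on circumstances — computed logP, coordinates, bond
    dissociation enthalpies — and must therefore reference a
    :class:`ChemicalConfiguration`, the bundle of conditions (data provider,
    temperature, geometry, electronic state, computational context) under
    which the value holds;
composite
    has no value of its own but contains component descriptors, e.g. a 3D
    coordinate made of x/y/z components.

Computationally derived descriptors additionally carry :class:`Provenance`:
the algorithm class, a (possibly parameterized) software execution, and the
software name/version. Experimentally derived ones reuse the same structure
with an observation-process term in place of the software execution.

Values are stored and serialized as strings in their source lexical form
("104.5" stays "104.5"), which keeps identifier hashing and round-trip
retrieval byte-faithful.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import (
    DegenerateConfigurationError,
    MissingConfigurationError,
    ProvenanceError,
)
from .vocab import VocabularyTerm, chess_term, term

__all__ = [
    "ChemicalConfiguration",
    "Provenance",
    "Descriptor",
    "make_invariant_descriptor",
    "make_variable_descriptor",
    "make_coordinate_descriptor",
    "make_bde_annotation",
    "descriptors_from_table",
]


@dataclass(frozen=True)
class ChemicalConfiguration:
    """An order-independent map of condition annotations.

    Keys are free annotation names (``provider``, ``temperature``,
    ``geometry``, ``electronic state``, ...); equality is map equality, so
    two configurations built in different insertion orders are the same
    entity and hash to the same identifier.
    """

    annotations: tuple[tuple[str, str], ...]

    def __init__(self, annotations):
        items = dict(annotations)
        if not items:
            raise DegenerateConfigurationError(
                "chemical configuration requires at least one annotation")
        object.__setattr__(
            self, "annotations",
            tuple(sorted((str(k), str(v)) for k, v in items.items())))

    def as_dict(self) -> dict[str, str]:
        return dict(self.annotations)


@dataclass(frozen=True)
class Provenance:
    """Computational (or experimental) origin of a descriptor value."""

    algorithm_term: VocabularyTerm | None = None
    software: tuple[str, str] | None = None  # (name, version)
    parameters: tuple = ()  # (term-or-name, value, unit-or-None) triples

    def __post_init__(self):
        if self.parameters and self.software is None:
            raise ProvenanceError(
                "parameterized execution requires a software agent")
        object.__setattr__(self, "parameters", tuple(
            (p if isinstance(p, tuple) else tuple(p)) for p in self.parameters))

    def signature(self) -> str:
        """Deterministic serialization (feeds configuration derivation)."""
        parts = [self.algorithm_term.iri if self.algorithm_term else ""]
        if self.software:
            parts.append("/".join(self.software))
        for t, v, u in sorted(self.parameters,
                              key=lambda p: getattr(p[0], "name", str(p[0]))):
            name = getattr(t, "name", str(t))
            parts.append(f"{name}={v}{'' if u is None else ' ' + str(u)}")
        return ";".join(parts)


@dataclass(frozen=True)
class Descriptor:
    kind: str  # invariant | variable | composite
    type_term: VocabularyTerm
    value: str | None = None
    uncertainty: str | None = None
    unit: object | None = None  # literal string or VocabularyTerm/IRI
    components: tuple["Descriptor", ...] = ()
    configuration: ChemicalConfiguration | None = None
    provenance: Provenance | None = None

    def __post_init__(self):
        if self.kind not in ("invariant", "variable", "composite"):
            raise ValueError(f"unknown descriptor kind {self.kind!r}")
        has_value = self.value is not None
        if has_value == bool(self.components):
            raise ValueError(
                "descriptor must have a value xor component descriptors")
        if self.kind == "variable" and self.configuration is None:
            raise MissingConfigurationError(
                f"variable descriptor {self.type_term.name!r} requires a "
                "chemical configuration")
        if self.kind == "invariant" and self.configuration is not None:
            raise ValueError("invariant descriptors carry no configuration")
        if self.value is not None:
            object.__setattr__(self, "value", str(self.value))
        if self.uncertainty is not None:
            object.__setattr__(self, "uncertainty", str(self.uncertainty))
        object.__setattr__(self, "components", tuple(self.components))


def make_invariant_descriptor(type_term, value, unit=None, uncertainty=None,
                              provenance=None) -> Descriptor:
    return Descriptor(kind="invariant", type_term=type_term, value=value,
                      unit=unit, uncertainty=uncertainty,
                      provenance=provenance)


def make_variable_descriptor(type_term, value, config, unit=None,
                             uncertainty=None, provenance=None) -> Descriptor:
    return Descriptor(kind="variable", type_term=type_term, value=value,
                      unit=unit, uncertainty=uncertainty, configuration=config,
                      provenance=provenance)


def _finite(x) -> bool:
    try:
        return float(x) == float(x) and abs(float(x)) != float("inf")
    except (TypeError, ValueError):
        return False


def make_coordinate_descriptor(x, y, z, unit, config) -> Descriptor:
    """Composite 3D Cartesian coordinate with x/y/z component descriptors.

    Component construction order never matters: the composite's identifier
    hashes the lexicographically sorted component identifiers.
    """
    for v in (x, y, z):
        if not _finite(v):
            raise ValueError(f"coordinate component {v!r} is not finite")
    comps = tuple(
        Descriptor(kind="variable", type_term=term(f"{axis} cartesian coordinate"),
                   value=v, unit=unit, configuration=config)
        for axis, v in (("x", x), ("y", y), ("z", z)))
    return Descriptor(kind="composite", type_term=term("3D cartesian coordinate"),
                      components=comps, configuration=config)


def make_bde_annotation(value, unit, method_term, software, params=(),
                        uncertainty=None) -> Descriptor:
    """Bond dissociation enthalpy descriptor with computational provenance.

    ``method_term`` names the algorithm (e.g. a CHESS-namespace AM1 node,
    typed to the CHEMINF algorithm class on encoding); ``software`` is a
    (name, version) pair; ``params`` are (term-or-name, value, unit) triples
    such as a temperature. The computational context doubles as the
    descriptor's chemical configuration — it is exactly the set of
    conditions under which the value holds — so two identical values
    produced by different methods remain distinct entities.
    """
    if software is None and params:
        raise ProvenanceError("parameters supplied without a software agent")
    prov = Provenance(algorithm_term=method_term,
                      software=tuple(software) if software else None,
                      parameters=tuple(params))
    config = ChemicalConfiguration({"computational context": prov.signature()})
    return Descriptor(kind="variable",
                      type_term=term("bond dissociation energy descriptor"),
                      value=value, unit=unit, uncertainty=uncertainty,
                      configuration=config, provenance=prov)


_TABLE_COLUMNS = ("owner", "kind", "type", "value", "uncertainty", "unit",
                  "configuration")


def descriptors_from_table(table: pd.DataFrame):
    """Batch-ingest descriptor records from a delimited table.

    Expected columns: ``owner`` (entity IRI or local name), ``kind``,
    ``type`` (vocabulary term name), ``value``, and optionally
    ``uncertainty``, ``unit``, ``configuration`` (semicolon-separated
    ``key=value`` pairs). Returns a list of (owner, Descriptor) pairs.
    """
    out = []
    for _, row in table.iterrows():
        kind = str(row["kind"])
        type_name = str(row["type"])
        try:
            ttype = term(type_name)
        except KeyError:
            ttype = chess_term(type_name.replace(" ", ""))
        unit = row.get("unit")
        unit = None if pd.isna(unit) else str(unit)
        unc = row.get("uncertainty")
        unc = None if pd.isna(unc) else str(unc)
        config = None
        raw_cfg = row.get("configuration")
        if raw_cfg is not None and not pd.isna(raw_cfg) and str(raw_cfg):
            pairs = [p.split("=", 1) for p in str(raw_cfg).split(";") if p]
            config = ChemicalConfiguration({k: v for k, v in pairs})
        if kind == "variable":
            desc = make_variable_descriptor(ttype, str(row["value"]), config,
                                            unit=unit, uncertainty=unc)
        else:
            desc = make_invariant_descriptor(ttype, str(row["value"]),
                                             unit=unit, uncertainty=unc)
        out.append((str(row["owner"]), desc))
    return out
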