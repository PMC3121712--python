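"""Reaction specifications: participants, roles, stoichiometry, mappings.

Reactions are modelled as abstract transformations identified purely by
their participants and stoichiometry — no kinetics, no likelihood. Two
levels of participant exist: *class*-level (a functional-group class, for
generic transformations such as primary alcohol -> aldehyde) and
*instance*-level (a concrete molecule URI). A *transforms-into* mapping
pairs each reactant group or atom with its product counterpart, which is
what later allows an atom's fate to be traced through chains of reactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import MalformedReactionError, MappingError
from .fragments import FragmentClass
from .identifiers import EntityURI, reaction_uri
from .vocab import CHESS_BASE

__all__ = [
    "Participant",
    "ReactionSpec",
    "group_atom_ref",
    "build_generic_reaction",
    "trace_atom",
]


@dataclass(frozen=True)
class Participant:
    """One reaction participant: a class or instance reference plus its
    stoichiometric coefficient."""

    ref: object  # FragmentClass | EntityURI | str (IRI)
    coefficient: int = 1
    level: str = "class"  # class | instance

    def __post_init__(self):
        if self.coefficient < 1 or int(self.coefficient) != self.coefficient:
            raise MalformedReactionError(
                f"stoichiometric coefficient must be a positive integer, "
                f"got {self.coefficient!r}")
        if self.level not in ("class", "instance"):
            raise MalformedReactionError(f"unknown participant level {self.level!r}")

    def iri(self) -> str:
        ref = self.ref
        if isinstance(ref, FragmentClass):
            return ref.class_uri.iri
        if isinstance(ref, EntityURI):
            return ref.iri
        return str(ref)

    def local_name(self) -> str:
        iri = self.iri()
        return iri.rsplit("/", 1)[-1].rsplit("#", 1)[-1]


def group_atom_ref(group: FragmentClass, element: str, index: int) -> EntityURI:
    """Class-level atom node inside a functional-group class.

    E.g. the oxygen of an alcohol-group class gets local name
    ``<grouplocal>A<element><index>``; it is what instance atoms are typed to
    when reactions map atoms between groups.
    """
    return EntityURI(group.class_uri.base,
                     f"{group.class_uri.local}A{element}{index}")


@dataclass
class ReactionSpec:
    inputs: list[Participant]
    products: list[Participant]
    agents: list[Participant] = field(default_factory=list)
    #: (source IRI-bearing ref, target IRI-bearing ref) transforms-into pairs;
    #: endpoints must be participants or class-atom parts of participants.
    mappings: list[tuple] = field(default_factory=list)
    base: str = CHESS_BASE

    def __post_init__(self):
        if not self.inputs:
            raise MalformedReactionError("reaction has no inputs")
        if not self.products:
            raise MalformedReactionError("reaction has no products")
        member_iris = self._participant_iris()
        for src, dst in self.mappings:
            for end in (src, dst):
                iri = _end_iri(end)
                if not any(iri == m or iri.startswith(m + "A")
                           for m in member_iris):
                    raise MappingError(
                        f"transforms-into endpoint {iri} is not a participant "
                        "or a part of one")

    def _participant_iris(self):
        return [p.iri() for p in self.inputs + self.products + self.agents]

    @property
    def uri(self) -> EntityURI:
        return reaction_uri(self, base=self.base)

    def atom_balance_warnings(self) -> list[str]:
        """Optional matter-balance check over atom-level mappings.

        Generic class-level reactions cannot always be balanced, so this is
        advisory only: it reports reactant-side mapped atoms with no product
        counterpart and vice versa.
        """
        mapped_sources = {_end_iri(s) for s, _ in self.mappings}
        mapped_targets = {_end_iri(t) for _, t in self.mappings}
        warnings = []
        if len(mapped_sources) != len(mapped_targets):
            warnings.append(
                f"atom mapping is unbalanced: {len(mapped_sources)} sources "
                f"vs {len(mapped_targets)} targets")
        return warnings


def _end_iri(end) -> str:
    if isinstance(end, FragmentClass):
        return end.class_uri.iri
    iri = getattr(end, "iri", None)
    if isinstance(iri, str):
        return iri
    if callable(iri):
        return end.iri()
    return str(end)


def build_generic_reaction(input_groups, product_groups, agents=(),
                           atom_maps=(), coefficients=None,
                           base: str = CHESS_BASE) -> ReactionSpec:
    """Validated class-level reaction between functional-group classes.

    ``atom_maps`` pairs class-atom references (see :func:`group_atom_ref`)
    across the reaction, e.g. mapping the alcohol oxygen onto the aldehyde
    oxygen. ``agents`` may be molecule URIs (e.g. an InChI-keyed catalyst).
    """
    if not input_groups or not product_groups:
        raise MalformedReactionError(
            "generic reaction requires input and product groups")
    coefficients = coefficients or {}

    def participants(groups, level="class"):
        return [Participant(ref=g,
                            coefficient=coefficients.get(_ref_key(g), 1),
                            level=level)
                for g in groups]

    spec = ReactionSpec(
        inputs=participants(input_groups),
        products=participants(product_groups),
        agents=[Participant(ref=a, level="instance") for a in agents],
        mappings=list(atom_maps) + [
            (g, h) for g, h in zip(input_groups, product_groups)
            if len(input_groups) == len(product_groups)],
        base=base)
    return spec


def _ref_key(ref):
    if isinstance(ref, FragmentClass):
        return ref.class_key
    return str(ref)


def trace_atom(kb, atom) -> list[dict]:
    """Follow transforms-into edges reachable from an atom's class bindings.

    Returns an ordered chain of records ``{"reaction": iri | None,
    "source": iri, "target": iri}``: the atom's own node and every class-atom
    node it is typed to are used as starting points, then transforms-into
    edges are walked breadth-first. The reaction field names the reaction a
    hop belongs to when the source is one of its input participants' parts.
    """
    from rdflib import RDF, URIRef

    from .vocab import term

    g = kb.graph
    start = URIRef(getattr(atom, "iri", str(atom)))
    transforms = URIRef(term("transforms into").iri)
    has_input = URIRef(term("has input").iri)
    part = URIRef(term("has proper part").iri)

    seeds = [start] + list(g.objects(start, RDF.type))
    chain, seen = [], set()
    frontier = [s for s in seeds]
    while frontier:
        nxt = []
        for node in frontier:
            for target in sorted(g.objects(node, transforms)):
                if (node, target) in seen:
                    continue
                seen.add((node, target))
                reaction = _owning_reaction(g, node, has_input, part)
                chain.append({"reaction": reaction, "source": str(node),
                              "target": str(target)})
                nxt.append(target)
        frontier = nxt
    return chain


def _owning_reaction(g, node, has_input, part):
    for rx in g.subjects(has_input, node):
        return str(rx)
    # atom-level node: find the group that has it as proper part, then its
    # reaction
    for group in g.subjects(part, node):
        for rx in g.subjects(has_input, group):
            return str(rx)
    return None
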