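"""Triple-graph emission, serialization, and knowledgebase loading.

``encode_molecule`` turns a chemical graph plus its canonical numbering into
RDF: the molecule typed as a molecular entity, atoms typed to element
classes, bonds either as first-class entities typed by order (annotatable
with descriptors) or as direct bidirectional atom-atom predicates (fast to
query), or both — both is the default, since entity-only encodings make
pattern queries crawl while predicate-only encodings cannot carry bond
annotations. Parthood (*has proper part*) links molecule -> atoms/bonds/
fragments, bond -> endpoint atoms, fragment -> member atoms.

Because every URI is a pure function of chemistry, separately emitted graphs
for the same molecule collapse into one node on load — that is the whole
integration story.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdflib import Graph, Literal, Namespace, RDF, URIRef

from . import vocab
from .annotations import Descriptor
from .chemgraph import CanonicalNumbering, MolecularGraph
from .errors import KnowledgebaseError, SerializationError
from .fragments import atom_centered_fragments, fragment_class
from .identifiers import (
    EntityURI,
    atom_uri,
    bond_uri,
    configuration_uri,
    descriptor_uri,
    molecule_uri,
)
from .reactions import ReactionSpec, _end_iri
from .vocab import CHESS_BASE

__all__ = [
    "TripleGraph",
    "EncodingOptions",
    "encode_molecule",
    "attach_descriptor",
    "encode_reaction",
    "write_graph",
    "load_knowledgebase",
    "validate",
]

_PREFIXES = {
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "sio": "http://semanticscience.org/resource/SIO_",
    "chess": CHESS_BASE,
    "chebi": "http://purl.org/obo/owl/CHEBI#",
    "cheminf": "http://semanticscience.org/resource/CHEMINF_",
}


def _p(name: str) -> URIRef:
    return URIRef(vocab.term(name).iri)


class TripleGraph:
    """A set of subject-predicate-object triples with a prefix map.

    Thin wrapper over an :class:`rdflib.Graph`; set semantics come for free,
    and SPARQL runs directly against it.
    """

    def __init__(self, graph: Graph | None = None,
                 namespaces: dict[str, str] | None = None):
        self.graph = graph if graph is not None else Graph()
        self.namespaces = dict(_PREFIXES)
        if namespaces:
            self.namespaces.update(namespaces)
        for prefix, iri in self.namespaces.items():
            self.graph.bind(prefix, Namespace(iri), replace=True)

    def add(self, s, p, o):
        self.graph.add((_node(s), _node(p), o if isinstance(o, Literal)
                        else _node(o)))

    def add_literal(self, s, p, text):
        self.graph.add((_node(s), _node(p), Literal(str(text))))

    def __len__(self):
        return len(self.graph)

    def __iter__(self):
        return iter(self.graph)

    def __contains__(self, triple):
        s, p, o = triple
        return (_node(s), _node(p),
                o if isinstance(o, Literal) else _node(o)) in self.graph

    def query(self, sparql: str):
        return self.graph.query(sparql)

    def union(self, other: "TripleGraph") -> "TripleGraph":
        g = Graph()
        for t in self.graph:
            g.add(t)
        for t in other.graph:
            g.add(t)
        return TripleGraph(g, {**self.namespaces, **other.namespaces})


def _node(x) -> URIRef:
    if isinstance(x, URIRef):
        return x
    iri = getattr(x, "iri", None)
    if isinstance(iri, str):
        return URIRef(iri)
    return URIRef(str(x))


@dataclass(frozen=True)
class EncodingOptions:
    """Switches controlling what a molecule encoding emits."""

    emit_bond_entities: bool = True
    emit_direct_bond_predicates: bool = True
    depths: frozenset = frozenset({1, 2, 3})
    include_hydrogens: bool = False
    #: additionally type each fragment member atom to the matching
    #: class-level atom node of the fragment's class (enables atom-level
    #: reaction matching and atom-history tracing)
    type_atom_classes: bool = False
    base: str = CHESS_BASE

    def __post_init__(self):
        if not (self.emit_bond_entities or self.emit_direct_bond_predicates):
            raise ValueError("at least one bond encoding must be enabled")
        object.__setattr__(self, "depths", frozenset(self.depths))


def encode_molecule(mol: MolecularGraph, numbering: CanonicalNumbering,
                    opts: EncodingOptions = EncodingOptions(),
                    graph: TripleGraph | None = None,
                    extra_fragments=()) -> TripleGraph:
    """Emit the full triple encoding of one molecule.

    ``extra_fragments`` lets callers add custom registered groups (with their
    own class typing) alongside the automatic atom-centered vocabulary.
    Returns the graph (a fresh one unless ``graph`` is given, so several
    molecules can be encoded into one knowledgebase).
    """
    g = graph if graph is not None else TripleGraph()
    base = opts.base

    if opts.include_hydrogens:
        # Re-derive numbering on the explicit-hydrogen graph: heavy canonical
        # indices are unchanged (same molecule), hydrogens gain derived ones.
        from .chemgraph import canonical_numbering as _canon
        work = mol.with_explicit_hydrogens()
        work_numbering = _canon(work)
    else:
        work, work_numbering = mol, numbering
    mol_ref = molecule_uri(numbering, base)
    g.add(mol_ref, RDF.type, _p("molecular entity"))
    g.add(mol_ref, RDF.type, _p("molecule"))

    part = _p("has proper part")
    canon = {}
    for i, atom in enumerate(work.atoms):
        if atom.element == "H" and not opts.include_hydrogens:
            continue
        ci = work_numbering.canonical_index(i)
        canon[i] = ci
        a_ref = atom_uri(work_numbering, ci, base)
        g.add(a_ref, RDF.type, vocab.element_term(atom.element).iri)
        g.add(mol_ref, part, a_ref)
        if atom.charge:
            g.add_literal(a_ref, _p("has formal charge"), atom.charge)
        if atom.isotope:
            g.add_literal(a_ref, _p("has isotope"), atom.isotope)

    for bond in work.bonds:
        if bond.a not in canon or bond.b not in canon:
            continue  # hydrogen bond ends suppressed
        ia, ib = canon[bond.a], canon[bond.b]
        a_ref = atom_uri(work_numbering, ia, base)
        b_ref = atom_uri(work_numbering, ib, base)
        if opts.emit_bond_entities:
            b_uri = bond_uri(work_numbering, ia, ib, base)
            g.add(b_uri, RDF.type, vocab.bond_order_term(bond.order).iri)
            g.add(b_uri, RDF.type, _p("covalent bond"))
            g.add(mol_ref, part, b_uri)
            g.add(b_uri, part, a_ref)
            g.add(b_uri, part, b_ref)
        if opts.emit_direct_bond_predicates:
            pred = vocab.direct_bond_predicate(bond.order).iri
            g.add(a_ref, pred, b_ref)
            g.add(b_ref, pred, a_ref)

    fragments = set(extra_fragments)
    if opts.depths:
        fragments |= atom_centered_fragments(mol, numbering, opts.depths, base)
    for frag in fragments:
        fc = fragment_class(frag, base)
        g.add(frag.uri, RDF.type, _p("organic group"))
        g.add(frag.uri, RDF.type, fc.class_uri)
        g.add(mol_ref, part, frag.uri)
        for ci in frag.members:
            g.add(frag.uri, part, atom_uri(numbering, ci, base))
        if opts.type_atom_classes:
            _type_fragment_atoms(g, mol, numbering, frag, base)
    return g


def _type_fragment_atoms(g, mol, numbering, frag, base):
    """Type fragment member atoms to the class-level atom nodes.

    The class graph (parsed from the class key) is substructure-matched onto
    the fragment's induced subgraph; each member atom is then typed to the
    class atom node with the corresponding element and class-canonical
    index. Class keys that are not standalone-parseable SMILES (e.g. partial
    aromatic rings) are skipped.
    """
    from rdkit import Chem

    from .chemgraph import canonical_numbering as _canon
    from .chemgraph import parse_molecule as _parse
    from .errors import ChessError
    from .reactions import group_atom_ref

    try:
        cls_graph = _parse(frag.class_key, "smiles")
        cls_num = _canon(cls_graph)
        cls_rd = cls_graph.to_rdkit()
    except ChessError:
        return
    inv = {ci: i for i, ci in numbering.heavy_map.items()}
    member_inputs = [inv[ci] for ci in frag.members]
    pos_of = {i: pos for pos, i in enumerate(member_inputs)}

    rw = Chem.RWMol()
    for i in member_inputs:
        a = Chem.Atom(mol.atoms[i].element)
        a.SetFormalCharge(mol.atoms[i].charge)
        rw.AddAtom(a)
    order_map = {"single": Chem.BondType.SINGLE,
                 "double": Chem.BondType.DOUBLE,
                 "triple": Chem.BondType.TRIPLE,
                 "aromatic": Chem.BondType.AROMATIC}
    for bond in mol.bonds:
        if bond.a in pos_of and bond.b in pos_of:
            rw.AddBond(pos_of[bond.a], pos_of[bond.b], order_map[bond.order])
            if bond.order == "aromatic":
                rw.GetAtomWithIdx(pos_of[bond.a]).SetIsAromatic(True)
                rw.GetAtomWithIdx(pos_of[bond.b]).SetIsAromatic(True)
    submol = rw.GetMol()
    try:
        Chem.SanitizeMol(submol)
    except Exception:
        return
    match = submol.GetSubstructMatch(cls_rd)
    if not match:
        return
    fc = fragment_class(frag, base)
    for cls_idx, sub_idx in enumerate(match):
        input_idx = member_inputs[sub_idx]
        element = mol.atoms[input_idx].element
        class_atom = group_atom_ref(fc, element, cls_num.heavy_map[cls_idx])
        g.add(atom_uri(numbering, numbering.heavy_map[input_idx], base),
              RDF.type, class_atom)


def attach_descriptor(g: TripleGraph, owner: EntityURI, descriptor: Descriptor,
                      base: str = CHESS_BASE) -> EntityURI:
    """Emit a descriptor subgraph attached to its owning entity.

    Handles components (composite descriptors), configuration nodes with
    their annotations, and computational provenance (algorithm typing,
    parameterized execution, software agent + version).
    """
    d_ref = descriptor_uri(descriptor, owner, base)
    g.add(owner, _p("has attribute"), d_ref)
    g.add(d_ref, RDF.type, descriptor.type_term.iri)
    if descriptor.value is not None:
        g.add_literal(d_ref, _p("has value"), descriptor.value)
    if descriptor.uncertainty is not None:
        g.add_literal(d_ref, _p("has uncertainty"), descriptor.uncertainty)
    if descriptor.unit is not None:
        unit = descriptor.unit
        unit_iri = getattr(unit, "iri", None)
        if unit_iri:
            g.add(d_ref, _p("has unit"), unit_iri)
        else:
            g.add_literal(d_ref, _p("has unit"), unit)
    for comp in descriptor.components:
        c_ref = descriptor_uri(comp, owner, base)
        g.add(d_ref, _p("has direct part"), c_ref)
        attach_descriptor(g, owner, comp, base)
        # component attachment is via the composite, not the owner directly
        g.graph.remove((_node(owner), _p("has attribute"), _node(c_ref)))
    if descriptor.configuration is not None:
        cc_ref = configuration_uri(descriptor.configuration, base)
        g.add(cc_ref, RDF.type, _p("chemical configuration"))
        g.add(d_ref, _p("has attribute"), cc_ref)
        for key, value in descriptor.configuration.annotations:
            if key in ("provider", "has provider"):
                g.add_literal(cc_ref, _p("has provider"), value)
            else:
                g.add_literal(cc_ref, vocab.chess_term(
                    "annotation_" + key.replace(" ", "_"), base).iri, value)
    if descriptor.provenance is not None:
        _attach_provenance(g, d_ref, descriptor.provenance, base)
    return d_ref


def _attach_provenance(g, d_ref, prov, base):
    if prov.algorithm_term is not None:
        alg = URIRef(prov.algorithm_term.iri)
        g.add(d_ref, _p("is specified output of"), alg)
        g.add(alg, RDF.type, _p("algorithm"))
    if prov.software is not None:
        name, version = prov.software
        exe = EntityURI(base, "EX" + _exe_hash(prov))
        g.add(d_ref, _p("is output of"), exe)
        g.add(exe, RDF.type, _p("parameterized software execution"))
        for t, v, u in prov.parameters:
            term_obj = t if hasattr(t, "iri") else vocab.chess_term(
                str(t).replace(" ", ""), base)
            p_ref = EntityURI(base, exe.local + "P" + _param_hash(t, v, u))
            g.add(exe, _p("has attribute"), p_ref)
            g.add(p_ref, RDF.type, term_obj.iri)
            g.add_literal(p_ref, _p("has value"), v)
            if u is not None:
                u_iri = getattr(u, "iri", None)
                if u_iri:
                    g.add(p_ref, _p("has unit"), u_iri)
                else:
                    g.add_literal(p_ref, _p("has unit"), u)
        sw = EntityURI(base, "SW" + _sw_hash(name, version))
        g.add(exe, _p("has participant"), sw)
        g.add(sw, RDF.type, _p("software application"))
        g.add_literal(sw, vocab.chess_term("hasName", base).iri, name)
        ver = EntityURI(base, sw.local + "V")
        g.add(sw, _p("has attribute"), ver)
        g.add(ver, RDF.type, _p("software version"))
        g.add_literal(ver, _p("has value"), version)


def _exe_hash(prov):
    from .identifiers import sha1_hex
    return sha1_hex([prov.signature()])


def _param_hash(t, v, u):
    from .identifiers import sha1_hex
    return sha1_hex([getattr(t, "name", str(t)), v, u])


def _sw_hash(name, version):
    from .identifiers import sha1_hex
    return sha1_hex([name, version])


def encode_reaction(rxn: ReactionSpec, graph: TripleGraph | None = None,
                    group_keys: dict | None = None) -> TripleGraph:
    """Emit a reaction definition.

    The reaction node is typed *chemical reaction*; participants hang off
    *has input* / *has product* / *has agent*; transforms-into edges record
    group- and atom-level correspondences; class-level atom nodes are typed
    to their element classes and linked to their group by parthood.
    ``group_keys`` optionally maps a group IRI -> element list for atom
    typing of mapped class atoms.
    """
    g = graph if graph is not None else TripleGraph()
    rx_ref = rxn.uri
    g.add(rx_ref, RDF.type, _p("chemical reaction"))
    for role, participants in (("has input", rxn.inputs),
                               ("has product", rxn.products),
                               ("has agent", rxn.agents)):
        for p in participants:
            g.add(rx_ref, _p(role), URIRef(p.iri()))
            if p.level == "class":
                g.add(URIRef(p.iri()), RDF.type, _p("organic group"))
            if p.coefficient != 1:
                g.add_literal(URIRef(p.iri()),
                              _p("has stoichiometric coefficient"),
                              p.coefficient)
    for src, dst in rxn.mappings:
        s_iri, d_iri = _end_iri(src), _end_iri(dst)
        g.add(URIRef(s_iri), _p("transforms into"), URIRef(d_iri))
        for end_iri in (s_iri, d_iri):
            owner = _owning_participant(rxn, end_iri)
            if owner is not None and owner != end_iri:
                g.add(URIRef(owner), _p("has proper part"), URIRef(end_iri))
                element = _class_atom_element(end_iri)
                if element is not None:
                    g.add(URIRef(end_iri), RDF.type,
                          vocab.element_term(element).iri)
                    # also expose as reaction participant for atom-level match
                    role = ("has input"
                            if any(owner == p.iri() for p in rxn.inputs)
                            else "has product")
                    g.add(rx_ref, _p(role), URIRef(end_iri))
    return g


def _owning_participant(rxn, end_iri):
    for p in rxn.inputs + rxn.products + rxn.agents:
        if end_iri == p.iri():
            return end_iri
        if end_iri.startswith(p.iri() + "A"):
            return p.iri()
    return None


import re as _re

_CLASS_ATOM = _re.compile(r"A([A-Z][a-z]?)(\d+)$")


def _class_atom_element(iri: str) -> str | None:
    m = _CLASS_ATOM.search(iri)
    return m.group(1) if m else None


def write_graph(g: TripleGraph, path, dialect: str = "turtle") -> None:
    """Serialize to Turtle (readable) or N-Triples (sorted, byte-stable)."""
    if dialect not in ("turtle", "ntriples"):
        raise SerializationError(f"unknown dialect {dialect!r}")
    path = str(path)
    try:
        if dialect == "turtle":
            g.graph.serialize(destination=path, format="turtle")
        else:
            lines = sorted(
                f"{s.n3()} {p.n3()} {o.n3()} ." for s, p, o in g.graph)
            with open(path, "w", encoding="utf-8") as fh:
                fh.write("\n".join(lines) + ("\n" if lines else ""))
    except Exception as exc:  # rdflib raises assorted serialization errors
        raise SerializationError(str(exc)) from exc


def load_knowledgebase(paths) -> TripleGraph:
    """Parse one or more Turtle/N-Triples files into a union graph.

    Identical URIs from different files merge automatically (set semantics),
    which is how independently encoded repositories collapse into a single
    knowledgebase.
    """
    if isinstance(paths, (str, bytes)) or hasattr(paths, "__fspath__"):
        paths = [paths]
    g = Graph()
    for path in paths:
        path = str(path)
        fmt = "nt" if path.endswith(".nt") else "turtle"
        try:
            g.parse(path, format=fmt)
        except Exception as exc:
            raise KnowledgebaseError(f"failed to parse {path}: {exc}") from exc
    return TripleGraph(g)


def validate(g: TripleGraph) -> list[str]:
    """Integrity report over a knowledgebase.

    Flags: CHESS-minted subjects without a type triple, variable-style
    descriptors (value + provenance context expected) lacking a
    configuration, descriptors without units, and descriptor URIs carrying
    conflicting literal values.
    """
    report = []
    graph = g.graph
    has_value = _p("has value")
    has_unit = _p("has unit")
    has_attr = _p("has attribute")
    config_cls = _p("chemical configuration")

    typed = {s for s in graph.subjects(RDF.type, None)}
    for s in sorted({s for s, _, _ in graph if isinstance(s, URIRef)}):
        if str(s).startswith(CHESS_BASE) and s not in typed:
            report.append(f"untyped entity: {s}")

    descriptor_nodes = {
        s for s in graph.subjects(has_value, None)
        if "-D" in str(s).rsplit("/", 1)[-1]}
    for d in sorted(descriptor_nodes):
        values = sorted({str(v) for v in graph.objects(d, has_value)})
        if len(values) > 1:
            report.append(
                f"conflicting values for descriptor {d}: {', '.join(values)}")
        if not any(True for _ in graph.objects(d, has_unit)):
            report.append(f"descriptor without unit: {d}")
        configs = [o for o in graph.objects(d, has_attr)
                   if (o, RDF.type, config_cls) in graph]
        local = str(d).rsplit("-D", 1)[0]
        if not configs and _looks_variable(graph, d):
            report.append(f"variable descriptor without configuration: {d}")
        _ = local
    return report


def _looks_variable(graph, d) -> bool:
    variable_types = {
        vocab.term(n).iri
        for n in ("bond dissociation energy descriptor",
                  "logP descriptor", "3D cartesian coordinate",
                  "x cartesian coordinate", "y cartesian coordinate",
                  "z cartesian coordinate")}
    return any(str(t) in variable_types for t in graph.objects(d, RDF.type))
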