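"""Query repertoire over an encoded knowledgebase.

Structural queries (substructure search) are *generated* as standard SPARQL
1.1 text — usable against any endpoint — and *executed* in-process with
rdflib against the loaded graph. The pattern language is deliberately small:
element-typed atom variables, direct bond-order predicates between them, and
pairwise inequality filters, which together compute subgraph monomorphism
(injective matching) rather than induced-subgraph matching.

Numeric filters (the drug-likeness rule, dissociation-enthalpy windows) are
evaluated closed-world over the loaded descriptors: a molecule passes only
if witness descriptors of every required type are present and in range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
from rdflib import Literal, RDF, URIRef
from rdflib.term import Node

from . import vocab
from .chemgraph import MolecularGraph, canonical_numbering
from .errors import PatternError
from .fragments import atom_centered_fragments
from .rdfio import TripleGraph
from .vocab import CHESS_BASE, VocabularyTerm

__all__ = [
    "QueryGraph",
    "SimilarityResult",
    "LipinskiCriteria",
    "substructure_query",
    "run_substructure_search",
    "brute_force_substructure_search",
    "similarity_rank",
    "retrieve_descriptors",
    "lipinski_pass",
    "bde_window_search",
    "reaction_candidates",
    "emit_dl_safe_rule",
]

_SPARQL_PREFIXES = """\
prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#>
prefix sio: <http://semanticscience.org/resource/SIO_>
prefix chess: <{base}>
prefix chebi: <http://purl.org/obo/owl/CHEBI#>
"""


@dataclass
class QueryGraph:
    """A structural search pattern: element-labelled nodes, order-labelled
    edges, and variable pairs constrained unequal (all pairs by default)."""

    nodes: list[tuple[str, str]]  # (variable name, element symbol)
    edges: list[tuple[str, str, str]] = field(default_factory=list)
    distinct_pairs: list[tuple[str, str]] | None = None

    def __post_init__(self):
        declared = {v for v, _ in self.nodes}
        if not declared:
            raise PatternError("query graph requires at least one atom")
        for a, b, order in self.edges:
            if a not in declared or b not in declared:
                raise PatternError(f"edge ({a},{b}) uses undeclared variable")
            if order not in ("single", "double", "triple", "aromatic"):
                raise PatternError(f"unknown bond order {order!r}")
        g = nx.Graph()
        g.add_nodes_from(declared)
        g.add_edges_from((a, b) for a, b, _ in self.edges)
        if len(declared) > 1 and not nx.is_connected(g):
            raise PatternError("query graph must be connected")
        if self.distinct_pairs is None:
            ordered = [v for v, _ in self.nodes]
            self.distinct_pairs = [
                (ordered[i], ordered[j])
                for i in range(len(ordered)) for j in range(i + 1, len(ordered))]

    @classmethod
    def from_molecule(cls, mol: MolecularGraph) -> "QueryGraph":
        """Pattern matching a molecule's full heavy-atom graph."""
        heavy = mol.heavy_indices()
        var = {i: f"a{k}" for k, i in enumerate(heavy)}
        nodes = [(var[i], mol.atoms[i].element) for i in heavy]
        edges = [(var[b.a], var[b.b], b.order) for b in mol.bonds
                 if b.a in var and b.b in var]
        return cls(nodes=nodes, edges=edges)

    @classmethod
    def chain(cls, n: int, element: str = "C") -> "QueryGraph":
        """Linear single-bonded chain pattern (ethyl, propyl, ...)."""
        nodes = [(f"a{i}", element) for i in range(n)]
        edges = [(f"a{i}", f"a{i+1}", "single") for i in range(n - 1)]
        return cls(nodes=nodes, edges=edges)


@dataclass
class SimilarityResult:
    """Molecules ranked by the number of fragment classes shared with the
    query; scores are non-increasing down the list."""

    ranking: list[tuple[str, int]]
    limit: int


@dataclass(frozen=True)
class LipinskiCriteria:
    """Rule-of-Five thresholds: mass and logP bounds strict, hydrogen-bond
    acceptor/donor counts inclusive."""

    mass_max: float = 500.0
    hba_max: int = 10
    hbd_max: int = 5
    logp_min: float = -5.0
    logp_max: float = 5.0


def substructure_query(q: QueryGraph, base: str = CHESS_BASE) -> str:
    """Generate the SPARQL text for a structural pattern.

    One molecule-typing triple, one element-typing + parthood pair per atom
    variable, one direct bond-order predicate per edge, and inequality
    filters over the distinct pairs. Triple patterns are emitted in a
    selective order — a rare-element anchor atom first, then bond predicates
    breadth-first with each newly bound atom typed immediately — so that
    naive in-order join evaluators (rdflib included) never build large cross
    products; the solution set is order-independent.
    """
    element_of = dict(q.nodes)
    # anchor on the scarcest element class: heteroatoms before carbon
    rarity = {"C": 2, "H": 3}
    start = min((v for v, _ in q.nodes),
                key=lambda v: (rarity.get(element_of[v], 0), v))

    adjacency: dict[str, list] = {v: [] for v in element_of}
    for a, b, order in q.edges:
        adjacency[a].append((b, order, a, b))
        adjacency[b].append((a, order, a, b))

    lines = ["SELECT distinct ?m", "WHERE {"]

    def type_line(var):
        iri = vocab.element_term(element_of[var]).iri
        return f"  ?{var} rdf:type <{iri}>."

    lines.append(type_line(start))
    visited, frontier = {start}, [start]
    emitted_edges = set()
    while frontier:
        nxt = []
        for v in frontier:
            for w, order, a, b in adjacency[v]:
                key = (a, b, order)
                if key not in emitted_edges:
                    pred = vocab.direct_bond_predicate(order).iri
                    lines.append(f"  ?{a} <{pred}> ?{b}.")
                    emitted_edges.add(key)
                if w not in visited:
                    lines.append(type_line(w))
                    visited.add(w)
                    nxt.append(w)
        frontier = nxt

    part = vocab.term("has proper part").iri
    lines.append(f"  ?m <{part}> ?{start}.")
    lines.append(f"  ?m rdf:type <{vocab.term('molecule').iri}>.")
    for var, _ in q.nodes:
        if var != start:
            lines.append(f"  ?m <{part}> ?{var}.")
    for a, b in q.distinct_pairs:
        lines.append(f"  FILTER(?{a} != ?{b}).")
    lines.append("}")
    return _SPARQL_PREFIXES.format(base=base) + "\n".join(lines)


def _match_pattern(graph, patterns, distinct_groups=()):
    """Backtracking join of triple patterns against an rdflib store.

    ``patterns`` is an ordered list of (s, p, o) where each position is a
    bound rdflib term or a variable name string; ``distinct_groups`` lists
    sets of variables whose bindings must be pairwise distinct (checked
    incrementally, pruning early). The pattern order supplied by callers is
    preserved — selective patterns first keep the join linear, which is the
    point of bypassing rdflib's static reordering for in-process execution.
    Yields binding dicts.
    """
    distinct_groups = [set(group) for group in distinct_groups]

    def is_var(x):
        # rdflib terms subclass str; a variable is a *plain* string name
        return isinstance(x, str) and not isinstance(x, Node)

    def rec(i, binding):
        if i == len(patterns):
            yield binding
            return
        s, p, o = patterns[i]
        sb = binding.get(s) if is_var(s) else s
        ob = binding.get(o) if is_var(o) else o
        for s2, _, o2 in graph.triples((sb, p, ob)):
            nb = binding
            new = []
            if is_var(s) and sb is None:
                new.append((s, s2))
            if is_var(o) and ob is None:
                new.append((o, o2))
            if new:
                nb = dict(binding)
                nb.update(new)
                ok = True
                for var, val in new:
                    for group in distinct_groups:
                        if var in group and any(
                                nb.get(other) == val
                                for other in group if other != var):
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    continue
            yield from rec(i + 1, nb)

    yield from rec(0, {})


def _structural_patterns(q: QueryGraph):
    """Ordered triple patterns mirroring the generated SPARQL's join order."""
    element_of = dict(q.nodes)
    rarity = {"C": 2, "H": 3}
    start = min((v for v, _ in q.nodes),
                key=lambda v: (rarity.get(element_of[v], 0), v))
    adjacency: dict[str, list] = {v: [] for v in element_of}
    for a, b, order in q.edges:
        adjacency[a].append((b, order, a, b))
        adjacency[b].append((a, order, a, b))

    def type_pattern(var):
        return (var, RDF.type, URIRef(vocab.element_term(element_of[var]).iri))

    patterns = [type_pattern(start)]
    visited, frontier = {start}, [start]
    emitted = set()
    while frontier:
        nxt = []
        for v in frontier:
            for w, order, a, b in adjacency[v]:
                key = (a, b, order)
                if key not in emitted:
                    pred = URIRef(vocab.direct_bond_predicate(order).iri)
                    patterns.append((a, pred, b))
                    emitted.add(key)
                if w not in visited:
                    patterns.append(type_pattern(w))
                    visited.add(w)
                    nxt.append(w)
        frontier = nxt
    part = URIRef(vocab.term("has proper part").iri)
    patterns.append(("m", part, start))
    patterns.append(("m", RDF.type, URIRef(vocab.term("molecule").iri)))
    for var, _ in q.nodes:
        if var != start:
            patterns.append(("m", part, var))
    return patterns


def run_substructure_search(kb: TripleGraph, q: QueryGraph,
                            base: str = CHESS_BASE) -> set[str]:
    """Molecules whose graph admits an injective embedding of the pattern.

    Evaluates the same logical pattern as :func:`substructure_query` against
    the in-process store, joining in the generator's selective order (the
    SPARQL text itself is meant for external endpoints, whose optimizers
    choose their own join order). The knowledgebase must have been encoded
    with direct bond predicates.
    """
    patterns = _structural_patterns(q)
    groups = [{a, b} for a, b in (q.distinct_pairs or [])]
    hits = set()
    for binding in _match_pattern(kb.graph, patterns, groups):
        hits.add(str(binding["m"]))
    return hits


def brute_force_substructure_search(molecules, q: QueryGraph) -> set[str]:
    """Independent oracle: VF2 subgraph monomorphism on labelled graphs.

    ``molecules`` is an iterable of (molecule IRI, MolecularGraph). A
    molecule matches when the pattern graph maps injectively into its
    heavy-atom graph with elements and bond orders preserved.
    """
    pattern = nx.Graph()
    for var, element in q.nodes:
        pattern.add_node(var, element=element)
    for a, b, order in q.edges:
        pattern.add_edge(a, b, order=order)

    hits = set()
    for iri, mol in molecules:
        heavy = set(mol.heavy_indices())
        host = nx.Graph()
        for i in heavy:
            host.add_node(i, element=mol.atoms[i].element)
        for bond in mol.bonds:
            if bond.a in heavy and bond.b in heavy:
                host.add_edge(bond.a, bond.b, order=bond.order)
        gm = nx.algorithms.isomorphism.GraphMatcher(
            host, pattern,
            node_match=lambda h, p: h["element"] == p["element"],
            edge_match=lambda h, p: h["order"] == p["order"])
        if gm.subgraph_is_monomorphic():
            hits.add(iri)
    return hits


def similarity_rank(kb: TripleGraph, query_mol: MolecularGraph,
                    limit: int = 100, depths=frozenset({1, 2, 3}),
                    base: str = CHESS_BASE) -> SimilarityResult:
    """Rank knowledgebase molecules by shared fragment-class count.

    The query molecule is fragmented with the same depth set used to encode
    the knowledgebase; each molecule's score is the number of *distinct*
    fragment classes it shares with the query. Ties break by URI
    lexicographic order.
    """
    numbering = canonical_numbering(query_mol)
    query_classes = {
        "FGC" + _frag_class_hash(f.class_key)
        for f in atom_centered_fragments(query_mol, numbering, depths, base)}
    if not query_classes:
        return SimilarityResult(ranking=[], limit=limit)

    part = URIRef(vocab.term("has proper part").iri)
    mol_cls = URIRef(vocab.term("molecule").iri)
    scores: dict[str, set] = {}
    for m in kb.graph.subjects(RDF.type, mol_cls):
        shared = set()
        for f in kb.graph.objects(m, part):
            for cls in kb.graph.objects(f, RDF.type):
                local = str(cls).rsplit("_", 1)[-1]
                if local in query_classes:
                    shared.add(local)
        scores[str(m)] = shared
    ranking = sorted(((iri, len(shared)) for iri, shared in scores.items()),
                     key=lambda t: (-t[1], t[0]))[:limit]
    return SimilarityResult(ranking=ranking, limit=limit)


def _frag_class_hash(class_key: str) -> str:
    from .identifiers import sha1_hex
    return sha1_hex([class_key])


def retrieve_descriptors(kb: TripleGraph, molecule, type_term: VocabularyTerm,
                         provider: str | None = None,
                         configuration=None) -> list[dict]:
    """Rows of descriptor values for one molecule, filtered by provenance.

    Composite descriptors yield one row with the component values joined in
    (atom, x, y, z)-style columns; scalar descriptors yield (entity, value,
    unit) rows. ``provider`` filters on the configuration's data provider;
    ``configuration`` (a ChemicalConfiguration) pins the exact condition
    bundle, so rows from different conformers are never mixed.
    """
    g = kb.graph
    mol_ref = URIRef(getattr(molecule, "iri", str(molecule)))
    part = URIRef(vocab.term("has proper part").iri)
    has_attr = URIRef(vocab.term("has attribute").iri)
    has_value = URIRef(vocab.term("has value").iri)
    has_unit = URIRef(vocab.term("has unit").iri)
    has_part = URIRef(vocab.term("has direct part").iri)
    has_provider = URIRef(vocab.term("has provider").iri)
    config_cls = URIRef(vocab.term("chemical configuration").iri)
    ttype = URIRef(type_term.iri)

    wanted_config = None
    if configuration is not None:
        from .identifiers import configuration_uri
        wanted_config = configuration_uri(configuration).iri

    owners = [mol_ref] + sorted(g.objects(mol_ref, part))
    rows = []
    for owner in owners:
        for d in sorted(g.objects(owner, has_attr)):
            if (d, RDF.type, ttype) not in g:
                continue
            configs = [c for c in g.objects(d, has_attr)
                       if (c, RDF.type, config_cls) in g]
            if provider is not None:
                if not any(str(v) == provider for c in configs
                           for v in g.objects(c, has_provider)):
                    continue
            if wanted_config is not None:
                if not any(str(c) == wanted_config for c in configs):
                    continue
            row = {"entity": str(owner), "descriptor": str(d)}
            comps = sorted(g.objects(d, has_part))
            if comps:
                for comp in comps:
                    axis = _axis_of(g, comp)
                    value = next((str(v) for v in g.objects(comp, has_value)),
                                 None)
                    row[axis or str(comp)] = value
            else:
                row["value"] = next(
                    (str(v) for v in g.objects(d, has_value)), None)
                row["unit"] = next(
                    (str(u) for u in g.objects(d, has_unit)), None)
            rows.append(row)
    return rows


def _axis_of(g, comp):
    for axis in ("x", "y", "z"):
        if (comp, RDF.type,
                URIRef(vocab.term(f"{axis} cartesian coordinate").iri)) in g:
            return axis
    return None


def _witness_values(g, mol_ref, type_iri):
    has_attr = URIRef(vocab.term("has attribute").iri)
    has_value = URIRef(vocab.term("has value").iri)
    out = []
    for d in g.objects(mol_ref, has_attr):
        if (d, RDF.type, URIRef(type_iri)) in g:
            for v in g.objects(d, has_value):
                try:
                    out.append(float(str(v)))
                except ValueError:
                    continue
    return out


def lipinski_pass(kb: TripleGraph,
                  criteria: LipinskiCriteria = LipinskiCriteria()) -> set[str]:
    """Molecules satisfying the Rule of Five over loaded descriptors.

    Boundary semantics: mass and logP bounds are strict (mass exactly 500.0
    fails), acceptor/donor counts are inclusive (10 and 5 pass). A molecule
    missing any of the four descriptor types has no witness and is excluded
    — the filter is closed-world over the knowledgebase.
    """
    g = kb.graph
    mol_cls = URIRef(vocab.term("molecule").iri)
    mass_t = vocab.term("mass descriptor").iri
    hba_t = vocab.term("hydrogen bond acceptor count").iri
    hbd_t = vocab.term("hydrogen bond donor count").iri
    logp_t = vocab.term("logP descriptor").iri

    passing = set()
    for m in g.subjects(RDF.type, mol_cls):
        mass_ok = any(v < criteria.mass_max
                      for v in _witness_values(g, m, mass_t))
        hba_ok = any(v <= criteria.hba_max
                     for v in _witness_values(g, m, hba_t))
        hbd_ok = any(v <= criteria.hbd_max
                     for v in _witness_values(g, m, hbd_t))
        logp_ok = any(criteria.logp_min < v < criteria.logp_max
                      for v in _witness_values(g, m, logp_t))
        if mass_ok and hba_ok and hbd_ok and logp_ok:
            passing.add(str(m))
    return passing


def bde_window_query(low, high, method_iri, unit: str,
                     phenol_class_iri: str, base: str = CHESS_BASE) -> str:
    """SPARQL text of the antioxidant-window retrieval pattern."""
    t = vocab.term
    return (_SPARQL_PREFIXES.format(base=base) + f"""\
select ?m ?value where {{
  ?m rdf:type <{t('molecular entity').iri}>.
  ?m <{t('has proper part').iri}> ?f.
  ?f rdf:type <{phenol_class_iri}>.
  ?m <{t('has proper part').iri}> ?b.
  ?b rdf:type <{t('single bond').iri}>.
  ?b <{t('has proper part').iri}> ?o.
  ?o rdf:type <{t('oxygen atom').iri}>.
  ?b <{t('has proper part').iri}> ?h.
  ?h rdf:type <{t('hydrogen atom').iri}>.
  ?b <{t('has attribute').iri}> ?d.
  ?d rdf:type <{t('bond dissociation energy descriptor').iri}>.
  ?d <{t('is specified output of').iri}> <{method_iri}>.
  ?d <{t('has unit').iri}> "{unit}".
  ?d <{t('has value').iri}> ?value.
  FILTER(?value > {low} && ?value < {high})
}}""")


def bde_window_search(kb: TripleGraph, low: float, high: float,
                      method_term: VocabularyTerm, unit: str = "kcal/mol",
                      phenol_class: str | None = None,
                      base: str = CHESS_BASE) -> list[tuple[str, float]]:
    """Phenolic molecules whose O-H dissociation enthalpy lies strictly
    inside (low, high), computed with the given method and unit.

    The structural part of the generated SPARQL runs in-process; the numeric
    window is applied to the retrieved values (strict at both ends), keeping
    behaviour independent of literal-datatype coercion rules.
    """
    phenol_iri = phenol_class or vocab.chess_term("FGPhenol", base).iri
    method_iri = getattr(method_term, "iri", str(method_term))
    t = vocab.term
    part = URIRef(t("has proper part").iri)
    # same shape as bde_window_query, anchored on the (rare) phenol class
    patterns = [
        ("f", RDF.type, URIRef(phenol_iri)),
        ("m", part, "f"),
        ("m", RDF.type, URIRef(t("molecular entity").iri)),
        ("m", part, "b"),
        ("b", RDF.type, URIRef(t("single bond").iri)),
        ("b", part, "o"),
        ("o", RDF.type, URIRef(t("oxygen atom").iri)),
        ("b", part, "h"),
        ("h", RDF.type, URIRef(t("hydrogen atom").iri)),
        ("b", URIRef(t("has attribute").iri), "d"),
        ("d", RDF.type,
         URIRef(t("bond dissociation energy descriptor").iri)),
        ("d", URIRef(t("is specified output of").iri), URIRef(method_iri)),
        ("d", URIRef(t("has unit").iri), Literal(unit)),
        ("d", URIRef(t("has value").iri), "value"),
    ]
    rows = set()
    for binding in _match_pattern(kb.graph, patterns,
                                  [{"o", "h"}, {"f", "b"}]):
        try:
            value = float(str(binding["value"]))
        except ValueError:
            continue
        if low < value < high:  # strict at both window edges
            rows.add((str(binding["m"]), value))
    return sorted(rows)


def reaction_candidates(kb: TripleGraph, molecule,
                        base: str = CHESS_BASE) -> list[dict]:
    """Reactions whose input requirements the molecule can instantiate.

    A reaction is a candidate when every class-level input group is typed by
    at least one of the molecule's fragments, and every atom-level input
    (a class atom inside an input group) is matched by an atom of the right
    element inside such a fragment. Returns one row per reaction with the
    instance bindings.
    """
    g = kb.graph
    mol_ref = URIRef(getattr(molecule, "iri", str(molecule)))
    part = URIRef(vocab.term("has proper part").iri)
    has_input = URIRef(vocab.term("has input").iri)
    rx_cls = URIRef(vocab.term("chemical reaction").iri)

    mol_parts = set(g.objects(mol_ref, part))
    fragment_types = {}
    for f in mol_parts:
        fragment_types[f] = set(g.objects(f, RDF.type))

    candidates = []
    for rx in sorted(g.subjects(RDF.type, rx_cls)):
        inputs = set(g.objects(rx, has_input))
        # atom-level inputs are proper parts of other (group) inputs
        atom_inputs = {a for a in inputs
                       if any((grp, part, a) in g for grp in inputs)}
        group_inputs = inputs - atom_inputs
        bindings, ok = {}, True
        for grp in sorted(group_inputs):
            matched = sorted(f for f, types in fragment_types.items()
                             if grp in types)
            if not matched:
                ok = False
                break
            bindings[str(grp)] = str(matched[0])
            for a in sorted(atom_inputs):
                if (grp, part, a) not in g:
                    continue
                a_types = set(g.objects(a, RDF.type))
                hit = next(
                    (atom for atom in sorted(g.objects(matched[0], part))
                     if a_types & set(g.objects(atom, RDF.type))), None)
                if hit is None:
                    ok = False
                    break
                bindings[str(a)] = str(hit)
            if not ok:
                break
        if ok and group_inputs:
            candidates.append({"reaction": str(rx), "bindings": bindings})
    return candidates


def emit_dl_safe_rule(q: QueryGraph, class_name: str) -> str:
    """Textual description-logic-safe rule for a structural class.

    Emission only — no reasoner runs here. One atom-typing literal per node,
    parthood literals per node, bond-order literals per edge, and
    'different from' literals per distinct pair, with the target class in
    the head.
    """
    body = ["'molecule'(?m1)"]
    for var, element in q.nodes:
        body.append(f"'{vocab.element_term(element).name}'(?{var})")
    for var, _ in q.nodes:
        body.append(f"'is part of'(?{var}, ?m1)")
    for a, b, order in q.edges:
        body.append(f"'{order} bond'(?{a}, ?{b})")
    for a, b in q.distinct_pairs:
        body.append(f"'different from'(?{a}, ?{b})")
    return ", ".join(body) + f" -> '{class_name}'(?m1)"
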