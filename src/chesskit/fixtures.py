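"""Deterministic fixture molecules and annotation plans.

Supplies the small organic test corpus every capability is exercised with —
alcohols, phenols, alkanes, lipid-like chains, ring systems — plus synthetic
descriptor annotations (drug-likeness boundary values, O-H bond dissociation
enthalpies, conformer coordinates). The worked-example molecules (ethanol,
n-propanol, a phenol, an aldehyde) are always present. The same
(n, seed, families, plan) specification reproduces byte-identical output.

``build_knowledgebase`` is the one-stop assembly used by the CLI, the
examples, and the test-bench: it encodes the molecules, registers phenol
groups, applies the annotation plan, and (optionally) adds the generic
primary-alcohol -> aldehyde oxidation reaction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import pandas as pd
from rdflib import RDF
from rdkit import Chem

from .annotations import (
    ChemicalConfiguration,
    make_bde_annotation,
    make_coordinate_descriptor,
    make_invariant_descriptor,
    make_variable_descriptor,
)
from .chemgraph import canonical_numbering, parse_molecule
from .errors import FixtureConfigError
from .fragments import fragment_class, register_custom_group
from .identifiers import bond_uri, molecule_uri
from .queries import LipinskiCriteria
from .rdfio import EncodingOptions, TripleGraph, attach_descriptor, \
    encode_molecule, encode_reaction
from .reactions import build_generic_reaction, group_atom_ref
from .vocab import CHESS_BASE, chess_term, term

__all__ = [
    "FixtureSpec",
    "FixtureSet",
    "generate_fixtures",
    "build_knowledgebase",
    "alcohol_oxidation_reaction",
]

FAMILIES = {
    "alkanes": ["C", "CC", "CCC", "CCCC", "CC(C)C", "CCCCC", "CC(C)CC",
                "CCCCCC"],
    "alcohols": ["CO", "CCCCO", "CC(C)O", "OCCO", "CCCCCO", "CC(C)CO",
                 "CCC(C)O"],
    "phenols": ["Cc1ccc(O)cc1", "Oc1ccc(O)cc1", "Cc1ccccc1O",
                "COc1ccc(O)cc1", "CC(C)c1ccc(O)cc1"],
    "fatty-chains": ["CCCCCCCC=O", "CCCCCCCC(=O)O", "CCCCCC(=O)O",
                     "CCCCC=O", "CCCCCCCCO", "CCCCCCC(=O)O"],
    "ring-systems": ["c1ccccc1", "C1CCCCC1", "C1=CCCC1", "c1ccncc1",
                     "c1ccoc1", "Cc1ccccc1", "C1CCCC1"],
}

#: The worked-example molecules, always emitted first.
MANDATORY = [("ethanol", "CCO"), ("n-propanol", "CCCO"),
             ("phenol", "Oc1ccccc1"), ("acetaldehyde", "CC=O")]

ANNOTATION_PLANS = ("none", "lipinski-boundary", "bde", "coordinates")


@dataclass(frozen=True)
class FixtureSpec:
    n_molecules: int = 10
    seed: int = 1
    families: tuple[str, ...] = tuple(sorted(FAMILIES))
    annotation_plan: str = "none"

    def __post_init__(self):
        unknown = set(self.families) - set(FAMILIES)
        if unknown:
            raise FixtureConfigError(f"unknown fixture families: {sorted(unknown)}")
        if self.annotation_plan not in ANNOTATION_PLANS:
            raise FixtureConfigError(
                f"unknown annotation plan {self.annotation_plan!r}")
        if self.n_molecules < 1:
            raise FixtureConfigError("n_molecules must be >= 1")
        object.__setattr__(self, "families", tuple(sorted(set(self.families))))


@dataclass
class FixtureSet:
    molecules: pd.DataFrame  # columns: name, smiles, family
    annotations: pd.DataFrame
    spec: FixtureSpec


def generate_fixtures(spec: FixtureSpec) -> FixtureSet:
    """Deterministic molecule list plus annotation table for a spec."""
    rng = random.Random(spec.seed)

    def canonical(smi):
        return Chem.MolToSmiles(Chem.MolFromSmiles(smi))

    rows = [{"name": n, "smiles": s, "family": "mandatory"}
            for n, s in MANDATORY]
    seen = {canonical(s) for _, s in MANDATORY}

    pool = [(fam, smi) for fam in spec.families for smi in FAMILIES[fam]]
    rng.shuffle(pool)
    counter = 0
    while len(rows) < max(spec.n_molecules, len(MANDATORY)):
        if pool:
            fam, smi = pool.pop()
        else:  # extend deterministically: chains C_k, C_kO, branched C_k
            k, variant = divmod(counter, 3)
            body = "C" * (k % 14 + 2)
            smi = [body, body + "O", "CC(C)" + body][variant]
            fam = "generated"
            counter += 1
        key = canonical(smi)
        if key in seen:
            continue
        seen.add(key)
        rows.append({"name": smi, "smiles": smi, "family": fam})
    molecules = pd.DataFrame(rows[:max(spec.n_molecules, len(MANDATORY))])
    annotations = _annotation_table(spec, molecules)
    return FixtureSet(molecules=molecules, annotations=annotations, spec=spec)


_PUBCHEM = "http://pubchem.ncbi.nlm.nih.gov"


def _annotation_table(spec: FixtureSpec, molecules: pd.DataFrame) -> pd.DataFrame:
    rng = random.Random(spec.seed + 1)
    rows = []
    if spec.annotation_plan == "lipinski-boundary":
        # Values straddling each Rule-of-Five threshold, cycled over the
        # fixture list: all-pass boundary, strict-mass fail, strict-logP fail,
        # count-threshold passes, and a missing-descriptor case.
        c = LipinskiCriteria()
        patterns = [
            {"mass": "499.9", "hba": "10", "hbd": "5", "logp": "4.9"},
            {"mass": str(c.mass_max), "hba": "2", "hbd": "1", "logp": "1.0"},
            {"mass": "300.0", "hba": "4", "hbd": "2", "logp": str(c.logp_max)},
            {"mass": "250.0", "hba": "11", "hbd": "2", "logp": "0.5"},
            {"mass": "180.0", "hba": "3", "hbd": "6", "logp": "-1.2"},
            {"mass": "420.0", "hba": "9", "hbd": "4", "logp": None},  # missing
            {"mass": "120.5", "hba": "1", "hbd": "0", "logp": "-4.9"},
        ]
        types = {"mass": ("mass descriptor", "dalton"),
                 "hba": ("hydrogen bond acceptor count", None),
                 "hbd": ("hydrogen bond donor count", None),
                 "logp": ("logP descriptor", None)}
        for i, row in molecules.iterrows():
            pattern = patterns[i % len(patterns)]
            for key, value in pattern.items():
                if value is None:
                    continue
                tname, unit = types[key]
                rows.append({"smiles": row.smiles, "target": "molecule",
                             "kind": "invariant" if key == "mass" else "variable",
                             "type": tname, "value": value, "unit": unit,
                             "provider": _PUBCHEM})
    elif spec.annotation_plan == "bde":
        # O-H dissociation enthalpies: ethanol at 104.5 (outside the
        # antioxidant window), phenols at 72 then exactly at the 67/78
        # window edges to exercise strict exclusion.
        phenol_values = ["72.0", "67.0", "78.0", "74.5", "70.1"]
        k = 0
        for _, row in molecules.iterrows():
            mol = Chem.MolFromSmiles(row.smiles)
            if row.smiles == "CCO":
                value = "104.5"
            elif mol.HasSubstructMatch(Chem.MolFromSmarts("c[OX2H]")):
                value = phenol_values[k % len(phenol_values)]
                k += 1
            else:
                continue
            rows.append({"smiles": row.smiles, "target": "bond:O-H",
                         "kind": "variable",
                         "type": "bond dissociation energy descriptor",
                         "value": value, "unit": "kcal/mol", "method": "AM1",
                         "software_name": "MOPAC",
                         "software_version": "7.1.11",
                         "temperature": "298"})
    elif spec.annotation_plan == "coordinates":
        for _, row in molecules.iterrows():
            mol = Chem.MolFromSmiles(row.smiles)
            for atom in mol.GetAtoms():
                x, y, z = (round(rng.uniform(-5, 5), 2) for _ in range(3))
                rows.append({"smiles": row.smiles,
                             "target": f"atom:{atom.GetIdx()}",
                             "kind": "composite",
                             "type": "3D cartesian coordinate",
                             "value": f"{x},{y},{z}", "unit": "angstrom",
                             "provider": _PUBCHEM})
    return pd.DataFrame(rows)


def alcohol_oxidation_reaction(base: str = CHESS_BASE):
    """The generic primary-alcohol -> aldehyde transformation.

    Input group class CCO, product group class CC=O, ruthenium-on-alumina
    agent (by InChI key), and the oxygen atom mapped across the reaction.
    """
    cco = fragment_class("CCO", base)
    ccdo = fragment_class("CC=O", base)
    o_in = group_atom_ref(cco, "O", 3)
    o_out = group_atom_ref(ccdo, "O", 3)
    return build_generic_reaction(
        input_groups=[cco], product_groups=[ccdo],
        agents=["http://semanticscience.org/resource/CHESS_"
                "KJFCCLURYALNSL-UHFFFAOYSA-N"],
        atom_maps=[(o_in, o_out)], base=base)


_PHENOL_PATTERN = Chem.MolFromSmarts("c1ccccc1[OX2H]")


def build_knowledgebase(fixtures: FixtureSet,
                        opts: EncodingOptions = EncodingOptions(),
                        include_reaction: bool = False,
                        register_phenols: bool = True) -> TripleGraph:
    """Encode a fixture set into one queryable triple graph.

    Molecules receiving bond-level annotations are encoded with explicit
    hydrogens (the annotated O-H bond must exist as an entity); phenol
    ring+OH groups are registered under the curated class ``chess:FGPhenol``.
    """
    g = TripleGraph()
    if include_reaction and not opts.type_atom_classes:
        from dataclasses import replace as _replace
        opts = _replace(opts, type_atom_classes=True)
    base = opts.base
    ann = fixtures.annotations
    by_smiles = (dict(tuple(ann.groupby("smiles"))) if len(ann) else {})

    for _, row in fixtures.molecules.iterrows():
        mol = parse_molecule(row.smiles, "smiles")
        numbering = canonical_numbering(mol)
        mol_ann = by_smiles.get(row.smiles)
        needs_h = mol_ann is not None and any(
            str(t).startswith("bond:") for t in mol_ann.target)
        if needs_h:
            from dataclasses import replace as _replace
            mol_opts = _replace(opts, include_hydrogens=True)
        else:
            mol_opts = opts

        extra = []
        if register_phenols:
            rd = mol.to_rdkit()
            for match in rd.GetSubstructMatches(_PHENOL_PATTERN):
                frag = register_custom_group(mol, numbering, list(match),
                                             chess_term("FGPhenol", base),
                                             base)
                extra.append(frag)
        encode_molecule(mol, numbering, mol_opts, graph=g,
                        extra_fragments=extra)
        for frag in extra:
            g.add(frag.uri, RDF.type, chess_term("FGPhenol", base).iri)
        if mol_ann is not None:
            _apply_annotations(g, mol, numbering, mol_ann, base)

    if include_reaction:
        encode_reaction(alcohol_oxidation_reaction(base), graph=g)
    return g


def _apply_annotations(g, mol, numbering, table, base):
    mol_ref = molecule_uri(numbering, base)
    for _, row in table.iterrows():
        target = str(row.target)
        provider = row.get("provider")
        config = None
        if provider is not None and not pd.isna(provider):
            config = ChemicalConfiguration({"provider": str(provider)})
        ttype = term(str(row.type))
        unit = row.get("unit")
        unit = None if unit is None or pd.isna(unit) else str(unit)

        if target == "molecule":
            if str(row.kind) == "variable":
                desc = make_variable_descriptor(
                    ttype, str(row.value), config
                    or ChemicalConfiguration({"provider": _PUBCHEM}),
                    unit=unit)
            else:
                desc = make_invariant_descriptor(ttype, str(row.value),
                                                 unit=unit)
            attach_descriptor(g, mol_ref, desc, base)
        elif target == "bond:O-H":
            owner = _hydroxyl_bond_uri(mol, numbering, base)
            if owner is None:
                continue
            desc = make_bde_annotation(
                str(row.value), unit or "kcal/mol",
                chess_term(str(row.method), base),
                (str(row.software_name), str(row.software_version)),
                params=[(term("temperature"), str(row.temperature),
                         term("kelvin"))])
            attach_descriptor(g, owner, desc, base)
        elif target.startswith("atom:"):
            input_idx = int(target.split(":", 1)[1])
            ci = numbering.heavy_map.get(input_idx)
            if ci is None:
                continue
            from .identifiers import atom_uri
            x, y, z = str(row.value).split(",")
            desc = make_coordinate_descriptor(
                x, y, z, term("angstrom"),
                config or ChemicalConfiguration({"provider": _PUBCHEM}))
            attach_descriptor(g, atom_uri(numbering, ci, base), desc, base)


def _hydroxyl_bond_uri(mol, numbering, base):
    """URI of the (first) O-H bond, on the explicit-hydrogen encoding."""
    work = mol.with_explicit_hydrogens()
    wnum = canonical_numbering(work)
    for bond in work.bonds:
        pair = {work.atoms[bond.a].element, work.atoms[bond.b].element}
        if pair == {"O", "H"}:
            ia = wnum.canonical_index(bond.a)
            ib = wnum.canonical_index(bond.b)
            return bond_uri(wnum, ia, ib, base)
    return None
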