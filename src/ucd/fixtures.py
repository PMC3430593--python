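"""Deterministic synthetic compound sets with known ground truth.

The generator writes SDF files whose records realize requested categories —
clean structures, auto-fixable drawing flaws, hard errors, duplicates under
atom renumbering, tautomer pairs, salt variants and No Structure entries —
together with a manifest stating, per record, what the registration pipeline
is expected to do with it.  Importing a generated file and comparing the
dispositions against the manifest is the system-level integration test.

Everything is a pure function of the seed: the same seed yields a
byte-identical file.
"""

from __future__ import annotations

import json
import random
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from rdkit import Chem

from ucd import _rdkit
from ucd import standardizer as _std
from ucd.chem_model import Bond, StructureRecord

__all__ = ["FixtureRecord", "FixtureManifest", "generate_fixtures", "CLEAN_SCAFFOLDS"]

#: clean, registration-ready structures; the first entries are the worked
#: compounds of the figure examples (2-cyanoacetic acid, a fully specified
#: 4-chloropentan-2-ol, alpha-D-glucopyranose as drawn from a Haworth
#: projection) followed by common drug-like and tobacco-relevant scaffolds.
#: Entries marked acidic can carry cationic counter-ions in salt variants.
CLEAN_SCAFFOLDS: List[Tuple[str, str, bool]] = [
    ("2-cyanoacetic acid", "N#CCC(=O)O", True),
    ("(2R,4R)-4-chloropentan-2-ol", "C[C@@H](O)C[C@@H](C)Cl", False),
    ("alpha-D-glucopyranose", "OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O", False),
    ("aspirin", "CC(=O)Oc1ccccc1C(=O)O", True),
    ("benzoic acid", "OC(=O)c1ccccc1", True),
    ("caffeine", "Cn1cnc2c1c(=O)n(C)c(=O)n2C", False),
    ("paracetamol", "CC(=O)Nc1ccc(O)cc1", False),
    ("nicotinic acid", "OC(=O)c1cccnc1", True),
    ("harmane", "Cc1nccc2c1[nH]c1ccccc12", False),
    ("furfural", "O=Cc1ccco1", False),
    ("L-phenylalanine", "N[C@@H](Cc1ccccc1)C(=O)O", True),
    ("menthol", "C[C@@H]1CC[C@H](C(C)C)[C@H](O)C1", False),
    ("ethyl acetate", "CCOC(=O)C", False),
    ("naphthalene", "c1ccc2ccccc2c1", False),
    ("sorbic acid", "C/C=C/C=C/C(=O)O", True),
    ("pyrazine", "c1cnccn1", False),
]

#: tautomer pairs whose drawings must collapse to one molecule
TAUTOMER_PAIRS: List[Tuple[str, str, str]] = [
    ("2-pyridone", "O=c1cccc[nH]1", "Oc1ccccn1"),
    ("4-methylimidazole", "Cc1c[nH]cn1", "Cc1cnc[nH]1"),
    ("2-pyridinethione", "S=c1cccc[nH]1", "Sc1ccccn1"),
]

CATEGORIES = (
    "clean",
    "fixable",
    "valence_error",
    "stereo_error",
    "duplicate",
    "tautomer_pair",
    "salt_variant",
    "no_structure",
)

CATIONIC_SALTS = ["sodium", "potassium", "lithium"]


@dataclass(frozen=True)
class FixtureRecord:
    """Ground truth for one SDF record."""

    index: int
    category: str
    name: str
    expected: str  # registered | registered-with-warnings | rejected
    expected_new_molecule: bool
    ref: Optional[int] = None  # index of the parent/duplicated record


@dataclass
class FixtureManifest:
    seed: int
    counts: Dict[str, int]
    records: List[FixtureRecord] = field(default_factory=list)

    @property
    def expected_molecules(self) -> int:
        return sum(1 for r in self.records if r.expected_new_molecule)

    @property
    def expected_registered(self) -> int:
        return sum(1 for r in self.records if r.expected != "rejected")

    @property
    def expected_rejected(self) -> int:
        return sum(1 for r in self.records if r.expected == "rejected")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "counts": self.counts,
                "records": [asdict(r) for r in self.records],
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# record builders


def _bend_triple_bond(record: StructureRecord) -> StructureRecord:
    """Distort the drawing so a nitrile is bent (a fixable flaw)."""
    coords = list(record.coords2d)
    neighbors: Dict[int, List[int]] = {}
    for b in record.bonds:
        neighbors.setdefault(b.i, []).append(b.j)
        neighbors.setdefault(b.j, []).append(b.i)
    for b in record.bonds:
        if b.order == 3:
            # move a terminal triple-bond atom off the axis
            terminal = b.i if len(neighbors[b.i]) == 1 else b.j
            x, y = coords[terminal]
            coords[terminal] = (x + 0.9, y + 0.9)
            break
    return replace(record, coords2d=tuple(coords))


def _doubled_wedge(record: StructureRecord) -> StructureRecord:
    """Add a redundant second wedge of the same direction at a stereocenter
    (a fixable flaw: one up and one down wedge suffice)."""
    wedged = next(b for b in record.bonds if b.wedge in ("up", "down"))
    for b in record.bonds:
        if b.wedge == "none" and b.order == 1 and wedged.i in (b.i, b.j):
            extra = (wedged.i, b.j if b.i == wedged.i else b.i)
            return record.with_wedges({extra: wedged.wedge})
    raise RuntimeError("no bond available for a redundant wedge")


def _misoriented_wedge(record: StructureRecord) -> StructureRecord:
    """Flip a wedge so its narrow end sits on the substituent instead of the
    stereocenter (fixable: the standardizer re-points it)."""
    wedged = next(b for b in record.bonds if b.wedge in ("up", "down"))
    return record.with_wedges({(wedged.j, wedged.i): wedged.wedge})


def _pentavalent_carbon() -> StructureRecord:
    from ucd.chem_model import Atom

    atoms = (Atom("C"),) + tuple(Atom("C", hydrogens=3) for _ in range(5))
    bonds = tuple(Bond(0, i) for i in range(1, 6))
    return StructureRecord(atoms=atoms, bonds=bonds)


def _wedge_on_non_stereocenter() -> StructureRecord:
    record = _std.parse_structure("CCC")
    return record.with_wedges({(record.bonds[0].i, record.bonds[0].j): "up"})


def _renumbered(record: StructureRecord, rng: random.Random) -> StructureRecord:
    """The same drawing under a random atom permutation."""
    mol, problems = _rdkit.record_to_mol(record)
    order = list(range(mol.GetNumAtoms()))
    rng.shuffle(order)
    shuffled = Chem.RenumberAtoms(mol, order)
    return _rdkit.mol_to_record(shuffled)


# ---------------------------------------------------------------------------


def generate_fixtures(
    seed: int, counts: Dict[str, int], path: str
) -> Tuple[str, FixtureManifest]:
    """Write an SDF realizing ``counts`` records per category (see
    :data:`CATEGORIES`; ``tautomer_pair`` counts pairs, i.e. two records
    each) plus its manifest.  Deterministic given the seed."""
    unknown = set(counts) - set(CATEGORIES)
    if unknown:
        raise ValueError(f"unknown fixture categories: {sorted(unknown)}")
    counts = {c: int(counts.get(c, 0)) for c in CATEGORIES}
    if any(v < 0 for v in counts.values()):
        raise ValueError("fixture counts must be non-negative")
    if not any(counts.values()):
        raise ValueError("at least one fixture category count must be positive")
    if counts["duplicate"] and not counts["clean"]:
        raise ValueError("duplicates need at least one clean record")
    if counts["salt_variant"] and not counts["clean"]:
        raise ValueError("salt variants need at least one clean record")

    rng = random.Random(seed)
    manifest = FixtureManifest(seed=seed, counts=dict(counts))
    entries: List[Tuple[FixtureRecord, StructureRecord, Dict[str, str]]] = []
    clean_indices: List[int] = []
    acid_indices: List[int] = []

    def metadata() -> Dict[str, str]:
        return {
            "project": rng.choice(["ALK-1", "FLAV-2", "TSNA-3", "LEAF-4"]),
            "scientist": rng.choice(["e.martin", "a.monge", "p.pospisil", "j.duret"]),
            "source": rng.choice(["synthesis", "purchase", "literature", "ms-peak"]),
        }

    seen_recipes: set = set()

    def add(category, name, record, expected, recipe=None, ref=None, extra=None):
        # a record mints a new molecule only the first time its recipe
        # appears (category counts may cycle through the scaffold lists)
        index = len(entries)
        if recipe is None:
            new_molecule = False
        else:
            new_molecule = recipe not in seen_recipes
            seen_recipes.add(recipe)
        rec = FixtureRecord(index, category, name, expected, new_molecule, ref)
        manifest.records.append(rec)
        entries.append((rec, record, {**metadata(), **(extra or {})}))
        return index

    scaffolds = list(CLEAN_SCAFFOLDS)
    for k in range(counts["clean"]):
        name, smiles, acidic = scaffolds[k % len(scaffolds)]
        record = _std.parse_structure(smiles)
        idx = add("clean", name, record, "registered",
                  recipe=("scaffold", k % len(scaffolds)))
        clean_indices.append(idx)
        if acidic:
            acid_indices.append(idx)

    fixable_builders = [
        ("bent nitrile",
         lambda rng: _bend_triple_bond(_std.parse_structure("N#CCCC(=O)O"))),
        ("doubled wedge",
         lambda rng: _doubled_wedge(_std.parse_structure("C[C@@H](O)CC"))),
        ("mis-oriented wedge",
         lambda rng: _misoriented_wedge(_std.parse_structure("C[C@H](O)c1ccccc1"))),
        ("charged carboxylate",
         lambda rng: _std.parse_structure("CCCC(=O)[O-]")),
    ]
    for k in range(counts["fixable"]):
        name, builder = fixable_builders[k % len(fixable_builders)]
        add("fixable", name, builder(rng), "registered-with-warnings",
            recipe=("fixable", k % len(fixable_builders)))

    for k in range(counts["valence_error"]):
        add("valence_error", "pentavalent carbon", _pentavalent_carbon(), "rejected")

    for k in range(counts["stereo_error"]):
        add("stereo_error", "wedge on non-stereocenter",
            _wedge_on_non_stereocenter(), "rejected")

    for k in range(counts["duplicate"]):
        ref = clean_indices[k % len(clean_indices)]
        src = entries[ref][1]
        add("duplicate", f"renumbered copy of record {ref}",
            _renumbered(src, rng), "registered", ref=ref)

    for k in range(counts["tautomer_pair"]):
        pair_idx = k % len(TAUTOMER_PAIRS)
        name, a, b = TAUTOMER_PAIRS[pair_idx]
        first = add("tautomer_pair", f"{name} (form A)", _std.parse_structure(a),
                    "registered", recipe=("tautomer", pair_idx))
        add("tautomer_pair", f"{name} (form B)", _std.parse_structure(b),
            "registered", ref=first)

    for k in range(counts["salt_variant"]):
        ref = acid_indices[k % len(acid_indices)] if acid_indices else clean_indices[0]
        salt = CATIONIC_SALTS[k % len(CATIONIC_SALTS)]
        add("salt_variant", f"{salt} salt of record {ref}", entries[ref][1],
            "registered", ref=ref, extra={"salt": salt})

    for k in range(counts["no_structure"]):
        # No Structure entries never merge: each one mints a molecule code
        add("no_structure", f"unidentified MS peak {k + 1}",
            StructureRecord(no_structure=True), "registered",
            recipe=("no-structure", k), extra={"no_structure": "1"})

    writer = Chem.SDWriter(path)
    for rec, record, fields in entries:
        if record.no_structure:
            mol = Chem.RWMol().GetMol()
        else:
            mol, problems = _rdkit.record_to_mol(record)
            try:
                Chem.ReapplyMolBlockWedging(mol)
            except Exception:
                pass
        mol.SetProp("_Name", rec.name)
        for key, value in fields.items():
            mol.SetProp(key, value)
        writer.write(mol)
    writer.close()
    return path, manifest
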