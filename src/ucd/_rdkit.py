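"""Conversion layer between :class:`~ucd.chem_model.StructureRecord` and
RDKit molecules, plus molfile/SMILES I/O.

The record keeps the *drawing* (graph, charges, wedges, 2D coordinates,
stereo groups); RDKit supplies perception (chirality from wedges, double-bond
stereo from coordinates, aromaticity) and the molfile writers.  Wedge
placement is preserved bit-for-bit through molblock round trips by carrying
the MDL wedge codes on bond properties.
"""

from __future__ import annotations

import contextlib
import io
from typing import Dict, List, Optional, Tuple

from rdkit import Chem, rdBase
from rdkit.Chem import rdDepictor
from rdkit.Geometry import Point3D

from ucd.chem_model import Atom, Bond, StereoGroup, StructureRecord

rdBase.DisableLog("rdApp.warning")
rdBase.DisableLog("rdApp.error")

# MDL V2000 wedge codes
_WEDGE_TO_V2000 = {"up": 1, "either": 4, "down": 6}
_V2000_TO_WEDGE = {v: k for k, v in _WEDGE_TO_V2000.items()}
# V3000 CFG codes
_V3000_TO_WEDGE = {1: "up", 2: "either", 3: "down"}

_WEDGE_TO_DIR = {
    "up": Chem.BondDir.BEGINWEDGE,
    "down": Chem.BondDir.BEGINDASH,
    "either": Chem.BondDir.UNKNOWN,
}

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
    "aromatic": Chem.BondType.AROMATIC,
}

_GROUP_TYPES = {
    "absolute": Chem.StereoGroupType.STEREO_ABSOLUTE,
    "and": Chem.StereoGroupType.STEREO_AND,
    "or": Chem.StereoGroupType.STEREO_OR,
}
_GROUP_KINDS = {v: k for k, v in _GROUP_TYPES.items()}


class ParseError(ValueError):
    """Structure text could not be parsed."""


def record_to_mol(record: StructureRecord, need_conformer: bool = True):
    """Build an RDKit molecule from a record.

    Returns ``(mol, problems)`` where ``problems`` is the list of
    sanitization issues (empty for a chemically valid record).  Stereo
    perception (wedges + 2D -> chiral tags, coordinates -> double-bond
    stereo) only runs on problem-free molecules.
    """
    if record.no_structure:
        raise ValueError("a No Structure record has no molecular graph")
    rw = Chem.RWMol()
    for a in record.atoms:
        try:
            atom = Chem.Atom(a.symbol)
        except Exception as exc:  # unknown element symbol
            raise ParseError(f"unknown element symbol {a.symbol!r}") from exc
        atom.SetFormalCharge(a.charge)
        if a.isotope:
            atom.SetIsotope(a.isotope)
        atom.SetNumExplicitHs(a.hydrogens)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for b in record.bonds:
        rw.AddBond(b.i, b.j, _BOND_TYPES[b.order])
        if b.order == "aromatic":
            rw.GetAtomWithIdx(b.i).SetIsAromatic(True)
            rw.GetAtomWithIdx(b.j).SetIsAromatic(True)
            rw.GetBondBetweenAtoms(b.i, b.j).SetIsAromatic(True)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    problems = list(Chem.DetectChemistryProblems(mol))
    if not problems:
        Chem.SanitizeMol(mol)

    if record.coords2d is not None:
        conf = Chem.Conformer(mol.GetNumAtoms())
        for i, (x, y) in enumerate(record.coords2d):
            conf.SetAtomPosition(i, Point3D(x, y, 0.0))
        conf.Set3D(False)
        mol.AddConformer(conf, assignId=True)
    elif need_conformer and not problems:
        rdDepictor.Compute2DCoords(mol)

    for b in record.bonds:
        if b.wedge != "none":
            bond = mol.GetBondBetweenAtoms(b.i, b.j)
            bond.SetBondDir(_WEDGE_TO_DIR[b.wedge])
            bond.SetIntProp("_MolFileBondStereo", _WEDGE_TO_V2000[b.wedge])

    if not problems and mol.GetNumConformers():
        Chem.AssignChiralTypesFromBondDirs(mol)
        Chem.DetectBondStereochemistry(mol)
        Chem.AssignStereochemistry(mol, cleanIt=True, force=True)

    if record.stereo_groups:
        mol = Chem.RWMol(mol)  # SetStereoGroups lives on the editable class
        groups = []
        for g in record.stereo_groups:
            groups.append(
                Chem.CreateStereoGroup(_GROUP_TYPES[g.kind], mol, list(g.atoms))
            )
        mol.SetStereoGroups(groups)
    return mol, problems


def mol_to_record(mol: Chem.Mol) -> StructureRecord:
    """Read an RDKit molecule (possibly unsanitized) back into a record."""
    if mol.GetNumAtoms() == 0:
        return StructureRecord(no_structure=True)
    try:
        mol.UpdatePropertyCache(strict=False)
    except Exception:
        pass
    atoms = []
    for a in mol.GetAtoms():
        atoms.append(
            Atom(
                symbol=a.GetSymbol(),
                charge=a.GetFormalCharge(),
                isotope=a.GetIsotope() or None,
                hydrogens=a.GetTotalNumHs(),
            )
        )
    bonds = []
    for b in mol.GetBonds():
        bt = b.GetBondType()
        if bt == Chem.BondType.AROMATIC:
            order = "aromatic"
        elif bt == Chem.BondType.DOUBLE:
            order = 2
        elif bt == Chem.BondType.TRIPLE:
            order = 3
        else:
            order = 1
        wedge = "none"
        if b.HasProp("_MolFileBondStereo"):
            wedge = _V2000_TO_WEDGE.get(b.GetIntProp("_MolFileBondStereo"), "none")
        elif b.HasProp("_MolFileBondCfg"):
            wedge = _V3000_TO_WEDGE.get(b.GetIntProp("_MolFileBondCfg"), "none")
        elif b.GetBondDir() == Chem.BondDir.BEGINWEDGE:
            wedge = "up"
        elif b.GetBondDir() == Chem.BondDir.BEGINDASH:
            wedge = "down"
        elif b.GetBondDir() == Chem.BondDir.UNKNOWN:
            wedge = "either"
        if wedge != "none" and order != 1:
            wedge = "none"  # squiggle markers on multiple bonds are dropped
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order, wedge))
    coords = None
    if mol.GetNumConformers():
        conf = mol.GetConformer()
        coords = tuple(
            (conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y)
            for i in range(mol.GetNumAtoms())
        )
    groups = []
    counters: Dict[str, int] = {}
    for g in mol.GetStereoGroups():
        kind = _GROUP_KINDS[g.GetGroupType()]
        counters[kind] = counters.get(kind, 0) + 1
        groups.append(
            StereoGroup(kind, tuple(a.GetIdx() for a in g.GetAtoms()), counters[kind])
        )
    return StructureRecord(
        atoms=tuple(atoms), bonds=tuple(bonds), coords2d=coords,
        stereo_groups=tuple(groups),
    )


@contextlib.contextmanager
def _capture_rdkit_errors():
    """Collect RDKit C++ log output so parse diagnostics (with line numbers)
    can be surfaced in exceptions."""
    stream = io.StringIO()
    rdBase.EnableLog("rdApp.error")
    rdBase.LogToPythonStderr()
    try:
        with contextlib.redirect_stderr(stream):
            yield stream
    finally:
        rdBase.LogToCppStreams()
        rdBase.DisableLog("rdApp.warning")
        rdBase.DisableLog("rdApp.error")


def molblock_to_record(text: str) -> StructureRecord:
    """Parse a V2000/V3000 molblock.  Chemically invalid but syntactically
    well-formed blocks (e.g. a pentavalent carbon) still yield a record so
    that validation can report them; syntax errors raise :class:`ParseError`.
    """
    if not text or not text.strip():
        raise ParseError("empty molfile input")
    with _capture_rdkit_errors() as stream:
        mol = Chem.MolFromMolBlock(text, sanitize=True, removeHs=True)
        if mol is None:
            mol = Chem.MolFromMolBlock(text, sanitize=False, removeHs=False)
    if mol is None:
        diag = stream.getvalue().strip().splitlines()
        raise ParseError(
            "molfile parse failure" + (f": {diag[-1]}" if diag else "")
        )
    return mol_to_record(mol)


def smiles_to_record(text: str) -> StructureRecord:
    """Parse SMILES (CXSMILES enhanced-stereo extensions accepted), generate
    a standard 2D depiction and wedge it, so the record is a drawing."""
    if not text or not text.strip():
        raise ParseError("empty SMILES input")
    with _capture_rdkit_errors() as stream:
        mol = Chem.MolFromSmiles(text)
    if mol is None:
        diag = stream.getvalue().strip().splitlines()
        raise ParseError("SMILES parse failure" + (f": {diag[-1]}" if diag else ""))
    rdDepictor.Compute2DCoords(mol)
    Chem.WedgeMolBonds(mol, mol.GetConformer())
    return mol_to_record(mol)


def parse_any(text: str) -> StructureRecord:
    """Auto-detect SMILES vs molfile: molblocks are multi-line with a counts
    line, SMILES is a single line."""
    if not text or not text.strip():
        raise ParseError("empty structure input")
    if "\n" in text.strip() or "V2000" in text or "V3000" in text:
        return molblock_to_record(text)
    return smiles_to_record(text.strip())


def record_to_molblock(record: StructureRecord, force_v3000: bool = False) -> str:
    """Write a molblock; V3000 whenever stereo groups are present."""
    if record.no_structure:
        return Chem.MolToMolBlock(Chem.RWMol().GetMol())
    mol, problems = record_to_mol(record)
    kekulize = not problems
    try:
        Chem.ReapplyMolBlockWedging(mol)
    except Exception:
        pass
    if record.stereo_groups or force_v3000:
        return Chem.MolToV3KMolBlock(mol, kekulize=kekulize)
    return Chem.MolToMolBlock(mol, kekulize=kekulize)


def canonical_ranks(mol: Chem.Mol, chirality: bool = False) -> List[int]:
    return list(Chem.CanonicalRankAtoms(mol, includeChirality=chirality))


def drawing_fingerprint(record: StructureRecord):
    """A hashable canonical form of the full drawing: canonical SMILES plus
    wedge and stereo-group multisets over canonical atom ranks.  Two records
    are the same drawing iff their fingerprints are equal, regardless of atom
    numbering."""
    if record.no_structure:
        return ("no-structure",)
    mol, problems = record_to_mol(record, need_conformer=True)
    if problems:
        # canonical SMILES needs a sanitized mol; fall back to a raw form
        smiles = Chem.MolToSmiles(mol, canonical=False)
        return ("unsanitized", smiles)
    ranks = canonical_ranks(mol, chirality=True)
    smiles = Chem.MolToSmiles(mol)
    wedges = tuple(
        sorted(
            (ranks[b.i], ranks[b.j], b.wedge)
            for b in record.bonds
            if b.wedge != "none"
        )
    )
    groups = tuple(
        sorted(
            (g.kind, tuple(sorted(ranks[a] for a in g.atoms)))
            for g in record.stereo_groups
        )
    )
    return (smiles, wedges, groups)


def stereocenter_status(mol: Chem.Mol) -> Dict[int, str]:
    """Map atom index -> 'specified' | 'unspecified' | 'unknown' for every
    potential tetrahedral stereocenter."""
    out: Dict[int, str] = {}
    try:
        elements = Chem.FindPotentialStereo(mol)
    except Exception:
        return out
    for el in elements:
        if el.type == Chem.StereoType.Atom_Tetrahedral:
            name = str(el.specified)
            out[int(el.centeredOn)] = {
                "Specified": "specified",
                "Unspecified": "unspecified",
                "Unknown": "unknown",
            }.get(name, "unspecified")
    return out


def double_bond_status(mol: Chem.Mol) -> List[Tuple[int, str, str]]:
    """List of (bond index, status, descriptor) for stereogenic double
    bonds."""
    out = []
    try:
        elements = Chem.FindPotentialStereo(mol)
    except Exception:
        return out
    for el in elements:
        if el.type == Chem.StereoType.Bond_Double:
            name = str(el.specified)
            status = {
                "Specified": "specified",
                "Unspecified": "unspecified",
                "Unknown": "unknown",
            }.get(name, "unspecified")
            out.append((int(el.centeredOn), status, str(el.descriptor)))
    return out
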