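"""Salt dictionary and theoretical-mass arithmetic.

A substance is a neutral molecule plus counter-ions and/or waters of
hydration at fixed stoichiometry.  Because the molecule is stored in its
neutral (protonated/deprotonated) form while the real salt pairs the ionized
form with the counter-ion, the substance mass is

    total = M(molecule) + sum(coeff_i * M(salt_i)) + n_water * M(H2O)
            - n_H * M(H)

where ``n_H`` is the signed number of molecule protons displaced by ionic
pairing: one proton is *removed* per unit of cationic counter-ion charge
(e.g. the sodium salt of an acid) and one proton is *added* per unit of
anionic counter-ion charge (e.g. an amine hydrochloride).  A permanently
charged molecule (quaternary ammonium) pairs its own charge with the
counter-ion and displaces no proton.

Atomic masses are average (standard) atomic weights, pinned in this module
so mass arithmetic is reproducible offline.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass
from fractions import Fraction
from importlib import resources
from typing import Dict, Iterable, Mapping, Optional, Sequence

from ucd import _rdkit
from ucd.chem_model import SaltEntry, StructureRecord, SubstanceComposition

__all__ = [
    "ATOMIC_WEIGHTS",
    "MassBreakdown",
    "SaltDictionaryError",
    "CompositionError",
    "formula_weight",
    "parse_formula",
    "molecular_formula",
    "molecular_mass",
    "substance_mass",
    "load_salt_dictionary",
    "default_salt_dictionary",
    "ionizable_sites",
]

# IUPAC standard atomic weights (conventional/abridged values), g/mol.
ATOMIC_WEIGHTS: Dict[str, float] = {
    "H": 1.008, "He": 4.003, "Li": 6.94, "Be": 9.012, "B": 10.81,
    "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998, "Ne": 20.180,
    "Na": 22.990, "Mg": 24.305, "Al": 26.982, "Si": 28.085, "P": 30.974,
    "S": 32.06, "Cl": 35.45, "Ar": 39.95, "K": 39.098, "Ca": 40.078,
    "Sc": 44.956, "Ti": 47.867, "V": 50.942, "Cr": 51.996, "Mn": 54.938,
    "Fe": 55.845, "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38,
    "Ga": 69.723, "Ge": 72.630, "As": 74.922, "Se": 78.971, "Br": 79.904,
    "Kr": 83.798, "Rb": 85.468, "Sr": 87.62, "Y": 88.906, "Zr": 91.224,
    "Mo": 95.95, "Ru": 101.07, "Rh": 102.906, "Pd": 106.42, "Ag": 107.868,
    "Cd": 112.414, "In": 114.818, "Sn": 118.710, "Sb": 121.760,
    "Te": 127.60, "I": 126.904, "Xe": 131.293, "Cs": 132.905,
    "Ba": 137.327, "W": 183.84, "Pt": 195.084, "Au": 196.967,
    "Hg": 200.592, "Tl": 204.38, "Pb": 207.2, "Bi": 208.980,
}

WATER_MASS = 2 * ATOMIC_WEIGHTS["H"] + ATOMIC_WEIGHTS["O"]
HYDROGEN_MASS = ATOMIC_WEIGHTS["H"]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


class SaltDictionaryError(ValueError):
    """A salt dictionary file is malformed or internally inconsistent."""


class CompositionError(ValueError):
    """A substance composition is not chemically consistent."""


@dataclass(frozen=True)
class MassBreakdown:
    """Itemized theoretical mass of a substance, g/mol.

    ``total == molecule + salt + hydrate + hydrogen_correction`` exactly.
    The correction is negative when molecule protons are displaced by
    cationic counter-ions, positive when anionic counter-ions protonate the
    molecule, and zero for neutral substances and permanent cations.
    """

    molecule: float
    salt: float = 0.0
    hydrate: float = 0.0
    hydrogen_correction: float = 0.0

    @property
    def total(self) -> float:
        return self.molecule + self.salt + self.hydrate + self.hydrogen_correction


def parse_formula(text: str) -> Dict[str, int]:
    """Parse a Hill-style formula string ('C2H3O2', 'Na') into an
    element -> count map."""
    text = text.strip()
    if not text:
        raise SaltDictionaryError("empty formula")
    out: Dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(text):
        if m.start() != pos:
            raise SaltDictionaryError(f"cannot parse formula {text!r}")
        pos = m.end()
        sym, count = m.group(1), int(m.group(2) or 1)
        if sym not in ATOMIC_WEIGHTS:
            raise SaltDictionaryError(f"unknown element {sym!r} in formula {text!r}")
        out[sym] = out.get(sym, 0) + count
    if pos != len(text):
        raise SaltDictionaryError(f"cannot parse formula {text!r}")
    return out


def formula_weight(formula: Mapping[str, int]) -> float:
    """Sum of standard atomic weights over an element->count map."""
    total = 0.0
    for sym, n in formula.items():
        if sym not in ATOMIC_WEIGHTS:
            raise CompositionError(f"unknown element symbol {sym!r}")
        total += ATOMIC_WEIGHTS[sym] * n
    return total


def molecular_formula(record: StructureRecord) -> Dict[str, int]:
    """Element->count map of a structure, hydrogens included."""
    if record.no_structure:
        raise CompositionError("a No Structure entry has no formula")
    out: Dict[str, int] = {}
    h = 0
    for a in record.atoms:
        out[a.symbol] = out.get(a.symbol, 0) + 1
        h += a.hydrogens
    if h:
        out["H"] = out.get("H", 0) + h
    return out


def molecular_mass(record: StructureRecord) -> float:
    """Average molecular mass of a structure (implicit hydrogens included)."""
    return formula_weight(molecular_formula(record))


def hill_formula(record: StructureRecord) -> str:
    """Hill-order formula string (C first, H second, rest alphabetical)."""
    counts = molecular_formula(record)
    parts = []
    for sym in ["C", "H"] + sorted(k for k in counts if k not in ("C", "H")):
        if sym in counts:
            n = counts[sym]
            parts.append(sym + (str(n) if n > 1 else ""))
    return "".join(parts)


# ---------------------------------------------------------------------------
# ionizable-site counting (for charge-balance checks)

_ACIDIC_SMARTS = [
    "[OX2H1][CX3]=[OX1]",          # carboxylic acid
    "[OX2H1][SX4](=[OX1])=[OX1]",  # sulfonic acid
    "[OX2H1][SX3]=[OX1]",          # sulfinic acid
    "[OX2H1][PX4]=[OX1]",          # phosphonic/phosphoric acid O-H
    "[OX2H1]c",                    # phenol
    "[SX2H1]",                     # thiol
    "[nH]",                        # azole / aromatic lactam N-H
]
_BASIC_SMARTS = [
    "[NX3;H2,H1,H0;!$(N[CX3]=[OX1]);!$(N[SX4](=O)=O);!$([N+]);!$(Na)]",  # amine
    "[nX2;!$([n+])]",              # pyridine-type aromatic nitrogen
]


def ionizable_sites(record: StructureRecord) -> Dict[str, int]:
    """Count acidic protons and basic sites of a neutral structure; used to
    check that a salt composition is chemically balanceable."""
    from rdkit import Chem

    mol, problems = _rdkit.record_to_mol(record, need_conformer=False)
    if problems:
        raise CompositionError("cannot count ionizable sites of an invalid structure")
    acidic = set()
    for smarts in _ACIDIC_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            acidic.add(match[0])
    basic = set()
    for smarts in _BASIC_SMARTS:
        patt = Chem.MolFromSmarts(smarts)
        for match in mol.GetSubstructMatches(patt):
            basic.add(match[0])
    return {"acidic": len(acidic), "basic": len(basic)}


# ---------------------------------------------------------------------------
# salt dictionary

#: mass consistency tolerance between a salt row's mass column and the
#: formula-weight of its formula column, g/mol
MASS_TOLERANCE = 1e-3


class SaltTable(dict):
    """Mapping of salt id -> :class:`SaltEntry`."""

    def require(self, salt_id: str) -> SaltEntry:
        if salt_id not in self:
            raise CompositionError(f"unknown salt id {salt_id!r}")
        return self[salt_id]


def _validate_entry(entry: SaltEntry) -> SaltEntry:
    expected = formula_weight(entry.formula)
    if abs(expected - entry.mass) > MASS_TOLERANCE:
        raise SaltDictionaryError(
            f"salt {entry.salt_id!r}: mass {entry.mass} disagrees with its "
            f"formula weight {expected:.3f}"
        )
    return entry


def load_salt_dictionary(path) -> SaltTable:
    """Load a delimiter-separated salt dictionary with columns
    id, name, formula, charge, mass.  Every row's mass is cross-checked
    against its formula weight; a mismatch beyond 1e-3 g/mol fails the load
    naming the entry."""
    table = SaltTable()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            warnings.warn(f"salt dictionary {path} is empty")
            return table
        required = {"id", "name", "formula", "charge", "mass"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise SaltDictionaryError(
                f"salt dictionary {path} lacks columns: {sorted(missing)}"
            )
        for row in reader:
            entry = SaltEntry(
                salt_id=row["id"].strip(),
                name=row["name"].strip(),
                formula=parse_formula(row["formula"]),
                charge=int(row["charge"]),
                mass=float(row["mass"]),
            )
            if entry.salt_id in table:
                raise SaltDictionaryError(f"duplicate salt id {entry.salt_id!r}")
            table[entry.salt_id] = _validate_entry(entry)
    if not table:
        warnings.warn(f"salt dictionary {path} contains no entries")
    return table


def default_salt_dictionary() -> SaltTable:
    """The shipped dictionary of common pharmaceutical counter-ions."""
    with resources.as_file(
        resources.files("ucd").joinpath("data/salts.tsv")
    ) as path:
        return load_salt_dictionary(path)


# ---------------------------------------------------------------------------
# substance mass

def substance_mass(
    structure: StructureRecord,
    composition: SubstanceComposition,
    salts: Optional[SaltTable] = None,
    permanent_cation: bool = False,
) -> MassBreakdown:
    """Theoretical mass of molecule + counter-ions + hydrate.

    The composition must be charge-balanced: cationic counter-ion charge is
    matched by acidic protons of the molecule, anionic counter-ion charge by
    basic sites (or by the molecule's own permanent positive charge, in
    which case no proton is displaced).
    """
    if salts is None:
        salts = default_salt_dictionary()
    mol_mass = molecular_mass(structure)
    if composition.is_neutral_form:
        return MassBreakdown(molecule=mol_mass)

    salt_mass = 0.0
    salt_charge = Fraction(0)
    for sid, coeff in composition.salt_parts:
        entry = salts.require(sid)
        salt_mass += float(coeff) * entry.mass
        salt_charge += coeff * entry.charge

    mol_charge = structure.net_charge()
    displaced = salt_charge + mol_charge  # protons displaced from the molecule
    if displaced != int(displaced):
        raise CompositionError(
            f"counter-ion stoichiometry leaves a fractional charge "
            f"({salt_charge}) unbalanced"
        )
    displaced = int(displaced)

    if permanent_cation or mol_charge > 0:
        if displaced != 0:
            raise CompositionError(
                "counter-ion charge does not balance the permanent cation"
            )
    elif displaced:
        sites = ionizable_sites(structure)
        if displaced > 0 and sites["acidic"] < displaced:
            raise CompositionError(
                f"composition needs {displaced} acidic proton(s) but the "
                f"molecule has {sites['acidic']}"
            )
        if displaced < 0 and sites["basic"] < -displaced:
            raise CompositionError(
                f"composition needs {-displaced} basic site(s) but the "
                f"molecule has {sites['basic']}"
            )

    return MassBreakdown(
        molecule=mol_mass,
        salt=salt_mass,
        hydrate=composition.hydrate_count * WATER_MASS,
        hydrogen_correction=-displaced * HYDROGEN_MASS,
    )
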