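"""Per-molecule physicochemical properties computed on registration.

Molecular weight comes from the same formula-weight arithmetic as the
substance masses (single source of truth); logP is the Crippen
atomic-contribution estimate; donor/acceptor counts use the N+O conventions
of the rule of five.  Two drug-likeness indicators are derived:

* Lipinski (rule of five): MW <= 500, logP <= 5, donors <= 5, acceptors <= 10.
* lead-like: MW <= 350, logP <= 3.5, rotatable bonds <= 7.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

from rdkit.Chem import Crippen, rdMolDescriptors

from ucd import _rdkit, substances
from ucd.chem_model import StructureRecord

__all__ = [
    "PropertySet",
    "compute_properties",
    "lipinski_pass",
    "leadlike_pass",
]

LIPINSKI_MW = 500.0
LIPINSKI_LOGP = 5.0
LIPINSKI_DONORS = 5
LIPINSKI_ACCEPTORS = 10
LEADLIKE_MW = 350.0
LEADLIKE_LOGP = 3.5
LEADLIKE_ROTATABLE = 7


def lipinski_pass(mw: float, logp: float, donors: int, acceptors: int) -> bool:
    return (
        mw <= LIPINSKI_MW
        and logp <= LIPINSKI_LOGP
        and donors <= LIPINSKI_DONORS
        and acceptors <= LIPINSKI_ACCEPTORS
    )


def leadlike_pass(mw: float, logp: float, rotatable: int) -> bool:
    return mw <= LEADLIKE_MW and logp <= LEADLIKE_LOGP and rotatable <= LEADLIKE_ROTATABLE


@dataclass(frozen=True)
class PropertySet:
    formula: str
    molecular_weight: float
    logp: float
    h_donors: int
    h_acceptors: int
    rotatable_bonds: int
    lipinski_pass: bool
    leadlike_pass: bool

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PropertySet":
        return cls(**d)


def compute_properties(record: StructureRecord) -> PropertySet:
    """Compute the molecule-level property table entry.

    Raises :class:`ValueError` for a No Structure entry — there is nothing
    to compute; the registry logs an audit note instead.
    """
    if record.no_structure:
        raise ValueError("properties are undefined for a No Structure entry")
    mol, problems = _rdkit.record_to_mol(record, need_conformer=False)
    if problems:
        raise ValueError("properties are undefined for an invalid structure")
    mw = substances.molecular_mass(record)
    logp = Crippen.MolLogP(mol)
    donors = rdMolDescriptors.CalcNumLipinskiHBD(mol)
    acceptors = rdMolDescriptors.CalcNumLipinskiHBA(mol)
    rotatable = rdMolDescriptors.CalcNumRotatableBonds(mol)
    return PropertySet(
        formula=substances.hill_formula(record),
        molecular_weight=mw,
        logp=logp,
        h_donors=donors,
        h_acceptors=acceptors,
        rotatable_bonds=rotatable,
        lipinski_pass=lipinski_pass(mw, logp, donors, acceptors),
        leadlike_pass=leadlike_pass(mw, logp, rotatable),
    )
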