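"""Structure standardization, validation and uniqueness keys.

Registration-quality structures follow a small set of drawing rules; this
module enforces them the way the registry's intake pipeline does:

1. **Neutralization** — molecules are stored as neutral entities.  Each
   ionizable charged atom is neutralized by adding (anions) or removing
   (cations) one hydrogen per unit of charge.  Nitrogen cations with no
   attached hydrogen (quaternary ammoniums and N-alkylated aromatic cations)
   are permanently charged independent of pH and are left untouched.
2. **Drawing fixes** — redundant wedges are dropped (a stereocenter needs at
   most one up and one down wedge), wedges are re-pointed so the narrow end
   sits on the stereocenter, and 2D coordinates are regenerated so triple
   bonds are drawn linearly and the depiction is non-perspective.
3. **Error detection** — valence violations, stereo bonds on bridging/ring
   fusion atoms, ambiguous or undeterminable stereocenters and unresolvable
   charges are reported; they cannot be auto-fixed and block registration.
4. **Canonical keys** — the identity key (``ucd_key``) digests the
   tautomer-canonicalized skeleton, a canonical serialization of
   stereocenters/stereo groups (including "either" and unspecified states
   that SMILES and InChI cannot carry), and the normalized mixture ratio.
"""

from __future__ import annotations

import hashlib
import math
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

from rdkit import Chem
from rdkit.Chem import inchi as rd_inchi
from rdkit.Chem import rdCIPLabeler, rdDepictor
from rdkit.Chem.MolStandardize import rdMolStandardize

from ucd import _rdkit
from ucd.chem_model import (
    Atom,
    CanonicalKeys,
    StructureRecord,
    normalize_ratio,
)
from ucd._rdkit import ParseError

__all__ = [
    "NormalizationResult",
    "ValidationIssue",
    "ValidationReport",
    "ParseError",
    "StandardizationError",
    "parse_structure",
    "neutralize",
    "standardize",
    "validate",
    "canonical_keys",
    "structure_key",
]


class StandardizationError(ValueError):
    """A structure cannot be brought to registration form."""


@dataclass(frozen=True)
class NormalizationResult:
    """Outcome of standardization: the fixed structure, the rule ids that
    fired, the net hydrogen change of neutralization, and whether the
    molecule is a permanent cation."""

    structure: StructureRecord
    applied_rules: Tuple[str, ...] = ()
    proton_delta: int = 0
    permanent_cation: bool = False


@dataclass(frozen=True)
class ValidationIssue:
    rule: str
    locus: str
    message: str


@dataclass(frozen=True)
class ValidationReport:
    errors: Tuple[ValidationIssue, ...] = ()
    warnings: Tuple[ValidationIssue, ...] = ()

    @property
    def ok(self) -> bool:
        """True when the structure is registrable (no errors)."""
        return not self.errors


# ---------------------------------------------------------------------------
# parsing


def parse_structure(text: str, dialect: str = "auto") -> StructureRecord:
    """Parse SMILES (with CXSMILES enhanced-stereo extensions) or a V2000 /
    V3000 molfile into a :class:`StructureRecord`.

    ``dialect`` may be ``"smiles"``, ``"molfile"`` or ``"auto"`` (detect:
    multi-line input is a molfile).
    """
    if dialect == "smiles":
        return _rdkit.smiles_to_record(text)
    if dialect in ("molfile", "molfile-auto"):
        return _rdkit.molblock_to_record(text)
    if dialect == "auto":
        return _rdkit.parse_any(text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# neutralization


def _neutralize_atoms(record: StructureRecord):
    """Per-atom charge neutralization.  Returns
    (new_record, proton_delta, permanent_cation, changed, failures) where
    failures lists atom indices whose charge cannot be resolved."""
    new_atoms: List[Atom] = []
    delta = 0
    permanent = False
    changed = False
    failures: List[int] = []
    for idx, a in enumerate(record.atoms):
        q = a.charge
        if q == 0:
            new_atoms.append(a)
            continue
        if q > 0:
            if a.symbol == "N" and a.hydrogens == 0:
                # quaternary ammonium (four non-H substituents) or an
                # N-alkylated aromatic cation: permanently charged.
                permanent = True
                new_atoms.append(a)
            elif a.hydrogens >= q:
                new_atoms.append(replace(a, charge=0, hydrogens=a.hydrogens - q))
                delta -= q
                changed = True
            else:
                failures.append(idx)
                new_atoms.append(a)
        else:
            new_atoms.append(replace(a, charge=0, hydrogens=a.hydrogens - q))
            delta += -q
            changed = True
    return (
        replace(record, atoms=tuple(new_atoms)),
        delta,
        permanent,
        changed,
        failures,
    )


def neutralize(record: StructureRecord) -> NormalizationResult:
    """Neutralize every ionizable charged atom (one hydrogen per unit of
    charge); quaternary ammonium nitrogens stay charged and are flagged.
    The heavy-atom graph is never touched — only H counts and formal charges
    change."""
    if record.no_structure:
        return NormalizationResult(record)
    new, delta, permanent, changed, failures = _neutralize_atoms(record)
    if failures:
        syms = ", ".join(f"{record.atoms[i].symbol}{i}" for i in failures)
        raise StandardizationError(
            f"charge on atom(s) {syms} can be neutralized neither by H "
            "addition nor removal and is not a recognized permanent cation"
        )
    rules = ("neutralize-charges",) if changed else ()
    return NormalizationResult(new, rules, delta, permanent)


# ---------------------------------------------------------------------------
# standardization


def _triple_bond_bent(record: StructureRecord) -> bool:
    """True when an atom on a triple-bond axis deviates from 180 degrees in
    the input drawing (e.g. a bent nitrile)."""
    if record.coords2d is None:
        return False
    neighbors = defaultdict(list)
    for b in record.bonds:
        neighbors[b.i].append(b.j)
        neighbors[b.j].append(b.i)
    for b in record.bonds:
        if b.order != 3:
            continue
        for center in (b.i, b.j):
            if len(neighbors[center]) != 2:
                continue
            n1, n2 = neighbors[center]
            ax, ay = record.coords2d[n1]
            bx, by = record.coords2d[center]
            cx, cy = record.coords2d[n2]
            v1 = (ax - bx, ay - by)
            v2 = (cx - bx, cy - by)
            n1n = math.hypot(*v1)
            n2n = math.hypot(*v2)
            if n1n < 1e-9 or n2n < 1e-9:
                continue
            cosang = (v1[0] * v2[0] + v1[1] * v2[1]) / (n1n * n2n)
            angle = math.degrees(math.acos(max(-1.0, min(1.0, cosang))))
            if abs(angle - 180.0) > 2.0:
                return True
    return False


def _clear_wedging(mol: Chem.Mol) -> None:
    for b in mol.GetBonds():
        b.SetBondDir(Chem.BondDir.NONE)
        for prop in ("_MolFileBondStereo", "_MolFileBondCfg"):
            if b.HasProp(prop):
                b.ClearProp(prop)


def standardize(record: StructureRecord) -> NormalizationResult:
    """Full standardization: neutralize, clean up wedges, regenerate a
    canonical 2D depiction (linear triple bonds, narrow wedge ends on the
    stereocenters, at most one wedge per center).  Idempotent: running it on
    its own output changes nothing and fires no rules."""
    if record.no_structure:
        return NormalizationResult(record)
    rules: List[str] = []
    s, delta, permanent, changed, failures = _neutralize_atoms(record)
    if changed:
        rules.append("neutralize-charges")
    if failures:
        # unresolvable charge: leave it; validate() reports the error
        s = record
        delta = 0

    mol, problems = _rdkit.record_to_mol(s)
    if problems:
        # chemically invalid (e.g. bad valence): nothing further can be
        # standardized; validate() is responsible for the report
        return NormalizationResult(s, tuple(rules), delta, permanent)

    centers = _rdkit.stereocenter_status(mol)

    # rule detection on the input drawing -------------------------------
    updown = defaultdict(lambda: {"up": 0, "down": 0})
    for b in s.bonds:
        if b.wedge in ("up", "down"):
            updown[b.i][b.wedge] += 1
    if any(c["up"] > 1 or c["down"] > 1 for c in updown.values()):
        rules.append("redundant-wedges")
    flips = {
        (b.j, b.i): b.wedge
        for b in s.bonds
        if b.wedge in ("up", "down") and b.i not in centers and b.j in centers
    }
    if flips:
        # re-point the wedge so the narrow end sits on the stereocenter; the
        # drawn meaning (substituent above/below the plane) is preserved
        rules.append("wedge-orientation")
        s = s.with_wedges(flips)
        mol, problems = _rdkit.record_to_mol(s)
        if problems:
            return NormalizationResult(s, tuple(rules), delta, permanent)
    if _triple_bond_bent(s):
        rules.append("linear-triple-bond")
    if s.coords2d is None:
        rules.append("depiction-generated")

    # canonical depiction regeneration ----------------------------------
    either_bonds = [(b.i, b.j) for b in s.bonds if b.wedge == "either"]
    _clear_wedging(mol)
    rdDepictor.Compute2DCoords(mol)
    Chem.WedgeMolBonds(mol, mol.GetConformer())
    out = _rdkit.mol_to_record(mol)
    if either_bonds:
        out = out.with_wedges({(i, j): "either" for i, j in either_bonds})
    return NormalizationResult(out, tuple(dict.fromkeys(rules)), delta, permanent)


# ---------------------------------------------------------------------------
# validation

#: elements whose valences the organic-subset check knows; anything else
#: passes with a warning.
ORGANIC_SUBSET = {
    "H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I",
}


def validate(record: StructureRecord) -> ValidationReport:
    """Report non-fixable problems (errors block registration) and advisory
    findings (warnings do not).

    Errors: valence violations, unresolvable charges, stereo bonds on
    bridging/ring-fusion atoms, wedges that determine no configuration.
    Warnings: exotic elements, potential stereocenters left unmarked.
    """
    errors: List[ValidationIssue] = []
    warnings: List[ValidationIssue] = []
    if record.no_structure:
        return ValidationReport()

    mol, problems = _rdkit.record_to_mol(record)
    for p in problems:
        locus = ""
        atom_idx = getattr(p, "GetAtomIdx", None)
        if atom_idx is not None:
            try:
                i = p.GetAtomIdx()
                locus = f"atom {i}"
                if record.atoms[i].symbol not in ORGANIC_SUBSET:
                    warnings.append(
                        ValidationIssue("exotic-element", locus, p.Message())
                    )
                    continue
            except Exception:
                pass
        errors.append(ValidationIssue("valence", locus, p.Message()))
    for i, a in enumerate(record.atoms):
        if a.symbol not in ORGANIC_SUBSET and not any(
            w.locus == f"atom {i}" for w in warnings
        ):
            warnings.append(
                ValidationIssue(
                    "exotic-element", f"atom {i}",
                    f"element {a.symbol} is outside the standard valence table",
                )
            )
    if errors:
        return ValidationReport(tuple(errors), tuple(warnings))

    # unresolvable charges ----------------------------------------------
    _, _, _, _, failures = _neutralize_atoms(record)
    for i in failures:
        errors.append(
            ValidationIssue(
                "charge-unresolvable", f"atom {i}",
                f"charge on {record.atoms[i].symbol}{i} cannot be neutralized",
            )
        )

    centers = _rdkit.stereocenter_status(mol)
    ring_info = mol.GetRingInfo()

    for b in record.bonds:
        if b.wedge == "none":
            continue
        bond = mol.GetBondBetweenAtoms(b.i, b.j)
        # stereo bond attached to a bridging / ring-fusion atom: the drawing
        # rules require explicit hydrogens there instead
        if bond.IsInRing() and ring_info.NumAtomRings(b.i) >= 2:
            errors.append(
                ValidationIssue(
                    "bridge-stereo", f"bond {b.i}-{b.j}",
                    "stereo bond attached to a bridging/ring-fusion atom",
                )
            )
            continue
        if b.wedge in ("up", "down"):
            if b.i not in centers and b.j not in centers:
                errors.append(
                    ValidationIssue(
                        "ambiguous-stereo", f"bond {b.i}-{b.j}",
                        "wedge bond on atoms that are not stereocenters",
                    )
                )
            elif b.i in centers and centers[b.i] == "unspecified":
                errors.append(
                    ValidationIssue(
                        "undetermined-stereo", f"atom {b.i}",
                        "the configuration of the stereocenter cannot be "
                        "determined from the wedges present",
                    )
                )

    wedged_atoms = {b.i for b in record.bonds if b.wedge != "none"}
    wedged_atoms |= {b.j for b in record.bonds if b.wedge == "either"}
    grouped = {a for g in record.stereo_groups for a in g.atoms}
    for idx, status in centers.items():
        if status == "unspecified" and idx not in wedged_atoms:
            warnings.append(
                ValidationIssue(
                    "unmarked-stereocenter", f"atom {idx}",
                    "potential stereocenter with no stereo annotation",
                )
            )
    for g in record.stereo_groups:
        for a in g.atoms:
            if centers.get(a, "none") not in ("specified",):
                errors.append(
                    ValidationIssue(
                        "stereo-group-member", f"atom {a}",
                        f"{g.kind} stereo group member carries no tetrahedral "
                        "configuration",
                    )
                )

    # de-duplicate (an issue may be found via more than one path)
    def _uniq(items):
        return tuple(dict.fromkeys(items))

    return ValidationReport(_uniq(errors), _uniq(warnings))


# ---------------------------------------------------------------------------
# canonical keys

_TAUTOMER_CANONICALIZER = rdMolStandardize.TautomerEnumerator()


def _skeleton_smiles(mol: Chem.Mol) -> str:
    """Tautomer-insensitive, stereo-free canonical SMILES of the neutral
    form: the constitution layer of the identity key."""
    skel = Chem.Mol(mol)
    Chem.RemoveStereochemistry(skel)
    skel = _TAUTOMER_CANONICALIZER.Canonicalize(skel)
    return Chem.MolToSmiles(skel)


def _stereo_tokens(record: StructureRecord, mol: Chem.Mol) -> List[str]:
    """Canonical serialization of stereocenters, double-bond stereo and
    stereo-group membership over canonical atom ranks (permutation
    invariant)."""
    ranks = _rdkit.canonical_ranks(mol, chirality=False)
    try:
        rdCIPLabeler.AssignCIPLabels(mol)
    except Exception:
        pass

    # normalize stereo-group ordinals by the sorted rank tuple of members
    group_of: Dict[int, str] = {}
    keyed = []
    for g in record.stereo_groups:
        keyed.append((g.kind, tuple(sorted(ranks[a] for a in g.atoms)), g))
    counters: Dict[str, int] = defaultdict(int)
    for kind, _, g in sorted(keyed, key=lambda t: (t[0], t[1])):
        if kind == "absolute":
            label = "abs"
        else:
            counters[kind] += 1
            label = f"{kind}{counters[kind]}"
        for a in g.atoms:
            group_of[a] = label

    either_atoms = set()
    for b in record.bonds:
        if b.wedge == "either":
            either_atoms.add(b.i)
            either_atoms.add(b.j)

    tokens: List[str] = []
    for idx, status in _rdkit.stereocenter_status(mol).items():
        atom = mol.GetAtomWithIdx(idx)
        if status == "specified":
            desc = atom.GetPropsAsDict().get("_CIPCode", "spec")
        elif status == "unknown" or idx in either_atoms:
            desc = "either"
        else:
            desc = "unspec"
        tokens.append(f"T{ranks[idx]}:{desc}:{group_of.get(idx, 'abs')}")
    for bidx, status, desc in _rdkit.double_bond_status(mol):
        bond = mol.GetBondWithIdx(bidx)
        lo, hi = sorted((ranks[bond.GetBeginAtomIdx()], ranks[bond.GetEndAtomIdx()]))
        if status != "specified":
            desc = "unspec" if status == "unspecified" else "either"
        tokens.append(f"D{lo}-{hi}:{desc}")
    return sorted(tokens)


def canonical_keys(
    record: StructureRecord, mixture_ratio: Optional[Sequence[int]] = None
) -> CanonicalKeys:
    """Compute the uniqueness keys of a standardized structure.

    The ``ucd_key`` is a digest of (tautomer-canonicalized skeleton,
    canonical stereo serialization, normalized mixture ratio): invariant
    under atom renumbering and tautomer redrawing, distinct across
    enhanced-stereo variants and mixture ratios.
    """
    if record.no_structure:
        raise StandardizationError("a No Structure entry has no chemical key")
    mol, problems = _rdkit.record_to_mol(record)
    if problems:
        raise StandardizationError(
            "structure has validation errors; keys are only defined for "
            "registrable structures"
        )
    smiles = Chem.MolToCXSmiles(
        mol, Chem.SmilesWriteParams(),
        Chem.rdmolfiles.CXSmilesFields.CX_ENHANCEDSTEREO,
    )
    inchi_str = rd_inchi.MolToInchi(mol, treatWarningAsError=False) or ""
    ratio = normalize_ratio(mixture_ratio)
    payload = "\n".join(
        [
            _skeleton_smiles(mol),
            ";".join(_stereo_tokens(record, mol)),
            ":".join(str(p) for p in ratio) if ratio else "-",
        ]
    )
    digest = hashlib.sha256(payload.encode()).hexdigest()
    return CanonicalKeys(canonical_smiles=smiles, inchi=inchi_str, ucd_key=digest)


def structure_key(record: StructureRecord) -> str:
    """The ratio-stripped identity key used by exact structure search: all
    mixture-ratio variants of one stereo drawing share it."""
    return canonical_keys(record, None).ucd_key
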