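"""Domain types for the compound registry.

The registry distinguishes three levels of chemical identity:

* **molecule** — the neutral, counter-ion-free, hydrate-free structure; the
  unit of uniqueness.  Each registered molecule owns a code like
  ``UCD01234567``.
* **substance** — a molecule paired with counter-ions and/or waters of
  hydration at fixed stoichiometry; coded by appending a letter
  (``UCD01234567-A``).
* **batch** — one occurrence of a substance (a physical sample, an MS
  identification, a literature reference) with its metadata; coded by an
  incrementing integer that doubles as the submission id.

This module defines the passive data carriers shared by every other module.
It contains no chemistry logic: parsing, standardization and key generation
live in :mod:`ucd.standardizer`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Optional, Sequence, Tuple

__all__ = [
    "Atom",
    "Bond",
    "StereoGroup",
    "StructureRecord",
    "CanonicalKeys",
    "Molecule",
    "SaltEntry",
    "SubstanceComposition",
    "Substance",
    "Batch",
    "AuditEvent",
    "User",
    "ROLES",
    "WEDGE_KINDS",
    "normalize_ratio",
    "substance_letter",
    "molecule_code",
]

ROLES = ("viewer", "submitter", "registrar")
WEDGE_KINDS = ("none", "up", "down", "either")
STEREO_GROUP_KINDS = ("absolute", "and", "or")


class ModelError(ValueError):
    """An invariant of a domain type was violated."""


@dataclass(frozen=True)
class Atom:
    """One heavy atom of a structure drawing.

    ``hydrogens`` is the total hydrogen count attached to the atom; drawings
    never carry explicit H atoms, so the count is part of the atom record.
    """

    symbol: str
    charge: int = 0
    isotope: Optional[int] = None
    hydrogens: int = 0


@dataclass(frozen=True)
class Bond:
    """A bond between atoms ``i`` and ``j`` (0-based indices).

    For wedge bonds the narrow end sits at atom ``i``.  ``order`` is 1, 2, 3
    or the string ``"aromatic"``.
    """

    i: int
    j: int
    order: object = 1
    wedge: str = "none"


@dataclass(frozen=True)
class StereoGroup:
    """An enhanced-stereochemistry collection (absolute / AND / OR).

    AND groups express a mixture of the drawn stereoisomer and its inverse at
    the member centers; OR groups express "one of the two, unknown which".
    These labels live in V3000 connection tables and cannot be expressed in
    plain SMILES or InChI, which is why the registry keys carry them
    separately.
    """

    kind: str
    atoms: Tuple[int, ...]
    ordinal: int = 1

    def __post_init__(self):
        if self.kind not in STEREO_GROUP_KINDS:
            raise ModelError(f"unknown stereo group kind: {self.kind!r}")


@dataclass(frozen=True)
class StructureRecord:
    """A chemical graph as drawn: atoms, bonds, wedges, 2D coordinates and
    stereo groups.  ``no_structure`` marks a registrable entry whose
    structure is unknown (e.g. an unidentified MS peak)."""

    atoms: Tuple[Atom, ...] = ()
    bonds: Tuple[Bond, ...] = ()
    coords2d: Optional[Tuple[Tuple[float, float], ...]] = None
    stereo_groups: Tuple[StereoGroup, ...] = ()
    no_structure: bool = False

    def __post_init__(self):
        object.__setattr__(self, "atoms", tuple(self.atoms))
        object.__setattr__(self, "bonds", tuple(self.bonds))
        if self.coords2d is not None:
            object.__setattr__(
                self, "coords2d", tuple((float(x), float(y)) for x, y in self.coords2d)
            )
        object.__setattr__(self, "stereo_groups", tuple(self.stereo_groups))
        self._check()

    def _check(self):
        n = len(self.atoms)
        if self.no_structure and (self.atoms or self.bonds):
            raise ModelError("a No Structure record must have no atoms or bonds")
        seen = set()
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n):
                raise ModelError(f"bond ({b.i},{b.j}) references a missing atom")
            if b.i == b.j:
                raise ModelError(f"self-bond on atom {b.i}")
            key = frozenset((b.i, b.j))
            if key in seen:
                raise ModelError(f"duplicate bond ({b.i},{b.j})")
            seen.add(key)
            if b.wedge not in WEDGE_KINDS:
                raise ModelError(f"unknown wedge kind: {b.wedge!r}")
            if b.wedge != "none" and b.order != 1:
                raise ModelError("wedge annotations are only valid on single bonds")
        if self.coords2d is not None and len(self.coords2d) != n:
            raise ModelError("coords2d length must match atom count")
        ordinals = {}
        for g in self.stereo_groups:
            for a in g.atoms:
                if not 0 <= a < n:
                    raise ModelError(f"stereo group references missing atom {a}")
            if g.ordinal in ordinals.setdefault(g.kind, set()):
                raise ModelError(f"duplicate {g.kind} stereo group ordinal {g.ordinal}")
            ordinals[g.kind].add(g.ordinal)

    # -- convenience ----------------------------------------------------

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    def net_charge(self) -> int:
        return sum(a.charge for a in self.atoms)

    def with_wedges(self, wedges: Mapping[Tuple[int, int], str]) -> "StructureRecord":
        """Return a copy with the wedge of listed bonds replaced; the key
        (i, j) is directional — the narrow end moves to ``i``."""
        new_bonds = []
        for b in self.bonds:
            if (b.i, b.j) in wedges:
                new_bonds.append(replace(b, wedge=wedges[(b.i, b.j)]))
            elif (b.j, b.i) in wedges:
                new_bonds.append(Bond(b.j, b.i, b.order, wedges[(b.j, b.i)]))
            else:
                new_bonds.append(b)
        return replace(self, bonds=tuple(new_bonds))

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "atoms": [[a.symbol, a.charge, a.isotope, a.hydrogens] for a in self.atoms],
            "bonds": [[b.i, b.j, b.order, b.wedge] for b in self.bonds],
            "coords2d": [list(c) for c in self.coords2d] if self.coords2d else None,
            "stereo_groups": [[g.kind, list(g.atoms), g.ordinal] for g in self.stereo_groups],
            "no_structure": self.no_structure,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StructureRecord":
        return cls(
            atoms=tuple(Atom(s, c, i, h) for s, c, i, h in d["atoms"]),
            bonds=tuple(Bond(i, j, o, w) for i, j, o, w in d["bonds"]),
            coords2d=tuple((x, y) for x, y in d["coords2d"]) if d.get("coords2d") else None,
            stereo_groups=tuple(StereoGroup(k, tuple(a), o) for k, a, o in d["stereo_groups"]),
            no_structure=d.get("no_structure", False),
        )

    def to_molfile(self) -> str:
        """Serialize as an MDL molfile.  V3000 is emitted whenever stereo
        groups are present (V2000 cannot express them), V2000 otherwise."""
        from ucd import _rdkit

        return _rdkit.record_to_molblock(self)

    @classmethod
    def from_molfile(cls, text: str) -> "StructureRecord":
        from ucd import _rdkit

        return _rdkit.molblock_to_record(text)

    def same_drawing(self, other: "StructureRecord") -> bool:
        """Graph isomorphism with matching charges, isotopes, H counts,
        wedges and stereo groups, insensitive to atom numbering."""
        from ucd import _rdkit

        return _rdkit.drawing_fingerprint(self) == _rdkit.drawing_fingerprint(other)


@dataclass(frozen=True)
class CanonicalKeys:
    """Uniqueness keys of a standardized structure.

    ``ucd_key`` is the registry's identity key: a digest of the
    tautomer-canonicalized skeleton, the canonical serialization of
    stereocenters and stereo groups, and the normalized mixture ratio.  It is
    invariant under atom renumbering and tautomer redrawing, and sensitive to
    enhanced-stereo labels that SMILES and InChI cannot carry.
    """

    canonical_smiles: str
    inchi: str
    ucd_key: str


def normalize_ratio(ratio: Optional[Sequence[int]]) -> Optional[Tuple[int, ...]]:
    """Reduce a stereoisomer mixture ratio by its GCD (50:50 -> 1:1)."""
    if ratio is None:
        return None
    parts = tuple(int(r) for r in ratio)
    if not parts or any(p <= 0 for p in parts):
        raise ModelError(f"mixture ratio parts must be positive: {ratio!r}")
    g = math.gcd(*parts)
    return tuple(p // g for p in parts)


def molecule_code(number: int, width: int = 8, prefix: str = "UCD") -> str:
    """Format a molecule code, e.g. ``molecule_code(1234567) == 'UCD01234567'``."""
    if number <= 0:
        raise ModelError("molecule numbers start at 1")
    return f"{prefix}{number:0{width}d}"


def substance_letter(index: int) -> str:
    """Letter suffix for the ``index``-th substance of a molecule (0-based):
    A..Z, then AA, AB, ..."""
    if index < 0:
        raise ModelError("substance index must be >= 0")
    letters = ""
    index += 1
    while index:
        index, rem = divmod(index - 1, 26)
        letters = chr(ord("A") + rem) + letters
    return letters


@dataclass
class Molecule:
    """A registered neutral structure with its unique code and keys."""

    code: str
    structure: StructureRecord
    keys: Optional[CanonicalKeys]
    mixture_ratio: Optional[Tuple[int, ...]] = None
    permanent_cation: bool = False
    status: str = "active"

    @property
    def no_structure(self) -> bool:
        return self.structure.no_structure


@dataclass(frozen=True)
class SaltEntry:
    """One row of the salt dictionary."""

    salt_id: str
    name: str
    formula: Mapping[str, int]
    charge: int
    mass: float


@dataclass(frozen=True)
class SubstanceComposition:
    """Counter-ions and waters of hydration attached to a molecule.

    ``salt_parts`` maps salt ids to positive stoichiometric coefficients
    (rationals, so hemisalts like 1/2 sulfate are expressible).
    """

    salt_parts: Tuple[Tuple[str, Fraction], ...] = ()
    hydrate_count: int = 0
    molecule_code: Optional[str] = None

    def __post_init__(self):
        parts = tuple(
            (str(sid), Fraction(coeff)) for sid, coeff in self.salt_parts
        )
        object.__setattr__(self, "salt_parts", parts)
        for sid, coeff in parts:
            if coeff <= 0:
                raise ModelError(f"stoichiometric coefficient for {sid} must be > 0")
        if self.hydrate_count < 0:
            raise ModelError("hydrate count must be >= 0")

    def identity(self) -> tuple:
        """Hashable identity: sorted salt parts plus hydrate count.  Both
        stoichiometry and hydrate count distinguish substances."""
        return (tuple(sorted(self.salt_parts)), self.hydrate_count)

    @property
    def is_neutral_form(self) -> bool:
        return not self.salt_parts and self.hydrate_count == 0


@dataclass
class Substance:
    """A molecule + composition with its letter-suffixed code."""

    code: str
    molecule_code: str
    composition: SubstanceComposition
    theoretical_mass: Optional[float] = None
    status: str = "active"


@dataclass
class Batch:
    """One occurrence of a substance.  ``code`` is the submission id."""

    code: int
    substance_code: str
    metadata: dict = field(default_factory=dict)
    restricted_fields: dict = field(default_factory=dict)  # team -> {field: value}
    status: str = "submitted"


@dataclass(frozen=True)
class AuditEvent:
    """Immutable record of one state transition.  The audit log is
    append-only; nothing in the registry is ever deleted."""

    timestamp: str
    actor: str
    action: str
    entity: str
    prior: Optional[str]
    new: Optional[str]
    reason: str = ""


@dataclass(frozen=True)
class User:
    user_id: str
    role: str
    team: str = ""

    def __post_init__(self):
        if self.role not in ROLES:
            raise ModelError(f"role must be one of {ROLES}, got {self.role!r}")
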