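"""Bulk SDF migration: import whole compound libraries through the same
standardization, validation and uniqueness path as manual entry, and export
registered entries back to SDF.

Each SDF record carries the structure (V2000 or V3000 connection table) and
data fields holding batch metadata, salt/hydrate composition and the mixture
ratio.  Records are processed independently: a malformed or invalid record
is rejected with its reasons and the import continues.  Structures are
expected in the file; migration from name lists is possible by passing a
``name_resolver`` callable that turns a name field into structure text.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Tuple

from rdkit import Chem

from ucd import _rdkit
from ucd import standardizer as _std
from ucd import substances as _sub
from ucd.chem_model import StructureRecord, SubstanceComposition
from ucd.registry import Registry, RegistryError, SubmissionRefused

__all__ = [
    "ImportReport",
    "Disposition",
    "DEFAULT_FIELD_MAP",
    "import_sdf",
    "export_sdf",
]

#: SDF data field -> submission slot.  The reserved targets ``salt``,
#: ``hydrate_count``, ``mixture_ratio``, ``no_structure`` and ``name`` feed
#: the composition/ratio/no-structure machinery; everything else is batch
#: metadata.  Unmapped fields are preserved verbatim under ``extra``.
DEFAULT_FIELD_MAP: Dict[str, str] = {
    "project": "project",
    "scientist": "scientist",
    "notebook_ref": "notebook_ref",
    "source": "source",
    "common_name": "common_name",
    "experimental_mw": "experimental_mw",
    "salt": "salt",
    "hydrate_count": "hydrate_count",
    "mixture_ratio": "mixture_ratio",
    "no_structure": "no_structure",
    "name": "name",
}

RESERVED = {"salt", "hydrate_count", "mixture_ratio", "no_structure", "name"}


@dataclass(frozen=True)
class Disposition:
    """Outcome of one SDF record."""

    index: int
    outcome: str  # registered | registered-with-warnings | submitted |
    #               submitted-with-warnings | rejected
    rules: Tuple[str, ...] = ()
    reasons: Tuple[str, ...] = ()
    molecule_code: Optional[str] = None
    substance_code: Optional[str] = None
    batch_code: Optional[int] = None


@dataclass
class ImportReport:
    """Aggregate import outcome; registered + registered_with_warnings +
    rejected always equals total."""

    total: int = 0
    registered: int = 0
    registered_with_warnings: int = 0
    rejected: int = 0
    dispositions: List[Disposition] = field(default_factory=list)

    def add(self, d: Disposition):
        self.dispositions.append(d)
        self.total += 1
        if d.outcome == "rejected":
            self.rejected += 1
        elif d.outcome.endswith("-with-warnings"):
            self.registered_with_warnings += 1
        else:
            self.registered += 1


def _parse_salt_field(text: str) -> Tuple[Tuple[str, Fraction], ...]:
    """'sodium' or 'sodium:1;chloride:1/2' -> salt parts."""
    parts = []
    for chunk in str(text).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if ":" in chunk:
            sid, coeff = chunk.split(":", 1)
            parts.append((sid.strip(), Fraction(coeff.strip())))
        else:
            parts.append((chunk, Fraction(1)))
    return tuple(parts)


def _record_inputs(props: dict, field_map: Dict[str, str]):
    """Split SDF data fields into (metadata, composition, ratio,
    no_structure, name) according to the field map."""
    metadata: dict = {}
    extra: dict = {}
    salt_parts: Tuple[Tuple[str, Fraction], ...] = ()
    hydrate = 0
    ratio = None
    no_structure = False
    name = None
    for key, value in props.items():
        target = field_map.get(key)
        if target is None:
            extra[key] = str(value)
        elif target == "salt":
            salt_parts = _parse_salt_field(value)
        elif target == "hydrate_count":
            hydrate = int(value)
        elif target == "mixture_ratio":
            ratio = tuple(int(p) for p in str(value).split(":"))
        elif target == "no_structure":
            no_structure = str(value).strip() in ("1", "true", "True", "yes")
        elif target == "name":
            name = str(value)
        else:
            metadata[target] = value
    if extra:
        metadata["extra"] = extra
    composition = SubstanceComposition(salt_parts=salt_parts, hydrate_count=hydrate)
    return metadata, composition, ratio, no_structure, name


def import_sdf(
    reg: Registry,
    path: str,
    actor: str,
    auto_approve: bool = False,
    field_map: Optional[Dict[str, str]] = None,
    name_resolver: Optional[Callable[[str], str]] = None,
) -> ImportReport:
    """Import every record of an SDF through parse -> standardize ->
    validate -> submit (-> approve when ``auto_approve``).  Uniqueness
    semantics are identical to manual entry: a record whose standardized
    structure matches a registered molecule lands under the existing code.
    """
    reg._require(actor, "registrar" if auto_approve else "submitter", "registrar")
    field_map = field_map or DEFAULT_FIELD_MAP
    report = ImportReport()
    supplier = Chem.ForwardSDMolSupplier(path, sanitize=False, removeHs=False)
    for index, mol in enumerate(supplier):
        if mol is None:
            report.add(
                Disposition(index, "rejected", reasons=("unparseable record",))
            )
            continue
        props = mol.GetPropsAsDict(includePrivate=False, includeComputed=False)
        try:
            metadata, composition, ratio, no_structure, name = _record_inputs(
                props, field_map
            )
            if name is not None and name_resolver is not None and mol.GetNumAtoms() == 0:
                record = _std.parse_structure(name_resolver(name))
            else:
                record = _rdkit.mol_to_record(mol)
            if record.no_structure:
                no_structure = True
            submission = reg.submit(
                actor,
                None if no_structure else record,
                no_structure=no_structure,
                composition=composition,
                mixture_ratio=ratio,
                metadata=metadata,
            )
            warned = bool(submission.normalized.applied_rules) or bool(
                submission.report.warnings
            )
            if auto_approve:
                batch = reg.decide_submission(actor, submission.id, True)
                substance = reg.substances[batch.substance_code]
                outcome = "registered-with-warnings" if warned else "registered"
                report.add(
                    Disposition(
                        index, outcome,
                        rules=submission.normalized.applied_rules,
                        molecule_code=substance.molecule_code,
                        substance_code=substance.code,
                        batch_code=batch.code,
                    )
                )
            else:
                outcome = "submitted-with-warnings" if warned else "submitted"
                report.add(
                    Disposition(
                        index, outcome,
                        rules=submission.normalized.applied_rules,
                        batch_code=submission.id,
                    )
                )
        except (SubmissionRefused, RegistryError, _std.ParseError,
                _std.StandardizationError, _sub.CompositionError,
                ValueError) as exc:
            report.add(Disposition(index, "rejected", reasons=(str(exc),)))
    return report


def export_sdf(
    reg: Registry,
    path: str,
    molecule_codes: Optional[Sequence[str]] = None,
    include_archived: bool = False,
) -> int:
    """Write one SDF record per batch (structure + codes + composition +
    metadata).  Returns the record count; V3000 connection tables are used
    whenever enhanced stereo is present.  Round-trips through
    :func:`import_sdf` to an equivalent registry."""
    selection = []
    for code in sorted(reg.batches):
        batch = reg.batches[code]
        if batch.status != "registered" and not include_archived:
            continue
        substance = reg.substances[batch.substance_code]
        molecule = reg.molecules[substance.molecule_code]
        if molecule_codes is not None and molecule.code not in molecule_codes:
            continue
        selection.append((batch, substance, molecule))

    force_v3000 = any(m.structure.stereo_groups for _, _, m in selection)
    writer = Chem.SDWriter(path)
    if force_v3000:
        writer.SetForceV3000(True)
    count = 0
    for batch, substance, molecule in selection:
        if molecule.no_structure:
            mol = Chem.RWMol().GetMol()
        else:
            mol, problems = _rdkit.record_to_mol(molecule.structure)
            try:
                Chem.ReapplyMolBlockWedging(mol)
            except Exception:
                pass
        mol.SetProp("_Name", molecule.code)
        mol.SetProp("molecule_code", molecule.code)
        mol.SetProp("substance_code", substance.code)
        mol.SetProp("batch_code", str(batch.code))
        if molecule.no_structure:
            mol.SetProp("no_structure", "1")
        if substance.composition.salt_parts:
            mol.SetProp(
                "salt",
                ";".join(
                    f"{sid}:{coeff}" for sid, coeff in substance.composition.salt_parts
                ),
            )
        if substance.composition.hydrate_count:
            mol.SetProp("hydrate_count", str(substance.composition.hydrate_count))
        if molecule.mixture_ratio:
            mol.SetProp("mixture_ratio", ":".join(map(str, molecule.mixture_ratio)))
        for key, value in batch.metadata.items():
            if key == "extra":
                for k, v in value.items():
                    mol.SetProp(k, str(v))
            else:
                mol.SetProp(key, str(value))
        writer.write(mol)
        count += 1
    writer.close()
    return count
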