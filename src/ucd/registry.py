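"""The registration workflow: submission area, registration area, codes,
uniqueness, roles and the archive-never-delete audit trail.

Data flows in two stages.  A *submitter* drafts a submission (structure +
composition + batch metadata); automatic standardization and validation run
at that point and the submitter approves the normalized form.  A *registrar*
reviews each submission and approves or rejects it.  On approval the
submission's data is copied into the registration area: the standardized
structure either matches an existing molecule's identity key (the batch
lands under the existing code) or mints the next molecule code; likewise the
composition either reuses an existing substance letter or mints the next
one.  The batch code is the submission id.

Nothing is ever deleted.  Batches can be archived or reassigned to another
substance; a substance left with no registered batch is archived, and a
molecule left with no active substance is archived in turn.  Every state
transition appends exactly one :class:`~ucd.chem_model.AuditEvent`.
"""

from __future__ import annotations

import datetime as _dt
import json
import sqlite3
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Dict, List, Optional, Sequence, Set, Tuple

from ucd import properties as _properties
from ucd import standardizer as _std
from ucd import substances as _sub
from ucd.chem_model import (
    AuditEvent,
    Batch,
    CanonicalKeys,
    Molecule,
    StructureRecord,
    Substance,
    SubstanceComposition,
    User,
    molecule_code,
    normalize_ratio,
    substance_letter,
)

__all__ = [
    "Registry",
    "Submission",
    "MetadataField",
    "DEFAULT_METADATA_SCHEMA",
    "MASKED",
    "RegistryError",
    "PermissionDenied",
    "AuthenticationError",
    "StateError",
    "SubmissionRefused",
]


class RegistryError(Exception):
    pass


class PermissionDenied(RegistryError):
    pass


class AuthenticationError(RegistryError):
    pass


class StateError(RegistryError):
    pass


class SubmissionRefused(RegistryError):
    """Submission rejected by automatic control; carries the reasons."""

    def __init__(self, message: str, report=None):
        super().__init__(message)
        self.report = report


#: sentinel returned when a restricted field is read by the wrong team
MASKED = "<restricted>"


@dataclass(frozen=True)
class MetadataField:
    """One field of the configurable batch-metadata schema."""

    name: str
    dtype: str = "str"  # 'str' | 'number'
    mandatory: bool = False
    restricted_team: Optional[str] = None


DEFAULT_METADATA_SCHEMA: Tuple[MetadataField, ...] = (
    MetadataField("project", mandatory=True),
    MetadataField("scientist", mandatory=True),
    MetadataField("notebook_ref"),
    MetadataField("source"),
    MetadataField("common_name"),
    MetadataField("experimental_mw", dtype="number"),
)


@dataclass
class Submission:
    """A submission-area record awaiting registrar review."""

    id: int
    submitter: str
    raw_text: Optional[str]
    record: StructureRecord
    normalized: _std.NormalizationResult
    report: _std.ValidationReport
    composition: SubstanceComposition
    mixture_ratio: Optional[Tuple[int, ...]]
    metadata: dict
    restricted_fields: dict
    normalization_approved: bool
    state: str = "draft"  # draft | submitted | approved | rejected
    reason: str = ""


def _now() -> str:
    return _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")


class Registry:
    """An in-process compound registry with optional sqlite persistence."""

    def __init__(
        self,
        salts: Optional[_sub.SaltTable] = None,
        metadata_schema: Sequence[MetadataField] = DEFAULT_METADATA_SCHEMA,
        code_width: int = 8,
        accept: Optional[Callable[[StructureRecord], bool]] = None,
    ):
        self.salts = salts if salts is not None else _sub.default_salt_dictionary()
        self.schema: Dict[str, MetadataField] = {f.name: f for f in metadata_schema}
        self.code_width = code_width
        #: registrability predicate (the workflow's "criteria table");
        #: default accepts everything parseable
        self.accept = accept or (lambda record: True)

        self.users: Dict[str, User] = {}
        self.submissions: Dict[int, Submission] = {}
        self.molecules: Dict[str, Molecule] = {}
        self.substances: Dict[str, Substance] = {}
        self.batches: Dict[int, Batch] = {}
        self.audit: List[AuditEvent] = []
        self.properties: Dict[str, _properties.PropertySet] = {}

        self._next_molecule = 1
        self._next_submission = 1
        self._key_index: Dict[str, str] = {}        # ucd_key -> molecule code
        self._structure_key: Dict[str, str] = {}    # molecule code -> ratio-free key
        self._search_cache: Dict[str, object] = {}  # used by ucd.search

    # -- users ----------------------------------------------------------

    def add_user(self, user_id: str, role: str, team: str = "") -> User:
        user = User(user_id, role, team)
        self.users[user_id] = user
        return user

    def _auth(self, user_id: str) -> User:
        if user_id not in self.users:
            raise AuthenticationError(f"unknown user {user_id!r}")
        return self.users[user_id]

    def _require(self, user_id: str, *roles: str) -> User:
        user = self._auth(user_id)
        if user.role not in roles:
            raise PermissionDenied(
                f"user {user_id!r} has role {user.role!r}; needs one of {roles}"
            )
        return user

    # -- audit ----------------------------------------------------------

    def _audit(self, actor, action, entity, prior, new, reason=""):
        self.audit.append(
            AuditEvent(_now(), actor, action, entity, prior, new, reason)
        )

    def replay_statuses(self) -> Dict[str, str]:
        """Reconstruct every entity's current status from the audit log
        alone (used to verify audit completeness)."""
        out: Dict[str, str] = {}
        for ev in self.audit:
            if ev.action == "reassign-batch":
                continue  # prior/new carry the substance assignment, not a status
            if ev.new is not None:
                out[ev.entity] = ev.new
        return out

    # -- metadata -------------------------------------------------------

    def _check_metadata(self, metadata: dict) -> dict:
        metadata = dict(metadata or {})
        for f in self.schema.values():
            if f.mandatory and not str(metadata.get(f.name, "") or "").strip():
                raise SubmissionRefused(f"mandatory metadata field {f.name!r} missing")
            if f.name in metadata and f.dtype == "number":
                value = metadata[f.name]
                try:
                    metadata[f.name] = float(value)
                except (TypeError, ValueError):
                    raise SubmissionRefused(
                        f"metadata field {f.name!r} accepts only numbers, "
                        f"got {value!r}"
                    )
        return metadata

    # -- submission -----------------------------------------------------

    def submit(
        self,
        user_id: str,
        structure: Optional[str] = None,
        *,
        no_structure: bool = False,
        composition: Optional[SubstanceComposition] = None,
        mixture_ratio: Optional[Sequence[int]] = None,
        metadata: Optional[dict] = None,
        restricted_fields: Optional[dict] = None,
        approve_normalization: bool = True,
    ) -> Submission:
        """Standardize, validate and place a new entry in the submission
        area.  Refused (with the validation report) when the structure has
        errors, mandatory metadata is missing, or the composition is
        inconsistent.  Nothing touches the registration area."""
        self._require(user_id, "submitter", "registrar")

        if no_structure:
            record = StructureRecord(no_structure=True)
            normalized = _std.NormalizationResult(record)
            report = _std.ValidationReport()
        else:
            if structure is None or structure == "":
                raise SubmissionRefused("no structure given and no_structure not set")
            if isinstance(structure, StructureRecord):
                record = structure
                if record.no_structure:
                    return self.submit(
                        user_id, no_structure=True, composition=composition,
                        metadata=metadata, restricted_fields=restricted_fields,
                        approve_normalization=approve_normalization,
                    )
            else:
                record = _std.parse_structure(structure)
            report = _std.validate(record)
            if not report.ok:
                msgs = "; ".join(e.message for e in report.errors)
                raise SubmissionRefused(f"structure has errors: {msgs}", report)
            normalized = _std.standardize(record)
        if not self.accept(record):
            raise SubmissionRefused("structure does not meet the registration criteria")

        metadata = self._check_metadata(metadata)
        composition = composition or SubstanceComposition()
        if not record.no_structure:
            # dry-run the mass arithmetic: resolves salt ids and checks
            # charge balance before the record enters the queue
            _sub.substance_mass(
                normalized.structure, composition, self.salts,
                permanent_cation=normalized.permanent_cation,
            )
        ratio = normalize_ratio(mixture_ratio)

        sid = self._next_submission
        self._next_submission += 1
        state = "submitted" if approve_normalization else "draft"
        sub = Submission(
            id=sid,
            submitter=user_id,
            raw_text=structure if isinstance(structure, str) else None,
            record=record,
            normalized=normalized,
            report=report,
            composition=composition,
            mixture_ratio=ratio,
            metadata=metadata,
            restricted_fields=dict(restricted_fields or {}),
            normalization_approved=approve_normalization,
            state=state,
        )
        self.submissions[sid] = sub
        self._audit(user_id, "submit", f"submission:{sid}", None, state)
        return sub

    def approve_normalization(self, user_id: str, submission_id: int) -> Submission:
        """Move a draft to the submitted state once the submitter accepts
        the normalized structure."""
        sub = self.submissions[submission_id]
        if user_id != sub.submitter:
            self._require(user_id, "registrar")
        if sub.state != "draft":
            raise StateError(f"submission {submission_id} is {sub.state}, not draft")
        sub.normalization_approved = True
        prior, sub.state = sub.state, "submitted"
        self._audit(user_id, "approve-normalization", f"submission:{sub.id}", prior, sub.state)
        return sub

    # -- registration ---------------------------------------------------

    def _resolve_molecule(
        self,
        actor: str,
        normalized: _std.NormalizationResult,
        ratio: Optional[Tuple[int, ...]],
    ) -> Molecule:
        record = normalized.structure
        if record.no_structure:
            # No Structure entries never merge: each gets its own code
            code = molecule_code(self._next_molecule, self.code_width)
            self._next_molecule += 1
            mol = Molecule(code, record, keys=None, mixture_ratio=None)
            self.molecules[code] = mol
            self._audit(actor, "register-molecule", f"molecule:{code}", None, "active",
                        "No Structure entry")
            self._audit(actor, "properties-skipped", f"molecule:{code}", None, None,
                        "No Structure entry has no computable properties")
            return mol
        keys = _std.canonical_keys(record, ratio)
        if keys.ucd_key in self._key_index:
            mol = self.molecules[self._key_index[keys.ucd_key]]
            if mol.status == "archived":
                mol.status = "active"
                self._audit(actor, "reactivate-molecule", f"molecule:{mol.code}",
                            "archived", "active")
            return mol
        code = molecule_code(self._next_molecule, self.code_width)
        self._next_molecule += 1
        mol = Molecule(
            code, record, keys=keys, mixture_ratio=ratio,
            permanent_cation=normalized.permanent_cation,
        )
        self.molecules[code] = mol
        self._key_index[keys.ucd_key] = code
        self._structure_key[code] = _std.structure_key(record)
        self.properties[code] = _properties.compute_properties(record)
        self._audit(actor, "register-molecule", f"molecule:{code}", None, "active")
        return mol

    def _substances_of(self, molecule_code_: str) -> List[Substance]:
        return [s for s in self.substances.values() if s.molecule_code == molecule_code_]

    def _resolve_substance(
        self,
        actor: str,
        mol: Molecule,
        composition: SubstanceComposition,
        permanent_cation: bool,
    ) -> Substance:
        existing = self._substances_of(mol.code)
        for sub in existing:
            if sub.composition.identity() == composition.identity():
                if sub.status == "archived":
                    sub.status = "active"
                    self._audit(actor, "reactivate-substance", f"substance:{sub.code}",
                                "archived", "active")
                return sub
        letter = substance_letter(len(existing))
        code = f"{mol.code}-{letter}"
        mass = None
        if not mol.no_structure:
            mass = _sub.substance_mass(
                mol.structure, composition, self.salts,
                permanent_cation=permanent_cation,
            ).total
        sub = Substance(code, mol.code, composition, theoretical_mass=mass)
        self.substances[code] = sub
        self._audit(actor, "register-substance", f"substance:{code}", None, "active")
        return sub

    def decide_submission(
        self, user_id: str, submission_id: int, approve: bool, reason: str = ""
    ):
        """Registrar review: approve (copy into the registration area under
        the uniqueness rules) or reject (the submitter may modify and
        resubmit under a fresh id)."""
        self._require(user_id, "registrar")
        if submission_id not in self.submissions:
            raise StateError(f"no submission {submission_id}")
        sub = self.submissions[submission_id]
        if sub.state != "submitted":
            raise StateError(
                f"submission {submission_id} is {sub.state!r}; only submitted "
                "entries can be decided"
            )
        if not approve:
            prior, sub.state = sub.state, "rejected"
            sub.reason = reason
            self._audit(user_id, "reject", f"submission:{sub.id}", prior, "rejected", reason)
            return sub

        prior, sub.state = sub.state, "approved"
        self._audit(user_id, "approve", f"submission:{sub.id}", prior, "approved", reason)
        mol = self._resolve_molecule(user_id, sub.normalized, sub.mixture_ratio)
        substance = self._resolve_substance(
            user_id, mol, sub.composition, sub.normalized.permanent_cation
        )
        batch = Batch(
            code=sub.id,
            substance_code=substance.code,
            metadata=dict(sub.metadata),
            restricted_fields=dict(sub.restricted_fields),
            status="registered",
        )
        self.batches[batch.code] = batch
        self._audit(user_id, "register-batch", f"batch:{batch.code}", "submitted",
                    "registered")
        return batch

    # -- reassignment & archiving ---------------------------------------

    def _cascade_archive(self, actor: str, substance_code: str, reason: str = ""):
        sub = self.substances[substance_code]
        live = [
            b for b in self.batches.values()
            if b.substance_code == substance_code and b.status == "registered"
        ]
        if live or sub.status == "archived":
            return
        sub.status = "archived"
        self._audit(actor, "archive-substance", f"substance:{sub.code}",
                    "active", "archived", reason)
        mol = self.molecules[sub.molecule_code]
        if all(s.status == "archived" for s in self._substances_of(mol.code)):
            mol.status = "archived"
            self._audit(actor, "archive-molecule", f"molecule:{mol.code}",
                        "active", "archived", reason)

    def reassign_batch(
        self,
        user_id: str,
        batch_code: int,
        *,
        structure: Optional[str] = None,
        no_structure: bool = False,
        composition: Optional[SubstanceComposition] = None,
        mixture_ratio: Optional[Sequence[int]] = None,
        reason: str = "",
    ) -> Batch:
        """Move a registered batch to a different substance (minting a new
        molecule/substance if the target is new chemistry), then archive the
        emptied source substance/molecule.  Nothing is deleted."""
        self._require(user_id, "registrar")
        if batch_code not in self.batches:
            raise StateError(f"no batch {batch_code}")
        batch = self.batches[batch_code]
        if batch.status != "registered":
            raise StateError(f"batch {batch_code} is {batch.status!r}, not registered")

        if no_structure:
            record = StructureRecord(no_structure=True)
            normalized = _std.NormalizationResult(record)
        else:
            if structure is None:
                raise StateError("reassignment target needs a structure or no_structure")
            record = _std.parse_structure(structure)
            report = _std.validate(record)
            if not report.ok:
                msgs = "; ".join(e.message for e in report.errors)
                raise SubmissionRefused(f"target structure has errors: {msgs}", report)
            normalized = _std.standardize(record)
        composition = composition or SubstanceComposition()
        ratio = normalize_ratio(mixture_ratio)

        mol = self._resolve_molecule(user_id, normalized, ratio)
        target = self._resolve_substance(
            user_id, mol, composition, normalized.permanent_cation
        )
        old = batch.substance_code
        if target.code == old:
            return batch
        batch.substance_code = target.code
        self._audit(user_id, "reassign-batch", f"batch:{batch.code}", old,
                    target.code, reason)
        self._cascade_archive(user_id, old, reason)
        return batch

    def archive_batch(self, user_id: str, batch_code: int, reason: str = "") -> Batch:
        """Archive a registered batch; the record is retained and emptied
        parents are cascade-archived."""
        self._require(user_id, "registrar")
        if batch_code not in self.batches:
            raise StateError(f"no batch {batch_code}")
        batch = self.batches[batch_code]
        if batch.status != "registered":
            raise StateError(f"batch {batch_code} is {batch.status!r}, not registered")
        batch.status = "archived"
        self._audit(user_id, "archive-batch", f"batch:{batch.code}", "registered",
                    "archived", reason)
        self._cascade_archive(user_id, batch.substance_code, reason)
        return batch

    # -- access control --------------------------------------------------

    def enforce_access(self, user_id: str, batch_code: int, field_name: str):
        """Return the field value, or :data:`MASKED` when it is restricted
        to another team."""
        user = self._auth(user_id)
        if batch_code not in self.batches:
            raise StateError(f"no batch {batch_code}")
        batch = self.batches[batch_code]
        for team, fields in batch.restricted_fields.items():
            if field_name in fields:
                return fields[field_name] if user.team == team else MASKED
        return batch.metadata.get(field_name)

    # -- queries ----------------------------------------------------------

    def batches_of_substance(self, substance_code: str) -> List[Batch]:
        return [b for b in self.batches.values() if b.substance_code == substance_code]

    def audit_for(self, entity: str) -> List[AuditEvent]:
        return [ev for ev in self.audit if ev.entity == entity]

    def refresh_properties(self) -> int:
        """Recompute the property table for every active molecule (the
        overnight job).  Returns the number of molecules refreshed."""
        n = 0
        for mol in self.molecules.values():
            if mol.no_structure:
                continue
            self.properties[mol.code] = _properties.compute_properties(mol.structure)
            n += 1
        return n

    # -- persistence ------------------------------------------------------

    def save(self, path: str) -> None:
        """Persist the registry to an embedded sqlite database (submission
        and registration areas in separate tables)."""
        con = sqlite3.connect(path)
        cur = con.cursor()
        cur.executescript(
            """
            DROP TABLE IF EXISTS users; DROP TABLE IF EXISTS submissions;
            DROP TABLE IF EXISTS molecules; DROP TABLE IF EXISTS substances;
            DROP TABLE IF EXISTS batches; DROP TABLE IF EXISTS audit;
            DROP TABLE IF EXISTS counters; DROP TABLE IF EXISTS properties;
            CREATE TABLE users (id TEXT PRIMARY KEY, role TEXT, team TEXT);
            CREATE TABLE submissions (id INTEGER PRIMARY KEY, data TEXT);
            CREATE TABLE molecules (
                code TEXT PRIMARY KEY, structure TEXT, smiles TEXT, inchi TEXT,
                ucd_key TEXT, structure_key TEXT, ratio TEXT,
                permanent_cation INTEGER, status TEXT);
            CREATE TABLE substances (
                code TEXT PRIMARY KEY, molecule_code TEXT, composition TEXT,
                mass REAL, status TEXT);
            CREATE TABLE batches (
                code INTEGER PRIMARY KEY, substance_code TEXT, metadata TEXT,
                restricted TEXT, status TEXT);
            CREATE TABLE audit (
                seq INTEGER PRIMARY KEY, ts TEXT, actor TEXT, action TEXT,
                entity TEXT, prior TEXT, new TEXT, reason TEXT);
            CREATE TABLE properties (code TEXT PRIMARY KEY, data TEXT);
            CREATE TABLE counters (name TEXT PRIMARY KEY, value INTEGER);
            """
        )
        for u in self.users.values():
            cur.execute("INSERT INTO users VALUES (?,?,?)", (u.user_id, u.role, u.team))
        for s in self.submissions.values():
            cur.execute(
                "INSERT INTO submissions VALUES (?,?)",
                (s.id, json.dumps(_submission_to_json(s))),
            )
        for m in self.molecules.values():
            cur.execute(
                "INSERT INTO molecules VALUES (?,?,?,?,?,?,?,?,?)",
                (
                    m.code,
                    json.dumps(m.structure.to_dict()),
                    m.keys.canonical_smiles if m.keys else None,
                    m.keys.inchi if m.keys else None,
                    m.keys.ucd_key if m.keys else None,
                    self._structure_key.get(m.code),
                    ":".join(map(str, m.mixture_ratio)) if m.mixture_ratio else None,
                    int(m.permanent_cation),
                    m.status,
                ),
            )
        for s in self.substances.values():
            cur.execute(
                "INSERT INTO substances VALUES (?,?,?,?,?)",
                (s.code, s.molecule_code, json.dumps(_composition_to_json(s.composition)),
                 s.theoretical_mass, s.status),
            )
        for b in self.batches.values():
            cur.execute(
                "INSERT INTO batches VALUES (?,?,?,?,?)",
                (b.code, b.substance_code, json.dumps(b.metadata),
                 json.dumps(b.restricted_fields), b.status),
            )
        for i, ev in enumerate(self.audit):
            cur.execute(
                "INSERT INTO audit VALUES (?,?,?,?,?,?,?,?)",
                (i, ev.timestamp, ev.actor, ev.action, ev.entity, ev.prior,
                 ev.new, ev.reason),
            )
        for code, props in self.properties.items():
            cur.execute(
                "INSERT INTO properties VALUES (?,?)",
                (code, json.dumps(props.to_dict())),
            )
        cur.execute("INSERT INTO counters VALUES ('molecule', ?)", (self._next_molecule,))
        cur.execute("INSERT INTO counters VALUES ('submission', ?)", (self._next_submission,))
        con.commit()
        con.close()

    @classmethod
    def load(cls, path: str, **kwargs) -> "Registry":
        reg = cls(**kwargs)
        con = sqlite3.connect(path)
        cur = con.cursor()
        for uid, role, team in cur.execute("SELECT id, role, team FROM users"):
            reg.users[uid] = User(uid, role, team)
        for sid, data in cur.execute("SELECT id, data FROM submissions"):
            reg.submissions[sid] = _submission_from_json(json.loads(data))
        for row in cur.execute(
            "SELECT code, structure, smiles, inchi, ucd_key, structure_key, "
            "ratio, permanent_cation, status FROM molecules"
        ):
            code, structure, smiles, inchi, key, skey, ratio, perm, status = row
            record = StructureRecord.from_dict(json.loads(structure))
            keys = CanonicalKeys(smiles, inchi, key) if key else None
            mol = Molecule(
                code, record, keys,
                mixture_ratio=tuple(int(p) for p in ratio.split(":")) if ratio else None,
                permanent_cation=bool(perm), status=status,
            )
            reg.molecules[code] = mol
            if key:
                reg._key_index[key] = code
            if skey:
                reg._structure_key[code] = skey
        for code, mcode, comp, mass, status in cur.execute(
            "SELECT code, molecule_code, composition, mass, status FROM substances"
        ):
            reg.substances[code] = Substance(
                code, mcode, _composition_from_json(json.loads(comp)), mass, status
            )
        for code, scode, meta, restricted, status in cur.execute(
            "SELECT code, substance_code, metadata, restricted, status FROM batches"
        ):
            reg.batches[code] = Batch(
                code, scode, json.loads(meta), json.loads(restricted), status
            )
        for _, ts, actor, action, entity, prior, new, reason in cur.execute(
            "SELECT seq, ts, actor, action, entity, prior, new, reason "
            "FROM audit ORDER BY seq"
        ):
            reg.audit.append(AuditEvent(ts, actor, action, entity, prior, new, reason))
        for code, data in cur.execute("SELECT code, data FROM properties"):
            reg.properties[code] = _properties.PropertySet.from_dict(json.loads(data))
        for name, value in cur.execute("SELECT name, value FROM counters"):
            if name == "molecule":
                reg._next_molecule = value
            elif name == "submission":
                reg._next_submission = value
        con.close()
        return reg


# ---------------------------------------------------------------------------
# JSON helpers for persistence


def _composition_to_json(c: SubstanceComposition) -> dict:
    return {
        "salt_parts": [[sid, str(coeff)] for sid, coeff in c.salt_parts],
        "hydrate_count": c.hydrate_count,
    }


def _composition_from_json(d: dict) -> SubstanceComposition:
    return SubstanceComposition(
        salt_parts=tuple((sid, Fraction(coeff)) for sid, coeff in d["salt_parts"]),
        hydrate_count=d["hydrate_count"],
    )


def _submission_to_json(s: Submission) -> dict:
    return {
        "id": s.id,
        "submitter": s.submitter,
        "raw_text": s.raw_text,
        "record": s.record.to_dict(),
        "normalized": {
            "structure": s.normalized.structure.to_dict(),
            "applied_rules": list(s.normalized.applied_rules),
            "proton_delta": s.normalized.proton_delta,
            "permanent_cation": s.normalized.permanent_cation,
        },
        "composition": _composition_to_json(s.composition),
        "mixture_ratio": list(s.mixture_ratio) if s.mixture_ratio else None,
        "metadata": s.metadata,
        "restricted_fields": s.restricted_fields,
        "normalization_approved": s.normalization_approved,
        "state": s.state,
        "reason": s.reason,
    }


def _submission_from_json(d: dict) -> Submission:
    return Submission(
        id=d["id"],
        submitter=d["submitter"],
        raw_text=d["raw_text"],
        record=StructureRecord.from_dict(d["record"]),
        normalized=_std.NormalizationResult(
            StructureRecord.from_dict(d["normalized"]["structure"]),
            tuple(d["normalized"]["applied_rules"]),
            d["normalized"]["proton_delta"],
            d["normalized"]["permanent_cation"],
        ),
        report=_std.ValidationReport(),
        composition=_composition_from_json(d["composition"]),
        mixture_ratio=tuple(d["mixture_ratio"]) if d["mixture_ratio"] else None,
        metadata=d["metadata"],
        restricted_fields=d["restricted_fields"],
        normalization_approved=d["normalization_approved"],
        state=d["state"],
        reason=d["reason"],
    )
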