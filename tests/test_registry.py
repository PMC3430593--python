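"""Workflow, uniqueness, roles, cascades and the audit trail."""

import random

import pytest

from ucd.chem_model import SubstanceComposition
from ucd.registry import (
    MASKED,
    AuthenticationError,
    PermissionDenied,
    Registry,
    StateError,
    SubmissionRefused,
)
from tests.conftest import register


class TestSubmission:
    def test_charged_structure_normalized_on_submit(self, registry, meta):
        sub = registry.submit(
            "alice", "N#CCC(=O)[O-]",
            composition=SubstanceComposition(salt_parts=(("sodium", 1),)),
            metadata=meta,
        )
        assert sub.state == "submitted"
        assert "neutralize-charges" in sub.normalized.applied_rules
        assert sub.normalized.structure.net_charge() == 0
        assert sub.record.net_charge() == -1  # raw form kept alongside

    def test_viewer_cannot_submit(self, registry, meta):
        with pytest.raises(PermissionDenied):
            registry.submit("vera", "CCO", metadata=meta)

    def test_non_numeric_experimental_mw_refused(self, registry, meta):
        with pytest.raises(SubmissionRefused, match="number"):
            registry.submit(
                "alice", "CCO", metadata={**meta, "experimental_mw": "heavy"}
            )

    def test_missing_mandatory_metadata_refused(self, registry):
        with pytest.raises(SubmissionRefused, match="project"):
            registry.submit("alice", "CCO", metadata={"scientist": "alice"})

    def test_validation_errors_refuse_with_report(self, registry, meta):
        from ucd.fixtures import _pentavalent_carbon

        with pytest.raises(SubmissionRefused) as exc:
            registry.submit("alice", _pentavalent_carbon(), metadata=meta)
        assert exc.value.report is not None

    def test_draft_until_normalization_approved(self, registry, meta):
        sub = registry.submit(
            "alice", "CCO", metadata=meta, approve_normalization=False
        )
        assert sub.state == "draft"
        with pytest.raises(StateError):
            registry.decide_submission("ruth", sub.id, True)
        registry.approve_normalization("alice", sub.id)
        assert registry.decide_submission("ruth", sub.id, True).status == "registered"


class TestUniqueness:
    def test_first_approval_mints_initial_codes(self, registry, meta):
        batch = register(registry, "N#CCC(=O)O", meta)
        assert batch.code == 1
        assert batch.substance_code == "UCD00000001-A"
        assert "UCD00000001" in registry.molecules

    def test_same_molecule_different_salt_new_letter(self, registry, meta):
        register(registry, "N#CCC(=O)O", meta)
        batch = register(
            registry, "N#CCC(=O)[O-]", meta,
            composition=SubstanceComposition(salt_parts=(("sodium", 1),)),
        )
        assert batch.substance_code == "UCD00000001-B"
        assert len(registry.molecules) == 1

    def test_atom_ordering_and_tautomer_collapse(self, registry, meta):
        register(registry, "O=c1cccc[nH]1", meta)
        register(registry, "Oc1ccccn1", meta)          # tautomer drawing
        register(registry, "c1cc[nH]c(=O)c1", meta)     # renumbered SMILES
        assert len(registry.molecules) == 1
        assert len(registry.batches) == 3

    def test_hydrate_count_distinguishes_substances(self, registry, meta):
        register(registry, "CCO", meta)
        batch = register(
            registry, "CCO", meta,
            composition=SubstanceComposition(hydrate_count=1),
        )
        assert batch.substance_code.endswith("-B")

    def test_no_structure_entries_never_merge(self, registry, meta):
        b1 = register(registry, None, meta, no_structure=True)
        b2 = register(registry, None, meta, no_structure=True)
        s1 = registry.substances[b1.substance_code]
        s2 = registry.substances[b2.substance_code]
        assert s1.molecule_code != s2.molecule_code

    def test_mixture_ratios_mint_distinct_molecules(self, registry, meta):
        racemate = "C[C@@H](O)C[C@@H](C)Cl |&1:1,4|"
        register(registry, racemate, meta, mixture_ratio=(50, 50))
        register(registry, racemate, meta, mixture_ratio=(30, 70))
        register(registry, racemate, meta, mixture_ratio=(1, 1))  # = 50:50
        assert len(registry.molecules) == 2


class TestDecision:
    def test_reject_then_resubmit_fresh_id(self, registry, meta):
        sub = registry.submit("alice", "CCO", metadata=meta)
        rejected = registry.decide_submission("ruth", sub.id, False, "wrong salt")
        assert rejected.state == "rejected" and rejected.reason == "wrong salt"
        resub = registry.submit("alice", "CCO", metadata=meta)
        assert resub.id != sub.id
        assert registry.submissions[sub.id].state == "rejected"  # retained

    def test_submitter_cannot_decide(self, registry, meta):
        sub = registry.submit("alice", "CCO", metadata=meta)
        with pytest.raises(PermissionDenied):
            registry.decide_submission("alice", sub.id, True)

    def test_deciding_twice_is_a_state_error(self, registry, meta):
        sub = registry.submit("alice", "CCO", metadata=meta)
        registry.decide_submission("ruth", sub.id, True)
        with pytest.raises(StateError):
            registry.decide_submission("ruth", sub.id, True)


class TestReassignAndArchive:
    def test_sole_batch_reassignment_cascades(self, registry, meta):
        batch = register(registry, "CCO", meta)
        old_substance = batch.substance_code
        old_molecule = registry.substances[old_substance].molecule_code
        registry.reassign_batch("ruth", batch.code, structure="CCCO")
        assert registry.batches[batch.code].status == "registered"
        assert registry.substances[old_substance].status == "archived"
        assert registry.molecules[old_molecule].status == "archived"
        # nothing deleted
        assert old_substance in registry.substances

    def test_one_of_two_batches_no_cascade(self, registry, meta):
        b1 = register(registry, "CCO", meta)
        b2 = register(registry, "CCO", meta)
        registry.reassign_batch("ruth", b2.code, structure="CCCO")
        assert registry.substances[b1.substance_code].status == "active"

    def test_no_structure_batch_rehomed_when_elucidated(self, registry, meta):
        batch = register(registry, None, meta, no_structure=True)
        old = batch.substance_code
        registry.reassign_batch(
            "ruth", batch.code, structure="N#CCC(=O)O", reason="structure elucidated"
        )
        events = registry.audit_for(f"batch:{batch.code}")
        reassign = next(e for e in events if e.action == "reassign-batch")
        assert reassign.prior == old
        assert reassign.new == registry.batches[batch.code].substance_code

    def test_archive_last_batch_cascades_and_retains(self, registry, meta):
        batch = register(registry, "CCO", meta)
        registry.archive_batch("ruth", batch.code, "duplicate entry")
        assert registry.batches[batch.code].status == "archived"
        substance = registry.substances[batch.substance_code]
        assert substance.status == "archived"
        assert registry.molecules[substance.molecule_code].status == "archived"

    def test_archive_twice_is_state_error(self, registry, meta):
        batch = register(registry, "CCO", meta)
        registry.archive_batch("ruth", batch.code)
        with pytest.raises(StateError):
            registry.archive_batch("ruth", batch.code)

    def test_archived_molecule_reactivated_by_new_registration(self, registry, meta):
        batch = register(registry, "CCO", meta)
        registry.archive_batch("ruth", batch.code)
        register(registry, "CCO", meta)
        code = registry.substances[batch.substance_code].molecule_code
        assert registry.molecules[code].status == "active"

    def test_submitter_cannot_archive_or_reassign(self, registry, meta):
        batch = register(registry, "CCO", meta)
        with pytest.raises(PermissionDenied):
            registry.archive_batch("alice", batch.code)
        with pytest.raises(PermissionDenied):
            registry.reassign_batch("alice", batch.code, structure="CCCO")


class TestAccessControl:
    def test_restricted_field_visible_to_owning_team_only(self, registry, meta):
        sub = registry.submit(
            "alice", "CCO", metadata=meta,
            restricted_fields={"A": {"study_activity": "IC50 5 nM"}},
        )
        batch = registry.decide_submission("ruth", sub.id, True)
        assert registry.enforce_access("alice", batch.code, "study_activity") == "IC50 5 nM"
        assert registry.enforce_access("vera", batch.code, "study_activity") is MASKED
        assert registry.enforce_access("vera", batch.code, "project") == "P1"

    def test_unknown_user_is_authentication_error(self, registry, meta):
        batch = register(registry, "CCO", meta)
        with pytest.raises(AuthenticationError):
            registry.enforce_access("mallory", batch.code, "project")


class TestAudit:
    def test_replay_reconstructs_statuses(self, registry, meta):
        b1 = register(registry, "CCO", meta)
        b2 = register(registry, "N#CCC(=O)O", meta)
        registry.archive_batch("ruth", b1.code)
        registry.reassign_batch("ruth", b2.code, structure="CCCO")
        replay = registry.replay_statuses()
        for code, mol in registry.molecules.items():
            assert replay[f"molecule:{code}"] == mol.status
        for code, sub in registry.substances.items():
            assert replay[f"substance:{code}"] == sub.status
        for code, batch in registry.batches.items():
            assert replay[f"batch:{code}"] == batch.status

    def test_every_transition_audited(self, registry, meta):
        before = len(registry.audit)
        batch = register(registry, "CCO", meta)
        registry.archive_batch("ruth", batch.code)
        actions = [e.action for e in registry.audit[before:]]
        for expected in ["submit", "approve", "register-molecule",
                         "register-substance", "register-batch",
                         "archive-batch", "archive-substance", "archive-molecule"]:
            assert expected in actions


STRUCTURE_POOL = [
    "CCO", "N#CCC(=O)O", "c1ccccc1", "CC(=O)Oc1ccccc1C(=O)O", "CCN",
    "O=c1cccc[nH]1", "C[C@@H](O)C[C@@H](C)Cl", "CC(C)CC(=O)O",
]


def test_randomized_operation_sequences_conserve_records(registry, meta):
    """Batch records are never lost, batches are never orphaned, and empty
    parents are always cascade-archived, under random operation mixes."""
    rng = random.Random(4711)
    submitted = []
    registered = []
    max_batches = 0
    for _ in range(300):
        op = rng.choice(["submit", "approve", "reject", "reassign", "archive"])
        try:
            if op == "submit":
                sub = registry.submit(
                    "alice", rng.choice(STRUCTURE_POOL), metadata=meta
                )
                submitted.append(sub.id)
            elif op == "approve" and submitted:
                batch = registry.decide_submission("ruth", submitted.pop(0), True)
                registered.append(batch.code)
            elif op == "reject" and submitted:
                registry.decide_submission("ruth", submitted.pop(0), False, "no")
            elif op == "reassign" and registered:
                registry.reassign_batch(
                    "ruth", rng.choice(registered),
                    structure=rng.choice(STRUCTURE_POOL),
                )
            elif op == "archive" and registered:
                registry.archive_batch("ruth", registered.pop(0))
        except StateError:
            pass
        total = len(registry.submissions)  # every batch record ever created
        assert total >= max_batches
        max_batches = total
    # no orphans: every batch points at an existing substance and molecule
    for batch in registry.batches.values():
        substance = registry.substances[batch.substance_code]
        assert substance.molecule_code in registry.molecules
    # cascade invariant: every substance was created with a batch, so a
    # substance left without any registered batch must have been archived
    for substance in registry.substances.values():
        live = [b for b in registry.batches.values()
                if b.substance_code == substance.code and b.status == "registered"]
        if not live:
            assert substance.status == "archived"
    # archived molecules have no active substances
    for mol in registry.molecules.values():
        if mol.status == "archived":
            assert all(
                s.status == "archived"
                for s in registry.substances.values()
                if s.molecule_code == mol.code
            )
    replay = registry.replay_statuses()
    for code, batch in registry.batches.items():
        assert replay[f"batch:{code}"] == batch.status


def test_persistence_round_trip(registry, meta, tmp_path):
    batch = register(
        registry, "N#CCC(=O)O", meta,
        composition=SubstanceComposition(salt_parts=(("sodium", 1),)),
    )
    registry.archive_batch("ruth", batch.code)
    path = tmp_path / "reg.sqlite"
    registry.save(path)
    loaded = Registry.load(path)
    assert set(loaded.molecules) == set(registry.molecules)
    assert set(loaded.substances) == set(registry.substances)
    assert len(loaded.audit) == len(registry.audit)
    # the loaded registry keeps working: same molecule is recognized
    loaded.add_user("alice", "submitter")
    loaded.add_user("ruth", "registrar")
    b2 = register(loaded, "N#CCC(=O)O", meta)
    assert b2.substance_code.startswith("UCD00000001")
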