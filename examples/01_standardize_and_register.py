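"""Standardize a charged drawing and register it through the two-stage
workflow.

A submitter enters the sodium carboxylate of 2-cyanoacetic acid; the system
neutralizes the charge (the salt is recorded at the substance level), a
registrar approves it, and the molecule/substance/batch codes are minted.
"""

from ucd import Registry, SubstanceComposition

reg = Registry()
reg.add_user("alice", "submitter", team="chemistry")
reg.add_user("ruth", "registrar", team="cheminformatics")

submission = reg.submit(
    "alice",
    "N#CCC(=O)[O-]",                      # carboxylate as drawn
    composition=SubstanceComposition(salt_parts=(("sodium", 1),)),
    metadata={"project": "FLAV-2", "scientist": "alice",
              "experimental_mw": "107.0"},
)
print(f"submission {submission.id}: state={submission.state}")
print(f"  applied rules: {submission.normalized.applied_rules}")
print(f"  proton delta:  {submission.normalized.proton_delta:+d}")

batch = reg.decide_submission("ruth", submission.id, True)
substance = reg.substances[batch.substance_code]
molecule = reg.molecules[substance.molecule_code]
print(f"registered: molecule {molecule.code}, substance {substance.code}, "
      f"batch {batch.code}")
print(f"  neutral form:   {molecule.keys.canonical_smiles}")
print(f"  substance mass: {substance.theoretical_mass:.3f} g/mol")
# The substance mass is molecule (85.062) + sodium (22.990) - one hydrogen
# (1.008): the acid proton is displaced by the counter-ion.
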