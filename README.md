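# ucd — a chemical registration system

`ucd` is an open re-implementation of a corporate compound-registration
("unique compound database") workflow for R&D organizations that need to
track small molecules across projects, teams and assays.  It is aimed at
cheminformaticians who run a registry at desk scale: every molecule is
registered exactly once, alternative drawings are normalized to one
representation, and the full history of every record is auditable.

## The model

Chemical data is organized in three levels:

* **Molecule** — the neutral form of a structure, without counter-ions or
  hydrates; the unit of uniqueness, coded `UCD` + 8 digits
  (`UCD00000001`).  Charged drawings are neutralized on entry by adding
  (anions) or removing (cations) one hydrogen per unit of charge;
  quaternary ammonium cations, being permanently charged independent of
  pH, are kept charged and flagged.
* **Substance** — a molecule plus counter-ion(s) and/or waters of hydration
  at fixed stoichiometry, coded by a letter suffix (`UCD00000001-A`).  The
  theoretical mass follows

  `M(substance) = M(molecule) + Σᵢ cᵢ·M(saltᵢ) + n·M(H₂O) − n_H·M(H)`

  where `n_H` is the number of molecule protons displaced by ionic pairing
  (one per unit of cationic counter-ion charge; negative for anionic
  counter-ions, which protonate the molecule; zero for permanent cations).
* **Batch** — one occurrence of a substance (physical sample, MS
  identification, literature reference) with its metadata; the batch code
  is the submission id.

Identity is decided by a **tautomer-insensitive, enhanced-stereo-aware
key**: a digest of the tautomer-canonicalized, stereo-stripped skeleton;
a canonical serialization of stereocenters (CIP descriptors, `either` for
wavy bonds, `unspec` for unmarked centers) with their absolute/AND/OR
stereo-group labels; and the normalized mixture ratio.  This captures
distinctions — relative stereochemistry groups, wavy bonds, enantiomer
ratios — that canonical SMILES and InChI cannot encode, while collapsing
tautomer drawings and atom renumberings.

Registration is two-stage: submitters place standardized, validated entries
in a submission area; registrars approve them into the registration area
(or reject them for resubmission).  Batches can be reassigned or archived —
never deleted — with cascade archiving of emptied substances/molecules and
an append-only audit trail.  Exact, substructure and similarity search run
over the registration area.

## A worked example

```python
from ucd import Registry, SubstanceComposition

reg = Registry()
reg.add_user("alice", "submitter")
reg.add_user("ruth", "registrar")

sub = reg.submit(
    "alice", "N#CCC(=O)[O-]",                      # drawn as the carboxylate
    composition=SubstanceComposition(salt_parts=(("sodium", 1),)),
    metadata={"project": "FLAV-2", "scientist": "alice"},
)
print(sub.normalized.applied_rules)   # ('neutralize-charges',)
batch = reg.decide_submission("ruth", sub.id, True)
print(batch.substance_code)           # UCD00000001-A
print(reg.substances[batch.substance_code].theoretical_mass)  # 107.044
```

The charged drawing is stored as the neutral acid (85.062 g/mol); the
sodium substance mass is 85.062 + 22.990 − 1.008 = 107.044 g/mol — the
counter-ion displaces the acid proton.  Running
`python examples/01_standardize_and_register.py` prints exactly this
session; the other scripts under `examples/` demonstrate enhanced-stereo
uniqueness (six drawings of 4-chloropentan-2-ol → six molecules), salt and
hydrate mass arithmetic, the three search modes, and bulk SDF migration.

A command-line interface wraps the same library (state in an sqlite file):

```bash
ucd user add ruth --role registrar
ucd submit 'N#CCC(=O)[O-]' --as alice --salt sodium \
    --meta project=FLAV-2 --meta scientist=alice
ucd review approve 1 --as ruth
ucd search sub --smiles 'C#N'
ucd import library.sdf --as ruth --auto-approve
```

## Layout

| Module | Role |
| --- | --- |
| `ucd.chem_model` | domain types (structures, molecules, substances, batches, audit events) |
| `ucd.standardizer` | parsing, drawing-rule fixes, neutralization, validation, canonical keys |
| `ucd.substances` | salt dictionary and theoretical-mass arithmetic |
| `ucd.registry` | two-stage workflow, codes, roles, reassignment, audit, persistence |
| `ucd.search` | exact / substructure / similarity search |
| `ucd.importer` | bulk SDF import/export |
| `ucd.properties` | formula, MW, Crippen logP, rule-of-five and lead-like indicators |
| `ucd.fixtures` | deterministic synthetic compound sets with ground-truth manifests |
| `ucd.cli` | the `ucd` command |

See `docs/methods.md` for the scientific conventions, numerical choices and
known limitations.
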