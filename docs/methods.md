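# Methods

This note records the scientific conventions, algorithms and numerical
choices behind `ucd`, and what the test suite does and does not establish.

## Structures as drawings

The unit of input is a 2D drawing: a labeled graph (elements, formal
charges, isotopes, total hydrogen counts), bond orders, wedge annotations
(up / down / either, narrow end on the first atom), 2D coordinates, and
V3000-style stereo groups (absolute, AND, OR).  `StructureRecord` stores the
drawing; RDKit supplies perception (chirality from wedges + coordinates,
double-bond stereo from geometry, aromaticity) and molfile/SMILES I/O.
Molfiles are written as V3000 whenever stereo groups are present — V2000
cannot express them — and V2000 otherwise.  Wedge placement survives
round trips bit-for-bit (wedge codes are carried on bond properties rather
than re-derived), so "same drawing" is a well-defined equality: graph
isomorphism with matching charges, wedges and stereo groups.

A record may instead be flagged **No Structure**: a registrable entry whose
chemistry is unknown (an unidentified MS peak).  No Structure entries have
no keys, never merge with anything, and can later be re-homed by batch
reassignment once the structure is elucidated.

## Neutralization

Molecules are stored neutral.  Each charged atom is handled independently:

* anion (charge −q): add q hydrogens;
* cation (charge +q) with ≥ q attached hydrogens: remove q;
* nitrogen cation with **no** attached hydrogen: left charged and flagged
  `permanent_cation`.  This covers quaternary ammoniums (four non-H
  substituents) and N-alkylated aromatic cations (e.g. N-methylpyridinium),
  both of which are charged independent of pH and have no proton to remove;
* anything else (e.g. a carbocation) is an unresolvable charge and blocks
  registration.

Zwitterions neutralize both centers; a permanent cation plus an ionizable
anion keeps the cation.  Neutralization never touches the heavy-atom graph;
the net hydrogen change is reported as `proton_delta` and verified in tests
by mass bookkeeping (Δm = proton_delta × 1.008).

## Standardization rules

`standardize()` applies, in order: neutralization; re-pointing of wedges
whose narrow end sits on the substituent rather than the stereocenter (the
drawn meaning — substituent out of plane — is preserved); detection of
redundant wedges (a center needs at most one up and one down) and of bent
triple-bond geometry (> 2° from collinear); then wholesale regeneration of
a canonical depiction (RDKit coordinates + canonical wedging).  Coordinate
regeneration subsumes the non-perspective-drawing rule: input geometry is
never trusted, only its stereo interpretation.  Wavy (either) bonds are
re-applied to the same bond after regeneration.  The operation is
idempotent — on its own output it fires no rules and reproduces the same
record — which the suite checks over the whole scaffold set.

`validate()` reports, as errors (blocking): valence violations (RDKit's
valence model, restricted to an organic subset — B, C, N, O, F, Si, P, S,
Se, halogens; other elements pass with an `exotic-element` warning),
unresolvable charges, stereo bonds attached to bridging/ring-fusion atoms
inside rings (explicit hydrogens should be drawn instead), wedges on atoms
that are not stereocenters, and wedged centers whose configuration still
cannot be perceived.  Unmarked potential stereocenters are warnings only:
an unspecified-stereo drawing is registrable and is its own identity (see
below).

## The identity key

The paper-level contract is that tautomer drawings of one molecule must
collide and all stereochemically distinct drawings must not.  The key is a
SHA-256 digest of three layers:

1. **skeleton** — canonical SMILES of the neutralized structure with all
   stereochemistry removed, passed through RDKit's rule-based tautomer
   canonicalizer (`rdMolStandardize.TautomerEnumerator`).  The original
   system's tautomer rules are proprietary; the contract here is defined by
   the fixture pairs (2-pyridone/2-hydroxypyridine, 4-methylimidazole,
   2-pyridinethione), not by any specific rule set.
2. **stereo layer** — per potential stereocenter, a token
   `T<rank>:<desc>:<group>` where `rank` is the canonical atom rank
   (chirality-blind, so the layer is invariant under renumbering), `desc`
   is the CIP descriptor, `either` (wavy bond / unknown), or `unspec`, and
   `group` is `abs` or a normalized AND/OR group label (ordinals renumbered
   by member rank order).  Stereogenic double bonds contribute
   `D<rank>-<rank>:<E|Z|unspec>` tokens.  Tokens are sorted.
3. **ratio** — the mixture ratio reduced by its GCD (50:50 ≡ 1:1; 30:70 is
   distinct), or a placeholder when absent.

Consequences: the six stereo cases of 4-chloropentan-2-ol (two absolute
configurations, AND, OR, either-bond, unspecified) produce six distinct
keys; every mixture ratio of one drawing is a distinct molecule, while the
*ratio-stripped* key — used by exact search — retrieves all of them
together.  Canonical SMILES (with enhanced-stereo CXSMILES extensions) and
InChI are also stored for interoperability, but uniqueness rests on the
key alone.

Known limitation: when the tautomeric proton shift itself creates or
destroys a stereogenic double bond (e.g. a keto/enol pair with a
trisubstituted enol), the two drawings carry different stereo tokens and do
not merge.  This matches the principle that the detailed drawing is the
identity; the shipped tautomer fixtures avoid such pairs.

## Mass arithmetic

Average molecular masses are summed from an IUPAC standard-atomic-weights
table pinned in `ucd.substances` (61 elements), so results are reproducible
offline and independent of the toolkit's periodic table (tests cross-check
against RDKit's `MolWt` at 0.01 g/mol).  Substance mass:

    total = M(molecule) + Σ cᵢ·M(saltᵢ) + n_water·M(H₂O) − n_H·M(H)
    n_H   = Σ cᵢ·chargeᵢ + charge(molecule)

`n_H` is the signed count of protons displaced by ionic pairing: +1 per
sodium on an acid (correction −1.008), −1 per chloride on an amine
(correction +1.008, the hydrochloride gains HCl), and 0 for permanent
cations, whose own charge balances the counter-ion.  Compositions are
checked for balance against a SMARTS-based ionizable-site count (carboxylic,
sulfonic, sulfinic, phosphonic acids, phenols, thiols, azole/aromatic
lactam N–H as acids; aliphatic amines and pyridinic nitrogens as bases).
The counter is a deliberate heuristic — it gates obviously impossible
compositions (sodium "salt" of ethanol) without attempting pKa prediction.

The salt dictionary is a TSV (id, name, formula, charge, mass) shipped with
26 common pharmaceutical counter-ions; every row's mass column is
cross-checked against its formula weight at load time (tolerance 1e-3
g/mol) so a corrupted dictionary cannot silently skew masses.  Fractional
stoichiometry (hemisalts) is carried as exact rationals.

## Registry semantics

Two-stage workflow: `submit` standardizes, validates (errors refuse the
submission with its report), checks mandatory/typed metadata and dry-runs
the composition arithmetic, then queues the entry with an incremental
submission id.  `decide_submission` (registrar only) either rejects — the
record is kept, resubmission gets a fresh id — or approves: the identity
key is looked up (reuse the molecule code, reactivating it if archived) or
the next code is minted; the composition is matched against the molecule's
substances (hydrate count and stoichiometry both identity-bearing) or the
next letter (A…Z, AA…) is assigned; the batch code is the submission id,
so batch codes are strictly increasing in submission order.

Reassignment moves a registered batch to a target substance resolved
through the same uniqueness path (possibly minting new entities); archiving
marks records inactive.  Both cascade: a substance left without registered
batches is archived, and a molecule left without active substances is
archived in turn.  Nothing is ever deleted; every status transition appends
exactly one audit event, and the registry can replay entity statuses from
the log alone (verified in tests and the acceptance run).  Re-registering
archived chemistry reactivates it rather than minting a duplicate code.
Roles are exactly viewer ⊂ submitter ⊂ registrar; restricted batch fields
are visible only to the owning team.  Persistence is an embedded sqlite
database with submission and registration areas in separate tables;
authentication is a local user table.

The workflow's inclusion criteria (what belongs in the registry at all) are
exposed as a configurable predicate on the parsed structure, defaulting to
"everything parseable" — the original criteria are site policy, not
chemistry.

## Search

* **Exact**: equality of the ratio-stripped identity key, hence
  tautomer-insensitive and mixture-ratio-insensitive by construction.
* **Substructure**: RDKit subgraph matching with a pattern-fingerprint
  prescreen that can only discard guaranteed non-matches; stereochemistry
  is enforced only when the query carries wedges.  The contract (no false
  negatives) is verified against a naive networkx subgraph-monomorphism
  oracle on element/charge/bond-order labels.
* **Similarity**: Tanimoto over 2048-bit hashed topological path
  fingerprints (RDKit `RDKFingerprint`), descending scores, ties broken by
  molecule code.  A linear scan with prescreen is used rather than database
  indexing: adequate at desk scale, and the behavioral contract is what
  matters.

## Bulk migration

`import_sdf` runs every record through the identical parse → standardize →
validate → submit (→ approve) path as manual entry, so uniqueness semantics
are the same by construction (asserted in tests).  SDF data fields map to
metadata and composition through a configurable field map; unmapped fields
are preserved verbatim.  Malformed or invalid records are rejected
individually with reasons; dispositions always satisfy registered +
registered-with-warnings + rejected = total.  Records whose only findings
were auto-applied rules or warnings land in the "with warnings" bucket.
Name-to-structure conversion is out of scope (proprietary in the original
pipeline); a `name_resolver` hook accepts a user-supplied callable.
`export_sdf` writes one record per batch and round-trips to an equivalent
registry (same counts, same identity keys; codes match modulo renumbering).
Molecule-level idempotence (re-import creates zero new molecules) holds for
files of structured records; No Structure records are each a distinct
unknown and mint a fresh code on every import by design.

## Properties

Formula (Hill order) and MW come from the same mass arithmetic as
substances (single source of truth, asserted).  logP is the Crippen
atomic-contribution estimate; donors/acceptors use the N+O rule-of-five
conventions; indicators are Lipinski (MW ≤ 500, logP ≤ 5, donors ≤ 5,
acceptors ≤ 10) and lead-like (MW ≤ 350, logP ≤ 3.5, rotatable bonds ≤ 7)
— the common literature cutoffs, since the original system's lead-like
component is proprietary.  Threshold behavior is boundary-tested on the
pure predicate functions.  ADMET, IUPAC naming and solubility prediction
are omitted (proprietary engines); the property table leaves room for
externally supplied values.

## Synthetic fixtures

`generate_fixtures(seed, counts, path)` writes an SDF realizing requested
categories — clean scaffolds (including the worked figure compounds:
2-cyanoacetic acid, fully specified 4-chloropentan-2-ol,
α-D-glucopyranose), auto-fixable flaws (bent nitrile, doubled wedge,
mis-oriented wedge, charged carboxylate), hard errors (pentavalent carbon,
wedge on a non-stereocenter), duplicates under random atom renumbering,
tautomer pairs, salt variants and No Structure entries — plus a manifest
stating each record's expected disposition and whether it mints a new
molecule.  Output is byte-identical for a given seed.  The suite's
system-level test imports a full sweep and checks every disposition against
the manifest.  What fixtures do **not** emulate: realistic chemical-space
distributions, drawing styles of real sketchers beyond the modeled flaw
recipes, or name-only legacy records; passing tests therefore demonstrate
the pipeline's contracts, not field performance on arbitrary corpora.

## Problem sizes and randomization

The shipped checks use desk-scale sizes chosen to exercise every code path:
a 50-molecule registry with 20 substructure queries, ≥ 100 randomized
salt/hydrate compositions against the mass oracle (agreement required to
1e-6 g/mol), 1000-operation randomized workflow sequences, and fixture
sweeps of 20–30 records.  Pure invariants (ratio normalization, substance
letters, formula round trips, composition identity) are property-tested
with hypothesis under a derandomized profile; chemistry-heavy randomized
suites use seeded `random.Random` generators so failures reproduce exactly.
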