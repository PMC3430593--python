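"""Enhanced stereochemistry: six drawings of 4-chloropentan-2-ol register
as six distinct molecules.

The two stereocenters can be drawn as two absolute configurations, a racemic
AND group, an OR group ("one of the two, unknown which"), an either (wavy)
bond, or left unspecified.  Plain SMILES/InChI cannot distinguish all of
these; the registry's identity key carries the stereo-group labels and
either/unspecified states explicitly.
"""

from ucd import Registry, canonical_keys, parse_structure, standardize
from ucd import _rdkit

META = {"project": "STEREO", "scientist": "alice"}

reg = Registry()
reg.add_user("alice", "submitter")
reg.add_user("ruth", "registrar")


def register(structure, ratio=None):
    sub = reg.submit("alice", structure, metadata=META, mixture_ratio=ratio)
    return reg.decide_submission("ruth", sub.id, True)


variants = {
    "(2R,4R) absolute":   "C[C@@H](O)C[C@@H](C)Cl",
    "(2R,4S) absolute":   "C[C@@H](O)C[C@H](C)Cl",
    "AND group (racemate)": "C[C@@H](O)C[C@@H](C)Cl |&1:1,4|",
    "OR group":           "C[C@@H](O)C[C@@H](C)Cl |o1:1,4|",
    "unspecified":        "CC(O)CC(C)Cl",
}
for label, smiles in variants.items():
    batch = register(smiles)
    code = reg.substances[batch.substance_code].molecule_code
    print(f"{label:24s} -> {code}")

# one absolute center plus a wavy "either" bond at the other
partial = parse_structure("C[C@@H](O)CC(C)Cl")
mol, _ = _rdkit.record_to_mol(partial)
unspec = next(i for i, s in _rdkit.stereocenter_status(mol).items()
              if s == "unspecified")
bond = next(b for b in partial.bonds
            if unspec in (b.i, b.j) and b.order == 1 and b.wedge == "none")
other = bond.j if bond.i == unspec else bond.i
batch = register(partial.with_wedges({(unspec, other): "either"}))
code = reg.substances[batch.substance_code].molecule_code
print(f"{'either (wavy) bond':24s} -> {code}")

print(f"\ndistinct molecules: {len(reg.molecules)} (expected 6)")

# mixture ratios mint distinct codes but share the structure-only key
racemate = standardize(parse_structure(variants["AND group (racemate)"])).structure
k5050 = canonical_keys(racemate, (50, 50)).ucd_key
k3070 = canonical_keys(racemate, (30, 70)).ucd_key
print(f"50:50 vs 30:70 keys differ: {k5050 != k3070}")
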