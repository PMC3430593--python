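"""Theoretical substance masses: molecule + counter-ions + hydrate, with the
hydrogen correction for displaced protons.

Molecules are stored neutral; the real salt pairs the ionized form with the
counter-ion, so a cationic counter-ion displaces one acid proton per unit of
charge (mass decreases by 1.008) and an anionic counter-ion protonates a
basic site (mass increases by 1.008).  Quaternary ammoniums carry their own
permanent charge and displace nothing.
"""

from fractions import Fraction

from ucd import SubstanceComposition, parse_structure, substance_mass
from ucd.standardizer import neutralize

cases = [
    ("2-cyanoacetic acid, neutral", "N#CCC(=O)O", (), 0),
    ("... sodium salt", "N#CCC(=O)O", (("sodium", Fraction(1)),), 0),
    ("... potassium salt, monohydrate", "N#CCC(=O)O",
     (("potassium", Fraction(1)),), 1),
    ("ethylamine hydrochloride", "CCN", (("chloride", Fraction(1)),), 0),
    ("ethylamine hemisulfate", "CCN", (("sulfate", Fraction(1, 2)),), 0),
]
for label, smiles, parts, hydrate in cases:
    record = parse_structure(smiles)
    bd = substance_mass(
        record, SubstanceComposition(salt_parts=parts, hydrate_count=hydrate)
    )
    print(f"{label:36s} total {bd.total:8.3f}  "
          f"(molecule {bd.molecule:.3f}, salt {bd.salt:+.3f}, "
          f"hydrate {bd.hydrate:+.3f}, H correction {bd.hydrogen_correction:+.3f})")

quat = parse_structure("C[N+](C)(C)C")
result = neutralize(quat)
bd = substance_mass(
    result.structure,
    SubstanceComposition(salt_parts=(("chloride", Fraction(1)),)),
    permanent_cation=result.permanent_cation,
)
print(f"{'tetramethylammonium chloride':36s} total {bd.total:8.3f}  "
      f"(permanent cation: H correction {bd.hydrogen_correction:+.3f})")
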