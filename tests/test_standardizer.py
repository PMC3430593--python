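"""Standardization rules, validation and canonical uniqueness keys."""

import random

import pytest
from rdkit import Chem

from ucd import _rdkit
from ucd.chem_model import Atom, Bond, StructureRecord
from ucd.fixtures import CLEAN_SCAFFOLDS, TAUTOMER_PAIRS
from ucd.standardizer import (
    ParseError,
    StandardizationError,
    canonical_keys,
    neutralize,
    parse_structure,
    standardize,
    structure_key,
    validate,
)
from ucd.substances import molecular_mass


class TestParse:
    def test_cyanoacetic_acid(self):
        record = parse_structure("N#CCC(=O)O")
        assert record.num_atoms == 6  # heavy atoms only
        assert record.net_charge() == 0

    def test_v3000_or_collection_maps_to_stereo_group(self):
        record = parse_structure("C[C@H](O)C[C@H](Cl)C |o1:1,4|")
        block = record.to_molfile()
        reparsed = parse_structure(block)
        assert len(reparsed.stereo_groups) == 1
        assert reparsed.stereo_groups[0].kind == "or"

    @pytest.mark.parametrize("bad", ["", "   ", "xyz((", "C1CC"])
    def test_parse_failures_raise(self, bad):
        with pytest.raises(ParseError):
            parse_structure(bad)


class TestNeutralize:
    @pytest.mark.parametrize(
        "smiles,expected_smiles,delta,permanent",
        [
            ("N#CCC(=O)[O-]", "N#CCC(=O)O", +1, False),   # carboxylate
            ("C[N+](C)(C)C", "C[N+](C)(C)C", 0, True),     # quaternary ammonium
            ("CC[NH3+]", "CCN", -1, False),                # protonated amine
            ("CCO", "CCO", 0, False),                      # already neutral
            ("[NH3+]CC(=O)[O-]", "NCC(=O)O", 0, False),    # zwitterion
        ],
    )
    def test_examples(self, smiles, expected_smiles, delta, permanent):
        result = neutralize(parse_structure(smiles))
        mol, problems = _rdkit.record_to_mol(result.structure)
        assert not problems
        expected = Chem.CanonSmiles(expected_smiles)
        assert Chem.MolToSmiles(mol) == expected
        assert result.proton_delta == delta
        assert result.permanent_cation is permanent

    @pytest.mark.parametrize("smiles", ["N#CCC(=O)[O-]", "CC[NH3+]", "[O-]S(=O)(=O)O"])
    def test_mass_bookkeeping_matches_proton_delta(self, smiles):
        """Neutralization changes the mass by exactly proton_delta hydrogens."""
        record = parse_structure(smiles)
        result = neutralize(record)
        assert molecular_mass(result.structure) == pytest.approx(
            molecular_mass(record) + result.proton_delta * 1.008, abs=1e-9
        )

    def test_heavy_atom_graph_conserved(self):
        record = parse_structure("N#CCC(=O)[O-]")
        result = neutralize(record)
        assert [a.symbol for a in result.structure.atoms] == [
            a.symbol for a in record.atoms
        ]
        assert [(b.i, b.j, b.order) for b in result.structure.bonds] == [
            (b.i, b.j, b.order) for b in record.bonds
        ]

    def test_unresolvable_charge_raises(self):
        # carbocation: no H to remove would fix it, not a permanent cation
        record = parse_structure("C[C+](C)C")
        with pytest.raises(StandardizationError):
            neutralize(record)


def _bent_nitrile():
    from ucd.fixtures import _bend_triple_bond

    return _bend_triple_bond(parse_structure("N#CCC(=O)O"))


def _angle(coords, a, center, b):
    import math

    v1 = (coords[a][0] - coords[center][0], coords[a][1] - coords[center][1])
    v2 = (coords[b][0] - coords[center][0], coords[b][1] - coords[center][1])
    dot = v1[0] * v2[0] + v1[1] * v2[1]
    n = math.hypot(*v1) * math.hypot(*v2)
    return math.degrees(math.acos(max(-1, min(1, dot / n))))


class TestStandardize:
    def test_bent_nitrile_redrawn_linearly(self):
        result = standardize(_bent_nitrile())
        assert "linear-triple-bond" in result.applied_rules
        out = result.structure
        triple = next(b for b in out.bonds if b.order == 3)
        neighbors = [b for b in out.bonds if triple.j in (b.i, b.j) and b != triple]
        other = neighbors[0].i if neighbors[0].j == triple.j else neighbors[0].j
        assert _angle(out.coords2d, triple.i, triple.j, other) == pytest.approx(
            180.0, abs=2.0
        )

    def test_redundant_wedges_dropped(self):
        from ucd.fixtures import _doubled_wedge

        record = _doubled_wedge(parse_structure("C[C@@H](O)CC"))
        result = standardize(record)
        assert "redundant-wedges" in result.applied_rules
        per_center = {}
        for b in result.structure.bonds:
            if b.wedge in ("up", "down"):
                per_center.setdefault(b.i, []).append(b.wedge)
        for wedges in per_center.values():
            assert wedges.count("up") <= 1 and wedges.count("down") <= 1

    def test_misoriented_wedge_repointed(self):
        from ucd.fixtures import _misoriented_wedge

        record = _misoriented_wedge(parse_structure("C[C@H](O)c1ccccc1"))
        result = standardize(record)
        assert "wedge-orientation" in result.applied_rules
        # the stereocenter configuration is recovered, not lost
        mol, _ = _rdkit.record_to_mol(result.structure)
        assert "@" in Chem.MolToSmiles(mol)

    @pytest.mark.parametrize("smiles", [s for _, s, _ in CLEAN_SCAFFOLDS])
    def test_idempotence(self, smiles):
        """standardize . standardize == standardize, with no rules fired on
        the second pass."""
        first = standardize(parse_structure(smiles))
        second = standardize(first.structure)
        assert second.applied_rules == ()
        assert second.structure == first.structure

    def test_no_structure_passthrough(self):
        record = StructureRecord(no_structure=True)
        result = standardize(record)
        assert result.structure == record and result.applied_rules == ()


class TestValidate:
    def test_pentavalent_carbon(self):
        atoms = (Atom("C"),) + tuple(Atom("C", hydrogens=3) for _ in range(5))
        record = StructureRecord(atoms=atoms, bonds=tuple(Bond(0, i) for i in range(1, 6)))
        report = validate(record)
        assert any(e.rule == "valence" and "atom 0" in e.locus for e in report.errors)

    def test_bridgehead_wedge_rejected(self):
        record = parse_structure("C1CC2CCC1C2")  # norbornane
        mol, _ = _rdkit.record_to_mol(record)
        info = mol.GetRingInfo()
        bridge = next(
            b for b in record.bonds
            if info.NumAtomRings(b.i) >= 2
            and mol.GetBondBetweenAtoms(b.i, b.j).IsInRing()
        )
        report = validate(record.with_wedges({(bridge.i, bridge.j): "up"}))
        assert any(e.rule == "bridge-stereo" for e in report.errors)

    def test_wedge_on_non_stereocenter_is_ambiguous(self):
        record = parse_structure("CCC").with_wedges({(0, 1): "up"})
        report = validate(record)
        assert any(e.rule == "ambiguous-stereo" for e in report.errors)

    def test_clean_structure_empty_report(self):
        record = standardize(parse_structure("N#CCC(=O)O")).structure
        report = validate(record)
        assert report.ok and not report.warnings

    def test_unmarked_stereocenter_warns_but_registrable(self):
        report = validate(parse_structure("CC(O)CC(C)Cl"))
        assert report.ok
        assert any(w.rule == "unmarked-stereocenter" for w in report.warnings)

    def test_exotic_element_warns(self):
        record = StructureRecord(atoms=(Atom("Pt"),))
        report = validate(record)
        assert report.ok
        assert any(w.rule == "exotic-element" for w in report.warnings)


STEREO_VARIANTS = {
    "abs-RR": "C[C@@H](O)C[C@@H](C)Cl",
    "abs-RS": "C[C@@H](O)C[C@H](C)Cl",
    "and-group": "C[C@@H](O)C[C@@H](C)Cl |&1:1,4|",
    "or-group": "C[C@@H](O)C[C@@H](C)Cl |o1:1,4|",
    "unspecified": "CC(O)CC(C)Cl",
}


def _stereo_variant_records():
    records = {
        name: standardize(parse_structure(s)).structure
        for name, s in STEREO_VARIANTS.items()
    }
    # one absolute center + one "either" wavy bond
    partial = parse_structure("C[C@@H](O)CC(C)Cl")
    mol, _ = _rdkit.record_to_mol(partial)
    unspec = next(
        i for i, s in _rdkit.stereocenter_status(mol).items() if s == "unspecified"
    )
    bond = next(b for b in partial.bonds
                if unspec in (b.i, b.j) and b.order == 1 and b.wedge == "none")
    partial = partial.with_wedges({(unspec, b.j if (b := bond).i == unspec else bond.i): "either"})
    records["either-bond"] = standardize(partial).structure
    return records


class TestCanonicalKeys:
    @pytest.mark.parametrize("name,a,b", TAUTOMER_PAIRS)
    def test_tautomer_pairs_share_key(self, name, a, b):
        ka = canonical_keys(standardize(parse_structure(a)).structure)
        kb = canonical_keys(standardize(parse_structure(b)).structure)
        assert ka.ucd_key == kb.ucd_key

    def test_six_stereo_variants_all_distinct(self):
        records = _stereo_variant_records()
        keys = {name: canonical_keys(r).ucd_key for name, r in records.items()}
        assert len(keys) == 6
        assert len(set(keys.values())) == 6

    def test_mixture_ratio_in_key(self):
        record = standardize(parse_structure(STEREO_VARIANTS["and-group"])).structure
        assert canonical_keys(record, (50, 50)) == canonical_keys(record, (1, 1))
        assert (
            canonical_keys(record, (50, 50)).ucd_key
            != canonical_keys(record, (30, 70)).ucd_key
        )
        # the ratio-stripped key is shared by every ratio variant
        assert structure_key(record) == canonical_keys(record, None).ucd_key

    @pytest.mark.parametrize(
        "smiles",
        ["N#CCC(=O)O", "C[C@@H](O)C[C@@H](C)Cl |&1:1,4|",
         "OC[C@H]1O[C@H](O)[C@H](O)[C@@H](O)[C@@H]1O"],
    )
    def test_permutation_invariance(self, smiles):
        """Keys do not depend on input atom numbering."""
        record = standardize(parse_structure(smiles)).structure
        reference = canonical_keys(record)
        rng = random.Random(20123)
        mol, _ = _rdkit.record_to_mol(record)
        for _ in range(8):
            order = list(range(mol.GetNumAtoms()))
            rng.shuffle(order)
            shuffled = _rdkit.mol_to_record(Chem.RenumberAtoms(mol, order))
            keys = canonical_keys(standardize(shuffled).structure)
            assert keys.ucd_key == reference.ucd_key
            assert keys.canonical_smiles == reference.canonical_smiles
            assert keys.inchi == reference.inchi

    def test_no_structure_refused(self):
        with pytest.raises(StandardizationError):
            canonical_keys(StructureRecord(no_structure=True))
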