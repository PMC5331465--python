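"""PDB bookkeeping: parsing, truncation, variant application, regions."""

import numpy as np
import pytest

from evbscreen import (
    apply_variant,
    assign_regions,
    parse_variant,
    read_structure,
    truncate_to_alanine,
    write_structure,
)
from evbscreen.errors import (
    CannotTruncateError,
    EmptyStructureError,
    IdentityError,
    SelectorError,
    StructureError,
    UnsupportedSubstitutionError,
)
from evbscreen.structure import TruncationNotice


def _atom_line(serial, name, resname, chain, resnum, x, y, z,
               occ=1.0, b=0.0, altloc=" ", element=None):
    element = element or name[0]
    name_f = f" {name:<3}" if len(name) < 4 else name
    return (f"ATOM  {serial:>5} {name_f}{altloc}{resname:>3} {chain}"
            f"{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}"
            f"          {element:>2}")


def _leu_tripeptide() -> str:
    """GLY92-LEU93-SER94 with hydrogens on the leucine."""
    rows = [
        # GLY 92 backbone
        ("N", "GLY", 92, 0.0, 0.0, 0.0), ("CA", "GLY", 92, 1.4, 0.0, 0.0),
        ("C", "GLY", 92, 2.0, 1.3, 0.0), ("O", "GLY", 92, 1.4, 2.4, 0.0),
        # LEU 93 full side chain
        ("N", "LEU", 93, 3.3, 1.3, 0.0), ("CA", "LEU", 93, 4.1, 2.5, 0.0),
        ("C", "LEU", 93, 5.6, 2.2, 0.0), ("O", "LEU", 93, 6.1, 1.1, 0.0),
        ("CB", "LEU", 93, 3.8, 3.4, 1.2), ("CG", "LEU", 93, 4.4, 4.8, 1.2),
        ("CD1", "LEU", 93, 3.9, 5.6, 2.4), ("CD2", "LEU", 93, 4.1, 5.6, 0.0),
        ("H", "LEU", 93, 3.8, 0.4, 0.0), ("HA", "LEU", 93, 3.8, 3.0, -0.9),
        ("HB2", "LEU", 93, 2.7, 3.5, 1.2), ("HB3", "LEU", 93, 4.1, 2.9, 2.1),
        ("HG", "LEU", 93, 5.5, 4.7, 1.2), ("HD11", "LEU", 93, 4.3, 6.6, 2.4),
        # SER 94
        ("N", "SER", 94, 6.3, 3.3, 0.0), ("CA", "SER", 94, 7.8, 3.2, 0.0),
        ("C", "SER", 94, 8.4, 4.6, 0.0), ("O", "SER", 94, 7.7, 5.6, 0.0),
        ("CB", "SER", 94, 8.3, 2.4, 1.2), ("OG", "SER", 94, 9.7, 2.2, 1.1),
    ]
    lines = [_atom_line(i + 1, n, rn, "A", num, x, y, z)
             for i, (n, rn, num, x, y, z) in enumerate(rows)]
    return "\n".join(lines) + "\nEND\n"


@pytest.fixture(scope="module")
def tripeptide_pdb():
    # normalize through one read/write pass so round-trip tests compare
    # like with like (fixed-column conventions of the writer)
    return write_structure(read_structure(_leu_tripeptide()))


def _heavy_names(res):
    return sorted(a.name for a in res if not a.is_hydrogen())


class TestReadWrite:
    def test_reads_three_residues_with_written_atom_counts(
            self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        residues = list(s.residues())
        assert [(r.seqid.num, r.name) for _, r in residues] == [
            (92, "GLY"), (93, "LEU"), (94, "SER")]
        assert len([a for _, r in residues for a in r]) == 24

    def test_round_trip_preserves_atom_records(self, tripeptide_pdb):
        again = write_structure(read_structure(tripeptide_pdb))

        def atom_records(text):
            return [l.rstrip() for l in text.splitlines()
                    if l.startswith(("ATOM", "HETATM"))]

        assert atom_records(again) == atom_records(tripeptide_pdb)

    def test_altloc_highest_occupancy_kept(self):
        lines = [
            _atom_line(1, "N", "ALA", "A", 1, 0, 0, 0),
            _atom_line(2, "CA", "ALA", "A", 1, 1.0, 0, 0, occ=0.6,
                       altloc="A"),
            _atom_line(3, "CA", "ALA", "A", 1, 9.0, 0, 0, occ=0.4,
                       altloc="B"),
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        _, res = s.find_residue("A", 1)
        cas = [a for a in res if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].pos.x == pytest.approx(1.0)

    def test_altloc_tie_goes_to_label_a(self):
        lines = [
            _atom_line(1, "CA", "ALA", "A", 1, 9.0, 0, 0, occ=0.5,
                       altloc="B"),
            _atom_line(2, "CA", "ALA", "A", 1, 1.0, 0, 0, occ=0.5,
                       altloc="A"),
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        _, res = s.find_residue("A", 1)
        assert [a.pos.x for a in res] == [pytest.approx(1.0)]

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyStructureError):
            read_structure("REMARK nothing here\nEND\n")

    def test_variant_remark_recorded(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        text = write_structure(s, variant_label="L93A")
        assert text.splitlines()[0] == "REMARK 220 VARIANT L93A"


class TestTruncation:
    def test_leu_to_ala_keeps_five_heavy_atoms(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        out = truncate_to_alanine(s, "A", 93, "ALA")
        _, res = out.find_residue("A", 93)
        assert res.name == "ALA"
        assert _heavy_names(res) == ["C", "CA", "CB", "N", "O"]
        # hydrogens on kept heavy atoms stay, the rest go
        hs = sorted(a.name for a in res if a.is_hydrogen())
        assert hs == ["H", "HA", "HB2", "HB3"]

    def test_leu_to_gly_keeps_backbone_only(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        out = truncate_to_alanine(s, "A", 93, "GLY")
        _, res = out.find_residue("A", 93)
        assert res.name == "GLY"
        assert _heavy_names(res) == ["C", "CA", "N", "O"]

    def test_truncation_is_idempotent(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        once = truncate_to_alanine(s, "A", 93, "ALA")
        with pytest.warns(TruncationNotice):
            twice = truncate_to_alanine(once, "A", 93, "ALA")
        _, r1 = once.find_residue("A", 93)
        _, r2 = twice.find_residue("A", 93)
        assert [a.name for a in r1] == [a.name for a in r2]

    def test_proline_declared_unsupported(self):
        lines = [
            _atom_line(i + 1, n, "PRO", "A", 7, float(i), 0, 0)
            for i, n in enumerate(["N", "CA", "C", "O", "CB", "CG", "CD"])
        ]
        s = read_structure("\n".join(lines) + "\nEND\n")
        with pytest.raises(CannotTruncateError, match="PRO"):
            truncate_to_alanine(s, "A", 7, "ALA")

    def test_missing_backbone_rejected(self):
        lines = [_atom_line(1, "CB", "LEU", "A", 5, 0, 0, 0)]
        s = read_structure("\n".join(lines) + "\nEND\n")
        with pytest.raises(CannotTruncateError, match="backbone"):
            truncate_to_alanine(s, "A", 5, "ALA")

    def test_original_structure_never_mutated(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        before = len([a for _, r in s.residues() for a in r])
        truncate_to_alanine(s, "A", 93, "GLY")
        after = len([a for _, r in s.residues() for a in r])
        assert before == after


class TestApplyVariant:
    def test_ala_target_truncates_internally(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        out = apply_variant(s, parse_variant("L93A"))
        _, res = out.find_residue("A", 93)
        assert res.name == "ALA"

    def test_identity_mismatch_fails_before_any_change(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        with pytest.raises(IdentityError, match="93"):
            apply_variant(s, parse_variant("V93A"))
        # a multi-substitution variant with one bad site changes nothing
        with pytest.raises(IdentityError):
            apply_variant(s, parse_variant("G92A+V93A"))
        _, res = s.find_residue("A", 92)
        assert res.name == "GLY"

    def test_non_ala_gly_requires_adapter(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        with pytest.raises(UnsupportedSubstitutionError):
            apply_variant(s, parse_variant("L93H"))

    def test_adapter_receives_substitution_and_frozen_set(
            self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        seen = {}

        def adapter(structure, sub, frozen):
            seen["sub"] = sub
            seen["frozen"] = frozen
            return structure

        exclusion = {("A", 94, "OG")}
        apply_variant(s, parse_variant("L93H"), rotamer_adapter=adapter,
                      exclusion_set=exclusion)
        assert seen["sub"].label == "L93H"
        assert seen["frozen"] == frozenset(exclusion)

    def test_untouched_residues_keep_coordinates(self, tripeptide_pdb):
        s = read_structure(tripeptide_pdb)
        out = apply_variant(s, parse_variant("L93A"))

        def coords(struct, resnum):
            _, res = struct.find_residue("A", resnum)
            return {a.name: (a.pos.x, a.pos.y, a.pos.z) for a in res}

        for resnum in (92, 94):
            assert coords(out, resnum) == coords(s, resnum)


class TestRegions:
    @staticmethod
    def _spread_structure(shift=(0.0, 0.0, 0.0)):
        dx, dy, dz = shift
        rows = [
            (1, "N", 0.0), (2, "N", 5.0), (3, "N", 16.9), (4, "N", 18.0),
            (5, "N", 20.0), (6, "N", 25.0),
        ]
        lines = [_atom_line(i, n, "GLY", "A", i, x + dx, dy, dz)
                 for i, n, x in rows]
        return read_structure("\n".join(lines) + "\nEND\n")

    def test_distance_labels_and_constants(self):
        s = self._spread_structure()
        reg = assign_regions(s, ("A", 1, "N"))
        assert reg.labels == ("mobile", "mobile", "mobile", "boundary",
                              "boundary", "frozen")
        assert reg.force_constants == (10.0, 200.0)
        assert reg.radii == (17.0, 20.0)

    def test_labels_invariant_under_rigid_translation(self):
        a = assign_regions(self._spread_structure(), ("A", 1, "N"))
        b = assign_regions(self._spread_structure((100.0, -30.0, 7.0)),
                           ("A", 1, "N"))
        assert a.labels == b.labels

    def test_selector_must_match_exactly_one_atom(self):
        s = self._spread_structure()
        with pytest.raises(SelectorError):
            assign_regions(s, ("A", 99, "N"))
        with pytest.raises(SelectorError):
            assign_regions(s, (None, 1, "ZZ"))
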