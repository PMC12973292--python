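"""PDB parsing, binding-site shells, peptide mapping, and ΔCoM geometry."""

import numpy as np
import pandas as pd
import pytest

from afdip.exceptions import LigandNotFoundError, StructureParseError
from afdip.simulate import TOY_PEPTIDES
from afdip.structure import (
    AtomRecord,
    binding_site_residues,
    center_of_mass,
    chain_sequences,
    localize_binding_site,
    map_peptide_to_structure,
    parse_structure,
)


def _pdb_line(serial, name, resname, chain, resnum, x, y, z, occ=1.0,
              element="C", altloc=" ", hetero=False):
    record = "HETATM" if hetero else "ATOM  "
    return (f"{record}{serial:>5} {name:>4}{altloc}{resname:>3} {chain}{resnum:>4}"
            f"    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
            f"          {element:>2}")


def _mini_pdb(lines):
    return "\n".join(lines) + "\nEND\n"


class TestParseStructure:
    def test_toy_fixture_round_trip(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        assert len(atoms) == 44  # 40 CA + 4 ligand atoms
        ca1 = atoms[0]
        assert (ca1.residue_name, ca1.chain_id, ca1.residue_number) == ("ALA", "A", 1)
        assert ca1.xyz == pytest.approx((3.8, 1.0, 0.0))
        assert not ca1.is_hetero
        assert sum(a.is_hetero for a in atoms) == 4

    def test_altloc_keeps_highest_occupancy(self):
        text = _mini_pdb([
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0, occ=0.4, altloc="A"),
            _pdb_line(2, "CA", "ALA", "A", 1, 5, 0, 0, occ=0.6, altloc="B"),
            _pdb_line(3, "CA", "GLY", "A", 2, 1, 0, 0),
        ])
        atoms = parse_structure(text)
        ca = [a for a in atoms if a.residue_number == 1]
        assert len(ca) == 1
        assert ca[0].xyz[0] == pytest.approx(5.0)

    def test_waters_dropped(self):
        text = _mini_pdb([
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0),
            _pdb_line(2, "CA", "GLY", "A", 2, 3.8, 0, 0),
            _pdb_line(3, "O", "HOH", "A", 101, 9, 9, 9, element="O", hetero=True),
        ])
        assert all(a.residue_name != "HOH" for a in parse_structure(text))

    def test_malformed_record_names_line(self, tmp_path):
        bad = "ATOM      1  CA  ALA A   1        bad coords\n"
        with pytest.raises(StructureParseError, match="line 1"):
            parse_structure(bad + "END\n")

    def test_element_masses_assigned(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        assert all(a.mass > 0 for a in atoms)
        assert atoms[0].mass == pytest.approx(12.011, abs=0.01)


class TestBindingSiteResidues:
    def _structure(self, nearest_distances):
        """One ligand atom at the origin; residue i has its nearest atom at
        the given distance along x."""
        lines = [_pdb_line(99, "C1", "LIG", "A", 50, 0, 0, 0, hetero=True)]
        for i, d in enumerate(nearest_distances, start=1):
            lines.append(_pdb_line(i, "CA", "ALA", "A", i, d, 0, 0))
        return parse_structure(_mini_pdb(lines))

    def test_cutoff_is_inclusive(self):
        atoms = self._structure([4.9, 5.0, 5.1])
        site = binding_site_residues(atoms, "LIG", cutoff=5.0)
        assert [r[1] for r in site] == [1, 2]

    def test_zero_cutoff_keeps_exact_contacts_only(self):
        atoms = self._structure([0.0, 1.0])
        site = binding_site_residues(atoms, "LIG", cutoff=0.0)
        assert [r[1] for r in site] == [1]

    def test_empty_shell_warns(self, caplog):
        atoms = self._structure([8.0, 9.0])
        with caplog.at_level("WARNING"):
            assert binding_site_residues(atoms, "LIG", cutoff=5.0) == []
        assert "no protein residues" in caplog.text

    def test_missing_ligand_lists_available(self):
        atoms = self._structure([1.0])
        with pytest.raises(LigandNotFoundError, match="LIG"):
            binding_site_residues(atoms, "MTX")

    def test_shell_monotone_in_cutoff(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        shells = [
            set(binding_site_residues(atoms, "LIG", cutoff=c))
            for c in (3.0, 5.0, 8.0, 12.0)
        ]
        for smaller, larger in zip(shells, shells[1:]):
            assert smaller <= larger


class TestPeptideMapping:
    def test_exact_span(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        (span,) = map_peptide_to_structure("IKLMNPQR", atoms)
        assert (span.chain_id, span.start_residue, span.end_residue) == ("A", 8, 15)
        assert not span.ambiguous

    def test_every_toy_peptide_maps_where_declared(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        for seq, (start, end) in TOY_PEPTIDES.items():
            (span,) = map_peptide_to_structure(seq, atoms)
            assert (span.start_residue, span.end_residue) == (start, end)

    def test_absent_peptide_unmapped(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        assert map_peptide_to_structure("WWWWWW", atoms) == []

    def test_homodimer_gives_two_ambiguous_spans(self):
        lines = []
        serial = 1
        for chain in "AB":
            for i, aa in enumerate("GLY ALA PHE LYS LEU".split(), start=1):
                lines.append(_pdb_line(serial, "CA", aa, chain, i, serial * 2.0, 0, 0))
                serial += 1
        atoms = parse_structure(_mini_pdb(lines))
        spans = map_peptide_to_structure("AFK", atoms)
        assert len(spans) == 2
        assert all(s.ambiguous for s in spans)
        assert {s.chain_id for s in spans} == {"A", "B"}


class TestCenterOfMass:
    def test_equal_masses_midpoint(self):
        atoms = parse_structure(_mini_pdb([
            _pdb_line(1, "CA", "ALA", "A", 1, 0, 0, 0),
            _pdb_line(2, "CA", "GLY", "A", 2, 2, 0, 0),
        ]))
        assert center_of_mass(atoms) == pytest.approx([1.0, 0.0, 0.0])

    def test_mass_weighting_carbon_oxygen(self):
        atoms = parse_structure(_mini_pdb([
            _pdb_line(1, "C", "ALA", "A", 1, 0, 0, 0, element="C"),
            _pdb_line(2, "O", "ALA", "A", 1, 1.23, 0, 0, element="O"),
        ]))
        expected = 15.999 * 1.23 / (12.011 + 15.999)
        assert center_of_mass(atoms)[0] == pytest.approx(expected, abs=1e-3)
        assert center_of_mass(atoms, mass_weighted=False)[0] == pytest.approx(0.615)

    def test_single_atom(self):
        atoms = parse_structure(_mini_pdb([_pdb_line(1, "CA", "ALA", "A", 1, 3, 4, 5)]))
        assert center_of_mass(atoms) == pytest.approx([3.0, 4.0, 5.0])

    def test_union_is_weighted_combination(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        part1, part2 = atoms[:10], atoms[10:]
        m1 = sum(a.mass for a in part1)
        m2 = sum(a.mass for a in part2)
        combined = (center_of_mass(part1) * m1 + center_of_mass(part2) * m2) / (m1 + m2)
        assert center_of_mass(atoms) == pytest.approx(combined)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            center_of_mass([])


def _shift_frame(p_by_sequence):
    return pd.DataFrame(
        [{"sequence": s, "p_value": p} for s, p in p_by_sequence.items()]
    )


class TestLocalizeBindingSite:
    """The toy chain runs along x with the LIG ligand beside residues 9-11."""

    def test_site_adjacent_peptides_beat_distal_decoys(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        near = {"ACDEFGHI": 1e-5, "IKLMNPQR": 1e-6, "RSTVWYAY": 1e-4,
                "YCWDVETG": 0.2, "GSHFIMKN": 0.5, "KNLPQR": 0.9}
        report_near = localize_binding_site(_shift_frame(near), atoms, "LIG")
        far = {k: 1 - v for k, v in near.items()}  # invert the ordering
        report_far = localize_binding_site(_shift_frame(far), atoms, "LIG")
        assert report_near.delta_com < report_far.delta_com
        assert report_near.peptides_used == ["IKLMNPQR", "ACDEFGHI", "RSTVWYAY"]

    def test_rigid_motion_invariance(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        frame = _shift_frame({"IKLMNPQR": 0.01, "ACDEFGHI": 0.02, "RSTVWYAY": 0.03})
        base = localize_binding_site(frame, atoms, "LIG").delta_com

        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        shift = np.array([10.0, -7.0, 3.0])
        moved = [
            AtomRecord(
                a.serial, a.name, a.element, a.residue_name, a.chain_id,
                a.residue_number, a.insertion_code,
                tuple(q @ np.array(a.xyz) + shift),
                a.occupancy, a.is_hetero, a.mass,
            )
            for a in atoms
        ]
        assert localize_binding_site(frame, moved, "LIG").delta_com == pytest.approx(
            base, abs=1e-9
        )

    def test_unmapped_peptides_reported_and_replaced(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        frame = _shift_frame({
            "WWWWWW": 1e-9,  # best p but absent from the chain
            "IKLMNPQR": 0.01, "ACDEFGHI": 0.02, "RSTVWYAY": 0.03,
        })
        report = localize_binding_site(frame, atoms, "LIG", top_k=3)
        assert report.peptides_unmapped == ["WWWWWW"]
        assert len(report.peptides_used) == 3

    def test_fewer_mappable_than_top_k_proceeds(self, toy_pdb_text, caplog):
        atoms = parse_structure(toy_pdb_text)
        frame = _shift_frame({"IKLMNPQR": 0.01, "WWWWWW": 0.5})
        with caplog.at_level("WARNING"):
            report = localize_binding_site(frame, atoms, "LIG", top_k=3)
        assert report.peptides_used == ["IKLMNPQR"]
        assert "only 1" in caplog.text

    def test_peptides_tiling_the_shell_give_zero_delta(self):
        """When the top peptides' atoms are exactly the shell atoms, ΔCoM = 0."""
        three = {"A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
                 "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS"}
        lines = [
            _pdb_line(i, "CA", three[aa], "A", i, 3.8 * i, 0, 0)
            for i, aa in enumerate("ACDEFGHIK", start=1)
        ]
        lines.append(_pdb_line(99, "C1", "LIG", "A", 50, 19.0, 3.0, 0, hetero=True))
        atoms = parse_structure(_mini_pdb(lines))
        frame = _shift_frame({"ACD": 0.001, "EFG": 0.002, "HIK": 0.003})
        # a huge cutoff makes the shell the whole chain, which the three
        # peptides tile exactly
        report = localize_binding_site(frame, atoms, "LIG", top_k=3, cutoff=100.0)
        assert report.delta_com == pytest.approx(0.0, abs=1e-9)


class TestChainSequences:
    def test_toy_sequence_reconstructed(self, toy_pdb_text):
        atoms = parse_structure(toy_pdb_text)
        seq, keys = chain_sequences(atoms)["A"]
        assert len(seq) == 40
        assert seq.startswith("ACDEFGHIKLMNPQRSTVWY")
        assert keys[0] == ("A", 1, "")
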