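"""Structure parsing, quality filtering, selection, stripping, MOL2 I/O."""
import copy

import numpy as np
import pytest

from pie import fixtures as fx
from pie.cavity import Pocket, Probe, ProbeType
from pie.interface import InterfacePatch, interaction_patch
from pie.model import Method, QualityRecord
from pie.structure_io import (MetadataError, ParseError,
                              check_altloc_at_interface, parse_quality,
                              passes_quality, read_mol2, read_structure,
                              select_heterodimer, select_protein_ligand,
                              strip_structure, write_mol2)

from conftest import make_atom


class TestReadStructure:
    def test_groove_fixture_has_two_polymer_chains(self, hd_structure):
        polymers = hd_structure.polymer_chains()
        assert len(polymers) == 2
        assert {c.chain_id for c in polymers} == {"A", "B"}
        assert [len(c.polymer_residues) for c in polymers] == [126, 9]
        assert polymers[0].entity_accession == "FIXA"
        assert polymers[1].entity_accession == "FIXB"

    def test_ligand_exposed_with_heavy_atom_count(self, pl_structure):
        ligands = [l for l in pl_structure.ligands() if l.name == "LIG"]
        assert len(ligands) == 1
        assert ligands[0].heavy_atom_count == 12

    def test_truncated_file_without_end_still_parses(self, hd_pdb, tmp_path):
        text = hd_pdb.read_text().replace("END\n", "")
        path = tmp_path / "trunc.pdb"
        path.write_text(text)
        s = read_structure(path)
        assert len(s.polymer_chains()) == 2

    def test_zero_atom_file_is_a_parse_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("HEADER    EMPTY\nEND\n")
        with pytest.raises(ParseError):
            read_structure(path)

    def test_missing_file_is_a_parse_error(self, tmp_path):
        with pytest.raises(ParseError):
            read_structure(tmp_path / "nope.pdb")


class TestParseQuality:
    def test_xray_header(self):
        header = "\n".join(fx.quality_header(
            method="X-RAY DIFFRACTION", resolution=2.10,
            r_factor=0.18, r_free=0.22))
        q = parse_quality(header)
        assert q.method is Method.XRAY
        assert q.resolution == pytest.approx(2.10)
        assert q.r_free == pytest.approx(0.22)
        assert q.r_factor == pytest.approx(0.18)

    def test_nmr_header_without_resolution(self):
        header = "\n".join(fx.quality_header(
            method="SOLUTION NMR", resolution=None,
            r_factor=None, r_free=None))
        q = parse_quality(header)
        assert q.method is Method.NMR
        assert q.resolution is None
        assert q.r_free is None

    def test_cryoem_header_with_fsc(self):
        header = "\n".join(fx.quality_header(
            method="ELECTRON MICROSCOPY", resolution=2.9,
            r_factor=None, r_free=None, fsc=0.143))
        q = parse_quality(header)
        assert q.method is Method.CRYOEM
        assert q.resolution == pytest.approx(2.9)
        assert q.fsc == pytest.approx(0.143)

    def test_header_without_method_record_fails(self):
        with pytest.raises(MetadataError):
            parse_quality("REMARK   2 RESOLUTION.    2.10 ANGSTROMS.\n")


class TestPassesQuality:
    @pytest.mark.parametrize("record, expected", [
        # X-ray boundaries: resolution <= 3.5, R-free - R-factor <= 0.07
        (QualityRecord("s", Method.XRAY, 3.5, r_free=0.25, r_factor=0.18),
         True),
        (QualityRecord("s", Method.XRAY, 3.6, r_free=0.22, r_factor=0.18),
         False),
        (QualityRecord("s", Method.XRAY, 2.0, r_free=0.26, r_factor=0.18),
         False),
        # cryo-EM boundaries: resolution <= 3.0, FSC <= 0.143
        (QualityRecord("s", Method.CRYOEM, 3.0, fsc=0.143), True),
        (QualityRecord("s", Method.CRYOEM, 3.0, fsc=0.144), False),
        (QualityRecord("s", Method.CRYOEM, 3.1, fsc=0.10), False),
        # NMR passes without metrics; other methods never pass
        (QualityRecord("s", Method.NMR), True),
        (QualityRecord("s", Method.OTHER, 1.0, r_free=0.2, r_factor=0.18),
         False),
        # fail-closed on missing required metric
        (QualityRecord("s", Method.XRAY, 2.0), False),
        (QualityRecord("s", Method.CRYOEM, 2.0), False),
    ])
    def test_method_and_threshold_boundaries(self, record, expected):
        ok, reason = passes_quality(record)
        assert ok is expected, reason

    def test_monotone_in_each_metric(self):
        """Worsening any single metric never converts fail into pass."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            res = rng.uniform(1.0, 5.0)
            r_factor = rng.uniform(0.1, 0.3)
            gap = rng.uniform(0.0, 0.15)
            base = QualityRecord("s", Method.XRAY, res,
                                 r_free=r_factor + gap, r_factor=r_factor)
            worse = QualityRecord("s", Method.XRAY,
                                  res + rng.uniform(0, 2),
                                  r_free=r_factor + gap + rng.uniform(0, .1),
                                  r_factor=r_factor)
            if not passes_quality(base)[0]:
                assert not passes_quality(worse)[0]
            fsc = rng.uniform(0.0, 0.3)
            em = QualityRecord("s", Method.CRYOEM, res, fsc=fsc)
            em_worse = QualityRecord("s", Method.CRYOEM, res,
                                     fsc=fsc + rng.uniform(0, 0.1))
            if not passes_quality(em)[0]:
                assert not passes_quality(em_worse)[0]

    def test_quality_table_fixture_boundary_rows(self):
        for sid, header, expect in fx.make_quality_table():
            q = parse_quality(header, structure_id=sid)
            ok, reason = passes_quality(q)
            assert ok is expect, f"{sid}: {reason}"


class TestSelectHeterodimer:
    def test_groove_fixture_accepted(self, hd_structure):
        sel = select_heterodimer(strip_structure(hd_structure, "HD"))
        assert sel.accepted
        assert sel.target_chain.chain_id == "A"
        assert sel.partner_chain.chain_id == "B"

    def test_same_accession_rejected_as_homodimer(self, hd_structure):
        s = copy.deepcopy(strip_structure(hd_structure, "HD"))
        for chain in s.chains:
            chain.entity_accession = "SAME"
        sel = select_heterodimer(s)
        assert not sel.accepted
        assert "homodimer" in sel.reason

    def test_three_residue_chain_rejected_too_short(self, hd_structure):
        s = copy.deepcopy(strip_structure(hd_structure, "HD"))
        s.get_chain("B").residues[:] = s.get_chain("B").residues[:3]
        sel = select_heterodimer(s)
        assert not sel.accepted
        assert "too short" in sel.reason

    def test_invariant_under_chain_reordering(self, hd_structure):
        s = strip_structure(hd_structure, "HD")
        reordered = copy.deepcopy(s)
        reordered.chains.reverse()
        assert select_heterodimer(s).accepted == \
            select_heterodimer(reordered).accepted


class TestSelectProteinLigand:
    def test_organic_ligand_accepted_at_defaults(self, pl_structure):
        sel = select_protein_ligand(pl_structure)
        assert sel.accepted
        assert sel.ligand.heavy_atom_count == 12

    def test_metal_containing_ligand_rejected(self, pl_structure):
        s = copy.deepcopy(pl_structure)
        lig_chain = s.get_chain("L")
        lig_chain.residues[0].atoms[0].element = "FE"
        sel = select_protein_ligand(
            s, allowed_elements=frozenset({"H", "C", "N", "O"}))
        assert not sel.accepted
        assert "non-drug-like" in sel.reason

    def test_small_fragment_rejected(self, pl_structure):
        s = copy.deepcopy(pl_structure)
        lig_chain = s.get_chain("L")
        lig_chain.residues[0].atoms[:] = lig_chain.residues[0].atoms[:5]
        sel = select_protein_ligand(s, min_heavy=8)
        assert not sel.accepted
        assert "too small" in sel.reason

    def test_no_ligand_is_a_rejection_not_an_error(self, hd_structure):
        sel = select_protein_ligand(strip_structure(hd_structure, "HD"))
        assert not sel.accepted
        assert "no ligand" in sel.reason


class TestAltlocAtInterface:
    def _patch(self, target_atoms, partner_atoms):
        return InterfacePatch(target_atoms=target_atoms,
                              partner_atoms=partner_atoms, cutoff=6.0)

    def test_blank_altlocs_do_not_exclude(self, hd_structure):
        a = make_atom([0, 0, 0])
        b = make_atom([1, 0, 0], chain_id="B")
        patch = self._patch([a], [b])
        assert check_altloc_at_interface(hd_structure, patch) is False

    def test_altloc_inside_patch_excludes(self, hd_structure):
        a = make_atom([0, 0, 0], altloc="B")
        b = make_atom([1, 0, 0], chain_id="B")
        assert check_altloc_at_interface(
            hd_structure, self._patch([a], [b])) is True

    def test_altloc_outside_patch_does_not_exclude(self, tmp_path):
        path = tmp_path / "alt.pdb"
        # altloc on a wall atom far from the channel is irrelevant when
        # the patch is built from channel-facing atoms only
        path.write_text(fx.make_groove_complex(seed=1, mode="HD"))
        s = read_structure(path)
        far = [a for a in s.get_chain("A").atoms()][-1]
        far.altloc = "B"
        near_a = make_atom([0, 0, 4])
        near_b = make_atom([1, 0, 4], chain_id="B")
        assert check_altloc_at_interface(
            s, self._patch([near_a], [near_b])) is False

    def test_fixture_with_interface_altloc_is_flagged(self, tmp_path):
        path = tmp_path / "altif.pdb"
        path.write_text(fx.make_groove_complex(seed=1, mode="HD",
                                               altloc_in_interface=True))
        s = read_structure(path)
        sel = select_heterodimer(strip_structure(s, "HD"))
        patch = interaction_patch(list(sel.target_chain.atoms()),
                                  list(sel.partner_chain.atoms()))
        assert check_altloc_at_interface(s, patch) is True


class TestStripStructure:
    def test_hd_mode_removes_waters_and_ions(self, hd_structure):
        stripped = strip_structure(hd_structure, "HD")
        assert len(stripped.polymer_chains()) == 2
        assert stripped.ligands() == []
        names = {r.name for c in stripped.chains for r in c.residues}
        assert "HOH" not in names and "NA" not in names

    def test_pl_mode_keeps_designated_ligand_drops_waters(self, pl_structure):
        stripped = strip_structure(pl_structure, "PL")
        ligands = stripped.ligands()
        assert [l.name for l in ligands] == ["LIG"]
        names = {r.name for c in stripped.chains for r in c.residues}
        assert "HOH" not in names

    def test_idempotent_and_identity_on_clean_input(self, hd_structure):
        once = strip_structure(hd_structure, "HD")
        twice = strip_structure(once, "HD")
        def snapshot(s):
            return [(c.chain_id, [(r.name, r.seqid, len(r.atoms))
                                  for r in c.residues]) for c in s.chains]
        assert snapshot(once) == snapshot(twice)


class TestMol2RoundTrip:
    def _pocket(self, n=10):
        rng = np.random.default_rng(3)
        types = list(ProbeType)
        probes = [Probe(coords=rng.uniform(-5, 5, 3),
                        probe_type=types[i % len(types)],
                        buriedness=int(rng.integers(0, 121)))
                  for i in range(n)]
        return Pocket(pocket_id="toy", probes=probes)

    def test_atom_record_count_matches_probes(self, tmp_path):
        pocket = self._pocket(10)
        path = tmp_path / "pocket.mol2"
        write_mol2(pocket, path)
        text = path.read_text()
        atom_block = text.split("@<TRIPOS>ATOM")[1]
        assert len([l for l in atom_block.splitlines() if l.strip()]) == 10

    def test_round_trip_preserves_types_and_coordinates(self, tmp_path):
        pocket = self._pocket(17)
        path = tmp_path / "pocket.mol2"
        write_mol2(pocket, path)
        back = read_mol2(path)
        assert back.n_probes == pocket.n_probes
        assert [p.probe_type for p in back.probes] == \
            [p.probe_type for p in pocket.probes]
        assert [p.buriedness for p in back.probes] == \
            [p.buriedness for p in pocket.probes]
        np.testing.assert_allclose(back.probe_coords(),
                                   pocket.probe_coords(), atol=1e-3)

    def test_empty_pocket_refused(self, tmp_path):
        with pytest.raises(ValueError):
            write_mol2(Pocket(pocket_id="x", probes=[]),
                       tmp_path / "empty.mol2")
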