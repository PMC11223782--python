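"""Descriptor vector contract: lengths, conservation, shape invariants."""
import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pie.cavity import CavityParams, Pocket, Probe, ProbeType
from pie.descriptors import (AMALGAMATED_NAMES, CATEGORY_ORDER,
                             GEOMETRIC_NAMES, N_BASE, N_DESCRIPTORS,
                             amalgamated_descriptors,
                             assemble_descriptor_vector, base_descriptors,
                             descriptor_names, geometric_descriptors,
                             gyration_spectrum)


def pocket_of(coords, types=None, burs=None, pocket_id="p"):
    n = len(coords)
    types = types or [ProbeType.HYDROPHOBIC] * n
    burs = burs if burs is not None else [60] * n
    return Pocket(pocket_id=pocket_id,
                  probes=[Probe(coords=np.asarray(c, float), probe_type=t,
                                buriedness=b)
                          for c, t, b in zip(coords, types, burs)])


def mixed_pocket(n=20, seed=4):
    rng = np.random.default_rng(seed)
    types = list(ProbeType)
    return pocket_of(rng.uniform(0, 8, (n, 3)).tolist(),
                     types=[types[i % len(types)] for i in range(n)],
                     burs=[int(b) for b in rng.integers(0, 121, n)])


class TestBaseDescriptors:
    def test_volume_is_probe_count_times_spacing_cubed(self):
        pocket = pocket_of(np.arange(30).reshape(10, 3).tolist())
        base = base_descriptors(pocket, spacing=1.5)
        assert base[0] == pytest.approx(10 * 1.5 ** 3)  # 33.75 A^3

    def test_all_hydrophobic_pocket_other_categories_zero(self):
        pocket = pocket_of(np.arange(15).reshape(5, 3).tolist())
        base = base_descriptors(pocket)
        names = descriptor_names()[:N_BASE]
        for name, val in zip(names, base):
            if "hydrophobic" in name:
                continue
            if name.startswith("count"):
                assert val == 0, name

    def test_decile_sums_equal_category_totals(self):
        pocket = mixed_pocket()
        base = base_descriptors(pocket)
        for i, cat in enumerate(CATEGORY_ORDER):
            total = base[1 + i]
            off = 1 + len(CATEGORY_ORDER) + 10 * i
            assert base[off:off + 10].sum() == pytest.approx(total), cat

    def test_category_counts_partition_probe_total(self):
        pocket = mixed_pocket()
        base = base_descriptors(pocket)
        typed = sum(base[1 + i] for i, c in enumerate(CATEGORY_ORDER)
                    if c != "polar")
        assert typed == pocket.n_probes


class TestAmalgamatedDescriptors:
    def test_all_hydrophobic_fractions(self):
        pocket = pocket_of(np.arange(15).reshape(5, 3).tolist())
        vals = amalgamated_descriptors(base_descriptors(pocket),
                                       pocket=pocket)
        named = dict(zip(AMALGAMATED_NAMES, vals))
        assert named["frac_hydrophobic"] == 1.0
        assert named["frac_polar"] == 0.0

    def test_typed_plus_dummy_fractions_sum_to_one(self):
        pocket = mixed_pocket()
        vals = dict(zip(AMALGAMATED_NAMES,
                        amalgamated_descriptors(base_descriptors(pocket),
                                                pocket=pocket)))
        total = (vals["frac_hydrophobic"] + vals["frac_aromatic"]
                 + vals["frac_hb_donor"] + vals["frac_hb_acceptor"]
                 + vals["frac_pos_ionizable"] + vals["frac_neg_ionizable"]
                 + vals["frac_dummy"])
        assert total == pytest.approx(1.0)

    def test_fully_buried_pocket_exposure_zero_mean_one(self):
        pocket = pocket_of(np.arange(15).reshape(5, 3).tolist(),
                           burs=[120] * 5)
        vals = dict(zip(AMALGAMATED_NAMES,
                        amalgamated_descriptors(base_descriptors(pocket),
                                                pocket=pocket)))
        assert vals["exposure"] == 0.0
        assert vals["mean_buriedness"] == pytest.approx(1.0)

    def test_all_values_in_unit_interval(self):
        vals = amalgamated_descriptors(
            base_descriptors(mixed_pocket()), pocket=mixed_pocket())
        assert np.all(vals >= 0.0) and np.all(vals <= 1.0)

    def test_zero_probe_pocket_is_an_error(self):
        with pytest.raises(ValueError):
            amalgamated_descriptors(np.zeros(N_BASE))


class TestGeometricDescriptors:
    def test_single_probe_conventions(self):
        vals = dict(zip(GEOMETRIC_NAMES,
                        geometric_descriptors(pocket_of([[1, 2, 3]]))))
        assert vals["radius_of_gyration"] == 0.0
        assert vals["npr1"] == 1.0 and vals["npr2"] == 1.0
        assert vals["eccentricity"] == 0.0

    def test_cube_corners_spherical_top(self):
        # 8 corners of a side-2 cube: gyration tensor = identity,
        # inertia moments all 16 -> asphericity 0, spherocity 1, NPRs 1
        corners = [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1)
                   for sz in (-1, 1)]
        lam, moments = gyration_spectrum(np.array(corners, float))
        np.testing.assert_allclose(lam, [1.0, 1.0, 1.0], atol=1e-12)
        np.testing.assert_allclose(moments, [16.0, 16.0, 16.0], atol=1e-12)
        vals = dict(zip(GEOMETRIC_NAMES,
                        geometric_descriptors(pocket_of(corners))))
        assert vals["asphericity"] == pytest.approx(0.0, abs=1e-12)
        assert vals["spherocity"] == pytest.approx(1.0)
        assert vals["npr1"] == pytest.approx(1.0)
        assert vals["npr2"] == pytest.approx(1.0)
        assert vals["radius_of_gyration"] == pytest.approx(np.sqrt(3.0))

    def test_collinear_rod_limit(self):
        rod = [[x, 0, 0] for x in np.linspace(0, 9, 7)]
        vals = dict(zip(GEOMETRIC_NAMES, geometric_descriptors(
            pocket_of(rod))))
        assert vals["npr1"] == pytest.approx(0.0, abs=1e-12)
        assert vals["npr2"] == pytest.approx(1.0)
        assert vals["eccentricity"] == pytest.approx(1.0)
        assert vals["asphericity"] == pytest.approx(1.0)

    def test_rigid_motion_invariance(self):
        pocket = mixed_pocket()
        base = geometric_descriptors(pocket)
        R = Rotation.random(random_state=23).as_matrix()
        t = np.array([3.0, -8.0, 5.0])
        moved = pocket_of([(p.coords @ R.T + t) for p in pocket.probes],
                          types=[p.probe_type for p in pocket.probes],
                          burs=[p.buriedness for p in pocket.probes])
        np.testing.assert_allclose(geometric_descriptors(moved), base,
                                   atol=1e-6)

    def test_scaling_laws(self):
        """Rg scales linearly, PMIs quadratically under coordinate scaling."""
        pocket = mixed_pocket()
        base = dict(zip(GEOMETRIC_NAMES, geometric_descriptors(pocket)))
        s = 2.5
        scaled = pocket_of([(p.coords * s) for p in pocket.probes])
        got = dict(zip(GEOMETRIC_NAMES, geometric_descriptors(scaled)))
        assert got["radius_of_gyration"] == pytest.approx(
            s * base["radius_of_gyration"])
        for name in ("pmi1", "pmi2", "pmi3"):
            assert got[name] == pytest.approx(s ** 2 * base[name])
        for name in ("asphericity", "spherocity", "npr1", "npr2",
                     "eccentricity"):
            assert got[name] == pytest.approx(base[name], abs=1e-9)

    def test_bounded_shape_indices(self):
        rng = np.random.default_rng(31)
        for _ in range(20):
            pocket = pocket_of(rng.uniform(0, 10, (12, 3)).tolist())
            vals = dict(zip(GEOMETRIC_NAMES, geometric_descriptors(pocket)))
            assert 0.0 <= vals["spherocity"] <= 1.0
            assert 0.0 <= vals["asphericity"] <= 1.0
            assert 0.0 <= vals["npr1"] <= vals["npr2"] <= 1.0

    def test_cross_check_against_rdkit_shape_descriptors(self):
        rdkit = pytest.importorskip("rdkit")
        from rdkit import Chem
        from rdkit.Chem import Descriptors3D
        from rdkit.Geometry import Point3D
        rng = np.random.default_rng(41)
        xyz = rng.uniform(0, 10, (15, 3))
        mol = Chem.RWMol()
        for _ in range(len(xyz)):
            mol.AddAtom(Chem.Atom(6))  # equal masses = unit-weight spectra
        conf = Chem.Conformer(len(xyz))
        for i, (x, y, z) in enumerate(xyz):
            conf.SetAtomPosition(i, Point3D(x, y, z))
        mol.AddConformer(conf)
        vals = dict(zip(GEOMETRIC_NAMES,
                        geometric_descriptors(pocket_of(xyz.tolist()))))
        assert vals["radius_of_gyration"] == pytest.approx(
            Descriptors3D.RadiusOfGyration(mol), rel=1e-6)
        assert vals["npr1"] == pytest.approx(Descriptors3D.NPR1(mol),
                                             rel=1e-6)
        assert vals["npr2"] == pytest.approx(Descriptors3D.NPR2(mol),
                                             rel=1e-6)


class TestAssembledVector:
    def test_length_and_name_registry(self):
        names = descriptor_names()
        assert len(names) == N_DESCRIPTORS == 109
        assert len(set(names)) == 109
        vec = assemble_descriptor_vector(mixed_pocket())
        assert len(vec.values) == 109
        assert vec.names == names

    def test_deterministic(self):
        a = assemble_descriptor_vector(mixed_pocket())
        b = assemble_descriptor_vector(mixed_pocket())
        np.testing.assert_array_equal(a.values, b.values)

    def test_geometric_block_rotation_invariant_in_assembly(self):
        pocket = mixed_pocket()
        R = Rotation.random(random_state=51).as_matrix()
        rotated = pocket_of([(p.coords @ R.T) for p in pocket.probes],
                            types=[p.probe_type for p in pocket.probes],
                            burs=[p.buriedness for p in pocket.probes])
        a = assemble_descriptor_vector(pocket).values[-10:]
        b = assemble_descriptor_vector(rotated).values[-10:]
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_groove_pocket_vector(self, groove_pocket):
        vec = assemble_descriptor_vector(groove_pocket)
        assert len(vec.values) == 109
        assert vec.values[0] > 0  # volume
        assert np.all(np.isfinite(vec.values))
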