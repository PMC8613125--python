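"""XYZ/cube IO and ligand/pocket geometry metrics."""

import math

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cueshift.errors import (
    AtomMismatchError,
    InvalidInputError,
    NoDonorHydrogenError,
    ParseError,
)
from cueshift.structures import (
    BOHR_TO_ANGSTROM,
    StructureModel,
    center_of_mass,
    combine,
    hbond_geometry,
    point_charge_dipole,
    positional_rmsd,
    read_cube,
    read_xyz,
    torsion_angle,
    write_xyz,
)
from cueshift.synthdata import GeneratorConfig, HBondConfig, gen_pocket_complex

CUBE_TEXT = """water fixture
atoms in Bohr, trivial 1-point density grid
    3    0.000000    0.000000    0.000000
    1    1.000000    0.000000    0.000000
    1    0.000000    1.000000    0.000000
    1    0.000000    0.000000    1.000000
    8    8.000000    0.000000    0.000000    0.221664
    1    1.000000    0.000000    1.430887   -0.886659
    1    1.000000    0.000000   -1.430887   -0.886659
  1.0
"""

CUBE_NEGATIVE_NATOMS = CUBE_TEXT.replace("    3    0.0", "   -3    0.0") + "  1 1\n"


def _rigid(structure, seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(random_state=rng).as_matrix()
    t = rng.normal(scale=5.0, size=3)
    return structure.transformed(rotation=R, translation=t)


class TestXyzIO:
    def test_water_fixture(self, water_xyz_path):
        s = read_xyz(water_xyz_path)
        assert len(s) == 3
        assert s.atom_symbols[0] == "O"
        assert s.coords[1, 1] == pytest.approx(0.7572)

    def test_roundtrip_preserves_coordinates(self, water_xyz_path, tmp_path):
        s = read_xyz(water_xyz_path)
        out = tmp_path / "copy.xyz"
        write_xyz(s, out)
        np.testing.assert_allclose(read_xyz(out).coords, s.coords, atol=1e-6)

    def test_malformed_header_names_line(self, tmp_path):
        p = tmp_path / "bad.xyz"
        p.write_text("three\ncomment\nO 0 0 0\n")
        with pytest.raises(ParseError, match="line 1"):
            read_xyz(p)

    def test_truncated_atom_block_names_line(self, tmp_path):
        p = tmp_path / "short.xyz"
        p.write_text("3\ncomment\nO 0 0 0\nH 0 0 1\n")
        with pytest.raises(ParseError):
            read_xyz(p)

    def test_non_numeric_coordinate_names_line(self, tmp_path):
        p = tmp_path / "nan.xyz"
        p.write_text("1\ncomment\nO zero 0 0\n")
        with pytest.raises(ParseError, match="line 3"):
            read_xyz(p)


class TestCubeIO:
    def test_bohr_conversion(self, tmp_path):
        p = tmp_path / "water.cube"
        p.write_text(CUBE_TEXT)
        s = read_cube(p)
        assert s.atom_symbols == ["O", "H", "H"]
        assert s.coords[1, 1] == pytest.approx(1.430887 * BOHR_TO_ANGSTROM, abs=1e-6)

    def test_negative_atom_count_convention(self, tmp_path):
        p = tmp_path / "oriented.cube"
        p.write_text(CUBE_NEGATIVE_NATOMS)
        s = read_cube(p)
        assert len(s) == 3

    def test_truncated_header_errors(self, tmp_path):
        p = tmp_path / "trunc.cube"
        p.write_text("a\nb\n  3 0 0 0\n")
        with pytest.raises(ParseError):
            read_cube(p)


class TestTorsionAngle:
    @staticmethod
    def chain(phi_deg):
        """Four-atom chain with the planted dihedral (z-matrix style)."""
        phi = math.radians(phi_deg)
        return StructureModel(
            ["C", "C", "C", "C"],
            np.array(
                [
                    [1.0, 0.0, 1.0],
                    [0.0, 0.0, 0.0],
                    [0.0, 0.0, -1.5],
                    [math.cos(phi), math.sin(phi), -2.5],
                ]
            ),
        )

    def test_planar_zigzag_is_anti(self):
        assert torsion_angle(self.chain(180.0), 0, 1, 2, 3) == pytest.approx(180.0)

    def test_mirror_image_flips_sign(self):
        s = self.chain(60.0)
        mirror = StructureModel(s.atom_symbols, s.coords * np.array([1.0, -1.0, 1.0]))
        assert torsion_angle(s, 0, 1, 2, 3) == pytest.approx(60.0, abs=1e-9)
        assert torsion_angle(mirror, 0, 1, 2, 3) == pytest.approx(-60.0, abs=1e-9)

    @pytest.mark.parametrize("phi", [-150.0, -60.0, 10.0, 61.8, 120.0, 180.0])
    def test_planted_angles_recovered(self, phi):
        assert torsion_angle(self.chain(phi), 0, 1, 2, 3) == pytest.approx(phi, abs=1e-9)

    @pytest.mark.parametrize("phi", [-170.0, -60.0, 45.0, 170.0])
    def test_reversal_invariance(self, phi):
        s = self.chain(phi)
        assert torsion_angle(s, 0, 1, 2, 3) == pytest.approx(
            torsion_angle(s, 3, 2, 1, 0), abs=1e-9
        )

    def test_rigid_motion_invariance(self):
        s = self.chain(61.8)
        for seed in range(5):
            moved = _rigid(s, seed)
            assert torsion_angle(moved, 0, 1, 2, 3) == pytest.approx(61.8, abs=1e-8)

    def test_collinear_triple_rejected(self):
        s = StructureModel(
            ["C"] * 4, np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [1.0, 0, 3]])
        )
        with pytest.raises(InvalidInputError, match="collinear"):
            torsion_angle(s, 0, 1, 2, 3)

    def test_duplicate_indices_rejected(self):
        with pytest.raises(InvalidInputError):
            torsion_angle(self.chain(60.0), 0, 1, 1, 3)


class TestHBond:
    def test_collinear_contact(self):
        s = StructureModel(
            ["N", "H", "O"],
            np.array([[0.0, 0, 0], [1.0, 0, 0], [2.8, 0, 0]]),
        )
        g = hbond_geometry(s, donor_idx=0, acceptor_idx=2)
        assert g.angle_DHA == pytest.approx(180.0)
        assert g.d_HA == pytest.approx(1.8)
        assert g.d_DA == pytest.approx(2.8)

    def test_generator_planted_contact_recovered(self):
        cfg = GeneratorConfig(seed=42, hbond=HBondConfig(d_DA=2.5, angle_DHA_deg=169.8))
        pocket, ligand, meta = gen_pocket_complex(cfg)
        comp = combine(pocket, ligand)
        g = hbond_geometry(comp, meta["donor_idx"], meta["acceptor_idx"])
        assert g.d_DA == pytest.approx(meta["planted_d_DA"], abs=1e-6)
        assert g.angle_DHA == pytest.approx(meta["planted_angle_DHA_deg"], abs=1e-6)
        assert g.hydrogen_idx == meta["hydrogen_idx"]

    def test_invariant_under_rigid_motion(self):
        cfg = GeneratorConfig(seed=43)
        pocket, ligand, meta = gen_pocket_complex(cfg)
        comp = combine(pocket, ligand)
        ref = hbond_geometry(comp, meta["donor_idx"], meta["acceptor_idx"])
        for seed in range(5):
            moved = _rigid(comp, seed)
            g = hbond_geometry(moved, meta["donor_idx"], meta["acceptor_idx"])
            assert g.d_DA == pytest.approx(ref.d_DA, abs=1e-8)
            assert g.d_HA == pytest.approx(ref.d_HA, abs=1e-8)
            assert g.angle_DHA == pytest.approx(ref.angle_DHA, abs=1e-7)

    def test_donor_without_hydrogen_errors(self):
        s = StructureModel(["N", "O"], np.array([[0.0, 0, 0], [3.0, 0, 0]]))
        with pytest.raises(NoDonorHydrogenError):
            hbond_geometry(s, 0, 1)


class TestRmsd:
    def test_identical_structures_zero(self, water_xyz_path):
        s = read_xyz(water_xyz_path)
        assert positional_rmsd(s, s) == 0.0

    def test_unit_translation(self, water_xyz_path):
        s = read_xyz(water_xyz_path)
        shifted = s.transformed(translation=[1.0, 0.0, 0.0])
        assert positional_rmsd(s, shifted) == pytest.approx(1.0, abs=1e-12)
        assert positional_rmsd(s, shifted, superpose=True) == pytest.approx(0.0, abs=1e-7)

    def test_symmetry_and_superposition_bound(self):
        rng = np.random.default_rng(5)
        a = StructureModel(["C"] * 8, rng.normal(size=(8, 3)))
        b = StructureModel(["C"] * 8, rng.normal(size=(8, 3)))
        assert positional_rmsd(a, b) == pytest.approx(positional_rmsd(b, a), abs=1e-12)
        for seed in range(10):
            moved = _rigid(b, seed)
            assert positional_rmsd(a, moved, superpose=True) <= positional_rmsd(a, moved) + 1e-9

    def test_mask_allows_extra_proton(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [0, 1.0, 0]])
        neutral = StructureModel(["N", "C", "H"], coords)
        extra = np.vstack([coords, [[-1.0, 0, 0]]])
        protonated = StructureModel(["N", "C", "H", "H"], extra, net_charge=1)
        with pytest.raises(AtomMismatchError):
            positional_rmsd(neutral, protonated)
        assert positional_rmsd(neutral, protonated, mask_b=[0, 1, 2]) == 0.0


class TestDipoleAndCom:
    def test_two_point_charges(self):
        s = StructureModel(
            ["H", "H"],
            np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            partial_charges=np.array([0.5, -0.5]),
        )
        d = point_charge_dipole(s, origin=[0, 0, 0])
        assert d.magnitude_D == pytest.approx(0.5 * 4.80320, abs=1e-9)
        np.testing.assert_allclose(d.direction, [-1.0, 0.0, 0.0], atol=1e-12)
        assert not d.origin_dependent

    def test_zero_charges_zero_dipole(self):
        s = StructureModel(
            ["C", "C"], np.array([[0.0, 0, 0], [1.0, 1, 1]]), partial_charges=np.zeros(2)
        )
        assert point_charge_dipole(s).magnitude_D == 0.0

    def test_neutral_cloud_origin_invariant(self, rng):
        q = rng.normal(size=10)
        q -= q.mean()  # net-neutral
        s = StructureModel(["C"] * 10, rng.normal(size=(10, 3)), partial_charges=q)
        d1 = point_charge_dipole(s, origin=[0, 0, 0])
        d2 = point_charge_dipole(s, origin=[5.0, -3.0, 2.0])
        assert d1.magnitude_D == pytest.approx(d2.magnitude_D, abs=1e-9)

    def test_magnitude_linear_in_charge_scale(self, rng):
        q = rng.normal(size=6)
        q -= q.mean()
        xyz = rng.normal(size=(6, 3))
        d1 = point_charge_dipole(StructureModel(["C"] * 6, xyz, partial_charges=q))
        d3 = point_charge_dipole(StructureModel(["C"] * 6, xyz, partial_charges=3 * q))
        assert d3.magnitude_D == pytest.approx(3 * d1.magnitude_D, rel=1e-9)

    def test_charged_cloud_flagged_origin_dependent(self):
        s = StructureModel(
            ["N", "H"], np.array([[0.0, 0, 0], [1.0, 0, 0]]),
            partial_charges=np.array([0.6, 0.4]), net_charge=1,
        )
        assert point_charge_dipole(s).origin_dependent

    def test_missing_charges_error(self, water_xyz_path):
        with pytest.raises(InvalidInputError, match="charges"):
            point_charge_dipole(read_xyz(water_xyz_path))

    def test_homonuclear_diatomic_midpoint(self):
        s = StructureModel(["N", "N"], np.array([[0.0, 0, 0], [0, 0, 1.1]]))
        np.testing.assert_allclose(center_of_mass(s), [0, 0, 0.55], atol=1e-12)

    def test_single_atom(self):
        s = StructureModel(["Ar"], np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(center_of_mass(s), [1.0, 2.0, 3.0])

    def test_water_hand_computed(self, water_xyz_path):
        # independent three-atom arithmetic with standard masses
        s = read_xyz(water_xyz_path)
        np.testing.assert_allclose(
            center_of_mass(s), [0.0, 0.0, 0.0516666944], atol=1e-7
        )
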