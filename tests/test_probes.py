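"""Peptide geometry probes: depth, tilt, rotation, dimer angle, gyration."""

import numpy as np
import pytest

from helpers import atom, make_traj
from memprobe.errors import ArityError, DegenerateGeometryError
from memprobe.model import BilayerGeometry
from memprobe.probes import (
    angle_table,
    interpeptide_angle,
    peptide_com_z,
    radius_of_gyration,
    residue_depth_profile,
    rotation_angle,
    tilt_angle,
)
from memprobe.synthetic import SyntheticConfig, generate_system


def single_peptide(coords, names=None, residues=None, leaflet="upper"):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    names = names or ["CA"] * n
    residues = residues or list(range(1, n + 1))
    rows = [
        atom(i, 0, "peptide", residues[i], "ALA", names[i], leaflet=leaflet)
        for i in range(n)
    ]
    return make_traj(rows, coords)


class TestComZ:
    def test_uniform_depth(self):
        traj = single_peptide([[0, 0, 11.6], [5, 5, 11.6]])
        assert peptide_com_z(traj, traj.frame(0), 0) == pytest.approx(11.6)

    def test_two_equal_masses_average(self):
        traj = single_peptide([[0, 0, 10.0], [0, 0, 12.0]])
        assert peptide_com_z(traj, traj.frame(0), 0) == pytest.approx(11.0)

    def test_lower_leaflet_is_mirrored(self):
        traj = single_peptide([[0, 0, -11.6]], leaflet="lower")
        assert peptide_com_z(traj, traj.frame(0), 0) == pytest.approx(11.6)


class TestTilt:
    def test_vertical_region_gives_zero(self):
        traj = single_peptide([[0, 0, 0.0], [0, 0, 1.0]])
        assert tilt_angle(traj, traj.frame(0), 0, region=(1, 2)) == pytest.approx(0.0)

    def test_in_plane_region_gives_90(self):
        traj = single_peptide([[0, 0, 5.0], [3, 4, 5.0]])
        assert tilt_angle(traj, traj.frame(0), 0, region=(1, 2)) == pytest.approx(90.0)

    def test_odd_region_drops_middle_residue(self):
        # middle residue wildly displaced: must not affect the angle
        traj = single_peptide([[0, 0, 0.0], [100, -50, 7.0], [0, 0, 1.0]])
        assert tilt_angle(traj, traj.frame(0), 0, region=(1, 3)) == pytest.approx(0.0)

    def test_degenerate_region_rejected(self):
        traj = single_peptide([[0, 0, 0.0], [0, 0, 0.0]])
        with pytest.raises(DegenerateGeometryError):
            tilt_angle(traj, traj.frame(0), 0, region=(1, 2))


class TestRotation:
    def _three_residue(self, ca3):
        # residues 1-2 define h along +x; residue 3 carries the probe CA
        return single_peptide(
            [[0, 0, 0.0], [2, 0, 0.0], ca3], residues=[1, 2, 3]
        )

    def test_up_is_90(self):
        traj = self._three_residue([1.0, 0.0, 2.0])
        beta = rotation_angle(traj, traj.frame(0), 0, residue=3, region=(1, 2))
        assert beta == pytest.approx(90.0)

    def test_down_is_270(self):
        traj = self._three_residue([1.0, 0.0, -2.0])
        beta = rotation_angle(traj, traj.frame(0), 0, residue=3, region=(1, 2))
        assert beta == pytest.approx(270.0)

    def test_along_y_prime_is_zero(self):
        # h = +x so y' = z x x = +y
        traj = self._three_residue([1.0, 2.0, 0.0])
        beta = rotation_angle(traj, traj.frame(0), 0, residue=3, region=(1, 2))
        assert beta == pytest.approx(0.0)

    def test_vertical_helix_rejected(self):
        traj = single_peptide(
            [[0, 0, 0.0], [0, 0, 2.0], [1, 0, 1.0]], residues=[1, 2, 3]
        )
        with pytest.raises(DegenerateGeometryError):
            rotation_angle(traj, traj.frame(0), 0, residue=3, region=(1, 2))

    def test_invariant_under_rotation_about_z_and_translation(self, noise_free_system):
        traj, truth = noise_free_system
        pid = traj.peptide_ids("upper")[0]
        beta0 = rotation_angle(traj, traj.frame(0), pid)
        theta = np.deg2rad(35.0)
        R = np.array(
            [[np.cos(theta), -np.sin(theta), 0],
             [np.sin(theta), np.cos(theta), 0],
             [0, 0, 1]]
        )
        rotated = traj.coordinates[0] @ R.T + np.array([3.0, -4.0, 0.0])
        moved = make_traj(
            [tuple(r) for r in traj.atoms.itertuples(index=False)], rotated,
            box=tuple(traj.boxes[0]),
        )
        beta1 = rotation_angle(moved, moved.frame(0), pid)
        assert beta1 == pytest.approx(beta0, abs=1e-8)


class TestInterpeptideAngle:
    def _pair(self, h2):
        rows = []
        coords = []
        for mol, h in ((0, [2.0, 0.0, 0.0]), (1, h2)):
            for res, pos in ((15, [0.0, 0.0, 0.0]), (20, h)):
                rows.append(atom(len(rows), mol, "peptide", res, "ALA", "CA", leaflet="upper"))
                coords.append([pos[0] + 10 * mol, pos[1], pos[2]])
        return make_traj(rows, np.array(coords))

    def test_identical_directions_give_zero(self):
        traj = self._pair([2.0, 0.0, 0.0])
        assert interpeptide_angle(traj, traj.frame(0), "upper") == pytest.approx(0.0)

    def test_orthogonal_directions_give_90(self):
        traj = self._pair([0.0, 2.0, 0.0])
        assert interpeptide_angle(traj, traj.frame(0), "upper") == pytest.approx(90.0)

    def test_antiparallel_directions_give_180(self):
        traj = self._pair([-2.0, 0.0, 0.0])
        assert interpeptide_angle(traj, traj.frame(0), "upper") == pytest.approx(180.0)

    def test_single_peptide_leaflet_rejected(self):
        traj = single_peptide([[0, 0, 0], [1, 0, 0]])
        with pytest.raises(ArityError):
            interpeptide_angle(traj, traj.frame(0), "upper")


class TestRadiusOfGyration:
    def test_coincident_atoms_give_zero(self):
        traj = single_peptide([[1, 2, 3], [1, 2, 3]])
        assert radius_of_gyration(traj, traj.frame(0), 0) == pytest.approx(0.0)

    def test_two_equal_masses_two_angstrom_apart(self):
        traj = single_peptide([[0, 0, 0], [2, 0, 0]])
        assert radius_of_gyration(traj, traj.frame(0), 0) == pytest.approx(1.0)

    def test_matches_brute_force_sum_on_helix(self, noise_free_system):
        traj, _ = noise_free_system
        pid = traj.peptide_ids()[0]
        idx = traj.atom_index(molecule_kind="peptide", molecule_id=pid, is_heavy=True)
        coords = traj.coordinates[0][idx]
        m = traj.atoms["mass"].to_numpy()[idx]
        com = (coords * m[:, None]).sum(0) / m.sum()
        expected = np.sqrt(sum(mi * ((c - com) ** 2).sum() for mi, c in zip(m, coords)) / m.sum())
        assert radius_of_gyration(traj, traj.frame(0), pid) == pytest.approx(expected)


class TestPlantedRecovery:
    def test_exact_recovery_at_zero_noise(self, noise_free_system):
        traj, truth = noise_free_system
        cfg = truth.config
        frame = traj.frame(0)
        for pid in traj.peptide_ids():
            assert peptide_com_z(traj, frame, pid) == pytest.approx(cfg.peptide_z, abs=1e-9)
            assert tilt_angle(traj, frame, pid) == pytest.approx(cfg.tilt, abs=1e-9)
            assert rotation_angle(traj, frame, pid) == pytest.approx(cfg.rotation, abs=1e-9)

    def test_recovery_within_tolerance_under_thermal_noise(self, clean_system):
        """Planted values shared by all four peptides: pool them for the mean."""
        traj, truth = clean_system
        cfg = truth.config
        table = angle_table(traj)
        per_pep = table.groupby("peptide_id")[["z_cm", "gamma"]].mean()
        for pid in traj.peptide_ids():
            assert per_pep.loc[pid, "z_cm"] == pytest.approx(cfg.peptide_z, abs=0.2)
            assert per_pep.loc[pid, "gamma"] == pytest.approx(cfg.tilt, abs=2.0)
        assert table["beta"].mean() == pytest.approx(cfg.rotation, abs=2.0)

    def test_low_ratio_depth_planting(self):
        cfg = SyntheticConfig(
            n_frames=1, noise=0.0, artifact_fraction=0.0,
            peptides_per_leaflet=1, peptide_z=13.1, seed=9,
        )
        traj, _ = generate_system(cfg)
        assert peptide_com_z(traj, traj.frame(0), traj.peptide_ids()[0]) == pytest.approx(13.1)


class TestDepthProfile:
    def _fixed_residue(self, z):
        traj = single_peptide([[0, 0, z]])
        return traj

    def test_insertion_is_strictly_below_z_p(self):
        geo = BilayerGeometry()
        profile, _ = residue_depth_profile(self._fixed_residue(17.55), geo)
        assert profile["inserted_fraction"].iloc[0] == pytest.approx(1.0)
        profile, _ = residue_depth_profile(self._fixed_residue(17.56), geo)
        assert profile["inserted_fraction"].iloc[0] == pytest.approx(0.0)

    def test_histograms_normalized(self, clean_system):
        traj, _ = clean_system
        profile, hist = residue_depth_profile(traj)
        sums = hist.groupby(["peptide_id", "residue"])["P"].sum()
        assert np.allclose(sums, 1.0)

    def test_mean_depth_monotone_along_planted_tilt(self, noise_free_system):
        """An inclined rigid helix orders its residues monotonically in z."""
        traj, truth = noise_free_system
        profile, _ = residue_depth_profile(traj)
        pid = traj.peptide_ids()[0]
        zs = profile[profile["peptide_id"] == pid].sort_values("residue")["mean_z"].to_numpy()
        diffs = np.diff(zs)
        # planted tilt > 90 deg: z decreases from N- to C-terminus
        assert (diffs < 0).all()
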