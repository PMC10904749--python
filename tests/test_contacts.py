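"""Side-chain contacts, C_d recovery, and the periodic-image screen."""

import numpy as np
import pytest

from helpers import atom, make_traj, two_peptide_rows
from memprobe.contacts import (
    bound_fraction,
    contact_probability_table,
    flag_periodic_image_artifacts,
    interpeptide_contacts,
    sidechain_centroid,
)
from memprobe.errors import ArityError
from memprobe.geometry import min_image_displacement
from memprobe.synthetic import SyntheticConfig, generate_system


def pair_at_distance(d, leaflet="upper"):
    """Two 1-residue peptides whose CB side chains sit d apart."""
    rows = two_peptide_rows()
    coords = np.array(
        [[10, 10, 10], [11, 10, 10],  # peptide 0: CA, CB
         [10 + 5, 10, 10], [11 + d, 10, 10]]  # peptide 1: CA, CB
    )
    return make_traj(rows, coords)


class TestSidechainCentroid:
    def test_single_atom_side_chain_is_that_atom(self):
        traj = pair_at_distance(3.0)
        c = sidechain_centroid(traj, traj.frame(0), 0, 1)
        assert np.allclose(c, [11, 10, 10])

    def test_glycine_uses_c_alpha(self):
        rows = [
            atom(0, 0, "peptide", 1, "GLY", "N"),
            atom(1, 0, "peptide", 1, "GLY", "CA"),
            atom(2, 0, "peptide", 1, "GLY", "C"),
            atom(3, 0, "peptide", 1, "GLY", "O"),
        ]
        coords = np.array([[0, 0, 0], [1, 1, 1], [2, 0, 0], [3, 0, 0]])
        traj = make_traj(rows, coords)
        assert np.allclose(sidechain_centroid(traj, traj.frame(0), 0, 1), [1, 1, 1])

    def test_matches_generator_pseudo_side_chain(self, noise_free_system):
        traj, _ = noise_free_system
        pid = traj.peptide_ids()[0]
        cb = traj.atom_index(
            molecule_kind="peptide", molecule_id=pid, residue_index=5, atom_name="CB"
        )
        got = sidechain_centroid(traj, traj.frame(0), pid, 5)
        assert np.allclose(got, traj.coordinates[0][cb[0]])


class TestContactCutoff:
    def test_just_inside_cutoff_counts(self):
        traj = pair_at_distance(6.4)
        assert interpeptide_contacts(traj, traj.frame(0), "upper").c_d == 1

    def test_exactly_at_cutoff_does_not_count(self):
        traj = pair_at_distance(6.5)
        assert interpeptide_contacts(traj, traj.frame(0), "upper").c_d == 0

    def test_requires_two_peptides(self):
        rows = [atom(0, 0, "peptide", 1, "ALA", "CB", leaflet="upper")]
        traj = make_traj(rows, np.array([[0.0, 0, 0]]))
        with pytest.raises(ArityError):
            interpeptide_contacts(traj, traj.frame(0), "upper")

    def test_symmetric_under_peptide_swap(self, dimer_system):
        traj, _ = dimer_system
        cs = interpeptide_contacts(traj, traj.frame(0), "upper")
        swapped = traj.atoms.copy()
        ids = {0: 1, 1: 0}
        swapped["molecule_id"] = swapped["molecule_id"].map(lambda m: ids.get(m, m))
        traj2 = traj.with_atoms(swapped)
        cs2 = interpeptide_contacts(traj2, traj2.frame(0), "upper")
        assert cs.c_d == cs2.c_d


def brute_force_cd(traj, truth, frame_idx, leaflet):
    """Independent double loop over all residue pairs via raw coordinates."""
    from memprobe.contacts import _peptide_centroids

    peps = traj.peptide_ids(leaflet)
    _, ca = _peptide_centroids(traj, traj.frame(frame_idx), peps[0])
    _, cb = _peptide_centroids(traj, traj.frame(frame_idx), peps[1])
    count = 0
    box = traj.boxes[frame_idx]
    for i in range(len(ca)):
        for j in range(len(cb)):
            d = min_image_displacement(ca[i], cb[j], box)
            if np.sqrt((d**2).sum()) < 6.5:
                count += 1
    return count


class TestPlantedDimer:
    def test_planted_contact_count_recovered_exactly(self, dimer_system):
        """C_d matches the generator's per-frame truth and a brute-force oracle."""
        traj, truth = dimer_system
        for f in range(traj.n_frames):
            for leaflet in ("upper", "lower"):
                expected = int(
                    truth.frame_contacts.query(
                        "frame == @f and leaflet == @leaflet"
                    )["c_d"].iloc[0]
                )
                cs = interpeptide_contacts(traj, traj.frame(f), leaflet)
                assert cs.c_d == expected
                assert cs.c_d == brute_force_cd(traj, truth, f, leaflet)

    def test_noise_free_base_has_16_contacts(self):
        cfg = SyntheticConfig(
            n_frames=1, noise=0.0, artifact_fraction=0.0,
            dimer=True, dimer_contacts=16, seed=103,
        )
        traj, truth = generate_system(cfg)
        cs = interpeptide_contacts(traj, traj.frame(0), "upper")
        assert cs.c_d == 16
        assert len(truth.base_contact_pairs["upper"]) == 16


class TestContactProbability:
    def test_constant_contact_has_unit_probability(self):
        traj = pair_at_distance(5.0)
        traj.coordinates = np.repeat(traj.coordinates, 4, axis=0)
        traj.boxes = np.repeat(traj.boxes, 4, axis=0)
        traj.weights = np.ones(4)
        traj.excluded = np.zeros(4, dtype=bool)
        table, mean_cd = contact_probability_table(traj, leaflets=("upper",))
        assert table["P_c"].iloc[0] == pytest.approx(1.0)
        assert mean_cd == pytest.approx(1.0)

    def test_bernoulli_contact_probability_recovered(self):
        rng = np.random.default_rng(17)
        n = 400
        present = rng.random(n) < 0.3
        frames = np.array(
            [
                [[10, 10, 10], [11, 10, 10], [15, 10, 10], [11 + (5.0 if on else 9.0), 10, 10]]
                for on in present
            ]
        )
        traj = make_traj(two_peptide_rows(), frames)
        table, _ = contact_probability_table(traj, leaflets=("upper",))
        p_hat = present.mean()
        assert table["P_c"].iloc[0] == pytest.approx(p_hat)
        assert abs(p_hat - 0.3) < 4 * np.sqrt(0.3 * 0.7 / n)


class TestContactTableAnnotations:
    def test_pair_labels_use_one_letter_codes(self, dimer_system):
        traj, _ = dimer_system
        table, _ = contact_probability_table(traj, leaflets=("upper",))
        assert "label" in table.columns
        # PGLa residue 17 is Ala, 20 is Ala
        row = table[(table["residue_i"] == 17) & (table["residue_j"] == 17)]
        if len(row):
            assert row["label"].iloc[0] == "A17-A17"
        assert table["label"].str.match(r"^[A-Z]\d+-[A-Z]\d+$").all()

    def test_per_trajectory_standard_errors(self, dimer_system):
        traj, _ = dimer_system
        traj_ids = np.arange(traj.n_frames) % 3  # treat frames as 3 trajectories
        table, _ = contact_probability_table(
            traj, leaflets=("upper",), traj_ids=traj_ids
        )
        assert "SE" in table.columns
        assert (table["SE"] >= 0).all()
        # a pair present in every frame has zero spread across trajectories
        always = table[table["P_c"] == 1.0]
        if len(always):
            assert np.allclose(always["SE"], 0.0)

    def test_two_leaflet_pooling_keeps_probabilities_in_range(self, dimer_system):
        traj, _ = dimer_system
        table, mean_cd = contact_probability_table(traj)
        assert (table["P_c"] <= 1.0 + 1e-12).all()
        assert mean_cd > 0


class TestPeriodicImageScreen:
    def test_centered_peptides_never_flagged(self, clean_system):
        traj, _ = clean_system
        mask, fraction = flag_periodic_image_artifacts(traj, apply=False)
        assert fraction == 0.0

    def test_flags_exactly_the_planted_boundary_frames(self):
        cfg = SyntheticConfig(n_frames=40, artifact_fraction=0.1, seed=105)
        traj, truth = generate_system(cfg)
        mask, fraction = flag_periodic_image_artifacts(traj, apply=True)
        assert np.array_equal(mask, truth.artifact_frames)
        assert fraction == pytest.approx(0.1)
        assert (traj.effective_weights[mask] == 0).all()

    def test_constructed_cross_image_contact_is_flagged(self):
        rows = two_peptide_rows()
        # partner's CB 5 A away only across the x boundary
        coords = np.array(
            [[1.0, 10, 10], [1.0, 10, 10], [55.0, 10, 10], [55.0, 10, 10]]
        )
        traj = make_traj(rows, coords)
        mask, fraction = flag_periodic_image_artifacts(traj, apply=False)
        assert mask[0]
        assert fraction == 1.0


def test_bound_fraction_on_planted_system(clean_system):
    """Peptides inserted below the head groups are always lipid-bound."""
    traj, _ = clean_system
    assert bound_fraction(traj) == pytest.approx(1.0)
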