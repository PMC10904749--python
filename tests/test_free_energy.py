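"""Histograms, free-energy surfaces, state partitioning, WHAM, and Eq.-style
dimer equilibrium arithmetic."""

import numpy as np
import pandas as pd
import pytest

from memprobe.constants import R_KCAL
from memprobe.errors import ConfigError, EmptySampleError
from memprobe.fel import (
    dimerization_free_energy,
    free_energy_surface,
    integer_bins,
    partition_states,
    state_statistics,
    trajectory_standard_error,
    weighted_histogram,
)
from memprobe.synthetic import generate_replica_energies
from memprobe.wham import ReplicaEnsemble, reweighted_mean, wham_weights

RT330 = R_KCAL * 330.0


class TestWeightedHistogram:
    def test_single_value_is_a_delta(self):
        P, edges = weighted_histogram(np.full(10, 3.2), bins=8, range=(0, 8))
        assert P.sum() == pytest.approx(1.0)
        assert P.max() == pytest.approx(1.0)

    def test_doubling_weights_changes_nothing(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=500)
        w = rng.uniform(0.5, 2.0, size=500)
        P1, _ = weighted_histogram(x, w, bins=20, range=(-4, 4))
        P2, _ = weighted_histogram(x, 2 * w, bins=20, range=(-4, 4))
        assert np.allclose(P1, P2)

    def test_gaussian_sample_matches_density(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=60000)
        P, edges = weighted_histogram(x, bins=16, range=(-4, 4))
        from scipy.stats import norm

        expected = np.diff(norm.cdf(edges))
        se = np.sqrt(expected * (1 - expected) / len(x))
        assert np.all(np.abs(P - expected) < 5 * se + 1e-12)

    def test_zero_weights_rejected(self):
        with pytest.raises(EmptySampleError):
            weighted_histogram(np.arange(5.0), np.zeros(5))


class TestFreeEnergySurface:
    def test_two_state_gap_reproduces_published_value(self):
        """P = {0.71, 0.15} at 330 K: a 1.0 kcal/mol free-energy gap."""
        P, _ = np.array([0.71, 0.15]), None
        surf = free_energy_surface(P, np.array([0.0, 1.0, 2.0]), 330.0)
        gap = np.nanmax(surf.G) - np.nanmin(surf.G)
        assert gap == pytest.approx(-RT330 * np.log(0.15 / 0.71), abs=1e-12)
        assert round(gap, 1) == 1.0

    def test_uniform_distribution_is_flat_zero(self):
        surf = free_energy_surface(np.full(5, 0.2), np.arange(6.0), 330.0)
        assert np.allclose(surf.G[surf.sampled], 0.0)

    def test_probability_ratio_e_gives_rt(self):
        surf = free_energy_surface(
            np.array([np.e, 1.0]), np.arange(3.0), 330.0
        )
        gap = np.nanmax(surf.G)
        assert gap == pytest.approx(RT330, abs=1e-12)
        assert gap == pytest.approx(0.65571, abs=1e-5)

    def test_invariant_to_normalization_constant(self):
        P = np.array([0.5, 0.3, 0.2])
        s1 = free_energy_surface(P, np.arange(4.0), 330.0)
        s2 = free_energy_surface(10 * P, np.arange(4.0), 330.0)
        assert np.allclose(s1.G, s2.G, equal_nan=True)

    def test_unsampled_cells_are_masked_not_zero(self):
        P = np.array([[0.7, 0.0], [0.3, 0.0]])
        surf = free_energy_surface(P, (np.arange(3.0), np.arange(3.0)), 330.0)
        assert np.isnan(surf.G[:, 1]).all()


def surface_from_G(G, temperature=330.0):
    """Build an FESurface carrying exactly the given G grid (NaN = unsampled)."""
    G = np.asarray(G, dtype=float)
    P = np.where(np.isfinite(G), np.exp(-G / (R_KCAL * temperature)), 0.0)
    z_edges = np.arange(G.shape[0] + 1, dtype=float)
    cd_edges = np.arange(G.shape[1] + 1, dtype=float) - 0.5
    return free_energy_surface(P, (z_edges, cd_edges), temperature)


def oracle_saddle(G, a, b):
    """Threshold-sweep max-min path height between cells a and b."""
    sampled = np.isfinite(G)
    levels = np.unique(G[sampled])
    for L in levels:
        allowed = sampled & (G <= L)
        if not (allowed[a] and allowed[b]):
            continue
        # BFS over 8-neighbors
        stack, seen = [a], {a}
        while stack:
            i, j = stack.pop()
            if (i, j) == b:
                return float(L)
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    ni, nj = i + di, j + dj
                    if (
                        (di or dj)
                        and 0 <= ni < G.shape[0]
                        and 0 <= nj < G.shape[1]
                        and allowed[ni, nj]
                        and (ni, nj) not in seen
                    ):
                        seen.add((ni, nj))
                        stack.append((ni, nj))
    return np.inf


class TestPartitionStates:
    def test_double_well_saddle_height_exact(self):
        """1D double well embedded in the grid: saddle equals the built barrier."""
        x = np.arange(13, dtype=float)
        G1 = np.minimum((x - 2) ** 2, (x - 10) ** 2) * 0.1
        barrier = G1[6]
        G = np.tile(G1[:, None], (1, 1))
        surf = surface_from_G(G)
        part = partition_states(surf, dimer_threshold=8.0)
        assert len(part.minima) == 2
        (saddle_g,) = part.saddles.values()
        assert saddle_g == pytest.approx(barrier, abs=1e-9)

    def test_single_well_has_one_state_and_no_saddles(self):
        x = np.arange(10, dtype=float)
        surf = surface_from_G((0.05 * (x - 3) ** 2)[:, None])
        part = partition_states(surf)
        assert len(part.minima) == 1
        assert part.saddles == {}
        assert part.barriers == {}

    def test_planted_barrier_between_monomer_and_dimer_states(self):
        """A landscape built with a 3.8 kcal/mol exit barrier from IM."""
        n_z, n_c = 9, 12
        G = np.full((n_z, n_c), np.nan)
        G[:, 0] = 0.5  # monomer column, C_d = 0
        G[4, 0] = 0.0  # IM minimum
        G[:, 9] = 2.0  # mature-dimer column, C_d = 9
        G[4, 9] = 1.0  # D minimum
        G[4, 1:9] = np.linspace(3.0, 3.3, 8)  # connecting ridge
        G[4, 5] = 3.8  # planted transition state
        surf = surface_from_G(G)
        part = partition_states(surf, dimer_threshold=8.0)
        assert part.barriers[("IM", "D")] == pytest.approx(3.8, abs=1e-9)
        assert part.barriers[("D", "IM")] == pytest.approx(2.8, abs=1e-9)

    def test_saddles_match_exhaustive_max_min_search(self):
        """Flooding saddles equal threshold-sweep connectivity on random grids."""
        rng = np.random.default_rng(55)
        for trial in range(6):
            G = rng.uniform(0, 5, size=(rng.integers(4, 12), rng.integers(4, 12)))
            G -= G.min()
            surf = surface_from_G(G)
            part = partition_states(surf)
            minima = part.minima
            for key, g in part.saddles.items():
                a, b = tuple(key)
                expected = oracle_saddle(G, minima[a], minima[b])
                assert g <= expected + 1e-9  # flooding finds the lowest connection
            # the pairwise minimum over flooding saddles equals the oracle
            for ia in range(len(minima)):
                for ib in range(ia + 1, len(minima)):
                    expected = oracle_saddle(G, minima[ia], minima[ib])
                    got = effective_saddle(part, ia, ib)
                    assert got == pytest.approx(expected, abs=1e-9)

    def test_nascent_cells_between_monomer_and_dimer(self):
        G = np.full((3, 10), np.nan)
        G[:, 0] = 0.0
        G[1, 1:4] = 1.0  # contact-bearing cells draining into the monomer basin
        surf = surface_from_G(G)
        part = partition_states(surf, dimer_threshold=8.0)
        assert part.state[1, 2] == "nascent"
        assert part.state[1, 0] == "IM"


def effective_saddle(part, ia, ib):
    """Min-max over basin-merge saddles: best path height between two minima."""
    # Floyd-Warshall on the basin graph with max-edge path metric
    n = len(part.minima)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, -np.inf)
    for key, g in part.saddles.items():
        a, b = tuple(key)
        d[a, b] = d[b, a] = min(d[a, b], g)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                d[i, j] = min(d[i, j], max(d[i, k], d[k, j]))
    return d[ia, ib]


class TestStateStatistics:
    def test_single_state_probability_one(self):
        states = np.array(["IM"] * 5)
        summary = state_statistics(states, np.ones(5), 330.0)
        assert summary.value("IM", "P") == pytest.approx(1.0)
        assert summary.value("IM", "G") == pytest.approx(0.0)

    def test_published_probabilities_give_one_kcal_gap(self):
        states = np.array(["IM"] * 71 + ["D"] * 15 + ["nascent"] * 14)
        summary = state_statistics(states, np.ones(100), 330.0)
        assert summary.value("D", "G") == pytest.approx(
            -RT330 * np.log(0.15 / 0.71), abs=1e-12
        )
        assert round(summary.value("D", "G"), 1) == 1.0

    def test_per_state_observable_means(self):
        states = np.array(["IM"] * 50 + ["D"] * 50)
        obs = pd.DataFrame(dict(gamma=[110.0] * 50 + [93.0] * 50))
        summary = state_statistics(states, np.ones(100), 330.0, obs)
        assert summary.value("IM", "gamma") == pytest.approx(110.0, abs=2.0)
        assert summary.value("D", "gamma") == pytest.approx(93.0, abs=2.0)

    def test_probabilities_sum_to_one(self):
        rng = np.random.default_rng(3)
        states = rng.choice(["IM", "nascent", "D"], 200)
        summary = state_statistics(states, rng.uniform(0.5, 1.5, 200), 330.0)
        assert summary.table["P"].sum() == pytest.approx(1.0)


class TestDimerizationFreeEnergy:
    def test_published_worked_example(self):
        """V = 59 x 59 x 37 A^3, P_d = 0.29, T = 330 K: about -2.4 kcal/mol."""
        dg = dimerization_free_energy(P_m=0.71, P_d=0.29, V=59 * 59 * 37, T=330.0)
        assert dg == pytest.approx(-2.49, abs=0.01)
        assert dg == pytest.approx(-2.4, abs=0.1)

    def test_unit_argument_gives_zero(self):
        from memprobe.constants import AVOGADRO, LITRE_PER_A3

        V = 1e5
        c0v = V * LITRE_PER_A3 * AVOGADRO
        p_m = 0.5
        p_d = p_m**2 / c0v
        assert dimerization_free_energy(p_m, p_d, V, 330.0) == pytest.approx(0.0, abs=1e-12)

    def test_doubling_volume_subtracts_rt_ln2(self):
        a = dimerization_free_energy(0.7, 0.3, 1e5, 330.0)
        b = dimerization_free_energy(0.7, 0.3, 2e5, 330.0)
        assert b - a == pytest.approx(-RT330 * np.log(2), abs=1e-12)

    def test_degenerate_probabilities_rejected(self):
        with pytest.raises(ConfigError):
            dimerization_free_energy(1.0, 0.0, 1e5, 330.0)


class TestTrajectoryStandardError:
    def test_identical_means_give_zero_se(self):
        mean, se = trajectory_standard_error([2.0, 2.0, 2.0])
        assert (mean, se) == (2.0, 0.0)

    def test_hand_arithmetic_example(self):
        mean, se = trajectory_standard_error([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert se == pytest.approx(1.0 / np.sqrt(3.0))

    def test_requires_two_samples(self):
        with pytest.raises(ConfigError):
            trajectory_standard_error([1.0])

    def test_recovers_planted_between_trajectory_spread(self):
        rng = np.random.default_rng(6)
        sigma = 0.5
        ses = [
            trajectory_standard_error(rng.normal(10.0, sigma, 3))[1]
            for _ in range(400)
        ]
        assert np.mean(ses) == pytest.approx(sigma / np.sqrt(3), rel=0.15)


class TestWham:
    def test_single_temperature_at_target_is_uniform(self):
        ens = generate_replica_energies([330.0], 500, 1.0, seed=2)
        w, f = wham_weights(ens, 330.0)
        assert np.allclose(w, 1.0 / len(w))
        assert np.allclose(f, 0.0)

    def test_ladder_recovery_of_analytic_moment(self):
        ladder = 330.0 * np.exp(np.linspace(0, np.log(450 / 330), 16))
        ens = generate_replica_energies(ladder, 4000, 1.0, seed=3)
        w, _ = wham_weights(ens, 330.0)
        mean, se = reweighted_mean(ens.payload**2, w)
        assert abs(mean - RT330) < 3 * se

    def test_reweighting_down_from_450(self):
        ens = generate_replica_energies([450.0], 30000, 1.0, seed=4)
        w, _ = wham_weights(ens, 330.0)
        mean, se = reweighted_mean(ens.payload**2, w)
        assert abs(mean - RT330) < 3 * se

    def test_permutation_invariance(self):
        ladder = np.array([330.0, 390.0, 450.0])
        ens = generate_replica_energies(ladder, 300, 1.0, seed=5)
        w1, _ = wham_weights(ens, 330.0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(ens.energies))
        shuffled = ReplicaEnsemble(
            ens.temperatures[perm], ens.energies[perm], ladder, ens.payload[perm]
        )
        w2, _ = wham_weights(shuffled, 330.0)
        assert np.allclose(w2, w1[perm], atol=1e-12)

    def test_target_above_ladder_rejected(self):
        ens = generate_replica_energies([330.0], 10, 1.0)
        with pytest.raises(ConfigError):
            wham_weights(ens, 500.0)


def test_integer_bins_give_one_bin_per_count():
    edges = integer_bins(np.array([0, 3, 7]))
    assert edges[0] == -0.5
    assert len(edges) == 9
    h, _ = np.histogram([0, 1, 1, 7], bins=edges)
    assert h[0] == 1 and h[1] == 2 and h[7] == 1
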