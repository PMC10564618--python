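"""Simulator: block connectivity, degree parameters, label evolution,
adjacency sampling and the two signal-sharing settings."""

import numpy as np
import pytest

from mudcod._rng import stream
from mudcod.metrics import ari
from mudcod.netsim import (
    MuSDynamicDCBM,
    SimulationConfig,
    evolve_labels,
    generate,
    generate_membership_series,
    init_labels,
    sample_adjacency,
    sample_connectivity,
    sample_degree_params,
)


class TestConnectivity:
    def test_degenerate_bounds_are_exact(self, rng):
        B = sample_connectivity(1, (0.3, 0.3), (0.1, 0.1), rng).B
        assert B.shape == (1, 1) and B[0, 0] == pytest.approx(0.3)

    def test_benchmark_densities(self, rng):
        B = sample_connectivity(3, (0.2, 0.4), (0.1, 0.1), rng).B
        off = B[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 0.1)
        assert np.all((np.diag(B) >= 0.2) & (np.diag(B) <= 0.4))
        assert np.allclose(B, B.T)

    def test_diagonal_mean_matches_uniform_law(self, rng):
        # law of large numbers against the uniform mean (p_lo + p_hi) / 2
        draws = np.array(
            [np.diag(sample_connectivity(4, (0.2, 0.4), (0.1, 0.1), rng).B)
             for _ in range(2500)]
        )
        se = (0.4 - 0.2) / np.sqrt(12 * draws.size)
        assert abs(draws.mean() - 0.3) < 5 * se

    def test_invalid_bounds_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_connectivity(3, (0.2, 0.4), (0.3, 0.5), rng)


class TestDegreeParams:
    def test_two_nodes_default_coefficients(self, rng):
        psi = sample_degree_params(2, 0.5, 1.0, rng).psi
        assert sorted(psi) == pytest.approx([1.0, 1.5])

    def test_zero_slope_is_constant(self, rng):
        psi = sample_degree_params(7, 0.8, 0.0, rng).psi
        assert np.allclose(psi, 0.8)

    def test_multiset_matches_enumeration(self, rng):
        G = 23
        psi = sample_degree_params(G, 0.5, 1.0, rng).psi
        expected = sorted(0.5 + 1.0 * j / G for j in range(1, G + 1))
        assert np.allclose(sorted(psi), expected)
        assert psi.min() > 0.5 and psi.max() <= 1.5


class TestLabels:
    def test_single_community(self, rng):
        assert np.all(init_labels(50, 1, rng) == 0)

    def test_uniform_frequencies(self, rng):
        from scipy.stats import chisquare

        z = init_labels(5000, 10, rng)
        counts = np.bincount(z, minlength=10)
        assert chisquare(counts).pvalue > 0.01

    def test_deterministic_given_seed(self):
        a = init_labels(100, 5, stream(7, "labels", 0, 0))
        b = init_labels(100, 5, stream(7, "labels", 0, 0))
        assert np.array_equal(a, b)

    def test_k_larger_than_g_rejected(self, rng):
        with pytest.raises(ValueError):
            init_labels(3, 5, rng)


class TestEvolveLabels:
    def test_zero_rate_is_identity(self, rng):
        z = init_labels(200, 4, rng)
        assert np.array_equal(evolve_labels(z, 0.0, 4, rng), z)

    def test_full_rate_forgets_input(self, rng):
        from scipy.stats import chisquare

        z = np.zeros(20000, dtype=int)
        out = evolve_labels(z, 1.0, 5, rng)
        assert chisquare(np.bincount(out, minlength=5)).pvalue > 0.01

    def test_churn_rate_closed_form(self, rng):
        # redraw includes the current label, so P(change) = r * (K-1) / K
        G, K, r = 100_000, 10, 0.2
        z = init_labels(G, K, rng)
        changed = np.mean(evolve_labels(z, r, K, rng) != z)
        p = r * (K - 1) / K
        se = np.sqrt(p * (1 - p) / G)
        assert abs(changed - p) < 5 * se


class TestMembershipSeries:
    def test_ssos_frozen_rates_all_equal(self):
        cfg = SimulationConfig(n_nodes=50, n_communities=4, n_subjects=3,
                               n_times=3, r_time=0.0, r_subject=0.0,
                               setting="SSoS", seed=1)
        z = generate_membership_series(cfg)
        assert all(np.array_equal(z[0, 0], z[s, t]) for s in range(3) for t in range(3))

    def test_ssot_shared_start_then_independent(self):
        cfg = SimulationConfig(n_nodes=200, n_communities=4, n_subjects=3,
                               n_times=3, r_time=0.3, r_subject=0.0,
                               setting="SSoT", seed=2)
        z = generate_membership_series(cfg)
        for s in range(1, 3):
            assert ari(z[0, 0], z[s, 0]) == pytest.approx(1.0)
        assert not np.array_equal(z[0, 1], z[1, 1])  # diverged after t=0

    def test_ssot_zero_time_rate_constant_per_subject(self):
        cfg = SimulationConfig(n_nodes=60, n_communities=3, n_subjects=2,
                               n_times=4, r_time=0.0, r_subject=0.5,
                               setting="SSoT", seed=3)
        z = generate_membership_series(cfg)
        for s in range(2):
            for t in range(1, 4):
                assert np.array_equal(z[s, 0], z[s, t])

    def test_ssos_subject_divergence_rate(self):
        # disagreement with the ancestor follows the same closed form
        K, r = 10, 0.2
        cfg = SimulationConfig(n_nodes=50_000, n_communities=K, n_subjects=2,
                               n_times=2, r_time=0.1, r_subject=r,
                               setting="SSoS", seed=4)
        z = generate_membership_series(cfg)
        p = r * (K - 1) / K
        se = np.sqrt(p * (1 - p) / 50_000)
        for t in range(2):
            frac = np.mean(z[1, t] != z[0, t])
            assert abs(frac - p) < 5 * se

    def test_unknown_setting_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(setting="bogus")


class TestAdjacency:
    def _parts(self, rng, G=40, K=3):
        z = init_labels(G, K, rng)
        B = sample_connectivity(K, (0.3, 0.4), (0.1, 0.1), rng)
        psi = sample_degree_params(G, 0.5, 1.0, rng)
        return z, B, psi

    def test_zero_connectivity_gives_empty_graph(self, rng):
        from mudcod.netsim import ConnectivityMatrix, DegreeParams

        z = np.zeros(10, dtype=int)
        A = sample_adjacency(z, ConnectivityMatrix(np.zeros((1, 1))),
                             DegreeParams(np.ones(10)), rng)
        assert A.sum() == 0

    def test_unit_probability_gives_complete_graph(self, rng):
        from mudcod.netsim import ConnectivityMatrix, DegreeParams

        z = np.zeros(10, dtype=int)
        A = sample_adjacency(z, ConnectivityMatrix(np.ones((1, 1))),
                             DegreeParams(np.ones(10)), rng)
        assert A.sum() == 10 * 9

    def test_symmetric_hollow_binary(self, rng):
        z, B, psi = self._parts(rng)
        A = sample_adjacency(z, B, psi, rng)
        assert np.array_equal(A, A.T)
        assert np.all(np.diag(A) == 0)
        assert set(np.unique(A)) <= {0.0, 1.0}

    def test_expected_edge_count(self, rng):
        # for fixed (z, B, psi) the edge count is a sum of independent
        # Bernoullis with known probabilities
        z, B, psi = self._parts(rng, G=60)
        P = np.clip(np.outer(psi.psi, psi.psi) * B.B[np.ix_(z, z)], 0, 1)
        iu = np.triu_indices(60, k=1)
        mean_expected = P[iu].sum()
        sd = np.sqrt((P[iu] * (1 - P[iu])).sum())
        counts = [sample_adjacency(z, B, psi, rng)[iu].sum() for _ in range(200)]
        se = sd / np.sqrt(200)
        assert abs(np.mean(counts) - mean_expected) < 5 * se

    def test_dimension_mismatch_rejected(self, rng):
        z, B, psi = self._parts(rng)
        from mudcod.netsim import DegreeParams

        with pytest.raises(ValueError):
            sample_adjacency(z, B, DegreeParams(np.ones(5)), rng)


class TestGenerate:
    def test_single_static_network(self):
        cfg = SimulationConfig(n_nodes=30, n_communities=3, n_subjects=1,
                               n_times=1, seed=9)
        nets, truth = generate(cfg)
        assert nets.shape == (1, 1, 30)
        assert truth.shape == (1, 1, 30)

    def test_benchmark_config_valid_grid(self):
        cfg = SimulationConfig(n_nodes=120, n_communities=10, n_subjects=2,
                               n_times=2, p_in=(0.2, 0.4), p_out=(0.1, 0.1),
                               seed=10)
        nets, _ = generate(cfg)
        for s in range(2):
            for t in range(2):
                A = nets[s, t]
                assert np.array_equal(A, A.T) and np.all(np.diag(A) == 0)

    def test_same_seed_bitwise_identical(self):
        sim = MuSDynamicDCBM(SimulationConfig(n_nodes=40, n_communities=3,
                                              n_subjects=2, n_times=2, seed=11))
        n1, z1 = sim.generate()
        n2, z2 = sim.generate()
        assert np.array_equal(n1.A, n2.A) and np.array_equal(z1.z, z2.z)

    def test_subgrid_insensitive_to_extra_subjects(self):
        # addressable RNG streams: subject 0's networks do not change when
        # more subjects are added to the simulation
        base = dict(n_nodes=40, n_communities=3, n_times=2, setting="SSoS", seed=12)
        small, _ = generate(SimulationConfig(n_subjects=2, **base))
        large, _ = generate(SimulationConfig(n_subjects=4, **base))
        assert np.array_equal(small.A[0], large.A[0])


class TestLatentAncestor:
    def test_latent_ancestor_keeps_subjects_exchangeable(self):
        # with a latent ancestor every subject, including the first, is a
        # perturbation; with r_subject=0 they all still equal the ancestor
        base = dict(n_nodes=60, n_communities=4, n_subjects=3, n_times=2,
                    r_time=0.3, setting="SSoS", seed=21)
        cfg = SimulationConfig(r_subject=0.0, ancestor_is_subject=False, **base)
        z = generate_membership_series(cfg)
        for t in range(2):
            assert all(np.array_equal(z[0, t], z[s, t]) for s in range(3))

    def test_first_subject_differs_from_ancestor_mode(self):
        base = dict(n_nodes=200, n_communities=4, n_subjects=3, n_times=2,
                    r_time=0.0, r_subject=0.5, setting="SSoS", seed=22)
        z_anc = generate_membership_series(SimulationConfig(**base))
        z_lat = generate_membership_series(
            SimulationConfig(ancestor_is_subject=False, **base)
        )
        # subject 0 is the ancestor chain itself in one mode, a perturbed
        # realization in the other
        assert not np.array_equal(z_anc[0, 0], z_lat[0, 0])
        # other subjects are unaffected by the mode switch
        assert np.array_equal(z_anc[1, 0], z_lat[1, 0])
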