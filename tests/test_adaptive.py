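"""Adaptive dynamics: gradient flow, splitting, merging, full runs."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from dimburst import (
    ADConfig,
    ModelParams,
    evolve,
    make_community,
    merge_close_clusters,
    run_adaptive_dynamics,
    split_random_cluster,
)
from dimburst.equilibrium import Cluster, Community


@pytest.fixture
def cfg():
    return ADConfig(t_max=50.0, seed=7)


class TestEvolve:
    def test_single_cluster_converges_to_optimum(self, p1):
        """d=1 gradient flow has its unique stable fixed point at C.

        The cubic gradient gives algebraic (not exponential) approach,
        |x - C| ~ t^{-1/2}, so a long horizon with large steps is used.
        """
        long_cfg = ADConfig(tau_c=1e7, dt=1e4, t_max=1e6)
        c = make_community([[0.5]], p1)
        out = evolve(c, 1e6, p1, long_cfg)
        assert abs(out.clusters[0].phenotype[0] - p1.C) < 1e-3

    def test_matches_independent_scalar_integration(self, p1, cfg):
        """Compare against a separately written scalar ODE for d=1.

        A lone cluster has N = K(x) (beta = 1) and gradient -(x-C)^3, so
        dx/dt = -K(x) (x - C)^3.
        """

        def rhs(t, x):
            K = np.exp(-((x - p1.C) ** 4) / 4.0)
            return -K * (x - p1.C) ** 3

        sol = solve_ivp(rhs, (0, 20.0), [0.5], rtol=1e-10, atol=1e-12)
        c = make_community([[0.5]], p1)
        out = evolve(c, 20.0, p1, cfg)
        assert out.clusters[0].phenotype[0] == pytest.approx(
            sol.y[0, -1], rel=1e-6
        )

    def test_fixed_point_is_stationary(self, p1, cfg):
        c = make_community([[1.0]], p1)
        out = evolve(c, 10.0, p1, cfg)
        assert out.clusters[0].phenotype[0] == pytest.approx(1.0, abs=1e-12)

    def test_branching_pair_diverges_monotonically(self, p1):
        """A pair split at the branching point moves apart, not together."""
        cfg = ADConfig(t_max=10.0, seed=0, delta_x=1e-3)
        n_half = 0.5  # about half the monomorphic equilibrium at C
        pair = Community(
            [
                Cluster(np.array([1.0 - 5e-4]), n_half),
                Cluster(np.array([1.0 + 5e-4]), n_half),
            ],
            p1,
        )
        dist = [1e-3]
        c = pair
        for _ in range(8):
            c = evolve(c, 1.0, p1, cfg)
            assert len(c) == 2
            dist.append(
                abs(c.clusters[1].phenotype[0] - c.clusters[0].phenotype[0])
            )
        assert all(b > a for a, b in zip(dist, dist[1:]))

    def test_zero_duration_is_identity(self, p1, cfg):
        c = make_community([[0.4]], p1)
        out = evolve(c, 0.0, p1, cfg)
        np.testing.assert_array_equal(
            out.phenotype_matrix(), c.phenotype_matrix()
        )


class TestSplit:
    def test_split_construction(self, p2, rng):
        c = make_community([[1.0, 0.0]], p2)
        parent_n = c.clusters[0].population
        out = split_random_cluster(c, rng, delta_x=1e-3)
        assert len(out) == 2
        a, b = out.clusters
        assert a.population == pytest.approx(parent_n / 2)
        assert b.population == pytest.approx(parent_n / 2)
        assert np.linalg.norm(a.phenotype - b.phenotype) == pytest.approx(1e-3)
        np.testing.assert_allclose(
            (a.phenotype + b.phenotype) / 2, [1.0, 0.0], atol=1e-15
        )

    def test_one_dimensional_displacement_is_sign_only(self, p1, rng):
        c = make_community([[1.0]], p1)
        seen = set()
        for _ in range(40):
            out = split_random_cluster(c, rng, delta_x=1e-3)
            d = out.clusters[1].phenotype[0] - out.clusters[0].phenotype[0]
            assert abs(abs(d) - 1e-3) < 1e-15
            seen.add(np.sign(d))
        assert seen == {-1.0, 1.0}

    def test_direction_distribution_is_isotropic(self, rng):
        p = ModelParams(d_max=3)
        c = make_community([[1.0, 0.0, 0.0]], p)
        dirs = []
        for _ in range(10_000):
            out = split_random_cluster(c, rng, delta_x=1.0)
            dirs.append(out.clusters[1].phenotype - np.array([1.0, 0.0, 0.0]))
        mean = np.mean(dirs, axis=0)
        # mean of 1e4 unit-sphere draws: each component ~ N(0, (2/sqrt(3))/100)
        assert np.all(np.abs(mean) < 0.02)

    def test_empty_community_is_noop(self, p2, rng):
        out = split_random_cluster(Community([], p2), rng, 1e-3)
        assert len(out) == 0


class TestMerge:
    def test_identity_when_all_far(self, p2):
        c = make_community([[0.3, 0.0], [1.7, 0.0]], p2)
        out = merge_close_clusters(c, 1e-3)
        np.testing.assert_array_equal(
            out.phenotype_matrix(), c.phenotype_matrix()
        )

    def test_equal_pair_merges_to_midpoint(self, p1):
        c = Community(
            [
                Cluster(np.array([0.9998]), 0.4),
                Cluster(np.array([1.0002]), 0.4),
            ],
            p1,
        )
        out = merge_close_clusters(c, 1e-3)
        assert len(out) == 1
        assert out.clusters[0].phenotype[0] == pytest.approx(1.0)

    def test_weighted_merge_position(self, p1):
        c = Community(
            [
                Cluster(np.array([1.0]), 0.6),
                Cluster(np.array([1.0003]), 0.2),
            ],
            p1,
        )
        out = merge_close_clusters(c, 1e-3)
        assert out.clusters[0].phenotype[0] == pytest.approx(
            (1.0 * 0.6 + 1.0003 * 0.2) / 0.8
        )

    def test_failed_split_merges_back(self, p1):
        """A split at a saturated interior site fails and is reabsorbed.

        In the saturated four-cluster state the interior sites are hemmed
        in by neighbours, so a fresh pair cannot diverge within tau_c and
        the merge pass undoes the split.
        """
        cfg = ADConfig(t_max=1.0, seed=0, delta_x=1e-3)
        c = make_community([[0.107], [0.768], [1.232], [1.893]], p1)
        c = evolve(c, 50.0, p1, cfg)  # settle onto the fixed point
        parent = c.clusters[1]
        c.clusters[1:2] = [
            Cluster(parent.phenotype - 5e-4, parent.population / 2),
            Cluster(parent.phenotype + 5e-4, parent.population / 2),
        ]
        c = evolve(c, cfg.tau_c, p1, cfg)
        assert len(c) == 5
        c = merge_close_clusters(c, cfg.delta_x)
        assert len(c) == 4


class TestRun:
    def test_deterministic_given_seed(self, p2):
        cfg = ADConfig(t_max=20.0, seed=11)
        c0 = make_community([[0.9, 0.0]], p2)
        t1 = run_adaptive_dynamics(c0, p2, cfg)
        t2 = run_adaptive_dynamics(c0, p2, cfg)
        assert len(t1.snapshots) == len(t2.snapshots)
        for (ta, ca), (tb, cb) in zip(t1.snapshots, t2.snapshots):
            assert ta == tb
            np.testing.assert_array_equal(
                ca.phenotype_matrix(), cb.phenotype_matrix()
            )
        assert t1.events == t2.events

    def test_zero_horizon_keeps_initial_snapshot_only(self, p2):
        cfg = ADConfig(t_max=0.0, seed=1)
        c0 = make_community([[0.9, 0.0]], p2)
        traj = run_adaptive_dynamics(c0, p2, cfg)
        assert len(traj.snapshots) == 1
        assert traj.snapshots[0][0] == 0.0

    def test_cluster_count_plateaus_in_one_dimension(self, p1):
        """Diversification saturates; failed splits merge back afterwards."""
        cfg = ADConfig(t_max=260.0, seed=1)
        traj = run_adaptive_dynamics(make_community([[0.5]], p1), p1, cfg)
        counts = [len(c) for t, c in traj.snapshots]
        # monotone growth phase up to the first time the plateau is hit,
        # then bounded fluctuation around it
        peak = max(counts)
        plateau = counts[-50:]
        assert max(plateau) - min(plateau) <= 1
        assert peak <= max(plateau) + 2

    def test_events_are_logged(self, p2):
        cfg = ADConfig(t_max=10.0, seed=5)
        traj = run_adaptive_dynamics(make_community([[0.9, 0.0]], p2), p2, cfg)
        kinds = {k for _, k, _ in traj.events}
        assert "split" in kinds
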