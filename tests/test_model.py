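"""Core model functions: kernels, rates, and analytic gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dimburst import (
    ModelParams,
    analytic_gradient_2d,
    birth_rate,
    carrying_capacity,
    competition_kernel,
    invasion_fitness,
    make_community,
    pair_repulsion,
    selection_gradient,
    selection_gradients,
)
from dimburst.equilibrium import Cluster, Community, equilibrium_populations

from conftest import random_community_params


class TestCarryingCapacity:
    def test_maximum_at_optimum(self):
        p = ModelParams(d_max=3, C=1.3)
        assert carrying_capacity([1.3, 1.3, 1.3], p) == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "d, x, expected",
        [
            (1, [0.0], np.exp(-0.25)),
            (2, [1.0, 2.0], np.exp(-0.25)),
        ],
    )
    def test_unit_deviation(self, d, x, expected):
        p = ModelParams(d_max=d, C=1.0)
        assert carrying_capacity(x, p) == pytest.approx(expected, rel=1e-12)

    def test_bounds_and_permutation_invariance(self, rng):
        p = ModelParams(d_max=4)
        X = rng.normal(0.5, 1.0, size=(50, 4))
        K = carrying_capacity(X, p)
        assert np.all((K > 0) & (K <= 1))
        perm = X[:, rng.permutation(4)]
        np.testing.assert_allclose(carrying_capacity(perm, p), K, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        p = ModelParams(d_max=3)
        with pytest.raises(ValueError):
            carrying_capacity([1.0, 1.0], p)


class TestBirthRate:
    def test_no_penalty_on_first_coordinate(self, rng):
        p = ModelParams(d_max=3, sigma_beta=0.15, b=0.8)
        for x1 in rng.normal(0, 2, size=10):
            assert birth_rate([x1, 0.0, 0.0], p) == pytest.approx(1.0)

    def test_one_dimensional_product_is_empty(self):
        assert birth_rate([0.3], ModelParams(d_max=1, b=0.5)) == 1.0

    def test_asymptotic_cost(self):
        p = ModelParams(d_max=2, sigma_beta=0.15, b=0.84)
        assert birth_rate([1.0, 50.0], p) == pytest.approx(p.b)

    def test_single_penalized_coordinate_value(self):
        # direct substitution: exp(-1/2) * (1 - b) + b with x2 = sigma_beta
        p = ModelParams(d_max=2, sigma_beta=0.15, b=0.84)
        expected = np.exp(-0.5) * 0.16 + 0.84
        assert birth_rate([1.0, 0.15], p) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9370449, abs=1e-7)

    @given(
        b=st.floats(0.0, 1.0),
        coords=st.lists(st.floats(-3, 3), min_size=2, max_size=4),
    )
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_symmetries(self, b, coords):
        d = len(coords)
        p = ModelParams(d_max=d, b=b)
        val = birth_rate(coords, p)
        assert b ** (d - 1) - 1e-12 <= val <= 1 + 1e-12
        if b == 1.0:
            assert val == pytest.approx(1.0)
        # sign flip of a penalized coordinate
        flipped = list(coords)
        flipped[-1] = -flipped[-1]
        assert birth_rate(flipped, p) == pytest.approx(val, rel=1e-12)
        # permutation of penalized coordinates
        swapped = [coords[0]] + list(reversed(coords[1:]))
        assert birth_rate(swapped, p) == pytest.approx(val, rel=1e-12)


class TestCompetitionKernel:
    def test_self_competition_is_one(self, rng):
        for d in range(1, 6):
            p = ModelParams(d_max=d)
            X = rng.normal(0, 2, size=(20, d))
            np.testing.assert_allclose(competition_kernel(X, X, p), 1.0)

    def test_symmetry(self, rng):
        p = ModelParams(d_max=3)
        x, y = rng.normal(0, 1, size=(2, 3))
        assert competition_kernel(x, y, p) == pytest.approx(
            competition_kernel(y, x, p), rel=1e-14
        )

    def test_offset_by_one_width(self):
        p = ModelParams(d_max=2, sigma_alpha=0.5)
        val = competition_kernel([0.0, 0.0], [0.5, 0.0], p)
        assert val == pytest.approx(np.exp(-0.5), rel=1e-12)


class TestInvasionFitness:
    def test_zero_at_single_resident_equilibrium(self, p2):
        c = make_community([[0.7, 0.1]], p2)
        assert invasion_fitness([0.7, 0.1], c, p2) == pytest.approx(0.0, abs=1e-12)

    def test_monomorphic_closed_form_without_cost(self):
        # with beta = 1 the two-phenotype fitness is beta - alpha K(x)/K(y)
        p = ModelParams(d_max=2, b=1.0)
        x = np.array([0.8, 0.2])
        z = np.array([1.1, -0.3])
        c = make_community([x], p)
        expected = 1.0 - competition_kernel(x, z, p) * carrying_capacity(
            x, p
        ) / carrying_capacity(z, p)
        assert invasion_fitness(z, c, p) == pytest.approx(expected, rel=1e-12)

    def test_far_mutant_grows_at_birth_rate(self, p2):
        # far in a penalized direction the kernel is negligible while the
        # carrying capacity stays moderate, so growth is the bare birth rate
        c = make_community([[1.0, 0.0]], p2)
        z = [1.0, 2.0]
        assert invasion_fitness(z, c, p2) == pytest.approx(
            birth_rate(z, p2), rel=1e-3
        )
        assert invasion_fitness(z, c, p2) > 0

    def test_empty_community_returns_birth_rate(self, p2):
        empty = Community([], p2)
        assert invasion_fitness([0.5, 0.1], empty, p2) == pytest.approx(
            birth_rate([0.5, 0.1], p2)
        )


def _numeric_gradient(z, community, p, h=1e-6):
    z = np.asarray(z, dtype=float)
    out = np.zeros_like(z)
    for i in range(z.size):
        zp, zm = z.copy(), z.copy()
        zp[i] += h
        zm[i] -= h
        out[i] = (
            invasion_fitness(zp, community, p) - invasion_fitness(zm, community, p)
        ) / (2 * h)
    return out


class TestSelectionGradient:
    def test_matches_numeric_gradient_random_communities(self, rng):
        """Analytic gradient vs central differences of the invasion fitness."""
        for d in range(1, 6):
            for _ in range(3):
                p = random_community_params(rng, d)
                n = int(rng.integers(1, 7))
                X = rng.uniform(-0.2, 1.8, size=(n, d))
                N = rng.uniform(0.05, 1.0, size=n)
                c = Community([Cluster(x, nr) for x, nr in zip(X, N)], p)
                for r in range(n):
                    s = selection_gradient(r, c, p)
                    num = _numeric_gradient(X[r], c, p)
                    np.testing.assert_allclose(
                        s, num, rtol=1e-6, atol=1e-6, err_msg=f"d={d} r={r}"
                    )

    def test_first_component_vanishes_at_optimum(self, p2):
        c = make_community([[1.0, 0.0]], p2)
        assert selection_gradient(0, c, p2)[0] == pytest.approx(0.0, abs=1e-14)

    def test_vertical_pull_at_origin_equals_C_cubed(self, p2):
        c = make_community([[1.0, 0.0]], p2)
        assert selection_gradient(0, c, p2)[1] == pytest.approx(
            p2.C**3, rel=1e-12
        )


class TestClosedForm2D:
    def test_matches_generic_gradient(self, rng):
        p = ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.84, sigma_alpha=0.5)
        for _ in range(20):
            x = rng.uniform(-0.3, 1.8, size=2)
            n = birth_rate(x, p) * carrying_capacity(x, p)
            c = Community([Cluster(x, float(n))], p)
            np.testing.assert_allclose(
                selection_gradient(0, c, p),
                analytic_gradient_2d(x, p),
                rtol=1e-10,
                atol=1e-12,
            )

    def test_cost_suppressed_far_from_origin(self):
        p = ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.84, sigma_alpha=0.5)
        x2 = 0.9  # many penalty widths from 0
        s = analytic_gradient_2d([1.0, x2], p)
        assert s[1] == pytest.approx(-((x2 - 1.0) ** 3) * p.b, rel=1e-2)

    def test_rejects_other_dimensions(self):
        with pytest.raises(ValueError):
            analytic_gradient_2d([1.0, 0.0, 0.0], ModelParams(d_max=3))


class TestPairRepulsion:
    def test_vanishes_for_identical_pair(self, p2):
        x = np.array([0.9, 0.1])
        np.testing.assert_array_equal(pair_repulsion(x, x, p2), 0.0)

    def test_antisymmetry(self, p2, rng):
        for _ in range(10):
            x, y = rng.normal(0.8, 0.3, size=(2, 2))
            np.testing.assert_allclose(
                pair_repulsion(x, y, p2), -pair_repulsion(y, x, p2), rtol=1e-14
            )

    def test_limit_of_generic_gradient(self, p2):
        """Sibling contribution to the gradient tends to the closed form.

        A fresh split replaces one cluster at the monomorphic equilibrium
        density with two halves; the gradient difference relative to the
        unsplit cluster isolates the repulsion term to first order.
        """
        delta = 1e-3
        n_full = float(
            birth_rate([1.0, 0.0], p2) * carrying_capacity([1.0, 0.0], p2)
        )
        x = np.array([1.0 + delta, 0.0])
        y = np.array([1.0 - delta, 0.0])
        pair = Community(
            [Cluster(x, n_full / 2), Cluster(y, n_full / 2)], p2
        )
        solo = Community([Cluster(x, n_full)], p2)
        extra = selection_gradient(0, pair, p2) - selection_gradient(0, solo, p2)
        expected = pair_repulsion(x, y, p2)
        np.testing.assert_allclose(extra, expected, atol=5 * delta)
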