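"""Core logistic-competition model in d-dimensional phenotype space.

The model describes frequency-dependent competition between phenotypic
clusters.  A phenotype is a point ``x`` in ``R^d``; its first coordinate is
the ancestral trait and coordinates ``x_2 .. x_d`` are potential new
capabilities ("dimensions") whose acquisition is costly.  Three ingredients
define the ecology:

* carrying capacity ``K(x) = exp(-sum_i (x_i - C)^4 / 4)``, single-humped
  with maximum 1 at ``x = (C, ..., C)``;
* birth rate ``beta(x) = prod_{i>=2} [exp(-x_i^2 / (2 sigma_beta^2))(1-b) + b]``,
  a multiplicative cost per acquired dimension that interpolates from 1
  (coordinate at 0) down to ``b`` (coordinate far from 0);
* a symmetric Gaussian competition kernel
  ``alpha(y, x) = exp(-sum_i (x_i - y_i)^2 / (2 sigma_alpha^2))``.

A rare mutant ``z`` in a resident community with clusters at ``y_r`` and
equilibrium populations ``N_r`` has per-capita growth rate (invasion fitness)

    f(z) = beta(z) - sum_r alpha(y_r, z) N_r / K(z),

and the selection gradient is the z-derivative of ``f`` at a resident point.
All derivatives are hand-coded analytic expressions; a finite-difference
version is kept in the test suite as an independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .equilibrium import Community

__all__ = [
    "ModelParams",
    "carrying_capacity",
    "birth_rate",
    "competition_kernel",
    "invasion_fitness",
    "selection_gradient",
    "selection_gradients",
    "analytic_gradient_2d",
    "pair_repulsion",
]


@dataclass(frozen=True)
class ModelParams:
    """Constants of the competition model.

    Parameters
    ----------
    d_max : int
        Dimension of phenotype space (number of trait coordinates).
    C : float
        Coordinate of the carrying-capacity optimum, the same in every
        dimension (dimensionless trait units, of order 1).
    sigma_beta : float
        Width of the birth-rate penalty around 0 in each costly coordinate.
    b : float
        Asymptotic birth-rate factor per acquired dimension, ``0 <= b <= 1``;
        the cost of a fully acquired dimension is ``1 - b``.
    sigma_alpha : float
        Width of the Gaussian competition kernel.
    """

    d_max: int = 5
    C: float = 1.0
    sigma_beta: float = 0.15
    b: float = 0.883
    sigma_alpha: float = 0.5

    def __post_init__(self) -> None:
        if int(self.d_max) != self.d_max or self.d_max < 1:
            raise ValueError(f"d_max must be an integer >= 1, got {self.d_max}")
        if not self.sigma_beta > 0:
            raise ValueError(f"sigma_beta must be > 0, got {self.sigma_beta}")
        if not self.sigma_alpha > 0:
            raise ValueError(f"sigma_alpha must be > 0, got {self.sigma_alpha}")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError(f"b must lie in [0, 1], got {self.b}")
        if not self.C > 0:
            raise ValueError(f"C must be > 0, got {self.C}")


def _as_phenotypes(x, d: int) -> np.ndarray:
    """Coerce ``x`` to a float array with trailing axis of length ``d``."""
    arr = np.asarray(x, dtype=float)
    if arr.shape[-1:] != (d,):
        raise ValueError(
            f"phenotype has {arr.shape[-1] if arr.ndim else 0} coordinates, "
            f"expected {d}"
        )
    return arr


def carrying_capacity(x, p: ModelParams):
    """Quartic single-humped carrying capacity ``K(x)`` in ``(0, 1]``.

    Accepts a single phenotype ``(d,)`` or a stack ``(..., d)``.
    """
    arr = _as_phenotypes(x, p.d_max)
    return np.exp(-np.sum((arr - p.C) ** 4, axis=-1) / 4.0)


def birth_rate(x, p: ModelParams):
    """Birth rate ``beta(x)``: product of per-dimension cost factors.

    The first coordinate carries no penalty; for ``d_max == 1`` the product
    is empty and the birth rate is identically 1.
    """
    arr = _as_phenotypes(x, p.d_max)
    if p.d_max == 1:
        return np.ones(arr.shape[:-1]) if arr.ndim > 1 else 1.0
    pen = arr[..., 1:]
    factors = np.exp(-(pen**2) / (2.0 * p.sigma_beta**2)) * (1.0 - p.b) + p.b
    return np.prod(factors, axis=-1)


def competition_kernel(y, x, p: ModelParams):
    """Symmetric Gaussian competition kernel ``alpha(y, x)``.

    Measures the competitive impact of phenotype ``y`` on ``x``; equals 1
    iff ``x == y`` and decays with the Euclidean trait distance.  ``y`` and
    ``x`` must have the same number of coordinates (broadcasting over
    leading axes is supported).
    """
    ya = np.asarray(y, dtype=float)
    xa = np.asarray(x, dtype=float)
    if ya.shape[-1:] != xa.shape[-1:]:
        raise ValueError("phenotypes have different lengths")
    return np.exp(-np.sum((xa - ya) ** 2, axis=-1) / (2.0 * p.sigma_alpha**2))


# ---------------------------------------------------------------------------
# array-level helpers used by the solvers (X: (n, d) matrix of phenotypes)


def alpha_matrix(X: np.ndarray, p: ModelParams) -> np.ndarray:
    """Pairwise kernel matrix ``A[r, j] = alpha(x_r, x_j)`` (symmetric)."""
    diff = X[:, None, :] - X[None, :, :]
    return np.exp(-np.sum(diff**2, axis=-1) / (2.0 * p.sigma_alpha**2))


def _beta_partials(X: np.ndarray, p: ModelParams) -> np.ndarray:
    """Analytic ``d beta / d x_i`` for each row of X, shape (n, d)."""
    n, d = X.shape
    out = np.zeros((n, d))
    if d == 1:
        return out
    pen = X[:, 1:]
    gauss = np.exp(-(pen**2) / (2.0 * p.sigma_beta**2))
    factors = gauss * (1.0 - p.b) + p.b
    beta = np.prod(factors, axis=1)
    dfac = -(pen / p.sigma_beta**2) * gauss * (1.0 - p.b)
    # beta * g'_i / g_i; factors >= b > 0 unless b == 0 and x_i large,
    # in which case the product form below stays finite.
    with np.errstate(divide="ignore", invalid="ignore"):
        out[:, 1:] = np.where(
            factors > 0, beta[:, None] * dfac / factors, 0.0
        )
    if p.b == 0.0:
        # recompute degenerate columns explicitly (factor can underflow to 0)
        for i in range(1, d):
            others = np.prod(np.delete(factors, i - 1, axis=1), axis=1)
            out[:, i] = others * dfac[:, i - 1]
    return out


def selection_gradients(
    X: np.ndarray, N: np.ndarray, p: ModelParams
) -> np.ndarray:
    """Selection gradient ``s_i(x_r)`` for every cluster, shape (n, d).

    Implements the z-gradient of the invasion fitness
    ``f(z) = beta(z) - sum_j alpha(y_j, z) N_j / K(z)`` evaluated at each
    resident phenotype, using analytic derivatives of beta, alpha and K.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    N = np.asarray(N, dtype=float)
    A = alpha_matrix(X, p)
    K = carrying_capacity(X, p)
    dbeta = _beta_partials(X, p)
    # competition-gradient term: + sum_j N_j alpha_jr (x_r - x_j)_i / (sa^2 K_r)
    diff = X[:, None, :] - X[None, :, :]  # (r, j, i)
    comp = np.einsum("j,rj,rji->ri", N, A, diff) / (p.sigma_alpha**2)
    comp /= K[:, None]
    # carrying-capacity term: - (x_r - C)^3 * sum_j alpha_jr N_j / K_r
    load = A @ N  # sum_j alpha(x_j, x_r) N_j
    kterm = -((X - p.C) ** 3) * (load / K)[:, None]
    return dbeta + comp + kterm


def invasion_fitness(z, community: "Community", p: ModelParams):
    """Per-capita growth rate of a rare mutant ``z`` in a resident community.

    Returns ``beta(z) - sum_r alpha(y_r, z) N_r / K(z)``.  An empty
    community gives just ``beta(z)``.
    """
    za = _as_phenotypes(z, p.d_max)
    beta = birth_rate(za, p)
    K = carrying_capacity(za, p)
    if len(community) == 0:
        return beta
    X = community.phenotype_matrix()
    N = community.populations()
    a = competition_kernel(X, za[..., None, :], p)  # (..., n)
    return beta - (a @ N) / K


def selection_gradient(r: int, community: "Community", p: ModelParams) -> np.ndarray:
    """Selection gradient acting on cluster ``r`` of a community."""
    X = community.phenotype_matrix()
    N = community.populations()
    return selection_gradients(X, N, p)[r]


# ---------------------------------------------------------------------------
# closed-form oracles for the one- and two-cluster geometries


def analytic_gradient_2d(x, p: ModelParams) -> np.ndarray:
    """Closed-form selection gradient of a lone 2-D cluster at equilibrium.

    Valid for ``d_max == 2`` and a single resident with population
    ``N = beta(x) K(x)``:

        s_1 = -(x_1 - C)^3 [exp(-x_2^2/(2 sb^2))(1-b) + b]
        s_2 = -(x_2/sb^2) exp(-x_2^2/(2 sb^2)) (1-b)
              -(x_2 - C)^3 [exp(-x_2^2/(2 sb^2))(1-b) + b]
    """
    if p.d_max != 2:
        raise ValueError("closed form is specific to d_max == 2")
    x1, x2 = _as_phenotypes(x, 2)
    gauss = np.exp(-(x2**2) / (2.0 * p.sigma_beta**2))
    g = gauss * (1.0 - p.b) + p.b
    s1 = -((x1 - p.C) ** 3) * g
    s2 = -(x2 / p.sigma_beta**2) * gauss * (1.0 - p.b) - ((x2 - p.C) ** 3) * g
    return np.array([s1, s2])


def pair_repulsion(x, y, p: ModelParams) -> np.ndarray:
    """Competitive repulsion between the two halves of a freshly split cluster.

    For two nearby clusters ``x`` and ``y`` each holding about half the
    local carrying capacity, the extra contribution to the selection
    gradient of ``x`` is

        s~_i(x) = (x_i - y_i) / (2 sigma_alpha^2)
                  * exp(-sum_k (x_k - y_k)^2 / (2 sigma_alpha^2)),

    antisymmetric under exchange of the pair: ``s~(y) = -s~(x)``.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    a = np.exp(-np.sum((xa - ya) ** 2, axis=-1) / (2.0 * p.sigma_alpha**2))
    return (xa - ya) / (2.0 * p.sigma_alpha**2) * a
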