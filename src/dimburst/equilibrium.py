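"""Ecological equilibrium of a set of phenotypic clusters.

At fixed phenotypes the cluster populations follow logistic dynamics

    dN_r/dt = N_r [ beta(y_r) - sum_j alpha(y_j, y_r) N_j / K(y_r) ],

whose interior stationary point solves the linear system
``sum_j alpha(y_j, y_r) N_j = beta(y_r) K(y_r)``.  Because the evolutionary
dynamics is slow relative to population growth, the simulators treat the
ecology as quasi-static: populations are always the stationary solution of
the system above, with non-viable clusters (non-positive solution) marked
extinct by iterative removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .model import ModelParams, alpha_matrix, birth_rate, carrying_capacity

__all__ = [
    "Cluster",
    "Community",
    "equilibrium_populations",
    "prune_extinct",
    "make_community",
]

#: phenotypes closer than this are numerically coincident and merged
#: before the linear solve to keep the interaction matrix non-singular
COINCIDENT_TOL = 1e-12

@dataclass
class Cluster:
    """A monomorphic population: a point in phenotype space with a density."""

    phenotype: np.ndarray
    population: float = 0.0

    def __post_init__(self) -> None:
        self.phenotype = np.asarray(self.phenotype, dtype=float)
        if self.population < 0:
            raise ValueError("population must be nonnegative")


@dataclass
class Community:
    """An ordered set of clusters with model parameters and a clock."""

    clusters: list[Cluster]
    params: ModelParams
    time: float = 0.0

    def __len__(self) -> int:
        return len(self.clusters)

    def phenotype_matrix(self) -> np.ndarray:
        """Cluster phenotypes stacked as an ``(n, d)`` array."""
        if not self.clusters:
            return np.empty((0, self.params.d_max))
        return np.array([c.phenotype for c in self.clusters])

    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.clusters])

    def copy(self) -> "Community":
        return Community(
            [Cluster(c.phenotype.copy(), c.population) for c in self.clusters],
            self.params,
            self.time,
        )


def _merge_coincident(X: np.ndarray, tol: float = COINCIDENT_TOL):
    """Group numerically coincident rows; return (unique X, group index)."""
    n = X.shape[0]
    group = -np.ones(n, dtype=int)
    reps: list[int] = []
    for i in range(n):
        for gi, rep in enumerate(reps):
            if np.linalg.norm(X[i] - X[rep]) < tol:
                group[i] = gi
                break
        else:
            group[i] = len(reps)
            reps.append(i)
    return X[reps], group


def equilibrium_populations(phenotypes, p: ModelParams) -> np.ndarray:
    """Stationary populations of the logistic system for given phenotypes.

    Solves the linear interaction system
    ``sum_j alpha(y_j, y_r) N_j = beta(y_r) K(y_r)`` and enforces
    feasibility: while any solution component is non-positive, the most
    negative cluster is removed (competitively excluded) and the system
    re-solved.  Excluded clusters are returned with population 0.

    Feasibility of the linear solution is the Lotka-Volterra condition for
    protected coexistence, so a freshly split pair straddling an
    evolutionary branching point keeps both halves, while a near-duplicate
    pair anywhere else loses one member to competitive exclusion.

    Parameters
    ----------
    phenotypes : array-like, shape (n, d) or sequence of length-d vectors
    p : ModelParams

    Returns
    -------
    ndarray, shape (n,) of nonnegative populations.
    """
    X = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    n = X.shape[0]
    if n == 0:
        return np.zeros(0)
    Xu, group = _merge_coincident(X)
    m = Xu.shape[0]
    # exactly coincident phenotypes share one equation; the solved density
    # is split evenly among the duplicates afterwards
    counts = np.bincount(group, minlength=m)
    A = alpha_matrix(Xu, p)
    target = birth_rate(Xu, p) * carrying_capacity(Xu, p)
    active = np.arange(m)
    Nu = np.zeros(m)
    while active.size:
        sol = np.linalg.solve(A[np.ix_(active, active)], target[active])
        if np.all(sol > 0):
            Nu[active] = sol
            break
        worst = np.argmin(sol)
        active = np.delete(active, worst)
    return Nu[group] / counts[group]


def make_community(
    phenotypes, p: ModelParams, time: float = 0.0
) -> Community:
    """Build a community at ecological equilibrium from bare phenotypes."""
    X = np.atleast_2d(np.asarray(phenotypes, dtype=float))
    N = equilibrium_populations(X, p)
    return Community(
        [Cluster(x.copy(), float(n)) for x, n in zip(X, N)], p, time
    )


def prune_extinct(community: Community) -> Community:
    """Drop zero-population clusters and re-equilibrate the survivors.

    Idempotent; an all-extinct input yields an empty community.
    """
    survivors = [c for c in community.clusters if c.population > 0]
    if not survivors:
        return Community([], community.params, community.time)
    X = np.array([c.phenotype for c in survivors])
    N = equilibrium_populations(X, community.params)
    keep = [
        Cluster(x.copy(), float(n)) for x, n in zip(X, N) if n > 0
    ]
    if len(keep) < len(survivors):
        # a removal can cascade; recurse until stable
        return prune_extinct(
            Community(keep, community.params, community.time)
        )
    return Community(keep, community.params, community.time)
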