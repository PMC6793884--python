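"""Individual-based stochastic realization of the competition model.

Every individual carries a phenotype ``x``; births occur at rate
``beta(x)`` and deaths at rate ``sum_{p != i} alpha(x_p, x_i) / (K0 K(x_i))``
(the competitive load of all other individuals, scaled by the carrying
capacity).  Offspring inherit the parental phenotype plus an independent
Gaussian offset per coordinate — mutation is the only source of phenotypic
novelty.  The simulation is an exact event-driven (Gillespie) scheme: event
times are exponential in the total rate, and the event type and focal
individual are drawn proportionally to the individual rates.

The inner loop caches the pairwise competition load ``S_i`` of every
individual and updates it in O(population) per event; the O(population^2)
from-scratch recomputation is kept in the test suite as an oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .model import ModelParams, alpha_matrix, birth_rate, carrying_capacity

__all__ = [
    "IBSConfig",
    "IndividualPopulation",
    "IBSTrajectory",
    "event_rates",
    "default_population",
    "run_ibs",
]


@dataclass(frozen=True)
class IBSConfig:
    """Settings of the individual-based run.

    K0 : carrying-capacity scale (individuals at the capacity optimum)
    sigma_mut : per-coordinate mutation standard deviation
    t_max : simulated time
    seed : RNG seed
    record_every : snapshot interval (time units)
    max_population : hard buffer bound; exceeding it aborts the run
    """

    K0: float = 500.0
    sigma_mut: float = 1e-2
    t_max: float = 100.0
    seed: int = 0
    record_every: float = 1.0
    max_population: int = 20000

    def __post_init__(self) -> None:
        if not self.K0 > 0:
            raise ValueError("K0 must be > 0")
        if self.sigma_mut < 0:
            raise ValueError("sigma_mut must be >= 0")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")


@dataclass
class IndividualPopulation:
    """Phenotypes of all living individuals at a moment in time."""

    phenotypes: np.ndarray  # (n, d)
    time: float = 0.0

    def __post_init__(self) -> None:
        self.phenotypes = np.atleast_2d(np.asarray(self.phenotypes, dtype=float))

    def __len__(self) -> int:
        return self.phenotypes.shape[0]


@dataclass
class IBSTrajectory:
    """Recorded snapshots of an individual-based run."""

    snapshots: list[tuple[float, np.ndarray]] = field(default_factory=list)
    status: str = "completed"  # completed | extinct | overflow | stopped

    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.snapshots])

    def final(self) -> IndividualPopulation:
        t, X = self.snapshots[-1]
        return IndividualPopulation(X.copy(), t)


def event_rates(
    popn: IndividualPopulation, p: ModelParams, cfg: IBSConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual birth and death rates, computed from scratch.

    Individual ``i`` is born at rate ``beta(x_i)`` and dies at rate
    ``sum_{p != i} alpha(x_p, x_i) / (K0 K(x_i))`` — competition excludes
    the individual itself, so a lone individual never dies.
    """
    X = popn.phenotypes
    n = len(popn)
    if n == 0:
        return np.zeros(0), np.zeros(0)
    births = np.atleast_1d(birth_rate(X, p))
    A = alpha_matrix(X, p)
    S = A.sum(axis=1) - 1.0  # subtract the self term alpha(x, x) = 1
    deaths = S / (cfg.K0 * np.atleast_1d(carrying_capacity(X, p)))
    return births, deaths


# ---------------------------------------------------------------------------
# numba kernels


@njit(cache=False)
def _seed_rng(seed):  # numba keeps a process-global RNG state
    np.random.seed(seed)


@njit(cache=False)
def _init_load(X, n, inv2sa2, S):
    """Pairwise competition load S_i = sum_{p != i} alpha(x_p, x_i)."""
    d = X.shape[1]
    for i in range(n):
        S[i] = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            s = 0.0
            for k in range(d):
                diff = X[i, k] - X[j, k]
                s += diff * diff
            a = np.exp(-s * inv2sa2)
            S[i] += a
            S[j] += a


@njit(cache=False)
def _beta_one(x, sigma_beta, b):
    out = 1.0
    for k in range(1, x.shape[0]):
        out *= np.exp(-x[k] * x[k] / (2.0 * sigma_beta * sigma_beta)) * (1.0 - b) + b
    return out


@njit(cache=False)
def _K_one(x, C):
    s = 0.0
    for k in range(x.shape[0]):
        diff = x[k] - C
        s += diff**4
    return np.exp(-s / 4.0)


@njit(cache=False)
def _advance(
    X, beta, Kv, S, n, t, t_end,
    C, sigma_beta, b, inv2sa2, K0, sigma_mut,
):
    """Run birth/death events in place until ``t_end``.

    Returns (n, t, status) with status 0 = reached t_end, 1 = extinct,
    2 = buffer overflow.
    """
    cap = X.shape[0]
    d = X.shape[1]
    while True:
        if n == 0:
            return n, t, 1
        B = 0.0
        D = 0.0
        for i in range(n):
            B += beta[i]
            D += S[i] / (K0 * Kv[i])
        tot = B + D
        dt = -np.log(np.random.random()) / tot
        if t + dt > t_end:
            return n, t_end, 0
        t += dt
        if np.random.random() * tot < B:
            # birth: pick parent proportional to beta
            u = np.random.random() * B
            acc = 0.0
            i = n - 1
            for j in range(n):
                acc += beta[j]
                if u < acc:
                    i = j
                    break
            if n >= cap:
                return n, t, 2
            Sn = 0.0
            for k in range(d):
                X[n, k] = X[i, k] + sigma_mut * np.random.normal(0.0, 1.0)
            for j in range(n):
                s = 0.0
                for k in range(d):
                    diff = X[n, k] - X[j, k]
                    s += diff * diff
                a = np.exp(-s * inv2sa2)
                S[j] += a
                Sn += a
            S[n] = Sn
            beta[n] = _beta_one(X[n], sigma_beta, b)
            Kv[n] = _K_one(X[n], C)
            n += 1
        else:
            # death: pick victim proportional to S_i / (K0 K_i)
            u = np.random.random() * D
            acc = 0.0
            i = n - 1
            for j in range(n):
                acc += S[j] / (K0 * Kv[j])
                if u < acc:
                    i = j
                    break
            for j in range(n):
                if j == i:
                    continue
                s = 0.0
                for k in range(d):
                    diff = X[i, k] - X[j, k]
                    s += diff * diff
                S[j] -= np.exp(-s * inv2sa2)
            last = n - 1
            if i != last:
                for k in range(d):
                    X[i, k] = X[last, k]
                beta[i] = beta[last]
                Kv[i] = Kv[last]
                S[i] = S[last]
            n -= 1


class _IBSState:
    """Buffers shared between the python driver and the numba kernels."""

    def __init__(self, X0: np.ndarray, p: ModelParams, cfg: IBSConfig):
        cap = cfg.max_population
        n, d = X0.shape
        if n > cap:
            raise ValueError("initial population exceeds max_population")
        self.X = np.zeros((cap, d))
        self.X[:n] = X0
        self.beta = np.zeros(cap)
        self.K = np.zeros(cap)
        self.S = np.zeros(cap)
        self.beta[:n] = np.atleast_1d(birth_rate(X0, p))
        self.K[:n] = np.atleast_1d(carrying_capacity(X0, p))
        inv2sa2 = 1.0 / (2.0 * p.sigma_alpha**2)
        _init_load(self.X, n, inv2sa2, self.S)
        self.n = n
        self.inv2sa2 = inv2sa2


def default_population(
    p: ModelParams, cfg: IBSConfig, rng: np.random.Generator | None = None
) -> IndividualPopulation:
    """Founding population: ``K0 beta K`` copies near ``(0.9 C, 0, ..., 0)``.

    Phenotypes are jittered by ``sigma_mut`` per coordinate so the initial
    cloud has the same spread a mutation-fed population would.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    base = np.zeros(p.d_max)
    base[0] = 0.9 * p.C
    n = max(1, int(round(cfg.K0 * birth_rate(base, p) * carrying_capacity(base, p))))
    X = base + cfg.sigma_mut * rng.standard_normal((n, p.d_max))
    return IndividualPopulation(X, 0.0)


def run_ibs(
    initial: IndividualPopulation,
    p: ModelParams,
    cfg: IBSConfig,
    stop=None,
) -> IBSTrajectory:
    """Exact event-driven simulation, recording snapshots at fixed intervals.

    Deterministic given ``cfg.seed``.  An optional ``stop`` predicate on
    ``IndividualPopulation`` is evaluated at every snapshot and ends the
    run early.  The run also ends on extinction or on hitting the
    population buffer bound.
    """
    if len(initial) == 0:
        raise ValueError("initial population must be nonempty")
    state = _IBSState(initial.phenotypes, p, cfg)
    _seed_rng(cfg.seed % 2**32)
    traj = IBSTrajectory()
    t = initial.time
    t_end = initial.time + cfg.t_max
    traj.snapshots.append((t, state.X[: state.n].copy()))
    while t < t_end - 1e-12:
        t_next = min(t + cfg.record_every, t_end)
        state.n, t, status = _advance(
            state.X, state.beta, state.K, state.S, state.n, t, t_next,
            p.C, p.sigma_beta, p.b, state.inv2sa2, cfg.K0, cfg.sigma_mut,
        )
        traj.snapshots.append((t, state.X[: state.n].copy()))
        if status == 1:
            traj.status = "extinct"
            return traj
        if status == 2:
            traj.status = "overflow"
            return traj
        if stop is not None and stop(IndividualPopulation(state.X[: state.n].copy(), t)):
            traj.status = "stopped"
            return traj
    return traj
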