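"""Adaptive dynamics of phenotypic clusters with stochastic diversification.

Between diversification events the cluster phenotypes follow the canonical
gradient dynamics

    dx_r/dt = N_r s(x_r),

with the populations N_r held at their quasi-static ecological equilibrium
(recomputed at every right-hand-side evaluation).  Diversification is a
split/merge procedure: every ``tau_c`` time units one cluster, picked
uniformly at random, is split into two halves separated by ``delta_x`` in a
random direction; just before the next split, any clusters closer than
``delta_x`` are merged back.  A split therefore only "takes" when disruptive
selection actively drives the halves apart — this is how evolutionary
branching enters the deterministic dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .equilibrium import (
    Cluster,
    Community,
    equilibrium_populations,
    prune_extinct,
)
from .model import ModelParams, selection_gradients

__all__ = [
    "ADConfig",
    "ADTrajectory",
    "evolve",
    "split_random_cluster",
    "merge_close_clusters",
    "run_adaptive_dynamics",
]


@dataclass(frozen=True)
class ADConfig:
    """Settings of the adaptive-dynamics run.

    tau_c : time between split attempts (model time units, ~1)
    delta_x : split separation and merge threshold (~1e-3)
    dt : upper bound on the integrator step
    t_max : total simulated time
    seed : RNG seed (splits are the only stochastic element)
    record_every : snapshot interval (snapshots align with tau_c boundaries)
    """

    tau_c: float = 1.0
    delta_x: float = 1e-3
    dt: float = 0.1
    t_max: float = 100.0
    seed: int = 0
    record_every: float = 1.0

    def __post_init__(self) -> None:
        if not self.tau_c > 0:
            raise ValueError("tau_c must be > 0")
        if not 0 < self.delta_x:
            raise ValueError("delta_x must be > 0")
        if self.dt > self.tau_c:
            raise ValueError("dt must not exceed tau_c")
        if self.t_max < 0:
            raise ValueError("t_max must be >= 0")


@dataclass
class ADTrajectory:
    """Time-stamped snapshots of a community plus the diversification log."""

    snapshots: list[tuple[float, Community]] = field(default_factory=list)
    events: list[tuple[float, str, str]] = field(default_factory=list)

    def times(self) -> np.ndarray:
        return np.array([t for t, _ in self.snapshots])

    def final(self) -> Community:
        return self.snapshots[-1][1]


def _rhs(t: float, y: np.ndarray, n: int, d: int, p: ModelParams) -> np.ndarray:
    X = y.reshape(n, d)
    N = equilibrium_populations(X, p)
    S = selection_gradients(X, N, p)
    return (N[:, None] * S).ravel()


def evolve(
    community: Community, duration: float, p: ModelParams, cfg: ADConfig
) -> Community:
    """Integrate the gradient dynamics of all clusters over ``duration``.

    Populations are recomputed from the ecological equilibrium at every
    right-hand-side evaluation; clusters driven extinct (equilibrium
    population 0) stop moving and are pruned from the returned community.
    """
    if len(community) == 0 or duration == 0:
        out = community.copy()
        out.time += duration
        return out
    n, d = len(community), p.d_max
    y0 = community.phenotype_matrix().ravel()
    sol = solve_ivp(
        _rhs,
        (0.0, duration),
        y0,
        method="RK45",
        max_step=cfg.dt,
        rtol=1e-8,
        atol=1e-10,
        args=(n, d, p),
    )
    if not sol.success:  # pragma: no cover - integrator failure diagnostics
        raise RuntimeError(
            f"integrator failed at t={community.time}: {sol.message}; "
            f"state={y0!r}"
        )
    X = sol.y[:, -1].reshape(n, d)
    N = equilibrium_populations(X, p)
    out = Community(
        [Cluster(x.copy(), float(nr)) for x, nr in zip(X, N)],
        p,
        community.time + duration,
    )
    return prune_extinct(out)


def split_random_cluster(
    community: Community, rng: np.random.Generator, delta_x: float
) -> Community:
    """Split one uniformly chosen cluster into two halves ``delta_x`` apart.

    Each daughter inherits half the parental population and is displaced by
    ``(delta_x / 2) * u`` on either side of the parent, with ``u`` uniform
    on the unit sphere, so the parental centroid is preserved.  An empty
    community is returned unchanged.
    """
    if len(community) == 0:
        return community.copy()
    out = community.copy()
    idx = int(rng.integers(len(out)))
    parent = out.clusters[idx]
    d = community.params.d_max
    u = rng.standard_normal(d)
    norm = np.linalg.norm(u)
    while norm < 1e-12:  # pragma: no cover - essentially impossible
        u = rng.standard_normal(d)
        norm = np.linalg.norm(u)
    u /= norm
    half = parent.population / 2.0
    lo = Cluster(parent.phenotype - 0.5 * delta_x * u, half)
    hi = Cluster(parent.phenotype + 0.5 * delta_x * u, half)
    out.clusters[idx : idx + 1] = [lo, hi]
    return out


def _merge_pass(
    community: Community, threshold: float
) -> tuple[Community, list[str]]:
    """Merge closest pairs under ``threshold`` until none remain."""
    items = [(c.phenotype.copy(), c.population) for c in community.clusters]
    merges: list[str] = []
    while len(items) > 1:
        X = np.array([x for x, _ in items])
        diff = X[:, None, :] - X[None, :, :]
        dist = np.sqrt(np.sum(diff**2, axis=-1))
        np.fill_diagonal(dist, np.inf)
        i, j = np.unravel_index(np.argmin(dist), dist.shape)
        if dist[i, j] >= threshold:
            break
        (xi, ni), (xj, nj) = items[i], items[j]
        tot = ni + nj
        xm = (xi * ni + xj * nj) / tot if tot > 0 else 0.5 * (xi + xj)
        merges.append(f"merged pair at distance {dist[i, j]:.3g}")
        keep = [it for k, it in enumerate(items) if k not in (i, j)]
        keep.append((xm, tot))
        items = keep
    if not merges:
        return community.copy(), merges
    X = np.array([x for x, _ in items])
    N = equilibrium_populations(X, community.params)
    merged = Community(
        [Cluster(x, float(n)) for x, n in zip(X, N)],
        community.params,
        community.time,
    )
    return prune_extinct(merged), merges


def merge_close_clusters(community: Community, threshold: float) -> Community:
    """Merge clusters pairwise while any two are closer than ``threshold``.

    The closest pair is replaced by a single cluster at the
    population-weighted mean phenotype with the summed population; the
    ecological equilibrium is recomputed afterwards.
    """
    merged, _ = _merge_pass(community, threshold)
    return merged


def run_adaptive_dynamics(
    initial: Community,
    p: ModelParams,
    cfg: ADConfig,
    stop: Optional[Callable[[Community], bool]] = None,
) -> ADTrajectory:
    """Run the full split/evolve/merge loop until ``cfg.t_max``.

    Per cycle of length ``tau_c``: the community evolves along the gradient
    dynamics, clusters closer than ``delta_x`` are merged, a snapshot is
    recorded, and one random cluster is split.  Runs are deterministic
    given ``cfg.seed``.  An optional ``stop`` predicate, evaluated on the
    post-merge community, ends the run early (used for saturation- or
    expansion-triggered experiments).
    """
    rng = np.random.default_rng(cfg.seed)
    traj = ADTrajectory()
    community = initial.copy()
    traj.snapshots.append((community.time, community.copy()))
    t0 = community.time
    next_record = t0 + cfg.record_every
    t = t0
    while t < t0 + cfg.t_max - 1e-12:
        step = min(cfg.tau_c, t0 + cfg.t_max - t)
        before = len(community)
        community = evolve(community, step, p, cfg)
        t = community.time
        if len(community) < before:
            traj.events.append(
                (t, "extinction", f"{before - len(community)} cluster(s) pruned")
            )
        community, merges = _merge_pass(community, cfg.delta_x)
        for msg in merges:
            traj.events.append((t, "merge", msg))
        if len(community) == 0:
            traj.events.append((t, "extinction", "community empty, run ended"))
            traj.snapshots.append((t, community.copy()))
            break
        if t >= next_record - 1e-9:
            traj.snapshots.append((t, community.copy()))
            while next_record <= t + 1e-9:
                next_record += cfg.record_every
        if stop is not None and stop(community):
            break
        if t < t0 + cfg.t_max - 1e-12:
            community = split_random_cluster(community, rng, cfg.delta_x)
            traj.events.append((t, "split", f"{len(community) - 1} -> {len(community)} clusters"))
    return traj
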