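"""Canned experiments: expansion timing, saturation, and burst detection.

These functions reproduce the model's reference numerical experiments —
when does a community first expand into a new phenotypic dimension, and
how many clusters does the existing dimension hold at that moment — with a
shared detector that separates *successful* expansions from transient
excursions.  A crossing of the acquisition threshold ``2 sigma_beta``
counts as an expansion only if some cluster stays above the threshold
continuously for a persistence window and climbs past an escape level
(``3 sigma_beta``) on the way to the new optimum; failed attempts collapse
back within a few time units and never reach that level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .adaptive import ADConfig, run_adaptive_dynamics
from .equilibrium import make_community
from .ibs import IBSConfig, default_population, run_ibs
from .model import ModelParams
from .observables import detect_clusters_points
from .pde import PDEConfig, default_field, run_pde

__all__ = [
    "ExpansionResult",
    "ad_expansion_experiment",
    "ibs_expansion_experiment",
    "pde_expansion_experiment",
    "ad_saturation_experiment",
    "burst_experiment",
]


@dataclass
class ExpansionResult:
    """Outcome of an expansion-timing experiment.

    t_cross : time of the first *sustained* crossing of the acquisition
        threshold by a cluster (nan if none happened before t_max)
    n_below : number of clusters at or below the threshold at that moment
    t_reach4 : first time the count of clusters at or below the threshold
        reached 4 (nan if never)
    history : (time, count at or below threshold) pairs up to t_cross
    """

    t_cross: float
    n_below: int
    t_reach4: float
    history: list[tuple[float, int]] = field(default_factory=list)


class _SustainedCrossing:
    """Online detector of a sustained threshold crossing.

    ``update`` is fed (time, x2 values of cluster centroids, count at or
    below threshold) per snapshot and returns True once some centroid has
    been continuously above ``threshold`` for ``persistence`` time units
    and the episode has reached ``escape_level``.  The reported crossing
    time and below-count refer to the first snapshot of that episode.
    """

    def __init__(self, threshold: float, escape_level: float, persistence: float):
        self.threshold = threshold
        self.escape_level = escape_level
        self.persistence = persistence
        self.episode_start: float | None = None
        self.episode_n_below = 0
        self.episode_escaped = False

    def update(self, t: float, x2: np.ndarray, n_below: int) -> bool:
        above = x2 > self.threshold
        if not np.any(above):
            self.episode_start = None
            self.episode_escaped = False
            return False
        if self.episode_start is None:
            self.episode_start = t
            self.episode_n_below = n_below
        if np.any(x2 > self.escape_level):
            self.episode_escaped = True
        return (
            self.episode_escaped
            and t - self.episode_start >= self.persistence
        )


def ad_expansion_experiment(
    seed: int,
    p: ModelParams | None = None,
    t_max: float = 2000.0,
    persistence: float = 10.0,
) -> ExpansionResult:
    """Adaptive-dynamics expansion from a single 1-D cluster.

    Runs the 2-D engine from one cluster near the carrying-capacity
    maximum until the first sustained crossing of ``x2 = 2 sigma_beta``
    and reports the number of clusters still at or below the threshold at
    the crossing snapshot.
    """
    if p is None:
        p = ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.85, sigma_alpha=0.5)
    cfg = ADConfig(t_max=t_max, seed=seed, record_every=1.0)
    thr = 2.0 * p.sigma_beta
    det = _SustainedCrossing(thr, 3.0 * p.sigma_beta, persistence)
    history: list[tuple[float, int]] = []

    def stop(community) -> bool:
        x2 = community.phenotype_matrix()[:, 1]
        n_below = int(np.sum(x2 <= thr))
        history.append((community.time, n_below))
        return det.update(community.time, x2, n_below)

    start = np.zeros(p.d_max)
    start[0] = 0.9 * p.C
    run_adaptive_dynamics(make_community([start], p), p, cfg, stop=stop)
    return _result_from(det, history)


def ibs_expansion_experiment(
    seed: int,
    p: ModelParams | None = None,
    cfg: IBSConfig | None = None,
    t_max: float = 4000.0,
    link_threshold: float = 0.15,
    persistence: float = 20.0,
) -> ExpansionResult:
    """Individual-based expansion from a monomorphic 1-D population.

    Individuals are grouped by single-linkage clustering; the experiment
    tracks cluster centroids and reports the number of clusters whose
    centroid is at or below ``2 sigma_beta`` at the first sustained
    centroid crossing.
    """
    if p is None:
        p = ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.75, sigma_alpha=0.5)
    if cfg is None:
        cfg = IBSConfig(K0=500.0, sigma_mut=1e-2, t_max=t_max, seed=seed,
                        record_every=2.0)
    thr = 2.0 * p.sigma_beta
    det = _SustainedCrossing(thr, 3.0 * p.sigma_beta, persistence)
    history: list[tuple[float, int]] = []

    def stop(popn) -> bool:
        clusters = detect_clusters_points(popn.phenotypes, link_threshold)
        if not clusters:
            return False
        x2 = np.array([c[0][1] for c in clusters])
        n_below = int(np.sum(x2 <= thr))
        history.append((popn.time, n_below))
        return det.update(popn.time, x2, n_below)

    run_ibs(default_population(p, cfg), p, cfg, stop=stop)
    return _result_from(det, history)


def _result_from(det: _SustainedCrossing, history) -> ExpansionResult:
    if det.episode_start is None or not det.episode_escaped:
        t_cross, n_below = float("nan"), 0
    else:
        t_cross, n_below = det.episode_start, det.episode_n_below
    t_reach4 = float("nan")
    for t, n in history:
        if n >= 4:
            t_reach4 = t
            break
    cut = [h for h in history if not np.isfinite(t_cross) or h[0] <= t_cross]
    return ExpansionResult(t_cross, n_below, t_reach4, cut)


def ad_saturation_experiment(
    seed: int,
    p: ModelParams | None = None,
    t_max: float = 300.0,
) -> list[tuple[float, int]]:
    """1-D diversification to saturation; returns (time, cluster count)."""
    if p is None:
        p = ModelParams(d_max=1, C=1.0, sigma_beta=0.15, b=0.84, sigma_alpha=0.5)
    cfg = ADConfig(t_max=t_max, seed=seed, record_every=1.0)
    start = np.zeros(p.d_max)
    start[0] = 0.5 * p.C
    traj = run_adaptive_dynamics(make_community([start], p), p, cfg)
    return [(t, len(c)) for t, c in traj.snapshots]


def burst_experiment(
    seed: int,
    p: ModelParams | None = None,
    t_max: float = 2000.0,
    settle: float = 60.0,
    window: float = 5.0,
    baseline: float = 50.0,
) -> dict:
    """Staircase run checking that dimension acquisitions come with speed bursts.

    Runs the adaptive dynamics in a cost-gated parameter regime until every
    dimension up to ``d_max`` has been acquired (plus a settling margin),
    then tests, for each first-acquisition time, whether the
    population-weighted evolutionary speed has a local maximum within
    ``window`` time units that exceeds the median speed over the
    ``baseline`` time units preceding the acquisition.

    Returns a dict with the speed/average-dimension series, the
    first-acquisition time of each dimension, and the per-acquisition
    burst verdicts.
    """
    from .observables import (
        _dimensions,
        average_dimension,
        counts_by_dimension,
        evolutionary_speed,
        expansion_times,
    )

    if p is None:
        p = ModelParams(d_max=3, C=1.0, sigma_beta=0.15, b=0.85, sigma_alpha=0.5)
    cfg = ADConfig(t_max=t_max, seed=seed, record_every=1.0)
    hits: dict[int, float] = {}

    def stop(community) -> bool:
        dims = _dimensions(community.phenotype_matrix(), p.sigma_beta)
        for k in range(2, p.d_max + 1):
            if k not in hits and np.any(dims >= k):
                hits[k] = community.time
        return len(hits) == p.d_max - 1 and community.time > max(hits.values()) + settle

    start = np.zeros(p.d_max)
    start[0] = 0.9 * p.C
    traj = run_adaptive_dynamics(make_community([start], p), p, cfg, stop=stop)
    snaps = traj.snapshots
    times = np.array([t for t, _ in snaps])
    speed = np.array([evolutionary_speed(c, p) for _, c in snaps])
    avg_dim = np.array([average_dimension(c) if len(c) else np.nan for _, c in snaps])
    counts = counts_by_dimension(snaps, p.sigma_beta, p.d_max)
    acq = expansion_times(counts)
    bursts = {}
    for k, t_k in acq.items():
        near = (times >= t_k - window) & (times <= t_k + window)
        pre = (times >= t_k - baseline) & (times < t_k)
        if not near.any() or not pre.any():
            bursts[k] = False
            continue
        bursts[k] = bool(speed[near].max() > np.median(speed[pre]))
    return {
        "times": times,
        "speed": speed,
        "avg_dim": avg_dim,
        "acquisitions": acq,
        "bursts": bursts,
        "trajectory": traj,
    }


def pde_expansion_experiment(
    p: ModelParams | None = None,
    cfg: PDEConfig | None = None,
    mass_fraction: float = 0.01,
) -> dict:
    """Density-field expansion: peak count when mass escapes the strip.

    Runs the 2-D PDE from a single blob until the density mass above
    ``x2 = 2 sigma_beta`` first exceeds ``mass_fraction`` of the total,
    then counts density peaks in the strip (``x2 <= 2 sigma_beta``).
    """
    from .observables import detect_clusters_density

    if p is None:
        p = ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.35, sigma_alpha=0.5)
    if cfg is None:
        cfg = PDEConfig(D=1e-6, dt=0.05, t_max=6000.0, record_every=5.0)
    thr = 2.0 * p.sigma_beta

    def escaped_fraction(field_) -> float:
        ys = field_.coords[1]
        total = field_.phi.sum()
        if total <= 0:
            return 0.0
        return float(field_.phi[:, ys > thr].sum() / total)

    def stop(field_) -> bool:
        return escaped_fraction(field_) > mass_fraction

    fields = run_pde(default_field(p, cfg), p, cfg, stop=stop)
    final = fields[-1]
    ys = final.coords[1]
    strip = final.phi.copy()
    strip[:, ys > thr] = 0.0
    strip_field = type(final)(strip, final.coords, final.time)
    peaks = detect_clusters_density(strip_field, smooth_width=1.5, rel_threshold=0.1)
    return {
        "t_escape": final.time,
        "n_peaks": len(peaks),
        "peaks": peaks,
        "escaped_fraction": escaped_fraction(final),
        "fields": fields,
    }
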