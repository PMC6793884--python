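"""Diversification of a one-dimensional community until it saturates.

A single cluster near the carrying-capacity optimum branches repeatedly
under frequency-dependent competition; with kernel width 0.5 the trait
axis holds exactly four clusters, after which every further split is
merged back.
"""

import numpy as np

from dimburst import ADConfig, ModelParams, make_community, run_adaptive_dynamics

p = ModelParams(d_max=1, C=1.0, sigma_beta=0.15, b=0.84, sigma_alpha=0.5)
cfg = ADConfig(t_max=300.0, seed=1)
traj = run_adaptive_dynamics(make_community([[0.5]], p), p, cfg)

counts = [(t, len(c)) for t, c in traj.snapshots]
for t, n in counts[::30]:
    print(f"t = {t:5.0f}   clusters = {n}")

final = traj.final()
print("\nfinal cluster positions:", np.round(np.sort(final.phenotype_matrix().ravel()), 3))
print("final populations:      ", np.round(final.populations(), 3))
print(
    "\nThe count rises from 1 and settles at 4 — the saturated diversity of"
    "\nthe one-dimensional niche; positions straddle the optimum C = 1."
)
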