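"""Stochastic (individual-based) realization of the same expansion.

An exact birth-death simulation with 500-individual carrying-capacity
scale and Gaussian mutation of size 0.01.  Individuals are grouped by
single-linkage clustering; the script reports the strip's cluster count
when a cluster centroid first crosses the acquisition threshold and
stays above it.
"""

from dimburst import IBSConfig, ModelParams
from dimburst.experiments import ibs_expansion_experiment

p = ModelParams(d_max=2, C=1.0, sigma_beta=0.15, b=0.75, sigma_alpha=0.5)
cfg = IBSConfig(K0=500.0, sigma_mut=1e-2, t_max=4000.0, seed=1, record_every=2.0)
r = ibs_expansion_experiment(seed=1, p=p, cfg=cfg)

print(f"first sustained centroid crossing of x2 = 0.3 at t = {r.t_cross:.0f}")
print(f"clusters with centroid x2 <= 0.3 at that moment: {r.n_below}")
print("strip cluster count in the approach to the crossing:")
for t, n in r.history[-10:]:
    print(f"  t = {t:6.0f}   clusters = {n}")
print(
    "\nDemographic noise makes the outcome seed-dependent: the strip"
    "\ntypically holds 3-4 clusters when the expansion takes off, and"
    "\ntransient excursions above the threshold collapse back within"
    "\n~10 time units (they are filtered by a persistence window)."
)
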