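"""Dissect conflicting topological signal with gene-wise delta scores.

Builds a synthetic per-site log-likelihood table for two candidate
resolutions of a contentious node, where support for topology T1
concentrates among the most useful loci, then tracks the mean per-locus
delta as less useful loci are added (in multiples of 20).
"""

import numpy as np

from chronospace import SiteLikelihoodTable, delta_trend, genewise_delta

rng = np.random.default_rng(3)
n_loci, sites = 200, 50
order = [f"L{i:03d}" for i in range(n_loci)]  # already usefulness-ranked

# per-site lnL: T1 advantage fades (and reverses) down the ranking
lnl_t2 = -rng.exponential(2.0, n_loci * sites)
advantage = np.repeat(np.linspace(0.04, -0.03, n_loci), sites)
lnl_t1 = lnl_t2 + advantage + rng.normal(0, 0.02, n_loci * sites)
parts = {l: (i * sites, (i + 1) * sites) for i, l in enumerate(order)}

table = SiteLikelihoodTable(lnl_t1, lnl_t2, parts)
deltas = genewise_delta(table)
print(f"gene-wise delta = sum over a locus's sites of lnL(T1) - lnL(T2);")
print(f"positive supports T1. Total lnL difference: {deltas.sum():.1f}")
print(f"loci favoring T1: {(deltas > 0).sum()} of {n_loci}\n")

trend, coeffs = delta_trend(deltas, order, step=20)
print("mean per-locus delta for datasets of the k most useful loci:")
print(trend.round(3).to_string(index=False))
print(f"\nsecond-degree polynomial fit (a, b, c): "
      f"{coeffs[0]:.2e}, {coeffs[1]:.2e}, {coeffs[2]:.3f}")
print("positive means at small k that shrink as k grows indicate the signal")
print("for T1 is concentrated among the most phylogenetically useful loci.")
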