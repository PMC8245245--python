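"""Build the default 120-unit motor neuron pool and inspect its organisation.

The pool follows exponential size-principle rules: recruitment thresholds span
a 40-fold range of excitation, twitch forces a 100-fold range, contraction
times a 3-fold range, and innervation numbers mirror the twitch distribution
over 70,000 fibers.
"""

import numpy as np

import mupool as mp

cfg = mp.PoolConfig()
pool = mp.build_pool(cfg)

rte = np.array([u.rte for u in pool])
print(f"units: {len(pool)}")
print(f"recruitment thresholds: {rte[0]:.2f}% ... {rte[-1]:.1f}% of max excitation")
print(f"units recruited below 10% drive: {(rte < 10).sum()} of {len(pool)}")
print(f"twitch force range: {pool[0].peak_twitch:.2f} ... {pool[-1].peak_twitch:.0f} au")
print(f"contraction time range: {pool[-1].contraction_time_ms:.1f} ... {pool[0].contraction_time_ms:.1f} ms")
print(f"innervation: smallest unit {pool[0].n_fibers} fibers, largest {pool[-1].n_fibers}, "
      f"total {sum(u.n_fibers for u in pool)}")
print()
print("Most of the pool is small, slow and recruited early; a few large fast")
print("units at the top of the recruitment order carry most of the force.")
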