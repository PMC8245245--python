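"""Compare how three motor unit loss patterns change maximum force and its variability.

Removes 60% of the pool — the largest units, the smallest units, or a random
subset — and simulates maximal contractions (100% drive) under the onion-skin
firing strategy, averaging 5 repetitions per condition.
"""

import numpy as np

import mupool as mp
from mupool.scenarios import trial_seed

cfg = mp.PoolConfig()
pool = mp.build_pool(cfg)

scenarios = {
    "intact pool": mp.LossScenario(),
    "largest 60% lost": mp.LossScenario("largest", 0.6),
    "smallest 60% lost": mp.LossScenario("smallest", 0.6),
    "random 60% lost": mp.LossScenario("unrestricted", 0.6),
}

stats = {}
for name, scen in scenarios.items():
    f, c = [], []
    for rep in range(5):
        seed = trial_seed(1, cfg.pfr_scheme, scen.pattern, scen.fraction, 100.0, rep)
        r = mp.run_trial(cfg, scen, 100.0, seed, pool=pool, rep=rep)
        f.append(r.force_mean)
        c.append(r.force_cov_pct)
    stats[name] = (np.mean(f), np.mean(c))

f0, c0 = stats["intact pool"]
print(f"{'condition':<20} {'force (au)':>11} {'vs intact':>10} {'COV %':>7} {'vs intact':>10}")
for name, (f, c) in stats.items():
    print(f"{name:<20} {f:>11.0f} {mp.percent_change(f0, f):>+9.1f}% "
          f"{c:>7.2f} {mp.percent_change(c0, c):>+9.1f}%")
print()
print("Losing the largest units is catastrophic for strength but smooths the")
print("force (small survivors fuse easily); losing the smallest units barely")
print("dents strength but leaves the poorly fused large units to generate a")
print("more variable force.")
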