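"""Simulate one voluntary contraction: 2 s ramp to 60% drive, 5 s hold.

Prints the steady-state force metrics and, with EMG enabled, the averaged
rectified value of the synthesized surface signal.
"""

import numpy as np

import mupool as mp

cfg = mp.PoolConfig(total_fibers=7_000)  # reduced fiber count keeps EMG fast
pool = mp.build_pool(cfg)
muscle = mp.build_muscle(
    np.array([u.n_fibers for u in pool]), mp.MuscleGeometry(), np.random.default_rng(0)
)

result, (t, force, emg) = mp.run_trial(
    cfg, mp.LossScenario(), level=60.0, seed=42,
    with_emg=True, muscle=muscle, return_traces=True,
)

recruited = sum(u.rte <= 60.0 for u in pool)
print(f"drive 60%: {recruited}/{len(pool)} units recruited")
print(f"steady-state force: {result.force_mean:.0f} au "
      f"(COV {result.force_cov_pct:.2f}% — ripple left after twitch fusion)")
print(f"surface EMG ARV: {result.emg_arv:.4f} (arbitrary voltage units)")
print(f"traces: {t.size} force samples at 1 kHz, {emg.size} EMG samples at 4 kHz")
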