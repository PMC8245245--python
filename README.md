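# mupool

Biophysical simulation of a motor unit pool — motor neuron recruitment and
rate coding, twitch-based muscle force with nonlinear fusion, and surface EMG
synthesized from current-tripole fiber action potentials — built to ask a
clinical question by simulation: **what happens to muscle strength, force
steadiness and the EMG-force relation when motor units are lost**, and does
it matter *which* units are lost?

Neurological injury and disease (stroke, ALS, peripheral neuropathies)
reduce the number of functional motor units, but experiments cannot easily
separate whether the lost units were the large ones, the small ones, or a
random mixture. `mupool` makes each pattern a controlled input and measures
the consequences for whole-muscle output. Intended users: neurophysiologists
and rehabilitation researchers interpreting force/EMG recordings, and
modellers who need a seeded, testable pool simulator.

## The model

A pool of `n = 120` units indexed in recruitment order obeys exponential
size-principle rules:

- recruitment threshold `RTE_i = e^{(ln RR / n) i}` with `RR = 40`% drive,
- firing rate `FR_i(E) = gain·(E − RTE_i) + MFR`, clamped at `PFR_i`
  (`MFR = 8` Hz; PFRs linear between 35 and 25 Hz — *onion skin*: small
  units fire fastest; *reverse onion skin*: mirrored),
- Gaussian interspike intervals with CV 0.20,
- twitch `f(t) = g·P_i (t/T_i) e^{1−t/T_i}` with `P_i = e^{(ln RP / n) i}`
  (`RP = 100`) and `T_i = T_L (1/P_i)^{1/log_{RT} RP}` (`RT = 3`,
  `T_L = 90` ms),
- per-discharge fusion gain `g = S(T/ISI)/S(0.4)` for `T/ISI > 0.4`,
  `S(x) = (1 − e^{−2x³})/x` (linear summation below the knee, maximal gain
  near `T = ISI`, saturation beyond),
- 70,000 muscle fibers split 100-fold exponentially across units (smallest
  unit: 28 fibers) in an 8 mm cylindrical muscle; fiber action potentials
  are two propagating current tripoles recorded monopolarly through a
  2.5 mm skin/fat layer; the EMG is the superposition of motor unit action
  potentials at the discharge times.

Trials drive the pool with a 2 s ramp + 5 s hold at 10–100% excitation and
analyse only the steady window: force mean, force COV (%), EMG averaged
rectified value, and the normalized EMG-force relation with its linear fit.
Loss scenarios remove 20/40/60% of units — largest, smallest, or an
unrestricted random subset. See `docs/methods.md` for assumptions and
numerical details.

## Worked example

`python examples/loss_patterns_force.py` (≈1 min) simulates maximal
contractions after 60% unit loss, onion-skin strategy, 5 repetitions:

```
condition             force (au)  vs intact   COV %  vs intact
intact pool                18067      +0.0%    1.65      +0.0%
largest 60% lost            1192     -93.4%    0.28     -82.9%
smallest 60% lost          14914     -17.5%    2.04     +23.6%
random 60% lost             7273     -59.7%    2.75     +66.6%
```

Losing the largest 60% of units erases ~93% of maximum force (they carry
the overwhelming share of twitch force) yet makes the remaining force
*smoother* (COV down ~83%): small units fuse at low rates. Losing the
smallest 60% barely costs strength (−17.5%) but increases variability —
the large survivors fire far below their fusion frequency, leaving ripple.
Force in `au` (arbitrary units) is meaningful only as ratios.

Other examples: `pool_anatomy.py` (pool organisation),
`single_contraction.py` (one trial with force + EMG traces),
`emg_force_relation.py` (linearity of the EMG-force curve and how
largest-unit loss breaks it).

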