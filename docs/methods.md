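# Methods

`mupool` simulates an isometric muscle contraction from first principles of
motor unit physiology: a motor neuron pool converts a common excitatory drive
into per-unit discharge trains, each discharge produces a twitch that fuses
nonlinearly with its predecessors, and each discharge also injects a motor
unit action potential (MUAP) into the surface EMG. The purpose of the package
is sensitivity analysis: how muscle strength, force steadiness and the
EMG-force relation change when motor units are removed in different patterns
(largest-first, smallest-first, or at random), under two peak-firing-rate
organisations.

## Motor neuron pool

The pool has `n_units` motor units (default 120) indexed by `i = 1..n` in
recruitment order. All per-unit properties follow exponential size-principle
rules:

- Recruitment threshold `RTE_i = exp(ln(RR)/n * i)`, in % of maximum
  excitation. `RR = 40` means the last unit is recruited at 40% drive; the
  exponential form places most thresholds low (74 of 120 units below 10%
  drive at the defaults).
- Firing rate above threshold: `FR_i(E) = gain * (E - RTE_i) + MFR`, clamped
  at the unit's peak firing rate `PFR_i`. `MFR = 8 Hz` at recruitment;
  `gain = 1 Hz per % excitation` for every unit. The gain value is a model
  convention (it is not uniquely determined by the physiology being emulated);
  with `RR = 40` it lets every unit reach its PFR below 60% drive, so maximal
  contractions probe the fully rate-saturated pool.
- Peak firing rates are linear in `RTE_i / RR` between `pfr_hi = 35 Hz` and
  `pfr_lo = 25 Hz`. The *onion-skin* scheme assigns the high rates to the
  early-recruited small units (PFR falls from ~35 to 25 Hz across the pool);
  the *reverse onion-skin* scheme is the mirror image (25 → 35 Hz). The
  endpoints are conventions of the classic pool model this package follows;
  both are configurable.
- Discharge trains are renewal processes: each interspike interval is drawn
  from a Gaussian with mean `1/FR` and SD `isi_cv * mean` (`isi_cv = 0.20`).
  The rate used for an interval is the rate at the previous discharge
  (a frozen-rate renewal approximation — exact during the hold phase, and the
  ramp is excluded from analysis). Negative draws are resampled; at CV 0.2
  the probability of a negative draw is ~3e-7, so resampling cannot bias the
  stated mean or SD meaningfully. A unit fires its first discharge at the
  instant the ramping drive first reaches its threshold; this makes first
  discharges deterministic, and the ISI noise decorrelates unit phases well
  before the analysis window begins.

## Force generation

Each discharge `j` of unit `i` contributes a critically damped twitch
`f(t) = g_ij * P_i * (t/T_i) * exp(1 - t/T_i)` with peak force `P_i` at the
contraction time `T_i`:

- `P_i = exp(ln(RP)/n * i)` spans an `RP = 100`-fold range, so the largest
  half of the pool carries ~85% of the summed twitch force.
- `T_i = T_L * (1/P_i)^(ln RT / ln RP)` spans an `RT = 3`-fold range
  downward from `T_L = 90 ms`: strong units are fast, weak units slow.
  `T_L` is a convention of the same model family and is config-exposed.
- The fusion gain `g_ij` depends on `x = T_i / ISI_j` (the interval preceding
  the discharge): `g = 1` for `x <= 0.4` (isolated twitches sum linearly) and
  `g = S(x)/S(0.4)` with `S(x) = (1 - exp(-2x^3))/x` beyond. The
  normalisation by `S(0.4)` makes the gain continuous at the knee (the
  unnormalised form would jump by ~3.3x); the gain peaks near `x = 1`, where
  the interval matches the contraction time, and the *mean* unit force
  saturates as `1 - exp(-2x^3)` — firing faster than ~3/T buys nothing.
  The first discharge of a train has `g = 1` so a lone twitch is the
  unloaded twitch.
- Whole-muscle force is the linear sum of unit traces. Spike times stay
  continuous; twitches are evaluated on the 1 ms force grid with a geometric
  recurrence that is algebraically identical to the term-by-term sum (tested
  to 1e-9 relative against a direct evaluation); each twitch is truncated
  where its kernel falls below ~4e-16 of peak (45 contraction times).

## Surface EMG

The muscle is a cylinder (radius 8 mm) of parallel fibers under a 2.5 mm
skin/fat layer. The 70,000 fibers are divided among units in proportion to
`exp(ln(100)/n * i)` — the same 100-fold spread as twitch force — with
largest-remainder rounding so counts are integers summing exactly to the
total (smallest unit: 28 fibers). Each unit's fibers are scattered uniformly
in a circular territory sized to hold fiber density at 20 fibers/mm², with
the territory placed uniformly at random wholly inside the cross-section.

A fiber discharge launches two current tripoles at the innervation zone
(scattered ±2.5 mm about the muscle midpoint) that travel toward the two
tendons (±50 mm) at the fiber's conduction velocity,
`v = 2.2 + 0.05 (d - 25) m/s` for diameter `d` (Gaussian, mean 55 µm,
SD 5 µm, truncated at 3 SD, identical for all units). Pole charges are
+0.9 / −1.0 / +0.1 at 0 / 2 / 6 mm behind the lead pole (zero net charge;
90:10 lead/trail split sets the terminal phase). The monopolar potential is
`sum(q_k / (4 pi sigma r_k))` in a homogeneous isotropic conductor with unit
effective conductivity — the fat layer enters as pure source-electrode
distance, since the analysis depends only on *relative* EMG amplitudes. At
the tendon all three pole charges of a tripole ramp linearly to zero over
one 2 mm pole spacing of lead-pole travel. Ramping the tripole as a whole
(rather than pole by pole) keeps the net source charge zero throughout
extinction, so the far field stays multipolar (|V| falls faster than 1/r)
while a finite terminal phase is preserved. A unit's MUAP template is the
sum of its fibers' waveforms (computed once per muscle realisation); the
trial EMG superposes each surviving unit's template at its discharge times,
sampled at 4 kHz (discharges align to the nearest sample, a 0.125 ms
worst-case jitter well inside the MUAP bandwidth).

## Experiment protocol and outcome measures

A trial drives the pool with a trapezoid: linear ramp over 2 s to the target
level (10%…100% in 10% steps), then a 5 s hold. Only the steady window
(t ≥ 2 s) is analysed: force mean, force COV (100·SD/mean, population SD,
computed per repetition and then averaged over repetitions), and EMG ARV
(mean rectified amplitude). Loss scenarios remove `round(fraction * n)`
units — the top indices (`largest`), bottom indices (`smallest`), or a
uniform random subset (`unrestricted`) redrawn each repetition but held
fixed across excitation levels within a repetition, since an EMG-force
relation follows one lesioned pool over the whole protocol; survivors keep
their original parameters (no reinnervation). The EMG-force relation of
a condition normalises the 10 per-level force means and ARVs each to their
own maximum and fits an ordinary least-squares line; R² of that fit
operationalises "linear", and the sign of mid-level residuals diagnoses EMG
rising disproportionately to force.

Seeding: every grid cell derives its own seed from the master seed and the
condition coordinates (strategy, pattern, fraction, level, repetition) via
`numpy.random.SeedSequence`, so any subset of the grid — or repetition `k`
of a longer run — reproduces the identical trials.

## Problem sizes and numerical choices

Default analyses use the full 120-unit pool. Force-only trials take well
under a second; EMG synthesis is dominated by the one-off MUAP template
construction, so EMG studies in the examples and tests use a 7,000-fiber
muscle with the same per-unit proportions — MUAP amplitude scales with fiber
count per unit, and all EMG conclusions here rest on normalised amplitudes.
Repetition counts: 10 per condition for force outcomes; force COV of a 5 s
window is a noisy statistic, so COV contrasts average 30 repetitions.
Degenerate inputs are rejected with explicit errors (zero-mean COV windows,
non-increasing spike times, territories larger than the muscle are clipped
with a warning, electrodes inside the muscle). Ties in largest-remainder
rounding break toward lower unit indices.

## What the simulation does and does not show

The generator *is* the study system: there is no external data, and passing
tests show internal consistency of the model plus reproduction of its
documented sensitivity pattern — they do not validate the model against
human recordings. Known idealisations: no motor unit synchronisation or
common-drive fluctuation, no doublets or rate adaptation, linear inter-unit
force summation, no fatigue, no reinnervation after loss, one shared fiber
diameter distribution for all units, a homogeneous volume conductor with a
single monopolar electrode, and an excitation drive assumed intact after
unit loss. Absolute force (au) and EMG (arbitrary voltage) scales depend on
unprinted conventions (PFR endpoints, gain, `T_L`, conductivity), so only
ratios and normalised relations are meaningful outputs.

Two structural consequences of the defaults are worth knowing when reading
results. First, every unit's rate is capped at its PFR by ≤57% drive, so
conditions at 60–100% excitation are statistically identical; COV falls
steeply with drive and then plateaus rather than decreasing strictly level
by level. Second, after largest-60% loss the surviving small units' force
fuses by ~15% drive while their rates (and hence EMG) keep rising until
~31% — the EMG-force curve therefore bends with force saturating first,
which is exactly the "EMG increasing faster than force" regime: the fitted
line degrades (R² drops from >0.98 to ~0.8) and mid-range points sit above
it.
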