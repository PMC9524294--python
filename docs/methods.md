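# Methods

## Model

`cogsync` simulates trial-level action control with two binding
mechanisms. Each input and output unit is a cortical column: one
rate-code neuron and an excitatory/inhibitory phase pair `(E, I)`. The
undriven phase update is a pure rotation by `C` radians per timestep,
plus (i) independent Gaussian jitter on the rotation angle and (ii) a
multiplicative attraction of the radius `r = √(E² + I²)` toward a target,
`r ← r·(1 + κ(r* − r))`. The rotation form was chosen because it is the
unique linear update for which the emergent frequency is
`f = C / (2π·dt)`, a single mapping that simultaneously yields 3.97,
5.57 and 8 Hz for C = 0.05, 0.07, 0.10 and places the shared gamma
rhythm of all processing columns at 46 Hz for C ≈ 0.578, all at the
default 2 ms step. The multiplicative (rather than additive) radius
attraction keeps the origin a fixed point of the undriven dynamics.

A theta-frequency MFC unit controls *when* binding happens. Its
amplitude is pinned to a near-zero baseline when synchronization is
disabled; when enabled it grows geometrically per pre-response step up
to a cap, and decays geometrically back to baseline after a response.
At every step the MFC emits a burst with probability equal to the
positive part of its excitatory phase clamped to [0, 1] — bursts are
theta-locked (silent on the negative half-cycle) and increasingly likely
as the trial drags on. A burst is one signed kick (`±burst_gain`, sign
drawn per event) added to the excitatory phase of every recipient at
once: all output columns, plus the input columns tagged by the LFC.
Common input is what synchronizes the recipients; untagged columns drift
apart again under the per-column phase jitter. The LFC tag vector
selects *which* inputs join: the current block's stimulus set
(extensive), or the four units of the relevant dimension (stroop, wcst).

Transmission is phase-gated: input `i` drives output `o` through weight
`W[i,o]` only at steps where both excitatory phases are positive.
Output rates are leaky integrators of the gated drive plus Gaussian
noise, floored at zero; they feed per-output accumulators, and the first
accumulator to reach the threshold ends the trial (RT = that step,
response = argmax accumulator, ties to the lowest index). If no
accumulator reaches threshold in 500 steps the trial is an omission,
still scored by the argmax readout — this is what produces the printed
chance levels (50% with two outputs, 75% with four) for untrained
models, and it is deliberate: an unreached threshold means "unable to
choose", but accuracy is still defined for the scoring rule.

Learning is the modified Rescorla–Wagner rule applied once per trial
after feedback: `ΔW[i,o] = β(Target_o − X_o)·X_i·X_o` with `X_i` the
maximal input rate over the trial (the clamped drive for active inputs,
0 otherwise), `X_o` the maximal output rate clipped to [0, 1], and a
one-hot target. Weights are unbounded and unclipped. Note the
self-calibrating consequence: learning stops when the maximal output
activation reaches 1, so a synchronizing learner (high transmission duty
cycle) and a non-synchronizing learner (low duty cycle) converge to
*different weights but similar asymptotic RT* on the separable task —
the mechanism behind the observed behavioral equivalence of the two
learning variants there.

## Parameters

| name | default | units | role |
|---|---|---|---|
| `C_theta` | 0.07 | rad/step | MFC coupling → 5.57 Hz |
| `C_gamma` | 0.578 | rad/step | column coupling → 46 Hz |
| `dt_ms` | 2 | ms | timestep; 500 steps = 1 s trial |
| `r_target`, `kappa` | 1.0, 0.1 | – | column radius attractor and strength |
| `phase_noise_sd` | 0.1 | rad/step | angular jitter; desynchronizes untagged columns |
| `baseline_radius` | 0.01 | – | resting MFC amplitude (theta power floor ≈ 10⁻⁴) |
| `grow_rate` | 0.015 | /step | MFC amplitude growth; reaches the cap ≈ step 310 |
| `decay_rate` | 0.05 | /step | post-response relaxation |
| `amplitude_cap` | 1.0 | – | MFC amplitude ceiling (burst probability ≤ 1) |
| `burst_gain` | 0.5 | – | kick magnitude; large enough to lock phases within a few events |
| `leak` | 0.1 | /step | output-rate decay |
| `input_drive` | 1.0 | – | clamped rate of active inputs |
| `rate_noise_sd` | 0.01 | /step | additive output-rate noise |
| `threshold` | 250 | – | accumulator bound (calibrated, see below) |
| `beta_learn` | 0.4 | – | learning-variant RW rate (0 for non-learning) |
| `w_word`, `w_color` | 0.3, 0.1 | – | hard-coded Stroop reading bias |
| init weights | U(0, 0.1) / U(0, 0.01) | – | extensive / stroop+wcst |

Calibrated constants. The threshold was set once from pilot accumulator
distributions under the default dynamics: untrained U(0, 0.1) weights on
the extensive task accumulate to ≈ 105 on average (p99 ≈ 212) over the
full 500 steps, while converged learners accumulate ≈ 285, so 250
separates "untrained times out" from "trained responds before timeout"
with margin on both sides; near-zero WCST weights accumulate ≈ 30 and
always time out. `phase_noise_sd = 0.1` was likewise chosen so that the
occasional lucky phase alignment of an untrained pathway cannot sustain
itself across a whole trial, and `grow_rate = 0.015` so that the MFC
amplitude saturates by about step 310 and synchronization actually
engages within the 500-step window. These three constants live in the
config, not in code.

Statistical operationalization. The original analyses report CI plots
without named tests; the test suite operationalizes "X exceeds Y" as a
one-sided paired t-test across agents at α = 0.05 (pairing is exact
because all variants of an agent share one design), and "no meaningful
difference" as an absolute bound: RT means within 10% of their pooled
mean, error rates within 5 percentage points. Per-agent means are
computed before any across-agent statistic; CI half-widths are
`1.96·sd/√n` with the sample standard deviation.

## What the generators emulate — and what they do not

The design generators reproduce the statistical structure the model
consumes: stimulus inventories, per-block counts, repetition schedules,
response-side balance, task-run alternation, and the exact per-block
congruency partition of the WCST space (4 none / 24 medium / 12
high-same / 24 high-different, from enumerating the 4³ stimuli). Trial
orders within blocks, the novel/repeating interleaving (8/8, otherwise
unconstrained), and response-side assignments are seeded uniform
shuffles. They do *not* replay the trial sequences of the human
participants the original designs were built from, so any phenomenon
that depends on sequential structure beyond these counts (e.g.,
first-order stimulus transition effects) is outside what passing tests
establish. Simulated RTs are in timesteps with a hard 500-step ceiling;
comparisons to empirical RT distributions are qualitative only.

## Numerical and implementation choices

* The per-trial loop is one function, JIT-compiled with numba; a
  `backend="python"` flag runs the identical source uncompiled. All
  randomness (initial angles, per-step jitter, burst uniforms and signs,
  rate noise) is pre-drawn with a numpy `Generator` outside the loop,
  which makes the two backends bit-identical, makes trajectories a pure
  function of the seed, and fixes the variate count per trial so that
  toggling synchronization or tagging never desynchronizes a seeded
  stream (this is what makes the `burst_gain = 0` Sync/NoSync
  equivalence exact).
* Grids derive agent designs from `base_seed + agent` and engine streams
  from `SeedSequence((agent_seed, variant_index))`, so agents and
  variants are order-independent.
* Degenerate inputs: a constant trace has no dominant frequency
  (error); `C ≤ 0`, non-finite states/weights, out-of-range active
  indices, non-one-hot targets and unknown paradigm/config keys all
  raise `ValueError`. Argmax ties (measure-zero with noise on) resolve
  to the lowest output index.
* Theta power is the mean of the squared MFC radius over steps 1..RT.
  Since the radius trajectory is deterministic and non-decreasing before
  the response, theta power is mechanically non-decreasing in RT — the
  within-variant theta/RT coupling is a structural property, not a
  fitted one.

## Problem sizes

The test suite exercises 29-agent grids for the extensive-learning
paradigm (matching the original cohort size) and 20-agent grids for
Stroop and WCST; the acceptance script uses 29 and 20 agents
respectively and 5000-step (10 s) noise-free traces for frequency
measurement. The full 100-agent Stroop/WCST grids of the original
study run with the same code path by passing `--agents 100`.

## Known limitations

* The phase update is the minimal rotation consistent with the printed
  coupling→frequency pairs; biophysical damping details of the
  predecessor oscillator models are not reproduced.
* LFC tags are scheduled (extensive, wcst) or cued by task units
  (stroop), never learned; there is no conflict monitoring and no
  cross-trial phase continuity (phases re-randomize each trial).
* Whether the integrator should accumulate gated or raw rates is
  underdetermined; it accumulates the post-gate output rates. Stroop
  task units carry ordinary learnable weights but are never tagged.
* The non-learning Stroop variants are *constant* across blocks but not
  at 75% error: the hard-coded word bias lets them beat chance on
  word-relevant trials, which is the intended consequence of building
  the reading advantage into the initial weights.
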