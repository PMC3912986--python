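# Methods

This note records the model equations as implemented, the numerical and
design choices made where the problem was genuinely open, what the
synthetic stimuli do and do not emulate, and the problem sizes the test
suite and acceptance script run at.

## Neuron and synapse integration

Izhikevich neurons are advanced by forward Euler. The network tick is 1 ms;
within a tick the order of operations is fixed:

1. spikes emitted at the previous tick are delivered (uniform 1 ms synaptic
   delay on every projection — the smallest delay compatible with the tick);
2. conductances decay one Euler step of dg/dt = −g/τ at dt = 1 ms;
3. the synaptic drive is computed once, from the fresh conductances and the
   tick-start membrane potentials;
4. the membrane equations take two 0.5 ms Euler substeps under that single
   drive (recomputing the drive per substep would double-count conductance
   decay);
5. spikes are recorded and plasticity accumulators updated.

**Sign convention.** The four-channel current
g_NMDA·s(v)·(v−0) + g_AMPA·(v−0) + g_GABA_A·(v+70) + g_GABA_B·(v+90),
with s(v) = ((v+80)/60)²/(1+((v+80)/60)²), is negative for excitatory
conductances at subthreshold v. The drive added to dv/dt is its negative,
so channels with 0 mV reversal depolarize and the GABA channels
hyperpolarize — the standard conductance-model convention. Each channel's
contribution vanishes exactly at its reversal potential.

**Reset and clamping.** The spike test runs at substep entry: v ≥ 30 mV
registers a spike and applies v ← c, u ← u + d with no integration that
substep; after integration v is capped at 30 mV (so the end-of-step
potential never exceeds the cutoff) and floored at −90 mV. The floor is a
numerical guard, not a model feature: without it, a large GABA_B
conductance can push a neuron so far below rest in one Euler step that the
quadratic term catapults it back with overshoot, and the v/u oscillation
diverges. −90 mV is the most negative synaptic reversal, below which
synaptic input cannot physically drive the membrane. Subthreshold
trajectories converge linearly in dt (first-order Euler), verified by the
step-halving test.

**Spike-to-conductance coupling.** The mapping from synaptic weight to
conductance increment is the identity: an excitatory spike of weight w adds
w to both g_AMPA and g_NMDA, an inhibitory spike adds w to both GABA
channels. The per-channel split factors are configurable (`SimConfig`);
1.0/1.0 is the default in the absence of a stated ratio.

## Plasticity

STDP is nearest-neighbor: a postsynaptic spike pairs each incoming synapse
with that presynapse's single most recent earlier spike, and symmetrically
for presynaptic spikes. Simultaneous pre/post spikes (dt = 0) contribute
nothing — both window branches are defined on strict inequalities. Window
contributions accumulate every tick into per-synapse LTP/LTD registers;
weights move only at 1-second boundaries (global, persisting across
stimulus segments), after which the registers reset. Last-spike registers
persist across boundaries. The bias term δ of the weight-update equation is
zero.

The E→E window is the classic curve (pre-before-post potentiates with
amplitude A₊ and time constant τ₊; post-before-pre depresses with A₋, τ₋).
The E→I window is reversed: pre-before-post depresses, pre-after-post
potentiates. The evolved amplitudes are treated as magnitudes; the polarity
is carried by the curve type.

**Homeostatic scaling.** Each postsynaptic neuron keeps an exponential
moving average R̄ of 1-second rate samples with time constant T = 10 s
(the averaging scheme is not uniquely determined by the model description;
an EMA is the natural streaming estimator). The stability factor is
implemented in the damping form

    K = R̄ / ( T · (1 + |1 − R̄/R_target|·γ) ),     γ = 50,

because K's stated purpose is to damp weight-update oscillations; the
multiplicative reading R̄/T·(1+…) amplifies updates far from target, the
opposite behavior. Both forms are selectable (`HomeostasisState.damping_form`).
Two consequences worth knowing: K = 0 freezes all plasticity on a silent
neuron (R̄ = 0), and far from target K is heavily damped, so homeostatic
convergence is deliberately slow — order 10³ seconds at the default
constants.

Exc→Inh synapses share the inhibitory group's homeostatic target
(homeostasis is per postsynaptic group).

**Weight scales.** Each projection's single evolved "strength" gene is used
as the upper bound of the uniform initial weight distribution, and, for
plastic projections, also as the clipping bound w_max applied after every
weight update.

## Stimuli

Counterphase gratings: cos(k·u − φ)·cos(2π f_cp t) on the centered pixel
grid, u the coordinate perpendicular to the bar orientation. Defaults:
2 cycles per grid, spatial phase 0, 2 Hz counterphase. With phase 0 the
pattern is exactly π-periodic in orientation. The time-varying contrast is
followed by piecewise-constant Poisson rates over 25 ms frames (20 samples
per counterphase period), each frame encoded at its midpoint.

On/Off encoding rectifies signed contrast into two rate channels scaled by
the evolved maximum Poisson rate; exactly one channel is nonzero per
nonzero pixel. Spike times are generated by iterating exponential
interspike intervals t_{i+1} = t_i − ln(x)/r with x uniform on the open
unit interval (endpoints excluded to avoid ln 0 and zero-length
intervals). Noise epochs drive every Poisson neuron at 1 Hz regardless of
the stimulus; they do not bypass the Poisson groups to reach the buffers
directly.

The one-to-one Poisson→buffer weight is fixed at 0.5, chosen so buffer
firing approximately tracks the input rate over the decodable 10–40 Hz
range (verified by the rate-transfer test). What the stimulus module does
*not* emulate: natural-image statistics, LGN temporal filtering beyond the
Poisson/buffer relay, eye movements, or contrast adaptation — so passing
tests show the learning machinery works on idealized drifting-contrast
input, not that it would survive natural video.

## Fitness

All orientation arithmetic is circular with period π:
d(θ,φ) = min(|θ−φ| mod π, π − |θ−φ| mod π), so the decorrelation target
π/4 is attainable by four evenly spread preferred orientations and the
Gaussian template wraps at π rather than developing edge artifacts. Tuning
curves and templates are both normalized to peak 1 before comparison; a
neuron with zero peak rate has no normalized curve and pushes the Gaussian
component above its limit (an unresponsive output is unfit). The
constraint penalty of 240 is applied once per violated component limit (up
to 720); the total is guarded by ε = 1e-9 against a zero denominator. The
test suite keeps independent plain-loop implementations of all three
components and requires agreement to 1e-12.

Tuning is measured over M = 40 test angles by default (matching the
objective's angle sum; the count is configurable, and 8-angle testing is
what the reduced presets use).

## Evolution strategies

Tournament size defaults to 2, deterministic (higher total fitness wins,
ties to the first-sampled contestant). Crossover is uniform per-gene
between two tournament winners with probability 0.5 per pair; mutation
adds N(0, 0.1²) per gene with probability 0.4 (interpreted per-gene), then
clips to [0,1]. Weak elitism copies the best parent over the worst
offspring, making the per-generation best monotone. Every individual draws
an evaluation seed from the master seed and a global individual counter,
so fitness is a pure function of (genome, seed), results are invariant to
evaluation order, and a worker pool (joblib, `n_workers > 1`) changes
nothing but wall time. An evaluation that diverges numerically is assigned
the worst constraint-violating fitness rather than aborting the run.

## Problem sizes used by the tests and the acceptance script

The full-scale protocol (N = 32 grid, 40 patterns × 2 s + 500 ms noise,
60 passes ≈ 100 simulated minutes per individual, hundreds of generations)
is a multi-day CPU computation; the shipped checks run the same code at
reduced sizes chosen to exercise every mechanism:

* **micro protocol** (`ProtocolConfig.micro()`): 6 patterns × 1 s, 250 ms
  noise, one pass, 8 test angles × 500 ms — used for the reduced-scale
  evolutionary runs (grid 8, μ = λ = 6, 20 generations).
* **desk protocol** (`ProtocolConfig.desk()`): 10 patterns, 24 passes
  (~10 simulated minutes), for interactive exploration.
* Homeostasis system tests run 120-s segments (weight-drift direction);
  Poisson statistics use 10⁵ ms at 20 Hz; oracle sweeps use 1000 random
  tuning-curve sets and 100 random spike trains.
* Population-vector decoding is demonstrated on a synthetic 400-neuron
  Gaussian-tuned population (σ = 15°, peak 60 Hz, additive rate noise),
  standing in for the 100-retrain-trial study of a fully tuned network.

At these scales the outputs fire well below the 60 Hz target — with 128
buffer inputs instead of 2048, the feed-forward drive available within the
evolved weight ranges is an order of magnitude smaller — so reduced-scale
runs exercise selection pressure and monotone improvement, not full SORF
formation. Receptive-field structure and near-target rates require the
full-scale protocol.

## Known limitations

* Forward Euler at fixed step: no adaptive error control; the −90 mV floor
  and 30 mV cap are part of the discrete dynamics.
* The EMA rate estimate and the damping form of K are one reasonable
  resolution of an under-determined description; both alternatives are one
  flag away.
* Orientation decoding uses the doubled-angle trick, which is exact for
  orientation (period π) data but cannot represent direction selectivity.
* No GPU or multi-machine execution; parallelism is process-level over
  individuals.
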