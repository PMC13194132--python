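# Methods

`snnkit` is a modular spiking-neural-network toolkit: models are directed
graphs of self-contained components (somas, synapses, encoders, decoders)
described by a declarative blueprint and executed by a synchronous
fixed-step scheduler.  This note records the models, the numerical
choices, the free parameters and their defaults, and what the synthetic
test conditions do and do not establish.

## Execution model

A blueprint names components and port-to-port edges.  `build_model`
instantiates it deterministically: every component draws its initial
state from a counter-based random stream keyed by (global seed, node id),
so builds are bit-identical regardless of construction order.  Stepping
follows a topological order of the graph computed once (Kahn's algorithm,
lexicographic tie-break); cycles are broken by releasing the
lexicographically smallest blocked node, whose unresolved inputs then
read the previous tick's outputs.  Forward edges deliver same-tick
values; back edges one-tick-delayed values — the standard synchronous
convention that makes recurrent inhibitory loops well defined.  Multiple
edges into one port sum elementwise.  The clock is integer step
accounting: `t = step_index * dt` exactly, never a floating-point
accumulation.

One global float width applies per model (float32 default; float16 and
float64 available).  Components treat their inputs as read-only.

## Soma models

*LIF* (the unit used by the cartpole agent): exponential-Euler leak
(exact on the homogeneous part), forward-Euler input term, adaptive
threshold that decays toward its base with time constant `tau_th` and
jumps by `a` per spike, and an input-gating refractory mechanism: a spike
sets the refractory variable `r <- -r_spike`; `r` relaxes upward at unit
rate (clamped at `r_spike`) and the input term is applied only while
`r > 0`.  The spike test `v > theta` runs after the integration update of
each step, with the threshold already decayed — the evaluation point is a
convention fixed for determinism.  Defaults (`tau_m` 20 ms, `v_rest`
-65 mV, `theta_base` -50 mV, R 1, `a` 2 mV, `tau_th` 50 ms, `r_spike`
5 ms, `v_reset = v_rest`) are standard textbook values; every one is a
blueprint parameter.

*AdEx*: the two-variable adaptive-exponential model with the
regular-spiking parameter set (C 281 pF, gL 30 nS, EL -70.6 mV, VT
-50.4 mV, slope 2 mV, tau_w 144 ms, a 4 nS, b 80.5 pA), forward Euler
with the exponential argument clamped and `v` clipped at the cutoff
`VT + 5*slope` before reset.

*HH*: the classic squid-axon set (gNa 120, gK 36, gL 0.3 mS/cm^2; ENa 50,
EK -77, EL -54.4 mV; C 1 uF/cm^2), exponential-Euler gating updates (which
keep m, h, n in [0,1] by construction), forward-Euler voltage, rate
functions in the singularity-free `x/expm1` form.  Spikes are upward
crossings of 0 mV.  The resting equilibrium used for initialization is
found by fixed-point iteration.

## Synapses and delays

Each connection (j -> i) carries a traced current: exponential decay with
`tau_s` plus an increment of `w_ji` when the presynaptic spike emitted
`d_ji` earlier arrives.  The increment is `w_ji` itself, with no `1/tau_s`
normalization.  Delays are integer multiples of dt, drawn uniformly from
[1, d_max] steps per connection.  Inhibition is carried by negative
weights and clipping is sign-preserving (Dale-like): excitatory weights
stay in [w_min, w_max], inhibitory in [-w_max, -w_min].  Weights are
sparsely and uniformly initialized: each connection exists with
probability `density`, with magnitude Uniform(0, w_max).

Storage is dense arrays with a boolean mask at these scales.  The model
component additionally keeps a ring buffer of presynaptic spike history
and per-neuron eligibility-trace rings, and processes spike *arrivals*
event-by-event (numba-compiled kernel with a pure-numpy fallback), which
makes the cost per step proportional to spike traffic rather than to the
full connection matrix.  A per-connection trace is recovered exactly from
the per-neuron ring by a delayed lookup, because increments are unit-sized
and the decay is uniform.  The dense functional reference path
(`synapse_step`, `stdp_update`) defines the semantics; the component is
equivalence-tested against it.

## Plasticity

The three-factor quadruplet STDP rule per connection:

    dw/dt = eta * M3rd * ( S_post * [alpha + beta * x_pre]
                         + S_pre(t-d) * [gamma + delta * x_post] )

applied as forward-Euler per-step increments and clipped to the signed
bounds.  Eligibility traces are exponential with unit increments; the
pre trace is driven by the *delayed* presynaptic spike (the one the
synapse sees), the post trace by the postsynaptic spike.  An update at
step t uses trace values after decay but before that step's increments,
so a spike never pairs with itself.  Inside a model, the post-spike
factor reaches a synapse over a back edge, i.e. lagged by one tick (1 ms
at the agent's dt); the functional API is lag-free and the caller owns
the pairing.

The rule's scaling constants have package defaults alpha -0.1, beta 1.0,
gamma 1.0, delta -0.1 (a pre-before-post-potentiating quadruplet with
mild offsets); they are per-connection-broadcastable in the functional
API and scalar in the component.  Structural turnover prunes connections
with |w| below `prune_eps` and adds absent ones with probability
`growth_prob` per invocation at magnitude `growth_w` with the
population's sign.  Weight updates *and* structural turnover are gated by
the modulation value: with `M3rd == 0` a synapse is exactly static, which
is how frozen evaluation is implemented and why a zero-modulation
trajectory is bit-identical to a frozen one.

## I/O interfaces

The topological spiker tiles each observation dimension with `n_units`
Gaussian tuning curves (width `sigma` as a fraction of the range, peak
Bernoulli rate `rate_max` per ms, refreshed every millisecond).  A `line`
topology clips out-of-range values; a `circle` glues the borders with
wrap-around distance, making the two endpoints statistically identical.
The decoder is k saturable traces in [0,1]:
`y *= exp(-dt/tau_out); y += (1-y) * (1-exp(-gain * count))`, each fed
exclusively by one spike population; the greedy policy takes the argmax
at the interaction step, ties to the lowest index.  The saturating
increment form is one bounded, monotone choice among many; it is exact
under test.

## Cartpole environment

Self-contained implementation of the standard cart-pole parameterization
(gravity 9.8 m/s^2, cart 1.0 kg, pole 0.1 kg, half-length 0.5 m, force
10 N, step 0.02 s, limits 12 degrees and 2.4 m), semi-implicit Euler
(velocities first), episode caps 200 (v0) or 500 (v1).  Initial states
are Uniform(-0.05, 0.05) on all four variables.  Failure flags
distinguish the pole falling (`pole_fell`) from the cart leaving the
track (`oob`); reaching the cap is truncation, not failure.

## Sparse-reward training

The agent holds each observation for a 50 ms interaction step (50
network steps at dt 1 ms), reads the integrator, acts greedily, and
steps the environment.  During the episode every plasticity update uses
the background constant lambda.  When the episode terminates, one extra
50 ms interaction runs on the final observation; on failure it delivers
the decaying third factor

    M3rd(t) = (N_ema / N_max) * R_step * exp(-tau_R (t - t_step)),

independently per motor: the motor whose action was chosen last (the
action being suppressed) receives M3rd, the other receives -xi * M3rd.
`N_ema`, the exponential moving average of episode lengths, is
initialized to the first episode's length and updated once per episode
after the extra step (coefficient 0.05), so it is always a convex
combination of observed lengths.

Because learning is online, the network keeps adapting — and can
un-learn — after every episode; the final weights of a run are whatever
the last failure left behind.  Training therefore checkpoints the
plastic weights whenever the rolling three-episode performance (worst
episode of the window first, total length second) reaches a new best,
and ends on that checkpoint; evaluation freezes those declared weights.
Training also stops early once three consecutive episodes reach the
cap, since a capped episode delivers no failure signal and continued
exposure only accumulates background drift.

Free constants never fixed by the problem itself, with the working
defaults recorded in the agent blueprint: lambda 5e-5, xi 0.3, tau_R
0.02/ms, EMA coefficient 0.05, learning rate eta 0.075, trace constants
tau_pre = tau_post = 300 ms, input-synapse bounds [0.3, 1.5], and
quadruplet coefficients alpha -0.1, beta 1.0, gamma 0.0, delta -0.1.
Five of these deserve comment:

* *Trace constants.*  With sparse terminal reward, the eligibility traces
  are the only bridge between the behavior that caused a failure and the
  moment the reward signal arrives.  At 50 ms per environment step,
  300 ms traces span roughly the last six environment steps — the final
  approach to the failure — which is what the credit assignment needs;
  20 ms traces (a common pairing-STDP choice) see only the final held
  observation and learn far more slowly.
* *Weight floor.*  The lower bound `w_min = 0.2 * w_max` on the plastic
  input synapses keeps a punished motor pool excitable.  With a floor of
  zero, a strong failure signal can silence a pool outright, after which
  it emits no postsynaptic spikes and the Hebbian terms can never
  recover it — the agent locks into the opposite action permanently.
* *Opposite-motor gain xi.*  The positive factor delivered to the
  non-suppressed motor is the constructive half of the failure signal:
  it strengthens the corrective action in the failure region rather than
  merely weakening the wrong one.
* *gamma = 0 in the agent.*  The package-level quadruplet default keeps
  a positive pre-spike constant term (gamma 1.0), but in the agent that
  term potentiates every active input connection on every delayed spike
  arrival regardless of postsynaptic activity — a non-Hebbian drift that
  destabilized learned policies in practice.  The agent blueprint
  therefore sets gamma to zero, leaving the pre-spike factor purely as
  the delta-weighted depression of pre-after-post pairings.
* *EMA coefficient 0.05.*  The failure dose scales with N_ema, the
  moving average of episode lengths.  A fast-moving average lets a first
  run of successes immediately amplify the next failure's punishment,
  which tends to destroy a freshly learned policy; the slower average
  gives the agent a consolidation window in which successes accumulate
  before failures regain full weight.

The inhibitory partner pools are fast-spiking (no threshold adaptation,
2 ms refractory); mutual inhibition sharpens the competition between the
motor pools so the greedy readout sees a clear winner.

## Fidelity harness

Each soma model is driven for 1 s by a seeded Ornstein-Uhlenbeck current
(Euler-Maruyama; constants per soma chosen for a 10-50 Hz firing regime
and recorded in `metrics.FIDELITY_DRIVE`), once at the step of record
(0.1 ms for LIF/AdEx, 0.05 ms for HH) and once at a 10x-finer step under
the identical realized drive.  Agreement is quantified with the
ISI-distance and the SPIKE-distance, computed by exact piecewise
integration of their defining profiles (auxiliary spikes at 0 and T
handle the edges).  The reference for "how far is far" is the same
distance against an ISI-permutation surrogate of the reference train —
a shuffle that preserves spike count, duration and the interval
multiset while destroying timing.

## What the synthetic conditions do and do not show

All inputs are generated: OU currents, Bernoulli encodings of cartpole
observations, and the internal environment's trajectories.  Passing
tests establish internal consistency (integration error shrinking with
dt, exact metric integration, oracle equivalence of the vectorized and
scalar rules, bit-exact freezing) and that the learning mechanism solves
this control task under the stated conditions.  They do not establish
fidelity to any external simulator's trajectories, robustness to sensor
noise models other than Bernoulli encoding, or performance on tasks with
richer reward structure.  Training outcomes are strongly seed-dependent: in cross-seed
validation roughly half of the initializations reach a stable balancing
policy within a 300-episode budget, and the rest remain in intermittent
or stuck regimes — the initialization is the only difference between
agents, and sparse terminal reward gives the learner few bits to escape
a bad draw.

## Problem sizes used by tests

The unit suite runs on small fixtures (tens of units, hundreds of
steps).  The end-to-end checks train the full 256E + 64I-per-motor agent
with early stopping (training halts after three consecutive cap-length
episodes), evaluate 50 frozen episodes, and run 100 fidelity trials of
1 s per soma; these sizes are the package's standard benchmark
configuration.
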