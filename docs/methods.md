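# Methods

This note documents the models, the plasticity rules, the numerical choices
and the known limitations of `isnplast`.

## The two-population rate model

The core model is a threshold-linear Wilson–Cowan system for the firing
rates of an excitatory (E) and an inhibitory (I) population,

    tau_E dE/dt = -E + f_E(W_EE E - W_EI I + eta_E + ext_E)
    tau_I dI/dt = -I + f_I(W_IE E - W_II I + eta_I + ext_I)

with transfer f_Y(x) = 0 for x < theta_Y and g_Y (x - theta_Y) otherwise.
Default parameters: tau_E = 10 ms, tau_I = 2 ms, g_E = 1, g_I = 4,
theta_E = 4.8, theta_I = 25 (the higher inhibitory threshold and gain
reflect the fast-spiking interneuron phenotype).  eta_Y are independent
Ornstein–Uhlenbeck processes (mean 0, time constant 1 ms, amplitude
parameter sigma) entering *inside* the transfer argument.

Each trial starts from quiescence; a brief step current onto E
(amplitude 7, 10 ms) kicks the network out of the trivially stable silent
state.  With balanced weights the dynamics settles onto a stable nontrivial
fixed point — self-sustained activity.  When W_EE g_E > 1 the network is
inhibition-stabilized (ISN) and shows the paradoxical effect: tonic
excitatory drive onto I *lowers* the steady-state I rate, because the
I→E→I loop forces a new E/I balance with less total drive onto I.

Fixed points are found by enumerating the four piecewise-linear branches
(E and I each active or quiescent), solving each 2×2 linear system in
closed form, and keeping branch-consistent solutions; each is classified by
the eigenvalues of its branch Jacobian.  Singular branch systems are
reported as degenerate rather than dropped.

Numerics: forward Euler with dt = 0.1 ms (1/20 of the fastest time
constant); a convergence test against dt/10 is part of the suite.  The
threshold-linear transfer is unbounded, so a divergence guard flags a trial
"runaway" when either rate exceeds 10^4 Hz and freezes the trace; window
means are then taken over the pre-divergence segment.  Euler from
non-negative initial rates cannot produce negative rates for dt ≤ tau_I.

Trial length (1,000 ms), per-trial initial rates (0) and the averaging
window (the last 500 ms, well past the transient: ≥ 50 slow time
constants) are package choices; they are not prescribed by the model.
Noise is resampled across trials with per-trial seeds derived from one run
seed.

## Plasticity rule families

All rules update the four weight classes from the deviation of the
window-averaged rates from setpoints (E_set, I_set) = (5, 14) Hz by
default (empirically motivated ex vivo values; I_set > E_set).

* standard homeostatic: dW_EE = +a_EE (E_set - E), dW_EI = -a_EI (E_set - E),
  dW_IE = +a_IE (I_set - I), dW_II = -a_II (I_set - I).
* cross-homeostatic: dW_EE = +a_EE (I_set - I), dW_EI = -a_EI (I_set - I),
  dW_IE = -a_IE (E_set - E), dW_II = +a_II (E_set - E).
* two-term: the sum of both patterns; an approximate gradient of
  L = 1/2 (E - E_set)^2 + 1/2 (I - I_set)^2.

A generic constructor (`make_rule`) builds arbitrary sign/error-source
combinations (hybrid and anti-homeostatic families) and multiplicative
(synaptic-scaling) variants, and reproduces the three canonical families
exactly.

Weights are clipped at 0 after every update: the equations hard-code the
sign of each pathway, so a sign flip would silently change excitation into
inhibition.  Quiescent trials still update weights using their ~0 window
means — this is what lets the rules grow a silent developmental network
into an active one.  Training always runs the configured number of trials;
"converged" is a report (relative setpoint error < 5% over the last 10% of
trials), never a stopping rule.

Training noise defaults to sigma = 2 (low), since development experiments
require avoiding fluctuation-induced transitions between the bistable
active and silent states; the core-model default sigma = 10 remains
available per experiment.

The trial-based loop updates weights at the end of every trial.  The
online variant runs one continuous simulation, feeds exponential moving
averages of the rates (time constant 1,000 ms) to the rule every 10 ms,
scales the per-update learning rates by update_interval/trial_length so
small rates match the trial-based loop, and re-applies the kick every
1,000 ms to mirror the trial structure.

Convergence note: with the cross-homeostatic family at alpha = 5e-4 the
slowest weight mode has a relaxation scale of several hundred trials;
training runs of 3,000–5,000 trials are used where plateau values are
reported.

## Stability analysis

The coupled system is fast–slow: rates relax in milliseconds, weights
drift over trials.  Stability of a self-sustained setpoint solution
requires both

1. neural stability — the 2×2 Jacobian of the rate subsystem at the
   fully active fixed point, [[(g_E W_EE - 1)/tau_E, -g_E W_EI/tau_E],
   [g_I W_IE/tau_I, -(1 + g_I W_II)/tau_I]], has eigenvalues with negative
   real parts (this is the ISN regime plus determinant condition); and
2. rule stability — under a quasi-steady-state approximation (QSSA) the
   slow vector field F(W) = rule(E*(W), I*(W)) has a stable linearization.

The QSSA Jacobian is computed by central finite differences of F
(adaptive step 1e-6 · max(1, |W|)); the analytic 2×2 neural Jacobian is
retained and cross-checked against numerical differentiation of the
simulated vector field.

Structural zero modes.  Every rule family depends on W only through the
two rate errors, so the 4×4 QSSA Jacobian has rank ≤ 2: two eigenvalues
are exactly zero.  These are not numerical noise — they are the directions
along the weight-space attractor plane defined by the steady-state balance
constraints

    W_EI = (W_EE E_set + ext_E - theta_E - E_set/g_E) / I_set
    W_II = (W_IE E_set - theta_I - I_set/g_I) / I_set

(slope E_set/I_set: the E/I balance line), where motion is neutral by
construction.  "Rule stable" therefore means *transverse* stability: no
eigenvalue with real part above a scale-aware zero band
(1e-8 × spectral radius).  Requiring all four real parts to be strictly
negative would misclassify every rule, including provably stable ones.

Stability maps scan the free weights (W_EE, W_IE) with (W_EI, W_II) pinned
to the balance constraints, so the setpoints are a fixed point at every
cell by construction.  Cells where a constrained weight is negative have
no valid self-sustained network and are flagged invalid, but the QSSA
field is still evaluated formally (fully-active-branch linear solve)
everywhere, so region boundaries remain visible — this mirrors how the
analytic region diagrams are drawn.  A tonic external current onto E
shifts the W_EI constraint and enlarges both the valid and the neurally
stable region.

Qualitative structure reproduced by the maps (and asserted by the suite):

* cross-homeostatic: rule-stable at every neurally stable cell, for
  learning-rate ratios 1:1, 100:1 and 1:100;
* standard, equal rates: the jointly stable region is a small strict
  subset of the neural region;
* standard, a_E >> a_I: a substantial joint region appears (the "fast
  excitation" escape);
* standard, a_E << a_I: the rule-stable region is confined to the
  non-paradoxical half-plane W_EE g_E < 1.  The rule-stability boundary
  *coincides* with the paradoxical line, so cells within one grid spacing
  of W_EE g_E = 1 are genuinely marginal (transverse eigenvalues O(a_E))
  and are excluded from region-level assertions.  Without external input
  the non-paradoxical half-plane contains no valid self-sustained network
  (the constrained W_EI is negative there), so the realized region is
  empty; with tonic drive onto E it is realized and remains confined.

The "much faster/slower" learning-rate ratios default to 100:1 and 1:100.

## Multiunit network

80 excitatory and 20 inhibitory threshold-linear units (configurable),
all-to-all connected within and between classes except E→E
self-connections, with the same cell parameters as the two-population
model and independent per-unit OU noise.  Per-synapse weights are scaled
by 1/(presynaptic partner count), so class totals live on the
two-population scale and a zero-spread network reduces *exactly* to the
two-population model (asserted to machine precision in the suite).

Initialization draws each synapse from a normal (default, sd = 20% of the
class mean, clipped at 0) or a moment-matched log-normal distribution.
Class means default to the balanced two-population anchor
(5, 1.0857, 10, 1.5357) — the weight set whose fixed point sits exactly at
the (5, 14) Hz setpoints — so the initial population state is active with
dispersed unit rates.

Plasticity is per-synapse and local.  For a synapse onto unit i, the
cross term uses the mean rate error of i's presynaptic partners of the
opposite class — the quantity a neuron could read through metabotropic
receptor activation — with the cross-homeostatic sign pattern; the
two-term rule adds i's own error with the homeostatic pattern.  With full
connectivity the presynaptic mean equals the population mean, so the
choice of partner set is only observable under sparse masks.

The single-term cross rule drives the *population means* to the setpoints
while individual units keep dispersed rates (they only satisfy the
setpoints on average, and their summed input weights do not collapse onto
a single E/I balance line).  Adding the own-error term (two-term rule)
drives every unit to its class setpoint and onto the common balance line.
Training runs use 400 ms trials (window 200–400 ms) — long enough for the
transient to clear at tau_E = 10 ms — and 2,000–3,000 trials at the
published learning rates (2e-5 single-term, 1e-5 two-term), which is past
the plateau of both population means and per-unit dispersion at this
scale.

## Spiking network

A sparsely connected (25% Bernoulli) network of adaptive leaky
integrate-and-fire neurons; the desk-scale default is 400E/100I (the full
1,600E/400I build is a parameter choice; all claims tested here are
size-robust qualitative properties: setpoint convergence, MSE reduction,
CV_ISI, the paradoxical sign).

Cell model: C_m dV/dt = -g_L (V - E_L) - w + I_syn + I_ext + I_noise,
spike at a per-unit threshold (mean -50 mV, cell-to-cell sd 1.5 mV — the
heterogeneity a real population has and an extra desynchronizer), reset to
E_L = -60 mV, spike-triggered adaptation w += b (2 pA) decaying with
150 ms.  Excitatory cells: C_m = 200 pF (tau_m = 20 ms), refractory 2 ms.
Inhibitory cells are fast-spiking: C_m = 70 pF (tau_m = 7 ms), refractory
1 ms.  Per-unit OU current noise (60 pA stationary std, 10 ms time
constant): the slow noise produces millivolt-scale membrane fluctuations,
which is what puts the units in the fluctuation-driven regime with
CV_ISI ~ 1; with fast (few-ms) noise of the same amplitude the units fire
quasi-regularly inside the up-state.

Synapses deliver the weight's worth of charge (w pA × 1 ms) as an
exponentially decaying current.  The decay constant is per class:
E→E 15 ms (slow, NMDA-like recurrent excitation), E→I 3 ms, I→E and
I→I 5 ms (fast GABA_A-like inhibition).  This architecture — slow
recurrent excitation, fast high-gain inhibition — is the spiking analog of
the rate model's tau_I << tau_E and g_I > g_E, and it is load-bearing:
with instantaneous (delta) synapses and homogeneous cells the desk-scale
network has *no* stable intermediate up-state.  A single volley fires
every unit, the entire population is then refractory simultaneously, the
volley's charge is lost, and activity annihilates; the only attractors are
silence and refractory-limited saturation.  Spreading each spike's charge
over a few milliseconds (inputs arriving during the refractory period are
then delayed, not discarded) and giving inhibition the speed advantage
restores the inhibition-stabilized operating point.

Weights are initialized around the silent developmental class means
(W_EE = 80, W_EI = 350, W_IE = 100, W_II = 225 pA, 20% spread): after the
kick (300 pA for 20 ms onto all E units, per-unit amplitudes jittered
±50% so ignition is not artificially synchronous), activity dies.  The
local two-term rule — own-error homeostatic term plus the mean error of
the unit's actual presynaptic partners of the opposite class, per synapse,
clipped at 0 — then reshapes all four class means until the network
sustains asynchronous irregular spiking at the setpoints.  The default
learning rate (0.02 pA per Hz of error per trial) keeps per-trial class-
mean changes well below 1% of class means in the converged regime.

Assays: per-unit rates as spike counts over a 100–1,000 ms window;
CV_ISI per unit (≥ 3 spikes) with the population median reported;
paradoxical test as the mean I rate during a tonic current injection into
all I units (400–800 ms window) versus the pre-injection baseline, across
probe amplitudes and trials.

## What the synthetic conditions do and do not show

All inputs are model parameters; there is no external data.  The
generators emulate the study conditions: seeded random weight
initializations (normal/log-normal; around-attractor, broad and verified-
silent strategies), the per-trial kick protocol, and low-amplitude OU
noise.  Passing tests therefore demonstrate the self-organization
properties of the *models* under these conditions — they do not establish
anything about biological tissue, and the spiking results specifically
depend on the synaptic/cellular time-scale asymmetry documented above.
Known limitations: no conductance-based synapses, no transmission delays,
no short-term or associative plasticity, no heterogeneous per-unit
setpoints; the spiking cell constants are a conventional parameterization,
not fitted values.
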