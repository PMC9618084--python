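# isnplast

Self-organization of inhibition-stabilized cortical dynamics through
families of homeostatic and cross-homeostatic synaptic plasticity rules.

## The problem

Cortical circuits settle, without supervision, into a regime in which
strong recurrent excitation is held in check by recurrent inhibition — an
*inhibition-stabilized network* (ISN).  Its signature is the paradoxical
effect: adding excitatory drive to the inhibitory population *lowers* the
inhibitory firing rate, because the I→E→I loop forces a new E/I balance.
How do synaptic learning rules acting in parallel on all four weight
classes (W_EE, W_EI, W_IE, W_II) drive a silent developing network to
self-sustained activity at prescribed firing-rate setpoints?

This package implements, for modelers studying that question:

* the two-population threshold-linear Wilson–Cowan model

      tau_E dE/dt = -E + f_E(W_EE E - W_EI I + eta_E)
      tau_I dI/dt = -I + f_I(W_IE E - W_II I + eta_I)

  with OU noise, trial kick protocol, closed-form fixed points and the
  paradoxical-effect condition W_EE g_E - 1 > 0;
* three plasticity families driven by the rate errors (E_set - E,
  I_set - I): **standard homeostatic** (own-population error),
  **cross-homeostatic** (errors crossed between populations) and the
  **two-term** sum of both — plus a constructor for hybrid,
  anti-homeostatic and synaptic-scaling variants;
* fast–slow stability machinery: neural Jacobians, quasi-steady-state
  Jacobians of the 4D weight subsystem, and (W_EE, W_IE) stability-region
  maps with (W_EI, W_II) pinned to the E/I balance constraints
  W_EI = (W_EE E_set - theta_E - E_set/g_E)/I_set (slope E_set/I_set);
* an 80E/20I multiunit rate network with per-unit local plasticity;
* a sparse (25%) adaptive leaky integrate-and-fire network (400E/100I
  desk scale) trained by the local two-term rule, with rate, CV_ISI,
  E/I-balance and paradoxical-probe assays.

The headline result the package reproduces: standard homeostatic rules are
defeated by the paradoxical effect (stable only when excitatory plasticity
far outpaces inhibitory plasticity), whereas the cross-homeostatic and
two-term families robustly self-organize ISN dynamics at the setpoints
from a silent initial state.

## Worked example

```python
import isnplast as ip

params = ip.NetworkParams()                 # tau_E=10, tau_I=2, g=(1,4), theta=(4.8,25)
w = ip.WeightSet(5.0, 1.52, 10.0, 2.25)     # a balanced ISN weight set

fp = [f for f in ip.steady_state(params, w) if f.neural_stable and f.nontrivial][0]
print(f"fixed point: E={fp.E:.2f} Hz, I={fp.I:.2f} Hz")
before, after, delta = ip.paradoxical_probe(params, w, probe_current=7.0)
print(f"paradoxical probe: I {before:.2f} -> {after:.2f} Hz (delta {delta:+.2f})")

h = ip.train_trials(ip.WeightSet(2.1, 3.0, 4.0, 2.0), ip.cross_rule,
                    n_trials=4000, setpoints=ip.SetPoints(5.0, 14.0),
                    rates=ip.LearningRates.uniform(5e-4), seed=1)
print(f"after development: E={h.E_avg[-50:].mean():.2f} Hz, "
      f"I={h.I_avg[-50:].mean():.2f} Hz, converged={h.converged(ip.SetPoints())}")
```

prints

```
fixed point: E=5.00 Hz, I=10.00 Hz
paradoxical probe: I 10.00 -> 4.62 Hz (delta -5.38)
after development: E=5.01 Hz, I=13.98 Hz, converged=True
```

The probe *lowers* the inhibitory rate from 10 to 4.62 Hz — the network is
inhibition-stabilized — and cross-homeostatic training carries a silent
developmental weight set to self-sustained activity at the (5, 14) Hz
setpoints.

A command-line front end wraps the experiment presets:

```bash
isnplast train --rule cross --n-trials 4000 --out results/
isnplast stability-map --rule standard --rate-ratio 1 1 --out results/
isnplast preset --preset multiunit_two_term --out results/
```

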