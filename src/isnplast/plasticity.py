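"""Homeostatic plasticity rule families and training loops.

All rules update the four weight classes from the deviation of the average
E and I rates from ontogenetic setpoints (E_set, I_set):

* standard homeostatic   — each weight class is driven by the error of its
  *postsynaptic* population (dW_EE = +a (E_set - E), dW_EI = -a (E_set - E),
  dW_IE = +a (I_set - I), dW_II = -a (I_set - I));
* cross-homeostatic      — the setpoints are crossed: weights onto E minimize
  the *inhibitory* error and weights onto I the *excitatory* error
  (dW_EE = +a (I_set - I), dW_EI = -a (I_set - I), dW_IE = -a (E_set - E),
  dW_II = +a (E_set - E));
* two-term               — the sum of both, an approximate gradient of the
  quadratic loss L = 1/2 (E - E_set)^2 + 1/2 (I - I_set)^2.

A generic rule constructor covers hybrid/anti-homeostatic sign patterns and
multiplicative (synaptic-scaling) variants.  Training is trial-based (the
network is kicked, rates are averaged over a steady-state window, weights
are updated at the end of every trial) or online (running exponential
averages feed the rule during one continuous simulation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.signal import lfilter

from .core import (
    DEFAULT_DT,
    DEFAULT_KICK,
    DEFAULT_TRIAL_DURATION,
    DEFAULT_WINDOW,
    LOW_NOISE,
    RATE_CEILING,
    NetworkParams,
    NoiseParams,
    StimulusProtocol,
    WeightSet,
    simulate_trial,
    trial_mean_rates,
)
from ._kernels import simulate_two_pop

__all__ = [
    "SetPoints",
    "LearningRates",
    "WeightDelta",
    "RuleSpec",
    "ClassSpec",
    "TrainingHistory",
    "delta_standard",
    "delta_cross",
    "delta_two_term",
    "make_rule",
    "standard_rule",
    "cross_rule",
    "two_term_rule",
    "apply_delta",
    "train_trials",
    "train_online",
    "loss",
]


@dataclass(frozen=True)
class SetPoints:
    """Target firing rates (Hz) for the E and I populations."""

    E_set: float = 5.0
    I_set: float = 14.0

    def __post_init__(self) -> None:
        if self.E_set <= 0 or self.I_set <= 0:
            raise ValueError("setpoints must be positive")


@dataclass(frozen=True)
class LearningRates:
    """Per-weight-class learning rates (weight units per Hz per trial)."""

    alpha_EE: float
    alpha_EI: float
    alpha_IE: float
    alpha_II: float

    def __post_init__(self) -> None:
        if min(self.alpha_EE, self.alpha_EI, self.alpha_IE, self.alpha_II) < 0:
            raise ValueError("learning rates must be non-negative")

    @classmethod
    def uniform(cls, alpha: float) -> "LearningRates":
        return cls(alpha, alpha, alpha, alpha)

    @classmethod
    def per_population(cls, alpha_E: float, alpha_I: float) -> "LearningRates":
        """alpha_E drives the weights onto E, alpha_I the weights onto I."""
        return cls(alpha_E, alpha_E, alpha_I, alpha_I)

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha_EE, self.alpha_EI, self.alpha_IE, self.alpha_II])


@dataclass(frozen=True)
class WeightDelta:
    dW_EE: float
    dW_EI: float
    dW_IE: float
    dW_II: float

    def as_array(self) -> np.ndarray:
        return np.array([self.dW_EE, self.dW_EI, self.dW_IE, self.dW_II])

    @classmethod
    def from_array(cls, a) -> "WeightDelta":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


def delta_standard(E_avg: float, I_avg: float, setpoints: SetPoints,
                   rates: LearningRates) -> WeightDelta:
    """Standard homeostatic family: each class driven by its postsynaptic error."""
    eE = setpoints.E_set - E_avg
    eI = setpoints.I_set - I_avg
    return WeightDelta(
        +rates.alpha_EE * eE,
        -rates.alpha_EI * eE,
        +rates.alpha_IE * eI,
        -rates.alpha_II * eI,
    )


def delta_cross(E_avg: float, I_avg: float, setpoints: SetPoints,
                rates: LearningRates) -> WeightDelta:
    """Cross-homeostatic family: the setpoints are crossed between populations."""
    eE = setpoints.E_set - E_avg
    eI = setpoints.I_set - I_avg
    return WeightDelta(
        +rates.alpha_EE * eI,
        -rates.alpha_EI * eI,
        -rates.alpha_IE * eE,
        +rates.alpha_II * eE,
    )


def delta_two_term(E_avg: float, I_avg: float, setpoints: SetPoints,
                   rates: LearningRates,
                   cross_rates: Optional[LearningRates] = None) -> WeightDelta:
    """Two-term family: homeostatic plus cross-homeostatic contributions.

    ``cross_rates`` defaults to ``rates``; setting either term's rates to
    zero recovers the pure standard or pure cross family.
    """
    cr = rates if cross_rates is None else cross_rates
    h = delta_standard(E_avg, I_avg, setpoints, rates)
    c = delta_cross(E_avg, I_avg, setpoints, cr)
    return WeightDelta.from_array(h.as_array() + c.as_array())


def loss(E_avg: float, I_avg: float, setpoints: SetPoints) -> float:
    """Quadratic setpoint loss 1/2 (E - E_set)^2 + 1/2 (I - I_set)^2."""
    return 0.5 * (E_avg - setpoints.E_set) ** 2 + 0.5 * (I_avg - setpoints.I_set) ** 2


# ---------------------------------------------------------------------------
# Generic rule constructor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassSpec:
    """Update recipe for one weight class.

    ``own_sign``/``cross_sign`` multiply the postsynaptic population's own
    error and the other population's error respectively (0 disables a term);
    ``scaling`` multiplies the whole update by the current weight, as in
    synaptic scaling.
    """

    own_sign: float = 0.0
    cross_sign: float = 0.0
    scaling: bool = False

    def __post_init__(self) -> None:
        for s in (self.own_sign, self.cross_sign):
            if s not in (-1.0, 0.0, 1.0, -1, 0, 1):
                raise ValueError("signs must be -1, 0 or +1")


@dataclass(frozen=True)
class RuleSpec:
    """Sign/error-source/scaling pattern for all four weight classes."""

    EE: ClassSpec
    EI: ClassSpec
    IE: ClassSpec
    II: ClassSpec
    name: str = "custom"


#: Canonical specs of the three published families.
STANDARD_SPEC = RuleSpec(
    EE=ClassSpec(own_sign=+1), EI=ClassSpec(own_sign=-1),
    IE=ClassSpec(own_sign=+1), II=ClassSpec(own_sign=-1),
    name="standard",
)
CROSS_SPEC = RuleSpec(
    EE=ClassSpec(cross_sign=+1), EI=ClassSpec(cross_sign=-1),
    IE=ClassSpec(cross_sign=-1), II=ClassSpec(cross_sign=+1),
    name="cross",
)
TWO_TERM_SPEC = RuleSpec(
    EE=ClassSpec(own_sign=+1, cross_sign=+1), EI=ClassSpec(own_sign=-1, cross_sign=-1),
    IE=ClassSpec(own_sign=+1, cross_sign=-1), II=ClassSpec(own_sign=-1, cross_sign=+1),
    name="two_term",
)

#: Signature shared by all rule callables.
Rule = Callable[[float, float, WeightSet, SetPoints, LearningRates], WeightDelta]


def make_rule(spec: RuleSpec) -> Rule:
    """Build a rule function from a sign/error/scaling spec.

    The per-class update is sign * alpha * error (* weight if scaling);
    the canonical specs reproduce the three published families exactly.
    """
    if not isinstance(spec, RuleSpec):
        raise TypeError("spec must be a RuleSpec")

    classes = (spec.EE, spec.EI, spec.IE, spec.II)
    # own error of classes onto E is the E error; onto I the I error
    own_is_E = (True, True, False, False)

    def rule(E_avg: float, I_avg: float, weights: WeightSet,
             setpoints: SetPoints, rates: LearningRates) -> WeightDelta:
        eE = setpoints.E_set - E_avg
        eI = setpoints.I_set - I_avg
        alphas = rates.as_array()
        w = weights.as_array()
        out = np.empty(4)
        for k, (cs, own_e) in enumerate(zip(classes, own_is_E)):
            own = eE if own_e else eI
            cross = eI if own_e else eE
            d = alphas[k] * (cs.own_sign * own + cs.cross_sign * cross)
            if cs.scaling:
                d *= w[k]
            out[k] = d
        return WeightDelta.from_array(out)

    rule.spec = spec  # type: ignore[attr-defined]
    rule.__name__ = f"{spec.name}_rule"
    return rule


def _wrap(fn, name):
    def rule(E_avg, I_avg, weights, setpoints, rates):
        return fn(E_avg, I_avg, setpoints, rates)
    rule.__name__ = name
    return rule


#: The three published families as training-ready rule callables.
standard_rule: Rule = _wrap(delta_standard, "standard_rule")
cross_rule: Rule = _wrap(delta_cross, "cross_rule")
two_term_rule: Rule = _wrap(delta_two_term, "two_term_rule")


def apply_delta(weights: WeightSet, delta: WeightDelta,
                lower_bound: float = 0.0) -> WeightSet:
    """Element-wise update with clipping at ``lower_bound`` (no sign flips)."""
    d = delta.as_array()
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite weight delta")
    return WeightSet.from_array(np.maximum(weights.as_array() + d, lower_bound))


# ---------------------------------------------------------------------------
# Training loops
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    """Per-trial record of simulated development."""

    E_avg: np.ndarray          # (n_trials,) window-mean E rate per trial
    I_avg: np.ndarray          # (n_trials,)
    weights: np.ndarray        # (n_trials, 4) weights *used* in each trial
    runaway: np.ndarray        # (n_trials,) bool
    final_weights: WeightSet
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def n_trials(self) -> int:
        return len(self.E_avg)

    def quiescent(self, tol: float = 1e-3) -> np.ndarray:
        return (self.E_avg < tol) & (self.I_avg < tol)

    def converged(self, setpoints: SetPoints, rel_tol: float = 0.05,
                  tail_frac: float = 0.1) -> bool:
        """Relative setpoint error below ``rel_tol`` sustained over the last
        ``tail_frac`` of trials (a report, not a stopping criterion)."""
        n = max(1, int(round(self.n_trials * tail_frac)))
        eE = np.abs(self.E_avg[-n:] / setpoints.E_set - 1.0)
        eI = np.abs(self.I_avg[-n:] / setpoints.I_set - 1.0)
        return bool(np.all(eE < rel_tol) and np.all(eI < rel_tol))

    def to_tsv(self, path: str) -> None:
        data = np.column_stack([
            np.arange(self.n_trials), self.E_avg, self.I_avg,
            self.weights, self.runaway.astype(int),
        ])
        np.savetxt(path, data, delimiter="\t", comments="",
                   header="trial\tE_avg\tI_avg\tW_EE\tW_EI\tW_IE\tW_II\trunaway")

    def to_npz(self, path: str) -> None:
        """Compact binary container for batch post-processing."""
        np.savez_compressed(path, E_avg=self.E_avg, I_avg=self.I_avg,
                            weights=self.weights, runaway=self.runaway)


def _trial_seeds(seed: Optional[int], n: int) -> np.ndarray:
    ss = np.random.SeedSequence(0 if seed is None else seed)
    return (ss.generate_state(n, dtype=np.uint32) >> 1).astype(np.int64)


def train_trials(
    initial_weights: WeightSet,
    rule: Rule,
    n_trials: int,
    setpoints: SetPoints,
    rates: LearningRates,
    params: Optional[NetworkParams] = None,
    stimulus: StimulusProtocol = DEFAULT_KICK,
    noise: NoiseParams = LOW_NOISE,
    duration: float = DEFAULT_TRIAL_DURATION,
    dt: float = DEFAULT_DT,
    window: tuple = DEFAULT_WINDOW,
    seed: Optional[int] = 0,
    lower_bound: float = 0.0,
    ext_E: float = 0.0,
) -> TrainingHistory:
    """Trial-based simulated development of the two-population model.

    Every trial starts from quiescence, is kicked by ``stimulus``, rates are
    averaged over ``window`` and the weights are updated at the end of the
    trial.  Runaway trials still update (their window means come from the
    pre-divergence segment), as do quiescent trials (window means ~0), which
    is what lets the rules grow weights out of silence.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    params = params or NetworkParams()
    seeds = _trial_seeds(seed, n_trials)
    w = initial_weights
    E_avg = np.empty(n_trials)
    I_avg = np.empty(n_trials)
    W = np.empty((n_trials, 4))
    run = np.zeros(n_trials, dtype=bool)
    for t in range(n_trials):
        W[t] = w.as_array()
        trace = simulate_trial(params, w, stimulus, noise, duration, dt,
                               seed=int(seeds[t]), ext_E=ext_E)
        E_avg[t], I_avg[t] = trial_mean_rates(trace, *window)
        run[t] = trace.runaway
        w = apply_delta(w, rule(E_avg[t], I_avg[t], w, setpoints, rates),
                        lower_bound)
    cfg = dict(rule=getattr(rule, "__name__", str(rule)), n_trials=n_trials,
               duration=duration, dt=dt, window=window,
               noise_sigma=noise.sigma if noise.enabled else 0.0,
               setpoints=(setpoints.E_set, setpoints.I_set),
               rates=tuple(rates.as_array()), ext_E=ext_E)
    return TrainingHistory(E_avg, I_avg, W, run, w, cfg, seed)


def train_online(
    initial_weights: WeightSet,
    rule: Rule,
    total_time: float,
    setpoints: SetPoints,
    rates: LearningRates,
    params: Optional[NetworkParams] = None,
    averaging_time_constant: float = 1000.0,
    update_interval: float = 10.0,
    kick: StimulusProtocol = DEFAULT_KICK,
    kick_interval: float = DEFAULT_TRIAL_DURATION,
    noise: NoiseParams = LOW_NOISE,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = 0,
    lower_bound: float = 0.0,
) -> TrainingHistory:
    """Online variant: weights are updated continuously during one long run.

    Exponential moving averages of the rates (time constant
    ``averaging_time_constant`` ms) feed the rule every ``update_interval``
    ms, with the per-update learning rates interpreted per trial-equivalent
    (scaled by update_interval / kick_interval) so that small learning rates
    match the trial-based loop.  The kick is re-applied every
    ``kick_interval`` ms, mirroring the trial structure.  History entries
    are recorded per update.
    """
    if update_interval < dt:
        raise ValueError("update_interval must be >= dt")
    params = params or NetworkParams()
    n_updates = int(round(total_time / update_interval))
    steps_per_update = int(round(update_interval / dt))
    kick_every = max(1, int(round(kick_interval / update_interval)))
    amp_E, amp_I, on_ms, off_ms = (kick.amplitude if kick.target in ("E", "both") else 0.0,
                                   kick.amplitude if kick.target in ("I", "both") else 0.0,
                                   kick.onset, kick.onset + kick.duration) if kick else (0, 0, 0, 0)
    scale = update_interval / kick_interval
    rng = np.random.default_rng(seed)
    w = initial_weights
    E = I = etaE = etaI = 0.0
    mE = mI = 0.0
    lam = dt / averaging_time_constant
    E_hist = np.empty(n_updates)
    I_hist = np.empty(n_updates)
    W_hist = np.empty((n_updates, 4))
    run = np.zeros(n_updates, dtype=bool)
    noise_on = bool(noise.enabled and noise.sigma > 0)
    scaled = LearningRates(*(rates.as_array() * scale))
    for u in range(n_updates):
        W_hist[u] = w.as_array()
        if u % kick_every == 0:
            E = I = 0.0  # trial boundary: network restarts from quiescence
            s_on, s_off = int(round(on_ms / dt)), int(round(off_ms / dt))
        else:
            s_on = s_off = -1
        draws = rng.standard_normal((steps_per_update, 2)) if noise_on else np.zeros((1, 2))
        Et, It, n_valid, etaE, etaI = simulate_two_pop(
            E, I, etaE, etaI, steps_per_update, dt,
            params.tau_E, params.tau_I, params.g_E, params.g_I,
            params.theta_E, params.theta_I,
            w.W_EE, w.W_EI, w.W_IE, w.W_II,
            amp_E, amp_I, s_on, s_off, 0.0, 0.0,
            noise_on, noise.mu, noise.inv_tau, noise.sigma,
            draws, RATE_CEILING,
        )
        run[u] = n_valid < steps_per_update + 1
        # recursive EMA over the chunk: m_k = (1 - lam) m_{k-1} + lam x_k
        b_f, a_f = [lam], [1.0, -(1.0 - lam)]
        yE, zE = lfilter(b_f, a_f, Et[1:], zi=[(1.0 - lam) * mE])
        yI, zI = lfilter(b_f, a_f, It[1:], zi=[(1.0 - lam) * mI])
        mE, mI = float(yE[-1]), float(yI[-1])
        E, I = float(Et[n_valid - 1]), float(It[n_valid - 1])
        if run[u]:
            E = I = 0.0
        E_hist[u], I_hist[u] = mE, mI
        w = apply_delta(w, rule(mE, mI, w, setpoints, scaled), lower_bound)
    cfg = dict(rule=getattr(rule, "__name__", str(rule)), mode="online",
               total_time=total_time, update_interval=update_interval,
               averaging_time_constant=averaging_time_constant)
    return TrainingHistory(E_hist, I_hist, W_hist, run, w, cfg, seed)
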