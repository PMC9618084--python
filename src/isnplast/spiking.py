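"""Sparse adaptive LIF network trained by the local two-term rule.

The network is a sparsely connected (Bernoulli, default 25%) population of
adaptive leaky integrate-and-fire neurons with current-pulse synapses:
each presynaptic spike delivers its weight's worth of charge (w pA x 1 ms)
as an exponentially decaying current, slow for recurrent E->E (NMDA-like)
and fast onto and from the low-capacitance fast-spiking I cells — the
spiking analog of the rate model's tau_I << tau_E and g_I > g_E, which is
what stabilizes the up-state.  Weights are initialized in an early
"developmental" regime that does not sustain activity after the kick; the
two-term cross-homeostatic rule — own-error homeostatic term plus the mean
error of each neuron's presynaptic partners of the opposite class — then
grows the four synapse classes until the network self-sustains
asynchronous irregular spiking (CV_ISI ~ 1) at the firing-rate setpoints
and exhibits the paradoxical effect.

Cell parameters are a conventional adaptive-LIF set producing ~5-15 Hz
irregular firing under balanced input; every constant is exposed in
``SpikingParams``.  The default network is a reduced 400E/100I build (the
full 1,600E/400I size is a configuration choice away) with the same
mean-weight ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import run_lif
from .plasticity import SetPoints

__all__ = [
    "SpikingParams",
    "SpikingNetwork",
    "SpikeData",
    "SpikingHistory",
    "build_spiking_network",
    "run_spiking_trial",
    "estimate_rates",
    "update_spiking_weights",
    "cv_isi",
    "train_spiking",
    "paradoxical_test_spiking",
]

#: Initial class-mean weights (pA) of the silent developmental regime.
DEFAULT_INIT_MEANS = {"EE": 80.0, "EI": 350.0, "IE": 100.0, "II": 225.0}


@dataclass(frozen=True)
class SpikingParams:
    """Adaptive LIF cell and noise constants (ms, mV, pA, pF, nS)."""

    C_m: float = 200.0          # E membrane capacitance, pF (tau_m = 20 ms)
    C_m_I: float = 70.0         # I membrane capacitance, pF — fast, high-gain
                                # interneurons (tau_m = 7 ms), the analog of
                                # tau_I << tau_E and g_I > g_E in rate terms
    g_L: float = 10.0           # leak conductance, nS
    E_L: float = -60.0          # resting potential, mV
    V_reset: float = -60.0      # post-spike reset, mV
    V_th: float = -50.0         # mean spike threshold, mV
    V_th_spread: float = 1.5    # cell-to-cell threshold sd, mV — breaks the
                                # fast E-I population rhythm that otherwise
                                # regularizes single-unit firing
    t_ref: float = 2.0          # E absolute refractory period, ms
    t_ref_I: float = 1.0        # I refractory period, ms (fast-spiking)
    b: float = 2.0              # spike-triggered adaptation increment, pA
    tau_w: float = 150.0        # adaptation decay, ms
    syn_pulse: float = 1.0      # charge per pA of weight, pA*ms
    # synaptic current decay per class (ms): slow recurrent excitation onto
    # E, fast drive onto I and fast inhibition — the speed asymmetry that
    # lets inhibition stabilize the up-state (tau_I << tau_E in rate terms)
    tau_syn_EE: float = 15.0
    tau_syn_EI: float = 5.0
    tau_syn_IE: float = 3.0
    tau_syn_II: float = 5.0
    noise_sigma: float = 60.0   # stationary std of OU current noise, pA
    noise_tau: float = 10.0     # OU noise time constant, ms — slow enough to
                                # produce the large membrane fluctuations of
                                # the asynchronous-irregular regime

    def __post_init__(self) -> None:
        if self.V_th <= self.V_reset:
            raise ValueError("threshold must exceed reset")
        if self.tau_w <= 0:
            raise ValueError("adaptation time constant must be positive")


@dataclass
class SpikingNetwork:
    """Dense per-class weight matrices (pA, zeros off the adjacency masks)."""

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    W_II: np.ndarray
    mask_EE: np.ndarray
    mask_EI: np.ndarray
    mask_IE: np.ndarray
    mask_II: np.ndarray
    params: SpikingParams = field(default_factory=SpikingParams)
    V_th_units: Optional[np.ndarray] = None  # per-unit thresholds, mV

    @property
    def N_E(self) -> int:
        return self.W_EE.shape[0]

    @property
    def N_I(self) -> int:
        return self.W_IE.shape[0]

    def weights(self, cls: str) -> np.ndarray:
        return getattr(self, f"W_{cls}")

    def mask(self, cls: str) -> np.ndarray:
        return getattr(self, f"mask_{cls}")

    def class_means(self) -> dict:
        """Mean weight per existing synapse, by class (pA)."""
        out = {}
        for cls in ("EE", "EI", "IE", "II"):
            m = self.mask(cls)
            out[cls] = float(self.weights(cls)[m].mean()) if m.any() else 0.0
        return out

    def charge_matrix(self) -> np.ndarray:
        """Signed (N, N) charge matrix in pA*ms, E units first."""
        nE, nI = self.N_E, self.N_I
        Q = np.zeros((nE + nI, nE + nI))
        Q[:nE, :nE] = self.W_EE
        Q[:nE, nE:] = -self.W_EI
        Q[nE:, :nE] = self.W_IE
        Q[nE:, nE:] = -self.W_II
        return Q * self.params.syn_pulse

    def copy(self) -> "SpikingNetwork":
        return SpikingNetwork(
            self.W_EE.copy(), self.W_EI.copy(), self.W_IE.copy(), self.W_II.copy(),
            self.mask_EE, self.mask_EI, self.mask_IE, self.mask_II, self.params,
            None if self.V_th_units is None else self.V_th_units.copy(),
        )

    def to_triplets(self, path: str) -> None:
        """Sparse triplet text snapshot: post, pre, weight (signed, pA)."""
        Q = self.charge_matrix() / self.params.syn_pulse
        post, pre = np.nonzero(Q)
        np.savetxt(path, np.column_stack([post, pre, Q[post, pre]]),
                   delimiter="\t", comments="", header="post\tpre\tweight_pA")


@dataclass
class SpikeData:
    """Flat spike record of one trial."""

    times: np.ndarray   # ms, sorted
    units: np.ndarray   # unit index, E units are 0..N_E-1
    N_E: int
    N_I: int
    duration: float
    seed: Optional[int] = None

    @property
    def n_units(self) -> int:
        return self.N_E + self.N_I

    def unit_spike_times(self, unit: int) -> np.ndarray:
        return self.times[self.units == unit]

    def to_event_list(self, path: str) -> None:
        np.savetxt(path, np.column_stack([self.units, self.times]),
                   delimiter="\t", comments="", header="unit\ttime_ms")


def build_spiking_network(
    N_E: int = 400,
    N_I: int = 100,
    p_connect: float = 0.25,
    mean_weights: Optional[dict] = None,
    weight_spread: float = 0.2,
    seed: Optional[int] = 0,
    params: Optional[SpikingParams] = None,
) -> SpikingNetwork:
    """Seeded Bernoulli connectivity with normal weights around class means.

    ``mean_weights`` maps class -> mean weight in pA (defaults to the silent
    developmental regime); draws are clipped at 0.  E->E self-connections
    are excluded.
    """
    if not 0 < p_connect <= 1:
        raise ValueError("p_connect must be in (0, 1]")
    if N_E < 1 or N_I < 1:
        raise ValueError("invalid population sizes")
    mean_weights = dict(DEFAULT_INIT_MEANS, **(mean_weights or {}))
    rng = np.random.default_rng(seed)
    shapes = {"EE": (N_E, N_E), "EI": (N_E, N_I), "IE": (N_I, N_E), "II": (N_I, N_I)}
    mats, masks = {}, {}
    for cls, shape in shapes.items():
        m = rng.random(shape) < p_connect
        if cls == "EE":
            np.fill_diagonal(m, False)
        mu = mean_weights[cls]
        W = rng.normal(mu, weight_spread * mu, size=shape)
        np.clip(W, 0.0, None, out=W)
        W[~m] = 0.0
        masks[cls], mats[cls] = m, W
    params = params or SpikingParams()
    vth = rng.normal(params.V_th, params.V_th_spread, size=N_E + N_I)
    return SpikingNetwork(
        mats["EE"], mats["EI"], mats["IE"], mats["II"],
        masks["EE"], masks["EI"], masks["IE"], masks["II"],
        params, vth,
    )


def run_spiking_trial(
    network: SpikingNetwork,
    kick: tuple = (300.0, 20.0),
    duration: float = 600.0,
    dt: float = 0.1,
    seed: Optional[int] = 0,
    probe: tuple = (0.0, 0.0, 0.0),
    noise: bool = True,
    max_rate_per_unit: float = 500.0,
) -> SpikeData:
    """One trial: ``kick`` = (pA, ms) onto all E units at t = 0;
    ``probe`` = (pA, on_ms, off_ms) tonic current onto all I units."""
    p = network.params
    n_steps = int(round(duration / dt))
    nE = network.N_E
    N = nE + network.N_I
    max_spikes = int(N * duration / 1000.0 * max_rate_per_unit) + 1000
    tau_exc = np.where(np.arange(N) < nE, p.tau_syn_EE, p.tau_syn_IE)
    tau_inh = np.where(np.arange(N) < nE, p.tau_syn_EI, p.tau_syn_II)
    C = np.where(np.arange(N) < nE, p.C_m, p.C_m_I)
    t_sp, u_sp = run_lif(
        network.charge_matrix(), nE,
        n_steps, dt,
        C, p.g_L, p.E_L, p.V_reset,
        network.V_th_units if network.V_th_units is not None
        else np.full(N, p.V_th),
        np.where(np.arange(N) < nE, int(round(p.t_ref / dt)),
                 int(round(p.t_ref_I / dt))),
        p.b, p.tau_w, tau_exc, tau_inh,
        p.noise_sigma if noise else 0.0, p.noise_tau,
        kick[0], int(round(kick[1] / dt)),
        probe[0], int(round(probe[1] / dt)), int(round(probe[2] / dt)),
        0 if seed is None else int(seed) & 0x7FFFFFFF,
        max_spikes,
    )
    return SpikeData(t_sp, u_sp, network.N_E, network.N_I, duration, seed)


def estimate_rates(spikes: SpikeData, window: tuple = (300.0, 600.0)) -> tuple:
    """Per-unit firing rates (Hz) as spike counts / window length.

    Returns ``(rates, E_mean, I_mean)``; rates has one entry per unit.
    """
    t0, t1 = window
    if t0 < 0 or t1 > spikes.duration or t1 <= t0:
        raise ValueError("window outside trial bounds")
    sel = (spikes.times >= t0) & (spikes.times < t1)
    counts = np.bincount(spikes.units[sel].astype(np.int64),
                         minlength=spikes.n_units)
    rates = counts / ((t1 - t0) / 1000.0)
    return rates, float(rates[:spikes.N_E].mean()), float(rates[spikes.N_E:].mean())


def update_spiking_weights(
    network: SpikingNetwork,
    rates: np.ndarray,
    setpoints: SetPoints,
    rate: float,
    lower_bound: float = 0.0,
) -> None:
    """In-place local two-term update of all four synapse classes.

    For each synapse onto unit i: the homeostatic term uses i's own rate
    error and the cross term the mean error of i's presynaptic partners of
    the opposite class (zero, and logged via the returned count, if a unit
    has no such partners).  Sign pattern as in the two-term rate rule;
    clipping at ``lower_bound``; absent synapses untouched.
    """
    nE = network.N_E
    eE = setpoints.E_set - rates[:nE]
    eI = setpoints.I_set - rates[nE:]

    def row_mean(mask, err):
        cnt = mask.sum(axis=1)
        out = (mask @ err)
        out[cnt > 0] /= cnt[cnt > 0]
        out[cnt == 0] = 0.0
        return out

    cross_onto_E = row_mean(network.mask_EI, eI)
    cross_onto_I = row_mean(network.mask_IE, eE)
    dEE = rate * (eE + cross_onto_E)
    dEI = rate * (-eE - cross_onto_E)
    dIE = rate * (eI - cross_onto_I)
    dII = rate * (-eI + cross_onto_I)
    for cls, d in zip(("EE", "EI", "IE", "II"), (dEE, dEI, dIE, dII)):
        W = network.weights(cls)
        m = network.mask(cls)
        W += d[:, None] * m
        np.clip(W, lower_bound, None, out=W)
        W[~m] = 0.0


def cv_isi(spikes, window: tuple = (300.0, 600.0),
           min_spikes: int = 3) -> tuple:
    """Per-unit coefficient of variation of inter-spike intervals.

    ``spikes`` is one SpikeData or a list of them: with several trials the
    within-window intervals are pooled per unit across trials, so slowly
    firing units accumulate enough intervals for a stable estimate.  Units
    with fewer than ``min_spikes`` pooled intervals + 1 are excluded.
    Returns ``(per_unit_cv, median_cv, n_excluded)``.
    """
    trials = spikes if isinstance(spikes, (list, tuple)) else [spikes]
    n_units = trials[0].n_units
    pooled = [[] for _ in range(n_units)]
    for sd in trials:
        sel = (sd.times >= window[0]) & (sd.times < window[1])
        times, units = sd.times[sel], sd.units[sel].astype(np.int64)
        order = np.argsort(times, kind="stable")
        times, units = times[order], units[order]
        for u in np.unique(units):
            ts = times[units == u]
            if len(ts) >= 2:
                pooled[u].extend(np.diff(np.sort(ts)))
    cvs = []
    excluded = 0
    for u in range(n_units):
        isi = np.asarray(pooled[u])
        if len(isi) < min_spikes - 1 or isi.mean() == 0:
            excluded += 1
            continue
        cvs.append(float(isi.std() / isi.mean()))
    cvs = np.asarray(cvs)
    med = float(np.median(cvs)) if len(cvs) else float("nan")
    return cvs, med, excluded


@dataclass
class SpikingHistory:
    """Class-mean rates, weights and setpoint MSE across training trials.

    ``mse`` is the mean squared error of each unit's *average* firing rate
    (exponential moving average over ~50 trials — the quantity a
    homeostatic sensor integrates) with respect to its class setpoint.
    """

    E_mean: np.ndarray
    I_mean: np.ndarray
    class_means: np.ndarray      # (n_trials, 4): EE, EI, IE, II mean pA
    mse: np.ndarray              # MSE of trial-averaged unit rates
    network: SpikingNetwork
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None


def _unit_mse(rates: np.ndarray, nE: int, setpoints: SetPoints) -> float:
    err = np.concatenate([rates[:nE] - setpoints.E_set, rates[nE:] - setpoints.I_set])
    return float(np.mean(err ** 2))


def train_spiking(
    network: SpikingNetwork,
    n_trials: int,
    setpoints: SetPoints,
    rate: float = 0.05,
    kick: tuple = (300.0, 20.0),
    duration: float = 600.0,
    dt: float = 0.1,
    window: tuple = (300.0, 600.0),
    seed: Optional[int] = 0,
) -> SpikingHistory:
    """Trial-based development of the spiking network (in place).

    The default learning rate (pA per Hz of error per trial) keeps
    class-mean weight changes per trial at or below ~1% of class means.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(0 if seed is None else seed)
    seeds = (ss.generate_state(n_trials, dtype=np.uint32) >> 1).astype(np.int64)
    Em = np.empty(n_trials)
    Im = np.empty(n_trials)
    cm = np.empty((n_trials, 4))
    mse = np.empty(n_trials)
    avg_rates = None
    lam = 1.0 / 50.0  # ~50-trial averaging of per-unit rates
    for t in range(n_trials):
        means = network.class_means()
        cm[t] = [means["EE"], means["EI"], means["IE"], means["II"]]
        sd = run_spiking_trial(network, kick, duration, dt, seed=int(seeds[t]))
        rates, Em[t], Im[t] = estimate_rates(sd, window)
        avg_rates = rates if avg_rates is None else avg_rates + lam * (rates - avg_rates)
        mse[t] = _unit_mse(avg_rates, network.N_E, setpoints)
        update_spiking_weights(network, rates, setpoints, rate)
    cfg = dict(n_trials=n_trials, rate=rate, duration=duration, dt=dt,
               window=window, kick=kick,
               setpoints=(setpoints.E_set, setpoints.I_set))
    return SpikingHistory(Em, Im, cm, mse, network, cfg, seed)


def paradoxical_test_spiking(
    network: SpikingNetwork,
    probe_currents: Sequence[float] = (0.0, 25.0, 50.0, 100.0),
    n_trials_per_level: int = 5,
    kick: tuple = (300.0, 20.0),
    duration: float = 600.0,
    probe_window: tuple = (300.0, 550.0),
    dt: float = 0.1,
    seed: Optional[int] = 0,
) -> dict:
    """Mean I-population rate during tonic current injection into all I units.

    Probe trials inject a tonic current during ``probe_window`` (placed in
    the late, steady part of the trial); the 0-amplitude level is the
    control.  Because the within-trial rate is not perfectly stationary,
    the comparison is made across amplitude levels in the *same* window:
    the network is paradoxical when the during-injection I rate decreases
    monotonically with increasing positive probe.  Per-level pre-injection
    baselines and a collapse flag (activity died under the probe) are also
    reported.  Requires a trained, self-sustaining network: raises if the
    control condition is (near-)silent in the probe window.
    """
    ss = np.random.SeedSequence(0 if seed is None else seed)
    # common random numbers: the same trial seeds at every amplitude, so
    # level differences are paired and trial-to-trial up-state variability
    # cancels out of the comparison
    seeds = (ss.generate_state(n_trials_per_level,
                               dtype=np.uint32) >> 1).astype(np.int64)
    baseline_window = (probe_window[0] - 200.0, probe_window[0])
    base = np.zeros(len(probe_currents))
    during = np.zeros(len(probe_currents))
    collapsed = np.zeros(len(probe_currents), dtype=bool)
    for li, amp in enumerate(probe_currents):
        b_acc = d_acc = 0.0
        e_acc = 0.0
        for k in range(n_trials_per_level):
            sd = run_spiking_trial(network, kick, duration, dt,
                                   seed=int(seeds[k]),
                                   probe=(amp, probe_window[0], probe_window[1]))
            _, _, ib = estimate_rates(sd, baseline_window)
            _, edur, idur = estimate_rates(sd, probe_window)
            b_acc += ib
            d_acc += idur
            e_acc += edur
        base[li] = b_acc / n_trials_per_level
        during[li] = d_acc / n_trials_per_level
        collapsed[li] = during[li] < 0.1 and base[li] > 1.0
        if amp == 0.0 and e_acc / n_trials_per_level < 0.5:
            # noise alone can make the fast I cells tick over, so
            # self-sustainment is judged by recurrent excitatory activity
            raise ValueError(
                "network is not self-sustaining; paradoxical test undefined")
    amps = np.asarray(probe_currents, dtype=float)
    zero = np.flatnonzero(amps == 0.0)
    if len(zero):
        # paradoxical: every positive injection lowers the I rate below the
        # zero-probe control (very strong probes eventually silence E and
        # drive I directly — the non-ISN branch — so monotonicity across
        # arbitrary amplitudes is not required)
        paradoxical = bool(np.all(during[amps > 0] < during[zero[0]]))
    else:
        paradoxical = bool(np.all(np.diff(during[np.argsort(amps)]) < 0))
    return dict(probe_currents=amps,
                baseline_I=base, during_I=during, collapsed=collapsed,
                paradoxical=paradoxical)
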