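"""Two-population inhibition-stabilized rate model.

The model is a threshold-linear Wilson-Cowan system for the firing rates of
one excitatory (E) and one inhibitory (I) population,

    tau_E dE/dt = -E + f_E(W_EE E - W_EI I + eta_E + ext_E),
    tau_I dI/dt = -I + f_I(W_IE E - W_II I + eta_I + ext_I),

with f_Y(x) = 0 for x < theta_Y and g_Y (x - theta_Y) otherwise, and eta_Y
an Ornstein-Uhlenbeck noise process injected inside the transfer argument.
Self-sustained activity is elicited by a brief step current (the "kick") on
the excitatory population at trial onset; with all four weights balanced the
network settles onto a stable nontrivial fixed point and, when
W_EE * g_E > 1, operates as an inhibition-stabilized network exhibiting the
paradoxical effect (extra drive to I *lowers* the steady-state I rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from ._kernels import simulate_two_pop

__all__ = [
    "NetworkParams",
    "NoiseParams",
    "WeightSet",
    "StimulusProtocol",
    "RateTrace",
    "FixedPoint",
    "transfer",
    "ou_step",
    "simulate_trial",
    "steady_state",
    "paradoxical_probe",
    "is_paradoxical",
    "trial_mean_rates",
]

#: Divergence guard for the unbounded threshold-linear transfer (Hz).
RATE_CEILING = 1.0e4

#: Default integration step (ms); tau_I = 2 ms is the fastest neural scale.
DEFAULT_DT = 0.1

#: Default trial length and steady-state averaging window (ms).
DEFAULT_TRIAL_DURATION = 1000.0
DEFAULT_WINDOW = (500.0, 1000.0)


@dataclass(frozen=True)
class NetworkParams:
    """Time constants (ms), transfer gains (Hz per input unit) and thresholds."""

    tau_E: float = 10.0
    tau_I: float = 2.0
    g_E: float = 1.0
    g_I: float = 4.0
    theta_E: float = 4.8
    theta_I: float = 25.0

    def __post_init__(self) -> None:
        if self.tau_E <= 0 or self.tau_I <= 0:
            raise ValueError("time constants must be positive")
        if self.g_E <= 0 or self.g_I <= 0:
            raise ValueError("gains must be positive")


@dataclass(frozen=True)
class NoiseParams:
    """Ornstein-Uhlenbeck noise: d(eta) = inv_tau (mu - eta) dt + sigma dW.

    With this Euler-Maruyama discretization the stationary variance is
    sigma^2 dt / (1 - (1 - inv_tau dt)^2) ~ sigma^2 / (2 inv_tau).
    """

    mu: float = 0.0
    inv_tau: float = 1.0
    sigma: float = 10.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.inv_tau <= 0:
            raise ValueError("inv_tau must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


#: Low-amplitude noise used during simulated development ("low levels of
#: noise were used to avoid fluctuation-induced transitions").
LOW_NOISE = NoiseParams(sigma=2.0)
NO_NOISE = NoiseParams(sigma=0.0, enabled=False)


@dataclass(frozen=True)
class WeightSet:
    """The four synaptic weight classes W_{post<-pre} of the two-population model."""

    W_EE: float
    W_EI: float
    W_IE: float
    W_II: float

    def __post_init__(self) -> None:
        if min(self.W_EE, self.W_EI, self.W_IE, self.W_II) < 0:
            raise ValueError("weights must be non-negative; inhibition signs are explicit in the dynamics")

    def as_array(self) -> np.ndarray:
        return np.array([self.W_EE, self.W_EI, self.W_IE, self.W_II])

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "WeightSet":
        return cls(float(a[0]), float(a[1]), float(a[2]), float(a[3]))


@dataclass(frozen=True)
class StimulusProtocol:
    """Brief step current that kicks the network out of quiescence."""

    amplitude: float = 7.0
    duration: float = 10.0
    onset: float = 0.0
    target: str = "E"  # "E", "I" or "both"

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        if self.target not in ("E", "I", "both"):
            raise ValueError(f"unknown stimulus target {self.target!r}")


#: Kick used throughout simulated development (I_ext = 7 for 10 ms onto E).
DEFAULT_KICK = StimulusProtocol()


@dataclass
class RateTrace:
    """Simulated E/I firing-rate trajectory on a uniform time grid."""

    t: np.ndarray
    E: np.ndarray
    I: np.ndarray
    dt: float
    runaway: bool = False
    n_valid: Optional[int] = None
    seed: Optional[int] = None

    def to_tsv(self, path: str) -> None:
        np.savetxt(
            path,
            np.column_stack([self.t, self.E, self.I]),
            delimiter="\t",
            header="time_ms\tE_hz\tI_hz",
            comments="",
        )


def save_trace_batch(traces: Sequence["RateTrace"], path: str) -> None:
    """Compact binary container (npz) for a batch of equally sampled traces."""
    np.savez_compressed(
        path,
        t=traces[0].t,
        E=np.stack([tr.E for tr in traces]),
        I=np.stack([tr.I for tr in traces]),
        seeds=np.array([-1 if tr.seed is None else tr.seed for tr in traces]),
    )


@dataclass(frozen=True)
class FixedPoint:
    """A branch-consistent steady state of the neural subsystem."""

    E: float
    I: float
    branch: str  # e.g. "EI_active", "E_active", "I_active", "quiescent"
    neural_stable: bool
    eigenvalues: tuple
    degenerate: bool = False

    @property
    def nontrivial(self) -> bool:
        return self.E > 1e-9 or self.I > 1e-9


def transfer(x, gain: float, threshold: float):
    """Threshold-linear transfer: 0 below threshold, gain * (x - threshold) above."""
    if gain <= 0:
        raise ValueError("gain must be positive")
    return np.where(np.asarray(x) < threshold, 0.0, gain * (np.asarray(x) - threshold))[()]


def ou_step(value: float, noise: NoiseParams, dt: float, draw: float) -> float:
    """One Euler-Maruyama step of the OU noise process."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    return value + noise.inv_tau * (noise.mu - value) * dt + noise.sigma * math.sqrt(dt) * draw


def _stim_amps(stimulus: Optional[StimulusProtocol]):
    if stimulus is None:
        return 0.0, 0.0, 0, 0
    amp_E = stimulus.amplitude if stimulus.target in ("E", "both") else 0.0
    amp_I = stimulus.amplitude if stimulus.target in ("I", "both") else 0.0
    return amp_E, amp_I, stimulus.onset, stimulus.onset + stimulus.duration


def simulate_trial(
    params: NetworkParams,
    weights: WeightSet,
    stimulus: Optional[StimulusProtocol] = DEFAULT_KICK,
    noise: Optional[NoiseParams] = None,
    duration: float = DEFAULT_TRIAL_DURATION,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = None,
    initial_rates: tuple = (0.0, 0.0),
    ext_E: float = 0.0,
    ext_I: float = 0.0,
    rate_ceiling: float = RATE_CEILING,
) -> RateTrace:
    """Integrate one trial of the two-population model.

    Noise deviates are drawn from ``numpy.random.default_rng(seed)`` so that
    identical inputs and seed give bit-identical traces.  If either rate
    crosses ``rate_ceiling`` the trial is flagged runaway and the trace is
    frozen at the divergence point.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    noise = NO_NOISE if noise is None else noise
    if noise.enabled and dt > min(params.tau_I, 1.0 / noise.inv_tau) / 2:
        raise ValueError("dt too coarse for the fastest time scale")
    n_steps = int(round(duration / dt))
    amp_E, amp_I, on_ms, off_ms = _stim_amps(stimulus)
    if stimulus is not None and duration <= off_ms:
        raise ValueError("trial must outlast the stimulus")
    noise_on = bool(noise.enabled and noise.sigma > 0)
    if noise_on:
        rng = np.random.default_rng(seed)
        draws = rng.standard_normal((n_steps, 2))
    else:
        draws = np.zeros((1, 2))
    E, I, n_valid, _, _ = simulate_two_pop(
        float(initial_rates[0]), float(initial_rates[1]), 0.0, 0.0,
        n_steps, dt,
        params.tau_E, params.tau_I, params.g_E, params.g_I,
        params.theta_E, params.theta_I,
        weights.W_EE, weights.W_EI, weights.W_IE, weights.W_II,
        amp_E, amp_I, int(round(on_ms / dt)), int(round(off_ms / dt)),
        ext_E, ext_I,
        noise_on, noise.mu, noise.inv_tau, noise.sigma,
        draws,
        rate_ceiling,
    )
    t = np.arange(n_steps + 1) * dt
    runaway = n_valid < n_steps + 1
    return RateTrace(t=t, E=E, I=I, dt=dt, runaway=runaway,
                     n_valid=int(n_valid), seed=seed)


# ---------------------------------------------------------------------------
# Fixed points
# ---------------------------------------------------------------------------

_BRANCHES = ("EI_active", "E_active", "I_active", "quiescent")


def _branch_jacobian(params: NetworkParams, weights: WeightSet, e_active: bool, i_active: bool) -> np.ndarray:
    gE = params.g_E if e_active else 0.0
    gI = params.g_I if i_active else 0.0
    return np.array([
        [(gE * weights.W_EE - 1.0) / params.tau_E, -gE * weights.W_EI / params.tau_E],
        [gI * weights.W_IE / params.tau_I, -(1.0 + gI * weights.W_II) / params.tau_I],
    ])


def steady_state(
    params: NetworkParams,
    weights: WeightSet,
    ext_E: float = 0.0,
    ext_I: float = 0.0,
    tol: float = 1e-9,
) -> list:
    """Enumerate all branch-consistent fixed points of the noiseless model.

    Each of the four piecewise-linear branches (E active/quiescent x I
    active/quiescent) is solved in closed form; a solution is kept only if
    the net input on each active branch actually exceeds the threshold (and
    stays below it on each quiescent branch).  Branches whose linear system
    is singular are reported as degenerate rather than dropped.
    """
    out = []
    for branch in _BRANCHES:
        e_act = branch in ("EI_active", "E_active")
        i_act = branch in ("EI_active", "I_active")
        gE = params.g_E if e_act else 0.0
        gI = params.g_I if i_act else 0.0
        A = np.array([
            [1.0 - gE * weights.W_EE, gE * weights.W_EI],
            [-gI * weights.W_IE, 1.0 + gI * weights.W_II],
        ])
        b = np.array([
            gE * (ext_E - params.theta_E),
            gI * (ext_I - params.theta_I),
        ])
        det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
        if abs(det) < 1e-12:
            out.append(FixedPoint(math.nan, math.nan, branch, False, (), degenerate=True))
            continue
        E, I = np.linalg.solve(A, b)
        if E < -tol or I < -tol:
            continue
        E, I = max(E, 0.0), max(I, 0.0)
        xE = weights.W_EE * E - weights.W_EI * I + ext_E
        xI = weights.W_IE * E - weights.W_II * I + ext_I
        ok_E = (xE >= params.theta_E - tol) if e_act else (xE < params.theta_E + tol)
        ok_I = (xI >= params.theta_I - tol) if i_act else (xI < params.theta_I + tol)
        if not (ok_E and ok_I):
            continue
        J = _branch_jacobian(params, weights, e_act, i_act)
        eig = np.linalg.eigvals(J)
        fp = FixedPoint(float(E), float(I), branch,
                        bool(np.all(eig.real < 0)), tuple(eig))
        # deduplicate boundary solutions found by several branches
        if not any(abs(f.E - fp.E) < 1e-7 and abs(f.I - fp.I) < 1e-7 for f in out if not f.degenerate):
            out.append(fp)
    return out


def stable_nontrivial_fixed_point(
    params: NetworkParams,
    weights: WeightSet,
    ext_E: float = 0.0,
    ext_I: float = 0.0,
) -> Optional[FixedPoint]:
    """The stable fixed point with nonzero activity, if one exists."""
    cands = [f for f in steady_state(params, weights, ext_E, ext_I)
             if not f.degenerate and f.neural_stable and f.nontrivial]
    if not cands:
        return None
    # prefer the fully active branch (the self-sustained regime)
    cands.sort(key=lambda f: (f.branch != "EI_active", -f.E))
    return cands[0]


def paradoxical_probe(
    params: NetworkParams,
    weights: WeightSet,
    probe_current: float = 7.0,
) -> tuple:
    """Steady-state I rate without and with a tonic probe current on I.

    Returns ``(I_before, I_after, delta_I)``; a negative ``delta_I`` for a
    positive probe is the signature of the inhibition-stabilized
    (paradoxical) regime.  Raises if the unprobed network has no stable
    nontrivial fixed point, in which case the probe is undefined.
    """
    before = stable_nontrivial_fixed_point(params, weights)
    if before is None:
        raise ValueError("network has no stable nontrivial fixed point; paradoxical probe undefined")
    after = stable_nontrivial_fixed_point(params, weights, ext_I=probe_current)
    if after is None:
        raise ValueError("probe destroys the nontrivial fixed point")
    return before.I, after.I, after.I - before.I


def is_paradoxical(weights: WeightSet, params: NetworkParams) -> bool:
    """Inhibition-stabilized condition W_EE * g_E - 1 > 0 (strict)."""
    return weights.W_EE * params.g_E - 1.0 > 0.0


def trial_mean_rates(
    trace: RateTrace,
    window_start: float = DEFAULT_WINDOW[0],
    window_end: float = DEFAULT_WINDOW[1],
) -> tuple:
    """Arithmetic mean E and I rates over [window_start, window_end] ms.

    For runaway-flagged traces the mean is taken over the pre-divergence
    segment that intersects the window (falling back to the last valid
    sample if the trace diverged before the window opened).
    """
    if window_start < 0 or window_end <= window_start:
        raise ValueError("invalid averaging window")
    i0 = int(round(window_start / trace.dt))
    i1 = int(round(window_end / trace.dt)) + 1
    if i1 - 1 > len(trace.t) - 1:
        raise ValueError("window extends past the end of the trace")
    if trace.runaway and trace.n_valid is not None:
        i1 = min(i1, trace.n_valid)
        if i0 >= i1:
            i0, i1 = trace.n_valid - 1, trace.n_valid
    return float(np.mean(trace.E[i0:i1])), float(np.mean(trace.I[i0:i1]))
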