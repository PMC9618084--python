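"""Multiunit rate network (80E/20I) with per-unit homeostatic plasticity.

Each unit obeys the same threshold-linear rate dynamics as the
two-population model; weights are dense per-class matrices scaled by
1/(presynaptic partner count) so that class means are directly comparable
to the two-population weights (a zero-spread network reduces exactly to the
two-population model).  Plasticity is local: each synapse is updated from
the postsynaptic unit's own rate error and/or the mean error of the
postsynaptic unit's presynaptic partners of the opposite class — the
quantity a neuron could read out through metabotropic receptor activation.

With the single-term cross rule the population *means* converge to the
setpoints while individual units disperse around them; adding the
homeostatic own-error term (two-term rule) drives every unit to its class
setpoint and onto a common E/I balance line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import simulate_multi
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
)
from .plasticity import SetPoints

__all__ = [
    "MultiunitNetwork",
    "UnitRates",
    "MultiTrainingHistory",
    "init_multi_weights",
    "simulate_trial_multi",
    "presyn_mean_error",
    "update_weights_multi",
    "balance_summary",
    "train_multi",
]

_CLASSES = ("EE", "EI", "IE", "II")

#: Class-mean anchor: the two-population weight set whose fully-active fixed
#: point sits exactly at the default (5, 14) Hz setpoints.
DEFAULT_CLASS_MEANS = WeightSet(5.0, 1.0857142857142856, 10.0, 1.5357142857142858)


@dataclass
class MultiunitNetwork:
    """Dense per-class weight matrices (postsynaptic x presynaptic) + masks."""

    W_EE: np.ndarray
    W_EI: np.ndarray
    W_IE: np.ndarray
    W_II: np.ndarray
    mask_EE: np.ndarray
    mask_EI: np.ndarray
    mask_IE: np.ndarray
    mask_II: np.ndarray
    params: NetworkParams = field(default_factory=NetworkParams)
    noise: NoiseParams = field(default_factory=lambda: LOW_NOISE)

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

    def class_means(self) -> WeightSet:
        """Mean *total* class input per postsynaptic unit (two-population scale)."""
        vals = []
        for cls in _CLASSES:
            vals.append(float(self.weights(cls).sum(axis=1).mean()))
        return WeightSet(*vals)

    def save_matrices(self, directory: str, prefix: str = "weights") -> None:
        """Write the four weight matrices as dense delimited text files."""
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for cls in _CLASSES:
            np.savetxt(d / f"{prefix}_{cls}.tsv", self.weights(cls),
                       delimiter="\t")

    def copy(self) -> "MultiunitNetwork":
        return MultiunitNetwork(
            self.W_EE.copy(), self.W_EI.copy(), self.W_IE.copy(), self.W_II.copy(),
            self.mask_EE, self.mask_EI, self.mask_IE, self.mask_II,
            self.params, self.noise,
        )


@dataclass
class UnitRates:
    """Per-unit trial-mean rates and their population means."""

    E_units: np.ndarray
    I_units: np.ndarray
    runaway: bool = False

    @property
    def E_bar(self) -> float:
        return float(np.mean(self.E_units))

    @property
    def I_bar(self) -> float:
        return float(np.mean(self.I_units))


def init_multi_weights(
    N_E: int = 80,
    N_I: int = 20,
    distribution: str = "normal",
    class_means: WeightSet = DEFAULT_CLASS_MEANS,
    spread: float = 0.2,
    seed: Optional[int] = 0,
    params: Optional[NetworkParams] = None,
    noise: Optional[NoiseParams] = None,
) -> MultiunitNetwork:
    """Seeded random initialization of the multiunit network.

    ``class_means`` are on the two-population scale; per-synapse means are
    divided by the presynaptic partner count of the class so population
    input matches the two-population model.  ``spread`` is the relative
    per-synapse dispersion: normal draws (sd = spread * mean, clipped at 0)
    or log-normal draws parameterized to the same mean and CV.  Connectivity
    is all-to-all with no E->E self-connections.
    """
    if distribution not in ("normal", "log-normal", "lognormal"):
        raise ValueError(f"invalid distribution {distribution!r}")
    rng = np.random.default_rng(seed)
    mask_EE = ~np.eye(N_E, dtype=bool)
    mask_EI = np.ones((N_E, N_I), dtype=bool)
    mask_IE = np.ones((N_I, N_E), dtype=bool)
    mask_II = np.ones((N_I, N_I), dtype=bool)
    masks = dict(EE=mask_EE, EI=mask_EI, IE=mask_IE, II=mask_II)
    mats = {}
    for cls, mean_total in zip(_CLASSES, class_means.as_array()):
        m = masks[cls]
        n_partners = m.sum(axis=1)  # per-row presynaptic count
        mu = mean_total / n_partners[:, None]  # broadcast per row
        if spread == 0:
            W = np.broadcast_to(mu, m.shape).copy()
        elif distribution == "normal":
            W = rng.normal(mu, spread * mu, size=m.shape)
            np.clip(W, 0.0, None, out=W)
        else:
            # log-normal matched to mean mu and CV = spread
            s2 = np.log1p(spread ** 2)
            W = rng.lognormal(np.log(mu) - s2 / 2, np.sqrt(s2), size=m.shape)
        W[~m] = 0.0
        mats[cls] = W
    return MultiunitNetwork(
        mats["EE"], mats["EI"], mats["IE"], mats["II"],
        mask_EE, mask_EI, mask_IE, mask_II,
        params or NetworkParams(), noise if noise is not None else LOW_NOISE,
    )


def simulate_trial_multi(
    network: MultiunitNetwork,
    stimulus: Optional[StimulusProtocol] = DEFAULT_KICK,
    duration: float = DEFAULT_TRIAL_DURATION,
    dt: float = DEFAULT_DT,
    seed: Optional[int] = 0,
    window: tuple = DEFAULT_WINDOW,
    record: bool = False,
    rate_ceiling: float = RATE_CEILING,
):
    """One trial of the multiunit network (pulse delivered to all E units).

    Returns ``UnitRates`` of window means, plus (traceE, traceI) arrays of
    shape (n_steps + 1, N) when ``record`` is true.
    """
    p = network.params
    nz = network.noise
    n_steps = int(round(duration / dt))
    amp = stimulus.amplitude if stimulus is not None else 0.0
    on = int(round(stimulus.onset / dt)) if stimulus else 0
    off = int(round((stimulus.onset + stimulus.duration) / dt)) if stimulus else 0
    noise_on = bool(nz.enabled and nz.sigma > 0)
    mE, mI, runaway, _n_valid, trE, trI = simulate_multi(
        network.W_EE, network.W_EI, network.W_IE, network.W_II,
        n_steps, dt,
        p.tau_E, p.tau_I, p.g_E, p.g_I, p.theta_E, p.theta_I,
        amp, on, off,
        noise_on, nz.mu, nz.inv_tau, nz.sigma,
        int(round(window[0] / dt)),
        0 if seed is None else int(seed) & 0x7FFFFFFF,
        rate_ceiling,
        record,
    )
    rates = UnitRates(mE, mI, bool(runaway))
    if record:
        return rates, trE, trI
    return rates


def presyn_mean_error(
    network: MultiunitNetwork,
    unit: int,
    source_class: str,
    unit_rates: UnitRates,
    setpoints: SetPoints,
    post_class: str = "E",
) -> float:
    """Mean (setpoint - rate) over the unit's presynaptic partners.

    ``source_class`` is 'E' or 'I' (the presynaptic population);
    ``post_class`` identifies which population ``unit`` belongs to.
    """
    cls = post_class + source_class  # e.g. post E from I -> "EI"
    if cls not in _CLASSES:
        raise ValueError(f"invalid class {cls}")
    m = network.mask(cls)[unit]
    if not m.any():
        raise ValueError(f"unit {unit} has no presynaptic partners in class {cls}")
    r = unit_rates.E_units if source_class == "E" else unit_rates.I_units
    sp = setpoints.E_set if source_class == "E" else setpoints.I_set
    return float(np.mean(sp - r[m]))


def _masked_row_mean(mask: np.ndarray, err: np.ndarray) -> np.ndarray:
    """Per-row mean of ``err`` over the masked presynaptic partners."""
    cnt = mask.sum(axis=1)
    return (mask @ err) / np.maximum(cnt, 1)


def update_weights_multi(
    network: MultiunitNetwork,
    rule: str,
    unit_rates: UnitRates,
    setpoints: SetPoints,
    rate: float,
    lower_bound: float = 0.0,
) -> None:
    """In-place per-synapse update (rule = 'cross' or 'two_term').

    The cross term applied to synapses onto unit i uses the mean error of
    i's presynaptic partners of the opposite class, with the
    cross-homeostatic sign pattern; the two-term rule adds i's own error
    with the standard homeostatic sign pattern.  Updates are clipped at
    ``lower_bound`` and masked entries stay exactly zero.
    """
    if rule not in ("cross", "two_term"):
        raise ValueError(f"unknown multiunit rule {rule!r}")
    eE = setpoints.E_set - unit_rates.E_units  # per-unit E errors
    eI = setpoints.I_set - unit_rates.I_units
    # mean opposite-class presynaptic error seen by each postsynaptic unit
    cross_onto_E = _masked_row_mean(network.mask_EI, eI)  # (N_E,)
    cross_onto_I = _masked_row_mean(network.mask_IE, eE)  # (N_I,)
    dEE = +rate * cross_onto_E
    dEI = -rate * cross_onto_E
    dIE = -rate * cross_onto_I
    dII = +rate * cross_onto_I
    if rule == "two_term":
        dEE = dEE + rate * eE
        dEI = dEI - rate * eE
        dIE = dIE + rate * eI
        dII = dII - rate * eI
    for cls, d in zip(_CLASSES, (dEE, dEI, dIE, dII)):
        W = network.weights(cls)
        m = network.mask(cls)
        W += d[:, None] * m
        np.clip(W, lower_bound, None, out=W)
        W[~m] = 0.0


def balance_summary(network: MultiunitNetwork) -> dict:
    """Total incoming E and I weight per unit (scatter tables).

    Returns ``{"E": (N_E, 2), "I": (N_I, 2)}`` arrays of
    (summed excitatory, summed inhibitory) input weights per unit.
    """
    onto_E = np.column_stack([network.W_EE.sum(axis=1), network.W_EI.sum(axis=1)])
    onto_I = np.column_stack([network.W_IE.sum(axis=1), network.W_II.sum(axis=1)])
    return {"E": onto_E, "I": onto_I}


@dataclass
class MultiTrainingHistory:
    """Per-trial per-unit rates and class-mean weights across development."""

    E_units: np.ndarray        # (n_trials, N_E)
    I_units: np.ndarray        # (n_trials, N_I)
    class_means: np.ndarray    # (n_trials, 4) total-input class means
    runaway: np.ndarray        # (n_trials,)
    network: MultiunitNetwork  # final state
    config: dict = field(default_factory=dict)
    seed: Optional[int] = None

    @property
    def E_bar(self) -> np.ndarray:
        return self.E_units.mean(axis=1)

    @property
    def I_bar(self) -> np.ndarray:
        return self.I_units.mean(axis=1)

    def to_tsv(self, path: str) -> None:
        data = np.column_stack([
            np.arange(len(self.E_bar)), self.E_bar, self.I_bar,
            self.class_means, self.runaway.astype(int),
        ])
        np.savetxt(path, data, delimiter="\t", comments="",
                   header="trial\tE_bar\tI_bar\tW_EE\tW_EI\tW_IE\tW_II\trunaway")


def train_multi(
    network: MultiunitNetwork,
    rule: str,
    n_trials: int,
    setpoints: SetPoints,
    rate: float,
    stimulus: StimulusProtocol = DEFAULT_KICK,
    duration: float = DEFAULT_TRIAL_DURATION,
    dt: float = DEFAULT_DT,
    window: tuple = DEFAULT_WINDOW,
    seed: Optional[int] = 0,
    lower_bound: float = 0.0,
) -> MultiTrainingHistory:
    """Trial-based development of the multiunit network (in place)."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    ss = np.random.SeedSequence(0 if seed is None else seed)
    seeds = (ss.generate_state(n_trials, dtype=np.uint32) >> 1).astype(np.int64)
    nE, nI = network.N_E, network.N_I
    E_units = np.empty((n_trials, nE))
    I_units = np.empty((n_trials, nI))
    cm = np.empty((n_trials, 4))
    run = np.zeros(n_trials, dtype=bool)
    for t in range(n_trials):
        cm[t] = network.class_means().as_array()
        r = simulate_trial_multi(network, stimulus, duration, dt,
                                 seed=int(seeds[t]), window=window)
        E_units[t], I_units[t] = r.E_units, r.I_units
        run[t] = r.runaway
        update_weights_multi(network, rule, r, setpoints, rate, lower_bound)
    cfg = dict(rule=rule, n_trials=n_trials, rate=rate, duration=duration,
               dt=dt, window=window,
               setpoints=(setpoints.E_set, setpoints.I_set))
    return MultiTrainingHistory(E_units, I_units, cm, run, network, cfg, seed)
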