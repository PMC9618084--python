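"""Config-driven experiment presets with seeded batch runs and manifests.

Each preset reproduces one experiment of the study: failure of
standard homeostatic rules, instability at a balanced initialization,
cross-homeostatic convergence (including alternative setpoint pairs),
stability-region maps, multiunit training with the single- and two-term
rules, and the spiking network.  Outputs are plain delimited text plus a
JSON manifest sufficient to re-run bit-identically.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import __version__
from .core import NetworkParams, WeightSet, steady_state
from .plasticity import (
    LearningRates,
    SetPoints,
    cross_rule,
    standard_rule,
    train_trials,
    two_term_rule,
)
from .multiunit import init_multi_weights, train_multi
from .spiking import (
    build_spiking_network,
    cv_isi,
    run_spiking_trial,
    train_spiking,
)
from .stability import stability_map

__all__ = ["ExperimentConfig", "RunManifest", "run_experiment",
           "batch_initializer", "PRESETS", "load_config"]

_RULES = {"standard": standard_rule, "cross": cross_rule, "two_term": two_term_rule}


@dataclass
class ExperimentConfig:
    """Resolved preset plus overrides; seeds are always explicit."""

    preset: str
    seeds: list = field(default_factory=lambda: [0])
    out_dir: str = "results"
    options: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(
                f"unknown preset {self.preset!r}; choose from {sorted(PRESETS)}")
        if not self.seeds:
            raise ValueError("at least one explicit seed is required")


@dataclass
class RunManifest:
    """Everything needed to re-run a preset bit-identically."""

    preset: str
    seeds: list
    options: dict
    code_version: str
    outputs: list
    summary: dict

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_json_default)

    @classmethod
    def load(cls, path: str) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def load_config(path: str) -> ExperimentConfig:
    """Read an experiment config from a YAML key-value file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return ExperimentConfig(
        preset=raw.get("preset", "custom"),
        seeds=list(raw.get("seeds", [0])),
        out_dir=raw.get("out_dir", "results"),
        options=dict(raw.get("options", {})),
    )


# ---------------------------------------------------------------------------
# Weight-set batch generation
# ---------------------------------------------------------------------------

def batch_initializer(
    n: int,
    strategy: str = "around_attractor",
    seed: Optional[int] = 0,
    setpoints: Optional[SetPoints] = None,
    params: Optional[NetworkParams] = None,
    jitter: float = 0.2,
) -> list:
    """Generate ``n`` seeded random initial weight sets.

    Strategies:
      * ``around_attractor`` — sample the free weights, pin (W_EI, W_II) to
        the balance constraints and jitter all four relatively (jitter = 0
        gives exact constraint solutions);
      * ``broad`` — wide uniform ranges over all four weights;
      * ``silent`` — small weights verified (via fixed-point analysis) not
        to sustain activity after the kick.
    """
    from .stability import constrained_weights

    if n < 1:
        raise ValueError("n must be >= 1")
    setpoints = setpoints or SetPoints()
    params = params or NetworkParams()
    rng = np.random.default_rng(seed)
    out: list = []
    while len(out) < n:
        if strategy == "around_attractor":
            wee = rng.uniform(3.0, 7.0)
            wie = rng.uniform(7.0, 13.0)
            wei, wii = constrained_weights(wee, wie, setpoints, params)
            if wei < 0 or wii < 0:
                continue
            w = np.array([wee, wei, wie, wii])
            w *= 1.0 + jitter * rng.uniform(-1.0, 1.0, size=4)
            if np.any(w < 0):
                continue
            out.append(WeightSet.from_array(w))
        elif strategy == "broad":
            w = rng.uniform([0.5, 0.1, 1.0, 0.1], [8.0, 4.0, 16.0, 4.0])
            out.append(WeightSet.from_array(w))
        elif strategy == "silent":
            w = WeightSet.from_array(rng.uniform([0.0, 0.5, 0.5, 0.5],
                                                 [2.0, 4.0, 6.0, 3.0]))
            sustained = any(f.neural_stable and f.nontrivial
                            for f in steady_state(params, w) if not f.degenerate)
            if not sustained:
                out.append(w)
        else:
            raise ValueError(f"unknown strategy {strategy!r}")
    return out


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def _train_preset(rule_name, alphas, init, n_trials, setpoints, opts, seed):
    rates = (LearningRates.per_population(*alphas) if isinstance(alphas, tuple)
             else LearningRates.uniform(alphas))
    hist = train_trials(WeightSet(*init), _RULES[rule_name],
                        n_trials=n_trials, setpoints=setpoints, rates=rates,
                        seed=seed, **opts)
    tail = max(1, min(50, hist.n_trials // 10))
    return hist, dict(
        final_E=float(hist.E_avg[-tail:].mean()),
        final_I=float(hist.I_avg[-tail:].mean()),
        converged=hist.converged(setpoints),
        final_weights=list(hist.final_weights.as_array()),
    )


def _p_standard_failure(seed, opts):
    return _train_preset("standard", opts.pop("alpha", 1e-4),
                         opts.pop("init", (2.1, 3.0, 4.0, 2.0)),
                         opts.pop("n_trials", 1500), SetPoints(), opts, seed)


def _p_balanced_instability(seed, opts):
    return _train_preset("standard", opts.pop("alpha", 1e-4),
                         opts.pop("init", (5.0, 1.09, 10.0, 1.54)),
                         opts.pop("n_trials", 500), SetPoints(), opts, seed)


def _p_cross_development(seed, opts):
    sp = SetPoints(*opts.pop("setpoints", (5.0, 14.0)))
    return _train_preset("cross", opts.pop("alpha", 5e-4),
                         opts.pop("init", (2.1, 3.0, 4.0, 2.0)),
                         opts.pop("n_trials", 1500), sp, opts, seed)


def _p_cross_setpoint_pairs(seed, opts):
    results = {}
    hist = None
    for pair in opts.pop("setpoint_pairs", [(5.0, 14.0), (5.0, 28.0), (10.0, 14.0)]):
        hist, s = _p_cross_development(seed, dict(opts, setpoints=pair))
        results[f"E{pair[0]:g}_I{pair[1]:g}"] = s
    return hist, results


def _p_stability_map(seed, opts):
    rule = _RULES[opts.pop("rule", "cross")]
    ratio = opts.pop("rate_ratio", (1.0, 1.0))
    scale = opts.pop("rate_scale", 1e-4)
    rates = LearningRates.per_population(scale * ratio[0], scale * ratio[1])
    m = stability_map(rule, rates,
                      SetPoints(*opts.pop("setpoints", (5.0, 14.0))),
                      grid_n=opts.pop("grid_n", 50),
                      W_EE_range=tuple(opts.pop("W_EE_range", (1.0, 10.0))),
                      W_IE_range=tuple(opts.pop("W_IE_range", (1.0, 20.0))),
                      ext_current_E=opts.pop("ext_current_E", 0.0))
    return m, dict(
        n_neural_stable=int(m.neural_stable.sum()),
        n_rule_stable=int(m.rule_stable.sum()),
        n_joint=int(m.joint_stable.sum()),
        n_valid=int(m.valid.sum()),
    )


def _p_multiunit(rule):
    def run(seed, opts):
        net = init_multi_weights(
            N_E=opts.pop("N_E", 80), N_I=opts.pop("N_I", 20),
            distribution=opts.pop("distribution", "normal"),
            spread=opts.pop("spread", 0.2), seed=seed)
        sp = SetPoints(*opts.pop("setpoints", (5.0, 14.0)))
        hist = train_multi(net, rule,
                           n_trials=opts.pop("n_trials", 3000),
                           setpoints=sp,
                           rate=opts.pop("alpha", 2e-5 if rule == "cross" else 1e-5),
                           duration=opts.pop("duration", 400.0),
                           window=opts.pop("window", (200.0, 400.0)),
                           seed=seed, **opts)
        tail = max(1, min(100, hist.E_units.shape[0] // 10))
        fE = hist.E_units[-tail:].mean(axis=0)
        fI = hist.I_units[-tail:].mean(axis=0)
        return hist, dict(
            final_E_bar=float(fE.mean()), final_I_bar=float(fI.mean()),
            unit_sd_E=float(fE.std()), unit_sd_I=float(fI.std()),
        )
    return run


def _p_spiking_development(seed, opts):
    net = build_spiking_network(
        N_E=opts.pop("N_E", 400), N_I=opts.pop("N_I", 100),
        p_connect=opts.pop("p_connect", 0.25), seed=seed)
    sp = SetPoints(*opts.pop("setpoints", (5.0, 14.0)))
    hist = train_spiking(net, n_trials=opts.pop("n_trials", 2000),
                         setpoints=sp, rate=opts.pop("alpha", 0.02),
                         duration=opts.pop("duration", 600.0), seed=seed)
    base = seed + 1 if seed is not None else 1
    assay = [run_spiking_trial(net, duration=900.0, seed=base + s)
             for s in range(10)]
    _, med_cv, _ = cv_isi(assay, window=(300.0, 900.0))
    tail = max(1, hist.mse.shape[0] // 20)
    return hist, dict(
        final_E=float(hist.E_mean[-tail:].mean()),
        final_I=float(hist.I_mean[-tail:].mean()),
        initial_mse=float(hist.mse[0]), final_mse=float(hist.mse[-tail:].mean()),
        median_cv_isi=med_cv,
    )


PRESETS = {
    "standard_failure": _p_standard_failure,
    "balanced_instability": _p_balanced_instability,
    "cross_development": _p_cross_development,
    "cross_setpoint_pairs": _p_cross_setpoint_pairs,
    "stability_map": _p_stability_map,
    "multiunit_cross": _p_multiunit("cross"),
    "multiunit_two_term": _p_multiunit("two_term"),
    "spiking_development": _p_spiking_development,
    "custom": _p_cross_development,
}


def run_experiment(config: ExperimentConfig) -> RunManifest:
    """Run a preset across all configured seeds and write outputs + manifest.

    Exit semantics: completion, not convergence — summary statistics carry
    the convergence information.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    runner = PRESETS[config.preset]
    outputs = []
    per_seed = {}
    for seed in config.seeds:
        obj, summary = runner(seed, dict(config.options))
        per_seed[str(seed)] = summary
        base = out_dir / f"{config.preset}_seed{seed}"
        if hasattr(obj, "to_tsv"):
            path = f"{base}.tsv"
            obj.to_tsv(path)
            outputs.append(path)
    summary = dict(per_seed=per_seed)
    # aggregate final rates across seeds where available (mean +- SEM)
    for key in ("final_E", "final_I", "final_E_bar", "final_I_bar"):
        vals = [s[key] for s in per_seed.values() if isinstance(s, dict) and key in s]
        if vals:
            v = np.asarray(vals)
            summary[key] = dict(mean=float(v.mean()),
                                sem=float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0,
                                n=len(v))
    manifest = RunManifest(config.preset, list(config.seeds), config.options,
                           __version__, outputs, summary)
    manifest.save(str(out_dir / f"{config.preset}_manifest.json"))
    return manifest
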