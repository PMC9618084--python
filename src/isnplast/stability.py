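"""Fast-slow stability analysis of the coupled neural/plasticity system.

The neural subsystem (the two rate equations) is fast; the plasticity
subsystem (the four weight updates) is slow.  Stability of the full system
requires both: the 2x2 Jacobian of the rate equations at the fixed point,
and — under a quasi-steady-state approximation in which the rates are
assumed to sit at their fixed point E*(W), I*(W) — the 4x4 Jacobian of the
slow weight vector field F(W) = rule(E*(W), I*(W)).

Because every rule family depends on the weights only through the two rate
errors, the 4x4 QSSA Jacobian has rank <= 2 and always carries two zero
eigenvalues: these are the directions *along* the weight-space attractor
plane defined by the steady-state balance constraints (see
``constrained_weights``), where motion is neutral by construction.  A rule
is therefore classified stable when no eigenvalue has a positive real part
beyond tolerance (transverse stability).

``stability_map`` scans the free weights (W_EE, W_IE) with (W_EI, W_II)
pinned to the balance constraints, reproducing the region diagrams that
explain why cross-homeostatic rules self-organize inhibition-stabilized
dynamics and standard rules do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core import NetworkParams, WeightSet, is_paradoxical, steady_state
from .plasticity import LearningRates, Rule, SetPoints

__all__ = [
    "StabilityReport",
    "StabilityMap",
    "constrained_weights",
    "neural_jacobian",
    "qssa_plasticity_jacobian",
    "classify",
    "stability_report",
    "stability_map",
]


def constrained_weights(
    W_EE: float,
    W_IE: float,
    setpoints: SetPoints,
    params: Optional[NetworkParams] = None,
    ext_E: float = 0.0,
) -> tuple:
    """Solve the steady-state balance constraints for (W_EI, W_II).

    Setting dE/dt = dI/dt = 0 on the fully active branch and substituting
    the setpoints for the rates gives, for free weights W_EE and W_IE,

        W_EI = (W_EE E_set + ext_E - theta_E - E_set / g_E) / I_set
        W_II = (W_IE E_set - theta_I - I_set / g_I) / I_set

    so that the setpoints are a fixed point by construction.  The slope of
    W_EI against W_EE (and W_II against W_IE) is E_set / I_set — the weight
    space attractor line.  A negative result means no valid self-sustained
    network exists at that (W_EE, W_IE); the value is returned as-is (never
    silently clamped) so callers can flag the region.
    """
    p = params or NetworkParams()
    s = setpoints
    W_EI = (W_EE * s.E_set + ext_E - p.theta_E - s.E_set / p.g_E) / s.I_set
    W_II = (W_IE * s.E_set - p.theta_I - s.I_set / p.g_I) / s.I_set
    return float(W_EI), float(W_II)


def neural_jacobian(
    params: NetworkParams,
    weights: WeightSet,
    e_active: bool = True,
    i_active: bool = True,
) -> np.ndarray:
    """Analytic 2x2 Jacobian of the rate equations on a given branch.

    On the fully active branch:
        [[(g_E W_EE - 1)/tau_E,  -g_E W_EI/tau_E],
         [ g_I W_IE/tau_I,      -(1 + g_I W_II)/tau_I]]
    Quiescent branches zero the corresponding gain.
    """
    gE = params.g_E if e_active else 0.0
    gI = params.g_I if i_active else 0.0
    return np.array([
        [(gE * weights.W_EE - 1.0) / params.tau_E, -gE * weights.W_EI / params.tau_E],
        [gI * weights.W_IE / params.tau_I, -(1.0 + gI * weights.W_II) / params.tau_I],
    ])


def _active_fixed_point_formal(
    params: NetworkParams, w: np.ndarray, ext_E: float, ext_I: float
) -> tuple:
    """Fully-active-branch linear solve, with no consistency checks.

    Used by the map machinery, which evaluates the QSSA vector field over
    the whole (W_EE, W_IE) plane the way the analytic region diagrams do,
    regardless of whether the formal solution is a realizable rate pair.
    """
    gE, gI = params.g_E, params.g_I
    A = np.array([
        [1.0 - gE * w[0], gE * w[1]],
        [-gI * w[2], 1.0 + gI * w[3]],
    ])
    b = np.array([gE * (ext_E - params.theta_E), gI * (ext_I - params.theta_I)])
    det = A[0, 0] * A[1, 1] - A[0, 1] * A[1, 0]
    if abs(det) < 1e-12:
        return np.nan, np.nan
    E = (b[0] * A[1, 1] - A[0, 1] * b[1]) / det
    I = (A[0, 0] * b[1] - A[1, 0] * b[0]) / det
    return E, I


def _qssa_jacobian(
    rule: Rule,
    params: NetworkParams,
    w0: np.ndarray,
    setpoints: SetPoints,
    rates: LearningRates,
    step: float,
    ext_E: float,
    ext_I: float,
) -> np.ndarray:
    def F(w):
        E, I = _active_fixed_point_formal(params, w, ext_E, ext_I)
        # rules only read the weights for scaling variants; the duck-typed
        # container skips the non-negativity invariant inside the stencil
        return rule(E, I, _RawWeights(w), setpoints, rates).as_array()

    J = np.empty((4, 4))
    for j in range(4):
        h = step * max(1.0, abs(w0[j]))
        wp, wm = w0.copy(), w0.copy()
        wp[j] += h
        wm[j] -= h
        J[:, j] = (F(wp) - F(wm)) / (2 * h)
    return J


class _RawWeights:
    """Duck-typed weight container that skips the non-negativity invariant."""

    def __init__(self, w):
        self.W_EE, self.W_EI, self.W_IE, self.W_II = map(float, w)
        self._w = np.asarray(w, dtype=float)

    def as_array(self):
        return self._w


def qssa_plasticity_jacobian(
    rule: Rule,
    params: NetworkParams,
    weights: WeightSet,
    setpoints: SetPoints,
    rates: LearningRates,
    step: float = 1e-6,
    ext_E: float = 0.0,
    ext_I: float = 0.0,
) -> np.ndarray:
    """4x4 Jacobian of the slow weight vector field by central differences.

    The slow field is F(W) = rule(E*(W), I*(W)) with (E*, I*) the stable
    fully-active fixed point under the quasi-steady-state approximation.
    Raises if the neural subsystem has no stable fully-active fixed point at
    ``weights`` or loses it inside the difference stencil.
    """
    w0 = weights.as_array()

    def check(w, label):
        fps = [f for f in steady_state(params, WeightSet.from_array(np.maximum(w, 0)), ext_E, ext_I)
               if not f.degenerate and f.branch == "EI_active" and f.neural_stable]
        if not fps:
            raise ValueError(f"no stable fully-active fixed point at {label}; QSSA undefined")

    check(w0, "the base weights")
    for j, name in enumerate(("W_EE", "W_EI", "W_IE", "W_II")):
        h = step * max(1.0, abs(w0[j]))
        for sgn in (+1, -1):
            w = w0.copy()
            w[j] += sgn * h
            check(w, f"{name} {'+' if sgn > 0 else '-'}h")
    return _qssa_jacobian(rule, params, w0, setpoints, rates, step, ext_E, ext_I)


def classify(matrix: np.ndarray, tol: float = 1e-10) -> str:
    """'stable' (max Re < -tol), 'marginal' (within +-tol) or 'unstable'."""
    m = np.asarray(matrix, dtype=float) if np.isrealobj(matrix) else np.asarray(matrix)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix has non-finite entries")
    r = float(np.max(np.linalg.eigvals(m).real))
    if r < -tol:
        return "stable"
    if r <= tol:
        return "marginal"
    return "unstable"


def _rule_stable(eigs: np.ndarray) -> bool:
    """Transverse stability: no eigenvalue real part above the zero band.

    The two structural zero modes along the balance-constraint plane are
    neutral by construction and do not count against stability.
    """
    scale = max(float(np.max(np.abs(eigs))), 1e-300)
    ztol = max(1e-12, 1e-8 * scale)
    return bool(np.max(eigs.real) <= ztol)


@dataclass(frozen=True)
class StabilityReport:
    """Joint classification of the fast and slow subsystems at one weight set."""

    neural_eigenvalues: tuple
    plasticity_eigenvalues: tuple
    neural_stable: bool
    rule_stable: bool
    paradoxical: bool


def stability_report(
    rule: Rule,
    params: NetworkParams,
    weights: WeightSet,
    setpoints: SetPoints,
    rates: LearningRates,
    ext_E: float = 0.0,
    ext_I: float = 0.0,
) -> StabilityReport:
    """Analyze one weight set: neural eigenvalues, QSSA rule eigenvalues, flags."""
    Jn = neural_jacobian(params, weights)
    ne = np.linalg.eigvals(Jn)
    Jp = _qssa_jacobian(rule, params, weights.as_array(), setpoints, rates,
                        1e-6, ext_E, ext_I)
    pe = np.linalg.eigvals(Jp)
    return StabilityReport(
        tuple(ne), tuple(pe),
        bool(np.all(ne.real < 0)),
        _rule_stable(pe),
        is_paradoxical(weights, params),
    )


@dataclass
class StabilityMap:
    """Grid over the free weights (W_EE, W_IE) with per-cell flags.

    (W_EI, W_II) are pinned to the balance constraints for the map's
    setpoints; cells where a constrained weight is negative are flagged
    invalid (no self-sustained network exists there) but still evaluated
    formally so region boundaries remain visible, as in the analytic
    diagrams.
    """

    W_EE: np.ndarray           # (n,) grid values
    W_IE: np.ndarray           # (m,) grid values
    W_EI: np.ndarray           # (m, n) constrained values
    W_II: np.ndarray           # (m, n)
    neural_stable: np.ndarray  # (m, n) bool
    rule_stable: np.ndarray    # (m, n) bool
    paradoxical: np.ndarray    # (m, n) bool
    valid: np.ndarray          # (m, n) bool
    setpoints: SetPoints = field(default_factory=SetPoints)
    ext_E: float = 0.0
    rates: Optional[LearningRates] = None

    @property
    def joint_stable(self) -> np.ndarray:
        return self.neural_stable & self.rule_stable

    def to_tsv(self, path: str) -> None:
        rows = []
        for i, wie in enumerate(self.W_IE):
            for j, wee in enumerate(self.W_EE):
                rows.append([wee, wie, self.W_EI[i, j], self.W_II[i, j],
                             int(self.neural_stable[i, j]), int(self.rule_stable[i, j]),
                             int(self.paradoxical[i, j]), int(self.valid[i, j])])
        np.savetxt(path, np.asarray(rows), delimiter="\t", comments="",
                   header="W_EE\tW_IE\tW_EI\tW_II\tneural_stable\trule_stable\tparadoxical\tvalid")


def stability_map(
    rule: Rule,
    rates: LearningRates,
    setpoints: Optional[SetPoints] = None,
    params: Optional[NetworkParams] = None,
    W_EE_range: tuple = (1.0, 10.0),
    W_IE_range: tuple = (1.0, 20.0),
    grid_n: int = 50,
    ext_current_E: float = 0.0,
) -> StabilityMap:
    """Scan (W_EE, W_IE); classify both subsystems at every cell.

    A tonic external current on E (``ext_current_E``) shifts the balance
    constraint for W_EI and enlarges the neural stability region, the
    external-input variant of the region diagrams.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    setpoints = setpoints or SetPoints()
    params = params or NetworkParams()
    wee = np.linspace(*W_EE_range, grid_n)
    wie = np.linspace(*W_IE_range, grid_n)
    shape = (grid_n, grid_n)
    W_EI = np.empty(shape)
    W_II = np.empty(shape)
    ns = np.zeros(shape, dtype=bool)
    rs = np.zeros(shape, dtype=bool)
    par = np.zeros(shape, dtype=bool)
    valid = np.zeros(shape, dtype=bool)
    for i, b in enumerate(wie):
        for j, a in enumerate(wee):
            wei, wii = constrained_weights(a, b, setpoints, params, ext_current_E)
            W_EI[i, j], W_II[i, j] = wei, wii
            valid[i, j] = (wei >= 0) and (wii >= 0)
            w = np.array([a, wei, b, wii])
            Jn = np.array([
                [(params.g_E * a - 1.0) / params.tau_E, -params.g_E * wei / params.tau_E],
                [params.g_I * b / params.tau_I, -(1.0 + params.g_I * wii) / params.tau_I],
            ])
            ns[i, j] = bool(np.all(np.linalg.eigvals(Jn).real < 0))
            Jp = _qssa_jacobian(rule, params, w, setpoints, rates, 1e-6,
                                ext_current_E, 0.0)
            rs[i, j] = _rule_stable(np.linalg.eigvals(Jp))
            par[i, j] = a * params.g_E - 1.0 > 0.0
    return StabilityMap(wee, wie, W_EI, W_II, ns, rs, par, valid,
                        setpoints, ext_current_E, rates)
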