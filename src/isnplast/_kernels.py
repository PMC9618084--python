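"""Numba-compiled integration kernels.

The rate-model kernels integrate the threshold-linear Wilson-Cowan equations
with forward Euler; the spiking kernel integrates adaptive leaky
integrate-and-fire dynamics with instantaneous charge synapses.  Everything
here is deliberately free of Python objects so the hot loops compile to
machine code; the public modules wrap these functions with typed containers
and seed management.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _relu(x, gain, theta):
    if x < theta:
        return 0.0
    return gain * (x - theta)


@njit(cache=True)
def simulate_two_pop(
    E0, I0, etaE0, etaI0,
    n_steps, dt,
    tau_E, tau_I, g_E, g_I, th_E, th_I,
    wEE, wEI, wIE, wII,
    stim_E_amp, stim_I_amp, stim_on, stim_off,
    ext_E, ext_I,
    noise_on, mu, inv_tau, sigma,
    draws,
    ceiling,
):
    """Forward-Euler integration of the two-population rate model.

    ``draws`` is an (n_steps, 2) array of standard-normal deviates for the
    two Ornstein-Uhlenbeck noise processes (ignored when ``noise_on`` is
    false).  Returns the E and I traces (element k is the state after k
    steps, element 0 the initial condition), the number of valid samples
    (< n_steps + 1 if the divergence guard tripped) and the final OU states.
    """
    E = np.empty(n_steps + 1)
    I = np.empty(n_steps + 1)
    E[0] = E0
    I[0] = I0
    etaE = etaE0
    etaI = etaI0
    sq = np.sqrt(dt)
    n_valid = n_steps + 1
    for k in range(n_steps):
        sE = ext_E
        sI = ext_I
        if stim_on <= k < stim_off:
            sE += stim_E_amp
            sI += stim_I_amp
        xE = wEE * E[k] - wEI * I[k] + sE
        xI = wIE * E[k] - wII * I[k] + sI
        if noise_on:
            xE += etaE
            xI += etaI
            etaE += inv_tau * (mu - etaE) * dt + sigma * sq * draws[k, 0]
            etaI += inv_tau * (mu - etaI) * dt + sigma * sq * draws[k, 1]
        E[k + 1] = E[k] + dt / tau_E * (-E[k] + _relu(xE, g_E, th_E))
        I[k + 1] = I[k] + dt / tau_I * (-I[k] + _relu(xI, g_I, th_I))
        if E[k + 1] > ceiling or I[k + 1] > ceiling:
            n_valid = k + 2
            for j in range(k + 2, n_steps + 1):
                E[j] = E[k + 1]
                I[j] = I[k + 1]
            break
    return E, I, n_valid, etaE, etaI


@njit(cache=True)
def simulate_multi(
    WEE, WEI, WIE, WII,
    n_steps, dt,
    tau_E, tau_I, g_E, g_I, th_E, th_I,
    stim_amp, stim_on, stim_off,
    noise_on, mu, inv_tau, sigma,
    win_start,
    seed,
    ceiling,
    record,
):
    """Vectorized Euler integration of the multiunit rate network.

    Weights are dense per-class matrices (postsynaptic x presynaptic,
    masked entries exactly zero).  The external pulse is delivered to all
    excitatory units.  Per-unit OU noise is generated internally from
    ``seed``.  Returns per-unit means over [win_start, n_steps] plus the
    full traces when ``record`` is true.
    """
    np.random.seed(seed)
    nE = WEE.shape[0]
    nI = WIE.shape[0]
    rE = np.zeros(nE)
    rI = np.zeros(nI)
    etaE = np.zeros(nE)
    etaI = np.zeros(nI)
    accE = np.zeros(nE)
    accI = np.zeros(nI)
    if record:
        trE = np.empty((n_steps + 1, nE))
        trI = np.empty((n_steps + 1, nI))
        trE[0] = rE
        trI[0] = rI
    else:
        trE = np.empty((1, 1))
        trI = np.empty((1, 1))
    sq = np.sqrt(dt)
    n_acc = 0
    runaway = False
    n_valid = n_steps + 1
    for k in range(n_steps):
        xE = np.dot(WEE, rE) - np.dot(WEI, rI)
        xI = np.dot(WIE, rE) - np.dot(WII, rI)
        if stim_on <= k < stim_off:
            xE += stim_amp
        if noise_on:
            xE += etaE
            xI += etaI
            for i in range(nE):
                etaE[i] += inv_tau * (mu - etaE[i]) * dt + sigma * sq * np.random.standard_normal()
            for i in range(nI):
                etaI[i] += inv_tau * (mu - etaI[i]) * dt + sigma * sq * np.random.standard_normal()
        for i in range(nE):
            rE[i] += dt / tau_E * (-rE[i] + _relu(xE[i], g_E, th_E))
            if rE[i] > ceiling:
                runaway = True
        for i in range(nI):
            rI[i] += dt / tau_I * (-rI[i] + _relu(xI[i], g_I, th_I))
            if rI[i] > ceiling:
                runaway = True
        if record:
            trE[k + 1] = rE
            trI[k + 1] = rI
        if k + 1 >= win_start:
            accE += rE
            accI += rI
            n_acc += 1
        if runaway:
            n_valid = k + 2
            break
    if n_acc == 0:
        # divergence before the window opened: fall back to the last state
        accE[:] = rE
        accI[:] = rI
        n_acc = 1
    return accE / n_acc, accI / n_acc, runaway, n_valid, trE, trI


@njit(cache=True)
def run_lif(
    Q, n_E,
    n_steps, dt,
    C, gL, EL, V_reset, V_th_arr, ref_steps_arr,
    b, tau_w,
    tau_exc, tau_inh,
    noise_sigma, noise_tau,
    kick_amp, kick_steps,
    probe_amp, probe_on, probe_off,
    seed,
    max_spikes,
):
    """Adaptive LIF network trial with exponential current-pulse synapses.

    ``Q`` is the signed charge matrix in pA*ms (post x pre): a spike of
    presynaptic unit j adds |Q[i, j]| / tau to postsynaptic unit i's
    excitatory or inhibitory synaptic current, which decays with the
    per-neuron time constants ``tau_exc[i]`` / ``tau_inh[i]`` — the total
    delivered charge per spike is exactly |Q[i, j]|.  Distinct time
    constants per synapse class (slow recurrent excitation onto E, fast
    drive onto I, fast inhibition) give inhibition the speed advantage
    that stabilizes the up-state, mirroring the tau_I << tau_E asymmetry
    of the rate model.

    The kick current drives excitatory units for the first ``kick_steps``
    steps with per-unit amplitudes jittered uniformly in
    [0.5, 1.5] * kick_amp, so the volley that ignites activity is not
    artificially synchronous; the probe current drives inhibitory units
    during [probe_on, probe_off).  Per-unit OU current noise has
    stationary standard deviation ``noise_sigma`` (pA).  The membrane is
    clamped during the absolute refractory period but synaptic currents
    keep integrating, so input is delayed rather than lost.  Returns flat
    spike times (ms) and unit indices.
    """
    np.random.seed(seed)
    N = Q.shape[0]
    kick = np.empty(N)
    for i in range(N):
        kick[i] = kick_amp * (0.5 + np.random.random()) if i < n_E else 0.0
    V = np.full(N, EL)
    w = np.zeros(N)
    sE = np.zeros(N)      # excitatory synaptic current, pA
    sI = np.zeros(N)      # inhibitory synaptic current (magnitude), pA
    eta = np.zeros(N)
    ref = np.zeros(N, dtype=np.int64)
    spiked = np.zeros(N, dtype=np.bool_)
    t_sp = np.empty(max_spikes)
    u_sp = np.empty(max_spikes, dtype=np.int64)
    n_sp = 0
    amp = noise_sigma * np.sqrt(2.0 * dt / noise_tau)
    for k in range(n_steps):
        # synaptic-current increments from the previous step's spikes
        for j in range(N):
            if spiked[j]:
                if j < n_E:
                    for i in range(N):
                        sE[i] += Q[i, j] / tau_exc[i]
                else:
                    for i in range(N):
                        sI[i] += -Q[i, j] / tau_inh[i]
        spiked[:] = False
        for i in range(N):
            if noise_sigma > 0.0:
                eta[i] += -eta[i] * dt / noise_tau + amp * np.random.standard_normal()
            I_ext = eta[i]
            if i < n_E and k < kick_steps:
                I_ext += kick[i]
            if i >= n_E and probe_on <= k < probe_off:
                I_ext += probe_amp
            w[i] += -w[i] * dt / tau_w
            I_in = sE[i] - sI[i] + I_ext
            sE[i] *= 1.0 - dt / tau_exc[i]
            sI[i] *= 1.0 - dt / tau_inh[i]
            if ref[i] > 0:
                ref[i] -= 1
                V[i] = V_reset
                continue
            V[i] += dt * (-gL * (V[i] - EL) - w[i] + I_in) / C[i]
            if V[i] >= V_th_arr[i]:
                if n_sp < max_spikes:
                    t_sp[n_sp] = (k + 1) * dt
                    u_sp[n_sp] = i
                    n_sp += 1
                V[i] = V_reset
                w[i] += b
                ref[i] = ref_steps_arr[i]
                spiked[i] = True
    return t_sp[:n_sp].copy(), u_sp[:n_sp].copy()
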