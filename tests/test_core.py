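"""Two-population rate model: transfer, noise, simulation, fixed points."""

import numpy as np
import pytest

from isnplast.core import (
    LOW_NOISE,
    NO_NOISE,
    NetworkParams,
    NoiseParams,
    StimulusProtocol,
    WeightSet,
    is_paradoxical,
    ou_step,
    paradoxical_probe,
    simulate_trial,
    steady_state,
    stable_nontrivial_fixed_point,
    transfer,
    trial_mean_rates,
)

from conftest import active_branch_solve


@pytest.mark.parametrize("x, gain, theta, expected", [
    (30.0, 4.0, 25.0, 20.0),
    (25.0, 4.0, 25.0, 0.0),     # boundary belongs to the linear branch
    (10.0, 1.0, 4.8, 5.2),
    (-100.0, 1.0, 4.8, 0.0),
])
def test_transfer_threshold_linear(x, gain, theta, expected):
    assert transfer(x, gain, theta) == pytest.approx(expected)


def test_transfer_rejects_nonpositive_gain():
    with pytest.raises(ValueError):
        transfer(1.0, 0.0, 0.0)


class TestOUProcess:
    def test_deterministic_relaxation_to_mean(self):
        noise = NoiseParams(mu=0.0, inv_tau=1.0, sigma=0.0)
        x = 10.0
        for _ in range(10000):
            x = ou_step(x, noise, 0.1, 0.0)
        assert abs(x) < 1e-8

    def test_stationary_moments_match_discretization(self):
        # Euler-Maruyama stationary variance: sigma^2 dt / (1 - (1 - k dt)^2)
        noise = NoiseParams(mu=0.0, inv_tau=1.0, sigma=10.0)
        dt = 0.1
        rng = np.random.default_rng(7)
        n = 200_000
        x = 0.0
        samples = np.empty(n)
        for i in range(n):
            x = ou_step(x, noise, dt, rng.standard_normal())
            samples[i] = x
        burn = samples[5000:]
        var_expect = noise.sigma**2 * dt / (1 - (1 - noise.inv_tau * dt) ** 2)
        assert abs(burn.mean()) < 0.5
        assert burn.var() == pytest.approx(var_expect, rel=0.05)


class TestSimulateTrial:
    def test_quiescent_network_stays_silent(self, params):
        w = WeightSet(0, 0, 0, 0)
        tr = simulate_trial(params, w, stimulus=None, noise=NO_NOISE, duration=100.0)
        assert np.all(tr.E == 0.0) and np.all(tr.I == 0.0)

    def test_kick_engages_self_sustained_fixed_point(self, params, isn_weights):
        tr = simulate_trial(params, isn_weights, noise=NO_NOISE, seed=0)
        expected = active_branch_solve(params, isn_weights)
        assert tr.E[-1] == pytest.approx(expected[0], abs=1e-6)
        assert tr.I[-1] == pytest.approx(expected[1], abs=1e-6)

    def test_weak_weights_decay_after_pulse(self, params, weak_weights):
        tr = simulate_trial(params, weak_weights, noise=NO_NOISE)
        assert tr.E[-1] == pytest.approx(0.0, abs=1e-6)
        assert tr.I[-1] == pytest.approx(0.0, abs=1e-6)

    def test_rates_never_negative(self, params, isn_weights):
        tr = simulate_trial(params, isn_weights, noise=LOW_NOISE, seed=3)
        assert np.all(tr.E >= 0) and np.all(tr.I >= 0)

    def test_seeded_determinism_bit_identical(self, params, isn_weights):
        a = simulate_trial(params, isn_weights, noise=LOW_NOISE, seed=11)
        b = simulate_trial(params, isn_weights, noise=LOW_NOISE, seed=11)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.I, b.I)

    def test_runaway_guard_flags_unstable_regime(self, params):
        # strong recurrent excitation, no inhibition: unbounded growth
        w = WeightSet(20.0, 0.0, 0.0, 0.0)
        tr = simulate_trial(params, w, noise=NO_NOISE)
        assert tr.runaway
        assert tr.n_valid < len(tr.t)

    def test_euler_step_converges_with_dt(self, params, isn_weights):
        coarse = simulate_trial(params, isn_weights, noise=NO_NOISE, dt=0.1)
        fine = simulate_trial(params, isn_weights, noise=NO_NOISE, dt=0.01)
        mc = trial_mean_rates(coarse)
        mf = trial_mean_rates(fine, 500.0, 1000.0)
        assert mc[0] == pytest.approx(mf[0], rel=1e-4)
        assert mc[1] == pytest.approx(mf[1], rel=1e-4)


class TestSteadyState:
    def test_isn_weights_have_stable_active_and_trivial_points(self, params, isn_weights):
        fps = {f.branch: f for f in steady_state(params, isn_weights) if not f.degenerate}
        assert fps["EI_active"].E == pytest.approx(5.0)
        assert fps["EI_active"].I == pytest.approx(10.0)
        assert fps["EI_active"].neural_stable
        assert fps["quiescent"].E == 0.0 and fps["quiescent"].neural_stable

    def test_balanced_weights_fixed_point_near_setpoints(self, params, balanced_weights):
        fp = stable_nontrivial_fixed_point(params, balanced_weights)
        assert fp.E == pytest.approx(5.0, rel=0.02)
        assert fp.I == pytest.approx(14.0, rel=0.02)

    def test_zero_weights_single_quiescent_point(self, params):
        fps = [f for f in steady_state(params, WeightSet(0, 0, 0, 0)) if not f.degenerate]
        assert len(fps) == 1
        assert fps[0].E == 0.0 and fps[0].I == 0.0

    def test_stable_point_is_invariant_under_simulation(self, params, isn_weights):
        fp = stable_nontrivial_fixed_point(params, isn_weights)
        tr = simulate_trial(params, isn_weights, stimulus=None, noise=NO_NOISE,
                            duration=200.0, initial_rates=(fp.E, fp.I))
        assert np.all(np.abs(tr.E - fp.E) < 1e-6)
        assert np.all(np.abs(tr.I - fp.I) < 1e-6)

    def test_nearby_initial_conditions_converge_to_stable_point(self, params, isn_weights):
        fp = stable_nontrivial_fixed_point(params, isn_weights)
        tr = simulate_trial(params, isn_weights, stimulus=None, noise=NO_NOISE,
                            duration=500.0, initial_rates=(fp.E * 1.2, fp.I * 0.8))
        assert tr.E[-1] == pytest.approx(fp.E, abs=1e-6)
        assert tr.I[-1] == pytest.approx(fp.I, abs=1e-6)


class TestParadoxicalEffect:
    def test_probe_lowers_inhibitory_rate_in_isn(self, params, isn_weights):
        before, after, delta = paradoxical_probe(params, isn_weights, 7.0)
        oracle = active_branch_solve(params, isn_weights, ext_I=7.0)
        assert before == pytest.approx(10.0)
        assert after == pytest.approx(oracle[1])
        assert after == pytest.approx(4.6154, abs=1e-3)
        assert delta < 0

    def test_increasing_excitation_onto_I_lowers_its_rate(self, params):
        # raising W_IE from 10 to 12 mimics homeostatic strengthening onto I
        w = WeightSet(5.0, 1.52, 12.0, 2.25)
        fp = stable_nontrivial_fixed_point(params, w)
        assert fp.I == pytest.approx(5.1456, abs=1e-3)
        assert fp.I < 10.0

    def test_decoupled_network_is_not_paradoxical(self, params):
        w = WeightSet(0.0, 0.0, 10.0, 1.0)
        # give I tonic drive so a nontrivial point exists, then probe
        before = active_branch_solve(params, w, ext_I=30.0)[1]
        after = active_branch_solve(params, w, ext_I=37.0)[1]
        assert after > before

    def test_probe_undefined_without_nontrivial_fixed_point(self, params):
        # subcritical excitation, no drive: only the quiescent point exists
        with pytest.raises(ValueError):
            paradoxical_probe(params, WeightSet(0.5, 3.0, 1.0, 2.0), 7.0)

    @pytest.mark.parametrize("wee, expected", [
        (5.0, True), (0.5, False), (1.0, False),
    ])
    def test_paradoxical_condition(self, params, wee, expected):
        w = WeightSet(wee, 1.0, 1.0, 1.0)
        assert is_paradoxical(w, params) is expected

    def test_probe_sign_matches_condition_sign(self, params, isn_weights):
        # small probe: sign(delta_I) = -sign(W_EE g_E - 1) on the active branch
        _, _, delta = paradoxical_probe(params, isn_weights, 0.5)
        assert np.sign(delta) == -np.sign(isn_weights.W_EE * params.g_E - 1)


class TestTrialMeans:
    def test_constant_trace_mean(self, params, isn_weights):
        tr = simulate_trial(params, isn_weights, noise=NO_NOISE)
        mE, mI = trial_mean_rates(tr, 500.0, 1000.0)
        fp = stable_nontrivial_fixed_point(params, isn_weights)
        assert mE == pytest.approx(fp.E, abs=1e-4)
        assert mI == pytest.approx(fp.I, abs=1e-4)

    def test_quiescent_trace_mean_zero(self, params):
        tr = simulate_trial(params, WeightSet(0, 0, 0, 0), noise=NO_NOISE)
        mE, mI = trial_mean_rates(tr)
        assert mE == pytest.approx(0.0, abs=1e-12)
        assert mI == pytest.approx(0.0, abs=1e-12)

    def test_runaway_trace_uses_pre_divergence_segment(self, params):
        tr = simulate_trial(params, WeightSet(20.0, 0, 0, 0), noise=NO_NOISE)
        mE, mI = trial_mean_rates(tr)
        assert np.isfinite(mE) and np.isfinite(mI)

    def test_invalid_window_rejected(self, params, isn_weights):
        tr = simulate_trial(params, isn_weights, noise=NO_NOISE, duration=300.0)
        with pytest.raises(ValueError):
            trial_mean_rates(tr, 200.0, 100.0)
        with pytest.raises(ValueError):
            trial_mean_rates(tr, 200.0, 400.0)


def test_stimulus_validation():
    with pytest.raises(ValueError):
        StimulusProtocol(duration=-1.0)
    with pytest.raises(ValueError):
        StimulusProtocol(target="X")


def test_weightset_rejects_negative():
    with pytest.raises(ValueError):
        WeightSet(-0.1, 1, 1, 1)
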