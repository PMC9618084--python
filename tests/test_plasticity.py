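"""Plasticity rule families, the generic rule constructor, training loops."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isnplast.core import NO_NOISE, WeightSet
from isnplast.plasticity import (
    CROSS_SPEC,
    ClassSpec,
    LearningRates,
    RuleSpec,
    STANDARD_SPEC,
    SetPoints,
    TWO_TERM_SPEC,
    WeightDelta,
    apply_delta,
    cross_rule,
    delta_cross,
    delta_standard,
    delta_two_term,
    loss,
    make_rule,
    standard_rule,
    train_online,
    train_trials,
    two_term_rule,
)

SP = SetPoints(5.0, 14.0)


class TestRuleAlgebra:
    @pytest.mark.parametrize("fn", [delta_standard, delta_cross, delta_two_term])
    def test_zero_delta_exactly_at_setpoints(self, fn):
        d = fn(SP.E_set, SP.I_set, SP, LearningRates.uniform(1e-3))
        assert np.all(d.as_array() == 0.0)

    def test_standard_substitution(self):
        d = delta_standard(5.0, 10.0, SP, LearningRates.uniform(1e-4))
        assert d.as_array() == pytest.approx([0.0, 0.0, 4e-4, -4e-4])
        d = delta_standard(0.0, 0.0, SP, LearningRates.uniform(1e-4))
        assert d.as_array() == pytest.approx([5e-4, -5e-4, 1.4e-3, -1.4e-3])

    def test_cross_substitution(self):
        d = delta_cross(5.0, 10.0, SP, LearningRates.uniform(5e-4))
        assert d.as_array() == pytest.approx([2e-3, -2e-3, 0.0, 0.0])

    def test_cross_low_inhibition_strengthens_excitatory_weights(self):
        # I below setpoint: the E weights strengthen to pull I up via the loop
        d = delta_cross(5.0, 8.0, SP, LearningRates.uniform(1e-4))
        assert d.dW_EE > 0 and d.dW_EI < 0

    def test_two_term_substitution(self):
        d = delta_two_term(4.0, 10.0, SP, LearningRates.uniform(1e-5))
        assert d.as_array() == pytest.approx([5e-5, -5e-5, 3e-5, -3e-5])

    @given(E=st.floats(0, 50), I=st.floats(0, 50))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_two_term_degenerates_to_single_families(self, E, I):
        r = LearningRates.uniform(1e-4)
        zero = LearningRates.uniform(0.0)
        only_h = delta_two_term(E, I, SP, r, cross_rates=zero)
        only_c = delta_two_term(E, I, SP, zero, cross_rates=r)
        assert only_h.as_array() == pytest.approx(
            delta_standard(E, I, SP, r).as_array())
        assert only_c.as_array() == pytest.approx(
            delta_cross(E, I, SP, r).as_array())

    def test_loss_values_and_symmetry(self):
        assert loss(SP.E_set, SP.I_set, SP) == 0.0
        assert loss(5.0, 10.0, SP) == pytest.approx(8.0)
        assert loss(SP.E_set + 2, SP.I_set, SP) == loss(SP.E_set - 2, SP.I_set, SP)


class TestMakeRule:
    @pytest.mark.parametrize("spec, fn", [
        (STANDARD_SPEC, delta_standard),
        (CROSS_SPEC, delta_cross),
        (TWO_TERM_SPEC, delta_two_term),
    ])
    def test_canonical_specs_reproduce_published_families(self, spec, fn):
        rule = make_rule(spec)
        rng = np.random.default_rng(0)
        r = LearningRates(*rng.uniform(1e-5, 1e-3, 4))
        w = WeightSet(*rng.uniform(0.5, 5, 4))
        for _ in range(10):
            E, I = rng.uniform(0, 30, 2)
            assert rule(E, I, w, SP, r).as_array() == pytest.approx(
                fn(E, I, SP, r).as_array())

    def test_scaling_variant_cannot_revive_zero_weight(self):
        spec = RuleSpec(EE=ClassSpec(own_sign=+1, scaling=True),
                        EI=ClassSpec(own_sign=-1), IE=ClassSpec(own_sign=+1),
                        II=ClassSpec(own_sign=-1), name="scaling")
        rule = make_rule(spec)
        d = rule(0.0, 0.0, WeightSet(0.0, 1, 1, 1), SP, LearningRates.uniform(1e-3))
        assert d.dW_EE == 0.0

    def test_anti_homeostatic_sign_pattern(self):
        # dW_IE proportional to -(I_set - I_avg): I below setpoint weakens W_IE
        spec = RuleSpec(EE=ClassSpec(own_sign=+1), EI=ClassSpec(own_sign=-1),
                        IE=ClassSpec(own_sign=-1), II=ClassSpec(own_sign=+1),
                        name="anti_I")
        d = make_rule(spec)(5.0, 8.0, WeightSet(1, 1, 1, 1), SP,
                            LearningRates.uniform(1e-4))
        assert d.dW_IE < 0

    def test_malformed_spec_rejected(self):
        with pytest.raises(TypeError):
            make_rule("standard")
        with pytest.raises(ValueError):
            ClassSpec(own_sign=2)


class TestApplyDelta:
    def test_elementwise_addition(self):
        w = apply_delta(WeightSet(1, 1, 1, 1), WeightDelta(0.5, 0.5, 0.5, 0.5))
        assert w.as_array() == pytest.approx([1.5, 1.5, 1.5, 1.5])

    def test_clipping_at_lower_bound(self):
        w = apply_delta(WeightSet(0.1, 1, 1, 1), WeightDelta(-0.5, 0, 0, 0))
        assert w.W_EE == 0.0

    def test_zero_delta_identity(self):
        w0 = WeightSet(1, 2, 3, 4)
        assert apply_delta(w0, WeightDelta(0, 0, 0, 0)).as_array() == pytest.approx(
            w0.as_array())

    def test_nonfinite_delta_rejected(self):
        with pytest.raises(ValueError):
            apply_delta(WeightSet(1, 1, 1, 1), WeightDelta(np.nan, 0, 0, 0))


class TestTrainTrials:
    def test_zero_learning_rates_keep_weights_constant(self, weak_weights):
        h = train_trials(weak_weights, cross_rule, 5, SP,
                         LearningRates.uniform(0.0), seed=0)
        assert np.all(h.weights == weak_weights.as_array())

    def test_deterministic_given_seed(self, weak_weights):
        kw = dict(n_trials=20, setpoints=SP, rates=LearningRates.uniform(5e-4), seed=9)
        a = train_trials(weak_weights, cross_rule, **kw)
        b = train_trials(weak_weights, cross_rule, **kw)
        assert np.array_equal(a.E_avg, b.E_avg)
        assert np.array_equal(a.weights, b.weights)

    def test_weights_stay_nonnegative_throughout(self, weak_weights):
        h = train_trials(weak_weights, standard_rule, 300, SP,
                         LearningRates.uniform(1e-3), seed=1)
        assert np.all(h.weights >= 0)

    def test_cross_rule_converges_noiselessly(self, weak_weights):
        h = train_trials(weak_weights, cross_rule, 3000, SP,
                         LearningRates.uniform(5e-4), noise=NO_NOISE, seed=0)
        assert h.E_avg[-1] == pytest.approx(SP.E_set, rel=0.05)
        assert h.I_avg[-1] == pytest.approx(SP.I_set, rel=0.05)

    def test_quiescent_trials_still_drive_weight_growth(self, weak_weights):
        # trial 1 is silent after the pulse, yet the errors grow W_EE
        h = train_trials(weak_weights, cross_rule, 10, SP,
                         LearningRates.uniform(5e-4), noise=NO_NOISE, seed=0)
        assert h.E_avg[0] == pytest.approx(0.0, abs=0.1)
        assert h.weights[-1, 0] > h.weights[0, 0]


class TestTrainOnline:
    def test_zero_rates_is_pure_simulation(self, isn_weights):
        h = train_online(isn_weights, cross_rule, 2000.0, SP,
                         LearningRates.uniform(0.0), noise=NO_NOISE, seed=0)
        assert np.all(h.weights == isn_weights.as_array())

    def test_online_matches_trial_based_for_small_rates(self, weak_weights):
        sp = SP
        rates = LearningRates.uniform(5e-4)
        ht = train_trials(weak_weights, cross_rule, 1200, sp, rates,
                          noise=NO_NOISE, seed=0)
        ho = train_online(weak_weights, cross_rule, 1200 * 1000.0, sp, rates,
                          noise=NO_NOISE, seed=0)
        # same attractor plane, comparable endpoint rates
        assert ho.E_avg[-1] == pytest.approx(ht.E_avg[-1], rel=0.15)
        assert ho.I_avg[-1] == pytest.approx(ht.I_avg[-1], rel=0.15)
        assert np.all(np.abs(ho.final_weights.as_array()
                             - ht.final_weights.as_array()) < 1.0)


class TestConvergenceProperties:
    def test_cross_rule_convergence_basin(self):
        """At least 95% of seeded random initializations reach mean rates
        within 10% of the setpoints under cross-homeostatic training."""
        from isnplast.experiments import batch_initializer
        n = 20
        ok = 0
        for i, w0 in enumerate(batch_initializer(n, "around_attractor", seed=5)):
            h = train_trials(w0, cross_rule, 3000, SP,
                             LearningRates.uniform(5e-4), seed=100 + i)
            eE = abs(h.E_avg[-30:].mean() / SP.E_set - 1)
            eI = abs(h.I_avg[-30:].mean() / SP.I_set - 1)
            ok += (eE < 0.1 and eI < 0.1)
        assert ok >= 0.95 * n

    def test_two_term_trajectory_descends_quadratic_loss(self, weak_weights):
        """Along a converging two-term run the setpoint loss evaluated on
        trial means trends downward after the ignition transient (trend,
        not per-step monotonicity — trials are stochastic)."""
        h = train_trials(weak_weights, two_term_rule, 3000, SP,
                         LearningRates.uniform(2.5e-4), seed=7)
        L = np.array([loss(E, I, SP) for E, I in zip(h.E_avg, h.I_avg)])
        thirds = [L[300:1200].mean(), L[1200:2100].mean(), L[2100:].mean()]
        assert thirds[0] > thirds[1] > thirds[2]
        assert thirds[2] < 0.05 * thirds[0]
        assert h.E_avg[-30:].mean() == pytest.approx(SP.E_set, rel=0.05)
        assert h.I_avg[-30:].mean() == pytest.approx(SP.I_set, rel=0.05)


class TestLineAttractor:
    def test_final_weights_fall_on_balance_lines(self, weak_weights):
        """Converged runs satisfy the steady-state constraints; the fitted
        W_EI-vs-W_EE slope across seeds equals E_set / I_set within 5%."""
        from isnplast.stability import constrained_weights
        finals = []
        for seed in range(6):
            w0 = WeightSet(*(weak_weights.as_array()
                             * (1 + 0.3 * np.random.default_rng(seed).uniform(-1, 1, 4))))
            h = train_trials(w0, cross_rule, 5000, SP,
                             LearningRates.uniform(5e-4), seed=seed)
            if h.converged(SP, rel_tol=0.05):
                finals.append(h.final_weights.as_array())
        assert len(finals) >= 4
        finals = np.asarray(finals)
        for wee, wei, wie, wii in finals:
            cei, cii = constrained_weights(wee, wie, SP)
            assert wei == pytest.approx(cei, rel=0.1, abs=0.05)
            assert wii == pytest.approx(cii, rel=0.1, abs=0.08)
        slope = np.polyfit(finals[:, 0], finals[:, 1], 1)[0]
        assert slope == pytest.approx(SP.E_set / SP.I_set, rel=0.05)
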