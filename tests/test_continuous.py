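"""Continuous engine: membership function, ODE integration, steady states.

The integration cross-check uses an independent fixed-step RK4 oracle built
directly on the public fuzzy evaluation and the logistic drive, bypassing
the compiled right-hand side.
"""

import math
import random

import numpy as np
import pytest

from fuzzycell.continuous import (
    ConvergenceError,
    MembershipParams,
    find_steady_state,
    membership,
    rhs,
    simulate,
)
from fuzzycell.rules import Node, NetworkModel, eval_fuzzy, parse_rules
from fuzzycell.assets import NAIVE_INITIAL


# ---------------------------------------------------------------------------
# Independent RK4 oracle
# ---------------------------------------------------------------------------


def rk4_reference(model, inputs, initial, horizon, dt=0.01):
    """Fixed-step RK4 on dq = mu(w(q)) - d q, straight from eval_fuzzy."""
    free = model.free_names
    decay = {n: model.nodes[n].decay for n in free}

    def deriv(levels):
        clamped = {k: min(1.0, max(0.0, v)) for k, v in levels.items()}
        clamped.update(inputs)
        out = {}
        for n in free:
            rule = model.nodes[n].rule
            w = 0.0 if rule is None else eval_fuzzy(rule, clamped)
            mu = 1.0 / (1.0 + math.exp(-model.beta * (w - model.w_thr)))
            out[n] = mu - decay[n] * levels[n]
        return out

    t, q = 0.0, dict(initial)
    path = [(t, dict(q))]
    while t < horizon - 1e-12:
        k1 = deriv(q)
        k2 = deriv({n: q[n] + 0.5 * dt * k1[n] for n in free})
        k3 = deriv({n: q[n] + 0.5 * dt * k2[n] for n in free})
        k4 = deriv({n: q[n] + dt * k3[n] for n in free})
        q = {n: q[n] + dt / 6.0 * (k1[n] + 2 * k2[n] + 2 * k3[n] + k4[n]) for n in free}
        t += dt
        path.append((t, dict(q)))
    return path


# ---------------------------------------------------------------------------
# Membership function
# ---------------------------------------------------------------------------


class TestMembership:
    @pytest.mark.parametrize("beta", [1.0, 5.0, 50.0])
    def test_half_at_threshold(self, beta):
        assert membership(0.5, beta=beta, w_thr=0.5) == pytest.approx(0.5)

    def test_hand_value(self):
        # w=1, w_thr=0.5, beta=5 -> 1/(1+e^-2.5)
        assert membership(1.0, beta=5.0, w_thr=0.5) == pytest.approx(
            1.0 / (1.0 + math.exp(-2.5)), abs=1e-12
        )
        assert membership(1.0, beta=5.0, w_thr=0.5) == pytest.approx(0.9241, abs=5e-5)

    def test_sigmoid_symmetry(self):
        rng = random.Random(5)
        for _ in range(50):
            w = rng.uniform(-1, 2)
            assert membership(w, beta=7.0) + membership(1.0 - w, beta=7.0) == pytest.approx(1.0)

    def test_strictly_increasing_and_bounded(self):
        ws = np.linspace(-2, 3, 101)
        mu = membership(ws, beta=5.0)
        assert np.all(np.diff(mu) > 0)
        assert np.all((mu > 0) & (mu < 1))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            MembershipParams(beta=0.0)
        with pytest.raises(ValueError):
            MembershipParams(w_thr=0.0)


# ---------------------------------------------------------------------------
# Right-hand side semantics
# ---------------------------------------------------------------------------


def _isolated(decay=1.0, beta=5.0):
    """One node driven by a clamped input (w equals the input level)."""
    model = parse_rules("input U\nX = U\n", beta=beta)
    model.set_decay("X", decay)
    return model


class TestRhs:
    def test_no_rule_decays_exponentially_in_large_beta_limit(self):
        model = NetworkModel({"X": Node("X", None, initial=1.0)}, beta=50.0)
        traj = simulate(model, {}, horizon=5.0, n_points=200)
        expected = np.exp(-traj.times)
        assert np.allclose(traj["X"], expected, atol=1e-4)

    def test_constant_drive_settles_at_mu_over_d(self):
        for d in (1.0, 2.0):
            model = _isolated(decay=d)
            ss = find_steady_state(model, {"U": 1.0})
            assert ss.levels["X"] == pytest.approx(
                membership(1.0, beta=5.0) / d, abs=1e-8
            )
            assert ss.residual <= 1e-6

    def test_doubling_decay_halves_steady_level(self):
        lv1 = find_steady_state(_isolated(1.0), {"U": 1.0}).levels["X"]
        lv2 = find_steady_state(_isolated(2.0), {"U": 1.0}).levels["X"]
        assert lv1 / lv2 == pytest.approx(2.0, rel=1e-8)

    def test_reference_rhs_map(self, metabolism):
        state = {n: 0.0 for n in metabolism.free_names}
        dq = rhs(metabolism, state, inputs={"AKT": 1.0})
        # every node below its drive floor rises, none is missing
        assert set(dq) == set(metabolism.free_names)
        assert all(v > 0 for v in dq.values())

    def test_negative_levels_rejected(self, metabolism):
        state = {n: -0.1 for n in metabolism.free_names}
        with pytest.raises(ValueError):
            rhs(metabolism, state)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------


class TestSimulate:
    def test_agrees_with_rk4_oracle(self, metabolism):
        initial = {n: 0.0 for n in metabolism.free_names}
        initial.update(NAIVE_INITIAL)
        inputs = {n: 0.0 for n in metabolism.input_names}
        traj = simulate(metabolism, inputs, initial=initial, horizon=10.0,
                        n_points=101)
        ref = rk4_reference(metabolism, inputs, initial, horizon=10.0, dt=0.01)
        ref_t = np.array([t for t, _ in ref])
        for name in metabolism.free_names:
            ref_x = np.array([q[name] for _, q in ref])
            interp = np.interp(traj.times, ref_t, ref_x)
            assert np.abs(traj[name] - interp).max() < 1e-4

    def test_decay_toward_floor_with_zero_inputs(self, metabolism):
        initial = {n: 1.0 for n in metabolism.free_names}
        traj = simulate(metabolism, {}, initial=initial, horizon=30.0)
        floor = float(membership(0.0, beta=metabolism.beta))
        tail = traj.times >= 24.0
        for name in metabolism.free_names:
            # settles near the beta-dependent floor, monotone in the tail
            assert floor / 2 < traj.final(name) < 0.15
            assert np.all(np.diff(traj[name][tail]) <= 1e-6)

    def test_box_invariance_for_unit_decay(self, metabolism):
        rng = random.Random(19)
        initial = {n: rng.random() for n in metabolism.free_names}
        inputs = {n: rng.random() for n in metabolism.input_names}
        traj = simulate(metabolism, inputs, initial=initial, horizon=40.0)
        levels = traj.levels[metabolism.free_names].to_numpy()
        assert levels.min() >= -1e-9
        assert levels.max() <= 1.0 + 1e-6

    def test_levels_bounded_by_inverse_decay(self):
        model = _isolated(decay=0.5, beta=50.0)
        traj = simulate(model, {"U": 1.0}, horizon=30.0)
        assert traj.peak("X") <= 1.0 / 0.5 + 1e-6
        assert traj.final("X") == pytest.approx(2.0 * float(membership(1.0, beta=50.0)), abs=1e-4)

    def test_bitwise_deterministic(self, tcd4):
        a = simulate(tcd4, {}, horizon=10.0, n_points=50)
        b = simulate(tcd4, {}, horizon=10.0, n_points=50)
        assert np.array_equal(a.levels.to_numpy(), b.levels.to_numpy())

    def test_invalid_horizon(self, metabolism):
        with pytest.raises(ValueError):
            simulate(metabolism, {}, horizon=0.0)

    def test_unknown_input_rejected(self, metabolism):
        with pytest.raises(Exception, match="unknown input"):
            simulate(metabolism, {"NOPE": 1.0}, horizon=1.0)


# ---------------------------------------------------------------------------
# Steady states
# ---------------------------------------------------------------------------


class TestSteadyState:
    def test_metabolism_floor_state(self, metabolism):
        ss = find_steady_state(metabolism, {n: 0.0 for n in metabolism.input_names})
        assert ss.residual <= 1e-6
        assert all(v < 0.15 for v in ss.levels.values())

    def test_oscillatory_regime_reported_distinctly(self):
        # three-node repressilator ring: no stable steady state at high gain
        model = parse_rules("A = not C\nB = not A\nC = not B\n", beta=50.0)
        for n in "ABC":
            model.set_initial(n, {"A": 0.9, "B": 0.1, "C": 0.5}[n])
        with pytest.raises(ConvergenceError):
            find_steady_state(model, {})

    def test_callable_inputs_rejected(self, metabolism):
        with pytest.raises(ValueError):
            find_steady_state(metabolism, {"AKT": lambda t: 1.0})
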